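"""Per-gene age assignment and taxonomic representativeness.

The trace-back logic: a gene's age is the oldest (deepest) lineage level
with at least one homolog — but that single deepest hit is only trusted
in proportion to how well the intermediate levels reconfirm it.  The
representativeness score

    L = 100 * RP / (AP - 1)

counts the intermediate levels {2..AP} that carry at least one hit (RP)
against all levels separating the deepest hit from the focal species
(AP - 1; the species level is excluded because the query gene itself
evidences it).  L runs from 100 (every intermediate level represented)
down to 100/(AP-1) (only the deepest level represented).  Genes below a
flag threshold (default 30%) are flagged as putative horizontal
transfer, contamination or false-positive matches and excluded from
family dating, but stay in the output so users can re-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .hits_io import HitRecord
from .taxonomy import Lineage, TaxonomyDB, divergence_level

__all__ = [
    "AgeConfig",
    "GeneAge",
    "levels_present",
    "assign_age",
    "representativeness",
    "flag_gene",
    "best_distant_hit",
    "infer_gene_ages",
    "write_gene_ages_tsv",
]

STATUS_ASSIGNED = "assigned"
STATUS_FLAGGED = "flagged"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class AgeConfig:
    """Thresholds for age assignment.

    flag_threshold: percent of representativeness below which a gene is
    flagged (strict ``<``); default 30.
    """

    flag_threshold: float = 30.0

    def __post_init__(self):
        if not 0.0 < self.flag_threshold <= 100.0:
            raise ValueError("flag_threshold must be in (0, 100]")


@dataclass(frozen=True)
class GeneAge:
    """Age assignment of one gene in collapsed-lineage coordinates."""

    gene: str
    k: int | None  # oldest divergence level (AP); None for absent genes
    levels: frozenset[int]  # all divergence levels with >= 1 hit
    rp: int | None  # represented intermediate levels in {2..k}
    score: float | None  # L, in (0, 100]
    status: str  # assigned | flagged | absent
    best_hit: HitRecord | None = None
    n_unmappable: int = 0


def levels_present(
    gene_hits: Iterable[HitRecord], lineage: Lineage, db: TaxonomyDB
) -> tuple[set[int], int]:
    """Divergence levels covered by a gene's hits.

    Subjects not contained under the lineage root are skipped; their
    count is returned alongside so callers can log them.
    """
    levels: set[int] = set()
    unmappable = 0
    for hit in gene_hits:
        j = divergence_level(lineage, db, hit.taxid)
        if j is None:
            unmappable += 1
        else:
            levels.add(j)
    return levels, unmappable


def assign_age(levels: set[int]) -> int:
    """Age = deepest level with a homolog (the most distant hit)."""
    if not levels:
        raise ValueError("cannot assign an age from an empty level set; gene is absent")
    return max(levels)


def representativeness(levels: set[int], k: int) -> tuple[int, float]:
    """(RP, L) for a gene of age ``k``.

    RP counts levels in {2..k} with a hit; level k itself necessarily
    counts (it carries the age-defining hit), hence the minimum score
    100/(k-1).  A gene found only in the focal species (k = 1) gets
    L = 100 by convention: the formula is undefined there and
    species-level presence is self-confirming.
    """
    if k == 1:
        return 0, 100.0
    if k != max(levels):
        raise ValueError("k must equal the deepest represented level")
    rp = len([j for j in levels if 2 <= j <= k])
    return rp, 100.0 * rp / (k - 1)


def flag_gene(score: float, config: AgeConfig | None = None) -> str:
    """Status from the representativeness score: flagged iff L < threshold."""
    config = config or AgeConfig()
    return STATUS_FLAGGED if score < config.flag_threshold else STATUS_ASSIGNED


def best_distant_hit(
    gene_hits: Iterable[HitRecord], k: int, lineage: Lineage, db: TaxonomyDB
) -> HitRecord | None:
    """The best hit (by bitscore) among those at the age-defining level k.

    Ties broken by smaller e-value, then lexicographic subject id —
    fully deterministic.
    """
    at_k = [h for h in gene_hits if divergence_level(lineage, db, h.taxid) == k]
    if not at_k:
        return None
    return min(at_k, key=lambda h: (-h.bitscore, h.evalue, h.subject))


def infer_gene_ages(
    all_query_ids: Sequence[str],
    hits: Iterable[HitRecord],
    lineage: Lineage,
    db: TaxonomyDB,
    config: AgeConfig | None = None,
) -> dict[str, GeneAge]:
    """Run the full trace-back for every query gene.

    Genes with no surviving hits get status "absent" (no age, no score).
    The result is keyed by gene id and deterministic for identical
    inputs.
    """
    config = config or AgeConfig()
    by_gene: dict[str, list[HitRecord]] = {g: [] for g in all_query_ids}
    for h in hits:
        # hits for genes outside the declared proteome are ignored
        if h.query in by_gene:
            by_gene[h.query].append(h)

    ages: dict[str, GeneAge] = {}
    for gene in sorted(by_gene):
        gene_hits = by_gene[gene]
        levels, unmappable = levels_present(gene_hits, lineage, db)
        if not levels:
            ages[gene] = GeneAge(
                gene, None, frozenset(), None, None, STATUS_ABSENT, None, unmappable
            )
            continue
        k = assign_age(levels)
        rp, score = representativeness(levels, k)
        status = flag_gene(score, config)
        best = best_distant_hit(gene_hits, k, lineage, db)
        ages[gene] = GeneAge(gene, k, frozenset(levels), rp, score, status, best, unmappable)
    return ages


def write_gene_ages_tsv(path: str | Path, ages: Mapping[str, GeneAge], lineage: Lineage) -> None:
    cols = [
        "gene", "k", "level_name", "rank", "RP", "L", "status",
        "best_hit_subject", "best_hit_bitscore", "best_hit_taxid", "evidence_source",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for gene in sorted(ages):
            a = ages[gene]
            if a.k is None:
                fh.write(f"{gene}\t\t\t\t\t\t{a.status}\t\t\t\t\n")
                continue
            lv = lineage.level(a.k)
            b = a.best_hit
            fh.write(
                f"{gene}\t{a.k}\t{lv.name}\t{lv.rank}\t{a.rp}\t{a.score:.4f}\t{a.status}\t"
                f"{b.subject if b else ''}\t{f'{b.bitscore:.1f}' if b else ''}\t"
                f"{b.taxid if b else ''}\t{b.source if b else ''}\n"
            )
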