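"""Homology detection failure (HDF): bitscore decay and founder confidence.

Pairwise-alignment bitscores of true homologs decay approximately
exponentially with evolutionary distance.  A gene that "appears" at
level k may therefore simply have outrun the aligner beyond k rather
than having been born there.  This module fits, per gene, the decay

    mu(d) = a * exp(-r * d)          sigma(d) = c * mu(d)

to the best bitscore observed in each species of a user-supplied
distance table (d in substitutions/site from a published phylogeny).
For the nearest species diverging deeper than the gene's assigned level
(the outgroup), the probability that the homolog's score falls below
the detectability threshold S_thr,

    p = Phi((S_thr - mu(d*)) / (c * mu(d*))),

is the HDF probability.  p < alpha (default 0.05, strict) means
detection failure alone cannot explain the absence: the age assignment
is a high-confidence founder event.  S_thr defaults to the
Karlin-Altschul transform of the pipeline's own e-value threshold,
S_thr = log2(m*n/E_thr), for query length m and database size n in
residues.

The test is bounded by the distance table's sampling: genes assigned at
or beyond the deepest sampled level have no outgroup and are
"untestable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .age_inference import GeneAge
from .gene_families import GeneFamily
from .hits_io import HitRecord
from .taxonomy import Lineage, TaxonomyDB, divergence_level

__all__ = [
    "DecayFit",
    "HDFAssessment",
    "load_distance_table",
    "map_distances_to_levels",
    "collect_decay_points",
    "fit_bitscore_decay",
    "bitscore_threshold",
    "hdf_probability",
    "classify_founder",
    "family_confidence",
    "write_hdf_tsv",
]

FIT_OK = "ok"
FIT_INSUFFICIENT = "insufficient_data"
FIT_DEGENERATE = "degenerate"

VERDICT_HIGH_CONFIDENCE = "high_confidence"
VERDICT_AMBIGUOUS = "hdf_ambiguous"
VERDICT_UNTESTABLE = "untestable"


@dataclass(frozen=True)
class DecayFit:
    """Fitted per-gene bitscore decay parameters."""

    gene: str
    a: float | None  # initial bitscore (bits)
    r: float | None  # decay rate per substitution/site
    c: float | None  # relative noise scale
    n_points: int
    status: str  # ok | insufficient_data | degenerate

    def mu(self, d: float) -> float:
        if self.status != FIT_OK:
            raise ValueError(f"fit for {self.gene} has status {self.status}")
        return self.a * math.exp(-self.r * d)


@dataclass(frozen=True)
class HDFAssessment:
    gene: str
    k: int | None
    outgroup_taxid: int | None
    outgroup_distance: float | None
    mu: float | None
    s_thr: float | None
    p: float | None
    verdict: str


def load_distance_table(path: str | Path) -> dict[int, float]:
    """Two-column TSV (taxid, distance in substitutions/site) -> mapping.

    Lines starting with '#' and a single header line of non-numeric
    fields are skipped.
    """
    out: dict[int, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                taxid, d = int(fields[0]), float(fields[1])
            except (ValueError, IndexError):
                continue  # header or junk line
            if d < 0:
                raise ValueError(f"negative distance for taxid {taxid}: {d}")
            out[taxid] = d
    return out


def map_distances_to_levels(
    distances: Mapping[int, float], lineage: Lineage, db: TaxonomyDB
) -> list[tuple[int, float, int]]:
    """Resolve each distance-table species to its divergence level.

    Returns (taxid, distance, level) sorted by distance then taxid;
    species not contained under the lineage root are dropped.
    """
    out = []
    for taxid in sorted(distances):
        j = divergence_level(lineage, db, taxid)
        if j is not None:
            out.append((taxid, distances[taxid], j))
    return sorted(out, key=lambda t: (t[1], t[0]))


def collect_decay_points(
    gene_hits: Iterable[HitRecord], distances: Mapping[int, float]
) -> tuple[list[tuple[float, float]], list[tuple[int, float]]]:
    """Per distance-table species: (distance, best bitscore) if it has hits.

    Species in the table with no hit to this gene are returned
    separately — they are the candidate species for HDF evaluation.
    """
    best: dict[int, float] = {}
    for h in gene_hits:
        if h.taxid in distances:
            if h.taxid not in best or h.bitscore > best[h.taxid]:
                best[h.taxid] = h.bitscore
    points = sorted((distances[t], s) for t, s in best.items())
    candidates = sorted((t, d) for t, d in distances.items() if t not in best)
    return points, candidates


def fit_bitscore_decay(points: Sequence[tuple[float, float]], gene: str = "") -> DecayFit:
    """Constrained least squares of S_i ~ a*exp(-r*d_i), a > 0, r >= 0.

    Initialization is deterministic: a0 = max observed bitscore, r0 from
    the log-ratio of scores at the distance extremes, clipped to >= 0.
    The relative noise scale c is the RMS of (S_i - mu_i)/mu_i.
    Fewer than 3 points -> insufficient_data; all distances equal ->
    degenerate (r unidentifiable).
    """
    n = len(points)
    if n < 3:
        return DecayFit(gene, None, None, None, n, FIT_INSUFFICIENT)
    d = np.asarray([p[0] for p in points], dtype=float)
    s = np.asarray([p[1] for p in points], dtype=float)
    if np.all(d == d[0]):
        return DecayFit(gene, None, None, None, n, FIT_DEGENERATE)

    i_min, i_max = int(np.argmin(d)), int(np.argmax(d))
    a0 = float(np.max(s))
    with np.errstate(divide="ignore", invalid="ignore"):
        r0 = math.log(max(s[i_min], 1e-9) / max(s[i_max], 1e-9)) / (d[i_max] - d[i_min])
    r0 = max(r0, 0.0)

    def resid(x: np.ndarray) -> np.ndarray:
        return s - x[0] * np.exp(-x[1] * d)

    sol = optimize.least_squares(
        resid, x0=[a0, r0], bounds=([1e-9, 0.0], [np.inf, np.inf]), method="trf"
    )
    a, r = float(sol.x[0]), float(sol.x[1])
    mu = a * np.exp(-r * d)
    c = float(np.sqrt(np.mean(((s - mu) / mu) ** 2)))
    return DecayFit(gene, a, r, c, n, FIT_OK)


def bitscore_threshold(
    query_length: float, database_size: float, e_thr: float, override: float | None = None
) -> float:
    """Detectability threshold in bits from E = m*n*2^(-S).

    S_thr = log2(m*n/E_thr); an explicit ``override`` wins.
    """
    if override is not None:
        return float(override)
    if query_length <= 0 or database_size <= 0 or e_thr <= 0:
        raise ValueError("query_length, database_size and e_thr must all be > 0")
    return math.log2(query_length * database_size / e_thr)


def hdf_probability(fit: DecayFit, d_star: float, s_thr: float) -> float:
    """Probability that the homolog's bitscore at d* falls below S_thr.

    Gaussian model S ~ N(mu(d*), (c*mu(d*))^2).  With c = 0 the model is
    deterministic: p is 1 below the threshold, 0 at or above it.
    """
    if fit.status != FIT_OK:
        raise ValueError(f"cannot compute HDF probability from a {fit.status} fit")
    if d_star < 0:
        raise ValueError("d_star must be >= 0")
    mu = fit.mu(d_star)
    if fit.c == 0:
        return 1.0 if mu < s_thr else 0.0
    return float(stats.norm.cdf((s_thr - mu) / (fit.c * mu)))


def classify_founder(
    gene_age: GeneAge,
    fit: DecayFit,
    level_distances: Sequence[tuple[int, float, int]],
    s_thr: float,
    alpha: float = 0.05,
) -> HDFAssessment:
    """Test whether the gene's assigned age survives the HDF null.

    The outgroup is the distance-table species with minimal distance
    among those whose divergence level exceeds the assigned level k
    (ties by taxid).  No such species (k at or beyond the sampling
    limit) or an unusable fit -> untestable.  Verdict is
    high_confidence iff p < alpha (strict).
    """
    k = gene_age.k
    if k is None or fit.status != FIT_OK:
        return HDFAssessment(gene_age.gene, k, None, None, None, s_thr, None, VERDICT_UNTESTABLE)
    beyond = [(d, t) for (t, d, j) in level_distances if j > k]
    if not beyond:
        return HDFAssessment(gene_age.gene, k, None, None, None, s_thr, None, VERDICT_UNTESTABLE)
    d_star, taxid = min(beyond)
    p = hdf_probability(fit, d_star, s_thr)
    verdict = VERDICT_HIGH_CONFIDENCE if p < alpha else VERDICT_AMBIGUOUS
    return HDFAssessment(gene_age.gene, k, taxid, d_star, fit.mu(d_star), s_thr, p, verdict)


def family_confidence(
    families: Sequence[GeneFamily],
    assessments: Mapping[str, HDFAssessment],
    gene_ages: Mapping[str, GeneAge],
) -> None:
    """Flag high-confidence families in place.

    A family founder event is high confidence iff some member is itself
    a high-confidence assignment AND that member's age equals the family
    founder age (a confident young member cannot vouch for a deeper
    founder).  Families whose members are all untestable keep
    high_confidence = None.
    """
    for fam in families:
        verdicts = [assessments[g].verdict for g in fam.members if g in assessments]
        if not verdicts or all(v == VERDICT_UNTESTABLE for v in verdicts):
            fam.high_confidence = None
            continue
        fam.high_confidence = any(
            g in assessments
            and assessments[g].verdict == VERDICT_HIGH_CONFIDENCE
            and gene_ages[g].k == fam.founder_age
            for g in fam.members
        )


def write_hdf_tsv(path: str | Path, assessments: Mapping[str, HDFAssessment]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tk\toutgroup_taxid\td_star\tmu\ts_thr\tp\tverdict\n")
        for gene in sorted(assessments):
            a = assessments[gene]
            fh.write(
                f"{gene}\t{a.k if a.k else ''}\t{a.outgroup_taxid or ''}\t"
                f"{f'{a.outgroup_distance:.6g}' if a.outgroup_distance is not None else ''}\t"
                f"{f'{a.mu:.4f}' if a.mu is not None else ''}\t"
                f"{f'{a.s_thr:.4f}' if a.s_thr is not None else ''}\t"
                f"{f'{a.p:.6g}' if a.p is not None else ''}\t{a.verdict}\n"
            )
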