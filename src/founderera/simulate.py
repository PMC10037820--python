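"""Synthetic benchmark generator for the founder-event pipeline.

The generator builds a ladder taxonomy around a focal species — a chain
of nested clades (levels 1..N, youngest to oldest) with a ring of
sampled species hanging off every level — and then emits the exact file
dialects the pipeline reads: a taxdump (nodes.dmp/names.dmp), a
protein hit table, an all-vs-all self-hit table, a distance table and a
ground-truth table.

The generative model mirrors the pipeline's assumptions: each gene
family is born at one level; every species inside the birth clade
carries a homolog (unless a per-(gene, ring) loss event applies); the
realized bitscore against a species at distance d is

    S = a * exp(-r * d) * (1 + c * eps),   eps ~ N(0, 1)

and a hit is emitted iff S >= S_thr, with the e-value back-computed via
the Karlin-Altschul identity E = m * n * 2^(-S).  Detection failure
beyond the birth clade therefore arises from decay alone, which is the
signal the HDF stage must separate from true founder events.
Contaminant genes break the nesting deliberately: they hit only the
focal species plus one random distant ring.

Everything is deterministic given the seed; the same config produces
byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["SimConfig", "SimBundle", "GeneTruth", "simulate_dataset", "noiseless_config"]

FOCAL_TAXID = 101
EVALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a moderately noisy, moderately sampled clade:
    7 nested levels, 2 genomes per level ring, 30 families of 1-4 genes,
    initial bitscores around 150 bits, decay rates around 0.8 per
    substitution/site, 5% relative score noise and a 5% per-(gene, ring)
    loss rate.  The detectability threshold is the Karlin-Altschul
    transform of the e-value threshold for a 400-residue query against a
    1e10-residue database (~58.5 bits).
    """

    seed: int = 42
    n_levels: int = 7
    species_per_level: int = 2
    n_families: int = 30
    genes_per_family: tuple[int, int] = (1, 4)
    birth_level_weights: tuple[float, ...] | None = None  # uniform over levels if None
    a_mean_log: float = math.log(150.0)
    a_sd_log: float = 0.3
    r_shape: float = 2.0
    r_scale: float = 0.4
    noise_c: float = 0.05
    level_distances: tuple[float, ...] | None = None  # d_1..d_N; default quadratic ladder
    contamination_fraction: float = 0.0
    contaminant_min_level: int = 5
    gene_loss_prob: float = 0.05
    e_thr: float = 1e-5
    query_length_m: float = 400.0
    database_size_n: float = 1e10
    s_thr: float | None = None  # None -> log2(m*n/e_thr)

    def __post_init__(self):
        if self.n_levels < 3:
            raise ValueError("n_levels must be >= 3")
        if self.species_per_level < 1:
            raise ValueError("species_per_level must be >= 1")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if not 0.0 <= self.gene_loss_prob <= 1.0:
            raise ValueError("gene_loss_prob must be in [0, 1]")
        d = self.distances
        if len(d) != self.n_levels or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("level_distances must be strictly increasing with one entry per level")
        if self.birth_level_weights is not None and len(self.birth_level_weights) != self.n_levels:
            raise ValueError("birth_level_weights needs one weight per level")
        if self.contaminant_min_level > self.n_levels:
            raise ValueError("contaminant_min_level exceeds n_levels")

    @property
    def distances(self) -> tuple[float, ...]:
        if self.level_distances is not None:
            return self.level_distances
        return tuple(0.06 * j + 0.04 * j * j for j in range(self.n_levels))

    @property
    def detect_threshold(self) -> float:
        if self.s_thr is not None:
            return self.s_thr
        return math.log2(self.query_length_m * self.database_size_n / self.e_thr)


def noiseless_config(seed: int = 42, **overrides) -> SimConfig:
    """The exact-recovery regime: no noise, no loss, no contamination,
    slow decay and high initial bitscores, so every homolog inside the
    birth clade is detected and every age is recovered exactly."""
    base = dict(
        seed=seed,
        noise_c=0.0,
        gene_loss_prob=0.0,
        contamination_fraction=0.0,
        a_mean_log=math.log(200.0),
        a_sd_log=0.1,
        r_shape=2.0,
        r_scale=0.03,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass(frozen=True)
class GeneTruth:
    gene: str
    family_id: int
    birth_level: int
    a: float
    r: float
    contaminant: bool


@dataclass
class SimBundle:
    """Paths of one simulated dataset plus in-memory truth."""

    config: SimConfig
    out_dir: Path
    nodes_path: Path
    names_path: Path
    hits_path: Path
    self_hits_path: Path
    distances_path: Path
    truth_path: Path
    genes_path: Path
    focal_taxid: int
    truth: dict[str, GeneTruth]
    ring_taxids: dict[int, list[int]]  # level -> ring species taxids


def _chain_taxid(level: int) -> int:
    return 100 + level


def _ring_taxid(level: int, i: int) -> int:
    return 1000 * level + i


def _evalue(bitscore: float, m: float, n: float) -> float:
    return max(m * n * math.pow(2.0, -bitscore), EVALUE_FLOOR)


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate one dataset bundle under ``out_dir``.

    All files are written in the dialects the pipeline's own readers
    parse (taxdump pipe format, outfmt-6-style TSV, two-column distance
    TSV).  Output is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = config.n_levels
    d = config.distances
    s_thr = config.detect_threshold
    m_res, n_db = config.query_length_m, config.database_size_n

    # ---- taxonomy: chain of nested clades + species rings -------------
    root = _chain_taxid(n)
    nodes: list[tuple[int, int, str, str]] = []  # taxid, parent, rank, name
    for j in range(1, n + 1):
        parent = root if j == n else _chain_taxid(j + 1)
        rank = "species" if j == 1 else ("no rank" if j == n else "clade")
        name = "focal_species" if j == 1 else (f"root" if j == n else f"clade_L{j}")
        nodes.append((_chain_taxid(j), parent, rank, name))
    ring_taxids: dict[int, list[int]] = {}
    for j in range(2, n + 1):
        ring_taxids[j] = []
        for i in range(1, config.species_per_level + 1):
            t = _ring_taxid(j, i)
            ring_taxids[j].append(t)
            nodes.append((t, _chain_taxid(j), "species", f"sp_L{j}_{i}"))

    nodes_path = out / "nodes.dmp"
    names_path = out / "names.dmp"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid, parent, rank, _ in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid, _, _, name in nodes:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")

    # ---- gene families and per-gene parameters ------------------------
    if config.birth_level_weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(config.birth_level_weights, dtype=float)
        weights = weights / weights.sum()

    truth: dict[str, GeneTruth] = {}
    families: list[list[str]] = []
    lo, hi = config.genes_per_family
    for f in range(1, config.n_families + 1):
        size = int(rng.integers(lo, hi + 1))
        birth = int(rng.choice(np.arange(1, n + 1), p=weights))
        members = []
        for g in range(1, size + 1):
            gene = f"fam{f:04d}_g{g}"
            a = float(rng.lognormal(config.a_mean_log, config.a_sd_log))
            r = float(rng.gamma(config.r_shape, config.r_scale))
            contaminant = bool(rng.random() < config.contamination_fraction)
            truth[gene] = GeneTruth(gene, f, birth, a, r, contaminant)
            members.append(gene)
        families.append(members)

    # ---- protein hit table --------------------------------------------
    hits_path = out / "protein_hits.tsv"
    with open(hits_path, "w", encoding="utf-8") as fh:

        def emit(query: str, subject: str, score: float, taxid: int) -> None:
            e = _evalue(score, m_res, n_db)
            fh.write(f"{query}\t{subject}\t{e:.6e}\t{score:.3f}\t{taxid}\n")

        for members in families:
            for gene in members:
                t = truth[gene]
                # self-alignment of the query against its own proteome entry
                eps = float(rng.standard_normal())
                s_self = t.a * (1.0 + config.noise_c * eps)
                if s_self >= s_thr:
                    emit(gene, gene, s_self, FOCAL_TAXID)
                if t.contaminant:
                    # contaminant: near-identical hits in one distant ring only
                    j_star = int(rng.integers(config.contaminant_min_level, n + 1))
                    for taxid in ring_taxids[j_star]:
                        eps = float(rng.standard_normal())
                        s = t.a * (1.0 + config.noise_c * eps)
                        if s >= s_thr:
                            emit(gene, f"{gene}|contam_{taxid}", s, taxid)
                    continue
                for j in range(2, t.birth_level + 1):
                    if rng.random() < config.gene_loss_prob:
                        continue  # the whole ring lost this gene
                    for taxid in ring_taxids[j]:
                        eps = float(rng.standard_normal())
                        s = t.a * math.exp(-t.r * d[j - 1]) * (1.0 + config.noise_c * eps)
                        if s >= s_thr:
                            emit(gene, f"{gene}|hom_{taxid}", s, taxid)

    # ---- all-vs-all self-hit table ------------------------------------
    self_hits_path = out / "self_hits.tsv"
    with open(self_hits_path, "w", encoding="utf-8") as fh:
        for members in families:
            for g1 in members:
                for g2 in members:
                    if g1 == g2:
                        e, s = EVALUE_FLOOR, 2000.0
                    else:
                        # paralog pair: e-value far below any sane threshold
                        expo = float(rng.uniform(30.0, 80.0))
                        e = 10.0 ** (-expo)
                        s = math.log2(m_res * n_db / e)
                    fh.write(f"{g1}\t{g2}\t{e:.6e}\t{s:.3f}\t{FOCAL_TAXID}\n")

    # ---- distance table (focal at 0 plus every ring species) ----------
    distances_path = out / "distances.tsv"
    with open(distances_path, "w", encoding="utf-8") as fh:
        fh.write("taxid\tdistance\n")
        fh.write(f"{FOCAL_TAXID}\t0.0\n")
        for j in range(2, n + 1):
            for taxid in ring_taxids[j]:
                fh.write(f"{taxid}\t{d[j - 1]:.6f}\n")

    # ---- truth + proteome listing -------------------------------------
    truth_path = out / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tfamily_id\tbirth_level\ta\tr\tcontaminant\n")
        for gene in sorted(truth):
            t = truth[gene]
            fh.write(
                f"{gene}\t{t.family_id}\t{t.birth_level}\t{t.a:.6f}\t{t.r:.6f}\t{int(t.contaminant)}\n"
            )
    genes_path = out / "genes.txt"
    with open(genes_path, "w", encoding="utf-8") as fh:
        for gene in sorted(truth):
            fh.write(gene + "\n")

    return SimBundle(
        config=config,
        out_dir=out,
        nodes_path=nodes_path,
        names_path=names_path,
        hits_path=hits_path,
        self_hits_path=self_hits_path,
        distances_path=distances_path,
        truth_path=truth_path,
        genes_path=genes_path,
        focal_taxid=FOCAL_TAXID,
        truth=truth,
        ring_taxids=ring_taxids,
    )
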