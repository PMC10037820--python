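"""Paralog clustering by Markov clustering (MCL) and family dating.

Paralogs descend from a single founder event, so dating them
independently double-counts founders and under-ages the least traceable
family members.  An all-vs-all similarity search of the proteome against
itself yields a weighted graph (weight = -log10 e-value, symmetrized by
the best e-value of the two directions, capped for underflowed
e-values); Markov clustering partitions it into families, and each
family is dated by the oldest reliable (non-flagged) member age.

The MCL implementation is deliberately self-contained and deterministic:
dense numpy matrices, canonical lexicographic vertex order, explicit
tie-breaking when a vertex is attracted to several clusters.  Proteomes
at the scale this pipeline targets produce graphs whose connected
components are small, so clustering runs per component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .age_inference import STATUS_ASSIGNED, GeneAge
from .hits_io import HitRecord
from .taxonomy import Lineage

__all__ = [
    "MCLConfig",
    "GeneFamily",
    "build_similarity_graph",
    "mcl_cluster",
    "family_founder_age",
    "founder_counts",
    "write_families_tsv",
    "write_founder_counts_tsv",
]


@dataclass(frozen=True)
class MCLConfig:
    """Markov clustering parameters (standard defaults).

    inflation: entrywise power; higher values give finer clusters.
    expansion: matrix power per iteration (2 = one squaring).
    pruning_epsilon: entries below this are zeroed between iterations.
    """

    inflation: float = 2.0
    expansion: int = 2
    pruning_epsilon: float = 1e-6
    max_iterations: int = 100
    convergence_tol: float = 1e-8

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.pruning_epsilon < 0:
            raise ValueError("pruning_epsilon must be >= 0")


@dataclass
class GeneFamily:
    family_id: int
    members: frozenset[str]
    founder_age: int | None  # None if every member is flagged/absent
    high_confidence: bool | None = None  # set by the HDF stage


def build_similarity_graph(
    self_hits: Iterable[HitRecord], evalue_cap_exponent: float = 200.0
) -> nx.Graph:
    """Undirected similarity graph from an all-vs-all hit table.

    Edge weight w(u,v) = min(-log10 e, cap) using the best (smallest)
    e-value seen in either direction; e-value 0 maps to the cap.
    Self-pairs contribute the vertex only (self-loops are handled inside
    MCL), so genes whose only hit is themselves appear as isolated
    vertices.
    """
    g = nx.Graph()
    for h in self_hits:
        g.add_node(h.query)
        g.add_node(h.subject)
        if h.query == h.subject:
            continue
        w = evalue_cap_exponent if h.evalue <= 0 else min(-np.log10(h.evalue), evalue_cap_exponent)
        if w <= 0:
            continue
        u, v = h.query, h.subject
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    return g


def _mcl_matrix(A: np.ndarray, config: MCLConfig) -> tuple[np.ndarray, bool]:
    """Iterate expansion/inflation on a column-stochastic matrix to a fixed point."""
    n = A.shape[0]
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(config.max_iterations):
        Mx = M
        for _ in range(config.expansion - 1):
            Mx = Mx @ M
        Mx = np.power(Mx, config.inflation)
        Mx[Mx < config.pruning_epsilon] = 0.0
        colsum = Mx.sum(axis=0, keepdims=True)
        # a column can only lose all mass through pruning; restore self-flow
        dead = np.where(colsum[0] == 0)[0]
        if dead.size:
            Mx[dead, dead] = 1.0
            colsum = Mx.sum(axis=0, keepdims=True)
        Mx = Mx / colsum
        if np.max(np.abs(Mx - M)) < config.convergence_tol:
            M = Mx
            converged = True
            break
        M = Mx
    return M, converged


def _clusters_from_matrix(M: np.ndarray, eps: float) -> list[set[int]]:
    """Read hard clusters off a converged MCL matrix.

    Attractors are vertices with positive self-flow; attractors whose
    rows overlap form one attractor system.  Every vertex joins the
    system receiving most of its flow; ties go to the system containing
    the lexicographically smallest attractor.
    """
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > eps]
    if not attractors:  # non-converged fallback: strongest row per column
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))

    # union attractors that co-occur in any column's support
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # systems form through attractor-to-attractor flow only; a non-attractor
    # vertex attracted to two systems is an overlap, resolved below
    att_set = set(attractors)
    for j in attractors:
        support = [i for i in attractors if M[i, j] > eps]
        for a, b in zip(support, support[1:]):
            union(a, b)

    assignment: dict[int, int] = {}
    for j in range(n):
        flows: dict[int, float] = {}
        for a in attractors:
            if M[a, j] > 0:
                flows[find(a)] = flows.get(find(a), 0.0) + M[a, j]
        if not flows:
            # numeric corner (no attractor support): follow the strongest row
            best_row = int(np.argmax(M[:, j]))
            flows = {find(best_row) if best_row in att_set else -(j + 1): 1.0}
        # deterministic tie-break: largest flow (to numerical tolerance), then
        # the system whose minimal attractor index is smallest (node order is
        # lexicographic, so system keys sort by their smallest attractor)
        top_flow = max(flows.values())
        assignment[j] = min(k for k, v in flows.items() if v >= top_flow - 1e-9)

    clusters: dict[int, set[int]] = {}
    for j, sys_key in assignment.items():
        clusters.setdefault(sys_key, set()).add(j)
    return [clusters[k] for k in sorted(clusters)]


def mcl_cluster(graph: nx.Graph, config: MCLConfig | None = None) -> list[frozenset[str]]:
    """Partition the similarity graph into gene families.

    Every vertex, including isolated ones, lands in exactly one cluster.
    Vertices are processed in lexicographic order and all tie-breaks are
    explicit, so the partition is deterministic.  Clustering runs per
    connected component (MCL flow never crosses components).
    """
    config = config or MCLConfig()
    out: list[frozenset[str]] = []
    warned = False
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out.append(frozenset(nodes))
            continue
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((n, n))
        for u, v, data in graph.subgraph(comp).edges(data=True):
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = data["weight"]
        # self-loops: max incident weight per vertex (uniform damping of flow)
        loops = A.max(axis=0)
        loops[loops <= 0] = 1.0
        A[np.diag_indices(n)] = loops
        M, converged = _mcl_matrix(A, config)
        if not converged and not warned:
            warnings.warn("MCL did not converge within max_iterations; using current clustering")
            warned = True
        for cl in _clusters_from_matrix(M, config.pruning_epsilon):
            out.append(frozenset(nodes[i] for i in cl))
    return sorted(out, key=lambda c: min(c))


def family_founder_age(
    partition: Iterable[frozenset[str]] | Iterable[set[str]],
    gene_ages: Mapping[str, GeneAge],
) -> list[GeneFamily]:
    """Date each family by its oldest reliable member.

    Founder age = max k over members with status "assigned"; flagged
    members never set the founder age (their deep hits are the very
    signal being distrusted).  A family whose members are all flagged
    gets founder_age None.
    """
    families = []
    for fid, members in enumerate(sorted((frozenset(m) for m in partition), key=min), start=1):
        reliable = [
            gene_ages[g].k
            for g in members
            if g in gene_ages and gene_ages[g].status == STATUS_ASSIGNED and gene_ages[g].k
        ]
        families.append(GeneFamily(fid, members, max(reliable) if reliable else None))
    return families


def founder_counts(families: Iterable[GeneFamily], n_levels: int, high_confidence_only: bool = False) -> dict[int, int]:
    """Founder events per lineage level: families whose founder age is that level."""
    counts = {j: 0 for j in range(1, n_levels + 1)}
    for fam in families:
        if fam.founder_age is None:
            continue
        if high_confidence_only and not fam.high_confidence:
            continue
        counts[fam.founder_age] += 1
    return counts


def write_families_tsv(path: str | Path, families: Sequence[GeneFamily], lineage: Lineage) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tfounder_level_index\tfounder_level_name\tn_members\thigh_confidence\tmember_ids\n")
        for fam in families:
            name = lineage.level(fam.founder_age).name if fam.founder_age else ""
            hc = "" if fam.high_confidence is None else int(fam.high_confidence)
            fh.write(
                f"{fam.family_id}\t{fam.founder_age if fam.founder_age else ''}\t{name}\t"
                f"{len(fam.members)}\t{hc}\t{','.join(sorted(fam.members))}\n"
            )


def write_founder_counts_tsv(
    path: str | Path,
    before: Mapping[int, int],
    after: Mapping[int, int] | None,
    lineage: Lineage,
) -> None:
    """Per-level founder-event counts, before and (optionally) after HDF filtering."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("level_index\tlevel_name\tn_founder_events\tn_high_confidence\n")
        for j in sorted(before):
            name = lineage.level(j).name
            hc = "" if after is None else after.get(j, 0)
            fh.write(f"{j}\t{name}\t{before[j]}\t{hc}\n")
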