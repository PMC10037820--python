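"""Taxonomy loading, lineage construction and level collapsing.

A gene's age is expressed as an index into the focal species' lineage:
level 1 is the focal species itself, level N is the root of the taxonomy
("cellular organisms" in NCBI terms), and intermediate levels are the
nested clades in between, ordered youngest to oldest.  Every downstream
stage (age assignment, representativeness, family dating, the HDF test)
speaks in these indices, so this module is the coordinate system of the
whole pipeline.

Two input dialects are supported: the NCBI taxdump pair
(``nodes.dmp``/``names.dmp``, pipe-with-tabs delimited) and a plain
4-column TSV (taxid, parent_taxid, rank, name).  No network access is
ever performed; merged/deleted-node resolution is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxonNode",
    "TaxonomyDB",
    "LineageLevel",
    "Lineage",
    "TaxonomyError",
    "load_taxonomy",
    "focal_lineage",
    "divergence_level",
    "collapse_levels",
    "write_lineage_tsv",
]


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, dangling parent, ...)."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyDB:
    """A validated, in-memory taxonomy: one root, acyclic parent pointers."""

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        self._nodes = dict(nodes)
        self._root = self._validate()

    def _validate(self) -> int:
        roots = [n.taxid for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (self-parent) node, found {len(roots)}: {sorted(roots)[:5]}"
            )
        root = roots[0]
        for node in self._nodes.values():
            if node.parent not in self._nodes:
                raise TaxonomyError(
                    f"node {node.taxid} references missing parent taxid {node.parent}"
                )
        # Cycle check: every parent chain must terminate at the root.
        ok: set[int] = {root}
        for taxid in self._nodes:
            chain = []
            cur = taxid
            seen: set[int] = set()
            while cur not in ok:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected in parent chain of taxid {taxid}")
                seen.add(cur)
                chain.append(cur)
                cur = self._nodes[cur].parent
            ok.update(chain)
        return root

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __getitem__(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"taxid {taxid} not in taxonomy") from None

    @property
    def root(self) -> int:
        return self._root

    def ancestors(self, taxid: int, include_self: bool = True) -> list[int]:
        """Parent chain from ``taxid`` up to and including the root."""
        out = [taxid] if include_self else []
        cur = taxid
        while cur != self._root:
            cur = self[cur].parent
            out.append(cur)
        if not include_self and taxid == self._root:
            out.append(self._root)
        return out


@dataclass(frozen=True)
class LineageLevel:
    index: int  # 1 = focal species, N = root
    taxid: int
    name: str
    rank: str


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic levels of the focal species, youngest to oldest."""

    focal_taxid: int
    levels: tuple[LineageLevel, ...]

    def __post_init__(self):
        if not self.levels:
            raise ValueError("lineage must have at least one level")
        if self.levels[0].taxid != self.focal_taxid:
            raise ValueError("level 1 must be the focal taxon")
        for i, lv in enumerate(self.levels, start=1):
            if lv.index != i:
                raise ValueError("lineage indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def depth(self) -> int:
        return len(self.levels)

    def level(self, index: int) -> LineageLevel:
        return self.levels[index - 1]

    def taxid_to_index(self) -> dict[int, int]:
        return {lv.taxid: lv.index for lv in self.levels}


def _parse_taxdump_nodes(path: Path) -> dict[int, tuple[int, str]]:
    out: dict[int, tuple[int, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.strip("\t|").split("\t|\t")]
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes.dmp line: {line!r}")
            out[int(fields[0])] = (int(fields[1]), fields[2])
    return out


def _parse_taxdump_names(path: Path) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.strip("\t|").split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                out[int(fields[0])] = fields[1]
            elif len(fields) < 4 and len(fields) >= 2:
                # tolerate name files without a class column
                out.setdefault(int(fields[0]), fields[1])
    return out


def _parse_lineage_tsv(path: Path) -> dict[int, TaxonNode]:
    nodes: dict[int, TaxonNode] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(f"lineage TSV needs 4 columns, got {len(fields)}: {line!r}")
            taxid, parent, rank, name = int(fields[0]), int(fields[1]), fields[2], fields[3]
            nodes[taxid] = TaxonNode(taxid, parent, rank, name)
    return nodes


def load_taxonomy(nodes_source: str | Path, names_source: str | Path | None = None) -> TaxonomyDB:
    """Load a taxonomy from taxdump files or a 4-column lineage TSV.

    With ``names_source`` given, ``nodes_source`` is parsed as NCBI
    ``nodes.dmp`` (pipe-with-tabs) and ``names_source`` as ``names.dmp``
    (only rows of class "scientific name" are used).  Without it,
    ``nodes_source`` is parsed as a TSV with columns
    (taxid, parent_taxid, rank, name).

    Raises :class:`TaxonomyError` on cycles, dangling parent references,
    or a root count other than one.
    """
    nodes_source = Path(nodes_source)
    if names_source is None:
        nodes = _parse_lineage_tsv(nodes_source)
    else:
        raw = _parse_taxdump_nodes(nodes_source)
        names = _parse_taxdump_names(Path(names_source))
        nodes = {
            taxid: TaxonNode(taxid, parent, rank, names.get(taxid, str(taxid)))
            for taxid, (parent, rank) in raw.items()
        }
    return TaxonomyDB(nodes)


def focal_lineage(db: TaxonomyDB, focal_taxid: int) -> Lineage:
    """Lineage of ``focal_taxid``: walk the parent chain to the root.

    Level 1 is the focal taxon, level N the root.
    """
    if focal_taxid not in db:
        raise KeyError(f"focal taxid {focal_taxid} not in taxonomy")
    levels = []
    for i, taxid in enumerate(db.ancestors(focal_taxid), start=1):
        node = db[taxid]
        levels.append(LineageLevel(i, taxid, node.name, node.rank))
    return Lineage(focal_taxid=focal_taxid, levels=tuple(levels))


def divergence_level(lineage: Lineage, db: TaxonomyDB, subject_taxid: int) -> int | None:
    """Lineage index at which ``subject_taxid`` diverges from the focal species.

    This is the smallest index j such that the subject belongs to the
    clade at level j — the lowest common ancestor expressed in lineage
    coordinates.  The focal species itself maps to 1.  Returns ``None``
    for subjects not contained under the lineage root (the caller counts
    and discards such hits).
    """
    if subject_taxid not in db:
        raise KeyError(f"subject taxid {subject_taxid} not in taxonomy")
    subject_anc = set(db.ancestors(subject_taxid))
    for lv in lineage.levels:
        if lv.taxid in subject_anc:
            return lv.index
    return None


def collapse_levels(
    lineage: Lineage,
    db: TaxonomyDB,
    per_species_match_fraction: Mapping[int, float],
    retention_fraction: float = 0.10,
    excluded_level_names: Iterable[str] = (),
) -> tuple[Lineage, dict[int, int]]:
    """Drop lineage levels that lack genomic representation.

    A level j (1 < j < N) is retained iff at least one species whose
    divergence level is j matches strictly more than ``retention_fraction``
    of the query proteome (fractions are computed over ALL query genes,
    not just age-assignable ones).  Levels named in
    ``excluded_level_names`` are removed regardless of their support
    (the escape hatch for known non-monophyletic ranks).  Level 1 and
    level N are never removed.

    Returns the re-indexed lineage and the old->new index map for the
    retained levels.
    """
    if not 0.0 <= retention_fraction <= 1.0:
        raise ValueError("retention_fraction must be in [0, 1]")
    excluded = set(excluded_level_names)
    n = len(lineage)
    supported: set[int] = set()
    for taxid, frac in per_species_match_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"match fraction for taxid {taxid} outside [0,1]: {frac}")
        if frac > retention_fraction:
            j = divergence_level(lineage, db, taxid)
            if j is not None:
                supported.add(j)

    keep: list[LineageLevel] = []
    for lv in lineage.levels:
        protected = lv.index in (1, n)
        if not protected and lv.name in excluded:
            continue
        if protected or lv.index in supported:
            keep.append(lv)

    index_map = {lv.index: new for new, lv in enumerate(keep, start=1)}
    new_levels = tuple(replace(lv, index=index_map[lv.index]) for lv in keep)
    return Lineage(focal_taxid=lineage.focal_taxid, levels=new_levels), index_map


def write_lineage_tsv(path: str | Path, full: Lineage, retained_map: Mapping[int, int]) -> None:
    """Write the lineage table with a retained flag for each original level."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index\ttaxid\trank\tname\tretained\tretained_index\n")
        for lv in full.levels:
            new = retained_map.get(lv.index)
            fh.write(
                f"{lv.index}\t{lv.taxid}\t{lv.rank}\t{lv.name}\t"
                f"{1 if new is not None else 0}\t{new if new is not None else ''}\n"
            )
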