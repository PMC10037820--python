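"""Reading, filtering and merging tabular homology-hit files.

Consumes the 12-ish column tab-separated dialect that BLAST and DIAMOND
emit as "outfmt 6", with subject taxonomy ids (``staxids``).  Only five
columns matter downstream — query id, subject id, e-value, bitscore and
subject taxid — and their positions are configurable because pipelines
reorder them freely.  Hits are filtered by e-value only; there is no cap
on hits per query (a ranked top-k cap silently discards distant species,
which is exactly the failure mode this pipeline is built to avoid).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "HitRecord",
    "HitFilterConfig",
    "HitTableFormatError",
    "ReadResult",
    "read_hit_table",
    "detect_absent_genes",
    "merge_hit_sources",
]

#: Default column layout: the classic ``outfmt 6`` prefix plus staxids.
DEFAULT_COLUMNS: tuple[str, ...] = ("qseqid", "sseqid", "evalue", "bitscore", "staxids")

MANDATORY = ("qseqid", "sseqid", "evalue", "bitscore", "staxids")


class HitTableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    """One filtered pairwise alignment."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    taxid: int
    source: str = "protein"  # "protein" | "genome"


@dataclass(frozen=True)
class HitFilterConfig:
    """E-value filtering and column layout for hit tables.

    ``evalue_threshold`` is inclusive: a hit at exactly the threshold is
    kept, matching aligner reporting semantics.  e-value 0.0 (underflow)
    is accepted as the strongest possible hit.
    """

    evalue_threshold: float = 1e-5
    columns: tuple[str, ...] = DEFAULT_COLUMNS

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        missing = [c for c in MANDATORY if c not in self.columns]
        if missing:
            raise HitTableFormatError(f"column layout is missing mandatory column(s): {missing}")


@dataclass
class ReadResult:
    """Filtered hit records plus per-file parsing statistics."""

    records: list[HitRecord]
    n_lines: int = 0
    n_malformed: int = 0
    n_filtered: int = 0

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def read_hit_table(
    path: str | Path,
    config: HitFilterConfig | None = None,
    source: str = "protein",
) -> ReadResult:
    """Read an outfmt-6-style TSV, keeping hits with e-value <= threshold.

    Semicolon-separated multi-taxid cells expand to one record per
    taxid.  Malformed lines (wrong field count, unparsable numbers) are
    counted, not fatal.  Every surviving record is emitted — no per-query
    truncation of any kind.
    """
    config = config or HitFilterConfig()
    path = Path(path)
    idx = {name: config.columns.index(name) for name in MANDATORY}
    need = max(idx.values()) + 1
    res = ReadResult(records=[])
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            res.n_lines += 1
            fields = line.split("\t")
            if len(fields) < need:
                res.n_malformed += 1
                continue
            try:
                evalue = float(fields[idx["evalue"]])
                bitscore = float(fields[idx["bitscore"]])
                taxids = [int(t) for t in fields[idx["staxids"]].split(";") if t.strip()]
            except ValueError:
                res.n_malformed += 1
                continue
            if evalue < 0 or bitscore <= 0 or not taxids:
                res.n_malformed += 1
                continue
            if evalue > config.evalue_threshold:
                res.n_filtered += 1
                continue
            q, s = fields[idx["qseqid"]], fields[idx["sseqid"]]
            for taxid in taxids:
                res.records.append(HitRecord(q, s, evalue, bitscore, taxid, source))
    if res.n_lines == 0:
        warnings.warn(f"hit table {path} is empty", stacklevel=2)
    return res


def detect_absent_genes(all_query_ids: Iterable[str], hits: Iterable[HitRecord]) -> set[str]:
    """Gene ids with zero surviving hits — not even a self-match.

    These genes cannot be assigned an age and are reported with status
    "absent".  Stringent e-value thresholds grow this set.
    """
    with_hits = {h.query for h in hits}
    return set(all_query_ids) - with_hits


def merge_hit_sources(
    protein_hits: Iterable[HitRecord], genome_hits: Iterable[HitRecord]
) -> list[HitRecord]:
    """Union of protein-vs-protein and protein-vs-genome (six-frame) evidence.

    Both streams must have been filtered at the same e-value threshold.
    Records keep their source tags; duplicates across sources are kept as
    distinct records.  Downstream, a gene's age is the oldest level
    supported by either source.
    """
    return list(protein_hits) + list(genome_hits)
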