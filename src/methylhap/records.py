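"""Core value types: CpG site index, read-level haplotypes, blocks, score matrices.

Coordinates are 0-based and half-open everywhere. A *methylation haplotype* is the
ordered pattern of methylated ('1') / unmethylated ('0') calls at consecutive CpG
sites on one sequencing read; unobserved calls inside a read are '?'.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

CALL_CHARS = "01?"
_CALL_TO_INT = {"1": 1, "0": 0, "?": -1}
_INT_TO_CALL = {1: "1", 0: "0", -1: "?"}


class CpGIndex:
    """Per-chromosome sorted lists of CpG cytosine positions.

    Haplotype records are anchored to ordinals in this index rather than to raw
    genomic positions, which makes "consecutive CpGs" a first-class notion.
    """

    def __init__(self, positions: Mapping[str, Iterable[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted({int(p) for p in pos}), dtype=np.int64)
            if arr.size and arr[0] < 0:
                raise SchemaError(f"negative CpG position on {chrom}")
            self._pos[str(chrom)] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        try:
            return self._pos[chrom]
        except KeyError:
            raise AlignmentError(f"unknown chromosome {chrom!r}") from None

    def n_sites(self, chrom: str) -> int:
        return int(self.positions(chrom).size)

    def ordinal(self, chrom: str, pos: int) -> int:
        """Ordinal of the CpG at genomic position ``pos`` (exact match required)."""
        arr = self.positions(chrom)
        i = int(np.searchsorted(arr, pos))
        if i == arr.size or arr[i] != pos:
            raise AlignmentError(f"{chrom}:{pos} is not a known CpG site")
        return i

    def position(self, chrom: str, index: int) -> int:
        arr = self.positions(chrom)
        if not 0 <= index < arr.size:
            raise AlignmentError(f"CpG ordinal {index} out of range on {chrom}")
        return int(arr[index])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CpGIndex):
            return NotImplemented
        return self._pos.keys() == other._pos.keys() and all(
            np.array_equal(self._pos[c], other._pos[c]) for c in self._pos
        )


@dataclass(frozen=True)
class HaplotypeRecord:
    """One read-level observation: consecutive CpG calls plus a multiplicity.

    ``start_index`` is the ordinal of the first covered CpG within its
    chromosome's sorted site list; ``calls[k]`` belongs to ordinal
    ``start_index + k``.
    """

    chrom: str
    start_index: int
    calls: str
    count: int = 1

    def __post_init__(self):
        if len(self.calls) < 1:
            raise SchemaError("haplotype must cover at least one CpG")
        if any(c not in CALL_CHARS for c in self.calls):
            raise SchemaError(f"invalid call characters in {self.calls!r}")
        if self.count < 1:
            raise SchemaError("count must be a positive integer")
        if self.start_index < 0:
            raise SchemaError("start_index must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    @property
    def high_missing(self) -> bool:
        """True when more than half of the calls are unobserved."""
        return self.calls.count("?") * 2 > len(self.calls)

    def to_int8(self) -> np.ndarray:
        return np.array([_CALL_TO_INT[c] for c in self.calls], dtype=np.int8)

    def complement(self) -> "HaplotypeRecord":
        swapped = self.calls.translate(str.maketrans("01", "10"))
        return HaplotypeRecord(self.chrom, self.start_index, swapped, self.count)


@dataclass(frozen=True)
class MHBRegion:
    """A methylation haplotype block: >= 2 consecutive CpGs in tight LD.

    ``start``/``end`` are the genomic half-open interval from the first CpG
    cytosine to the last CpG's dinucleotide end (last position + 2).
    """

    id: str
    chrom: str
    first_index: int
    n_sites: int
    start: int
    end: int

    def __post_init__(self):
        if self.n_sites < 2:
            raise SchemaError("an MHB needs at least two CpG sites")
        if not 0 <= self.start < self.end:
            raise SchemaError("invalid region interval")

    @property
    def site_indices(self) -> range:
        return range(self.first_index, self.first_index + self.n_sites)


SCORE_KINDS = ("MHL", "UMHL")


@dataclass
class ScoreMatrix:
    """Samples x MHB matrix of haplotype-load scores in [0, 1].

    NaN marks a block undetected (no qualifying reads) in that sample.
    """

    data: pd.DataFrame
    score_kind: str

    def __post_init__(self):
        if self.score_kind not in SCORE_KINDS:
            raise SchemaError(f"score_kind must be one of {SCORE_KINDS}")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise SchemaError("score values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mhb_ids(self) -> list[str]:
        return list(self.data.columns)


class HaplotypeTable:
    """Column-oriented store of haplotype records for vectorised scoring/LD.

    ``calls`` is an int8 matrix (1 methylated, 0 unmethylated, -1 missing),
    right-padded with -1 beyond each record's length. Rows are sorted by
    (chromosome, start ordinal).
    """

    def __init__(
        self,
        chroms: Sequence[str],
        chrom_code: np.ndarray,
        start_index: np.ndarray,
        calls: np.ndarray,
        length: np.ndarray,
        count: np.ndarray,
    ):
        order = np.lexsort((start_index, chrom_code))
        self.chroms = list(chroms)
        self.chrom_code = np.asarray(chrom_code, dtype=np.int32)[order]
        self.start_index = np.asarray(start_index, dtype=np.int64)[order]
        self.calls = np.asarray(calls, dtype=np.int8)[order]
        self.length = np.asarray(length, dtype=np.int32)[order]
        self.count = np.asarray(count, dtype=np.int64)[order]

    def __len__(self) -> int:
        return int(self.start_index.size)

    @property
    def total_reads(self) -> int:
        return int(self.count.sum())

    @classmethod
    def from_records(cls, records: Iterable[HaplotypeRecord]) -> "HaplotypeTable":
        records = list(records)
        chroms = sorted({r.chrom for r in records})
        code = {c: i for i, c in enumerate(chroms)}
        n = len(records)
        width = max((r.n_sites for r in records), default=1)
        calls = np.full((n, width), -1, dtype=np.int8)
        chrom_code = np.empty(n, dtype=np.int32)
        start = np.empty(n, dtype=np.int64)
        length = np.empty(n, dtype=np.int32)
        count = np.empty(n, dtype=np.int64)
        for i, r in enumerate(records):
            chrom_code[i] = code[r.chrom]
            start[i] = r.start_index
            length[i] = r.n_sites
            count[i] = r.count
            calls[i, : r.n_sites] = r.to_int8()
        return cls(chroms, chrom_code, start, calls, length, count)

    def to_records(self) -> list[HaplotypeRecord]:
        out = []
        for i in range(len(self)):
            s = "".join(
                _INT_TO_CALL[int(v)] for v in self.calls[i, : self.length[i]]
            )
            out.append(
                HaplotypeRecord(
                    self.chroms[self.chrom_code[i]],
                    int(self.start_index[i]),
                    s,
                    int(self.count[i]),
                )
            )
        return out


METADATA_COLUMNS = [
    "specimen",
    "tumor_status",
    "mvi_status",
    "pair_id",
    "surv_time",
    "surv_event",
]

_SPECIMENS = {"tissue", "plasma"}
_TUMOR_STATUS = {"tumor", "normal", "healthy"}
_MVI_STATUS = {"positive", "negative", "not_applicable"}
_SURV_EVENTS = {"event", "censored", "unknown"}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort metadata table (indexed by sample_id) and return it.

    Enforces the categorical vocabularies, that MVI status is only assigned to
    tumors, and that every pair id links exactly one tumor and one normal
    tissue sample.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise SchemaError("duplicate sample ids in metadata")
    for col, allowed in [
        ("specimen", _SPECIMENS),
        ("tumor_status", _TUMOR_STATUS),
        ("mvi_status", _MVI_STATUS),
        ("surv_event", _SURV_EVENTS),
    ]:
        bad = set(meta[col].dropna()) - allowed
        if bad:
            raise SchemaError(f"invalid {col} values: {sorted(bad)}")
    non_tumor = meta["tumor_status"] != "tumor"
    if (meta.loc[non_tumor, "mvi_status"] != "not_applicable").any():
        raise SchemaError("mvi_status must be not_applicable for non-tumor samples")
    times = pd.to_numeric(meta["surv_time"], errors="coerce")
    if (times.dropna() < 0).any():
        raise SchemaError("survival times must be non-negative")
    tissue = meta[meta["specimen"] == "tissue"]
    for pid, grp in tissue.dropna(subset=["pair_id"]).groupby("pair_id"):
        statuses = sorted(grp["tumor_status"])
        if statuses != ["normal", "tumor"]:
            raise SchemaError(
                f"pair {pid!r} must link exactly one tumor and one normal tissue"
            )
    return meta
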