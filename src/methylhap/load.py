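"""Methylated / un-methylated haplotype load (MHL / UMHL).

For a block of ``l`` CpGs, every read contributes its contiguous sub-haplotypes
(windows) of each length ``i = 1..l`` that lie wholly inside the block and
contain no missing call. With ``P(MH_i)`` the fraction of length-``i`` windows
that are fully methylated,

    MHL = sum_i w_i * P(MH_i) / sum_i w_i,      w_i = i ** weight_exponent,

summing over lengths with at least one evaluable window. UMHL is the mirror
statistic on fully un-methylated windows. The cubic default weight rewards long
consecutive methylated runs, the signature of tumour-derived epialleles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .records import (
    HaplotypeRecord,
    HaplotypeTable,
    MHBRegion,
    ScoreMatrix,
)


@dataclass
class LoadParams:
    """Tunables of the load statistics.

    weight_exponent : exponent of the per-length weight ``w_i = i ** e``
        (default 3, i.e. cubic emphasis on long runs; 1 recovers linear
        weighting).
    min_reads_detect : minimum total read count overlapping a block for the
        block to count as detected in a sample.
    count_weighted : when False each table row (distinct haplotype) contributes
        once regardless of its count.
    """

    weight_exponent: float = 3.0
    min_reads_detect: int = 1
    count_weighted: bool = True

    def __post_init__(self):
        if self.weight_exponent <= 0:
            raise SchemaError("weight_exponent must be positive")
        if self.min_reads_detect < 1:
            raise SchemaError("min_reads_detect must be >= 1")


Records = Union[HaplotypeTable, Iterable[HaplotypeRecord]]


def _as_table(records: Records) -> HaplotypeTable:
    if isinstance(records, HaplotypeTable):
        return records
    return HaplotypeTable.from_records(list(records))


def _align_to_block(table: HaplotypeTable, region: MHBRegion) -> tuple[np.ndarray, np.ndarray]:
    """Return (aligned int8 matrix (n, l), counts) of reads overlapping the block."""
    if region.chrom in table.chroms:
        code = table.chroms.index(region.chrom)
        rows = np.flatnonzero(table.chrom_code == code)
    else:
        rows = np.empty(0, dtype=int)
    l = region.n_sites
    if rows.size == 0:
        return np.empty((0, l), dtype=np.int8), np.empty(0, dtype=np.int64)
    start = table.start_index[rows]
    length = table.length[rows]
    keep = (start < region.first_index + l) & (start + length > region.first_index)
    rows = rows[keep]
    return _gather(table.calls[rows], table.start_index[rows], region.first_index, l), table.count[rows]


def _gather(calls: np.ndarray, start_index: np.ndarray, first: int, l: int) -> np.ndarray:
    """Align records to block columns; positions outside a read become -1."""
    src = (first - start_index)[:, None] + np.arange(l)[None, :]
    valid = (src >= 0) & (src < calls.shape[1])
    g = np.take_along_axis(calls, np.clip(src, 0, calls.shape[1] - 1), axis=1)
    return np.where(valid, g, np.int8(-1))


def _per_read_window_counts(aligned: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-read counts of fully methylated / un-methylated / evaluable windows.

    Returns three (n_reads, l) arrays whose column ``i-1`` refers to window
    length ``i``. A window is evaluable when it contains no missing (-1) call;
    missing calls therefore segment the read, as required.
    """
    n, l = aligned.shape
    meth = np.zeros((n, l), dtype=np.int64)
    unmeth = np.zeros((n, l), dtype=np.int64)
    ok = np.zeros((n, l), dtype=np.int64)
    for i in range(1, l + 1):
        win = np.lib.stride_tricks.sliding_window_view(aligned, i, axis=1)
        mn = win.min(axis=2)
        mx = win.max(axis=2)
        meth[:, i - 1] = (mn == 1).sum(axis=1)
        unmeth[:, i - 1] = ((mn == 0) & (mx == 0)).sum(axis=1)
        ok[:, i - 1] = (mn >= 0).sum(axis=1)
    return meth, unmeth, ok


def _load_from_sums(num: np.ndarray, den: np.ndarray, exponent: float) -> float:
    valid = den > 0
    if not valid.any():
        return float("nan")
    w = np.arange(1, den.size + 1, dtype=float) ** exponent
    w = w[valid]
    return float(np.sum(w * num[valid] / den[valid]) / np.sum(w))


def substring_fractions(
    records: Records, region: MHBRegion
) -> pd.DataFrame:
    """Fractions of fully methylated / un-methylated windows per length.

    Returns a frame indexed by window length ``1..l`` with columns
    ``meth_fraction``, ``unmeth_fraction`` (NaN when no window of that length
    is evaluable) and ``n_windows`` (count-weighted evaluable windows).
    """
    table = _as_table(records)
    aligned, counts = _align_to_block(table, region)
    meth, unmeth, ok = _per_read_window_counts(aligned)
    c = counts[:, None].astype(float)
    num_m = (meth * c).sum(axis=0)
    num_u = (unmeth * c).sum(axis=0)
    den = (ok * c).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fm = np.where(den > 0, num_m / np.maximum(den, 1e-300), np.nan)
        fu = np.where(den > 0, num_u / np.maximum(den, 1e-300), np.nan)
    return pd.DataFrame(
        {"meth_fraction": fm, "unmeth_fraction": fu, "n_windows": den},
        index=pd.RangeIndex(1, region.n_sites + 1, name="length"),
    )


def _block_load(
    records: Records, region: MHBRegion, params: LoadParams, kind: str
) -> float:
    table = _as_table(records)
    aligned, counts = _align_to_block(table, region)
    if not params.count_weighted:
        counts = np.ones_like(counts)
    covered = (aligned >= 0).any(axis=1)
    if counts[covered].sum() < params.min_reads_detect:
        return float("nan")
    meth, unmeth, ok = _per_read_window_counts(aligned)
    c = counts[:, None].astype(float)
    num = ((meth if kind == "MHL" else unmeth) * c).sum(axis=0)
    den = (ok * c).sum(axis=0)
    return _load_from_sums(num, den, params.weight_exponent)


def mhl(records: Records, region: MHBRegion, params: LoadParams | None = None) -> float:
    """Methylated haplotype load of one block in one sample (NaN if undetected)."""
    return _block_load(records, region, params or LoadParams(), "MHL")


def umhl(records: Records, region: MHBRegion, params: LoadParams | None = None) -> float:
    """Un-methylated haplotype load; equals MHL of the complemented calls."""
    return _block_load(records, region, params or LoadParams(), "UMHL")


def score_cohort(
    haplotypes: Mapping[str, Records],
    regions: Sequence[MHBRegion],
    params: LoadParams | None = None,
    score_kind: str = "MHL",
) -> ScoreMatrix:
    """Score every sample x block cell; NaN where the block is undetected.

    Processes one region at a time across all samples (vectorised), so cohorts
    with thousands of blocks score in seconds.
    """
    params = params or LoadParams()
    if score_kind not in ("MHL", "UMHL"):
        raise SchemaError("score_kind must be MHL or UMHL")
    sample_ids = list(haplotypes)
    tables = {s: _as_table(haplotypes[s]) for s in sample_ids}

    # Concatenate all samples into per-chromosome pooled arrays.
    chrom_names = sorted({c for t in tables.values() for c in t.chroms})
    pooled: dict[str, dict[str, np.ndarray]] = {}
    width = max((t.calls.shape[1] for t in tables.values() if len(t)), default=1)
    for chrom in chrom_names:
        starts, lens, cnts, scodes, call_rows = [], [], [], [], []
        for si, s in enumerate(sample_ids):
            t = tables[s]
            if chrom not in t.chroms or len(t) == 0:
                continue
            rows = np.flatnonzero(t.chrom_code == t.chroms.index(chrom))
            if rows.size == 0:
                continue
            starts.append(t.start_index[rows])
            lens.append(t.length[rows])
            cnts.append(t.count[rows])
            scodes.append(np.full(rows.size, si, dtype=np.int32))
            pad = np.full((rows.size, width), -1, dtype=np.int8)
            pad[:, : t.calls.shape[1]] = t.calls[rows]
            call_rows.append(pad)
        if not starts:
            continue
        start = np.concatenate(starts)
        order = np.argsort(start, kind="stable")
        pooled[chrom] = {
            "start": start[order],
            "length": np.concatenate(lens)[order],
            "count": np.concatenate(cnts)[order],
            "sample": np.concatenate(scodes)[order],
            "calls": np.concatenate(call_rows)[order],
        }

    n_samples = len(sample_ids)
    out = np.full((n_samples, len(regions)), np.nan)
    for j, region in enumerate(regions):
        blk = pooled.get(region.chrom)
        if blk is None:
            continue
        l = region.n_sites
        lo = int(np.searchsorted(blk["start"], region.first_index - width + 1))
        hi = int(np.searchsorted(blk["start"], region.first_index + l))
        if hi <= lo:
            continue
        sl = slice(lo, hi)
        start = blk["start"][sl]
        keep = start + blk["length"][sl] > region.first_index
        start = start[keep]
        calls = blk["calls"][sl][keep]
        counts = blk["count"][sl][keep]
        samples = blk["sample"][sl][keep]
        if start.size == 0:
            continue
        if not params.count_weighted:
            counts = np.ones_like(counts)
        aligned = _gather(calls, start, region.first_index, l)
        covered = (aligned >= 0).any(axis=1)
        det = np.bincount(samples, weights=counts * covered, minlength=n_samples)
        meth, unmeth, ok = _per_read_window_counts(aligned)
        target = meth if score_kind == "MHL" else unmeth
        cw = counts.astype(float)
        num = np.empty((n_samples, l))
        den = np.empty((n_samples, l))
        for i in range(l):
            num[:, i] = np.bincount(samples, weights=target[:, i] * cw, minlength=n_samples)
            den[:, i] = np.bincount(samples, weights=ok[:, i] * cw, minlength=n_samples)
        w = np.arange(1, l + 1, dtype=float) ** params.weight_exponent
        valid = den > 0
        wsum = np.where(valid, w, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            load = np.where(valid, w * num / np.maximum(den, 1e-300), 0.0).sum(axis=1)
            load = np.where(wsum > 0, load / np.maximum(wsum, 1e-300), np.nan)
        cell_ok = (det >= params.min_reads_detect) & (wsum > 0)
        out[cell_ok, j] = load[cell_ok]

    df = pd.DataFrame(out, index=sample_ids, columns=[r.id for r in regions])
    return ScoreMatrix(df, score_kind)
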