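"""Methylation haplotype block discovery from read-level haplotypes.

Adjacent CpG pairs are linked when the squared Pearson correlation (r^2) of
their binary methylation calls, over reads covering both sites, exceeds a
threshold (strictly greater than 0.5 by default). Maximal runs of linked
consecutive CpGs with at least two sites become blocks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .errors import MethylhapError, SchemaError
from .records import CpGIndex, HaplotypeRecord, HaplotypeTable, MHBRegion

# "strictly greater" linkage: a pair whose r^2 ties the threshold (up to float
# rounding of the 2x2-table formula) is excluded.
_R2_TIE_TOL = 1e-12

Records = Union[HaplotypeTable, Iterable[HaplotypeRecord]]
Haplotypes = Union[Records, Mapping[str, Records]]


@dataclass(frozen=True)
class PairLD:
    """LD between two adjacent CpG ordinals; ``r2`` is None when undefined
    (fewer than ``min_pairs`` co-covering reads or a constant margin)."""

    left_index: int
    right_index: int
    r2: float | None
    n_pairs: int


def _as_tables(haplotypes: Haplotypes) -> list[HaplotypeTable]:
    if isinstance(haplotypes, HaplotypeTable):
        return [haplotypes]
    if isinstance(haplotypes, Mapping):
        return [
            t if isinstance(t, HaplotypeTable) else HaplotypeTable.from_records(list(t))
            for t in haplotypes.values()
        ]
    return [HaplotypeTable.from_records(list(haplotypes))]


def _r2_from_table(tab: np.ndarray) -> float | None:
    """r^2 from a weighted 2x2 call table ``tab[left_call, right_call]``."""
    n = tab.sum()
    if n == 0:
        return None
    p = tab / n
    p_left = p[1, 0] + p[1, 1]
    p_right = p[0, 1] + p[1, 1]
    var = p_left * (1 - p_left) * p_right * (1 - p_right)
    if var <= 0:
        return None
    cov = p[1, 1] - p_left * p_right
    return float(cov * cov / var)


def _accumulate_pair_tables(tables: Sequence[HaplotypeTable], chrom: str, n_sites: int) -> np.ndarray:
    """Sum 2x2 tables for every adjacent ordinal pair on one chromosome.

    Returns an array of shape (n_sites - 1, 2, 2) indexed by the left ordinal.
    """
    tabs = np.zeros((max(n_sites - 1, 0), 2, 2), dtype=np.float64)
    for t in tables:
        if chrom not in t.chroms or len(t) == 0:
            continue
        rows = np.flatnonzero(t.chrom_code == t.chroms.index(chrom))
        if rows.size == 0:
            continue
        calls = t.calls[rows]
        start = t.start_index[rows]
        count = t.count[rows].astype(np.float64)
        for k in range(calls.shape[1] - 1):
            left = calls[:, k]
            right = calls[:, k + 1]
            ok = (left >= 0) & (right >= 0)
            if not ok.any():
                continue
            np.add.at(
                tabs,
                (start[ok] + k, left[ok].astype(int), right[ok].astype(int)),
                count[ok],
            )
    return tabs


def pairwise_r2(
    records: Records, left_index: int, right_index: int, min_pairs: int = 10
) -> PairLD:
    """LD of two *adjacent* CpG ordinals over reads covering both sites."""
    if right_index != left_index + 1:
        raise MethylhapError("pairwise_r2 requires adjacent CpG ordinals")
    tables = _as_tables(records)
    chroms = {c for t in tables for c in t.chroms}
    if len(chroms) > 1:
        raise SchemaError("records span multiple chromosomes")
    chrom = chroms.pop() if chroms else ""
    n_sites = right_index + 1
    for t in tables:
        if len(t):
            n_sites = max(n_sites, int((t.start_index + t.length).max()))
    tabs = _accumulate_pair_tables(tables, chrom, n_sites)
    tab = tabs[left_index] if left_index < tabs.shape[0] else np.zeros((2, 2))
    n = int(tab.sum())
    r2 = _r2_from_table(tab) if n >= min_pairs else None
    return PairLD(left_index, right_index, r2, n)


def adjacent_pair_ld(
    haplotypes: Haplotypes,
    index: CpGIndex,
    chrom: str,
    min_pairs: int = 10,
    mode: str = "pooled",
) -> list[PairLD]:
    """r^2 for every adjacent CpG pair on a chromosome.

    ``mode='pooled'`` pools reads across samples before correlating (default);
    ``mode='per_sample'`` computes r^2 within each sample and combines defined
    values by a pair-count-weighted mean.
    """
    n_sites = index.n_sites(chrom)
    tables = _as_tables(haplotypes)
    if mode == "pooled":
        tabs = _accumulate_pair_tables(tables, chrom, n_sites)
        out = []
        for k in range(n_sites - 1):
            n = int(tabs[k].sum())
            r2 = _r2_from_table(tabs[k]) if n >= min_pairs else None
            out.append(PairLD(k, k + 1, r2, n))
        return out
    if mode != "per_sample":
        raise SchemaError("mode must be 'pooled' or 'per_sample'")
    acc_num = np.zeros(max(n_sites - 1, 0))
    acc_w = np.zeros(max(n_sites - 1, 0))
    n_tot = np.zeros(max(n_sites - 1, 0))
    for t in tables:
        tabs = _accumulate_pair_tables([t], chrom, n_sites)
        for k in range(n_sites - 1):
            n = tabs[k].sum()
            n_tot[k] += n
            if n < min_pairs:
                continue
            r2 = _r2_from_table(tabs[k])
            if r2 is not None:
                acc_num[k] += n * r2
                acc_w[k] += n
    return [
        PairLD(k, k + 1, float(acc_num[k] / acc_w[k]) if acc_w[k] > 0 else None, int(n_tot[k]))
        for k in range(n_sites - 1)
    ]


def partition_blocks(
    haplotypes: Haplotypes,
    index: CpGIndex,
    r2_threshold: float = 0.5,
    min_pairs: int = 10,
    max_gap: int = 500,
    mode: str = "pooled",
) -> list[MHBRegion]:
    """Partition each chromosome into maximal runs of linked adjacent CpGs.

    A pair is linked when its r^2 is defined and strictly greater than
    ``r2_threshold`` and the genomic gap between the two cytosines is at most
    ``max_gap``. Runs shorter than two sites are discarded. Undefined r^2
    (too few co-covering reads, or a constant margin) breaks the chain.
    """
    regions: list[MHBRegion] = []
    for chrom in index.chroms:
        pos = index.positions(chrom)
        lds = adjacent_pair_ld(haplotypes, index, chrom, min_pairs, mode)
        linked = np.zeros(max(len(pos) - 1, 0), dtype=bool)
        for ld in lds:
            gap_ok = pos[ld.right_index] - pos[ld.left_index] <= max_gap
            linked[ld.left_index] = (
                ld.r2 is not None and ld.r2 > r2_threshold + _R2_TIE_TOL and gap_ok
            )
        for first, last in _runs(linked):
            start = int(pos[first])
            end = int(pos[last]) + 2
            regions.append(
                MHBRegion(
                    f"{chrom}:{start}-{end}", chrom, first, last - first + 1, start, end
                )
            )
    return regions


def _runs(linked: np.ndarray):
    """Maximal runs of consecutive sites joined by linked adjacent pairs."""
    i = 0
    n_pairs = linked.size
    while i < n_pairs:
        if linked[i]:
            j = i
            while j < n_pairs and linked[j]:
                j += 1
            yield i, j  # sites i .. j inclusive
            i = j
        else:
            i += 1
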