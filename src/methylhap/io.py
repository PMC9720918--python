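"""Readers and writers for the on-disk formats.

Formats (all plain text, tab-separated, '#'-prefixed header lines):

* CpG sites      — columns ``chrom, pos``.
* Haplotypes     — columns ``chrom, start, end, hap, count, strand`` (strand
  optional and ignored). ``start`` is the genomic position of the first covered
  CpG cytosine, ``end`` the last covered cytosine + 1 (half-open). ``hap`` is a
  string over '1' (methylated), '0' (unmethylated), '?' (missing call).
* Regions        — 4-column BED (chrom, start, end, name), 0-based half-open.
* Score matrices — TSV with sample rows, MHB columns, ``NA`` for undetected
  cells, and a leading ``# score_kind: MHL|UMHL`` line.
* Metadata       — TSV with a ``sample_id`` column plus the cohort fields.
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, SchemaError
from .records import (
    METADATA_COLUMNS,
    CpGIndex,
    HaplotypeRecord,
    HaplotypeTable,
    MHBRegion,
    ScoreMatrix,
    validate_metadata,
)

# ---------------------------------------------------------------------------
# CpG site index


def write_sites(index: CpGIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\n")
        for chrom in index.chroms:
            for pos in index.positions(chrom):
                fh.write(f"{chrom}\t{pos}\n")


def read_sites(path) -> CpGIndex:
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                pos = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {parts[1]!r}") from None
            sites.setdefault(parts[0], []).append(pos)
    return CpGIndex(sites)


# ---------------------------------------------------------------------------
# Haplotype records

_HAP_HEADER = "#chrom\tstart\tend\thap\tcount\tstrand\n"


def write_haplotypes(records: Iterable[HaplotypeRecord], path, index: CpGIndex) -> None:
    with open(path, "w") as fh:
        fh.write(_HAP_HEADER)
        for r in records:
            start = index.position(r.chrom, r.start_index)
            end = index.position(r.chrom, r.start_index + r.n_sites - 1) + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.calls}\t{r.count}\t+\n")


def write_haplotype_table(table: HaplotypeTable, path, index: CpGIndex) -> None:
    """Fast table writer; equivalent to write_haplotypes(table.to_records())."""
    n = len(table)
    if n == 0:
        with open(path, "w") as fh:
            fh.write(_HAP_HEADER)
        return
    chrom = np.array(table.chroms, dtype=object)[table.chrom_code]
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    haps = np.empty(n, dtype=object)
    call_chars = np.array(["0", "1"], dtype=object)
    for i in range(n):
        L = int(table.length[i])
        starts[i] = index.position(chrom[i], int(table.start_index[i]))
        ends[i] = index.position(chrom[i], int(table.start_index[i]) + L - 1) + 1
        row = table.calls[i, :L]
        haps[i] = "".join("?" if v < 0 else call_chars[v] for v in row)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "hap": haps,
            "count": table.count,
            "strand": "+",
        }
    )
    with open(path, "w") as fh:
        fh.write(_HAP_HEADER)
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_haplotypes(path, index: CpGIndex) -> list[HaplotypeRecord]:
    """Parse a haplotype TSV; every record must align to consecutive known CpGs."""
    out: list[HaplotypeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (5, 6):
                raise ParseError(f"{path}:{lineno}: expected 5 or 6 columns")
            chrom, start_s, end_s, hap, count_s = parts[:5]
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate/count") from None
            try:
                rec = HaplotypeRecord(chrom, 0, hap, count)
            except SchemaError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            try:
                first = index.ordinal(chrom, start)
                last_pos = index.position(chrom, first + len(hap) - 1)
            except AlignmentError as exc:
                raise AlignmentError(f"{path}:{lineno}: {exc}") from None
            if last_pos + 1 != end:
                raise AlignmentError(
                    f"{path}:{lineno}: end {end} does not match {len(hap)} "
                    f"consecutive CpGs from {chrom}:{start}"
                )
            out.append(HaplotypeRecord(chrom, first, hap, count))
    return out


def read_haplotype_table(path, index: CpGIndex) -> HaplotypeTable:
    records = read_haplotypes(path, index)
    if not records:
        return HaplotypeTable(
            [],
            np.empty(0, np.int32),
            np.empty(0, np.int64),
            np.empty((0, 1), np.int8),
            np.empty(0, np.int32),
            np.empty(0, np.int64),
        )
    return HaplotypeTable.from_records(records)


# ---------------------------------------------------------------------------
# Regions (BED)


def write_regions(regions: Iterable[MHBRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def read_regions(path, index: CpGIndex) -> list[MHBRegion]:
    out: list[MHBRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from None
            pos = index.positions(chrom)
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            if hi - lo < 2:
                raise SchemaError(
                    f"{path}:{lineno}: region {name} spans fewer than 2 CpGs"
                )
            out.append(MHBRegion(name, chrom, lo, hi - lo, start, end))
    return out


# ---------------------------------------------------------------------------
# Score matrices


def write_matrix(matrix: ScoreMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# score_kind: {matrix.score_kind}\n")
        matrix.data.to_csv(
            fh, sep="\t", na_rep="NA", index_label="sample_id", float_format="%.10g"
        )


def read_matrix(path) -> ScoreMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# score_kind:"):
            raise ParseError(f"{path}:1: missing '# score_kind:' header")
        kind = first.split(":", 1)[1].strip()
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values="NA")
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return ScoreMatrix(df, kind)


# ---------------------------------------------------------------------------
# Cohort metadata


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta)
    out = meta[METADATA_COLUMNS].copy()
    out.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id",
               float_format="%.10g")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA",
                     dtype={"pair_id": "string"})
    df.index = [str(i) for i in df.index]
    df.index.name = "sample_id"
    return validate_metadata(df)


# ---------------------------------------------------------------------------
# Cohort-level helpers


def read_cohort_haplotypes(directory, index: CpGIndex) -> dict[str, HaplotypeTable]:
    """Read every ``<sample>.tsv`` in a directory into haplotype tables."""
    out: dict[str, HaplotypeTable] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".tsv"):
            continue
        out[name[:-4]] = read_haplotype_table(os.path.join(directory, name), index)
    if not out:
        raise SchemaError(f"no haplotype files (*.tsv) found in {directory}")
    return out
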