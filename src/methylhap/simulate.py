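"""Synthetic cohorts of read-level methylation haplotypes.

Each read within a block is a two-state Markov chain over
{methylated, unmethylated}: the first CpG is methylated with probability
``theta``, and the state toggles with probability ``switch_rate`` at every
step. ``switch_rate`` therefore tunes haplotype consecutiveness — the property
the load statistics measure — while ``theta`` sets the methylation level.

A cohort contains normal liver tissue, tumour tissue split into MVI- and MVI+
groups, healthy plasma, and patient plasma. Spiked differential blocks shift
``theta`` in tumours (tumour markers) or in MVI+ tumours only (MVI markers).
Patient plasma draws each read from the matched tumour's distribution with
probability ``tumor_fraction`` (the circulating-tumour-DNA dilution), else
from a normal distribution. Per-sample, per-block Gaussian jitter on ``theta``
models inter-individual biological variability. Tumour patients get
exponential survival times whose hazard depends on MVI status, with
independent exponential censoring.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .errors import SchemaError
from .records import (
    CpGIndex,
    HaplotypeRecord,
    HaplotypeTable,
    MHBRegion,
)

_THETA_CLIP = (0.02, 0.98)


@dataclass
class BlockSpec:
    """Generative contract for one block.

    theta       : per-group probability that the first CpG of a read is
                  methylated.
    switch_rate : per-step toggle probability (0 = perfectly consecutive
                  haplotypes, 0.5 = independent adjacent sites).
    mean_depth  : expected reads per sample (Poisson).
    detect_prob : probability the block is observed at all in a sample.
    """

    n_cpgs: int = 5
    theta: Mapping[str, float] = field(default_factory=lambda: {"normal": 0.5})
    switch_rate: float = 0.05
    mean_depth: float = 30.0
    detect_prob: float = 1.0

    def __post_init__(self):
        if self.n_cpgs < 2:
            raise SchemaError("a block needs at least 2 CpGs")
        if self.mean_depth <= 0:
            raise SchemaError("mean_depth must be positive")
        for name, v in [("switch_rate", self.switch_rate), ("detect_prob", self.detect_prob)]:
            if not 0 <= v <= 1:
                raise SchemaError(f"{name} must lie in [0, 1]")
        for g, th in self.theta.items():
            if not 0 <= th <= 1:
                raise SchemaError(f"theta[{g!r}] must lie in [0, 1]")


def _markov_reads(theta, switch_rate: float, n_reads: int, n_cpgs: int, rng) -> np.ndarray:
    """(n_reads, n_cpgs) uint8 matrix of chain states; theta may be per-read."""
    first = (rng.random(n_reads) < theta).astype(np.uint8)
    if n_cpgs == 1:
        return first[:, None]
    toggles = (rng.random((n_reads, n_cpgs - 1)) < switch_rate).astype(np.uint8)
    parity = np.cumsum(toggles, axis=1, dtype=np.int64) & 1
    out = np.empty((n_reads, n_cpgs), dtype=np.uint8)
    out[:, 0] = first
    out[:, 1:] = first[:, None] ^ parity.astype(np.uint8)
    return out


def _pack(reads: np.ndarray) -> np.ndarray:
    """Encode each read row as an integer (first CpG in the high bit)."""
    l = reads.shape[1]
    weights = (1 << np.arange(l - 1, -1, -1)).astype(np.int64)
    return reads.astype(np.int64) @ weights


def _unpack(codes: np.ndarray, l: int) -> np.ndarray:
    shifts = np.arange(l - 1, -1, -1)
    return ((codes[:, None] >> shifts) & 1).astype(np.int8)


def simulate_block_reads(
    spec: BlockSpec,
    group: str,
    rng: np.random.Generator,
    chrom: str = "chr1",
    start_index: int = 0,
) -> list[HaplotypeRecord]:
    """Reads for one sample x block; may be empty (detection dropout)."""
    if rng.random() >= spec.detect_prob:
        return []
    n = int(rng.poisson(spec.mean_depth))
    if n == 0:
        return []
    reads = _markov_reads(spec.theta[group], spec.switch_rate, n, spec.n_cpgs, rng)
    codes, counts = np.unique(_pack(reads), return_counts=True)
    calls = _unpack(codes, spec.n_cpgs)
    return [
        HaplotypeRecord(chrom, start_index, "".join(map(str, row)), int(c))
        for row, c in zip(calls, counts)
    ]


@dataclass
class CohortSpec:
    """Full synthetic-cohort specification (defaults: desk-scale preset
    mirroring the study design: 25 normal tissues paired to tumours, 17 MVI-
    and 18 MVI+ tumours, 24 healthy plasma, one plasma sample per patient)."""

    n_blocks: int = 2000
    n_cpgs: int = 5
    n_normal_tissue: int = 25
    n_tumor_mvi_neg: int = 17
    n_tumor_mvi_pos: int = 18
    n_healthy_plasma: int = 24
    patient_plasma: bool = True
    n_diff_tumor: int = 20
    tumor_shift: float = 0.4
    n_diff_mvi: int = 8
    mvi_shift: float = 0.3
    tumor_fraction: float = 0.3
    mean_depth: float = 30.0
    detect_prob: float = 0.95
    switch_rate: float = 0.05
    theta_low: float = 0.2
    theta_high: float = 0.8
    theta_jitter: float = 0.10
    hazard_mvi_neg: float = 0.03   # events per month
    hazard_mvi_pos: float = 0.12   # hazard ratio 4 by default
    censor_rate: float = 0.02
    cpg_spacing: int = 30
    block_gap: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_diff_tumor + self.n_diff_mvi > self.n_blocks:
            raise SchemaError("spiked block counts exceed n_blocks")
        if self.n_normal_tissue < 1 or self.n_tumor_mvi_neg + self.n_tumor_mvi_pos < 1:
            raise SchemaError("group sizes must be >= 1")
        if not 0 <= self.tumor_fraction <= 1:
            raise SchemaError("tumor_fraction must lie in [0, 1]")

    @property
    def n_tumor(self) -> int:
        return self.n_tumor_mvi_neg + self.n_tumor_mvi_pos

    @property
    def n_paired(self) -> int:
        return min(self.n_normal_tissue, self.n_tumor)


@dataclass
class SyntheticCohort:
    """In-memory cohort: site index, true block regions, per-sample haplotype
    tables, metadata, and the truth table of spiked differential blocks."""

    spec: CohortSpec
    seed: int
    index: CpGIndex
    regions: list[MHBRegion]
    haplotypes: dict[str, HaplotypeTable]
    metadata: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, str]:
        """Emit the full io file set; returns a name -> path mapping."""
        os.makedirs(outdir, exist_ok=True)
        hapdir = os.path.join(outdir, "haplotypes")
        os.makedirs(hapdir, exist_ok=True)
        paths = {
            "sites": os.path.join(outdir, "sites.tsv"),
            "regions": os.path.join(outdir, "regions.bed"),
            "metadata": os.path.join(outdir, "metadata.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "haplotypes": hapdir,
        }
        mio.write_sites(self.index, paths["sites"])
        mio.write_regions(self.regions, paths["regions"])
        mio.write_metadata(self.metadata, paths["metadata"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA",
                          float_format="%.10g")
        for sample, table in self.haplotypes.items():
            mio.write_haplotype_table(
                table, os.path.join(hapdir, f"{sample}.tsv"), self.index
            )
        return paths


def _shift_theta(theta: np.ndarray, shift: float) -> np.ndarray:
    """Shift towards the far side of 0.5 so values stay within [0, 1]."""
    return np.where(theta < 0.5, theta + shift, theta - shift)


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort; fully reproducible from ``seed`` (default spec.seed)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    l = spec.n_cpgs

    # --- genome layout: one chromosome, evenly spaced blocks -----------------
    block_span = (l - 1) * spec.cpg_spacing
    starts = np.arange(spec.n_blocks) * (block_span + spec.block_gap)
    positions = (starts[:, None] + np.arange(l)[None, :] * spec.cpg_spacing).ravel()
    index = CpGIndex({"chr1": positions})
    regions = [
        MHBRegion(
            f"mhb_{b:05d}", "chr1", b * l, l,
            int(positions[b * l]), int(positions[b * l + l - 1]) + 2,
        )
        for b in range(spec.n_blocks)
    ]

    # --- per-block group theta ----------------------------------------------
    base = rng.uniform(spec.theta_low, spec.theta_high, spec.n_blocks)
    perm = rng.permutation(spec.n_blocks)
    tumor_idx = np.sort(perm[: spec.n_diff_tumor])
    mvi_idx = np.sort(perm[spec.n_diff_tumor: spec.n_diff_tumor + spec.n_diff_mvi])
    theta_tumor = base.copy()
    theta_tumor[tumor_idx] = _shift_theta(base[tumor_idx], spec.tumor_shift)
    theta_mvi_pos = theta_tumor.copy()
    theta_mvi_pos[mvi_idx] = _shift_theta(theta_tumor[mvi_idx], spec.mvi_shift)

    truth_rows = []
    for b in tumor_idx:
        truth_rows.append(
            ("mhb_%05d" % b, "tumor",
             "hyper" if theta_tumor[b] > base[b] else "hypo",
             base[b], theta_tumor[b])
        )
    for b in mvi_idx:
        truth_rows.append(
            ("mhb_%05d" % b, "mvi",
             "hyper" if theta_mvi_pos[b] > theta_tumor[b] else "hypo",
             theta_tumor[b], theta_mvi_pos[b])
        )
    truth = pd.DataFrame(
        truth_rows, columns=["block_id", "role", "direction", "theta_base", "theta_case"]
    )

    # --- samples -------------------------------------------------------------
    normals = [f"N{k + 1:02d}" for k in range(spec.n_normal_tissue)]
    tumors = [f"T{k + 1:02d}" for k in range(spec.n_tumor)]
    mvi_pos = np.array([k >= spec.n_tumor_mvi_neg for k in range(spec.n_tumor)])
    healthy_p = [f"HP{k + 1:02d}" for k in range(spec.n_healthy_plasma)]
    patient_p = [f"PP{k + 1:02d}" for k in range(spec.n_tumor)] if spec.patient_plasma else []
    samples = normals + tumors + healthy_p + patient_p
    n_samp = len(samples)

    # Realised per-sample theta (group theta + biological jitter, clipped).
    def jit(group_theta: np.ndarray, n: int) -> np.ndarray:
        eps = rng.normal(0.0, spec.theta_jitter, size=(n, spec.n_blocks))
        return np.clip(group_theta[None, :] + eps, *_THETA_CLIP)

    th_norm = jit(base, spec.n_normal_tissue)
    th_tum = np.empty((spec.n_tumor, spec.n_blocks))
    th_tum[~mvi_pos] = jit(theta_tumor, spec.n_tumor_mvi_neg)
    th_tum[mvi_pos] = jit(theta_mvi_pos, spec.n_tumor_mvi_pos)
    th_hp = jit(base, spec.n_healthy_plasma)
    th_pp_bg = jit(base, spec.n_tumor) if spec.patient_plasma else np.empty((0, spec.n_blocks))

    # Primary (background) theta per sample; plasma patients also carry the
    # matched tumour's realised theta for the ctDNA component.
    th_primary = np.concatenate([th_norm, th_tum, th_hp, th_pp_bg], axis=0)
    pp_offset = spec.n_normal_tissue + spec.n_tumor + spec.n_healthy_plasma
    is_pp = np.zeros(n_samp, dtype=bool)
    is_pp[pp_offset:] = True

    # --- survival ------------------------------------------------------------
    haz = np.where(mvi_pos, spec.hazard_mvi_pos, spec.hazard_mvi_neg)
    t_event = rng.exponential(1.0 / haz)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n_tumor)
    else:
        t_cens = np.full(spec.n_tumor, np.inf)
    surv_time = np.minimum(t_event, t_cens)
    surv_event = np.where(t_event <= t_cens, "event", "censored")

    # --- reads ----------------------------------------------------------------
    rows: list[list] = [[] for _ in range(n_samp)]  # (block, codes, counts)
    key_base = 1 << l
    for b in range(spec.n_blocks):
        detected = rng.random(n_samp) < spec.detect_prob
        depth = rng.poisson(spec.mean_depth, n_samp) * detected
        n_ct = np.zeros(n_samp, dtype=np.int64)
        if spec.patient_plasma:
            n_ct[is_pp] = rng.binomial(depth[is_pp], spec.tumor_fraction)
        n_bg = depth - n_ct
        # per-read theta: ctDNA reads first (plasma patients), then background
        theta_read = np.concatenate([
            np.repeat(th_tum[:, b], n_ct[pp_offset:]) if spec.patient_plasma else np.empty(0),
            np.repeat(th_primary[:, b], n_bg),
        ])
        sample_of_read = np.concatenate([
            np.repeat(np.arange(pp_offset, n_samp), n_ct[pp_offset:])
            if spec.patient_plasma else np.empty(0, dtype=np.int64),
            np.repeat(np.arange(n_samp), n_bg),
        ]).astype(np.int64)
        if theta_read.size == 0:
            continue
        reads = _markov_reads(theta_read, spec.switch_rate, theta_read.size, l, rng)
        key = sample_of_read * key_base + _pack(reads)
        uniq, counts = np.unique(key, return_counts=True)
        s_idx = uniq // key_base
        codes = uniq % key_base
        for si in np.unique(s_idx):
            m = s_idx == si
            rows[si].append((b, codes[m], counts[m]))

    haplotypes: dict[str, HaplotypeTable] = {}
    for si, sample in enumerate(samples):
        if rows[si]:
            blocks = np.concatenate([np.full(c.size, b) for b, c, _ in rows[si]])
            codes = np.concatenate([c for _, c, _ in rows[si]])
            counts = np.concatenate([n for _, _, n in rows[si]])
        else:
            blocks = codes = counts = np.empty(0, dtype=np.int64)
        haplotypes[sample] = HaplotypeTable(
            ["chr1"],
            np.zeros(codes.size, dtype=np.int32),
            blocks * l,
            _unpack(codes, l) if codes.size else np.empty((0, l), np.int8),
            np.full(codes.size, l, dtype=np.int32),
            counts,
        )

    # --- metadata -------------------------------------------------------------
    meta_rows = []
    for k, s in enumerate(normals):
        pair = f"P{k + 1:02d}" if k < spec.n_paired else None
        meta_rows.append((s, "tissue", "normal", "not_applicable", pair, np.nan, "unknown"))
    for k, s in enumerate(tumors):
        pair = f"P{k + 1:02d}" if k < spec.n_paired else None
        meta_rows.append(
            (s, "tissue", "tumor", "positive" if mvi_pos[k] else "negative",
             pair, float(surv_time[k]), surv_event[k])
        )
    for s in healthy_p:
        meta_rows.append((s, "plasma", "healthy", "not_applicable", None, np.nan, "unknown"))
    for k, s in enumerate(patient_p):
        meta_rows.append(
            (s, "plasma", "tumor", "positive" if mvi_pos[k] else "negative",
             None, np.nan, "unknown")
        )
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "specimen", "tumor_status", "mvi_status",
                 "pair_id", "surv_time", "surv_event"],
    ).set_index("sample_id")

    return SyntheticCohort(spec, seed, index, regions, haplotypes, metadata, truth)


# ---------------------------------------------------------------------------
# Presets


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale default cohort (2,000 blocks, study-design group sizes)."""
    return CohortSpec(seed=seed, **overrides)


def marker_recovery_spec(seed: int = 0) -> CohortSpec:
    """Tissue-only cohort for marker-recovery checks: 2,000 blocks, 20 spiked
    tumour blocks with a 0.4 theta shift, 20 normals vs 20 tumours, depth 30."""
    return CohortSpec(
        seed=seed,
        n_normal_tissue=20,
        n_tumor_mvi_neg=10,
        n_tumor_mvi_pos=10,
        n_healthy_plasma=0,
        patient_plasma=False,
        n_diff_tumor=20,
        tumor_shift=0.4,
        n_diff_mvi=0,
    )


def strong_signal_spec(seed: int = 0) -> CohortSpec:
    """Well-separated cohort: theta shift 0.5 for tumour markers, 0.4 for MVI,
    depth 50, 800 blocks, plasma tumour fraction 0.3, MVI hazard ratio 4."""
    return CohortSpec(
        seed=seed,
        n_blocks=800,
        n_diff_tumor=20,
        tumor_shift=0.5,
        n_diff_mvi=8,
        mvi_shift=0.4,
        mean_depth=50.0,
    )


def demo_spec(seed: int = 0) -> CohortSpec:
    """Small fast cohort for smoke tests and pipeline demonstrations."""
    return CohortSpec(
        seed=seed,
        n_blocks=250,
        n_normal_tissue=16,
        n_tumor_mvi_neg=8,
        n_tumor_mvi_pos=8,
        n_healthy_plasma=8,
        n_diff_tumor=6,
        tumor_shift=0.5,
        n_diff_mvi=5,
        mvi_shift=0.5,
        mean_depth=40.0,
    )


def cohort_spec_from_dict(d: Mapping) -> CohortSpec:
    return CohortSpec(**dict(d))


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
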