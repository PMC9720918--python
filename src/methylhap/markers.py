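"""Differential-marker selection: filter cascade, rank tests, FDR control.

The cascade keeps samples with enough detected blocks, then blocks detected in
enough of the retained samples with enough variability, then tests each block
between two groups (unpaired rank-sum, or signed-rank on matched tumour /
peritumoral-normal pairs) and controls the FDR with Benjamini-Hochberg.

One-sided testing is run in *both* directions with FDR control within each
direction (hyper- and hypo-methylated marker families), rather than choosing
the direction from the observed shift, which would double-dip.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyCohortError,
    PairingError,
    SchemaError,
    UndefinedTestError,
)
from .records import ScoreMatrix

_SD_TOL = 1e-12  # "no less than" thresholds are inclusive up to float rounding


@dataclass
class FilterConfig:
    """Marker-selection configuration.

    ``min_detected_per_sample`` scales with the size of the region catalogue
    (the study-scale value is 25,000 of 225,025 regions, about 11%);
    :func:`scaled_min_detected` applies that proportion to a smaller catalogue.
    """

    min_detected_per_sample: int = 0
    min_detection_fraction: float = 2.0 / 3.0
    min_sd: float = 0.02
    fdr_threshold: float = 0.05
    test: str = "rank_sum"           # or "signed_rank"
    alternative: str = "both"        # greater | less | two_sided | both

    def __post_init__(self):
        if not 0 < self.min_detection_fraction <= 1:
            raise SchemaError("min_detection_fraction must lie in (0, 1]")
        if not 0 < self.fdr_threshold < 1:
            raise SchemaError("fdr_threshold must lie in (0, 1)")
        if self.test not in ("rank_sum", "signed_rank"):
            raise SchemaError("test must be rank_sum or signed_rank")
        if self.alternative not in ("greater", "less", "two_sided", "both"):
            raise SchemaError("invalid alternative")


STUDY_DETECTION_FLOOR = 25000 / 225025  # detected-MHB sample floor, as a fraction


def scaled_min_detected(n_blocks: int) -> int:
    """Sample detection floor proportional to the study-scale 25,000/225,025."""
    return int(round(STUDY_DETECTION_FLOOR * n_blocks))


# ---------------------------------------------------------------------------
# Filters


def filter_samples(matrix: ScoreMatrix, min_detected_per_sample: int) -> list[str]:
    """Samples with at least the threshold number of detected (non-NaN) blocks."""
    detected = matrix.data.notna().sum(axis=1)
    kept = [s for s, n in detected.items() if n >= min_detected_per_sample]
    if not kept:
        raise EmptyCohortError("no sample passes the detection floor")
    return kept


def filter_blocks(
    matrix: ScoreMatrix,
    min_detection_fraction: float = 2.0 / 3.0,
    min_sd: float = 0.02,
) -> list[str]:
    """Blocks detected in enough samples with cross-sample SD above the floor.

    Both thresholds are inclusive; SD uses the n-1 denominator.
    """
    data = matrix.data
    frac = data.notna().mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    keep = (frac >= min_detection_fraction - _SD_TOL) & (sd >= min_sd - _SD_TOL)
    return [m for m in data.columns[keep.fillna(False)]]


# ---------------------------------------------------------------------------
# Tests


def wilcoxon_rank_sum(
    case: Sequence[float], control: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U of the case group) with mid-ranks.

    Exact p for small untied samples, normal approximation with tie and
    continuity correction otherwise.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if case.size == 0 or control.size == 0:
        raise UndefinedTestError("rank-sum test needs data in both groups")
    alt = "two-sided" if alternative == "two_sided" else alternative
    res = stats.mannwhitneyu(case, control, alternative=alt, method="auto")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    case: Sequence[float], control: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Paired signed-rank test; zero differences dropped; exact p for small
    untied samples, normal approximation otherwise."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape != control.shape:
        raise SchemaError("paired samples must have equal length")
    ok = ~(np.isnan(case) | np.isnan(control))
    diffs = case[ok] - control[ok]
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise UndefinedTestError("all paired differences are zero or missing")
    alt = "two-sided" if alternative == "two_sided" else alternative
    res = stats.wilcoxon(diffs, alternative=alt, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SchemaError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Marker selection


def contrast_groups(metadata: pd.DataFrame, contrast: str) -> tuple[list[str], list[str]]:
    """(case, control) sample ids for a named contrast on tissue samples.

    ``tumor_vs_normal``: tumour tissue vs normal tissue.
    ``mvi``: MVI+ tumour tissue vs MVI- tumour tissue.
    """
    tissue = metadata[metadata["specimen"] == "tissue"]
    if contrast == "tumor_vs_normal":
        case = tissue.index[tissue["tumor_status"] == "tumor"]
        control = tissue.index[tissue["tumor_status"] == "normal"]
    elif contrast == "mvi":
        tum = tissue[tissue["tumor_status"] == "tumor"]
        case = tum.index[tum["mvi_status"] == "positive"]
        control = tum.index[tum["mvi_status"] == "negative"]
    else:
        raise SchemaError(f"unknown contrast {contrast!r}")
    return list(case), list(control)


def _matched_pairs(metadata: pd.DataFrame) -> list[tuple[str, str]]:
    """(tumor_id, normal_id) tissue pairs from pair_id."""
    tissue = metadata[metadata["specimen"] == "tissue"].dropna(subset=["pair_id"])
    pairs = []
    for pid, grp in tissue.groupby("pair_id"):
        tum = grp.index[grp["tumor_status"] == "tumor"]
        nor = grp.index[grp["tumor_status"] == "normal"]
        if len(tum) != 1 or len(nor) != 1:
            raise PairingError(f"pair {pid!r} is not a tumor/normal tissue pair")
        pairs.append((tum[0], nor[0]))
    if not pairs:
        raise PairingError("paired test requested but no pair_id in metadata")
    return sorted(pairs)


def _test_blocks(
    data: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    config: FilterConfig,
    alternative: str,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    stats_, ps, ids = [], [], []
    if config.test == "signed_rank":
        pairs = [
            (t, n) for t, n in _matched_pairs(metadata)
            if t in data.index and n in data.index
        ]
        if not pairs:
            raise PairingError("no matched pairs present in the score matrix")
        case_m = data.loc[[t for t, _ in pairs]].to_numpy()
        ctrl_m = data.loc[[n for _, n in pairs]].to_numpy()
    else:
        case_m = data.loc[case_ids].to_numpy()
        ctrl_m = data.loc[control_ids].to_numpy()
    for j, mhb in enumerate(data.columns):
        try:
            if config.test == "signed_rank":
                s, p = wilcoxon_signed_rank(case_m[:, j], ctrl_m[:, j], alternative)
            else:
                s, p = wilcoxon_rank_sum(case_m[:, j], ctrl_m[:, j], alternative)
        except UndefinedTestError:
            continue
        ids.append(mhb)
        stats_.append(s)
        ps.append(p)
    out = pd.DataFrame({"mhb_id": ids, "statistic": stats_, "p_value": ps})
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out


def select_markers(
    matrices: ScoreMatrix | Mapping[str, ScoreMatrix],
    metadata: pd.DataFrame,
    config: FilterConfig,
    contrast: str = "tumor_vs_normal",
) -> pd.DataFrame:
    """Run the filter cascade and tests; return the retained marker set.

    When several score matrices are supplied (e.g. MHL and UMHL), each is
    filtered and tested independently, FDR control is applied within each
    (score kind, direction) family, and the marker sets are concatenated with
    a ``score_kind`` tag.

    Returns a frame with columns ``mhb_id, score_kind, direction, statistic,
    p_value, q_value`` containing only markers with ``q_value`` below the
    configured FDR threshold.
    """
    if isinstance(matrices, ScoreMatrix):
        matrices = {matrices.score_kind: matrices}
    case_ids, control_ids = contrast_groups(metadata, contrast)
    if not case_ids or not control_ids:
        raise EmptyCohortError(f"contrast {contrast!r} has an empty group")
    directions = (
        [("greater", "hyper"), ("less", "hypo")]
        if config.alternative == "both"
        else [(config.alternative,
               {"greater": "hyper", "less": "hypo", "two_sided": "either"}[config.alternative])]
    )
    results = []
    for kind, matrix in matrices.items():
        kept_samples = filter_samples(matrix, config.min_detected_per_sample)
        group_samples = [s for s in kept_samples if s in set(case_ids) | set(control_ids)]
        if not group_samples:
            raise EmptyCohortError("no contrast sample passes the detection floor")
        sub = ScoreMatrix(matrix.data.loc[group_samples], matrix.score_kind)
        kept_blocks = filter_blocks(sub, config.min_detection_fraction, config.min_sd)
        data = sub.data[kept_blocks]
        case_kept = [s for s in case_ids if s in data.index]
        ctrl_kept = [s for s in control_ids if s in data.index]
        for alternative, direction in directions:
            res = _test_blocks(data, case_kept, ctrl_kept, config, alternative, metadata)
            res["score_kind"] = kind
            res["direction"] = direction
            results.append(res[res["q_value"] < config.fdr_threshold])
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    cols = ["mhb_id", "score_kind", "direction", "statistic", "p_value", "q_value"]
    if len(out) == 0:
        return pd.DataFrame(columns=cols)
    return out[cols].sort_values(["score_kind", "q_value", "mhb_id"]).reset_index(drop=True)


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
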