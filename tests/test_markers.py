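import numpy as np
import pandas as pd
import pytest

import methylhap as mh
from methylhap.errors import EmptyCohortError, SchemaError, UndefinedTestError
from methylhap.markers import FilterConfig, scaled_min_detected, select_markers
from methylhap.records import ScoreMatrix
from tests._oracles import bh_stepup, ranksum_exact_p, signrank_exact_p


def _matrix(values, samples, blocks, kind="MHL"):
    return ScoreMatrix(pd.DataFrame(values, index=samples, columns=blocks), kind)


def test_sample_detection_floor():
    m = _matrix(
        [[0.1, 0.2, np.nan, np.nan, np.nan],
         [0.1, 0.2, 0.3, 0.4, np.nan],
         [0.1, 0.2, 0.3, 0.4, 0.5]],
        ["a", "b", "c"], list("vwxyz"),
    )
    assert mh.filter_samples(m, 5) == ["c"]
    assert mh.filter_samples(m, 4) == ["b", "c"]
    assert mh.filter_samples(m, 0) == ["a", "b", "c"]
    with pytest.raises(EmptyCohortError):
        mh.filter_samples(m, 6)


def test_block_filters_are_inclusive():
    m = _matrix(
        [[0.10, 0.5, 0.10, np.nan],
         [0.12, 0.5, 0.20, np.nan],
         [0.14, 0.5, np.nan, 0.2]],
        ["a", "b", "c"], ["sd_exact", "constant", "two_thirds", "rare"],
    )
    kept = mh.filter_blocks(m, min_detection_fraction=2 / 3, min_sd=0.02)
    # sd of {0.10,0.12,0.14} is exactly 0.02 ("no less than" is inclusive);
    # detection 2/3 is inclusive; constant blocks and rare blocks drop
    assert kept == ["sd_exact", "two_thirds"]


def test_rank_sum_exact_and_degenerate_cases():
    stat, p = mh.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less")
    assert p == pytest.approx(1 / 20, abs=1e-12)
    _, p_same = mh.wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0], "two_sided")
    assert p_same == pytest.approx(1.0)
    with pytest.raises(UndefinedTestError):
        mh.wilcoxon_rank_sum([], [1.0], "less")


def test_rank_sum_matches_permutation_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n, m = rng.integers(3, 8, 2)
        case = rng.normal(size=n)
        control = rng.normal(size=m)
        for alt in ("greater", "less"):
            _, p = mh.wilcoxon_rank_sum(case, control, alt)
            assert p == pytest.approx(ranksum_exact_p(case, control, alt), abs=1e-12)


def test_signed_rank_exact_and_degenerate_cases():
    case = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
    control = case - 1.0
    _, p = mh.wilcoxon_signed_rank(case, control, "greater")
    assert p == pytest.approx(1 / 32, abs=1e-12)
    with pytest.raises(UndefinedTestError):
        mh.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0], "greater")


def test_signed_rank_matches_sign_flip_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(15):
        n = int(rng.integers(4, 9))
        diffs = rng.normal(size=n)
        case = np.abs(diffs) + diffs
        control = np.abs(diffs)
        for alt in ("greater", "less"):
            _, p = mh.wilcoxon_signed_rank(case, control, alt)
            assert p == pytest.approx(signrank_exact_p(diffs, alt), abs=1e-12)


def test_bh_worked_example_and_oracle_agreement():
    np.testing.assert_allclose(
        mh.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
    )
    assert mh.benjamini_hochberg([0.2]) == pytest.approx([0.2])
    rng = np.random.default_rng(9)
    for _ in range(30):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(
            mh.benjamini_hochberg(p), bh_stepup(p), atol=1e-12
        )
    with pytest.raises(SchemaError):
        mh.benjamini_hochberg([0.5, 1.5])


def test_bh_is_monotone_in_raw_p():
    rng = np.random.default_rng(10)
    p = np.sort(rng.uniform(size=50))
    q = mh.benjamini_hochberg(p)
    assert np.all(np.diff(q) >= -1e-15)
    assert np.all(q >= p - 1e-15)


def _toy_cohort(rng, n_per_group=12, n_blocks=60, n_spiked=6, shift=0.35):
    samples = [f"N{i}" for i in range(n_per_group)] + [f"T{i}" for i in range(n_per_group)]
    base = rng.uniform(0.2, 0.6, n_blocks)
    vals = np.clip(rng.normal(base, 0.05, (2 * n_per_group, n_blocks)), 0, 1)
    vals[n_per_group:, :n_spiked] = np.clip(
        rng.normal(base[:n_spiked] + shift, 0.05, (n_per_group, n_spiked)), 0, 1
    )
    meta = pd.DataFrame(
        {
            "specimen": "tissue",
            "tumor_status": ["normal"] * n_per_group + ["tumor"] * n_per_group,
            "mvi_status": "not_applicable",
            "pair_id": None,
            "surv_time": np.nan,
            "surv_event": "unknown",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    meta.loc[meta.tumor_status == "tumor", "mvi_status"] = "negative"
    blocks = [f"mhb_{j:03d}" for j in range(n_blocks)]
    return _matrix(vals, samples, blocks), meta, blocks[:n_spiked]


def test_one_sided_direction_separates_hyper_from_hypo():
    rng = np.random.default_rng(12)
    matrix, meta, spiked = _toy_cohort(rng)
    cfg = FilterConfig(alternative="greater", fdr_threshold=0.05)
    markers = select_markers(matrix, meta, cfg, "tumor_vs_normal")
    assert set(markers["mhb_id"]) >= set(spiked)
    assert (markers["direction"] == "hyper").all()
    cfg_down = FilterConfig(alternative="less", fdr_threshold=0.05)
    down = select_markers(matrix, meta, cfg_down, "tumor_vs_normal")
    assert not set(down["mhb_id"]) & set(spiked)


def test_null_cohort_selects_almost_nothing():
    rng = np.random.default_rng(13)
    selected = 0
    tested = 0
    for _ in range(10):
        matrix, meta, _ = _toy_cohort(rng, n_spiked=0)
        markers = select_markers(matrix, meta, FilterConfig(), "tumor_vs_normal")
        selected += len(markers)
        tested += matrix.data.shape[1]
    # BH keeps the expected null selection fraction below the FDR threshold
    assert selected / tested <= 0.05


def test_filter_cascade_matches_joint_application():
    rng = np.random.default_rng(14)
    matrix, meta, _ = _toy_cohort(rng)
    matrix.data.iloc[0, :30] = np.nan
    cfg = FilterConfig(min_detected_per_sample=40)
    kept_samples = mh.filter_samples(matrix, cfg.min_detected_per_sample)
    sub = ScoreMatrix(matrix.data.loc[kept_samples], "MHL")
    sequential = mh.filter_blocks(sub, cfg.min_detection_fraction, cfg.min_sd)
    joint = [
        b for b in matrix.data.columns
        if sub.data[b].notna().mean() >= cfg.min_detection_fraction - 1e-12
        and sub.data[b].std(ddof=1) >= cfg.min_sd - 1e-12
    ]
    assert sequential == joint


def test_scaled_detection_floor_tracks_study_proportion():
    assert scaled_min_detected(225025) == 25000
    assert scaled_min_detected(2000) == round(2000 * 25000 / 225025)
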