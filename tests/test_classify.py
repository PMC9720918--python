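import numpy as np
import pandas as pd
import pytest

import methylhap as mh
from methylhap.classify import FittedModel, fit_model
from methylhap.errors import EmptyCohortError, SchemaError, StratificationError
from tests._oracles import auc_paircount


def test_auc_degenerate_cases_and_pair_counting():
    assert mh.auc([0, 1, 0, 1], [False, True, False, True]) == 1.0
    assert mh.auc([0.5] * 6, [True, False] * 3) == 0.5
    scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.1]
    labels = [True, True, False, True, False, False]
    assert mh.auc(scores, labels) == pytest.approx(
        auc_paircount(scores, labels), abs=1e-12
    )
    with pytest.raises(EmptyCohortError):
        mh.auc([0.1, 0.2], [True, True])


def test_roc_trapezoid_equals_rank_auc_on_random_inputs():
    rng = np.random.default_rng(21)
    for _ in range(20):
        n = int(rng.integers(6, 40))
        scores = np.round(rng.uniform(size=n), 2)  # force some ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        pts = mh.roc_points(scores, labels)
        trap = float(np.trapezoid(pts["tpr"], pts["fpr"]))
        assert trap == pytest.approx(auc_paircount(scores, labels), abs=1e-12)


def test_auc_confidence_interval_formula():
    mean, lo, hi = mh.auc_confidence_interval([0.9, 1.0])
    sd = np.std([0.9, 1.0], ddof=1)
    assert mean == pytest.approx(0.95)
    assert hi - mean == pytest.approx(min(1.0, 0.95 + 1.96 * sd / np.sqrt(2)) - 0.95)
    flat = mh.auc_confidence_interval([0.8, 0.8, 0.8])
    assert flat == pytest.approx((0.8, 0.8, 0.8), abs=1e-12)
    with pytest.raises(SchemaError):
        mh.auc_confidence_interval([0.9])


def _separable_features(rng, n=30, p=8, shift=3.0):
    X = rng.normal(size=(n, p))
    y = np.arange(n) % 2 == 0
    X[y] += shift
    feats = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
    feats.columns = [f"f{j}" for j in range(p)]
    labels = pd.Series(np.where(y, "case", "control"), index=feats.index)
    return feats, labels


def test_cross_validation_is_deterministic_and_separates_classes():
    rng = np.random.default_rng(31)
    feats, labels = _separable_features(rng)
    cfg = mh.ModelConfig(n_trees=60, seed=5)
    a = mh.cross_validate(feats, labels, cfg, positive_label="case")
    b = mh.cross_validate(feats, labels, cfg, positive_label="case")
    pd.testing.assert_frame_equal(a.oof_scores, b.oof_scores)
    pd.testing.assert_frame_equal(a.fold_assignments, b.fold_assignments)
    assert a.mean_auc == b.mean_auc
    assert a.mean_auc >= 0.95
    assert a.oof_scores.notna().all().all()  # every sample scored each repeat


def test_stratification_guard():
    rng = np.random.default_rng(32)
    feats, labels = _separable_features(rng, n=8)
    labels.iloc[:] = ["case"] * 2 + ["control"] * 6
    with pytest.raises(StratificationError):
        mh.cross_validate(feats, labels, mh.ModelConfig(k_folds=3), "case")


def test_svm_alternative_model_runs():
    rng = np.random.default_rng(33)
    feats, labels = _separable_features(rng, n=24, p=4)
    cfg = mh.ModelConfig(model="svm_rbf", n_repeats=2, seed=1)
    cv = mh.cross_validate(feats, labels, cfg, positive_label="case")
    assert cv.mean_auc >= 0.9


def test_transfer_identity_and_missing_column_error():
    rng = np.random.default_rng(34)
    feats, labels = _separable_features(rng, n=20, p=5)
    model = fit_model(feats, labels, mh.ModelConfig(n_trees=60, seed=2), "case")
    assert isinstance(model, FittedModel)
    same = mh.transfer_predict(model, feats)
    again = mh.transfer_predict(model, feats)
    pd.testing.assert_series_equal(same, again)
    assert mh.auc(same, labels == "case") == 1.0
    with pytest.raises(SchemaError):
        mh.transfer_predict(model, feats.drop(columns=["f0"]))


def test_missing_values_imputed_from_control_background():
    rng = np.random.default_rng(35)
    feats, labels = _separable_features(rng, n=20, p=5, shift=4.0)
    model = fit_model(feats, labels, mh.ModelConfig(n_trees=60, seed=2), "case")
    holey = feats.copy()
    holey.iloc[0, 0] = np.nan
    scores = mh.transfer_predict(model, holey)
    assert np.isfinite(scores).all()
    # control medians sit far below the case cloud, so a control sample with a
    # missing cell must not drift towards the positive class
    control_like = pd.DataFrame(
        [[np.nan] * 5], columns=feats.columns, index=["new"]
    )
    assert mh.transfer_predict(model, control_like).iloc[0] < 0.5


def test_mvi_hard_calls_partition_samples(strong_cohort, strong_markers):
    cohort, matrices = strong_cohort
    _, mvi = strong_markers
    meta = cohort.metadata
    tumors = meta[(meta.specimen == "tissue") & (meta.tumor_status == "tumor")]
    cols = []
    for kind in ("MHL", "UMHL"):
        ids = mvi.loc[mvi.score_kind == kind, "mhb_id"].unique()
        sub = matrices[kind].data.loc[tumors.index, list(ids)]
        sub.columns = [f"{kind}:{c}" for c in sub.columns]
        cols.append(sub)
    feats = pd.concat(cols, axis=1)
    cv, calls = mh.predict_mvi(feats, tumors["mvi_status"], mh.ModelConfig(seed=3))
    assert cv.mean_auc > 0.75
    assert set(calls.unique()) == {"positive", "negative"}
    acc = (calls == tumors["mvi_status"]).mean()
    assert acc > 0.8


def test_unsupervised_views_separate_shifted_clouds():
    rng = np.random.default_rng(36)
    X = rng.normal(size=(16, 40))
    X[:8] += 4.0
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(16)])
    df.columns = [f"m{j}" for j in range(40)]
    views = mh.unsupervised_views(df, top_k=20)
    pc1 = views.pc_scores["PC1"]
    assert (pc1[:8].min() > pc1[8:].max()) or (pc1[:8].max() < pc1[8:].min())
    assert views.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
    assert len(views.block_ids) == 20
    # duplicated samples end up at zero cophenetic distance
    dup = pd.concat([df.iloc[:4], df.iloc[:4]])
    dup.index = [f"d{i}" for i in range(8)]
    v2 = mh.unsupervised_views(dup, top_k=10)
    merged_at_zero = v2.linkage_matrix[v2.linkage_matrix[:, 2] < 1e-12]
    assert len(merged_at_zero) >= 4
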