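"""Splits, classifier, statistics, protocol bookkeeping and diagnostics."""

import copy

import numpy as np
import pytest
from scipy import stats as sstats

from emg_swn import (
    Cohort,
    EmgRecording,
    MotionRecording,
    ProtocolRunner,
    SplitSpec,
    SubjectProfile,
    Trial,
    accuracy,
    compare_groups,
    forward_kinematics,
    sd_feature_correlation,
    mean_sd_feature_correlation,
    split_trials,
    summarize,
    sweep_subject_counts,
    train_classifier,
)
from emg_swn.pipeline import result_digest
from emg_swn.records import SubjectData


def test_split_blocks_stay_together():
    train, test = split_trials(360, SplitSpec(seed=3))
    assert len(train) == len(test) == 180
    assert set(train) | set(test) == set(range(360))
    for ids in (train, test):
        blocks = np.unique(ids // 10)
        assert sorted(ids) == sorted(
            t for b in blocks for t in range(10 * b, 10 * b + 10)
        )


def test_split_deterministic_and_validating():
    a = split_trials(40, SplitSpec(seed=9))
    b = split_trials(40, SplitSpec(seed=9))
    assert np.array_equal(a[0], b[0])
    c = split_trials(40, SplitSpec(seed=10))
    assert not np.array_equal(a[0], c[0])
    with pytest.raises(ValueError, match="divisible"):
        split_trials(35, SplitSpec())


def test_classifier_fits_separable_three_class_data(rng):
    X = np.concatenate([rng.normal(c * 10, 0.5, (50, 4)) for c in range(3)])
    y = np.repeat([0, 1, 2], 50)
    clf = train_classifier(X, y)
    assert accuracy(clf.predict(X), y) == 100.0


def test_classifier_rejects_degenerate_input(rng):
    with pytest.raises(ValueError, match="single class"):
        train_classifier(rng.standard_normal((10, 2)), np.zeros(10))
    X = rng.standard_normal((10, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        train_classifier(X, np.repeat([0, 1], 5))


def test_duplicating_training_rows_leaves_predictions_unchanged(rng):
    X = np.concatenate([rng.normal(c * 8, 1.0, (40, 3)) for c in range(3)])
    y = np.repeat([0, 1, 2], 40)
    X_test = rng.standard_normal((60, 3)) * 6
    p1 = train_classifier(X, y).predict(X_test)
    p2 = train_classifier(np.vstack([X, X]), np.concatenate([y, y])).predict(X_test)
    assert np.array_equal(p1, p2)


def test_accuracy_arithmetic():
    assert accuracy(np.array([0, 1, 1]), np.array([0, 1, 2])) == pytest.approx(66.667, abs=0.01)
    assert accuracy(np.array([2, 2]), np.array([2, 2])) == 100.0
    truth = np.repeat([0, 1, 2], 10)
    assert accuracy(np.zeros(30), truth) == pytest.approx(33.333, abs=0.01)
    with pytest.raises(ValueError):
        accuracy(np.array([]), np.array([]))


def test_compare_groups_identical_and_bonferroni(rng):
    a = rng.standard_normal(10)
    p, p_adj = compare_groups(a, a.copy(), n_comparisons=5)
    assert p > 0.05
    assert p_adj == pytest.approx(min(1.0, p * 5))


def test_compare_groups_matches_closed_form_rank_sum():
    """Disjoint groups: p equals the asymptotic rank-sum formula by hand."""
    a = np.arange(1, 11, dtype=float)
    b = np.arange(11, 21, dtype=float)
    p, _ = compare_groups(a, b)
    n = m = 10
    w = np.sum(np.arange(1, 11))  # ranks of group a in the pooled sample
    z = (w - n * (n + m + 1) / 2.0) / np.sqrt(n * m * (n + m + 1) / 12.0)
    expected = 2.0 * sstats.norm.sf(abs(z))
    assert p == pytest.approx(expected, rel=1e-10)
    # the exact-enumeration option: complete separation tail 2/C(20,10)
    p_exact, _ = compare_groups(a, b, exact=True)
    from math import comb

    assert p_exact == pytest.approx(2.0 / comb(20, 10), rel=1e-9)


@pytest.fixture(scope="module")
def tiny_runner(tiny_pre_cohort):
    return ProtocolRunner(tiny_pre_cohort, split_spec=SplitSpec(seed=5))


def test_protocol_bookkeeping(tiny_runner):
    res = tiny_runner.run(
        methods=("swn", "none"), model_types=("OWN", "OTHER"),
        n_train_subjects=2, combo_cap=1, seed=5,
    )
    # every (method x model_type x subject) cell present
    cells = res.groupby(["method", "model_type"])["test_subject"].nunique()
    assert (cells == 3).all()
    assert res["accuracy"].between(0, 100).all()
    s = summarize(res)
    assert len(s) == 4


def test_other_excludes_held_out_subject(tiny_runner):
    res = tiny_runner.run(methods=("none",), model_types=("OTHER",),
                          n_train_subjects=2, seed=5)
    for _, row in res.iterrows():
        assert str(row.test_subject) not in row.combo_id.split("+")


def test_protocol_deterministic(tiny_pre_cohort):
    kw = dict(methods=("none",), model_types=("OWN",), seed=5)
    r1 = ProtocolRunner(tiny_pre_cohort, split_spec=SplitSpec(seed=5)).run(**kw)
    r2 = ProtocolRunner(tiny_pre_cohort, split_spec=SplitSpec(seed=5)).run(**kw)
    assert result_digest(r1) == result_digest(r2)


def test_zscore_stats_ignore_test_split(tiny_pre_cohort):
    """Calibration statistics must not see test-split samples."""
    runner = ProtocolRunner(tiny_pre_cohort, split_spec=SplitSpec(seed=5))
    stats0 = runner.zscore_stats(0)
    corrupted = copy.deepcopy(tiny_pre_cohort)
    _, test_ids = runner.splits[0]
    for i in test_ids:
        corrupted.subjects[0].trials[i].emg.samples[:] *= 100.0
    runner2 = ProtocolRunner(corrupted, split_spec=SplitSpec(seed=5))
    stats1 = runner2.zscore_stats(0)
    assert np.array_equal(stats0.mean, stats1.mean)
    assert np.array_equal(stats0.std, stats1.std)


def test_sweep_produces_one_summary_row_per_k(tiny_pre_cohort):
    res = sweep_subject_counts(
        tiny_pre_cohort, ks=(1, 2), methods=("none",), combo_cap=1,
        split_spec=SplitSpec(seed=5), seed=5,
    )
    s = summarize(res)
    assert len(s) == 2
    assert set(s["n_train_subjects"]) == {1, 2}


def test_best_over_grid_selection_rules():
    import pandas as pd

    from emg_swn import best_over_grid

    rows = []
    # subject 0 peaks at 100 ms, subject 1 at 500 ms: per-subject max differs
    # from the max of the group mean
    for subj, accs in ((0, {100.0: 80.0, 500.0: 60.0}), (1, {100.0: 50.0, 500.0: 75.0})):
        for lf, acc in accs.items():
            rows.append(
                dict(test_subject=subj, model_type="OWN", method="swn",
                     l_norm_ms=500.0, l_feature_ms=lf, feature="ALL",
                     n_train_subjects=np.nan, combo_id="own", accuracy=acc)
            )
    df = pd.DataFrame(rows)
    per_subject = best_over_grid(df, per_subject=True)
    assert per_subject["mean_accuracy"].iloc[0] == pytest.approx((80.0 + 75.0) / 2)
    group = best_over_grid(df, per_subject=False)
    assert group["mean_accuracy"].iloc[0] == pytest.approx(67.5)  # best group-mean cell
    assert group["l_feature_ms"].iloc[0] == 500.0


def _proportional_envelope_cohort():
    """Signal whose windowed SD is proportional to its MAV by construction."""
    rng = np.random.default_rng(7)
    fs, n = 500.0, 2300
    t = np.arange(n) / fs
    env = 1.5 + np.sin(2 * np.pi * 0.4 * t)  # slow positive envelope
    profile = SubjectProfile(
        subject_id=0, channel_gains=np.ones(2),
        channel_roles=("flexor", "extensor"), l_upper=0.3, l_fore=0.26,
    )
    elbow, hand = forward_kinematics(np.full(n, 90.0), np.full(n, 70.0), 0.3, 0.26)
    motion = MotionRecording(hand=hand, elbow=elbow, shoulder=np.zeros((2, n)),
                             fs=fs, l_upper=0.3, l_fore=0.26)
    trials = []
    for _ in range(10):
        x = env * rng.standard_normal((2, n))
        rec = EmgRecording(x, fs=fs, stage="preprocessed")
        trials.append(Trial(emg=rec, motion=motion))
    return Cohort(config=None, subjects=[SubjectData(profile=profile, trials=trials)])


def test_sd_mav_correlation_is_one_for_proportional_series():
    cohort = _proportional_envelope_cohort()
    corr = sd_feature_correlation(cohort)
    means = mean_sd_feature_correlation(corr)
    assert means["none"] > 0.99
    # SWN flattens the envelope: the correlation collapses
    assert abs(means["swn"]) < 0.5
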