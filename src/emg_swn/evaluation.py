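"""OWN/OTHER evaluation protocol, classifier, sweeps and diagnostics.

The experimental harness asks one question: how well does a multinomial
logistic-regression classifier decode rest/flexion/extension from windowed
EMG features, when trained on the test subject's own data (model type
``OWN``) versus exclusively on other subjects' data (``OTHER``), under
each normalization method? Trials are split 1:1 into train/test by
randomly assigning consecutive blocks of 10 trials. For ``OTHER`` with
``k`` training subjects, every combination of ``k`` of the remaining
subjects is evaluated (optionally a seeded subsample capped by
``combo_cap``); the held-out subject never contributes training rows.

Z-score statistics are per subject from that subject's *training split
only* — for the held-out subject this is exactly the calibration
measurement that sliding-window normalization is designed to remove.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .features import FeatureSpec, assemble_features, feature_sample_indices, _trailing_windows
from .kinematics import labels_from_motion
from .normalization import (
    NormalizationSpec,
    ZScoreStats,
    compute_zscore_stats,
    normalize,
)
from .preprocessing import preprocess_emg
from .records import Cohort, EmgRecording

MAX_ITER = 6000


@dataclass(frozen=True)
class SplitSpec:
    """Block-random 1:1 train/test split parameters."""

    block_size: int = 10
    train_fraction: float = 0.5
    seed: int = 0


def split_trials(n_trials: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole blocks of consecutive trials to train or test.

    Deterministic given ``spec.seed``; exactly
    ``round(n_blocks * train_fraction)`` blocks go to train.
    """
    if n_trials % spec.block_size != 0:
        raise ValueError(
            f"{n_trials} trials not divisible by block size {spec.block_size}"
        )
    n_blocks = n_trials // spec.block_size
    n_train = int(round(n_blocks * spec.train_fraction))
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_blocks)
    train_blocks = np.sort(order[:n_train])
    test_blocks = np.sort(order[n_train:])
    expand = lambda blocks: np.concatenate(
        [np.arange(b * spec.block_size, (b + 1) * spec.block_size) for b in blocks]
    ) if len(blocks) else np.empty(0, dtype=int)
    return expand(train_blocks), expand(test_blocks)


def train_classifier(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unregularized multinomial logistic regression, class-balanced.

    ``C=inf`` is the unpenalized fit; iteration cap 6000.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    clf = LogisticRegression(C=np.inf, class_weight="balanced", max_iter=MAX_ITER)
    clf.fit(X, y)
    return clf


def accuracy(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Percent correct: 100 x successes / (successes + failures)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and nonempty")
    return 100.0 * float(np.mean(predictions == truth))


def compare_groups(
    accuracies_a,
    accuracies_b,
    n_comparisons: int = 1,
    exact: bool = False,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p-value with Bonferroni adjustment.

    The default is the asymptotic rank-sum test (``scipy.stats.ranksums``);
    ``exact=True`` switches to the exact Mann-Whitney null distribution.
    Returns ``(p_raw, p_adjusted)`` with ``p_adjusted = min(1, p * n)``.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    if exact:
        p = float(sstats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(sstats.ranksums(a, b).pvalue)
    _, p_adj, _, _ = multipletests([p] * n_comparisons, method="bonferroni")
    return p, float(p_adj[0])


# ---------------------------------------------------------------------------
# feature-table preparation


@dataclass
class SubjectTable:
    """Stacked per-row features/labels for one subject, one configuration."""

    X: np.ndarray
    y: np.ndarray
    trial_id: np.ndarray

    def rows_for(self, trial_ids: np.ndarray) -> np.ndarray:
        return np.isin(self.trial_id, trial_ids)


class ProtocolRunner:
    """Caches the heavy per-configuration work behind the protocol ops.

    Preprocesses each trial once, derives 20 Hz labels once, and builds
    per-(method, L_norm, L_feature) feature tables on demand. All
    randomness (splits, combination subsampling) is seeded.
    """

    def __init__(
        self,
        cohort: Cohort,
        split_spec: SplitSpec = SplitSpec(),
        feature: str = "ALL",
    ) -> None:
        self.cohort = cohort
        self.feature = feature
        self.n_subjects = cohort.n_subjects
        self.splits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._pre: dict[int, list[EmgRecording]] = {}
        self._labels: dict[int, list[np.ndarray]] = {}
        self._tables: dict[tuple, dict[int, SubjectTable]] = {}
        self._zstats: dict[int, ZScoreStats] = {}

        for s, subject in enumerate(cohort.subjects):
            n_trials = len(subject.trials)
            self.splits[s] = split_trials(
                n_trials, SplitSpec(split_spec.block_size, split_spec.train_fraction,
                                    split_spec.seed + s)
            )
            recs, labels = [], []
            for trial in subject.trials:
                rec = trial.emg
                if rec.stage == "raw":
                    rec = preprocess_emg(rec)
                rec.require_stage("preprocessed")
                recs.append(rec)
                codes = labels_from_motion(trial.motion)
                ts = feature_sample_indices(rec.n_samples, rec.fs)
                labels.append(codes[ts])
            self._pre[s] = recs
            self._labels[s] = labels

    # -- normalization statistics ------------------------------------------

    def zscore_stats(self, s: int) -> ZScoreStats:
        """Per-channel stats of subject ``s``'s *training-split* data."""
        if s not in self._zstats:
            train_ids, _ = self.splits[s]
            concat = np.concatenate(
                [self._pre[s][i].samples for i in train_ids], axis=1
            )
            self._zstats[s] = compute_zscore_stats(concat)
        return self._zstats[s]

    # -- feature tables -----------------------------------------------------

    def tables(
        self, method: str, l_norm_ms: float | None, l_feature_ms: float
    ) -> dict[int, SubjectTable]:
        """Per-subject feature tables for one configuration (cached).

        For z-score and no normalization the tables do not depend on
        ``l_norm_ms`` and the cache key drops it.
        """
        key = (method, l_norm_ms if method == "swn" else None, l_feature_ms, self.feature)
        if key in self._tables:
            return self._tables[key]
        fspec = FeatureSpec(feature=self.feature, window_ms=l_feature_ms)
        nspec = NormalizationSpec(
            method=method, window_ms=l_norm_ms if method == "swn" else None
        )
        out: dict[int, SubjectTable] = {}
        for s in range(self.n_subjects):
            stats = self.zscore_stats(s) if method == "zscore" else None
            Xs, ys, tids = [], [], []
            for i, rec in enumerate(self._pre[s]):
                normed = normalize(rec, nspec, stats=stats)
                fm = assemble_features(normed, fspec)
                Xs.append(fm.values)
                ys.append(self._labels[s][i])
                tids.append(np.full(fm.n_rows, i))
            out[s] = SubjectTable(
                X=np.concatenate(Xs), y=np.concatenate(ys), trial_id=np.concatenate(tids)
            )
        self._tables[key] = out
        return out

    # -- protocols ----------------------------------------------------------

    def _combos(self, held_out: int, k: int, combo_cap: int | None, seed: int):
        others = [s for s in range(self.n_subjects) if s != held_out]
        if not 1 <= k <= len(others):
            raise ValueError(f"n_train_subjects must be in [1, {len(others)}]")
        combos = list(itertools.combinations(others, k))
        if combo_cap is not None and len(combos) > combo_cap:
            rng = np.random.default_rng(seed + held_out)
            idx = rng.choice(len(combos), size=combo_cap, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        return combos

    def run(
        self,
        methods=("swn", "zscore", "none"),
        l_norm_ms=(500.0,),
        l_feature_ms=(500.0,),
        model_types=("OWN", "OTHER"),
        n_train_subjects: int = None,
        combo_cap: int | None = None,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Grid evaluation; one row per (config, subject, combination)."""
        if n_train_subjects is None:
            n_train_subjects = self.n_subjects - 1
        if isinstance(methods, str):
            methods = (methods,)
        l_norm_ms = np.atleast_1d(l_norm_ms)
        l_feature_ms = np.atleast_1d(l_feature_ms)
        rows = []
        for method in methods:
            norm_grid = l_norm_ms if method == "swn" else [np.nan]
            for ln in norm_grid:
                for lf in l_feature_ms:
                    tables = self.tables(method, None if np.isnan(ln) else float(ln), float(lf))
                    for mt in model_types:
                        rows += self._evaluate(
                            tables, mt, method, ln, lf, n_train_subjects, combo_cap, seed
                        )
        return pd.DataFrame(rows)

    def _evaluate(self, tables, model_type, method, ln, lf,
                  n_train_subjects, combo_cap, seed) -> list[dict]:
        rows = []
        for s in range(self.n_subjects):
            train_ids, test_ids = self.splits[s]
            test_mask = tables[s].rows_for(test_ids)
            X_test, y_test = tables[s].X[test_mask], tables[s].y[test_mask]
            if model_type == "OWN":
                train_mask = tables[s].rows_for(train_ids)
                clf = train_classifier(tables[s].X[train_mask], tables[s].y[train_mask])
                acc = accuracy(clf.predict(X_test), y_test)
                combos_accs = [("own", acc)]
            elif model_type == "OTHER":
                combos_accs = []
                for combo in self._combos(s, n_train_subjects, combo_cap, seed):
                    Xp, yp = [], []
                    for o in combo:
                        o_train, _ = self.splits[o]
                        m = tables[o].rows_for(o_train)
                        Xp.append(tables[o].X[m])
                        yp.append(tables[o].y[m])
                    clf = train_classifier(np.concatenate(Xp), np.concatenate(yp))
                    combos_accs.append(
                        ("+".join(map(str, combo)), accuracy(clf.predict(X_test), y_test))
                    )
            else:
                raise ValueError(f"unknown model type {model_type!r}")
            for combo_id, acc in combos_accs:
                rows.append(
                    dict(
                        test_subject=s,
                        model_type=model_type,
                        method=method,
                        l_norm_ms=ln,
                        l_feature_ms=lf,
                        feature=self.feature,
                        n_train_subjects=n_train_subjects if model_type == "OTHER" else np.nan,
                        combo_id=combo_id,
                        accuracy=acc,
                    )
                )
        return rows


def run_protocol(
    cohort: Cohort,
    methods=("swn", "zscore", "none"),
    l_norm_ms=(500.0,),
    l_feature_ms=(500.0,),
    feature: str = "ALL",
    model_types=("OWN", "OTHER"),
    n_train_subjects: int | None = None,
    combo_cap: int | None = None,
    split_spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """One-shot wrapper around :class:`ProtocolRunner`."""
    runner = ProtocolRunner(cohort, split_spec=split_spec, feature=feature)
    return runner.run(
        methods=methods,
        l_norm_ms=l_norm_ms,
        l_feature_ms=l_feature_ms,
        model_types=model_types,
        n_train_subjects=n_train_subjects,
        combo_cap=combo_cap,
        seed=seed,
    )


def sweep_subject_counts(
    cohort_or_runner,
    ks=None,
    methods=("swn", "zscore", "none"),
    l_norm_ms: float = 500.0,
    l_feature_ms: float = 500.0,
    feature: str = "ALL",
    combo_cap: int | None = None,
    split_spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """OTHER accuracy as the number of training subjects grows."""
    runner = (
        cohort_or_runner
        if isinstance(cohort_or_runner, ProtocolRunner)
        else ProtocolRunner(cohort_or_runner, split_spec=split_spec, feature=feature)
    )
    if ks is None:
        ks = range(1, runner.n_subjects)
    frames = [
        runner.run(
            methods=methods,
            l_norm_ms=(l_norm_ms,),
            l_feature_ms=(l_feature_ms,),
            model_types=("OTHER",),
            n_train_subjects=k,
            combo_cap=combo_cap,
            seed=seed,
        )
        for k in ks
    ]
    return pd.concat(frames, ignore_index=True)


def summarize(result: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD accuracy per configuration.

    ``sd_subjects`` is the SD of per-subject mean accuracies;
    ``sd_cells`` the SD over all (subject x combination) cells.
    """
    keys = ["method", "model_type", "l_norm_ms", "l_feature_ms", "feature",
            "n_train_subjects"]
    per_subject = (
        result.groupby(keys + ["test_subject"], dropna=False)["accuracy"]
        .mean()
        .reset_index()
    )
    out = (
        per_subject.groupby(keys, dropna=False)["accuracy"]
        .agg(mean_accuracy="mean", sd_subjects="std")
        .reset_index()
    )
    cells = (
        result.groupby(keys, dropna=False)["accuracy"].std().rename("sd_cells").reset_index()
    )
    return out.merge(cells, on=keys)


def best_over_grid(result: pd.DataFrame, per_subject: bool = True) -> pd.DataFrame:
    """Best-window-configuration accuracy per method and model type.

    ``per_subject=True``: take each subject's maximum of mean accuracy over
    the (L_norm, L_feature) grid, then average across subjects.
    ``per_subject=False``: maximize the group-mean accuracy over the grid.
    """
    grid_keys = ["l_norm_ms", "l_feature_ms"]
    base_keys = ["method", "model_type", "feature", "n_train_subjects"]
    per_cell = (
        result.groupby(base_keys + grid_keys + ["test_subject"], dropna=False)["accuracy"]
        .mean()
        .reset_index()
    )
    if per_subject:
        best = (
            per_cell.groupby(base_keys + ["test_subject"], dropna=False)["accuracy"]
            .max()
            .reset_index()
        )
        return (
            best.groupby(base_keys, dropna=False)["accuracy"]
            .agg(mean_accuracy="mean", sd_subjects="std")
            .reset_index()
        )
    group_mean = (
        per_cell.groupby(base_keys + grid_keys, dropna=False)["accuracy"]
        .mean()
        .reset_index()
    )
    idx = group_mean.groupby(base_keys, dropna=False)["accuracy"].idxmax()
    return group_mean.loc[idx].rename(columns={"accuracy": "mean_accuracy"})


# ---------------------------------------------------------------------------
# SD-vs-feature diagnostic


def sd_feature_correlation(
    cohort_or_runner,
    l_feature_ms: float = 500.0,
    l_norm_ms: float = 500.0,
) -> pd.DataFrame:
    """Correlation of windowed pre-normalization SD with the MAV feature.

    For each subject and channel, Pearson r between the SD of the
    *preprocessed* EMG over each retained trailing window and the MAV
    computed over the same windows, once on the unnormalized signal
    (``none``) and once on the SWN stream (``swn``). A strongly positive
    ``none`` correlation with a near-zero ``swn`` correlation shows SWN
    decoupling feature magnitude from signal scale. Channels with zero
    variance in either series yield NaN and are excluded from means.
    """
    runner = (
        cohort_or_runner
        if isinstance(cohort_or_runner, ProtocolRunner)
        else ProtocolRunner(cohort_or_runner)
    )
    nspec = NormalizationSpec(method="swn", window_ms=l_norm_ms)
    rows = []
    for s in range(runner.n_subjects):
        recs = runner._pre[s]
        L = FeatureSpec(window_ms=l_feature_ms).window_samples(recs[0].fs)
        n_ch = recs[0].n_channels
        sd_w: list[list[np.ndarray]] = [[] for _ in range(n_ch)]
        mav_none: list[list[np.ndarray]] = [[] for _ in range(n_ch)]
        mav_swn: list[list[np.ndarray]] = [[] for _ in range(n_ch)]
        for rec in recs:
            ts = feature_sample_indices(rec.n_samples, rec.fs)
            normed = normalize(rec, nspec)
            for ch in range(n_ch):
                W_pre = _trailing_windows(rec.samples[ch], ts, L)
                W_swn = _trailing_windows(normed.samples[ch], ts, L)
                sd_w[ch].append(W_pre.std(axis=-1))
                mav_none[ch].append(np.abs(W_pre).mean(axis=-1))
                mav_swn[ch].append(np.abs(W_swn).mean(axis=-1))
        for ch in range(n_ch):
            sd = np.concatenate(sd_w[ch])
            if sd.size < 3:
                raise ValueError("need at least 3 windows per channel")
            for cond, mavs in (("none", mav_none), ("swn", mav_swn)):
                mav = np.concatenate(mavs[ch])
                if sd.std() == 0 or mav.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(sd, mav)[0, 1])
                rows.append(dict(subject=s, channel=ch, condition=cond, r=r))
    return pd.DataFrame(rows)


def mean_sd_feature_correlation(corr: pd.DataFrame) -> pd.Series:
    """Mean r per condition over (subject, channel), NaNs excluded."""
    return corr.groupby("condition")["r"].mean()
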