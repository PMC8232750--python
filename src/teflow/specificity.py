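"""Setting-specificity of information-flow profiles.

Are the outgoing-flow profiles of the selected channels characteristic of
the experimental setting that produced them?  The protocol: each setting
contributes one row per common channel (the channel's thresholded TE to
every channel of the montage); per simulation run one channel per setting
is held out, a multinomial logistic regression is fit on the remaining
rows, and the held-out rows are scored.  With three balanced classes the
chance accuracy is 33.33%; aggregation over 1000 runs gives the reported
means, SDs, the pooled confusion matrix, and per-setting weight maps.

This is not classification for its own sake — the classes are built from
grand-averaged matrices — but a check of whether the *distribution* of
outgoing flow carries setting-specific structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.preprocessing import StandardScaler

from teflow.stats import GroupTestResult, classify_effect, kruskal_wallis_r, wilcoxon_r

__all__ = [
    "FlowDataset",
    "SpecificityReport",
    "build_dataset",
    "run_protocol",
    "test_above_chance",
    "compare_weights",
]


@dataclass
class FlowDataset:
    """Balanced (setting, channel) rows of outgoing-TE feature vectors."""

    X: np.ndarray                      # (n_settings * n_channels, n_features)
    y: np.ndarray                      # integer labels 1..k
    settings: tuple[str, ...]          # label i+1 <-> settings[i]
    channels: tuple[str, ...]          # per-setting channel roster
    feature_labels: tuple[str, ...] | None = None

    @property
    def n_settings(self) -> int:
        return len(self.settings)

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class SpecificityReport:
    """Aggregates of the resampled hold-one-channel-per-class protocol."""

    accuracy_mean: float               # percent
    accuracy_sd: float
    precision_mean: float              # macro-averaged, 0..1
    precision_sd: float
    recall_mean: float
    recall_sd: float
    f1_mean: float
    f1_sd: float
    confusion: np.ndarray              # (k, k) counts over runs, rows = true
    weights: np.ndarray                # (k, n_features) mean coefficients
    chance_level: float                # percent
    run_accuracies: np.ndarray = field(repr=False, default=None)
    settings: tuple[str, ...] = ()
    seed: int | None = None
    runs: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": {"mean": self.accuracy_mean, "sd": self.accuracy_sd},
            "precision": {"mean": self.precision_mean, "sd": self.precision_sd},
            "recall": {"mean": self.recall_mean, "sd": self.recall_sd},
            "f1": {"mean": self.f1_mean, "sd": self.f1_sd},
            "confusion": self.confusion.tolist(),
            "chance_level": self.chance_level,
            "settings": list(self.settings),
            "runs": self.runs,
            "seed": self.seed,
            "notes": "features standardized on train folds; L2-regularized "
                     "multinomial regression (C=1.0); weights averaged over runs",
        }

    def weight_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights.T, columns=list(self.settings)
        )


def build_dataset(
    per_setting: dict[str, dict[str, np.ndarray]],
    feature_labels: tuple[str, ...] | None = None,
) -> FlowDataset:
    """Assemble rows from per-setting {channel: outgoing-TE vector} maps.

    Settings are labelled 1..k in the given key order.  All settings must
    share the same channel set and feature length (e.g., 3 settings x 6
    common channels x 62 targets -> an 18 x 62 design).
    """
    if len(per_setting) < 2:
        raise ValueError("need at least 2 settings (classes)")
    settings = tuple(per_setting)
    rosters = [tuple(sorted(per_setting[s])) for s in settings]
    if any(r != rosters[0] for r in rosters[1:]):
        raise ValueError("settings have unequal channel sets")
    channels = rosters[0]
    if not channels:
        raise ValueError("empty channel set")
    rows, labels = [], []
    for idx, s in enumerate(settings, start=1):
        for ch in channels:
            rows.append(np.asarray(per_setting[s][ch], dtype=float).ravel())
        labels.extend([idx] * len(channels))
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature lengths: {sorted(lengths)}")
    return FlowDataset(
        X=np.vstack(rows), y=np.asarray(labels), settings=settings,
        channels=channels, feature_labels=feature_labels,
    )


def run_protocol(
    ds: FlowDataset,
    runs: int = 1000,
    seed: int | np.random.Generator = 0,
    shuffle_labels: bool = False,
) -> SpecificityReport:
    """Hold one channel per class, fit, score; aggregate over ``runs``.

    Per run: one randomly chosen channel per setting forms the test set
    (k rows) and the rest the training set (k*(n_channels-1) rows — 15 x 62
    and 3 x 62 for 3 settings x 6 channels over a 62-channel montage).  The
    model is a multinomial logistic regression with L2 penalty (C = 1.0) on
    train-standardized features.  Precision/recall/F1 are macro-averaged
    over classes per run before averaging over runs; the confusion matrix
    accumulates counts over all runs.

    ``shuffle_labels=True`` permutes the class labels across rows afresh in
    every run (keeping the class balance), which severs any feature-label
    association: the resulting mean accuracy calibrates the chance level.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if np.all(np.ptp(ds.X, axis=0) == 0):
        raise ValueError("degenerate features: all columns constant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k, m = ds.n_settings, ds.n_channels
    if m < 2:
        raise ValueError("need >= 2 channels per setting to hold one out")
    classes = np.arange(1, k + 1)
    acc = np.empty(runs)
    prec = np.empty(runs)
    rec = np.empty(runs)
    f1 = np.empty(runs)
    confusion = np.zeros((k, k), dtype=int)
    weight_sum = np.zeros((k, ds.X.shape[1]))

    for run in range(runs):
        y_run = ds.y
        if shuffle_labels:
            y_run = ds.y[rng.permutation(ds.y.size)]
        row_of = y_run.argsort(kind="stable").reshape(k, m)  # rows by class
        test_rows = np.array([row_of[c, rng.integers(m)] for c in range(k)])
        test_mask = np.zeros(ds.X.shape[0], dtype=bool)
        test_mask[test_rows] = True
        X_tr, y_tr = ds.X[~test_mask], y_run[~test_mask]
        X_te, y_te = ds.X[test_mask], y_run[test_mask]
        scaler = StandardScaler().fit(X_tr)
        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_te))
        acc[run] = 100.0 * np.mean(pred == y_te)
        p_, r_, f_, _ = precision_recall_fscore_support(
            y_te, pred, labels=classes, average="macro", zero_division=0
        )
        prec[run], rec[run], f1[run] = p_, r_, f_
        for t, pr in zip(y_te, pred):
            confusion[t - 1, pr - 1] += 1
        coefs = clf.coef_
        if coefs.shape[0] == 1:  # binary fit returns one row
            coefs = np.vstack([-coefs[0], coefs[0]])
        weight_sum += coefs

    return SpecificityReport(
        accuracy_mean=float(acc.mean()), accuracy_sd=float(acc.std(ddof=1)) if runs > 1 else 0.0,
        precision_mean=float(prec.mean()), precision_sd=float(prec.std(ddof=1)) if runs > 1 else 0.0,
        recall_mean=float(rec.mean()), recall_sd=float(rec.std(ddof=1)) if runs > 1 else 0.0,
        f1_mean=float(f1.mean()), f1_sd=float(f1.std(ddof=1)) if runs > 1 else 0.0,
        confusion=confusion,
        weights=weight_sum / runs,
        chance_level=100.0 / k,
        run_accuracies=acc,
        settings=ds.settings,
        seed=seed if isinstance(seed, int) else None,
        runs=runs,
    )


def test_above_chance(report: SpecificityReport) -> GroupTestResult:
    """Signed-rank test of per-run accuracy against the chance level.

    The effect size uses N = number of runs.  If every run scored exactly
    at chance there is no evidence either way; that outcome is surfaced as
    a zero-effect result rather than an exception.
    """
    if report.run_accuracies is None:
        raise ValueError("report does not retain per-run accuracies")
    diffs = report.run_accuracies - report.chance_level
    if np.all(diffs == 0):
        return GroupTestResult(
            test="signed_rank", statistic=0.0, df=(report.runs - 1,), p=1.0,
            effect_r=0.0, magnitude=classify_effect(0.0), n=report.runs,
        )
    return wilcoxon_r(diffs, mode="signed_rank", n_override=report.runs)


def compare_weights(
    report: SpecificityReport,
) -> tuple[GroupTestResult, dict[tuple[str, str], GroupTestResult]]:
    """Kruskal-Wallis across per-setting weight maps, then pairwise rank sums.

    Treats each setting's mean coefficient vector (length = feature count)
    as a sample; N for the omnibus test is k * n_features.
    """
    k = report.weights.shape[0]
    if k < 2:
        raise ValueError("need weight vectors for at least 2 settings")
    vectors = [report.weights[i] for i in range(k)]
    omnibus = kruskal_wallis_r(vectors)
    pairwise: dict[tuple[str, str], GroupTestResult] = {}
    names = report.settings or tuple(f"class{i+1}" for i in range(k))
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(names[i], names[j])] = wilcoxon_r(
                vectors[i], vectors[j], mode="ranksum"
            )
    return omnibus, pairwise
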