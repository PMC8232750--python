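"""Channel-of-interest selection from lag-optimized transfer-entropy matrices.

The procedure, per experimental setting:

1. all ordered channel pairs of each preprocessed recording get a
   lag-optimized TE (maximum over delays 0..50 at the downsampled rate);
2. each odour setting's per-subject matrix is contrasted against the
   subject's voice-matched neutral matrix (AM/EM minus NM, AF/EF minus NF),
   leaving the flow attributable to the odour manipulation;
3. contrasts are grand-averaged over subjects into one matrix per setting;
4. the pooled off-diagonal entries are bootstrap-resampled (10000 draws of
   the mean); entries below the upper bound of the 95% CI of the mean are
   zeroed — a one-tailed "greater than the average" test at p < 0.025;
5. each channel's out-degree (count of surviving outgoing entries) is
   compared against a second bootstrap CI of the mean out-degree; channels
   whose degree exceeds the upper bound are selected;
6. the per-setting selections are intersected; settings with an empty
   selection are dropped from the intersection and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from teflow.synthetic import Recording
from teflow.te import TEConfig, lag_scan_te

logger = logging.getLogger(__name__)

__all__ = [
    "TEMatrix",
    "ThresholdedFlow",
    "pairwise_te",
    "lag_to_ms",
    "neutral_contrast",
    "grand_average",
    "bootstrap_upper_threshold",
    "select_channels",
    "common_channels",
]


@dataclass
class TEMatrix:
    """Directed source x target TE values (nats); entry (i, j) = TE(i -> j)."""

    values: np.ndarray
    labels: tuple[str, ...]
    condition: str = ""
    subject: str = ""
    lags: np.ndarray | None = None  # delay (samples) maximizing each entry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        C = len(self.labels)
        if self.values.shape != (C, C):
            raise ValueError(f"values shape {self.values.shape} != ({C}, {C})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TE matrix contains non-finite entries")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("TE matrix diagonal must be exactly 0")
        if self.lags is not None:
            self.lags = np.asarray(self.lags, dtype=int)
            if self.lags.shape != self.values.shape:
                raise ValueError("lag matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass
class ThresholdedFlow:
    """A contrast-averaged TE matrix after bootstrap upper-CI thresholding."""

    contrast_mean: np.ndarray
    threshold: float
    surviving: np.ndarray
    out_degree: np.ndarray
    labels: tuple[str, ...]
    condition: str = ""
    selected_channels: frozenset[str] = field(default_factory=frozenset)

    def degree_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": list(self.labels), "out_degree": self.out_degree}
        )


def pairwise_te(
    rec: Recording,
    te_cfg: TEConfig | None = None,
    lag_range: tuple[int, int] = (0, 50),
) -> TEMatrix:
    """Lag-optimized TE for every ordered channel pair; diagonal 0.

    Returns a :class:`TEMatrix` whose ``lags`` attribute holds the delay
    (samples at the recording's rate) that maximized each entry.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    te_cfg = te_cfg or TEConfig()
    lag_min, lag_max = lag_range
    C = rec.n_channels
    values = np.zeros((C, C))
    lags = np.zeros((C, C), dtype=int)
    for i in range(C):
        for j in range(C):
            if i == j:
                continue
            try:
                res = lag_scan_te(rec.data[i], rec.data[j], te_cfg, lag_min, lag_max)
            except ValueError as exc:
                raise ValueError(
                    f"TE failed for pair {rec.labels[i]}->{rec.labels[j]}: {exc}"
                ) from exc
            values[i, j] = res.value
            lags[i, j] = res.delay_used
    return TEMatrix(values=values, labels=rec.labels, condition=rec.condition,
                    subject=rec.subject_id, lags=lags)


def lag_to_ms(lag: int, rate_hz: float) -> float:
    """Delay in samples -> milliseconds (lag 50 at 100 Hz is 500 ms)."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    return lag * 1000.0 / rate_hz


def _check_congruent(a: TEMatrix, b: TEMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("channel label mismatch between matrices")


def neutral_contrast(setting: TEMatrix, neutral: TEMatrix) -> TEMatrix:
    """Element-wise setting minus voice-matched neutral, per subject.

    Negative residuals are retained; the later bootstrap threshold removes
    them.  The diagonal stays 0.
    """
    _check_congruent(setting, neutral)
    if setting.subject and neutral.subject and setting.subject != neutral.subject:
        raise ValueError(
            f"contrast pairs subjects {setting.subject!r} and {neutral.subject!r}"
        )
    diff = setting.values - neutral.values
    np.fill_diagonal(diff, 0.0)
    return TEMatrix(values=diff, labels=setting.labels,
                    condition=f"{setting.condition}-{neutral.condition}",
                    subject=setting.subject)


def grand_average(contrasts: list[TEMatrix]) -> TEMatrix:
    """Element-wise mean over subjects; order-invariant."""
    if not contrasts:
        raise ValueError("need at least one matrix to average")
    first = contrasts[0]
    for m in contrasts[1:]:
        _check_congruent(first, m)
    mean = np.mean([m.values for m in contrasts], axis=0)
    np.fill_diagonal(mean, 0.0)
    return TEMatrix(values=mean, labels=first.labels, condition=first.condition,
                    subject="grand-average")


def _bootstrap_mean_upper(
    sample: np.ndarray, B: int, level: float, rng: np.random.Generator
) -> float:
    """Upper bound of the bootstrap percentile CI of the sample mean."""
    n = sample.size
    idx = rng.integers(0, n, size=(B, n))
    means = sample[idx].mean(axis=1)
    upper_q = 100.0 - (100.0 - level) / 2.0
    return float(np.percentile(means, upper_q))


def bootstrap_upper_threshold(
    matrix: TEMatrix,
    B: int = 10_000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> ThresholdedFlow:
    """Threshold a grand-averaged contrast at the bootstrap upper CI of its mean.

    The pooled off-diagonal entries are resampled with replacement ``B``
    times; the 97.5th percentile (for a 95% CI) of the bootstrap mean
    distribution is the threshold.  Entries *less than* the threshold are
    zeroed — equivalently, only values greater than the average at p < 0.025
    are accepted (entries equal to the threshold survive).  Out-degrees are
    the per-source-row counts of surviving entries.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = len(matrix.labels)
    off = ~np.eye(C, dtype=bool)
    entries = matrix.values[off]
    if entries.size < 2:
        raise ValueError("need at least 2 off-diagonal entries")
    threshold = _bootstrap_mean_upper(entries, B, level, rng)
    if np.ptp(entries) == 0.0:
        logger.info("degenerate all-equal matrix; threshold equals the constant")
    surviving = np.where(matrix.values >= threshold, matrix.values, 0.0)
    np.fill_diagonal(surviving, 0.0)
    out_degree = (surviving != 0.0).sum(axis=1)
    return ThresholdedFlow(
        contrast_mean=matrix.values,
        threshold=threshold,
        surviving=surviving,
        out_degree=out_degree,
        labels=matrix.labels,
        condition=matrix.condition,
    )


def select_channels(
    flow: ThresholdedFlow,
    B: int = 10_000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> frozenset[str]:
    """Channels whose out-degree exceeds the bootstrap mean-degree bound.

    The out-degree vector's mean is bootstrap-resampled ``B`` times; a
    channel is kept when its out-degree strictly exceeds the upper bound of
    the 95% CI of the mean degree.  All-zero degrees yield an empty
    selection (a valid outcome: a setting can contribute no channels).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = flow.out_degree.astype(float)
    if np.all(degrees == 0):
        flow.selected_channels = frozenset()
        return flow.selected_channels
    bound = _bootstrap_mean_upper(degrees, B, level, rng)
    keep = frozenset(
        lab for lab, d in zip(flow.labels, degrees) if d > bound
    )
    flow.selected_channels = keep
    return keep


def common_channels(
    selections: dict[str, frozenset[str] | set[str]],
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Intersection of per-setting selections, dropping empty settings.

    Settings whose selection is empty contribute nothing and are excluded
    from the intersection; they are reported back as ``dropped`` (the
    behaviour that removed the estratetraenol/female-voice setting from the
    original analysis).
    """
    if len(selections) < 2:
        raise ValueError("need selections from at least 2 settings")
    dropped = tuple(sorted(k for k, v in selections.items() if not v))
    retained = {k: frozenset(v) for k, v in selections.items() if v}
    if not retained:
        return frozenset(), dropped
    common: frozenset[str] = frozenset.intersection(*retained.values())
    return common, dropped
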