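"""Synthetic multichannel EEG with known directed couplings.

Surrogate recordings stand in for the unavailable human data: each channel
is an order-1 autoregression driven by Gaussian innovations, and directed
information flow is injected as lagged linear couplings that are active
only in a chosen subset of experimental settings.  Because every coupling
(source, target, delay, strength, conditions) is declared explicitly, the
generator yields a ground-truth directed graph against which delay
estimation, thresholding and channel selection can be scored exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from teflow.montage import CONDITIONS, default_labels

_VALID_CONDITIONS = set(CONDITIONS) | {"baseline"}


@dataclass(frozen=True)
class CouplingSpec:
    """A directed lagged coupling between two channels.

    ``target[t] += strength * source[t - delay]`` whenever the recording's
    condition is in ``conditions``.
    """

    source: str
    target: str
    delay: int
    strength: float
    conditions: frozenset[str] = frozenset(CONDITIONS)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"coupling source equals target: {self.source}")
        if self.delay < 1:
            raise ValueError(f"coupling delay must be >= 1, got {self.delay}")
        if not np.isfinite(self.strength):
            raise ValueError("coupling strength must be finite")
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        unknown = self.conditions - _VALID_CONDITIONS
        if unknown:
            raise ValueError(f"unknown conditions in coupling: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full description of a simulated multichannel study.

    Parameters
    ----------
    n_channels : int
        Number of scalp channels (default 62, as in a 64-electrode cap with
        the two mastoid-adjacent electrodes removed).
    rate : float
        Sampling rate in Hz; the acquisition-grade default is 1000 Hz.
    duration_samples : int
        Samples per recording after burn-in removal.  The default 120000
        corresponds to the pre-downsampling length that decimation by 10
        reduces to 12000 points.
    ar_coeff : float or per-channel sequence
        Order-1 autoregressive coefficient(s); |a| < 1 for stationarity.
    noise_sd : float or per-channel sequence
        Innovation standard deviation(s), nominal microvolts.
    couplings : sequence of CouplingSpec
        Directed lagged couplings with condition masks.
    nonlinear : bool
        When set, the autoregressive + coupling drive passes through tanh,
        producing a non-Gaussian process that exercises the model-free
        claim of the nearest-neighbour estimator.
    inject_artifacts : bool
        When set, sporadic high-amplitude transients (>125 uV) are added so
        the amplitude-based artifact rejection rule has something to catch.
    """

    n_channels: int = 62
    channel_labels: tuple[str, ...] | None = None
    rate: float = 1000.0
    duration_samples: int = 120_000
    ar_coeff: float | tuple[float, ...] = 0.5
    noise_sd: float | tuple[float, ...] = 10.0
    couplings: tuple[CouplingSpec, ...] = ()
    n_subjects: int = 1
    seed: int = 0
    nonlinear: bool = False
    inject_artifacts: bool = False

    def __post_init__(self) -> None:
        labels = self.channel_labels
        if labels is None:
            labels = default_labels(self.n_channels)
        labels = tuple(labels)
        if len(labels) != self.n_channels:
            raise ValueError(
                f"{len(labels)} labels for {self.n_channels} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "channel_labels", labels)
        object.__setattr__(self, "couplings", tuple(self.couplings))
        ar = np.broadcast_to(np.asarray(self.ar_coeff, float), (self.n_channels,))
        if np.any(np.abs(ar) >= 1.0):
            raise ValueError("|ar_coeff| must be < 1 for stationarity")
        sd = np.broadcast_to(np.asarray(self.noise_sd, float), (self.n_channels,))
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be > 0")
        known = set(labels)
        for c in self.couplings:
            if c.source not in known or c.target not in known:
                raise ValueError(f"coupling references unknown channel: {c}")
        if self.couplings:
            max_delay = max(c.delay for c in self.couplings)
            if self.duration_samples < 10 * max_delay:
                raise ValueError(
                    "duration_samples must be >= 10x the maximum coupling delay"
                )
        if self.duration_samples < 1:
            raise ValueError("duration_samples must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def ar_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.ar_coeff, float), (self.n_channels,)).copy()

    @property
    def sd_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.noise_sd, float), (self.n_channels,)).copy()

    def max_delay(self, condition: str | None = None) -> int:
        active = self.couplings if condition is None else [
            c for c in self.couplings if condition in c.conditions
        ]
        return max((c.delay for c in active), default=1)


@dataclass
class Recording:
    """A channels x samples matrix with montage labels and metadata."""

    data: np.ndarray
    labels: tuple[str, ...]
    rate: float
    subject_id: str = "S00"
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy_with(self, data: np.ndarray, rate: float | None = None) -> "Recording":
        return Recording(
            data=data,
            labels=self.labels,
            rate=self.rate if rate is None else rate,
            subject_id=self.subject_id,
            condition=self.condition,
        )


def _substream_seed(design_seed: int, subject_id: str, condition: str) -> np.random.Generator:
    """Counter-based per-(subject, condition) stream.

    CRC32 of the identifying strings feeds a SeedSequence so subjects are
    exchangeable yet each (design, subject, condition) triple is bit-stable.
    """
    key = (
        int(design_seed) & 0xFFFFFFFF,
        zlib.crc32(str(subject_id).encode()),
        zlib.crc32(str(condition).encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def _transition_matrices(design: SyntheticDesign, condition: str) -> dict[int, np.ndarray]:
    """Lag -> coefficient matrix of the implied VAR, target rows."""
    C = design.n_channels
    idx = {lab: i for i, lab in enumerate(design.channel_labels)}
    mats: dict[int, np.ndarray] = {1: np.diag(design.ar_vector)}
    for c in design.couplings:
        if condition not in c.conditions:
            continue
        mats.setdefault(c.delay, np.zeros((C, C)))
        mats[c.delay][idx[c.target], idx[c.source]] += c.strength
    return mats


def check_stability(design: SyntheticDesign, condition: str) -> float:
    """Spectral radius of the companion matrix of the implied VAR.

    Raises ``ValueError`` naming the active couplings when >= 1.
    """
    mats = _transition_matrices(design, condition)
    p = max(mats)
    C = design.n_channels
    companion = np.zeros((C * p, C * p))
    for lag, mat in mats.items():
        companion[:C, (lag - 1) * C : lag * C] = mat
    if p > 1:
        companion[C:, : C * (p - 1)] = np.eye(C * (p - 1))
    radius = float(np.max(np.abs(np.linalg.eigvals(companion))))
    if radius >= 1.0:
        active = [c for c in design.couplings if condition in c.conditions]
        raise ValueError(
            f"unstable design for condition {condition}: spectral radius "
            f"{radius:.3f} >= 1 with couplings {active}"
        )
    return radius


def generate_recording(
    design: SyntheticDesign, subject_id: str, condition: str
) -> Recording:
    """Simulate one subject x condition recording.

    Each channel follows ``x_i[t] = a_i x_i[t-1] + sum couplings + eps`` with
    the condition-active couplings applied at their stated delays.  A burn-in
    of at least 10x the maximum coupling delay is discarded so the returned
    series is stationary.  Identical (design, subject, condition) inputs
    reproduce the identical matrix.
    """
    if condition not in _VALID_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {sorted(_VALID_CONDITIONS)}")
    check_stability(design, condition)
    rng = _substream_seed(design.seed, subject_id, condition)

    C, T = design.n_channels, design.duration_samples
    mats = _transition_matrices(design, condition)
    lags = sorted(mats)
    burn = max(200, 10 * design.max_delay(condition))
    total = T + burn
    sd = design.sd_vector

    data = np.empty((C, total))
    eps = rng.normal(0.0, 1.0, size=(C, total)) * sd[:, None]
    data[:, 0] = eps[:, 0]
    for t in range(1, total):
        drive = np.zeros(C)
        for lag in lags:
            if t - lag >= 0:
                drive += mats[lag] @ data[:, t - lag]
        if design.nonlinear:
            # tanh saturation keeps the drive bounded; scaled so the linear
            # regime applies for typical amplitudes.
            scale = 3.0 * sd
            drive = scale * np.tanh(drive / scale)
        data[:, t] = drive + eps[:, t]
    out = data[:, burn:]

    if design.inject_artifacts:
        # sprinkle transients so ~1% of samples exceed 100 uV
        n_spikes = max(1, int(0.01 * T / int(design.rate)))  # ~1 per 100 s
        n_spikes = max(n_spikes, int(0.0002 * T))
        for _ in range(n_spikes):
            ch = rng.integers(C)
            pos = rng.integers(T)
            width = int(rng.integers(10, 50))
            hi = min(T, pos + width)
            out[ch, pos:hi] += rng.choice([-1.0, 1.0]) * rng.uniform(150.0, 300.0)

    return Recording(
        data=out,
        labels=design.channel_labels,
        rate=design.rate,
        subject_id=str(subject_id),
        condition=condition,
    )


def ground_truth_graph(
    design: SyntheticDesign, condition: str
) -> set[tuple[str, str, int]]:
    """The (source, target, delay) edges active in ``condition``."""
    if condition not in _VALID_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return {
        (c.source, c.target, c.delay)
        for c in design.couplings
        if condition in c.conditions
    }


# ---------------------------------------------------------------------------
# fixture I/O: delimited matrix + JSON sidecar (canonical, diff-able format)


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.tsv`` (channels x samples) plus ``<path>.json`` sidecar."""
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    sidecar = path.with_suffix(".json")
    np.savetxt(tsv, rec.data, delimiter="\t", fmt="%.17g")
    sidecar.write_text(
        json.dumps(
            {
                "labels": list(rec.labels),
                "rate": rec.rate,
                "subject": rec.subject_id,
                "condition": rec.condition,
            },
            indent=1,
        )
    )
    return tsv, sidecar
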