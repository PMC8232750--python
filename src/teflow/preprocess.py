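"""Signal conditioning applied before transfer-entropy estimation.

The pipeline order is fixed: zero-phase band-pass filtering (0.5-50 Hz,
24 dB/octave equivalent), amplitude-based artifact rejection (contiguous
one-second segments containing any sample beyond 125 uV are excised from
all channels jointly), decimation to a tenth of the original length with
an anti-alias low-pass, and per-channel linear detrending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from teflow.synthetic import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "reject_artifacts",
    "downsample_tenth",
    "detrend_linear",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    band : (low, high) pass-band edges in Hz.
    filter_order : Butterworth order; 4 gives the 24 dB/octave roll-off.
    artifact_threshold : absolute amplitude bound in uV.
    artifact_segment_s : segment granularity of the rejection rule, seconds.
    downsample_factor : decimation factor (10 -> a tenth of the length).
    antialias : apply a low-pass before decimating; turning it off gives
        naive subsampling for sensitivity checks.
    """

    band: tuple[float, float] = (0.5, 50.0)
    filter_order: int = 4
    artifact_threshold: float = 125.0
    artifact_segment_s: float = 1.0
    downsample_factor: int = 10
    antialias: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid band {self.band}")
        if self.artifact_threshold <= 0:
            raise ValueError("artifact_threshold must be > 0")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def bandpass(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase Butterworth band-pass; removes DC, preserves length.

    Forward-backward filtering avoids the phase distortion that would bias
    downstream lag estimates.
    """
    cfg = cfg or PreprocessConfig()
    low, high = cfg.band
    nyq = rec.rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz not below the Nyquist frequency {nyq} Hz"
        )
    sos = signal.butter(cfg.filter_order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out)


def reject_artifacts(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[Recording, np.ndarray]:
    """Excise contiguous segments containing any sample beyond the threshold.

    The recording is tiled into ``artifact_segment_s``-long segments; a
    segment is flagged when any channel exceeds ``artifact_threshold`` (uV)
    in absolute value, and flagged segments are removed from all channels
    jointly so inter-channel time-locking is preserved.

    Returns the cleaned recording and a boolean per-sample mask of the
    *rejected* samples in the original time base.
    """
    cfg = cfg or PreprocessConfig()
    seg_len = max(1, int(round(cfg.artifact_segment_s * rec.rate)))
    n = rec.n_samples
    mask = np.zeros(n, dtype=bool)
    for start in range(0, n, seg_len):
        stop = min(n, start + seg_len)
        if np.any(np.abs(rec.data[:, start:stop]) > cfg.artifact_threshold):
            mask[start:stop] = True
    frac = mask.mean()
    if frac > 0.5:
        logger.warning(
            "artifact rejection flagged %.1f%% of recording %s/%s",
            100 * frac,
            rec.subject_id,
            rec.condition,
        )
    cleaned = rec.copy_with(rec.data[:, ~mask])
    return cleaned, mask


def downsample_tenth(rec: Recording, factor: int | None = None,
                     antialias: bool = True) -> Recording:
    """Decimate to 1/factor of the original length (default a tenth).

    An anti-alias FIR low-pass precedes the sample picking unless
    ``antialias`` is off (naive subsampling).  The new length is
    ``floor(old / factor)`` and the rate divides by ``factor``; 120000
    samples at 1000 Hz become 12000 points at 100 Hz.
    """
    factor = 10 if factor is None else int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if rec.n_samples < factor:
        raise ValueError("recording shorter than the decimation factor")
    if factor == 1:
        return rec.copy_with(rec.data.copy())
    new_len = rec.n_samples // factor
    if antialias:
        out = signal.decimate(rec.data, factor, ftype="fir", axis=1, zero_phase=True)
        out = out[:, :new_len]
    else:
        out = rec.data[:, : new_len * factor : factor]
    return rec.copy_with(out, rate=rec.rate / factor)


def detrend_linear(rec: Recording) -> Recording:
    """Remove each channel's least-squares line (mean and linear drift)."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to detrend")
    return rec.copy_with(signal.detrend(rec.data, axis=1, type="linear"))


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[Recording, np.ndarray]:
    """Full conditioning chain: filter -> reject -> downsample -> detrend."""
    cfg = cfg or PreprocessConfig()
    out = bandpass(rec, cfg)
    out, mask = reject_artifacts(out, cfg)
    out = downsample_tenth(out, cfg.downsample_factor, antialias=cfg.antialias)
    out = detrend_linear(out)
    return out, mask
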