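"""Streaming signal chain: low-pass filter, moving-average decimation,
and train-time min-max normalization.

The raw 1 kHz strap voltages carry high-frequency sensor noise far above
the band of voluntary posture changes, so each channel is passed through
a causal low-pass filter (default: 2nd-order Butterworth, 4 Hz cutoff)
and then decimated by a moving-average: one output per ``step`` new
samples, each the per-channel mean of the most recent ``window`` samples
(200/100 at defaults, i.e. a 10 Hz feature stream).  Early windows are
partial — the mean runs over the samples seen so far — so a 5 s segment
at 1 kHz yields exactly 50 feature samples and the chain can emit in
real time from the first 100 ms.

Normalization parameters (per-channel min and max) are learned from the
training buffer only and re-applied verbatim at test time; test-time
features may therefore fall outside [0, 1], which is deliberate — the
out-of-range information is preserved for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError

N_CHANNELS = 8


@dataclass(frozen=True)
class FilterSpec:
    """Causal low-pass filter parameters."""

    cutoff: float = 4.0
    sample_rate: float = 1000.0
    order: int = 2
    kind: str = "butterworth-causal"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ConfigurationError(
                f"cutoff must lie in (0, Nyquist={self.sample_rate / 2} Hz)"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if self.kind != "butterworth-causal":
            raise ConfigurationError(f"unsupported filter kind {self.kind!r}")

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return signal.butter(
            self.order, self.cutoff, btype="low", fs=self.sample_rate
        )


@dataclass(frozen=True)
class DecimatorSpec:
    """Moving-average decimator: ``window`` samples averaged, one output
    per ``step`` samples."""

    window: int = 200
    step: int = 100

    def __post_init__(self) -> None:
        if not self.window >= self.step >= 1:
            raise ConfigurationError("need window >= step >= 1")

    @property
    def output_rate_divisor(self) -> int:
        return self.step


def lowpass(raw, spec: FilterSpec) -> np.ndarray:
    """Causally low-pass filter each channel of a recording or array.

    Accepts a :class:`~fmgelm.sensor.RawRecording` (its sample rate must
    match the spec) or a plain ``(n, channels)`` array.  The filter state
    is initialised to the steady state of the first sample, so a constant
    input passes through unchanged (unity DC gain, no start-up edge).
    """
    if hasattr(raw, "voltages"):
        if raw.sample_rate != spec.sample_rate:
            raise ConfigurationError(
                f"recording rate {raw.sample_rate} Hz != filter rate "
                f"{spec.sample_rate} Hz"
            )
        x = raw.voltages
    else:
        x = np.asarray(raw, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] == 0:
        return x[:, 0] if squeeze else x
    b, a = spec.coefficients()
    zi = signal.lfilter_zi(b, a)
    out = np.empty_like(x, dtype=float)
    for c in range(x.shape[1]):
        out[:, c], _ = signal.lfilter(b, a, x[:, c], zi=zi * x[0, c])
    return out[:, 0] if squeeze else out


def decimate_mean(
    x: np.ndarray, spec: DecimatorSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Streaming moving-average decimation.

    One output is emitted after every ``step`` new input samples (plus a
    final output for a trailing partial block), each the per-channel mean
    of the most recent ``min(window, samples seen)`` inputs.  An input of
    length ``n`` therefore yields ``ceil(n / step)`` outputs.

    Returns ``(features, end_indices)`` where ``end_indices[k]`` is the
    1-based index of the last raw sample contributing to output ``k``
    (its emission time is ``end_indices[k] / sample_rate``).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n == 0:
        empty = np.empty((0,) if squeeze else (0, x.shape[1]))
        return empty, np.empty(0, dtype=int)
    ends = list(range(spec.step, n + 1, spec.step))
    if n % spec.step:
        ends.append(n)
    ends_arr = np.asarray(ends, dtype=int)
    starts = np.maximum(0, ends_arr - spec.window)
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    feats = (csum[ends_arr] - csum[starts]) / (ends_arr - starts)[:, None]
    return (feats[:, 0] if squeeze else feats), ends_arr


@dataclass
class NormalizationParams:
    """Per-channel min-max scaling learned from the training buffer.

    Channels where max equals min are flagged degenerate and map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (self.mins.shape == self.maxs.shape == self.degenerate.shape):
            raise ConfigurationError("normalization parameter shapes differ")
        if np.any(self.maxs < self.mins):
            raise ConfigurationError("per-channel max must be >= min")

    @property
    def n_channels(self) -> int:
        return self.mins.shape[0]


def fit_normalization(training: np.ndarray) -> NormalizationParams:
    """Learn per-channel min and max from training feature samples."""
    x = np.asarray(training, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ConfigurationError("need at least 2 training samples (2-D array)")
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    return NormalizationParams(mins=mins, maxs=maxs, degenerate=maxs == mins)


def apply_normalization(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Scale features with stored training parameters: (x - min)/(max - min).

    Values outside the training range are NOT clamped; degenerate
    channels map to 0.
    """
    x = np.asarray(x, dtype=float)
    span = np.where(params.degenerate, 1.0, params.maxs - params.mins)
    out = (x - params.mins) / span
    if params.degenerate.any():
        out = np.where(params.degenerate, 0.0, out)
    return out


def invert_normalization(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Undo :func:`apply_normalization` on non-degenerate channels."""
    x = np.asarray(x, dtype=float)
    span = np.where(params.degenerate, 1.0, params.maxs - params.mins)
    return x * span + params.mins
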