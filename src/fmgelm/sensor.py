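"""Synthetic force-sensing-resistor (FSR) strap recordings.

An FSR strap worn on the proximal forearm senses muscle-bulk pressure
changes (force myography) on eight channels.  Each sensor sits in a
voltage divider: a fixed base resistor in series with the FSR, driven by
a constant supply, so the measured voltage is

    V(p) = Vcc * R_base / (R_base + R_fsr(p))

The FSR rests above 10 MOhm with no contact and its resistance falls
roughly as the inverse of applied pressure once contact is made, so the
divider output rises monotonically with pressure and saturates at Vcc.

This module generates labelled multichannel recordings for scripted
posture sequences: each posture is an abstract 8-channel pressure
template, the simulated subject reacts to each command after a random
response delay, pressures ramp linearly between postures, templates are
jittered from repetition to repetition, and additive Gaussian noise and
a slow random-walk drift corrupt the voltages.  A "commands" track holds
the instructed class per sample and a separate "truth" track holds the
class actually being performed (commands shifted by the simulated
response delay), so downstream delay-compensation logic can be tested
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .exceptions import ConfigurationError, ParseError

#: Number of force channels on the strap.
N_CHANNELS = 8

_CSV_COLUMNS = ["time_s"] + [f"ch{i}" for i in range(1, N_CHANNELS + 1)] + [
    "command",
    "truth",
]


@dataclass(frozen=True)
class SensorConfig:
    """Electrical and noise model of one strap channel.

    Parameters
    ----------
    supply_voltage
        Divider supply Vcc in volts.
    base_resistance
        Fixed divider resistor in ohms.
    rest_resistance
        FSR resistance in ohms with no applied pressure (> 10 MOhm for a
        polymer thick-film sensor at rest).
    contact_pressure
        Pressure (arbitrary units) below which the sensor stays at
        ``rest_resistance``.
    resistance_scale
        Coefficient of the inverse-pressure law, ohm * pressure-units:
        above contact, ``R_fsr = resistance_scale / p`` (clamped at
        ``rest_resistance``).
    noise_sd
        Additive Gaussian voltage noise per sample, volts.
    drift_sd
        Standard deviation of the integrated random-walk drift
        accumulated over one minute, volts.
    sample_rate
        Sampling rate in Hz.
    """

    supply_voltage: float = 5.0
    base_resistance: float = 22_000.0
    rest_resistance: float = 1.0e7
    contact_pressure: float = 0.01
    resistance_scale: float = 22_000.0
    noise_sd: float = 0.01
    drift_sd: float = 0.005
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ConfigurationError("supply_voltage must be positive")
        if self.base_resistance <= 0:
            raise ConfigurationError("base_resistance must be positive")
        if self.rest_resistance < self.base_resistance:
            raise ConfigurationError(
                "rest_resistance must be at least base_resistance"
            )
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ConfigurationError("noise/drift standard deviations must be >= 0")
        if self.contact_pressure < 0 or self.resistance_scale <= 0:
            raise ConfigurationError(
                "contact_pressure must be >= 0 and resistance_scale > 0"
            )


@dataclass(frozen=True)
class PostureTemplate:
    """Abstract per-posture pressure pattern over the 8 strap channels."""

    class_label: int
    channel_pressures: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.channel_pressures, dtype=float)
        if p.shape != (N_CHANNELS,):
            raise ConfigurationError(
                f"template for class {self.class_label} must have exactly "
                f"{N_CHANNELS} channel pressures"
            )
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ConfigurationError("channel pressures must be finite and >= 0")
        object.__setattr__(self, "channel_pressures", tuple(float(v) for v in p))

    @property
    def pressures(self) -> np.ndarray:
        return np.asarray(self.channel_pressures, dtype=float)


@dataclass(frozen=True)
class SessionScript:
    """Ordered posture instructions plus subject-behaviour parameters.

    ``steps`` is a sequence of ``(class_label, duration_s)`` pairs.  After
    each new command the simulated subject waits a uniform response delay
    drawn from ``response_delay_range`` before starting to move, then
    ramps linearly to the new posture over ``transition_duration``.
    ``rep_jitter_sd`` is the fractional template perturbation applied
    independently to every scripted step, emulating rep-to-rep pattern
    variation.
    """

    steps: tuple[tuple[int, float], ...]
    response_delay_range: tuple[float, float] = (0.5, 1.5)
    transition_duration: float = 0.5
    rep_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        steps = tuple((int(lbl), float(dur)) for lbl, dur in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ConfigurationError("script must contain at least one step")
        if any(dur <= 0 for _, dur in steps):
            raise ConfigurationError("step durations must be positive")
        lo, hi = self.response_delay_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("response_delay_range must satisfy 0 <= min <= max")
        if self.transition_duration < 0:
            raise ConfigurationError("transition_duration must be >= 0")
        if self.rep_jitter_sd < 0:
            raise ConfigurationError("rep_jitter_sd must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(dur for _, dur in self.steps))


@dataclass
class RawRecording:
    """A 1 kHz multichannel voltage stream with aligned label tracks.

    ``commands`` holds the instructed class per sample (0 = none) and
    ``truth`` the class actually performed, i.e. the commands shifted by
    the simulated response delays.  ``response_delays`` records the drawn
    per-transition delays (seconds), when known.
    """

    sample_rate: float
    voltages: np.ndarray
    commands: np.ndarray
    truth: np.ndarray
    response_delays: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.commands = np.asarray(self.commands, dtype=int)
        self.truth = np.asarray(self.truth, dtype=int)
        if self.voltages.ndim != 2 or self.voltages.shape[1] != N_CHANNELS:
            raise ConfigurationError(
                f"voltages must be (n_samples, {N_CHANNELS})"
            )
        n = self.voltages.shape[0]
        if self.commands.shape != (n,) or self.truth.shape != (n,):
            raise ConfigurationError(
                "voltages, commands and truth must have equal length"
            )

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def slice(self, start: int, stop: int) -> "RawRecording":
        """Sub-recording over sample indices [start, stop)."""
        return RawRecording(
            sample_rate=self.sample_rate,
            voltages=self.voltages[start:stop],
            commands=self.commands[start:stop],
            truth=self.truth[start:stop],
        )


def fsr_resistance(p, cfg: SensorConfig) -> np.ndarray:
    """FSR resistance (ohms) at pressure ``p``.

    Rest resistance below the contact threshold, then an inverse-pressure
    law ``resistance_scale / p`` clamped at the rest value — log R falls
    linearly in log p, the standard behaviour of polymer thick-film FSRs.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    with np.errstate(divide="ignore"):
        loaded = cfg.resistance_scale / np.where(p > 0, p, np.inf)
    r = np.where(
        p <= cfg.contact_pressure,
        cfg.rest_resistance,
        np.minimum(cfg.rest_resistance, loaded),
    )
    return r


def pressure_to_voltage(p, cfg: SensorConfig | None = None) -> np.ndarray | float:
    """Voltage-divider output (volts) for pressure ``p`` (scalar or array).

    Strictly non-decreasing in ``p`` and bounded by ``[V(0), supply_voltage)``.
    """
    if cfg is None:
        cfg = SensorConfig()
    scalar = np.isscalar(p)
    r = fsr_resistance(p, cfg)
    v = cfg.supply_voltage * cfg.base_resistance / (cfg.base_resistance + r)
    return float(v) if scalar else v


def default_templates(
    seed: int,
    n_classes: int = 6,
    low: float = 0.5,
    high: float = 5.0,
    min_distance: float = 2.0,
    max_tries: int = 1000,
) -> list[PostureTemplate]:
    """Draw ``n_classes`` well-separated posture templates.

    Channel pressures are uniform on [low, high]; the draw is rejected
    until the minimum pairwise Euclidean distance between templates
    reaches ``min_distance``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pressures = rng.uniform(low, high, size=(n_classes, N_CHANNELS))
        if n_classes < 2 or pdist(pressures).min() >= min_distance:
            return [
                PostureTemplate(class_label=i + 1, channel_pressures=tuple(row))
                for i, row in enumerate(pressures)
            ]
    raise ConfigurationError(
        f"could not draw {n_classes} templates with min pairwise distance "
        f"{min_distance} in {max_tries} tries; lower min_distance"
    )


def generate_session(
    script: SessionScript,
    templates: Sequence[PostureTemplate],
    cfg: SensorConfig,
    seed: int,
) -> RawRecording:
    """Simulate one strap recording for a scripted posture sequence.

    The commands track follows the script exactly.  At each command
    change the performed posture (truth track) switches only after a
    per-step uniform response delay, then the channel pressures ramp
    linearly to the new (jittered) template over the transition duration.
    Voltages are the divider response plus Gaussian noise and random-walk
    drift, clipped to [0, supply_voltage].  Bit-reproducible for a given
    seed.
    """
    by_label = {t.class_label: t.pressures for t in templates}
    for lbl, _ in script.steps:
        if lbl not in by_label:
            raise ConfigurationError(f"no posture template for scripted class {lbl}")

    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate
    n_steps = len(script.steps)

    durations = [dur for _, dur in script.steps]
    bounds = np.round(np.cumsum([0.0] + durations) * fs).astype(int)
    n = int(bounds[-1])
    times = np.arange(n) / fs

    commands = np.empty(n, dtype=int)
    for k, (lbl, _) in enumerate(script.steps):
        commands[bounds[k] : bounds[k + 1]] = lbl

    # One jittered pressure target per scripted step.
    targets = np.empty((n_steps, N_CHANNELS))
    for k, (lbl, _) in enumerate(script.steps):
        base = by_label[lbl]
        jit = rng.normal(0.0, script.rep_jitter_sd, N_CHANNELS) if script.rep_jitter_sd > 0 else 0.0
        targets[k] = np.clip(base * (1.0 + jit), 0.0, None)

    lo, hi = script.response_delay_range
    delays = rng.uniform(lo, hi, size=n_steps)
    delays[0] = 0.0  # the session starts already in the first posture

    # Piecewise-linear pressure knots: hold, then ramp after each delayed
    # change.  A ramp shorter than half a sample stands in for an
    # instantaneous switch so the knot abscissae stay strictly increasing.
    tau = max(script.transition_duration, 0.5 / fs)
    truth = np.empty(n, dtype=int)
    truth[:] = script.steps[0][0]
    knot_t = [0.0]
    knot_v = [targets[0]]
    actual_delays = []
    for k in range(1, n_steps):
        t_cmd = bounds[k] / fs
        t_change = min(t_cmd + delays[k], (n - 1) / fs)
        t_change = max(t_change, knot_t[-1] + 0.5 / fs)
        actual_delays.append(t_change - t_cmd)
        knot_t.extend([t_change, t_change + tau])
        knot_v.extend([knot_v[-1], targets[k]])
        truth[int(round(t_change * fs)) :] = script.steps[k][0]

    knot_t_arr = np.asarray(knot_t)
    knot_v_arr = np.asarray(knot_v)
    pressures = np.empty((n, N_CHANNELS))
    for c in range(N_CHANNELS):
        pressures[:, c] = np.interp(times, knot_t_arr, knot_v_arr[:, c])

    voltages = pressure_to_voltage(pressures, cfg)
    if cfg.noise_sd > 0:
        voltages = voltages + rng.normal(0.0, cfg.noise_sd, size=voltages.shape)
    if cfg.drift_sd > 0:
        step_sd = cfg.drift_sd * np.sqrt(1.0 / (60.0 * fs))
        drift = np.cumsum(rng.normal(0.0, step_sd, size=voltages.shape), axis=0)
        voltages = voltages + drift
    voltages = np.clip(voltages, 0.0, cfg.supply_voltage)

    return RawRecording(
        sample_rate=fs,
        voltages=voltages,
        commands=commands,
        truth=truth,
        response_delays=np.asarray(actual_delays),
    )


def concatenate_recordings(recordings: Sequence[RawRecording]) -> RawRecording:
    """Join recordings end to end (all must share one sample rate)."""
    if not recordings:
        raise ConfigurationError("nothing to concatenate")
    fs = recordings[0].sample_rate
    if any(r.sample_rate != fs for r in recordings):
        raise ConfigurationError("sample rates differ across recordings")
    return RawRecording(
        sample_rate=fs,
        voltages=np.vstack([r.voltages for r in recordings]),
        commands=np.concatenate([r.commands for r in recordings]),
        truth=np.concatenate([r.truth for r in recordings]),
    )


def write_recording(recording: RawRecording, path) -> None:
    """Write a recording as CSV: ``time_s, ch1..ch8, command, truth``."""
    df = pd.DataFrame(
        recording.voltages, columns=[f"ch{i}" for i in range(1, N_CHANNELS + 1)]
    )
    df.insert(0, "time_s", recording.times)
    df["command"] = recording.commands
    df["truth"] = recording.truth
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path, sample_rate: float | None = None) -> RawRecording:
    """Read a session CSV written by :func:`write_recording`.

    The sample rate is inferred from the time column unless given.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse session file {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"session file {path} is missing required column(s) {missing} "
            f"(line 1: header {list(df.columns)})"
        )
    bad = df[_CSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"session file {path}: malformed value at line {line}")
    if sample_rate is None:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ParseError(f"session file {path}: too few samples to infer rate")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(
        sample_rate=float(sample_rate),
        voltages=df[[f"ch{i}" for i in range(1, N_CHANNELS + 1)]].to_numpy(float),
        commands=df["command"].to_numpy(int),
        truth=df["truth"].to_numpy(int),
    )
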