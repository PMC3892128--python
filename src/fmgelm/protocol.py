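"""Drinking-task experiment protocol: training-buffer assembly, model
fitting, and streaming classification of a test session.

Training phase: the subject holds each of six postures (relax, 90 deg
elbow flexion, fingers extension, soft grasp, 120 deg elbow flexion,
wrist pronation) for 7 s while 5 s of data are recorded, repeated three
times.  Each 5 s segment passes through the filter/decimator chain and
contributes exactly 50 feature samples, so the default training buffer
holds 6 x 3 x 50 = 900 labelled samples.  Min-max normalization is
fitted on this buffer and stored with the model.

Testing phase: a scripted sequence of 10 posture instructions per
repetition (up through the drinking motion and back down), repeated
three times.  The recorded stream is classified causally at the 10 Hz
decimator rate; command and ground-truth tracks are aligned to the same
grid by taking the label at each analysis window's end.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import elm
from .exceptions import ConfigurationError, ParseError, ProtocolError
from .preprocess import (
    DecimatorSpec,
    FilterSpec,
    NormalizationParams,
    apply_normalization,
    decimate_mean,
    fit_normalization,
    lowpass,
)
from .sensor import (
    PostureTemplate,
    RawRecording,
    SensorConfig,
    SessionScript,
    concatenate_recordings,
    generate_session,
)

logger = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = {
    1: "Relax",
    2: "90 deg Elbow Flexion",
    3: "Fingers Extension",
    4: "Soft Grasp",
    5: "120 deg Elbow Flexion",
    6: "Wrist Pronation",
}


@dataclass(frozen=True)
class TrainingProtocol:
    """Hold-and-record schedule of the training phase."""

    class_labels: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    class_names: tuple[str, ...] = tuple(DEFAULT_CLASS_NAMES.values())
    hold_duration: float = 7.0
    record_duration: float = 5.0
    repetitions: int = 3

    def __post_init__(self) -> None:
        if self.record_duration > self.hold_duration:
            raise ConfigurationError("record_duration must not exceed hold_duration")
        if self.repetitions < 1:
            raise ConfigurationError("need at least one repetition")
        if len(self.class_labels) < 2:
            raise ConfigurationError("need at least two classes")


@dataclass(frozen=True)
class TestProtocol:
    """Instruction sequence of the drinking-task test phase.

    The default sequence [1, 2, 3, 4, 5, 6, 5, 4, 3, 1] runs up through
    the drinking motion and back down (supinate, extend the elbow,
    extend the fingers, relax).  Every instruction lasts
    ``instruction_duration`` except the opening relax instruction of
    each repetition, which lasts ``class1_duration``.
    """

    __test__ = False  # not a pytest test class

    instruction_labels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 5, 4, 3, 1)
    instruction_duration: float = 3.0
    class1_duration: float = 5.0
    repetitions: int = 3

    def __post_init__(self) -> None:
        if self.instruction_duration <= 0 or self.class1_duration <= 0:
            raise ConfigurationError("instruction durations must be positive")
        if self.repetitions < 1:
            raise ConfigurationError("need at least one repetition")

    def step_durations(self) -> list[float]:
        """Per-instruction durations for one repetition."""
        return [
            self.class1_duration if (i == 0 and lbl == 1) else self.instruction_duration
            for i, lbl in enumerate(self.instruction_labels)
        ]


@dataclass
class TrainingSet:
    """Normalized training buffer: N x 8 features with class labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.shape[0]:
            raise ProtocolError("features and labels must have matching length")

    @property
    def N(self) -> int:
        return self.features.shape[0]


@dataclass
class SessionRecord:
    """10 Hz timeline of (command, truth, prediction) label triples."""

    timestamps: np.ndarray
    commands: np.ndarray
    truth: np.ndarray
    predictions: np.ndarray
    rate: float = 10.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.commands = np.asarray(self.commands, dtype=int)
        self.truth = np.asarray(self.truth, dtype=int)
        self.predictions = np.asarray(self.predictions, dtype=int)
        n = self.timestamps.shape[0]
        if not (
            self.commands.shape == (n,)
            and self.truth.shape == (n,)
            and self.predictions.shape == (n,)
        ):
            raise ProtocolError("session record tracks must have equal length")

    def __len__(self) -> int:
        return self.timestamps.shape[0]


def simulate_training_session(
    protocol: TrainingProtocol,
    templates: list[PostureTemplate],
    cfg: SensorConfig,
    seed: int,
    rep_jitter_sd: float = 0.05,
) -> RawRecording:
    """Simulate the full training phase as one concatenated recording.

    Each (repetition, class) pair is one steady ``hold_duration`` hold
    with its own jittered template; the subject is already in posture
    when the hold starts (no response delay inside a hold).
    """
    rng = np.random.default_rng(seed)
    segments = []
    for _rep in range(protocol.repetitions):
        for lbl in protocol.class_labels:
            script = SessionScript(
                steps=((lbl, protocol.hold_duration),),
                response_delay_range=(0.0, 0.0),
                transition_duration=0.0,
                rep_jitter_sd=rep_jitter_sd,
            )
            seg_seed = int(rng.integers(0, 2**31))
            segments.append(generate_session(script, templates, cfg, seg_seed))
    return concatenate_recordings(segments)


def split_training_session(
    raw: RawRecording, protocol: TrainingProtocol
) -> dict[tuple[int, int], RawRecording]:
    """Split a concatenated training recording into (class, rep) segments.

    Segments are contiguous runs of the command track; repetitions are
    counted per class in order of appearance.
    """
    cmds = raw.commands
    change = np.flatnonzero(np.diff(cmds)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(cmds)]])
    segments: dict[tuple[int, int], RawRecording] = {}
    seen: dict[int, int] = {}
    for s, e in zip(starts, stops):
        lbl = int(cmds[s])
        seen[lbl] = seen.get(lbl, 0) + 1
        segments[(lbl, seen[lbl])] = raw.slice(int(s), int(e))
    return segments


def build_training_set(
    segments: dict[tuple[int, int], RawRecording],
    protocol: TrainingProtocol = TrainingProtocol(),
    filter_spec: FilterSpec = FilterSpec(),
    dec_spec: DecimatorSpec = DecimatorSpec(),
) -> tuple[TrainingSet, NormalizationParams]:
    """Assemble the normalized training buffer from per-(class, rep)
    recordings.

    The central ``record_duration`` window of each hold is filtered,
    decimated and truncated to exactly
    ``record_duration * sample_rate / step`` feature samples (50 at
    defaults), then all segments are concatenated, normalization is
    fitted on the buffer and applied.
    """
    fs = filter_spec.sample_rate
    n_keep = int(round(protocol.record_duration * fs / dec_spec.step))
    feats_list, labels_list = [], []
    for lbl in protocol.class_labels:
        for rep in range(1, protocol.repetitions + 1):
            if (lbl, rep) not in segments:
                raise ProtocolError(
                    f"missing training segment for class {lbl}, repetition {rep}"
                )
            seg = segments[(lbl, rep)]
            need = int(round(protocol.record_duration * fs))
            if seg.n_samples < need:
                raise ProtocolError(
                    f"training segment for class {lbl}, repetition {rep} is "
                    f"{seg.n_samples / fs:.2f} s, shorter than the "
                    f"{protocol.record_duration} s record window"
                )
            start = (seg.n_samples - need) // 2  # centered within the hold
            crop = seg.slice(start, start + need)
            filtered = lowpass(crop, filter_spec)
            feats, _ = decimate_mean(filtered, dec_spec)
            if feats.shape[0] < n_keep:
                raise ProtocolError(
                    f"class {lbl} rep {rep}: expected {n_keep} feature samples, "
                    f"got {feats.shape[0]}"
                )
            feats_list.append(feats[:n_keep])
            labels_list.append(np.full(n_keep, lbl))
    raw_features = np.vstack(feats_list)
    labels = np.concatenate(labels_list)
    params = fit_normalization(raw_features)
    training = TrainingSet(
        features=apply_normalization(raw_features, params), labels=labels
    )
    logger.info(
        "training buffer: N=%d samples (%d classes x %d reps x %d)",
        training.N,
        len(protocol.class_labels),
        protocol.repetitions,
        n_keep,
    )
    return training, params


def train_session(
    training: TrainingSet,
    norm: NormalizationParams,
    L: int = 200,
    C: float = 2.0**7,
    seed: int = 0,
    class_labels: tuple[int, ...] | None = None,
) -> elm.ELMModel:
    """Fit the ELM on a training buffer (closed-form; logs wall time)."""
    basis = elm.random_basis(L, training.features.shape[1], seed)
    t0 = time.perf_counter()
    model = elm.train(
        training.features,
        training.labels,
        basis,
        C,
        class_labels=class_labels,
        norm=norm,
    )
    logger.info(
        "trained ELM: N=%d, L=%d, C=%g in %.3f s",
        training.N,
        L,
        C,
        time.perf_counter() - t0,
    )
    return model


def build_test_script(
    protocol: TestProtocol,
    response_delay_range: tuple[float, float] = (0.5, 1.5),
    transition_duration: float = 0.5,
    rep_jitter_sd: float = 0.05,
) -> SessionScript:
    """Expand the test protocol into a flat session script."""
    steps: list[tuple[int, float]] = []
    for _rep in range(protocol.repetitions):
        durs = protocol.step_durations()
        steps.extend(zip(protocol.instruction_labels, durs))
    return SessionScript(
        steps=tuple(steps),
        response_delay_range=response_delay_range,
        transition_duration=transition_duration,
        rep_jitter_sd=rep_jitter_sd,
    )


def simulate_test_session(
    protocol: TestProtocol,
    templates: list[PostureTemplate],
    cfg: SensorConfig,
    seed: int,
    response_delay_range: tuple[float, float] = (0.5, 1.5),
    transition_duration: float = 0.5,
    rep_jitter_sd: float = 0.05,
) -> RawRecording:
    """Simulate the full test phase as one recording."""
    script = build_test_script(
        protocol, response_delay_range, transition_duration, rep_jitter_sd
    )
    return generate_session(script, templates, cfg, seed)


def classify_stream(
    model: elm.ELMModel,
    raw: RawRecording,
    filter_spec: FilterSpec = FilterSpec(),
    dec_spec: DecimatorSpec = DecimatorSpec(),
) -> SessionRecord:
    """Causally classify a recorded session at the decimator rate.

    Each prediction uses only samples up to its window end; command and
    truth tracks are sampled at the window-end instants, so the output
    is exactly what a live classifier running on the stream would log.
    """
    if raw.sample_rate != filter_spec.sample_rate:
        raise ConfigurationError(
            f"recording rate {raw.sample_rate} Hz != pipeline rate "
            f"{filter_spec.sample_rate} Hz"
        )
    if model.norm is None:
        raise ConfigurationError("model carries no normalization parameters")
    filtered = lowpass(raw, filter_spec)
    feats, ends = decimate_mean(filtered, dec_spec)
    x = apply_normalization(feats, model.norm)
    preds, _scores = elm.predict(model, x)
    return SessionRecord(
        timestamps=ends / raw.sample_rate,
        commands=raw.commands[ends - 1],
        truth=raw.truth[ends - 1],
        predictions=preds,
        rate=raw.sample_rate / dec_spec.step,
    )


def write_session_record(record: SessionRecord, path) -> None:
    """Write a session record as CSV ``time_s, command, truth, prediction``."""
    pd.DataFrame(
        {
            "time_s": record.timestamps,
            "command": record.commands,
            "truth": record.truth,
            "prediction": record.predictions,
        }
    ).to_csv(path, index=False, float_format="%.3f")


def read_session_record(path) -> SessionRecord:
    """Read a session record CSV written by :func:`write_session_record`."""
    df = pd.read_csv(path)
    required = ["time_s", "command", "truth", "prediction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"session record {path} is missing column(s) {missing}")
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    return SessionRecord(
        timestamps=t,
        commands=df["command"].to_numpy(int),
        truth=df["truth"].to_numpy(int),
        predictions=df["prediction"].to_numpy(int),
        rate=rate,
    )
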