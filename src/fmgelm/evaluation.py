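"""Session evaluation: response-delay estimation, delay compensation,
accuracy scoring, random-base stability, and table aggregation.

A live subject needs 0.5-1.5 s to react to each posture instruction, so
the raw prediction track lags the command track.  The response delay is
estimated at the relax -> elbow-flexion command transition (one per
repetition), as the time from the command change to the first
prediction of the target class; that transition is used because subject
response there is consistent and essentially free of misclassification.
Scoring then shifts the prediction track forward by the average delay
(rounded to the 10 Hz grid) before comparing it with the command track.

Stability re-trains the classifier with several fresh random hidden
bases on the same buffer and re-scores the same session offline,
quantifying how little the random basis choice matters.

Aggregation uses the sample (n-1) standard deviation and rounds
half-away-from-zero, the conventions of the summary rows in published
accuracy tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from . import elm
from .exceptions import EvaluationError
from .preprocess import DecimatorSpec, FilterSpec, NormalizationParams
from .protocol import SessionRecord, TrainingSet, classify_stream, train_session
from .sensor import RawRecording


@dataclass
class DelayEstimate:
    """Per-section response delays (seconds) with mean and sample SD."""

    delays: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)


@dataclass
class EvaluationReport:
    """Accuracy summary of one (delay-compensated) session."""

    overall_accuracy: float
    per_class_accuracy: dict[int, float]
    most_misclassified_class: tuple[int, ...]
    most_misclassified_accuracy: float
    confusion: np.ndarray
    class_labels: tuple[int, ...]
    n_samples: int


@dataclass
class StabilityReport:
    """Accuracies across hidden-basis re-trainings, with mean and sample SD."""

    accuracies: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)


def round_half_away(value: float, decimals: int) -> float:
    """Round to ``decimals`` places, ties away from zero (table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate(values: Sequence[float], decimals: int = 2) -> tuple[float, float]:
    """Mean and sample (n-1) SD, rounded half-away-from-zero."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise EvaluationError("need at least 2 values for a sample SD")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return round_half_away(mean, decimals), round_half_away(sd, decimals)


def estimate_delay(
    session: SessionRecord, from_class: int = 1, to_class: int = 2
) -> DelayEstimate:
    """Response delay at each ``from_class -> to_class`` command transition.

    The per-section delay is the time from the command change to the
    first subsequent prediction equal to ``to_class``.
    """
    cmds = session.commands
    starts = np.flatnonzero((cmds[:-1] == from_class) & (cmds[1:] == to_class)) + 1
    if starts.size == 0:
        raise EvaluationError(
            f"session has no {from_class} -> {to_class} command transition"
        )
    delays = []
    for i in starts:
        hits = np.flatnonzero(session.predictions[i:] == to_class)
        if hits.size == 0:
            raise EvaluationError(
                f"class {to_class} never predicted after the command change at "
                f"t={session.timestamps[i]:.1f} s"
            )
        delays.append(session.timestamps[i + hits[0]] - session.timestamps[i])
    delays_arr = np.asarray(delays)
    sd = float(np.std(delays_arr, ddof=1)) if delays_arr.size > 1 else float("nan")
    return DelayEstimate(delays=delays_arr, mean=float(np.mean(delays_arr)), sd=sd)


def compensate_delay(session: SessionRecord, delay: float) -> SessionRecord:
    """Advance the prediction track by ``round(delay * rate)`` samples.

    The overhanging head of the predictions and tail of the commands are
    dropped, so the compensated session is shorter by the shift length.
    """
    if delay < 0:
        raise EvaluationError("delay must be >= 0")
    shift = int(round(delay * session.rate))
    n = len(session)
    if shift >= n:
        raise EvaluationError(f"delay {delay} s exceeds the session length")
    if shift == 0:
        return session
    return SessionRecord(
        timestamps=session.timestamps[: n - shift],
        commands=session.commands[: n - shift],
        truth=session.truth[: n - shift],
        predictions=session.predictions[shift:],
        rate=session.rate,
    )


def score(
    session: SessionRecord, class_labels: Sequence[int] = (1, 2, 3, 4, 5, 6)
) -> EvaluationReport:
    """Accuracy of predictions against the command track.

    Overall accuracy is correct points over total points (percent);
    per-class accuracy conditions on the commanded class.  The most
    misclassified class is the one (or ties) with minimum per-class
    accuracy among classes that appear in the commands.
    """
    if len(session) == 0:
        raise EvaluationError("empty session")
    class_labels = tuple(int(l) for l in class_labels)
    cmds, preds = session.commands, session.predictions
    overall = float(np.mean(preds == cmds) * 100.0)
    index = {lbl: j for j, lbl in enumerate(class_labels)}
    K = len(class_labels)
    confusion = np.zeros((K, K), dtype=int)
    for c, p in zip(cmds, preds):
        if c in index and p in index:
            confusion[index[c], index[p]] += 1
    per_class: dict[int, float] = {}
    for lbl in class_labels:
        mask = cmds == lbl
        if mask.any():
            per_class[lbl] = float(np.mean(preds[mask] == lbl) * 100.0)
    worst = min(per_class.values())
    worst_classes = tuple(lbl for lbl, acc in per_class.items() if acc == worst)
    return EvaluationReport(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        most_misclassified_class=worst_classes,
        most_misclassified_accuracy=worst,
        confusion=confusion,
        class_labels=class_labels,
        n_samples=len(session),
    )


def evaluate_session(
    model: elm.ELMModel,
    raw: RawRecording,
    filter_spec: FilterSpec = FilterSpec(),
    dec_spec: DecimatorSpec = DecimatorSpec(),
    from_class: int = 1,
    to_class: int = 2,
) -> tuple[SessionRecord, DelayEstimate, EvaluationReport]:
    """Classify, estimate the response delay, compensate, and score."""
    record = classify_stream(model, raw, filter_spec, dec_spec)
    delay = estimate_delay(record, from_class, to_class)
    compensated = compensate_delay(record, delay.mean)
    return record, delay, score(compensated, model.class_labels)


def stability(
    training: TrainingSet,
    norm: NormalizationParams,
    test_raw: RawRecording,
    filter_spec: FilterSpec = FilterSpec(),
    dec_spec: DecimatorSpec = DecimatorSpec(),
    L: int = 200,
    C: float = 2.0**7,
    basis_seeds: Sequence[int] = (1, 2, 3, 4, 5),
    realtime_accuracy: float | None = None,
) -> StabilityReport:
    """Offline accuracy spread across fresh random hidden bases.

    Each seed re-trains on the same buffer with a new basis and re-runs
    the full delay-compensated scoring on the same session.  When the
    live run's accuracy is supplied it is included in the aggregate,
    mirroring how offline random-base results are tabulated alongside
    the real-time one.
    """
    accs: list[float] = []
    if realtime_accuracy is not None:
        accs.append(float(realtime_accuracy))
    for seed in basis_seeds:
        model = train_session(training, norm, L=L, C=C, seed=int(seed))
        _, _, report = evaluate_session(model, test_raw, filter_spec, dec_spec)
        accs.append(report.overall_accuracy)
    accs_arr = np.asarray(accs)
    return StabilityReport(
        accuracies=accs_arr,
        mean=float(np.mean(accs_arr)),
        sd=float(np.std(accs_arr, ddof=1)) if accs_arr.size > 1 else float("nan"),
    )


def transition_error_concentration(
    session: SessionRecord, halfwidth: float = 0.5
) -> tuple[float, float]:
    """Misclassification rates near vs away from command transitions.

    Returns ``(rate_near, rate_far)`` where "near" means within
    ``halfwidth`` seconds of any command change in the (compensated)
    session.  On sessions with posture transitions the near rate should
    dominate: transitional patterns are absent from the training buffer.
    """
    cmds = session.commands
    changes = np.flatnonzero(np.diff(cmds)) + 1
    if changes.size == 0:
        raise EvaluationError("session has no command transitions")
    t = session.timestamps
    near = np.zeros(len(session), dtype=bool)
    for i in changes:
        near |= np.abs(t - t[i]) <= halfwidth
    errors = session.predictions != cmds
    rate_near = float(np.mean(errors[near])) if near.any() else 0.0
    rate_far = float(np.mean(errors[~near])) if (~near).any() else 0.0
    return rate_near, rate_far


def format_report(
    delay: DelayEstimate,
    report: EvaluationReport,
    stability_report: StabilityReport | None = None,
    class_names: dict[int, str] | None = None,
) -> str:
    """Human-readable evaluation summary."""
    lines = ["Delay estimate (class 1 -> 2 transitions)"]
    for k, d in enumerate(delay.delays, 1):
        lines.append(f"  section {k}: {d:.1f} s")
    lines.append(f"  mean {delay.mean:.2f} s, SD {delay.sd:.2f} s")
    lines.append("")
    lines.append(f"Overall accuracy: {report.overall_accuracy:.2f} %")
    lines.append("Per-class accuracy:")
    for lbl in report.class_labels:
        if lbl in report.per_class_accuracy:
            name = (class_names or {}).get(lbl, f"class {lbl}")
            lines.append(f"  {lbl} ({name}): {report.per_class_accuracy[lbl]:.2f} %")
    worst = " & ".join(str(l) for l in report.most_misclassified_class)
    lines.append(
        f"Most misclassified: class {worst} "
        f"({report.most_misclassified_accuracy:.2f} %)"
    )
    if stability_report is not None:
        lines.append("")
        accs = ", ".join(f"{a:.1f}" for a in stability_report.accuracies)
        lines.append(f"Random-base stability: [{accs}] %")
        lines.append(
            f"  mean {stability_report.mean:.1f} %, SD {stability_report.sd:.1f} %"
        )
    return "\n".join(lines) + "\n"
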