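"""Shared fixtures: posture templates, sensor configs, and a helper that
runs the complete simulate -> train -> classify -> evaluate pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from fmgelm import evaluation, protocol, sensor


@pytest.fixture(scope="session")
def templates():
    return sensor.default_templates(0)


@pytest.fixture(scope="session")
def quiet_cfg():
    """Sensor with no noise and no drift."""
    return sensor.SensorConfig(noise_sd=0.0, drift_sd=0.0)


@dataclass
class PipelineResult:
    training: protocol.TrainingSet
    norm: object
    model: object
    test_raw: sensor.RawRecording
    record: protocol.SessionRecord
    delay: evaluation.DelayEstimate
    report: evaluation.EvaluationReport


def run_drinking_task(
    templates,
    seed: int = 0,
    noise_sd: float = 0.01,
    drift_sd: float = 0.005,
    rep_jitter_sd: float = 0.05,
    response_delay_range: tuple[float, float] = (0.5, 1.5),
    transition_duration: float = 0.5,
    basis_seed: int = 42,
) -> PipelineResult:
    """Simulate one subject's full session and run the whole pipeline."""
    cfg = sensor.SensorConfig(noise_sd=noise_sd, drift_sd=drift_sd)
    tp = protocol.TrainingProtocol()
    train_raw = protocol.simulate_training_session(
        tp, templates, cfg, seed=seed * 1000 + 1, rep_jitter_sd=rep_jitter_sd
    )
    segments = protocol.split_training_session(train_raw, tp)
    training, norm = protocol.build_training_set(segments)
    model = protocol.train_session(training, norm, seed=basis_seed)
    test_raw = protocol.simulate_test_session(
        protocol.TestProtocol(),
        templates,
        cfg,
        seed=seed * 1000 + 2,
        response_delay_range=response_delay_range,
        transition_duration=transition_duration,
        rep_jitter_sd=rep_jitter_sd,
    )
    record, delay, report = evaluation.evaluate_session(model, test_raw)
    return PipelineResult(
        training=training,
        norm=norm,
        model=model,
        test_raw=test_raw,
        record=record,
        delay=delay,
        report=report,
    )


@pytest.fixture(scope="session")
def pipeline():
    """The end-to-end pipeline runner."""
    return run_drinking_task


@pytest.fixture(scope="session")
def default_run(templates):
    """One full pipeline run at the default operating point."""
    return run_drinking_task(templates, seed=0)
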