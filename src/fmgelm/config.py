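"""Declarative run configuration: one YAML file drives the whole
pipeline (sensor model, signal chain, protocol, classifier, seeds).

Defaults materialize the reference operating point: 1 kHz sampling,
4 Hz low-pass, 200/100 moving-average decimation, 6 classes x 3
repetitions, L = 200 hidden nodes and C = 2^7 regularization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .preprocess import DecimatorSpec, FilterSpec
from .protocol import TestProtocol, TrainingProtocol
from .sensor import SensorConfig


@dataclass(frozen=True)
class ElmParams:
    L: int = 200
    C: float = 2.0**7
    basis_seed: int = 0


@dataclass(frozen=True)
class SimulationParams:
    """Behavioural/scenario parameters of the synthetic subject."""

    seed: int = 0
    template_seed: int = 0
    template_min_distance: float = 2.0
    template_low: float = 0.5
    template_high: float = 5.0
    rep_jitter_sd: float = 0.05
    response_delay_min: float = 0.5
    response_delay_max: float = 1.5
    transition_duration: float = 0.5

    @property
    def response_delay_range(self) -> tuple[float, float]:
        return (self.response_delay_min, self.response_delay_max)


@dataclass(frozen=True)
class RunConfig:
    """Aggregate configuration for simulate/train/classify/evaluate runs."""

    sensor: SensorConfig = field(default_factory=SensorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    decimator: DecimatorSpec = field(default_factory=DecimatorSpec)
    training: TrainingProtocol = field(default_factory=TrainingProtocol)
    test: TestProtocol = field(default_factory=TestProtocol)
    elm: ElmParams = field(default_factory=ElmParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["training"]["class_labels"] = list(d["training"]["class_labels"])
        d["training"]["class_names"] = list(d["training"]["class_names"])
        d["test"]["instruction_labels"] = list(d["test"]["instruction_labels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def sub(section: str, factory, **coerce):
            payload = dict(d.get(section, {}))
            for key, fn in coerce.items():
                if key in payload:
                    payload[key] = fn(payload[key])
            return factory(**payload)

        return cls(
            sensor=sub("sensor", SensorConfig),
            filter=sub("filter", FilterSpec),
            decimator=sub("decimator", DecimatorSpec),
            training=sub(
                "training",
                TrainingProtocol,
                class_labels=tuple,
                class_names=tuple,
            ),
            test=sub("test", TestProtocol, instruction_labels=tuple),
            elm=sub("elm", ElmParams),
            simulation=sub("simulation", SimulationParams),
        )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})
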