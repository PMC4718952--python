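"""Run configuration: YAML round-trip, defaults, and hashing."""

from __future__ import annotations

import dataclasses
import hashlib

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binding import DialysisGeometry, LevelScale
from .simulate import AssayDesign, DegradationModel, DrugRates

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate → estimate → compare run.

    All thresholds default to the assay conventions: b window [0.4, 0.7],
    stability gate 0.90 surviving fraction at 24 h, 5 % bound-tracer
    classification threshold.  Concentrations are nM, volumes µL, times h.
    """

    # cassette + binding
    v_sample: float = 100.0
    v_buffer: float = 300.0
    site_conc: float = 2.4
    tracer_name: str = "D3-morphine"
    tracer_drug: str = "morphine"
    tracer_kd: float = 2.0
    tracer_conc: float = 5.0
    inhibitor_name: str = "morphine"
    inhibitor_kd: float | None = 2.0
    titration_amounts: list[float] | None = None  # nM·µL; None -> auto grid

    # assay conditions
    dilution: float | None = 400.0
    esterase_inhibitors: bool = False
    replicates: int = 3
    noise_cv: float = 0.02
    incubation_time: float = 24.0
    seed: int = 0

    # estimation
    i50_scale: LevelScale = "buffer-initial"
    b_window: tuple[float, float] = (0.4, 0.7)
    stability_threshold: float = 0.90
    classification_threshold: float = 5.0
    per_replicate: bool = True

    # degradation rate table (per drug)
    degradation_rates: dict[str, dict[str, float]] | None = None

    # outputs
    output_dir: str = "edaffinity_out"
    log_level: str = "INFO"

    def geometry(self) -> DialysisGeometry:
        return DialysisGeometry(self.v_sample, self.v_buffer)

    def degradation_model(self) -> DegradationModel:
        if self.degradation_rates is None:
            return DegradationModel()
        return DegradationModel(
            {drug: DrugRates(**rates) for drug, rates in self.degradation_rates.items()}
        )

    def design(self) -> AssayDesign:
        return AssayDesign(
            site_conc=self.site_conc,
            tracer_kd=self.tracer_kd,
            inhibitor_kd=self.inhibitor_kd,
            tracer_conc=self.tracer_conc,
            tracer_name=self.tracer_name,
            tracer_drug=self.tracer_drug,
            inhibitor_name=self.inhibitor_name,
            titration_amounts=(
                tuple(self.titration_amounts) if self.titration_amounts is not None else None
            ),
            geometry=self.geometry(),
            dilution=self.dilution,
            esterase_inhibitors=self.esterase_inhibitors,
            replicates=self.replicates,
            noise_cv=self.noise_cv,
            incubation_time=self.incubation_time,
            seed=self.seed,
            i50_scale=self.i50_scale,
            degradation=self.degradation_model(),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["b_window"] = list(self.b_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "b_window" in d:
            d = {**d, "b_window": tuple(d["b_window"])}
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable sha256 over the canonical YAML form (provenance key)."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
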