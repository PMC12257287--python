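"""Instrument and job configuration.

A single YAML file declares the instrument (objectives, DMD, light source)
and, for `litho run`, a job (design, objective, exposure). The default
instrument bundled here describes a common setup: a 600 x 800 mirror DMD
projected through Nikon objectives, a 395 nm LED source measured at
2.96 mW full power, and a measured 20x pixel size of 0.702 um (561.6 um
projected width / 800 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .optics import DmdSpec, LightSource, Objective


class ConfigurationError(ValueError):
    """The configuration is missing or inconsistent."""


DEFAULT_CONFIG_YAML = """\
dmd:
  rows: 600
  cols: 800
light_source:
  max_power_mW: 2.96
  wavelength_um: 0.395
  dmd_slope_mW_per_unit_fraction: 2.71
  dmd_intercept_mW: -0.02
reference_objective: 20x
objectives:
  4x:
    magnification: 4
    na: 0.13
    immersion_index: 1.0
  10x:
    magnification: 10
    na: 0.45
    immersion_index: 1.0
  20x:
    magnification: 20
    na: 0.75
    immersion_index: 1.0
    measured_pixel_size_um: 0.702
  40x:
    magnification: 40
    na: 0.95
    immersion_index: 1.0
  100x:
    magnification: 100
    na: 1.25
    immersion_index: 1.515
"""


@dataclass(frozen=True)
class InstrumentConfig:
    """Resolved instrument: objectives, DMD raster, light source."""

    objectives: dict[str, Objective]
    dmd: DmdSpec
    light_source: LightSource
    reference_objective: str

    def objective(self, name: str) -> Objective:
        try:
            return self.objectives[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown objective {name!r}; available: {sorted(self.objectives)}"
            ) from None

    @property
    def reference(self) -> Objective:
        return self.objective(self.reference_objective)

    def pixel_size_um(self, objective_name: str) -> float:
        return self.objective(objective_name).pixel_size_um(self.reference)


@dataclass(frozen=True)
class JobConfig:
    """One print job: which design, through which objective, how long.

    Exactly one of ``time_ms`` / ``target_dose_mJ_mm2`` must be given; a
    dose target is converted to a time through the LED power model.
    """

    objective_name: str
    design_path: str
    pixel_pitch_um: float
    time_ms: float | None = None
    target_dose_mJ_mm2: float | None = None
    led_fraction: float = 1.0
    seed: int = 0
    output_dir: str = "litho_out"

    def __post_init__(self) -> None:
        if (self.time_ms is None) == (self.target_dose_mJ_mm2 is None):
            raise ConfigurationError(
                "exactly one of time_ms / target_dose_mJ_mm2 must be given"
            )
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel_pitch_um must be positive")
        if not 0 <= self.led_fraction <= 1:
            raise ConfigurationError("led_fraction must lie in [0, 1]")


def _build_instrument(data: dict) -> InstrumentConfig:
    try:
        dmd = DmdSpec(**data["dmd"])
        src = LightSource(**data["light_source"])
        objectives = {
            name: Objective(name=name, **params)
            for name, params in data["objectives"].items()
        }
        ref = data.get("reference_objective")
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid instrument configuration: {exc}") from exc
    if ref is None:
        measured = [n for n, o in objectives.items() if o.measured_pixel_size_um]
        if not measured:
            raise ConfigurationError(
                "no reference_objective given and no objective has a "
                "measured pixel size"
            )
        ref = measured[0]
    if ref not in objectives:
        raise ConfigurationError(f"reference objective {ref!r} not declared")
    return InstrumentConfig(
        objectives=objectives, dmd=dmd, light_source=src, reference_objective=ref
    )


def default_instrument() -> InstrumentConfig:
    return _build_instrument(yaml.safe_load(DEFAULT_CONFIG_YAML))


def load_config(path) -> tuple[InstrumentConfig, JobConfig | None]:
    """Load a YAML config; returns (instrument, job or None).

    Instrument sections missing from the file fall back to the bundled
    default instrument.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    defaults = yaml.safe_load(DEFAULT_CONFIG_YAML)
    for key in ("dmd", "light_source", "objectives", "reference_objective"):
        data.setdefault(key, defaults[key])
    instrument = _build_instrument(data)
    job = None
    if "job" in data:
        try:
            job = JobConfig(**data["job"])
        except TypeError as exc:
            raise ConfigurationError(f"invalid job configuration: {exc}") from exc
        instrument.objective(job.objective_name)  # fail fast on unknown name
    return instrument, job


def resolved_yaml(instrument: InstrumentConfig, job: JobConfig | None = None) -> str:
    """Fully resolved configuration echoed back as YAML, for provenance logs."""
    data = {
        "dmd": {"rows": instrument.dmd.rows, "cols": instrument.dmd.cols},
        "light_source": {
            "max_power_mW": instrument.light_source.max_power_mW,
            "wavelength_um": instrument.light_source.wavelength_um,
            "dmd_slope_mW_per_unit_fraction": instrument.light_source.dmd_slope_mW_per_unit_fraction,
            "dmd_intercept_mW": instrument.light_source.dmd_intercept_mW,
        },
        "reference_objective": instrument.reference_objective,
        "objectives": {
            name: {
                "magnification": o.magnification,
                "na": o.na,
                "immersion_index": o.immersion_index,
                "measured_pixel_size_um": o.measured_pixel_size_um,
            }
            for name, o in sorted(instrument.objectives.items())
        },
    }
    if job is not None:
        data["job"] = {k: v for k, v in vars(job).items()}
    return yaml.safe_dump(data, sort_keys=True)
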