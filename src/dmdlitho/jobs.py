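"""Job execution: tie planning, dosimetry, the driver and artifacts together."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import optics, simulate, tiling
from .config import ConfigurationError, InstrumentConfig, JobConfig, resolved_yaml
from .driver import DriverContract, SimulatedDriver


@dataclass
class JobLog:
    """Structured, ordered event log of one job run."""

    events: list[dict] = field(default_factory=list)

    def record(self, level: str, module: str, event: str, **params) -> None:
        self.events.append(
            {"level": level, "module": module, "event": event, "params": params}
        )

    def to_lines(self) -> list[str]:
        return [
            f"[{e['level']}] {e['module']}: {e['event']} "
            + json.dumps(e["params"], sort_keys=True)
            for e in self.events
        ]


@dataclass
class JobResult:
    plan: tiling.TilePlan
    dose: simulate.DoseMap
    cured: simulate.CureMap
    log: JobLog
    time_ms: float
    artifacts: dict[str, str]


def load_mask(path) -> np.ndarray:
    """Read a PNG/TIFF design mask; any nonzero pixel is ON."""
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot read design mask {path}: {exc}") from exc
    if img.ndim == 3:  # collapse RGB(A) — masks are logically binary
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) > 0


def run_job(
    instrument: InstrumentConfig,
    job: JobConfig,
    driver: DriverContract | None = None,
    cure_threshold_mJ_mm2: float = 0.5,
) -> JobResult:
    """Plan, execute (against the driver) and simulate one print job.

    Configuration problems (unknown objective, unreadable mask, impossible
    dose) surface before any driver call. Exposure time comes either
    directly from the job or from a target dose inverted through the LED
    power model. Artifacts: plan JSON + frame TIFF, stage CSV, dose and
    cure TIFFs, and a structured text log, all under ``job.output_dir``.
    """
    log = JobLog()
    log.record(
        "INFO", "config", "resolved",
        yaml=resolved_yaml(instrument, job),
    )
    objective = instrument.objective(job.objective_name)
    mask = load_mask(job.design_path)
    design = tiling.Design(mask=mask, pixel_pitch_um=job.pixel_pitch_um)

    px = instrument.pixel_size_um(job.objective_name)
    power = optics.led_power(job.led_fraction, instrument.light_source)
    area = optics.fov_area_mm2(px, instrument.dmd)
    if job.time_ms is not None:
        time_ms = job.time_ms
    else:
        if power <= 0:
            raise ConfigurationError(
                "target dose requested but LED power is zero at this setting"
            )
        time_ms = optics.exposure_time_for_dose(job.target_dose_mJ_mm2, power, area)
    log.record(
        "INFO", "jobs", "exposure_derived",
        time_ms=time_ms, power_mW=power, fov_area_mm2=area,
    )

    plan = tiling.plan_tiles(
        design, objective, instrument.dmd, time_ms,
        reference_objective=instrument.reference,
    )
    log.record(
        "INFO", "tiling", "planned",
        n_exposures=len(plan.exposures), skipped_empty=plan.skipped_empty,
    )

    if driver is None:
        driver = SimulatedDriver(pixel_size_um=px, power_mW=power)
    for e in plan.exposures:
        driver.move_stage(e.stage_x_um, e.stage_y_um)
        driver.project_frame(e.frame, e.time_ms)
        dose = optics.energy_dose(optics.exposure_energy(power, e.time_ms), area)
        log.record(
            "INFO", "driver", "exposure",
            x_um=e.stage_x_um, y_um=e.stage_y_um,
            on_fraction=e.on_fraction, time_ms=e.time_ms, dose_mJ_mm2=dose,
        )

    sigma = simulate.default_psf_sigma_um(
        instrument.light_source.wavelength_um, objective.na
    )
    dose_map = simulate.simulate_print(
        plan, power_mW=power, psf_sigma_um=sigma, jitter_sd_um=0.0, seed=job.seed,
    )
    cured = simulate.cure(dose_map, cure_threshold_mJ_mm2) if plan.exposures else (
        simulate.CureMap(grid=np.zeros((1, 1), bool), threshold_mJ_mm2=cure_threshold_mJ_mm2)
    )

    out = Path(job.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "plan_json": str(out / "plan.json"),
        "frames_tiff": str(out / "frames.tiff"),
        "stage_csv": str(out / "stage.csv"),
        "dose_tiff": str(out / "dose.tiff"),
        "cure_tiff": str(out / "cure.tiff"),
        "log": str(out / "job.log"),
    }
    tiling.save_plan(plan, artifacts["plan_json"], artifacts["frames_tiff"])
    plan.stage_positions().to_csv(artifacts["stage_csv"], index=False)
    dose_map.save_tiff(artifacts["dose_tiff"])
    cured.save_tiff(artifacts["cure_tiff"])
    log.record("INFO", "jobs", "artifacts_written", **artifacts)
    Path(artifacts["log"]).write_text("\n".join(log.to_lines()) + "\n")

    return JobResult(
        plan=plan, dose=dose_map, cured=cured, log=log,
        time_ms=time_ms, artifacts=artifacts,
    )
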