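"""End-to-end pipeline: simulate -> preprocess -> calibrate -> monitor -> analyse.

The pipeline mirrors the plant workflow: a calibration batch provides LOD
reference samples for the PLS moisture model and endpoint spectra for the
MSPC model; a separate monitored batch is then followed in "real time" -
moisture predicted from its NIR spectra, the endpoint detected from the
Q-statistic chart, and the mass-transfer resistances extracted from the
NIR-predicted drying curve.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import io as gio
from .masstransfer import analyze_run
from .mspc import build_mspc, detect_endpoint, q_statistic
from .pls import calibrate_moisture_model, predict_moisture, relative_error
from .preprocess import preprocess_pipeline
from .simulate import generate_spectra, sample_lod, simulate_drying
from .types import BedConfig, DryingRun, OpticsConfig, ResistanceFit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "default_truth", "default_bed"]


def default_truth() -> ResistanceFit:
    """Resistance parameters of the reference 600 L/min operating point."""
    return ResistanceFit(omega_ext=0.028, omega_max=0.58, f_w_crit=0.10, f_w_end=0.05)


def default_bed() -> BedConfig:
    return BedConfig()


class SimSection(BaseModel):
    duration: float = Field(7200.0, gt=0)
    dt: float = Field(1.0, gt=0, le=1.0)
    f_w_initial: float = Field(0.34, ge=0, lt=1)
    gas_flow: float = Field(600.0, ge=0)
    inlet_temp: float = 25.0
    inlet_water_conc: Optional[float] = Field(0.36, ge=0)
    omega_ext: float = Field(0.028, ge=0)
    omega_max: float = Field(0.58, ge=0)
    f_w_crit: float = Field(0.10, gt=0)
    f_w_end: float = Field(0.05, ge=0)
    lod_interval: float = Field(400.0, gt=0)
    lod_rel_noise_sd: float = Field(0.02, ge=0)


class PreprocessSection(BaseModel):
    block: int = Field(10, ge=1)
    window: int = Field(75, ge=1)


class PLSSection(BaseModel):
    max_lv: int = Field(5, ge=1)
    folds: int = Field(5, ge=2)
    n_lv: Optional[int] = None
    max_pair_gap: float = Field(30.0, gt=0)


class MSPCSection(BaseModel):
    n_pc: Optional[int] = None  # None -> cross-validated
    alpha: float = Field(0.95, gt=0, lt=1)
    run_length: int = Field(10, ge=1)
    endpoint_moisture: float = Field(0.02, gt=0, lt=1)
    n_training_batches: int = Field(7, ge=1)


class MTRSection(BaseModel):
    half_window: int = Field(36, ge=2)
    inlet: str = "estimate"

    @model_validator(mode="after")
    def _check_inlet(self):
        if self.inlet not in ("estimate", "known"):
            raise ValueError("mtr.inlet must be 'estimate' or 'known'")
        return self


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline."""

    sim: SimSection = SimSection()
    preprocess: PreprocessSection = PreprocessSection()
    pls: PLSSection = PLSSection()
    mspc: MSPCSection = MSPCSection()
    mtr: MTRSection = MTRSection()
    seed: int = 0
    lod_path: Optional[str] = None  # external LOD file; None -> synthesised
    write_spectra: bool = False

    @model_validator(mode="after")
    def _check_paths(self):
        if self.lod_path is not None and not Path(self.lod_path).exists():
            raise ValueError(f"configured LOD file does not exist: {self.lod_path}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _endpoint_rows(pp, run, criterion: float, lag: float) -> np.ndarray:
    """Preprocessed spectra whose (lag-corrected) moisture is below the criterion."""
    t_content = np.maximum(pp.timestamps - lag, run.time[0])
    f_content = np.interp(t_content, run.time, run.moisture_fraction)
    return pp.values[f_content < criterion]


def _simulate_batch(cfg: RunConfig, seed: int):
    bed = BedConfig(
        gas_flow=cfg.sim.gas_flow,
        inlet_temp=cfg.sim.inlet_temp,
        inlet_water_conc=cfg.sim.inlet_water_conc,
    )
    truth = ResistanceFit(
        omega_ext=cfg.sim.omega_ext,
        omega_max=cfg.sim.omega_max,
        f_w_crit=cfg.sim.f_w_crit,
        f_w_end=cfg.sim.f_w_end,
    )
    formulation = gio.load_formulation()
    from .masstransfer import aggregate_isotherm

    _, agg = aggregate_isotherm(formulation)
    run = simulate_drying(
        bed, truth, agg,
        duration=cfg.sim.duration, dt=cfg.sim.dt, f_w_initial=cfg.sim.f_w_initial,
    )
    rng = np.random.default_rng(seed)
    run.lod_samples = sample_lod(
        run, cfg.sim.lod_interval, cfg.sim.lod_rel_noise_sd, rng=rng
    )
    optics = OpticsConfig(rng_seed=seed)
    spectra = generate_spectra(run, optics)
    return run, spectra, formulation, agg


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full workflow and write artefacts plus a JSON report.

    Stage failures propagate with the stage name; artefacts written before
    the failure are left in place for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    report: dict = {"seed": seed, "settings": json.loads(config.model_dump_json())}

    logger.info("stage simulate: calibration batch (seed %d)", seed)
    cal_run, cal_spectra, formulation, agg = _simulate_batch(config, seed)
    logger.info("stage simulate: monitored batch (seed %d)", seed + 1)
    mon_run, mon_spectra, _, _ = _simulate_batch(config, seed + 1)
    gio.write_run(cal_run, out / "calibration_run.csv")
    gio.write_run(mon_run, out / "monitored_run.csv")
    gio.write_lod(cal_run.lod_samples, out / "calibration_lod.csv")
    if config.write_spectra:
        gio.write_spectra(cal_spectra, out / "calibration_spectra.csv")
        gio.write_spectra(mon_spectra, out / "monitored_spectra.csv")

    if config.lod_path is not None:
        lod = gio.read_lod(config.lod_path)
    else:
        lod = cal_run.lod_samples
    if not lod:
        raise ValueError("stage calibrate: no LOD samples available for PLS training")

    logger.info("stage preprocess: block=%d window=%d",
                config.preprocess.block, config.preprocess.window)
    cal_pp = preprocess_pipeline(cal_spectra, config.preprocess.block, config.preprocess.window)
    mon_pp = preprocess_pipeline(mon_spectra, config.preprocess.block, config.preprocess.window)

    logger.info("stage train-pls")
    pls_model = calibrate_moisture_model(
        cal_pp.values, cal_pp.timestamps, lod, cal_pp.wavelengths,
        n_lv=config.pls.n_lv, max_lv=config.pls.max_lv, folds=config.pls.folds,
        max_gap=config.pls.max_pair_gap,
    )
    gio.pls_to_json(pls_model, out / "pls_model.json")
    report["pls"] = {"n_lv": pls_model.n_lv,
                     "n_calibration_samples": pls_model.meta["n_calibration_samples"]}

    # calibration-quality metric against the LOD reference
    from .pls import pair_lod_with_spectra

    idx, ref = pair_lod_with_spectra(lod, cal_pp.timestamps, config.pls.max_pair_gap)
    pred_cal, _ = predict_moisture(pls_model, cal_pp.values[idx])
    report["pls"]["e_rel_percent"] = relative_error(pred_cal, ref)

    logger.info("stage mspc-build: endpoint criterion %.3f, %d NOC batches",
                config.mspc.endpoint_moisture, config.mspc.n_training_batches)
    # label each smoothed spectrum by the moisture of the material it actually
    # measured: the causal moving-average window centres (window-1)/2 spectra
    # in the past
    lag = (config.preprocess.window - 1) / 2.0 * config.preprocess.block
    rows = [_endpoint_rows(cal_pp, cal_run, config.mspc.endpoint_moisture, lag)]
    for extra in range(1, config.mspc.n_training_batches):
        sp = generate_spectra(cal_run, OpticsConfig(rng_seed=seed + 10 + extra))
        pp = preprocess_pipeline(sp, config.preprocess.block, config.preprocess.window)
        rows.append(_endpoint_rows(pp, cal_run, config.mspc.endpoint_moisture, lag))
    endpoint_rows = np.vstack(rows)
    if endpoint_rows.shape[0] < 10:
        raise ValueError(
            "stage mspc-build: fewer than 10 endpoint spectra below the moisture criterion"
        )
    mspc_model = build_mspc(
        endpoint_rows,
        n_pc="auto" if config.mspc.n_pc is None else config.mspc.n_pc,
        wavelength_grid=cal_pp.wavelengths,
    )
    gio.mspc_to_json(mspc_model, out / "mspc_model.json")
    report["mspc"] = {"n_pc": mspc_model.n_pc,
                      "limit_95": mspc_model.limit_95,
                      "limit_99": mspc_model.limit_99}

    logger.info("stage mspc-monitor")
    q = q_statistic(mspc_model, mon_pp.values)
    limit = mspc_model.limit_95 if config.mspc.alpha == 0.95 else mspc_model.limit_99
    ep = detect_endpoint(q, limit, config.mspc.run_length)
    chart = np.column_stack([
        mon_pp.timestamps, q,
        np.full_like(q, mspc_model.limit_95), np.full_like(q, mspc_model.limit_99),
        (q < limit).astype(float),
    ])
    np.savetxt(out / "q_chart.csv", chart, delimiter=",",
               header="time,Q,limit95,limit99,below_limit", comments="")
    report["endpoint"] = {
        "detected": ep is not None,
        "index_1based": None if ep is None else ep + 1,
        "time_s": None if ep is None else float(mon_pp.timestamps[ep]),
        "time_min": None if ep is None else float(mon_pp.timestamps[ep]) / 60.0,
    }

    logger.info("stage mtr-analyze (NIR-predicted moisture)")
    f_pred, _ = predict_moisture(pls_model, mon_pp.values)
    f_pred = np.clip(f_pred, 1e-6, 0.999)
    nir_run = DryingRun(
        time=mon_pp.timestamps,
        moisture_fraction=f_pred,
        bed_temp=np.interp(mon_pp.timestamps, mon_run.time, mon_run.bed_temp),
        inlet_temp=np.interp(mon_pp.timestamps, mon_run.time, mon_run.inlet_temp),
        bed=mon_run.bed,
        meta={"source": "pls_prediction"},
    )
    trace, fit = analyze_run(
        nir_run, formulation,
        half_window=config.mtr.half_window, inlet=config.mtr.inlet,
        aggregate_params=agg,
    )
    gio.resistance_to_json(fit, out / "resistance_fit.json")
    np.savetxt(
        out / "mtr_trace.csv",
        np.column_stack([trace.time, trace.F_w, trace.a_w, trace.c_s_star,
                         trace.ndot_w, trace.ndot_inf, trace.f_mtr, trace.omega_tot]),
        delimiter=",",
        header="time,F_w,a_w,C_S_star,Ndot_w,Ndot_inf,f_MTR,Omega_tot",
        comments="",
    )
    report["resistance"] = {
        "omega_ext_s": fit.omega_ext, "omega_ext_se": fit.omega_ext_se,
        "omega_max_s": fit.omega_max, "omega_max_se": fit.omega_max_se,
        "f_w_crit": fit.f_w_crit, "f_w_crit_se": fit.f_w_crit_se,
        "f_w_end": fit.f_w_end,
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
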