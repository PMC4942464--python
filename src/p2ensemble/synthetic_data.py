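"""Seeded generators for dose-response tables and calcium-trace ensembles.

The trace generator emulates the statistical structure the analysis
assumes: several independent experiments, log-spaced ATP concentrations,
tens of cells per condition, baseline fluorescence in the tens of FU,
transient responses at low/mid concentrations versus prolonged responses
above ~1e-4 M, a two-peak amplitude dose dependence, injected outlier
cells, and small vehicle artifacts. Every cell draws from its own counter-
derived substream, so per-cell output is independent of generation order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError, InvalidParameterError
from .hill_core import DoseResponsePoint, HillFit, hill_response
from .ensemble_model import EnsembleModel, ensemble_response
from .receptor_catalog import make_basis
from .trace_features import CalciumTrace

__all__ = [
    "DurationModel",
    "SimulationConfig",
    "two_peak_amplitude_model",
    "default_duration_model",
    "generate_dose_response",
    "generate_trace",
    "generate_experiment_set",
    "traces_to_frame",
    "stimuli_frame",
    "write_dataset",
]

# Generating coefficients for the default two-peak amplitude model:
# stimulatory P2Y1 and P2X7, inhibitory P2Y4.
TWO_PEAK_BASIS = ("P2Y1", "P2Y4", "P2X7")
TWO_PEAK_COEFFICIENTS = (1.8, -1.4, 0.6)


def two_peak_amplitude_model(species: str = "rodent", scale: float = 1.0) -> EnsembleModel:
    """Ensemble amplitude model with a sub-micromolar and a high-[ATP] peak."""
    basis = make_basis(TWO_PEAK_BASIS, species)
    coefs = scale * np.asarray(TWO_PEAK_COEFFICIENTS, dtype=float)
    return EnsembleModel(basis=basis, coefficients=coefs)


@dataclass(frozen=True)
class DurationModel:
    """FWHM of the calcium transient versus [ATP]: short below the high-[ATP]
    activation threshold, prolonged above it."""

    base_s: float = 10.0
    max_s: float = 100.0
    k_half: float = 6.0e-4
    hill_coeff: float = 4.0

    def __post_init__(self) -> None:
        if self.base_s <= 0 or self.max_s < self.base_s:
            raise InvalidParameterError("need 0 < base_s <= max_s")

    def __call__(self, concentration) -> float:
        theta = hill_response(concentration, self.k_half, self.hill_coeff)
        return self.base_s + (self.max_s - self.base_s) * theta


@dataclass
class SimulationConfig:
    """Every knob of the trace-ensemble generator, with defaults mirroring
    the experimental design the analysis targets."""

    seed: int = 0
    concentrations: Tuple[float, ...] = tuple(np.logspace(-9, -2, 11))
    n_experiments: int = 8
    cells_per_condition: Tuple[int, int] = (11, 55)
    sampling_interval: float = 0.5
    trace_duration: float = 300.0
    stimulus_time: float = 30.0
    baseline_fu: Tuple[float, float] = (23.0, 78.0)  # per-experiment mean range
    baseline_cell_cv: float = 0.2  # per-cell spread around the experiment mean
    noise_sd: float = 0.005  # fluorescence noise, in (F/F0)-1 units
    # injected outlier fraction tapers with concentration: high at the low
    # end of the dose range, low at the high end
    outlier_fraction: Tuple[float, float] = (0.10, 0.25)
    # amplitude suppression applied at the top concentration, emulating
    # non-specific effects of very high [ATP]
    top_conc_suppression: float = 0.35
    amplitude_jitter_sd: float = 0.15
    duration_jitter_sd: float = 0.10
    amp_duration_anticorr: float = 0.8  # injected below anticorr_threshold
    anticorr_threshold: float = 1.0e-4
    experiment_scale_sd: float = 0.15  # inter-experiment amplitude variability
    amplitude_scale: float = 1.5  # peak (F/F0)-1 at model response 1
    include_vehicle: bool = True
    vehicle_response_prob: float = 0.2
    vehicle_amplitude: float = 0.1
    rise_tau_s: float = 2.0
    amplitude_model: Optional[EnsembleModel] = None
    duration_model: Optional[DurationModel] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(np.diff(conc) <= 0) or np.any(conc <= 0):
            raise DataError("concentrations must be positive and strictly increasing")
        if self.n_experiments < 1 or self.cells_per_condition[0] < 1:
            raise DataError("counts must be positive")
        if self.cells_per_condition[0] > self.cells_per_condition[1]:
            raise DataError("cells_per_condition range inverted")
        lo, hi = self.outlier_fraction
        if not (0 <= lo <= hi <= 1):
            raise DataError("outlier_fraction must lie in [0, 1]")
        if self.sampling_interval <= 0 or self.trace_duration <= self.stimulus_time:
            raise DataError("invalid sampling grid")
        if self.amplitude_model is None:
            self.amplitude_model = two_peak_amplitude_model()
        if self.duration_model is None:
            self.duration_model = DurationModel()

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "concentrations_M": list(self.concentrations),
            "n_experiments": self.n_experiments,
            "cells_per_condition": list(self.cells_per_condition),
            "sampling_interval_s": self.sampling_interval,
            "trace_duration_s": self.trace_duration,
            "stimulus_time_s": self.stimulus_time,
            "baseline_fu_range": list(self.baseline_fu),
            "baseline_cell_cv": self.baseline_cell_cv,
            "noise_sd": self.noise_sd,
            "outlier_fraction": list(self.outlier_fraction),
            "top_conc_suppression": self.top_conc_suppression,
            "amplitude_jitter_sd": self.amplitude_jitter_sd,
            "duration_jitter_sd": self.duration_jitter_sd,
            "amp_duration_anticorr": self.amp_duration_anticorr,
            "anticorr_threshold_M": self.anticorr_threshold,
            "experiment_scale_sd": self.experiment_scale_sd,
            "amplitude_scale": self.amplitude_scale,
            "include_vehicle": self.include_vehicle,
            "vehicle_response_prob": self.vehicle_response_prob,
            "vehicle_amplitude": self.vehicle_amplitude,
            "rise_tau_s": self.rise_tau_s,
            "amplitude_model": self.amplitude_model.to_dict(),
            "duration_model": {
                "base_s": self.duration_model.base_s,
                "max_s": self.duration_model.max_s,
                "k_half_M": self.duration_model.k_half,
                "hill_coeff": self.duration_model.hill_coeff,
            },
            "note": (
                "variance components are tuned to make pipeline recovery tests "
                "meaningful, not measured from any dataset"
            ),
        }


def _model_curve(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, EnsembleModel):
        return lambda c: np.atleast_1d(ensemble_response(c, model))
    if isinstance(model, HillFit):
        return lambda c: np.atleast_1d(model.predict(c))
    if callable(model):
        return lambda c: np.atleast_1d(np.asarray(model(c), dtype=float))
    raise DataError(f"unsupported model type {type(model)!r}")


def generate_dose_response(
    model, concentrations, noise_sd: float = 0.0, seed: int = 0
) -> List[DoseResponsePoint]:
    """Model curve plus i.i.d. Gaussian noise, reproducible per seed."""
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    curve = _model_curve(model)(conc)
    rng = np.random.default_rng(seed)
    resp = curve + rng.normal(0.0, noise_sd, size=conc.shape)
    return [
        DoseResponsePoint(concentration=float(c), response=float(r))
        for c, r in zip(conc, resp)
    ]


# ---------------------------------------------------------------------------
# pulse shape: unit-peak double exponential with calibrated FWHM


def _pulse_peak_time(tau_r: float, tau_d: float) -> float:
    return math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)


def _pulse_fwhm(tau_r: float, tau_d: float) -> float:
    g = lambda t: math.exp(-t / tau_d) - math.exp(-t / tau_r)
    tp = _pulse_peak_time(tau_r, tau_d)
    half = g(tp) / 2.0
    left = optimize.brentq(lambda t: g(t) - half, 1e-12, tp)
    hi = tp
    while g(hi) > half:
        hi *= 2.0
    right = optimize.brentq(lambda t: g(t) - half, tp, hi)
    return right - left


@lru_cache(maxsize=64)
def _min_fwhm(tau_r: float) -> float:
    """Shortest pulse width reachable with this rise constant (tau_d -> tau_r)."""
    return _pulse_fwhm(tau_r, tau_r * 1.001)


@lru_cache(maxsize=4096)
def _tau_decay_for_fwhm(fwhm: float, tau_r: float) -> float:
    """Invert the pulse FWHM for the decay constant (FWHM is monotone in it)."""
    lo = tau_r * 1.001
    if _pulse_fwhm(tau_r, lo) >= fwhm:
        raise DataError(f"target FWHM {fwhm} too short for rise tau {tau_r}")
    hi = max(10.0 * tau_r, fwhm)
    while _pulse_fwhm(tau_r, hi) < fwhm:
        hi *= 2.0
        if hi > 1e7:  # pragma: no cover - defensive
            raise DataError("FWHM calibration failed to bracket")
    return optimize.brentq(lambda td: _pulse_fwhm(tau_r, td) - fwhm, lo, hi)


def _unit_pulse(t_rel: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    g = np.zeros_like(t_rel)
    pos = t_rel > 0
    g[pos] = np.exp(-t_rel[pos] / tau_d) - np.exp(-t_rel[pos] / tau_r)
    tp = _pulse_peak_time(tau_r, tau_d)
    peak = math.exp(-tp / tau_d) - math.exp(-tp / tau_r)
    return g / peak


def _build_trace(
    *,
    concentration: float,
    amplitude: float,
    fwhm_s: float,
    baseline_fu: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    cell_id: str,
    experiment_id: str,
) -> CalciumTrace:
    t = np.arange(0.0, config.trace_duration + 1e-9, config.sampling_interval)
    response = np.zeros_like(t)
    if amplitude > 0:
        floor = max(2.5 * config.sampling_interval, 1.02 * _min_fwhm(config.rise_tau_s))
        fwhm_s = max(fwhm_s, floor)
        tau_d = _tau_decay_for_fwhm(round(float(fwhm_s), 3), config.rise_tau_s)
        response = amplitude * _unit_pulse(t - config.stimulus_time, config.rise_tau_s, tau_d)
    if config.noise_sd > 0:
        response = response + rng.normal(0.0, config.noise_sd, size=t.shape)
    fluor = baseline_fu * (1.0 + response)
    np.clip(fluor, 1e-3, None, out=fluor)
    return CalciumTrace(
        time=t,
        fluorescence=fluor,
        stimulus_time=config.stimulus_time,
        cell_id=cell_id,
        experiment_id=experiment_id,
        concentration=concentration,
    )


def generate_trace(
    concentration: float,
    amplitude_model,
    duration_model: DurationModel,
    config: SimulationConfig,
    amplitude_jitter: float = 0.0,
    duration_jitter: float = 0.0,
    seed: int = 0,
) -> CalciumTrace:
    """One cell's trace from the amplitude/duration models plus cell jitter.

    The peak (F/F0)-1 is ``amplitude_scale * model(L) * (1 + jitter)``
    floored at 0; the pulse FWHM is calibrated to ``duration_model(L)``
    scaled by its own jitter.
    """
    rng = np.random.default_rng(seed)
    curve = _model_curve(amplitude_model)(np.asarray([concentration]))[0]
    amp = max(0.0, config.amplitude_scale * curve * (1.0 + amplitude_jitter))
    fwhm = duration_model(concentration) * max(0.1, 1.0 + duration_jitter)
    f0 = float(np.mean(config.baseline_fu))
    return _build_trace(
        concentration=concentration,
        amplitude=amp,
        fwhm_s=fwhm,
        baseline_fu=f0,
        config=config,
        rng=rng,
        cell_id="cell",
        experiment_id="exp",
    )


def generate_experiment_set(
    config: SimulationConfig,
) -> Tuple[List[CalciumTrace], dict]:
    """Full multi-experiment trace ensemble plus a ground-truth manifest.

    Inter-experiment variability enters through a per-experiment amplitude
    scale and baseline level. Injected outlier cells get their amplitude
    multiplied by a factor far outside the cell-jitter spread. Vehicle
    conditions carry occasional small mechanical-artifact responses.
    """
    amp_curve = _model_curve(config.amplitude_model)
    traces: List[CalciumTrace] = []
    truth_cells = []

    conditions = list(config.concentrations)
    if config.include_vehicle:
        conditions = [0.0] + conditions

    for e in range(config.n_experiments):
        exp_id = f"exp{e + 1:02d}"
        exp_rng = np.random.default_rng([config.seed, e, 0xE])
        exp_scale = float(
            np.exp(exp_rng.normal(0.0, config.experiment_scale_sd))
        )
        base_mean = float(exp_rng.uniform(*config.baseline_fu))
        log_lo = math.log10(config.concentrations[0])
        log_hi = math.log10(config.concentrations[-1])
        top_conc = config.concentrations[-1]
        for c_idx, conc in enumerate(conditions):
            cond_rng = np.random.default_rng([config.seed, e, c_idx, 0xC])
            n_cells = int(
                cond_rng.integers(
                    config.cells_per_condition[0], config.cells_per_condition[1] + 1
                )
            )
            # contamination tapers from the high end of the range at the
            # lowest dose to the low end at the highest dose
            frac_lo, frac_hi = config.outlier_fraction
            if conc > 0 and log_hi > log_lo:
                x = (math.log10(conc) - log_lo) / (log_hi - log_lo)
                out_frac = frac_hi + (frac_lo - frac_hi) * min(1.0, max(0.0, x))
            else:
                out_frac = frac_hi
            model_amp = 0.0 if conc == 0.0 else float(amp_curve(np.asarray([conc]))[0])
            if conc == top_conc and config.top_conc_suppression > 0:
                model_amp *= 1.0 - config.top_conc_suppression
            for k in range(n_cells):
                rng = np.random.default_rng([config.seed, e, c_idx, k])
                cell_id = f"{exp_id}_c{c_idx:02d}_n{k:03d}"
                f0 = max(
                    1.0,
                    rng.normal(base_mean, config.baseline_cell_cv * base_mean),
                )
                ja = float(rng.normal(0.0, config.amplitude_jitter_sd))
                if conc and conc < config.anticorr_threshold:
                    rho = config.amp_duration_anticorr
                    jd = -rho * ja + math.sqrt(max(0.0, 1 - rho * rho)) * float(
                        rng.normal(0.0, config.duration_jitter_sd)
                    )
                else:
                    jd = float(rng.normal(0.0, config.duration_jitter_sd))
                if conc == 0.0:
                    amp = (
                        config.vehicle_amplitude * float(rng.uniform(0.5, 1.5))
                        if rng.uniform() < config.vehicle_response_prob
                        else 0.0
                    )
                else:
                    amp = max(
                        0.0, config.amplitude_scale * exp_scale * model_amp * (1.0 + ja)
                    )
                is_outlier = bool(rng.uniform() < out_frac) and amp > 0
                if is_outlier:
                    amp *= float(rng.uniform(3.0, 5.0))
                fwhm = config.duration_model(conc) * max(0.1, 1.0 + jd) if conc else 12.0
                traces.append(
                    _build_trace(
                        concentration=conc,
                        amplitude=amp,
                        fwhm_s=fwhm,
                        baseline_fu=f0,
                        config=config,
                        rng=rng,
                        cell_id=cell_id,
                        experiment_id=exp_id,
                    )
                )
                truth_cells.append(
                    {
                        "experiment_id": exp_id,
                        "cell_id": cell_id,
                        "concentration_M": conc,
                        "true_amplitude": amp,
                        "true_fwhm_s": fwhm if amp > 0 else None,
                        "injected_outlier": is_outlier,
                    }
                )

    manifest = {
        "config": config.to_manifest(),
        "generating_coefficients": {
            m.name: float(a)
            for m, a in zip(
                config.amplitude_model.basis, config.amplitude_model.coefficients
            )
        },
        "n_traces": len(traces),
        "cells": truth_cells,
    }
    return traces, manifest


def traces_to_frame(traces: Sequence[CalciumTrace]) -> pd.DataFrame:
    """Long-form table: experiment_id, cell_id, concentration_M, time_s, fluorescence."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": tr.experiment_id,
                    "cell_id": tr.cell_id,
                    "concentration_M": tr.concentration,
                    "time_s": tr.time,
                    "fluorescence": tr.fluorescence,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def stimuli_frame(traces: Sequence[CalciumTrace]) -> pd.DataFrame:
    rows = {}
    for tr in traces:
        rows[tr.experiment_id] = tr.stimulus_time
    return pd.DataFrame(
        {"experiment_id": list(rows), "stimulus_time_s": list(rows.values())}
    ).sort_values("experiment_id", ignore_index=True)


def write_dataset(config: SimulationConfig, outdir: Union[str, Path]) -> dict:
    """Generate and write traces.csv, stimuli.csv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces, manifest = generate_experiment_set(config)
    traces_to_frame(traces).to_csv(outdir / "traces.csv", index=False)
    stimuli_frame(traces).to_csv(outdir / "stimuli.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
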