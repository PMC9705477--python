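"""Composable pipeline stages binding generators to fitters.

Each stage reads its inputs (CSV paths in ``config.inputs``), runs one
analysis or simulation step, writes its outputs plus the effective
configuration into ``config.out_dir``, and returns a dict of result paths
and headline numbers. Identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from coacerlab import io, nmr, phase, rheology, synth
from coacerlab.errors import InputError
from coacerlab.indus import uwham_unbias
from coacerlab.io import RunConfig

__all__ = ["run_pipeline", "STAGES"]


def _out(config: RunConfig, name: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def _stage_simulate_tracks(config: RunConfig) -> dict:
    p = config.params
    tracks = synth.gen_brownian_tracks(
        viscosity_pa_s=p["viscosity_pa_s"],
        probe_radius_m=p.get("probe_radius_m", 1e-6),
        temperature_k=p.get("temperature_k", 295.15),
        frame_interval_s=p.get("frame_interval_s", 0.02),
        n_frames=p.get("n_frames", 2000),
        n_particles=p.get("n_particles", 50),
        noise_sd_m=p.get("noise_sd_m", 0.0),
        seed=config.seed,
    )
    path = _out(config, "tracks.csv")
    io.write_tracks_csv(path, tracks)
    return {"tracks": str(path)}


def _stage_rheo_fit(config: RunConfig) -> dict:
    tracks = io.read_tracks_csv(config.inputs["tracks"])
    result = rheology.microrheology_pipeline(
        tracks, config.params.get("max_lag_fraction", 0.25)
    )
    path = _out(config, "rheology.json")
    path.write_text(
        json.dumps(
            {
                "D_probe_m2_s": result.d_probe_m2_s,
                "alpha": result.alpha,
                "eta_Pa_s": result.eta_pa_s,
                "fit_lags_s": result.fit_lags_s,
            },
            indent=1,
        )
    )
    return {"rheology": str(path), "eta_Pa_s": result.eta_pa_s}


def _stage_simulate_echo(config: RunConfig) -> dict:
    p = config.params
    gradients = np.asarray(
        p.get("gradients_g_cm", np.linspace(0, 800, 16))
    )
    decay = synth.gen_echo_decay(
        d_m2_s=p["d_m2_s"],
        gradients_g_cm=gradients,
        delta_s=p.get("delta_s", 1e-3),
        big_delta_s=p.get("big_delta_s", 20e-3),
        noise_sd=p.get("noise_sd", 0.0),
        seed=config.seed,
    )
    path = _out(config, "echo.csv")
    io.write_echo_csv(path, decay)
    return {"echo": str(path)}


def _stage_nmr_fit(config: RunConfig) -> dict:
    decay = io.read_echo_csv(config.inputs["echo"])
    fit = nmr.fit_diffusion(decay)
    path = _out(config, "diffusion.json")
    path.write_text(
        json.dumps({"D_m2_s": fit.d_m2_s, **fit.diagnostics}, indent=1)
    )
    return {"diffusion": str(path), "D_m2_s": fit.d_m2_s}


def _stage_simulate_coalescence(config: RunConfig) -> dict:
    p = config.params
    series = synth.gen_coalescence_series(
        eta_pa_s=p["eta_pa_s"],
        sigma_n_m=p["sigma_n_m"],
        droplet_radius_m=p.get("droplet_radius_m", 10e-6),
        a0=p.get("a0", 0.5),
        n_frames=p.get("n_frames", 50),
        noise_sd=p.get("noise_sd", 0.0),
        seed=config.seed,
    )
    path = _out(config, "coalescence.csv")
    io.write_coalescence_csv(path, series)
    return {"coalescence": str(path)}


def _stage_tension_fit(config: RunConfig) -> dict:
    series = io.read_coalescence_csv(config.inputs["coalescence"])
    tau, a0 = rheology.fit_relaxation_time(series)
    eta = config.params["eta_pa_s"]
    radius = config.params.get("droplet_radius_m", series.droplet_radius_m)
    sigma = rheology.interfacial_tension(tau, eta, radius)
    path = _out(config, "tension.json")
    path.write_text(
        json.dumps({"tau_s": tau, "A0": a0, "sigma_N_m": sigma}, indent=1)
    )
    return {"tension": str(path), "sigma_N_m": sigma}


def _stage_phase_windows(config: RunConfig) -> dict:
    curve = io.read_turbidity_csv(config.inputs["turbidity"])
    result = phase.detect_phase_windows(
        curve, config.params.get("threshold_fraction", 0.1)
    )
    path = _out(config, "windows.json")
    path.write_text(
        json.dumps(
            {
                "windows": result.windows,
                "reentrant": result.reentrant,
                "threshold_used": result.threshold_used,
            },
            indent=1,
        )
    )
    return {"windows": str(path), "n_windows": len(result.windows)}


def _stage_indus_unbias(config: RunConfig) -> dict:
    windows = io.read_umbrella_windows(config.inputs["windows"])
    profile = uwham_unbias(windows)
    path = _out(config, "profile.csv")
    io.write_profile_csv(path, profile)
    return {"profile": str(path), "N0": profile.n0}


STAGES = {
    "simulate_tracks": _stage_simulate_tracks,
    "rheo_fit": _stage_rheo_fit,
    "simulate_echo": _stage_simulate_echo,
    "nmr_fit": _stage_nmr_fit,
    "simulate_coalescence": _stage_simulate_coalescence,
    "tension_fit": _stage_tension_fit,
    "phase_windows": _stage_phase_windows,
    "indus_unbias": _stage_indus_unbias,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one named stage; write outputs and the effective config."""
    if config.stage not in STAGES:
        raise InputError(
            f"unknown stage {config.stage!r}; available: {sorted(STAGES)}"
        )
    config.write_effective()
    return STAGES[config.stage](config)
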