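"""CSV/JSON readers and writers shared by the analysis stages.

All tables are plain UTF-8 CSV with units encoded in the column names
(``x_um``, ``t_s``, ``g_Gcm``); scalar metadata travel in ``# key=value``
header lines so a file is self-describing. Ground-truth parameters of
synthetic datasets are serialized as a JSON sidecar next to the data file.
Parsing is locale-independent (decimal point only) and NaN cells are
rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coacerlab.errors import InputError, SchemaError
from coacerlab.indus import FreeEnergyProfile, UmbrellaWindow
from coacerlab.nmr import EchoDecay
from coacerlab.phase import Ramp, TurbidityCurve
from coacerlab.rheology import CoalescenceSeries, ProbeTracks

__all__ = [
    "RunConfig",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_echo_csv",
    "write_echo_csv",
    "read_coalescence_csv",
    "write_coalescence_csv",
    "read_turbidity_csv",
    "write_turbidity_csv",
    "read_umbrella_windows",
    "write_umbrella_windows",
    "write_profile_csv",
    "read_profile_csv",
    "write_ground_truth",
]

TRACKS_SCHEMA = ["particle_id", "frame", "x_um", "y_um"]
ECHO_SCHEMA = ["g_Gcm", "psi"]
COALESCENCE_SCHEMA = ["t_s", "A"]
TURBIDITY_SCHEMA = ["control", "od600"]
PROFILE_SCHEMA = ["N", "betaF_kBT"]


def _read_with_header(path: str | Path, required: list[str]):
    """Read a CSV with ``# key=value`` metadata lines; validate columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    meta: dict[str, str] = {}
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    bad = df[required].isna()
    if bad.to_numpy().any():
        rows = (np.nonzero(bad.to_numpy().any(axis=1))[0] + skip + 2).tolist()
        raise SchemaError(f"{path.name}: NaN cells at line(s) {rows[:10]}")
    return df, meta


def _write_with_header(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def _require_meta(meta: dict, key: str, name: str) -> float:
    if key not in meta:
        raise SchemaError(f"{name}: missing required header field {key!r}")
    return float(meta[key])


# -- particle tracks ---------------------------------------------------------

def write_tracks_csv(path, tracks: ProbeTracks) -> None:
    df = pd.DataFrame(
        {
            "particle_id": tracks.particle_ids,
            "frame": tracks.frames,
            "x_um": tracks.x_um,
            "y_um": tracks.y_um,
        }
    )
    meta = {
        "frame_interval_s": repr(tracks.frame_interval_s),
        "probe_radius_um": repr(tracks.probe_radius_m * 1e6),
        "temperature_K": repr(tracks.temperature_k),
    }
    _write_with_header(path, df, meta)
    if tracks.ground_truth is not None:
        write_ground_truth(path, tracks.ground_truth)


def read_tracks_csv(path) -> ProbeTracks:
    df, meta = _read_with_header(path, TRACKS_SCHEMA)
    return ProbeTracks(
        df["particle_id"].to_numpy(),
        df["frame"].to_numpy(),
        df["x_um"].to_numpy(),
        df["y_um"].to_numpy(),
        frame_interval_s=_require_meta(meta, "frame_interval_s", Path(path).name),
        probe_radius_m=_require_meta(meta, "probe_radius_um", Path(path).name) * 1e-6,
        temperature_k=_require_meta(meta, "temperature_K", Path(path).name),
    )


# -- PFG-NMR echo decays -----------------------------------------------------

def write_echo_csv(path, decay: EchoDecay) -> None:
    df = pd.DataFrame({"g_Gcm": decay.gradients_g_cm, "psi": decay.attenuation})
    meta = {
        "delta_ms": repr(decay.delta_s * 1e3),
        "Delta_ms": repr(decay.big_delta_s * 1e3),
        "gamma_per_s_G": repr(decay.gamma_per_s_g),
    }
    _write_with_header(path, df, meta)
    if decay.ground_truth is not None:
        write_ground_truth(path, decay.ground_truth)


def read_echo_csv(path) -> EchoDecay:
    df, meta = _read_with_header(path, ECHO_SCHEMA)
    name = Path(path).name
    return EchoDecay(
        df["g_Gcm"].to_numpy(),
        df["psi"].to_numpy(),
        delta_s=_require_meta(meta, "delta_ms", name) * 1e-3,
        big_delta_s=_require_meta(meta, "Delta_ms", name) * 1e-3,
        gamma_per_s_g=_require_meta(meta, "gamma_per_s_G", name),
    )


# -- coalescence relaxations -------------------------------------------------

def write_coalescence_csv(path, series: CoalescenceSeries) -> None:
    df = pd.DataFrame({"t_s": series.times_s, "A": series.aspect})
    meta = {}
    if series.droplet_radius_m is not None:
        meta["droplet_radius_um"] = repr(series.droplet_radius_m * 1e6)
    _write_with_header(path, df, meta)
    if series.ground_truth is not None:
        write_ground_truth(path, series.ground_truth)


def read_coalescence_csv(path) -> CoalescenceSeries:
    df, meta = _read_with_header(path, COALESCENCE_SCHEMA)
    radius = (
        float(meta["droplet_radius_um"]) * 1e-6
        if "droplet_radius_um" in meta
        else None
    )
    return CoalescenceSeries(
        df["t_s"].to_numpy(), df["A"].to_numpy(), droplet_radius_m=radius
    )


# -- turbidity curves --------------------------------------------------------

def write_turbidity_csv(path, curve: TurbidityCurve) -> None:
    df = pd.DataFrame({"control": curve.control, "od600": curve.od600})
    meta = {"ramp": curve.ramp.value}
    if curve.replicate_id is not None:
        meta["replicate"] = str(curve.replicate_id)
    _write_with_header(path, df, meta)


def read_turbidity_csv(path) -> TurbidityCurve:
    df, meta = _read_with_header(path, TURBIDITY_SCHEMA)
    return TurbidityCurve(
        df["control"].to_numpy(),
        df["od600"].to_numpy(),
        ramp=Ramp(meta.get("ramp", "none")),
        replicate_id=meta.get("replicate"),
    )


# -- umbrella windows and free-energy profiles -------------------------------

def write_umbrella_windows(directory, windows: list[UmbrellaWindow]) -> None:
    """One ``window_<k>.csv`` per window plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, w in enumerate(windows):
        fname = f"window_{k:03d}.csv"
        pd.DataFrame({"Nv": w.samples}).to_csv(directory / fname, index=False)
        manifest.append(
            {
                "file": fname,
                "nstar": w.nstar,
                "kappa_kBT": w.kappa_kt,
                "n_equilibration_discarded": w.n_equilibration_discarded,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_umbrella_windows(directory) -> list[UmbrellaWindow]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {directory}")
    out = []
    for entry in json.loads(manifest_path.read_text()):
        df = pd.read_csv(directory / entry["file"])
        if "Nv" not in df.columns:
            raise SchemaError(f"{entry['file']}: missing column 'Nv'")
        out.append(
            UmbrellaWindow(
                nstar=float(entry["nstar"]),
                kappa_kt=float(entry["kappa_kBT"]),
                samples=df["Nv"].to_numpy(),
                n_equilibration_discarded=int(
                    entry.get("n_equilibration_discarded", 0)
                ),
            )
        )
    return out


def write_profile_csv(path, profile: FreeEnergyProfile) -> None:
    df = pd.DataFrame({"N": profile.n_grid, "betaF_kBT": profile.beta_f})
    _write_with_header(path, df, {"N0": str(profile.n0)})


def read_profile_csv(path) -> FreeEnergyProfile:
    df, meta = _read_with_header(path, PROFILE_SCHEMA)
    n = df["N"].to_numpy(dtype=int)
    f = df["betaF_kBT"].to_numpy()
    n0 = int(meta.get("N0", n[np.argmin(f)]))
    return FreeEnergyProfile(n, f, n0)


def write_ground_truth(data_path, ground_truth) -> None:
    """JSON sidecar ``<data file>.truth.json`` recording generator params."""
    sidecar = Path(str(data_path) + ".truth.json")
    sidecar.write_text(json.dumps(ground_truth.to_dict(), indent=1))


# -- run configuration -------------------------------------------------------

_CONFIG_KEYS = {
    "stage", "inputs", "params", "seed", "out_dir", "log_level",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline stage run (strict key schema)."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        if "stage" not in raw:
            raise InputError("config must name a stage")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "inputs": self.inputs,
            "params": self.params,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    def write_effective(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "effective_config.json"
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path
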