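"""Seeded synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here from stated
physical parameters, so each estimator can be validated end to end against
the truth that produced its input: Brownian probe tracks at a known
viscosity, single-exponential echo decays at a known diffusivity,
exponential aspect-ratio relaxations at a known interfacial tension,
single- and double-window turbidity profiles with heating/cooling
hysteresis, exact i.i.d. umbrella-window samples from a tabulated free
energy under harmonic bias, Poisson-solvated point-cloud frames, and
ideal-chain ensembles. Identical parameters and seed reproduce identical
data; the :class:`GroundTruth` used is attached to every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from coacerlab.constants import (
    M_TO_UM,
    ROOM_TEMPERATURE_K,
    stokes_einstein_diffusivity,
)
from coacerlab.errors import CoacerlabError, ParameterError
from coacerlab.indus import MolecularFrame, UmbrellaWindow, parse_nstar_schedule
from coacerlab.nmr import EchoDecay, stejskal_tanner
from coacerlab.phase import Ramp, TurbidityCurve
from coacerlab.rheology import CoalescenceSeries, ProbeTracks
from coacerlab.chain import ChainEnsemble

__all__ = [
    "GroundTruth",
    "gen_brownian_tracks",
    "gen_echo_decay",
    "gen_coalescence_series",
    "gen_turbidity_profile",
    "gen_umbrella_windows",
    "gen_solvated_frame",
    "gen_chain_ensemble",
]


@dataclass
class GroundTruth:
    """Parameters (name → (value, unit)) and seed that produced a dataset."""

    params: dict[str, tuple[float | str, str]] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": {k: {"value": v, "unit": u} for k, (v, u) in self.params.items()},
        }


class GenerationError(CoacerlabError, RuntimeError):
    """A stochastic generator exhausted its retry budget."""


def gen_brownian_tracks(
    viscosity_pa_s: float,
    probe_radius_m: float = 1e-6,
    temperature_k: float = ROOM_TEMPERATURE_K,
    frame_interval_s: float = 0.02,
    n_frames: int = 2000,
    n_particles: int = 50,
    noise_sd_m: float = 0.0,
    seed: int = 0,
) -> ProbeTracks:
    """Free 2-D Brownian probe tracks in a medium of known viscosity.

    Increments per axis are Gaussian with variance ``2 D Δt`` where
    ``D = kB T / (6 π η r)`` (Stokes–Einstein); independent Gaussian
    localization noise of standard deviation ``noise_sd_m`` is added to
    every stored position, so the population MSD at lag τ is
    ``4 D τ + 4 noise_sd²`` in expectation. Tracks are unconfined and purely
    diffusive (no viscoelastic memory).
    """
    if viscosity_pa_s <= 0 or probe_radius_m <= 0 or temperature_k <= 0:
        raise ParameterError("viscosity, radius, temperature must be positive")
    if frame_interval_s <= 0:
        raise ParameterError("frame_interval must be positive")
    if n_frames < 2:
        raise ParameterError("need at least 2 frames")
    if n_particles < 1 or noise_sd_m < 0:
        raise ParameterError("invalid particle count or noise level")
    d = stokes_einstein_diffusivity(viscosity_pa_s, probe_radius_m, temperature_k)
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2.0 * d * frame_interval_s)
    steps = rng.normal(0.0, step_sd, size=(n_particles, n_frames - 1, 2))
    pos = np.concatenate(
        [np.zeros((n_particles, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if noise_sd_m > 0:
        pos = pos + rng.normal(0.0, noise_sd_m, size=pos.shape)
    pos_um = pos * M_TO_UM
    pids = np.repeat(np.arange(n_particles), n_frames)
    frames = np.tile(np.arange(n_frames), n_particles)
    gt = GroundTruth(
        {
            "viscosity": (viscosity_pa_s, "Pa s"),
            "D": (d, "m^2/s"),
            "probe_radius": (probe_radius_m, "m"),
            "temperature": (temperature_k, "K"),
            "noise_sd": (noise_sd_m, "m"),
        },
        seed,
    )
    return ProbeTracks(
        pids,
        frames,
        pos_um[:, :, 0].ravel(),
        pos_um[:, :, 1].ravel(),
        frame_interval_s,
        probe_radius_m,
        temperature_k,
        ground_truth=gt,
    )


def gen_echo_decay(
    d_m2_s: float,
    gradients_g_cm: np.ndarray,
    delta_s: float = 1e-3,
    big_delta_s: float = 20e-3,
    gamma_per_s_g: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EchoDecay:
    """Stejskal–Tanner echo decay at known D with multiplicative noise."""
    from coacerlab.constants import PROTON_GAMMA_PER_S_G

    if gamma_per_s_g is None:
        gamma_per_s_g = PROTON_GAMMA_PER_S_G
    if d_m2_s < 0:
        raise ParameterError("diffusivity must be non-negative")
    gradients = np.asarray(gradients_g_cm, dtype=float)
    if np.any(gradients < 0) or len(np.unique(gradients)) < 2:
        raise ParameterError("need >= 2 distinct non-negative gradients")
    if big_delta_s <= delta_s / 3.0:
        raise ParameterError("Delta must exceed delta/3")
    psi = np.asarray(
        stejskal_tanner(gradients, d_m2_s, delta_s, big_delta_s, gamma_per_s_g)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        psi = psi * (1.0 + rng.normal(0.0, noise_sd, size=psi.shape))
        psi = np.clip(psi, 1e-12, None)
    gt = GroundTruth(
        {"D": (d_m2_s, "m^2/s"), "noise_sd": (noise_sd, "fraction")}, seed
    )
    return EchoDecay(
        gradients, psi, delta_s, big_delta_s, gamma_per_s_g, ground_truth=gt
    )


def gen_coalescence_series(
    eta_pa_s: float,
    sigma_n_m: float,
    droplet_radius_m: float,
    a0: float = 0.5,
    frame_interval_s: float | None = None,
    n_frames: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CoalescenceSeries:
    """Aspect-ratio relaxation with τ = (19/20) η R / σ and additive noise."""
    if not 0 < a0 < 1:
        raise ParameterError("initial aspect ratio must lie in (0, 1)")
    if eta_pa_s <= 0 or sigma_n_m <= 0 or droplet_radius_m <= 0:
        raise ParameterError("eta, sigma, radius must be positive")
    if n_frames < 4:
        raise ParameterError("need at least 4 frames")
    tau = (19.0 / 20.0) * eta_pa_s * droplet_radius_m / sigma_n_m
    if frame_interval_s is None:
        frame_interval_s = 4.0 * tau / n_frames  # sample ~4 decay times
    t = np.arange(n_frames) * frame_interval_s
    a = a0 * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    gt = GroundTruth(
        {
            "eta": (eta_pa_s, "Pa s"),
            "interfacial_tension": (sigma_n_m, "N/m"),
            "droplet_radius": (droplet_radius_m, "m"),
            "tau": (tau, "s"),
            "A0": (a0, "1"),
        },
        seed,
    )
    return CoalescenceSeries(t, a, droplet_radius_m, ground_truth=gt)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def gen_turbidity_profile(
    windows: list[tuple[float, float]],
    grid: np.ndarray,
    amplitude: float = 1.0,
    sharpness: float = 5.0,
    ramp: Ramp | str = Ramp.NONE,
    hysteresis_shift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TurbidityCurve:
    """Turbidity curve with one smooth bump per phase window.

    Each window [lo, hi] contributes a bump with sigmoid edges of width
    ``sharpness``. A heating ramp shifts both edges by +hysteresis_shift/2
    and a cooling ramp by −hysteresis_shift/2, emulating the lag between
    ramp directions in a temperature scan.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    ramp = Ramp(ramp)
    ws = sorted(windows)
    for (lo, hi), (lo2, _) in zip(ws[:-1], ws[1:]):
        if hi >= lo2:
            raise ParameterError("phase windows must be disjoint")
    for lo, hi in ws:
        if hi <= lo:
            raise ParameterError("each window needs hi > lo")
    shift = {Ramp.HEATING: 0.5, Ramp.COOLING: -0.5, Ramp.NONE: 0.0}[ramp]
    shift *= hysteresis_shift
    od = np.zeros_like(grid)
    for lo, hi in ws:
        od += amplitude * _sigmoid((grid - (lo + shift)) / sharpness) * _sigmoid(
            (((hi + shift)) - grid) / sharpness
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return TurbidityCurve(grid, od, ramp)


def gen_umbrella_windows(
    f_model: dict[int, float] | tuple[np.ndarray, np.ndarray],
    kappa_kt: float,
    nstar_schedule: list[float] | str,
    n_samples: int = 5000,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Exact i.i.d. samples from a tabulated βF(N) under harmonic bias.

    For each bias center N* the biased distribution
    ``P(N) ∝ exp(−βF(N) − ½ κ (N − N*)²)`` over the tabulated contiguous
    integer range is normalized and sampled directly (categorical sampling —
    no Markov chain, hence no burn-in and no equilibration discard). The
    schedule may be a list of centers or a ``"{start..step..stop}"`` string.
    Negative N* are legal: they push the count toward zero without clamping.
    """
    if isinstance(nstar_schedule, str):
        nstar_schedule = parse_nstar_schedule(nstar_schedule)
    if len(nstar_schedule) == 0:
        raise ParameterError("empty window schedule")
    if kappa_kt <= 0:
        raise ParameterError("kappa must be positive")
    if n_samples < 1:
        raise ParameterError("need at least one sample per window")
    if isinstance(f_model, dict):
        n_vals = np.array(sorted(f_model), dtype=int)
        f_vals = np.array([f_model[int(n)] for n in n_vals], dtype=float)
    else:
        n_vals = np.asarray(f_model[0], dtype=int)
        f_vals = np.asarray(f_model[1], dtype=float)
    if np.any(np.diff(n_vals) != 1):
        raise ParameterError("F_model must be tabulated on a contiguous integer range")
    if not np.all(np.isfinite(f_vals)):
        raise ParameterError("F_model must be finite")
    if np.any(n_vals < 0):
        raise ParameterError("occupancies must be non-negative")

    rng = np.random.default_rng(seed)
    out = []
    for nstar in nstar_schedule:
        log_p = -f_vals - 0.5 * kappa_kt * (n_vals - nstar) ** 2
        log_p -= log_p.max()
        p = np.exp(log_p)
        p /= p.sum()
        samples = rng.choice(n_vals, size=n_samples, p=p).astype(float)
        out.append(
            UmbrellaWindow(
                nstar=float(nstar),
                kappa_kt=kappa_kt,
                samples=samples,
                n_equilibration_discarded=0,
            )
        )
    return out


def gen_solvated_frame(
    solute_atom_positions_nm: np.ndarray,
    water_number_density_nm3: float,
    box_nm: tuple[float, float, float],
    seed: int = 0,
) -> MolecularFrame:
    """Toy solvated frame: uniform Poisson water oxygens around fixed solute.

    A stand-in for an explicit-solvent snapshot — no water structure, no
    excluded volume; the water count in any region is Poisson with mean
    density × volume, which is what the counting estimators are tested
    against.
    """
    box = np.asarray(box_nm, dtype=float)
    if np.any(box <= 0):
        raise ParameterError("box must be positive")
    if water_number_density_nm3 < 0:
        raise ParameterError("density must be non-negative")
    solute = np.atleast_2d(np.asarray(solute_atom_positions_nm, dtype=float))
    if np.any(solute < 0) or np.any(solute > box):
        raise ParameterError("solute atoms must lie inside the box")
    rng = np.random.default_rng(seed)
    n_w = rng.poisson(water_number_density_nm3 * np.prod(box))
    waters = rng.uniform(0.0, box, size=(n_w, 3))
    gt = GroundTruth(
        {"density": (water_number_density_nm3, "nm^-3"),
         "box_volume": (float(np.prod(box)), "nm^3")},
        seed,
    )
    return MolecularFrame(solute, waters, box=box, periodic=True, ground_truth=gt)


def gen_chain_ensemble(
    model: str = "freely_jointed",
    n_beads: int = 50,
    bond_length_nm: float = 0.38,
    n_frames: int = 2000,
    seed: int = 0,
    hardcore_fraction: float = 0.9,
    max_retries: int = 200,
) -> ChainEnsemble:
    """Ideal or self-avoiding random-walk chain ensembles.

    ``freely_jointed``: each bond is an independent uniform direction of
    exact length b, so ⟨dee²⟩ = (n−1)b² and ⟨Rg²⟩ ≈ (n−1)b²/6.
    ``self_avoiding``: the walk is regrown bead by bead, rejecting beads
    within ``hardcore_fraction × b`` of any previous bead; a chain that
    cannot be grown within ``max_retries`` restarts raises
    :class:`GenerationError`.
    """
    if n_beads < 2:
        raise ParameterError("need at least 2 beads")
    if n_frames < 1:
        raise ParameterError("need at least 1 frame")
    if bond_length_nm <= 0:
        raise ParameterError("bond length must be positive")
    if model not in ("freely_jointed", "self_avoiding"):
        raise ParameterError(f"unknown chain model {model!r}")
    rng = np.random.default_rng(seed)

    def random_units(n):
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    frames = np.empty((n_frames, n_beads, 3))
    if model == "freely_jointed":
        for f in range(n_frames):
            bonds = random_units(n_beads - 1) * bond_length_nm
            frames[f, 0] = 0.0
            frames[f, 1:] = np.cumsum(bonds, axis=0)
    else:
        hard2 = (hardcore_fraction * bond_length_nm) ** 2
        for f in range(n_frames):
            for attempt in range(max_retries + 1):
                coords = np.zeros((n_beads, 3))
                ok = True
                for b in range(1, n_beads):
                    placed = False
                    for _ in range(50):
                        cand = coords[b - 1] + random_units(1)[0] * bond_length_nm
                        d2 = np.sum((coords[: b - 1] - cand) ** 2, axis=1)
                        if b < 2 or np.all(d2 >= hard2):
                            coords[b] = cand
                            placed = True
                            break
                    if not placed:
                        ok = False
                        break
                if ok:
                    frames[f] = coords
                    break
            else:
                raise GenerationError(
                    f"self-avoiding chain generation failed after "
                    f"{max_retries} restarts"
                )
    gt = GroundTruth(
        {"model": (model, ""), "n_beads": (n_beads, ""),
         "bond_length": (bond_length_nm, "nm")},
        seed,
    )
    return ChainEnsemble(frames, ground_truth=gt)
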