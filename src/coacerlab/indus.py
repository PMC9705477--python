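"""Coarse-grained water counting and binless free-energy unbiasing.

The hydrophobicity of a residue can be probed by the free energy of emptying
its hydration shell of water. The observable is the number of water oxygens
inside a *hydration volume* — the union of spheres of radius ``Rv`` centered
on the residue's heavy atoms. Because a sharp count is discontinuous in the
coordinates, umbrella sampling biases a *coarse-grained* count ``Nv`` in
which each water contributes through a smoothed radial indicator (a Gaussian
of width σ truncated at rc, integrated against the sphere indicator). A
ladder of harmonically biased windows ``H = H0 + ½ κ (Nv − N*)²`` samples
the full range of occupancies, including pushed-empty states via negative
N*, and the unbiased distribution ``Pv(N)`` is recovered with the binless
(unbinned) weighted-histogram estimator (UWHAM); the dewetting free energy
is ``βF(N) = −ln Pv(N)``. Dividing the free energy of reaching ``N < N0``
waters by the ``N0 − N`` waters removed gives a per-water dewetting cost —
lower cost means a more hydrophobic surface.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import erf, logsumexp

from coacerlab.errors import (
    ConvergenceError,
    InputError,
    ParameterError,
)

__all__ = [
    "MolecularFrame",
    "IndusParams",
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "UnionOfSpheres",
    "hydration_volume",
    "sharp_count",
    "coarse_count",
    "sample_model_biased",
    "uwham_unbias",
    "per_water_profile",
    "mean_per_water_cost",
    "more_hydrophobic",
    "parse_nstar_schedule",
    "frame_from_structure",
]


@dataclass
class MolecularFrame:
    """Solute heavy atoms plus water oxygens, coordinates in nm."""

    heavy_atom_positions: np.ndarray
    water_oxygen_positions: np.ndarray
    box: np.ndarray | None = None
    periodic: bool = False
    ground_truth: Any = None

    def __post_init__(self) -> None:
        self.heavy_atom_positions = np.atleast_2d(
            np.asarray(self.heavy_atom_positions, dtype=float)
        )
        self.water_oxygen_positions = (
            np.asarray(self.water_oxygen_positions, dtype=float).reshape(-1, 3)
        )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.heavy_atom_positions)) or not np.all(
            np.isfinite(self.water_oxygen_positions)
        ):
            raise InputError("coordinates must be finite")
        if self.periodic and self.box is None:
            raise InputError("periodic frame requires a box")


@dataclass
class IndusParams:
    """Probe-volume and bias parameters (lengths nm, κ in kBT).

    ``Rv = 0.55`` nm covers the first hydration shell of an amino-acid
    residue; σ and rc set the width and truncation of the smoothing kernel
    (rc > σ so the kernel is not clipped mid-peak); κ is the harmonic bias
    stiffness.
    """

    rv_nm: float = 0.55
    sigma_nm: float = 0.01
    rc_nm: float = 0.02
    kappa_kt: float = 10.0

    def __post_init__(self) -> None:
        if not self.rc_nm > self.sigma_nm > 0:
            raise ParameterError("require rc > sigma > 0")
        if not self.rv_nm > self.rc_nm:
            raise ParameterError("require Rv > rc")
        if self.kappa_kt <= 0:
            raise ParameterError("kappa must be positive")


@dataclass
class UmbrellaWindow:
    """Biased samples of the coarse water number for one bias center.

    ``nstar`` may be negative — the harmonic center can sit below zero to
    push toward a fully dewetted volume even though Nv >= 0.
    """

    nstar: float
    kappa_kt: float
    samples: np.ndarray
    n_equilibration_discarded: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_equilibration_discarded:
            self.samples = self.samples[self.n_equilibration_discarded :]
        if len(self.samples) == 0:
            raise InputError("window has no samples after equilibration discard")
        if np.any(self.samples < 0):
            raise InputError("coarse water numbers must be non-negative")

    def bias_kt(self, n: np.ndarray | float) -> np.ndarray | float:
        """Harmonic bias energy ½ κ (N − N*)² in kBT."""
        return 0.5 * self.kappa_kt * (np.asarray(n, dtype=float) - self.nstar) ** 2


@dataclass
class FreeEnergyProfile:
    """Unbiased βF(N) on the integer occupancy grid, min-shifted to zero."""

    n_grid: np.ndarray
    beta_f: np.ndarray
    n0: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_grid = np.asarray(self.n_grid, dtype=int)
        self.beta_f = np.asarray(self.beta_f, dtype=float)

    def probability(self) -> np.ndarray:
        p = np.exp(-self.beta_f)
        return p / p.sum()


@dataclass
class UnionOfSpheres:
    """Hydration volume: spheres of common radius around given centers."""

    centers_nm: np.ndarray
    radius_nm: float

    def __post_init__(self) -> None:
        self.centers_nm = np.atleast_2d(np.asarray(self.centers_nm, dtype=float))
        if self.radius_nm <= 0:
            raise ParameterError("sphere radius must be positive")

    def monte_carlo_volume(
        self, n_samples: int = 200_000, seed: int = 0
    ) -> float:
        """Hit-or-miss estimate of the union volume in nm³."""
        rng = np.random.default_rng(seed)
        lo = self.centers_nm.min(axis=0) - self.radius_nm
        hi = self.centers_nm.max(axis=0) + self.radius_nm
        pts = rng.uniform(lo, hi, size=(n_samples, 3))
        d2 = np.min(
            np.sum((pts[:, None, :] - self.centers_nm[None]) ** 2, axis=2), axis=1
        )
        frac = np.mean(d2 <= self.radius_nm**2)
        return float(frac * np.prod(hi - lo))


def hydration_volume(
    frame: MolecularFrame,
    residue_atom_indices: Sequence[int],
    rv_nm: float = 0.55,
) -> UnionOfSpheres:
    """Union-of-spheres probe volume around the tagged residue's heavy atoms."""
    idx = np.asarray(residue_atom_indices, dtype=int)
    if idx.size == 0:
        raise InputError("residue atom index set is empty")
    if rv_nm <= 0:
        raise ParameterError("Rv must be positive")
    if idx.min() < 0 or idx.max() >= len(frame.heavy_atom_positions):
        raise InputError("residue atom index out of range")
    return UnionOfSpheres(frame.heavy_atom_positions[idx], rv_nm)


def _distances_to_centers(
    waters: np.ndarray, centers: np.ndarray, frame: MolecularFrame
) -> np.ndarray:
    """(n_waters, n_centers) distances, minimum-image if frame is periodic."""
    diff = waters[:, None, :] - centers[None, :, :]
    if frame.periodic:
        diff -= frame.box[None, None, :] * np.round(diff / frame.box[None, None, :])
    return np.sqrt(np.sum(diff * diff, axis=2))


def sharp_count(frame: MolecularFrame, volume: UnionOfSpheres) -> int:
    """Number of water oxygens strictly inside the union of spheres."""
    if len(frame.water_oxygen_positions) == 0:
        return 0
    d = _distances_to_centers(
        frame.water_oxygen_positions, volume.centers_nm, frame
    )
    return int(np.count_nonzero(np.min(d, axis=1) <= volume.radius_nm))


def _truncated_gaussian_cdf(x: np.ndarray, sigma: float, rc: float) -> np.ndarray:
    """CDF of the zero-mean truncated-and-shifted Gaussian kernel.

    The kernel is φ(u) = k [exp(−u²/2σ²) − exp(−rc²/2σ²)] on |u| <= rc and 0
    outside, with k normalizing ∫φ = 1; subtracting the plateau makes φ
    continuous at ±rc so the smoothed count is differentiable.
    """
    x = np.asarray(x, dtype=float)
    shift = math.exp(-(rc**2) / (2 * sigma**2))
    norm = math.sqrt(2 * math.pi) * sigma * erf(
        rc / (math.sqrt(2) * sigma)
    ) - 2 * rc * shift
    xc = np.clip(x, -rc, rc)
    integral = (
        math.sqrt(math.pi / 2)
        * sigma
        * (erf(xc / (math.sqrt(2) * sigma)) + erf(rc / (math.sqrt(2) * sigma)))
        - shift * (xc + rc)
    )
    return integral / norm


def coarse_count(
    frame: MolecularFrame,
    volume: UnionOfSpheres,
    sigma_nm: float = 0.01,
    rc_nm: float = 0.02,
) -> float:
    """Coarse-grained water number Nv of the hydration volume.

    Each water's per-sphere indicator is smoothed radially: a water at
    distance r from a sphere center contributes the kernel CDF evaluated at
    ``Rv − r``, i.e. exactly 1 deeper than rc inside the surface and exactly
    0 farther than rc outside it. Contributions from overlapping spheres
    combine by the complement product ``h̃ = 1 − Π_j (1 − h̃_j)``, which
    reduces to the single-sphere indicator for coincident spheres and keeps
    0 <= Nv <= n_waters.
    """
    if not rc_nm > sigma_nm > 0:
        raise ParameterError("require rc > sigma > 0")
    if len(frame.water_oxygen_positions) == 0:
        return 0.0
    d = _distances_to_centers(
        frame.water_oxygen_positions, volume.centers_nm, frame
    )
    h_per_sphere = _truncated_gaussian_cdf(volume.radius_nm - d, sigma_nm, rc_nm)
    h = 1.0 - np.prod(1.0 - h_per_sphere, axis=1)
    return float(np.sum(h))


def parse_nstar_schedule(text: str) -> list[float]:
    """Parse a ``"{start..step..stop}"`` window schedule (stop inclusive).

    ``"{-9..3..54}"`` gives the 22 centers −9, −6, …, 54.
    """
    m = re.fullmatch(
        r"\{\s*(-?\d+(?:\.\d+)?)\.\.(-?\d+(?:\.\d+)?)\.\.(-?\d+(?:\.\d+)?)\s*\}",
        text.strip(),
    )
    if not m:
        raise ParameterError(f"cannot parse schedule {text!r}")
    start, step, stop = (float(g) for g in m.groups())
    if step <= 0:
        raise ParameterError("schedule step must be positive")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    if n < 1:
        raise ParameterError("empty schedule")
    return [start + i * step for i in range(n)]


def sample_model_biased(
    f_model: dict[int, float] | tuple[np.ndarray, np.ndarray],
    params: IndusParams,
    nstar: float,
    n_samples: int,
    seed: int,
) -> UmbrellaWindow:
    """Draw exact biased samples from a tabulated model landscape.

    Delegates to :func:`coacerlab.synth.gen_umbrella_windows` for a single
    bias center; equilibration discard is 0 because the sampling is exact
    (i.i.d. categorical over the tabulated range — no Markov-chain burn-in).
    """
    from coacerlab import synth

    (window,) = synth.gen_umbrella_windows(
        f_model, params.kappa_kt, [nstar], n_samples, seed
    )
    return window


def _aggregate_windows(windows: Sequence[UmbrellaWindow]):
    """Unique sample values with per-window counts (binless sums collapse)."""
    values = np.unique(np.concatenate([w.samples for w in windows]))
    counts = np.zeros((len(windows), len(values)))
    for k, w in enumerate(windows):
        idx = np.searchsorted(values, w.samples)
        np.add.at(counts[k], idx, 1.0)
    return values, counts


def _check_overlap(
    windows: Sequence[UmbrellaWindow], floor: int = 1, max_gap: float = 5.0
) -> None:
    """Validate that the window ladder samples a connected occupancy range.

    The binless estimator bridges adjacent windows through the known
    harmonic bias energies, so strict sample-sharing is not required; narrow
    unsampled stretches (steep high-free-energy regions between stiffly
    biased windows) are tolerated up to ``max_gap`` occupancies, beyond
    which the chain is treated as disconnected. Weak sharing (fewer than
    ``floor`` samples inside the neighbour's support) only degrades the
    stitching variance, hence a warning.
    """
    order = np.argsort([w.nstar for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        lo_a, hi_a = windows[a].samples.min(), windows[a].samples.max()
        lo_b, hi_b = windows[b].samples.min(), windows[b].samples.max()
        gap_lo, gap_hi = min(hi_a, hi_b), max(lo_a, lo_b)
        if gap_hi - gap_lo > max_gap:
            raise InputError(
                f"windows at N*={windows[a].nstar} and N*={windows[b].nstar} "
                f"leave occupancies ({gap_lo}, {gap_hi}) unsampled; "
                "the window chain is disconnected"
            )
        lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
        shared = 0
        if hi >= lo:
            shared = min(
                np.count_nonzero(
                    (windows[a].samples >= lo) & (windows[a].samples <= hi)
                ),
                np.count_nonzero(
                    (windows[b].samples >= lo) & (windows[b].samples <= hi)
                ),
            )
        if shared < floor:
            warnings.warn(
                f"weak sample overlap between windows N*={windows[a].nstar} "
                f"and N*={windows[b].nstar}",
                stacklevel=3,
            )


def _bin_toward_nstar(samples: np.ndarray, nstar: float) -> np.ndarray:
    """Nearest-integer binning; half-integer ties round toward N*."""
    lower = np.floor(samples)
    frac = samples - lower
    n = np.where(frac > 0.5, lower + 1, lower)
    ties = frac == 0.5
    if np.any(ties):
        toward_up = nstar > samples[ties]
        n[ties] = lower[ties] + np.where(toward_up, 1, 0)
    return n.astype(int)


def uwham_unbias(
    windows: Sequence[UmbrellaWindow],
    tol_kt: float = 1e-8,
    max_iter: int = 100_000,
    damping: float = 1.0,
    overlap_floor: int = 1,
) -> FreeEnergyProfile:
    """Binless (unbinned) WHAM unbiasing of umbrella windows to βF(N).

    Solves the self-consistent equations for the per-window dimensionless
    free energies f_k (first window pinned to 0),

        f_k = −ln Σ_n exp(−u_k(x_n)) / Σ_l N_l exp(f_l − u_l(x_n)),

    to the stated self-consistency tolerance, then assembles the unbiased
    weights into Pv(N) on the integer grid (continuous samples are binned to
    the nearest integer, half-integer ties rounding toward the window's N*)
    and returns βF(N) = −ln Pv(N) shifted so min βF = 0.

    The fixed point is the stationary point of a convex log-likelihood; it
    is found by damped fixed-point warm-up followed by Newton iteration on
    the reduced (f_1-pinned) system, which converges quadratically even when
    adjacent windows share few samples and fixed-point iteration alone
    contracts too slowly. Convergence is declared when the self-consistent
    update moves every f_k by less than ``tol_kt``.
    """
    if len(windows) == 0:
        raise InputError("no umbrella windows given")
    if not 0 < damping <= 1:
        raise ParameterError("damping must be in (0, 1]")
    if len(windows) > 1:
        _check_overlap(windows, overlap_floor)

    values, counts = _aggregate_windows(windows)
    n_k = counts.sum(axis=1)  # samples per window
    log_c_v = np.log(counts.sum(axis=0))  # pooled multiplicity per value
    # u[k, v]: bias energy of window k at sample value v (kBT)
    u = np.stack([w.bias_kt(values) for w in windows])
    log_nk = np.log(n_k)
    c_v = counts.sum(axis=0)

    def sc_update(f: np.ndarray) -> np.ndarray:
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(log_c_v[None, :] - u - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    def objective(f: np.ndarray) -> float:
        # convex negative log-likelihood; stationary point solves the
        # self-consistent equations (invariant under a common shift in f)
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
        return float(np.sum(c_v * log_denom) - np.sum(n_k * f))

    def grad_hess(f: np.ndarray):
        # W[k, v] = N_k exp(f_k - u_k(v)) / sum_l N_l exp(f_l - u_l(v))
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
        w_kv = np.exp(log_nk[:, None] + f[:, None] - u - log_denom[None, :])
        grad = w_kv @ c_v - n_k
        hess = np.diag(w_kv @ c_v) - (w_kv * c_v[None, :]) @ w_kv.T
        return grad, hess

    f = np.zeros(len(windows))
    n_iter = 0
    residual = np.inf
    # damped fixed-point warm-up, then Newton on the f_1-pinned system
    for _ in range(min(50, max_iter)):
        f_new = sc_update(f)
        residual = float(np.max(np.abs(f_new - f)))
        f = (1 - damping) * f + damping * f_new
        n_iter += 1
        if residual < tol_kt:
            break
    while residual >= tol_kt:
        if n_iter >= max_iter:
            raise ConvergenceError(
                f"UWHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.3g} kBT)"
            )
        grad, hess = grad_hess(f)
        try:
            step = np.linalg.solve(hess[1:, 1:], -grad[1:])
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(hess[1:, 1:], -grad[1:], rcond=None)
        if np.all(np.isfinite(step)):
            # backtracking line search on the convex objective
            obj0 = objective(f)
            scale = 1.0
            for _ in range(40):
                trial = f.copy()
                trial[1:] += scale * step
                trial -= trial[0]
                if objective(trial) < obj0:
                    f = trial
                    break
                scale *= 0.5
            else:
                f = sc_update(f)
        else:
            f = sc_update(f)  # fall back to a fixed-point sweep
        residual = float(np.max(np.abs(sc_update(f) - f)))
        n_iter += 1

    log_denom = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
    log_w = -log_denom  # unbiased log-weight per unit multiplicity at value v

    # assemble Pv(N) on the integer grid in log space (the dynamic range of
    # the weights spans hundreds of kBT), with per-window tie handling
    log_contrib_by_n: dict[int, list[float]] = {}
    for k, w in enumerate(windows):
        sample_bins = _bin_toward_nstar(w.samples, w.nstar)
        for n in np.unique(sample_bins):
            sel = sample_bins == n
            idx = np.searchsorted(values, w.samples[sel])
            # multiplicity-weighted log-sum of unbiased weights in this bin
            log_contrib_by_n.setdefault(int(n), []).append(
                float(logsumexp(log_w[idx]))
            )

    n_grid = np.array(sorted(log_contrib_by_n))
    log_p = np.array(
        [logsumexp(log_contrib_by_n[int(n)]) for n in n_grid]
    )
    log_p -= logsumexp(log_p)
    beta_f = -log_p
    beta_f -= beta_f.min()
    n0 = int(n_grid[np.argmin(beta_f)])
    return FreeEnergyProfile(
        n_grid,
        beta_f,
        n0,
        diagnostics={"iterations": n_iter, "residual_kt": residual,
                     "window_free_energies_kt": f.tolist()},
    )


def per_water_profile(
    profile: FreeEnergyProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-water dewetting cost versus fractional occupancy.

    For each N < N0 the cost of removing the ``N0 − N`` waters is spread
    evenly: returns ``(x, y)`` with ``x = N/N0`` and
    ``y = (βF(N) − βF(N0)) / (N0 − N)`` in kBT per water, on x ∈ [0, 1).
    """
    i0 = int(np.argmin(profile.beta_f))
    # prefer the recorded equilibrium occupancy when it is degenerate with
    # the minimum (flat stretches make argmin arbitrary)
    hits = np.nonzero(profile.n_grid == profile.n0)[0]
    if hits.size and profile.beta_f[hits[0]] <= profile.beta_f[i0] + 1e-9:
        i0 = int(hits[0])
    if i0 == 0:
        raise InputError("profile has no interior minimum")
    n0 = int(profile.n_grid[i0])
    if n0 <= 0:
        raise InputError("equilibrium occupancy N0 must be positive")
    mask = profile.n_grid < n0
    n = profile.n_grid[mask]
    y = (profile.beta_f[mask] - profile.beta_f[i0]) / (n0 - n)
    return n / n0, y


def mean_per_water_cost(profile: FreeEnergyProfile) -> float:
    """Average per-water dewetting free energy over the depletion branch."""
    _, y = per_water_profile(profile)
    return float(np.mean(y))


def more_hydrophobic(a: FreeEnergyProfile, b: FreeEnergyProfile) -> bool:
    """True if ``a`` is the more hydrophobic surface (lower per-water cost)."""
    return mean_per_water_cost(a) < mean_per_water_cost(b)


def frame_from_structure(
    path: str,
    solute_selection: str = "protein and not name H*",
    water_selection: str = "name OW O and resname SOL HOH TIP3 TIP4 WAT",
    periodic: bool | None = None,
) -> MolecularFrame:
    """Read a single-frame PDB/GRO structure into a :class:`MolecularFrame`.

    Coordinates are converted Å → nm. Selections follow MDAnalysis syntax;
    the solute selection should pick the heavy atoms that define hydration
    volumes.
    """
    import MDAnalysis as mda

    u = mda.Universe(path)
    solute = u.select_atoms(solute_selection)
    waters = u.select_atoms(water_selection)
    if len(solute) == 0:
        raise InputError(f"solute selection {solute_selection!r} matched no atoms")
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = u.dimensions[:3] / 10.0
    if periodic is None:
        periodic = box is not None
    return MolecularFrame(
        heavy_atom_positions=solute.positions / 10.0,
        water_oxygen_positions=waters.positions.reshape(-1, 3) / 10.0,
        box=box,
        periodic=periodic,
    )
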