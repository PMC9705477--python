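"""Passive microrheology and droplet-coalescence interfacial tension.

The dense (coacervate) phase of a phase-separated polyelectrolyte solution is
too small and too viscous for bulk rheometry, so its viscosity is inferred
from the thermal motion of embedded probe particles: the ensemble- and
time-averaged mean-squared displacement (MSD) is fit to the power law
``MSD(τ) = 4 D τ^α`` and the Stokes–Einstein relation ``D = kB T / (6 π η r)``
converts the probe diffusivity to a viscosity. Interfacial tension follows
from the relaxation of two coalescing droplets: the aspect-ratio deviation
``A = (L − W)/(L + W)`` decays exponentially with time constant
``τ ≅ (19/20) η R / σ``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import curve_fit

from coacerlab.constants import (
    BOLTZMANN_J_PER_K,
    ROOM_TEMPERATURE_K,
    UM2_TO_M2,
)
from coacerlab.errors import FitError, InputError, ParameterError

__all__ = [
    "ProbeTracks",
    "MSDCurve",
    "RheologyResult",
    "CoalescenceSeries",
    "compute_msd",
    "fit_msd_powerlaw",
    "viscosity_stokes_einstein",
    "microrheology_pipeline",
    "aspect_ratio",
    "fit_relaxation_time",
    "interfacial_tension",
]


@dataclass
class ProbeTracks:
    """2-D trajectories of tracer particles embedded in a dense phase.

    Attributes
    ----------
    particle_ids, frames, x_um, y_um
        Flat per-observation arrays; rows of one particle must have strictly
        increasing frame indices.
    frame_interval_s
        Time between frames (20 ms for low-viscosity samples, 1 s for
        high-viscosity ones, following common video-microrheology practice).
    probe_radius_m, temperature_k
        Probe radius and sample temperature used downstream by
        Stokes–Einstein.
    """

    particle_ids: np.ndarray
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval_s: float
    probe_radius_m: float = 1e-6
    temperature_k: float = ROOM_TEMPERATURE_K
    ground_truth: Any = None

    def __post_init__(self) -> None:
        self.particle_ids = np.asarray(self.particle_ids)
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.particle_ids)
        if not (len(self.frames) == len(self.x_um) == len(self.y_um) == n):
            raise InputError("track columns must have equal length")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        for pid in np.unique(self.particle_ids):
            f = self.frames[self.particle_ids == pid]
            if np.any(np.diff(f) <= 0):
                raise InputError(
                    f"frames of particle {pid!r} are not strictly increasing"
                )

    def iter_tracks(self):
        """Yield ``(pid, frames, xy_um)`` per particle, frame-ordered."""
        for pid in np.unique(self.particle_ids):
            sel = self.particle_ids == pid
            yield pid, self.frames[sel], np.column_stack(
                [self.x_um[sel], self.y_um[sel]]
            )


@dataclass
class MSDCurve:
    """Averaged mean-squared displacement versus lag time."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags_s) <= 0):
            raise InputError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise InputError("MSD values must be non-negative")


@dataclass
class RheologyResult:
    """Outcome of the MSD → D → η pipeline."""

    d_probe_m2_s: float
    alpha: float
    eta_pa_s: float
    fit_lags_s: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CoalescenceSeries:
    """Aspect-ratio relaxation of a droplet after a coalescence event.

    ``A = (L − W)/(L + W)`` so a relaxed (spherical) droplet has A = 0.
    """

    times_s: np.ndarray
    aspect: np.ndarray
    droplet_radius_m: float | None = None
    ground_truth: Any = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.aspect = np.asarray(self.aspect, dtype=float)
        if len(self.times_s) != len(self.aspect):
            raise InputError("times and aspect ratios must have equal length")

    @classmethod
    def from_lengths(
        cls,
        times_s: np.ndarray,
        length_um: np.ndarray,
        width_um: np.ndarray,
        droplet_radius_m: float | None = None,
    ) -> "CoalescenceSeries":
        a = np.array(
            [aspect_ratio(l, w) for l, w in zip(length_um, width_um)]
        )
        return cls(times_s, a, droplet_radius_m)


def compute_msd(tracks: ProbeTracks, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged, then ensemble-averaged, mean-squared displacement.

    For every track the MSD at lag ``k`` frames is averaged over all
    overlapping time origins; tracks are then combined with equal weight.
    Lags run from 1 frame up to ``max_lag_fraction`` of the longest track,
    where the time average is still statistically meaningful.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ParameterError("max_lag_fraction must be in (0, 1]")
    track_data = [
        (frames, xy) for _, frames, xy in tracks.iter_tracks() if len(frames) >= 2
    ]
    if not track_data:
        raise InputError("no track with at least 2 frames")

    longest = max(frames[-1] - frames[0] for frames, _ in track_data)
    max_lag = max(1, int(math.floor(longest * max_lag_fraction)))

    sum_msd = np.zeros(max_lag)
    n_tracks_at_lag = np.zeros(max_lag, dtype=int)
    total_pairs = np.zeros(max_lag, dtype=int)
    for frames, xy in track_data:
        # Tracks may have missing frames; accumulate per (frame-index) lag.
        per_lag_sum = np.zeros(max_lag)
        per_lag_n = np.zeros(max_lag, dtype=int)
        n = len(frames)
        if frames[-1] - frames[0] == n - 1:
            # contiguous: vectorized over origins for each lag
            for k in range(1, min(n - 1, max_lag) + 1):
                d = xy[k:] - xy[:-k]
                per_lag_sum[k - 1] = np.sum(d * d)
                per_lag_n[k - 1] = n - k
        else:
            for i in range(n - 1):
                dk = frames[i + 1 :] - frames[i]
                ok = dk <= max_lag
                if not np.any(ok):
                    continue
                d = xy[i + 1 :][ok] - xy[i]
                sq = np.sum(d * d, axis=1)
                np.add.at(per_lag_sum, dk[ok] - 1, sq)
                np.add.at(per_lag_n, dk[ok] - 1, 1)
        has = per_lag_n > 0
        sum_msd[has] += per_lag_sum[has] / per_lag_n[has]
        n_tracks_at_lag += has
        total_pairs += per_lag_n

    has = n_tracks_at_lag > 0
    lags = (np.arange(1, max_lag + 1) * tracks.frame_interval_s)[has]
    msd = sum_msd[has] / n_tracks_at_lag[has]
    return MSDCurve(lags, msd, total_pairs[has])


def fit_msd_powerlaw(msd: MSDCurve) -> tuple[float, float]:
    """Fit ``MSD(τ) = 4 D τ^α`` by least squares on log MSD vs log τ.

    Returns ``(D, alpha)`` with D in m²/s (input MSD is in μm²). Non-positive
    MSD points cannot enter the log fit and are excluded with a warning.
    """
    pos = msd.msd_um2 > 0
    if np.count_nonzero(pos) < len(msd.msd_um2):
        warnings.warn(
            "non-positive MSD points excluded from power-law fit", stacklevel=2
        )
    if np.count_nonzero(pos) < 3:
        raise FitError("need at least 3 positive MSD points to fit")
    x = np.log(msd.lags_s[pos])
    y = np.log(msd.msd_um2[pos])
    alpha, log4d = np.polyfit(x, y, 1)
    d_um2_s = math.exp(log4d) / 4.0
    return d_um2_s * UM2_TO_M2, float(alpha)


def viscosity_stokes_einstein(
    d_m2_s: float, probe_radius_m: float = 1e-6,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> float:
    """Viscosity from the Stokes–Einstein relation, η = kB T / (6 π D r)."""
    if probe_radius_m <= 0 or temperature_k <= 0:
        raise ParameterError("probe radius and temperature must be positive")
    if d_m2_s <= 0:
        raise ParameterError("diffusivity must be positive")
    return BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * d_m2_s * probe_radius_m)


def microrheology_pipeline(
    tracks: ProbeTracks,
    max_lag_fraction: float = 0.25,
    alpha_band: tuple[float, float] = (0.9, 1.1),
) -> RheologyResult:
    """Full MSD → power-law D, α → Stokes–Einstein η pipeline.

    η is computed from the power-law D even when α departs from 1; an α
    outside ``alpha_band`` triggers a non-diffusive warning because
    Stokes–Einstein presumes simple diffusion.
    """
    msd = compute_msd(tracks, max_lag_fraction)
    d, alpha = fit_msd_powerlaw(msd)
    if not alpha_band[0] <= alpha <= alpha_band[1]:
        warnings.warn(
            f"diffusive exponent alpha={alpha:.3f} outside {alpha_band}; "
            "probe motion is non-diffusive, Stokes-Einstein viscosity is "
            "indicative only",
            stacklevel=2,
        )
    eta = viscosity_stokes_einstein(
        d, tracks.probe_radius_m, tracks.temperature_k
    )
    return RheologyResult(
        d_probe_m2_s=d,
        alpha=alpha,
        eta_pa_s=eta,
        fit_lags_s=(float(msd.lags_s[0]), float(msd.lags_s[-1])),
        diagnostics={"n_lags": len(msd.lags_s)},
    )


def aspect_ratio(length_um: float, width_um: float) -> float:
    """Droplet elongation A = (L − W)/(L + W), in [0, 1)."""
    if width_um <= 0:
        raise InputError("width must be positive")
    if length_um < width_um:
        raise InputError("length must be >= width")
    return (length_um - width_um) / (length_um + width_um)


def fit_relaxation_time(series: CoalescenceSeries) -> tuple[float, float]:
    """Fit ``A(t) = A0 exp(−t/τ)``; returns ``(tau_s, A0)``.

    A log-linear fit on the positive points initializes a nonlinear
    least-squares refinement, which tolerates noisy points near zero.
    """
    t = series.times_s
    a = series.aspect
    if len(t) < 4:
        raise InputError("need at least 4 time points")
    if a[0] <= 0:
        raise InputError("aspect ratio at the first point must be positive")
    pos = a > 0
    slope, loga0 = np.polyfit(t[pos], np.log(a[pos]), 1)
    if slope >= 0:
        raise FitError("series does not decay (log-linear slope >= 0)")
    tau0, a00 = -1.0 / slope, math.exp(loga0)
    try:
        popt, _ = curve_fit(
            lambda tt, a0, tau: a0 * np.exp(-tt / tau),
            t,
            a,
            p0=[a00, tau0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"relaxation fit did not converge: {exc}") from exc
    a0_fit, tau_fit = popt
    if tau_fit <= 0:
        raise FitError("fitted relaxation time is non-positive")
    if tau_fit > 100.0 * (t[-1] - t[0]):
        raise FitError(
            "no observable decay over the recorded time span "
            f"(tau = {tau_fit:.3g} s)"
        )
    return float(tau_fit), float(a0_fit)


def interfacial_tension(
    tau_s: float, eta_pa_s: float, droplet_radius_m: float
) -> float:
    """Interfacial tension σ = (19/20) η R / τ from the coalescence time.

    Inverts the inertialess droplet-shape relaxation law τ ≅ (19/20) η R / σ,
    with η the dense-phase viscosity from microrheology and R the radius of
    the merged droplet.
    """
    if tau_s <= 0:
        raise ParameterError("relaxation time must be positive")
    if eta_pa_s <= 0 or droplet_radius_m <= 0:
        raise ParameterError("viscosity and radius must be positive")
    return (19.0 / 20.0) * eta_pa_s * droplet_radius_m / tau_s
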