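"""Stejskal–Tanner fitting of pulsed-field-gradient NMR echo decays.

In a PFG stimulated-echo experiment the echo amplitude of freely diffusing
spins attenuates as

    ψ(g) = exp(−(γ g δ)² D (Δ − δ/3))

with γ the proton gyromagnetic ratio (s⁻¹ G⁻¹), g the gradient amplitude
(G/cm, converted to G/m internally so that (γ g δ)² D (Δ − δ/3) is
dimensionless with D in m²/s), δ the effective gradient-pulse duration and
Δ the diffusion time. A sweep of g (typically 16 amplitudes) at fixed δ, Δ
determines the self-diffusion coefficient of interstitial water in each
phase of a phase-separated sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import curve_fit

from coacerlab.constants import G_PER_CM_TO_G_PER_M, PROTON_GAMMA_PER_S_G
from coacerlab.errors import FitError, InputError, ParameterError

__all__ = ["EchoDecay", "stejskal_tanner", "fit_diffusion", "gradient_b_values"]


@dataclass
class EchoDecay:
    """Echo attenuation ψ versus gradient amplitude with pulse parameters."""

    gradients_g_cm: np.ndarray
    attenuation: np.ndarray
    delta_s: float
    big_delta_s: float
    gamma_per_s_g: float = PROTON_GAMMA_PER_S_G
    ground_truth: Any = None

    def __post_init__(self) -> None:
        self.gradients_g_cm = np.asarray(self.gradients_g_cm, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if len(self.gradients_g_cm) != len(self.attenuation):
            raise InputError("gradients and attenuations must have equal length")
        if np.any(self.gradients_g_cm < 0):
            raise InputError("gradient amplitudes must be non-negative")
        if len(np.unique(self.gradients_g_cm)) < 2:
            raise InputError("need >= 2 distinct gradient amplitudes")
        if self.big_delta_s <= self.delta_s / 3.0:
            raise ParameterError(
                "effective diffusion time Delta - delta/3 must be positive"
            )


def stejskal_tanner(
    g_g_cm: np.ndarray | float,
    d_m2_s: float,
    delta_s: float,
    big_delta_s: float,
    gamma_per_s_g: float = PROTON_GAMMA_PER_S_G,
) -> np.ndarray | float:
    """Echo attenuation ψ = exp(−(γ g δ)² D (Δ − δ/3))."""
    if big_delta_s <= delta_s / 3.0:
        raise ParameterError("Delta must exceed delta/3")
    if d_m2_s < 0:
        raise ParameterError("diffusivity must be non-negative")
    g_g_m = np.asarray(g_g_cm, dtype=float) * G_PER_CM_TO_G_PER_M
    b = (gamma_per_s_g * g_g_m * delta_s) ** 2 * (big_delta_s - delta_s / 3.0)
    return np.exp(-b * d_m2_s)


def gradient_b_values(decay: EchoDecay) -> np.ndarray:
    """Gradient factor b = (γ g δ)²(Δ − δ/3) in s/m² for each echo."""
    g_g_m = decay.gradients_g_cm * G_PER_CM_TO_G_PER_M
    return (decay.gamma_per_s_g * g_g_m * decay.delta_s) ** 2 * (
        decay.big_delta_s - decay.delta_s / 3.0
    )


@dataclass
class DiffusionFit:
    d_m2_s: float
    diagnostics: dict = field(default_factory=dict)


def fit_diffusion(
    decay: EchoDecay,
    log_weighting: bool = False,
    noise_tolerance: float = 0.1,
) -> DiffusionFit:
    """Single-exponential diffusion coefficient from an echo decay.

    The attenuations are fit to ψ = exp(−b D) in the gradient factor
    b = (γ g δ)²(Δ − δ/3). A log-linear solution initializes a nonlinear
    refinement with uniform weights in ψ; ``log_weighting=True`` keeps the
    log-linear solution instead (uniform weights in ln ψ).
    """
    if len(decay.attenuation) < 3:
        raise InputError("need at least 3 echoes")
    if np.any(decay.attenuation <= 0):
        raise InputError("attenuations must be positive")
    psi = decay.attenuation
    b = gradient_b_values(decay)

    order = np.argsort(b)
    rises = np.diff(psi[order])
    if np.any(rises > noise_tolerance * psi.max()):
        warnings.warn(
            "echo attenuation is non-monotone in b beyond noise tolerance",
            stacklevel=2,
        )

    denom = float(np.sum(b * b))
    if denom == 0:
        raise FitError("all gradients are zero; D is undetermined")
    # zero-intercept log-linear solution: ln psi = -D b
    d0 = float(-np.sum(b * np.log(psi)) / denom)
    if log_weighting:
        d_fit = d0
    else:
        popt, _ = curve_fit(
            lambda bb, d: np.exp(-bb * d), b, psi, p0=[max(d0, 0.0)],
            maxfev=10000,
        )
        d_fit = float(popt[0])
    if d_fit < -1e-18:
        raise FitError(f"fitted diffusivity is negative: {d_fit:.3g}")
    d_fit = max(d_fit, 0.0)
    resid = psi - np.exp(-b * d_fit)
    return DiffusionFit(
        d_m2_s=d_fit,
        diagnostics={
            "rss": float(np.sum(resid**2)),
            "n_echoes": len(psi),
            "d_loglinear": d0,
        },
    )
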