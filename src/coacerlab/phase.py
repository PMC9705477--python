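"""Phase behavior from turbidity curves and dense-phase composition.

Complex coacervation of oppositely charged polyelectrolytes is screened by
salt: turbidity (OD at 600 nm) reports where the mixture is two-phase. An
arginine-rich system can re-enter the two-phase region at molar salt, driven
by hydrophobic rather than electrostatic attraction, which shows up as a
second turbid window in a salt sweep. Temperature ramps of the same signal
locate cloud points (UCST/LCST transitions) and their heating/cooling
hysteresis. Dense-phase compositions come from amino-acid-analysis peak
areas via a linear calibration, closed by a mass balance over the two phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from coacerlab.errors import FitError, InconsistencyError, InputError, ParameterError

__all__ = [
    "Ramp",
    "TurbidityCurve",
    "PhaseWindows",
    "Transition",
    "CloudPoints",
    "CompositionCalibration",
    "PhaseComposition",
    "detect_phase_windows",
    "detect_cloud_points",
    "fit_calibration",
    "quantify_concentration",
    "dense_from_mass_balance",
    "composition_ratio",
    "average_replicates",
]

#: Default relative turbidity threshold for "turbid" (fraction of curve max).
DEFAULT_THRESHOLD_FRACTION = 0.1


class Ramp(str, Enum):
    NONE = "none"
    HEATING = "heating"
    COOLING = "cooling"


@dataclass
class TurbidityCurve:
    """OD600 versus a control variable (salt in mM or temperature in °C)."""

    control: np.ndarray
    od600: np.ndarray
    ramp: Ramp = Ramp.NONE
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.ramp = Ramp(self.ramp)
        if len(self.control) != len(self.od600):
            raise InputError("control and od600 must have equal length")
        if np.any(np.diff(self.control) <= 0):
            raise InputError("control values must be strictly increasing")
        if np.any(self.od600 < 0):
            raise InputError("od600 must be non-negative")


@dataclass
class PhaseWindows:
    """Maximal turbid intervals of the control variable."""

    windows: list[tuple[float, float]]
    reentrant: bool
    threshold_used: float


@dataclass
class Transition:
    temperature_c: float
    direction: str  # "appear" | "dissolve"
    ramp: Ramp


@dataclass
class CloudPoints:
    transitions: list[Transition]
    hysteresis_c: list[float] = field(default_factory=list)


@dataclass
class CompositionCalibration:
    """Linear peak-area → concentration calibration for one analyte.

    Standards' peak areas are blank-corrected before ordinary least squares;
    the instrument protocol uses a four-point calibration per analyte
    (arginine for the arginine-rich peptide, glucosamine for hyaluronic acid).
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    blank_mean: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards >= 4 and self.slope <= 0:
            raise FitError("calibration slope must be positive")


@dataclass
class PhaseComposition:
    """Per-component concentrations in each phase with the volumes used."""

    c_dense_mg_ml: dict[str, float]
    c_dilute_mg_ml: dict[str, float]
    c_total_mg_ml: dict[str, float]
    v_total: float
    v_dense: float
    v_dilute: float

    def check_mass_balance(self, rtol: float = 1e-6) -> None:
        for comp, ct in self.c_total_mg_ml.items():
            lhs = ct * self.v_total
            rhs = (
                self.c_dense_mg_ml[comp] * self.v_dense
                + self.c_dilute_mg_ml[comp] * self.v_dilute
            )
            if not np.isclose(lhs, rhs, rtol=rtol, atol=1e-12):
                raise InconsistencyError(
                    f"mass balance violated for {comp}: {lhs} vs {rhs}"
                )


def _crossings(control, od, threshold):
    """Linearly interpolated control values where od crosses threshold.

    Returns list of (control_value, rising) with rising=True when od goes
    from below to >= threshold with increasing control.
    """
    out = []
    above = od >= threshold
    for i in range(len(od) - 1):
        if above[i] == above[i + 1]:
            continue
        x0, x1 = control[i], control[i + 1]
        y0, y1 = od[i], od[i + 1]
        xc = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)
        out.append((float(xc), bool(above[i + 1])))
    return out


def detect_phase_windows(
    curve: TurbidityCurve,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> PhaseWindows:
    """Locate maximal intervals where the sample is turbid.

    A point is turbid when ``od600 >= threshold_fraction * max(od600)``;
    window edges are linearly interpolated between grid points. A curve with
    two disjoint windows in a salt sweep is flagged reentrant. An all-zero
    curve yields no windows (the threshold would be zero, meaning no signal).
    """
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold_fraction must be in (0, 1)")
    od = curve.od600
    peak = od.max()
    if peak <= 0:
        return PhaseWindows([], False, 0.0)
    thr = threshold_fraction * peak

    windows: list[tuple[float, float]] = []
    crossings = _crossings(curve.control, od, thr)
    lo = curve.control[0] if od[0] >= thr else None
    for xc, rising in crossings:
        if rising:
            lo = xc
        elif lo is not None:
            windows.append((lo, xc))
            lo = None
    if lo is not None:
        windows.append((lo, float(curve.control[-1])))
    return PhaseWindows(windows, reentrant=len(windows) >= 2, threshold_used=thr)


def detect_cloud_points(
    heating: TurbidityCurve,
    cooling: TurbidityCurve,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> CloudPoints:
    """Threshold crossings of heating/cooling temperature ramps.

    On a heating ramp a downward crossing is a dissolution (UCST-like) and an
    upward crossing is an appearance (LCST-like); the labels swap meaning on
    cooling only in the sense of time order, not of direction in temperature,
    so directions are reported with respect to increasing temperature for
    both ramps. Hysteresis is the heating-minus-cooling temperature of each
    matched crossing pair (paired in temperature order, same direction).
    """
    for c, expected in ((heating, Ramp.HEATING), (cooling, Ramp.COOLING)):
        if c.ramp != expected:
            raise InputError(
                f"curve labelled {c.ramp.value!r} where {expected.value!r} expected"
            )
    transitions: list[Transition] = []
    per_ramp: dict[Ramp, list[tuple[float, bool]]] = {}
    for curve in (heating, cooling):
        peak = curve.od600.max()
        cr = (
            _crossings(curve.control, curve.od600, threshold_fraction * peak)
            if peak > 0
            else []
        )
        per_ramp[curve.ramp] = cr
        for xc, rising in cr:
            transitions.append(
                Transition(xc, "appear" if rising else "dissolve", curve.ramp)
            )
    hyst = []
    heat_cr, cool_cr = per_ramp[Ramp.HEATING], per_ramp[Ramp.COOLING]
    if len(heat_cr) == len(cool_cr):
        for (th, rh), (tc, rc) in zip(heat_cr, cool_cr):
            if rh == rc:
                hyst.append(th - tc)
    return CloudPoints(transitions, hyst)


def fit_calibration(
    standards: list[tuple[float, float]],
    blank_mean: float,
    analyte: str = "analyte",
    force_zero_intercept: bool = False,
) -> CompositionCalibration:
    """OLS calibration of blank-corrected peak area on concentration.

    ``standards`` is a list of (concentration mg/mL, raw peak area) pairs;
    the mean blank peak area is subtracted before regression.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    area = np.array([a for _, a in standards], dtype=float) - blank_mean
    if len(np.unique(conc)) < 2:
        raise FitError("calibration needs >= 2 distinct concentrations")
    if len(standards) < 4:
        warnings.warn(
            "fewer than 4 calibration standards; protocol uses four-point "
            "calibration",
            stacklevel=2,
        )
    if force_zero_intercept:
        slope = float(np.sum(conc * area) / np.sum(conc * conc))
        intercept = 0.0
        ss_res = float(np.sum((area - slope * conc) ** 2))
        ss_tot = float(np.sum((area - area.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(conc, area)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(
            res.rvalue**2
        )
    return CompositionCalibration(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        blank_mean=blank_mean,
        n_standards=len(standards),
    )


def quantify_concentration(
    peak_area: float, cal: CompositionCalibration
) -> float:
    """Invert a calibration: concentration in mg/mL from a raw peak area.

    Negative inversions (area below the blank-adjusted intercept) are
    clipped to zero with a warning — concentration cannot be negative.
    """
    if cal.slope <= 0:
        raise FitError("calibration slope must be positive to invert")
    c = (peak_area - cal.blank_mean - cal.intercept) / cal.slope
    if c < 0:
        warnings.warn(
            f"negative concentration {c:.4g} clipped to 0", stacklevel=2
        )
        return 0.0
    return float(c)


def dense_from_mass_balance(
    c_total: float,
    c_dilute: float,
    v_total: float,
    v_dilute: float,
    v_dense: float,
    volume_rtol: float = 0.05,
) -> float:
    """Dense-phase concentration from the two-phase mass balance.

    ``c_dense = (c_total·V_total − c_dilute·V_dilute) / V_dense`` — used when
    the dense phase is too concentrated to assay directly, so its
    composition is inferred from the total load, the dilute-phase assay and
    the measured phase volumes.
    """
    if v_dense <= 0:
        raise ParameterError("V_dense must be positive")
    if v_dense + v_dilute > v_total * (1 + volume_rtol):
        raise InconsistencyError("phase volumes exceed total volume")
    c_dense = (c_total * v_total - c_dilute * v_dilute) / v_dense
    if c_dense < -volume_rtol * max(c_total, 1e-30):
        raise InconsistencyError(
            f"mass balance gives negative dense concentration {c_dense:.4g}"
        )
    return max(c_dense, 0.0)


def composition_ratio(c_a: float, c_b: float) -> float:
    """Concentration ratio c_a / c_b (e.g. peptide : polysaccharide)."""
    if c_b == 0:
        raise ZeroDivisionError("denominator concentration is zero")
    return c_a / c_b


def average_replicates(curves: list[TurbidityCurve]) -> TurbidityCurve:
    """Average replicate turbidity curves sampled on a common grid."""
    if not curves:
        raise InputError("no curves to average")
    grid = curves[0].control
    for c in curves[1:]:
        if len(c.control) != len(grid) or not np.allclose(c.control, grid):
            raise InputError("replicates must share the control grid")
    od = np.mean([c.od600 for c in curves], axis=0)
    return TurbidityCurve(grid, od, curves[0].ramp, replicate_id="mean")
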