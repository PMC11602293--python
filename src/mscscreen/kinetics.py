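"""Enzyme characterization math used to rank screened mutants.

Michaelis–Menten kinetics by nonlinear least squares, first-order thermal
inactivation with half-life, activity-profile normalization, fold/percent
comparisons against a reference variant, and fibrin-plate calibration
against a urokinase standard curve.

``VARIANT_PRESETS`` carries the characterized parameter sets for wild-type
rAprY and its position-216 mutants (Km in μmol/L, kcat in s⁻¹, half-life at
55 °C in min, specific activity in U/mg); they seed the synthetic-data
generator and the worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from mscscreen.errors import CalibrationError, FitError, NoDecayError

__all__ = [
    "KineticsResult",
    "InactivationFit",
    "PlateCalibration",
    "VARIANT_PRESETS",
    "michaelis_menten",
    "fit_michaelis_menten",
    "fit_first_order_decay",
    "fold_and_percent",
    "normalize_profile",
    "calibrate_plate",
    "zone_to_activity",
]

#: characterized parameter sets by variant name
VARIANT_PRESETS: dict[str, dict[str, float]] = {
    "rAprY": {"Km": 1.52, "kcat": 7.10, "half_life": 9.80, "specific_activity": 398.27},
    "A216E": {"Km": 2.44, "kcat": 9.21, "half_life": 54.30, "specific_activity": 428.98},
    "A216K": {"Km": 1.29, "kcat": 5.53, "half_life": 55.93, "specific_activity": 483.15},
    "A216R": {"Km": 2.27, "kcat": 20.38, "half_life": 35.36, "specific_activity": 436.40},
}


@dataclass
class KineticsResult:
    """Fitted Michaelis–Menten parameters.

    ``kcat`` and ``efficiency`` (kcat/Km) are populated when the enzyme
    concentration is known; standard errors come from the fit covariance.
    """

    Km: float  # μmol/L
    Vmax: float  # rate units of the input
    Km_se: float
    Vmax_se: float
    kcat: float | None = None  # s⁻¹
    kcat_se: float | None = None
    efficiency: float | None = None  # kcat/Km

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax <= 0:
            raise FitError(f"fit produced non-positive parameters "
                           f"(Km={self.Km}, Vmax={self.Vmax})")


@dataclass
class InactivationFit:
    """Single-exponential thermal inactivation A(t) = A0·exp(−k·t)."""

    k_inact: float  # min⁻¹
    half_life: float  # min, ln2/k
    A0: float  # % of untreated activity
    k_se: float = float("nan")

    def residual_activity(self, t) -> np.ndarray | float:
        """Predicted residual activity (%) at time t (min)."""
        return self.A0 * np.exp(-self.k_inact * np.asarray(t, dtype=float))


@dataclass
class PlateCalibration:
    """Radial-diffusion standard curve: log10(activity) linear in zone area."""

    slope: float  # per mm²
    intercept: float
    standards: list[tuple[float, float]]  # (activity U/ml, zone area mm²)


def michaelis_menten(substrate, Vmax: float, Km: float):
    """v = Vmax·S / (Km + S)."""
    substrate = np.asarray(substrate, dtype=float)
    return Vmax * substrate / (Km + substrate)


def fit_michaelis_menten(substrate, rate, enzyme_conc: float | None = None) -> KineticsResult:
    """Nonlinear least-squares Michaelis–Menten fit.

    Parameters
    ----------
    substrate, rate
        Substrate concentrations (μmol/L) and initial rates; at least 4
        levels spanning the eventual Km.
    enzyme_conc
        Enzyme concentration in the same amount units as Vmax per second;
        when given, kcat = Vmax / enzyme_conc and efficiency = kcat/Km.
    """
    substrate = np.asarray(substrate, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if len(substrate) < 4:
        raise FitError("need at least 4 substrate levels")
    if np.any(rate < 0):
        raise FitError("rates must be non-negative")
    vmax0 = float(rate.max()) or 1.0
    km0 = float(np.interp(vmax0 / 2.0, np.sort(rate), np.sort(substrate))) or 1.0
    try:
        popt, pcov = curve_fit(
            michaelis_menten, substrate, rate, p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge "
                       f"(initial guess Vmax={vmax0:.3g}, Km={km0:.3g})") from exc
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    result = KineticsResult(Km=km, Vmax=vmax, Km_se=float(se[1]), Vmax_se=float(se[0]))
    if enzyme_conc is not None:
        if enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        result.kcat = vmax / enzyme_conc
        result.kcat_se = float(se[0]) / enzyme_conc
        result.efficiency = result.kcat / km
    return result


def fit_first_order_decay(times, residual_activity) -> InactivationFit:
    """Fit A(t) = A0·exp(−k·t) to residual-activity data (% of untreated).

    Half-life is ln2/k. Raises :class:`~mscscreen.errors.NoDecayError` when
    the data show no decay (k ≤ 0).
    """
    times = np.asarray(times, dtype=float)
    activity = np.asarray(residual_activity, dtype=float)
    if len(times) < 3:
        raise FitError("need at least 3 time points")
    if np.any(activity <= 0) or np.any(activity > 100 + 1e-9):
        raise FitError("activities must lie in (0, 100] percent")
    # log-linear seed, then full nonlinear fit
    slope, intercept = np.polyfit(times, np.log(activity), 1)
    if slope >= 0:
        raise NoDecayError(f"data show no decay (log-linear slope {slope:.3g} >= 0)")
    p0 = [float(np.exp(intercept)), float(-slope)]
    try:
        popt, pcov = curve_fit(
            lambda t, a0, k: a0 * np.exp(-k * t), times, activity, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError("inactivation fit did not converge") from exc
    a0, k = float(popt[0]), float(popt[1])
    if k <= 0:
        raise NoDecayError(f"fitted rate constant {k:.3g} <= 0")
    return InactivationFit(
        k_inact=k,
        half_life=math.log(2.0) / k,
        A0=a0,
        k_se=float(np.sqrt(pcov[1, 1])),
    )


def fold_and_percent(reference: float, mutant: float) -> tuple[float, float]:
    """Fold change and percent change of a mutant value vs the reference.

    Returns full-precision values; round to one decimal for reporting
    (percent = 100·(fold − 1) by construction).
    """
    if reference <= 0:
        raise ValueError("reference value must be positive")
    fold = mutant / reference
    return fold, 100.0 * (fold - 1.0)


def normalize_profile(labels, activities) -> dict:
    """Scale an activity profile so its maximum is 100%."""
    activities = np.asarray(activities, dtype=float)
    if len(labels) != len(activities):
        raise ValueError("one label per activity required")
    peak = activities.max(initial=0.0)
    if peak <= 0:
        raise ValueError("profile maximum must be positive")
    return dict(zip(labels, (100.0 * activities / peak).tolist()))


def calibrate_plate(standards) -> PlateCalibration:
    """Fit the urokinase standard curve: log10(activity) vs clear-zone area.

    ``standards`` is a sequence of (activity U/ml, zone area mm²) pairs with
    at least two distinct areas.
    """
    standards = [(float(a), float(z)) for a, z in standards]
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards")
    activities = np.array([a for a, _ in standards])
    areas = np.array([z for _, z in standards])
    if np.ptp(areas) == 0:
        raise CalibrationError("standard zone areas are identical (rank deficient)")
    if np.any(activities <= 0):
        raise CalibrationError("standard activities must be positive")
    slope, intercept = np.polyfit(areas, np.log10(activities), 1)
    return PlateCalibration(slope=float(slope), intercept=float(intercept),
                            standards=sorted(standards))


def zone_to_activity(calibration: PlateCalibration, zone_area: float) -> float:
    """Invert the standard curve: clear-zone area (mm²) → activity (U/ml)."""
    return float(10.0 ** (calibration.slope * zone_area + calibration.intercept))
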