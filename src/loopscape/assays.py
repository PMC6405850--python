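"""Wet-lab curve fits: thermal-melt midpoint and stoichiometry of inhibition.

Thermal denaturation followed by a spectroscopic signal is fitted with a
Boltzmann sigmoid

    s(T) = b_f + (b_u − b_f) / (1 + exp((T_m − T)/slope))

yielding the melt midpoint T_m (°C). Residual protease activity versus
serpin:protease molar ratio r is fitted with a straight line on the
pre-saturation region; the x-intercept is the stoichiometry of inhibition
(SI), the number of serpin molecules consumed per protease inhibited (1 for
a perfect suicide inhibitor; larger when the substrate pathway competes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class MeltFit:
    tm: float  # °C
    slope: float  # °C
    base_folded: float
    base_unfolded: float
    tm_stderr: float
    residual_sd: float
    identifiable: bool
    converged: bool
    residuals: np.ndarray


@dataclass
class SiFit:
    si: float
    slope: float
    intercept: float
    si_stderr: float
    n_points_used: int
    residuals: np.ndarray


def boltzmann(t: np.ndarray, tm: float, slope: float,
              base_folded: float, base_unfolded: float) -> np.ndarray:
    # clipped exponent keeps the optimiser's wild intermediate steps finite
    z = np.clip((tm - t) / slope, -500.0, 500.0)
    return base_folded + (base_unfolded - base_folded) / (1.0 + np.exp(z))


def _melt_curve_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        t = curve["temperature_C"].to_numpy(dtype=float)
        s = curve["signal"].to_numpy(dtype=float)
    else:
        t, s = (np.asarray(x, dtype=float) for x in curve)
    if t.size < 6:
        raise ValueError("melt fit needs at least 6 points spanning both baselines")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly ascending")
    return t, s


def fit_boltzmann_melt(curve) -> MeltFit:
    """Least-squares Boltzmann-sigmoid fit of a melt curve.

    Initialisation: baselines from the terminal 10% of points at each end,
    T_m at the half-amplitude crossing, slope from the central signal span.
    A fit whose amplitude is indistinguishable from the residual noise
    (|b_u − b_f| < 3 × residual sd) is flagged unidentifiable — the expected
    outcome for a protein that never unfolds over the scanned range.
    """
    t, s = _melt_curve_arrays(curve)
    k = max(2, int(round(0.1 * t.size)))
    b_f0 = float(s[:k].mean())
    b_u0 = float(s[-k:].mean())
    half = (b_f0 + b_u0) / 2.0
    crossing = np.argmin(np.abs(s - half))
    tm0 = float(t[crossing])
    slope0 = max((t[-1] - t[0]) / 20.0, 1e-3)
    p0 = (tm0, slope0, b_f0, b_u0)
    converged = True
    try:
        import warnings
        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # a flat curve has a singular covariance; we flag it below
            # instead of warning mid-fit
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(boltzmann, t, s, p0=p0, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt = np.array(p0)
        perr = np.full(4, np.nan)
        converged = False
    resid = s - boltzmann(t, *popt)
    resid_sd = float(np.std(resid, ddof=min(4, t.size - 1)))
    amplitude = abs(popt[3] - popt[2])
    identifiable = bool(converged and amplitude >= 3.0 * resid_sd
                        and amplitude > 0)
    return MeltFit(tm=float(popt[0]), slope=float(popt[1]),
                   base_folded=float(popt[2]), base_unfolded=float(popt[3]),
                   tm_stderr=float(perr[0]), residual_sd=resid_sd,
                   identifiable=identifiable, converged=converged,
                   residuals=resid)


def melt_hysteresis(heat_curve, cool_curve) -> float:
    """T_m(heating) − T_m(cooling); near zero for a reversible melt."""
    return fit_boltzmann_melt(heat_curve).tm - fit_boltzmann_melt(cool_curve).tm


def fit_si(assay, activity_floor: float = 0.1) -> SiFit:
    """Stoichiometry of inhibition from a residual-activity titration.

    Ordinary least squares of activity vs ratio restricted to points with
    residual activity above ``activity_floor`` (the linear, pre-saturation
    region); SI = −intercept/slope with the standard error propagated from
    the coefficient covariance. A non-negative slope means no measurable
    inhibition and is an error.
    """
    if isinstance(assay, pd.DataFrame):
        r = assay["ratio"].to_numpy(dtype=float)
        a = assay["residual_activity"].to_numpy(dtype=float)
    else:
        r, a = (np.asarray(x, dtype=float) for x in assay)
    use = a > activity_floor
    if use.sum() < 3:
        raise ValueError(
            f"need >= 3 points with residual activity > {activity_floor}")
    x, y = r[use], a[use]
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    if slope >= -1e-10:
        raise ValueError("non-negative slope: no inhibition detected")
    si = -intercept / slope
    # first-order propagation through si = -b/m
    var = (cov[1, 1] / slope**2
           + intercept**2 * cov[0, 0] / slope**4
           - 2.0 * intercept * cov[0, 1] / slope**3)
    resid = y - (slope * x + intercept)
    return SiFit(si=si, slope=slope, intercept=intercept,
                 si_stderr=float(np.sqrt(max(var, 0.0))),
                 n_points_used=int(use.sum()), residuals=resid)
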