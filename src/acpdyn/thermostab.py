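"""Thermal stability from CD melts and DSC thermograms.

CD melts monitored at 222 nm are fitted to a two-state model with a van 't
Hoff enthalpy and linear folded/unfolded baselines (the heat-capacity change
of unfolding is neglected):

    dG(T) = dH_vH * (1 - T/Tm),   f_U = 1 / (1 + exp(dG/RT))

DSC thermograms yield the model-free calorimetric enthalpy dH_cal as the
area under the excess heat capacity after baseline subtraction, Tm as the
peak position, and -- under the two-state assumption -- a closed-form excess
heat capacity

    Cp_exc(T) = dH_cal * dH_vH * K / (R * T^2 * (1 + K)^2),
    K(T) = exp(-(dH_vH/R) * (1/T - 1/Tm))

whose peak height at Tm (where K = 1) is dH_cal*dH_vH/(4*R*Tm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .hdx import R_KCAL
from .io_tables import SeriesTable


@dataclass
class MeltFit:
    Tm: float  # K
    dH_vH: float  # kcal/mol
    aN: float
    bN: float
    aU: float
    bU: float
    Tm_err: float = float("nan")
    dH_err: float = float("nan")


@dataclass
class DSCResult:
    Tm: float  # K, argmax of excess Cp
    dH_cal: float  # kcal/mol, area under excess Cp
    Cp_max: float  # kcal/mol/K
    baseline: str = "linear"


def melt_fraction_unfolded(T, Tm: float, dH_vH: float):
    T = np.asarray(T, dtype=float)
    dG = dH_vH * (1.0 - T / Tm)
    return 1.0 / (1.0 + np.exp(dG / (R_KCAL * T)))


def melt_signal(T, fit: MeltFit):
    T = np.asarray(T, dtype=float)
    fU = melt_fraction_unfolded(T, fit.Tm, fit.dH_vH)
    return (fit.aN + fit.bN * T) * (1.0 - fU) + (fit.aU + fit.bU * T) * fU


def fit_melt(curve: SeriesTable) -> MeltFit:
    """Two-state fit of a thermal melt (temperatures in Kelvin)."""
    T, y = curve.x, curve.y
    if T.size < 10:
        raise ValueError(f"need >= 10 points to fit a melt, got {T.size}")

    def model(t, Tm, dH, aN, bN, aU, bU):
        fU = melt_fraction_unfolded(t, Tm, dH)
        return (aN + bN * t) * (1.0 - fU) + (aU + bU * t) * fU

    t_lo, t_hi = float(T.min()), float(T.max())
    span = float(y.max() - y.min()) or 1.0
    best = None
    for tm0 in np.linspace(t_lo + 2.0, t_hi - 2.0, 12):
        p0 = (tm0, 50.0, y[0], 0.0, y[-1], 0.0)
        try:
            popt, pcov = curve_fit(
                model, T, y, p0=p0,
                bounds=([t_lo, 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
                        [t_hi, 1e4, np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(T, *popt) - y) ** 2))
        if best is None or sse < best[0] - 1e-12 * span**2:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("melt fit did not converge")

    _, popt, pcov = best
    Tm, dH, aN, bN, aU, bU = (float(v) for v in popt)
    fU = melt_fraction_unfolded(T, Tm, dH)
    if fU.min() > 0.2 or fU.max() < 0.8:
        raise ValueError("thermal transition not bracketed by the data")
    return MeltFit(Tm=Tm, dH_vH=dH, aN=aN, bN=bN, aU=aU, bU=bU,
                   Tm_err=float(np.sqrt(pcov[0, 0])), dH_err=float(np.sqrt(pcov[1, 1])))


def _refine_peak(T: np.ndarray, cp: np.ndarray) -> tuple[float, float]:
    """Peak location/height with parabolic refinement around the grid argmax."""
    i = int(np.argmax(cp))
    if 0 < i < cp.size - 1:
        y0, y1, y2 = cp[i - 1], cp[i], cp[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            tm = T[i] + delta * (T[i + 1] - T[i])
            cmax = y1 - 0.25 * (y0 - y2) * delta
            return float(tm), float(cmax)
    return float(T[i]), float(cp[i])


def excess_heat_capacity(thermogram: SeriesTable, baseline: str = "linear",
                         edge_fraction: float = 0.1) -> np.ndarray:
    """Baseline-subtracted excess Cp.

    ``none``: the thermogram is already excess heat capacity; returned as is.
    ``linear``: pre- and post-transition lines fitted outside the detected
    transition window, mixed linearly in T.
    ``progress``: the same two lines mixed by the unfolding progress (the
    normalised running integral of the excess signal), the sigmoidal-baseline
    convention of DSC software.

    The transition window is found iteratively: a first chord between the
    outer ``edge_fraction`` of points locates where the signal rises above
    1% of the peak; the baselines are then refit on the points outside that
    window only, so the peak's tails are not absorbed into the baseline.
    """
    T, cp = thermogram.x, thermogram.y
    if baseline == "none":
        return cp.copy()
    if baseline not in ("linear", "progress"):
        raise ValueError(f"unknown baseline model {baseline!r}")

    n_edge = max(2, int(edge_fraction * T.size))
    pre = np.polyfit(T[:n_edge], cp[:n_edge], 1)
    post = np.polyfit(T[-n_edge:], cp[-n_edge:], 1)

    for _ in range(3):
        lo, hi = np.polyval(pre, T), np.polyval(post, T)
        w0 = (T - T[0]) / (T[-1] - T[0])
        rough = cp - ((1.0 - w0) * lo + w0 * hi)
        peak = rough.max()
        if peak <= 0:
            break
        inside = rough > 0.01 * peak
        i_lo = int(np.argmax(inside))
        i_hi = int(len(inside) - np.argmax(inside[::-1]))
        left, right = slice(0, max(i_lo, 2)), slice(min(i_hi, T.size - 2), T.size)
        pre = np.polyfit(T[left], cp[left], 1)
        post = np.polyfit(T[right], cp[right], 1)

    lo, hi = np.polyval(pre, T), np.polyval(post, T)
    if baseline == "linear":
        w = (T - T[0]) / (T[-1] - T[0])
    else:  # progress
        rough = np.clip(cp - (lo + hi) / 2.0, 0, None)
        integ = np.concatenate([[0.0], np.cumsum((rough[1:] + rough[:-1]) / 2 * np.diff(T))])
        w = integ / integ[-1] if integ[-1] > 0 else np.linspace(0, 1, T.size)
    return cp - ((1.0 - w) * lo + w * hi)


def dsc_analyze(thermogram: SeriesTable, baseline: str = "linear") -> DSCResult:
    """Model-free DSC analysis: Tm (peak), dH_cal (area), Cp_max.

    A flat thermogram (no resolvable transition) returns dH_cal = 0 with
    Tm = NaN.  A baseline misfit driving the excess Cp negative over more
    than half of the transition window raises.
    """
    T = thermogram.x
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    exc = excess_heat_capacity(thermogram, baseline=baseline)

    peak = float(exc.max())
    noise_floor = 10.0 * max(np.abs(exc[:3]).max(), np.abs(exc[-3:]).max(), 1e-12)
    if peak <= noise_floor:
        return DSCResult(Tm=float("nan"), dH_cal=0.0, Cp_max=0.0, baseline=baseline)

    in_transition = exc > 0.05 * peak
    window = slice(int(np.argmax(in_transition)),
                   int(len(exc) - np.argmax(in_transition[::-1])))
    if np.mean(exc[window] < 0) > 0.5:
        raise ValueError("excess Cp negative over most of the transition: baseline misfit")

    dH = float(np.trapezoid(np.clip(exc, 0.0, None), T))
    Tm, cp_max = _refine_peak(T, exc)
    return DSCResult(Tm=Tm, dH_cal=dH, Cp_max=cp_max, baseline=baseline)


def two_state_cp(T, Tm: float, dH_vH: float, dH_cal: float):
    """Closed-form two-state excess heat capacity (kcal/mol/K)."""
    T = np.asarray(T, dtype=float)
    K = np.exp(-(dH_vH / R_KCAL) * (1.0 / T - 1.0 / Tm))
    return dH_cal * dH_vH * K / (R_KCAL * T**2 * (1.0 + K) ** 2)


def dsc_two_state_fit(thermogram: SeriesTable) -> tuple[float, float, float]:
    """Fit the two-state excess-Cp model; returns (Tm, dH_vH, dH_cal).

    Expects a baseline-subtracted thermogram (see ``excess_heat_capacity``).
    """
    T, cp = thermogram.x, thermogram.y
    i_pk = int(np.argmax(cp))
    tm0 = float(T[i_pk])
    dh0 = max(float(np.trapezoid(np.clip(cp, 0, None), T)), 1.0)
    dhvh0 = max(4.0 * R_KCAL * tm0**2 * float(cp[i_pk]) / dh0, 1.0)
    try:
        popt, _ = curve_fit(
            two_state_cp, T, cp, p0=(tm0, dhvh0, dh0),
            bounds=([T.min(), 1.0, 0.1], [T.max(), 1e4, 1e4]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"two-state DSC fit failed: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])
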