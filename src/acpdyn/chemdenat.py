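"""Two-state chemical denaturation by the linear extrapolation method (LEM).

The unfolding free energy is assumed linear in denaturant concentration D:

    dG(D) = dG_H2O - m * D

so the midpoint Cm = dG_H2O / m, and the observed signal is a population
average of native and unfolded baselines, each linear in D:

    f_U(D) = exp(-dG/RT) / (1 + exp(-dG/RT))
    y(D)   = (aN + bN*D) * (1 - f_U) + (aU + bU*D) * f_U

The fit is parameterised internally in (Cm, m, baselines) for conditioning;
dG_H2O is reported as m * Cm, the zero-denaturant extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .hdx import R_KCAL, T_DEFAULT
from .io_tables import SeriesTable


@dataclass
class LEMFit:
    dG_H2O: float  # kcal/mol
    m_value: float  # kcal/mol/M
    Cm: float  # M
    aN: float
    bN: float
    aU: float
    bU: float
    dG_err: float = float("nan")
    m_err: float = float("nan")
    Cm_err: float = float("nan")
    T: float = T_DEFAULT
    covariance: np.ndarray | None = field(default=None, repr=False)


def fraction_unfolded(D, dG_H2O: float, m_value: float, T: float = T_DEFAULT):
    dG = dG_H2O - m_value * np.asarray(D, dtype=float)
    # exp(-dG/RT)/(1+exp(-dG/RT)) written as a logistic for overflow safety
    return 1.0 / (1.0 + np.exp(dG / (R_KCAL * T)))


def lem_signal(D, params: LEMFit, T: float | None = None):
    """Observed two-state signal at denaturant concentration(s) D."""
    D = np.asarray(D, dtype=float)
    T = params.T if T is None else T
    fU = fraction_unfolded(D, params.dG_H2O, params.m_value, T)
    return (params.aN + params.bN * D) * (1.0 - fU) + (params.aU + params.bU * D) * fU


def _model(D, Cm, m, aN, bN, aU, bU, T):
    fU = fraction_unfolded(D, m * Cm, m, T)
    return (aN + bN * D) * (1.0 - fU) + (aU + bU * D) * fU


def _signal_midpoint(D, y, fit: LEMFit) -> float:
    """Cm read off the data as the crossing of the baseline-normalised signal."""
    yN = fit.aN + fit.bN * D
    yU = fit.aU + fit.bU * D
    with np.errstate(divide="ignore", invalid="ignore"):
        fU = (yN - y) / (yN - yU)
    ok = np.isfinite(fU)
    # enforce monotonicity against point noise before locating the crossing
    fU_mono = np.maximum.accumulate(fU[ok])
    return float(np.interp(0.5, fU_mono, D[ok]))


def fit_lem(curve: SeriesTable, T: float = T_DEFAULT) -> LEMFit:
    """Fit the six-parameter LEM model with a multi-start grid on Cm.

    Raises if the transition is not bracketed by the data (the fitted
    unfolded fraction must pass from clearly native to clearly unfolded
    within the measured range) or if the fitted m-value is non-positive.
    """
    D, y = curve.x, curve.y
    if D.size < 8:
        raise ValueError(f"need >= 8 points to fit a LEM curve, got {D.size}")

    d_lo, d_hi = float(D.min()), float(D.max())
    span = float(y.max() - y.min()) or 1.0
    best = None
    for cm0 in np.arange(d_lo + 0.25, d_hi, 0.25):
        p0 = (cm0, 2.0, y[0], 0.0, y[-1], 0.0)
        try:
            popt, pcov = curve_fit(
                lambda d, cm, m, aN, bN, aU, bU: _model(d, cm, m, aN, bN, aU, bU, T),
                D, y, p0=p0,
                bounds=([d_lo, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf],
                        [d_hi, np.inf, np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_model(D, *popt, T) - y) ** 2))
        if best is None or sse < best[0] - 1e-12 * span**2:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("LEM fit did not converge from any start")

    _, popt, pcov = best
    Cm, m, aN, bN, aU, bU = (float(v) for v in popt)
    if m <= 0:
        raise ValueError("fitted m-value is non-positive")

    fU = fraction_unfolded(D, m * Cm, m, T)
    if fU.min() > 0.2 or fU.max() < 0.8:
        raise ValueError("transition not bracketed by the data")

    # dG = m*Cm; propagate errors through the product.
    cm_err = float(np.sqrt(pcov[0, 0]))
    m_err = float(np.sqrt(pcov[1, 1]))
    dg_err = float(np.sqrt((m * cm_err) ** 2 + (Cm * m_err) ** 2 + 2 * m * Cm * pcov[0, 1]))
    fit = LEMFit(dG_H2O=m * Cm, m_value=m, Cm=Cm, aN=aN, bN=bN, aU=aU, bU=bU,
                 dG_err=dg_err, m_err=m_err, Cm_err=cm_err, T=T, covariance=pcov)

    cm_data = _signal_midpoint(D, y, fit)
    if abs(cm_data - Cm) > 0.02 * Cm:
        raise ValueError(
            f"fitted Cm {Cm:.3f} M and signal-midpoint crossing {cm_data:.3f} M "
            "disagree by more than 2%"
        )
    return fit
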