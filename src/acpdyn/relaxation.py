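"""Backbone 15N spin-relaxation fitting and dynamics classification.

R1 and R2 rates come from mono-exponential fits of peak-height decays over
the relaxation-delay series, with the per-point noise estimated from
duplicated delays (rms of paired differences divided by sqrt(2)).  The
steady-state heteronuclear NOE is the simple ratio of saturated to
unsaturated intensities.  Residues are classified against trimmed cohort
statistics: R2 above mean+SD marks conformational-exchange broadening, hNOE
below mean-SD marks fast-timescale flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import mstats

from .io_tables import ResidueID, SeriesTable

#: Relaxation-delay schedules (s) of the underlying experiments, kept
#: verbatim as acquired; the R2 list is non-monotone in its 8th/9th entries.
R1_DELAYS = (0.01, 0.01, 0.05, 0.1, 0.2, 0.3, 0.3, 0.5, 0.8, 1.2)
R2_DELAYS = (0.0, 0.0, 0.01696, 0.03392, 0.05088, 0.05088, 0.0848,
             0.013568, 0.022048, 0.32224)


@dataclass(frozen=True)
class RelaxationFit:
    rid: ResidueID
    rate: float  # s^-1
    rate_err: float
    kind: str  # "R1" or "R2"
    sigma: float = float("nan")  # duplicate-based per-point noise


@dataclass(frozen=True)
class HNOERecord:
    rid: ResidueID
    hnoe: float
    err: float = float("nan")


def duplicate_sigma(delays: np.ndarray, intensities: np.ndarray) -> float:
    """Per-point noise from duplicated delays: rms of paired diffs / sqrt(2)."""
    diffs = []
    seen: dict[float, float] = {}
    for tau, y in zip(delays, intensities):
        if tau in seen:
            diffs.append(y - seen[tau])
        else:
            seen[tau] = y
    if not diffs:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(diffs)) / 2.0))


def fit_relaxation(series: SeriesTable, kind: str) -> RelaxationFit:
    """Fit I(tau) = I0 * exp(-rate * tau); error scaled by the duplicate noise."""
    if kind not in ("R1", "R2"):
        raise ValueError(f"kind must be R1 or R2, got {kind!r}")
    tau, y = series.x, series.y
    if tau.size < 6:
        raise ValueError(f"{series.rid.label}: need >= 6 delays, got {tau.size}")
    if np.unique(tau).size < 3:
        raise ValueError(f"{series.rid.label}: too few distinct delays")

    def model(t, I0, rate):
        return I0 * np.exp(-rate * t)

    span = float(tau.max() - tau.min()) or 1.0
    rate0 = 1.0 / span
    popt, pcov = curve_fit(model, tau, y, p0=(float(np.max(y)), rate0),
                           bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    I0, rate = (float(v) for v in popt)
    if rate <= 0:
        raise RuntimeError(f"{series.rid.label}: non-positive fitted rate")

    sigma = duplicate_sigma(tau, y)
    if np.isfinite(sigma) and sigma > 0:
        # curve_fit's covariance is scaled by the residual variance; rescale
        # to the independently estimated duplicate-based noise.
        dof = max(tau.size - 2, 1)
        s_res2 = float(np.sum((model(tau, *popt) - y) ** 2)) / dof
        scale = sigma**2 / s_res2 if s_res2 > 0 else 1.0
        rate_err = float(np.sqrt(pcov[1, 1] * scale))
    else:
        rate_err = float(np.sqrt(pcov[1, 1]))
    return RelaxationFit(series.rid, rate=rate, rate_err=rate_err, kind=kind, sigma=sigma)


def hnoe(rid: ResidueID, sat: float, unsat: float, sigma: float = float("nan")) -> HNOERecord:
    """hNOE = I_sat / I_unsat; negative saturated intensities pass through."""
    if unsat <= 0:
        raise ValueError(f"{rid.label}: reference (unsaturated) intensity must be > 0")
    ratio = sat / unsat
    err = float("nan")
    if np.isfinite(sigma):
        err = abs(ratio) * float(np.hypot(sigma / sat, sigma / unsat)) if sat != 0 else sigma / unsat
    return HNOERecord(rid, float(ratio), err)


def _trimmed_mean_sd(values: np.ndarray, cut: float = 0.05) -> tuple[float, float]:
    mean = float(mstats.trimmed_mean(values, limits=(cut, cut)))
    sd = float(mstats.trimmed_std(values, limits=(cut, cut), ddof=1))
    return mean, sd


def classify_dynamics(
    r2: list[RelaxationFit], noes: list[HNOERecord], trim: float = 0.05
) -> dict[ResidueID, dict[str, bool]]:
    """Flag exchange-broadened (high R2) and flexible (low hNOE) residues.

    Thresholds are mean +/- one SD of trimmed cohort statistics (``trim``
    fraction cut from each tail), mirroring the usual highlighting of
    outlier residues in relaxation summaries.
    """
    r2_vals = np.array([f.rate for f in r2])
    noe_vals = np.array([h.hnoe for h in noes])
    r2_mean, r2_sd = _trimmed_mean_sd(r2_vals, trim)
    noe_mean, noe_sd = _trimmed_mean_sd(noe_vals, trim)

    flags: dict[ResidueID, dict[str, bool]] = {}
    for f in r2:
        flags.setdefault(f.rid, {"exchange_broadened": False, "flexible": False})
        flags[f.rid]["exchange_broadened"] = bool(f.rate > r2_mean + r2_sd)
    for h in noes:
        flags.setdefault(h.rid, {"exchange_broadened": False, "flexible": False})
        flags[h.rid]["flexible"] = bool(h.hnoe < noe_mean - noe_sd)
    return flags
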