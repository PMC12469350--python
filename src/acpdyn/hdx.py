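"""Per-residue H/D exchange analysis: decay fitting, intrinsic rates, protection.

An amide proton protected by structure exchanges with solvent deuterium much
more slowly than it would in a random coil.  The observed exchange rate
``k_prot`` is obtained by fitting the HSQC peak-intensity decay to a single
exponential; the intrinsic random-coil rate ``k_rc`` is predicted from the
sequence context with the standard reference parameter set of Bai, Milne,
Mayne & Englander (Proteins 17:75-86, 1993).  The protection factor is

    P = k_rc / k_prot,      logP = log10(P)

and, under the local-unfolding (EX2) interpretation, the free energy of the
opening reaction exposing that amide is

    dG_local = -R*T*ln(k_prot / k_rc) = ln(10) * R * T * logP

with R = 1.9872e-3 kcal/(mol*K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_tables import ResidueID, SeriesTable

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default analysis temperature (experiments at 25 C).
T_DEFAULT = 298.15

#: Glass-electrode correction: pD = pH-meter reading + 0.4.
PD_METER_CORRECTION = 0.4

#: Fraction of decay over the observation window below which a fitted rate
#: is treated as unresolved and reported as an upper bound.
CENSOR_DECAY_FRACTION = 0.05

# ---------------------------------------------------------------------------
# Random-coil (intrinsic) exchange-rate parameter set
#
# Poly-DL-alanine reference rates in D2O at 20 C (log10; acid and base in
# M^-1 min^-1 against 10^-pD / 10^(pD-pKD), water in min^-1), sequence
# corrections as additive log10 factors, and Arrhenius activation energies.
# Constants transcribed from the Bai et al. (1993) reference set as packaged
# data; "L" is the effect of a side chain on its own backbone amide, "R" the
# effect on the following residue's amide.
# ---------------------------------------------------------------------------
LOG_KA_REF = 1.62
LOG_KB_REF = 10.05
LOG_KW_REF = -1.5
PKD = 15.05
T_REF = 293.15
EA_ACID = 14.0  # kcal/mol
EA_BASE = 17.0
EA_WATER = 19.0

#: aa -> (acid_L, acid_R, base_L, base_R); Asp/Glu ionized, His neutral,
#: Cys reduced, Pro trans.
SIDE_CHAIN_CORRECTIONS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}

#: Terminal-group corrections applied on top of the side-chain factors.
NTERM_ACID_R = -1.32  # free alpha-ammonium, affects the second residue's NH
NTERM_BASE_R = 1.62
CTERM_ACID_L = 0.96  # terminal carboxylate, affects the last residue's NH
CTERM_BASE_L = -1.80


@dataclass(frozen=True)
class ExchangeFit:
    """Single-exponential fit of one amide's intensity decay."""

    rid: ResidueID
    I0: float
    C: float
    k_ex: float  # s^-1; identified with k_prot
    k_err: float
    censored: bool = False


@dataclass(frozen=True)
class ProtectionResult:
    rid: ResidueID
    k_rc: float
    P: float
    logP: float
    dG_local: float  # kcal/mol
    T: float
    lower_bound: bool = False  # True when derived from a censored rate


def _exp_model(t, I0, k, C):
    return I0 * np.exp(-k * t) + C


def fit_exchange_decay(series: SeriesTable) -> ExchangeFit:
    """Fit I(t) = I0*exp(-k*t) + C by least squares with multi-start on k.

    A decay too slow to resolve over the observation window (fitted
    ``k*t_max`` below 5% decay) is censored: ``k_ex`` is replaced by the rate
    producing exactly 5% decay over the window and is to be read as an upper
    bound.
    """
    t, y = series.x, series.y
    if t.size < 5:
        raise ValueError(f"{series.rid.label}: need >= 5 points, got {t.size}")
    if np.any(y < 0):
        raise ValueError(f"{series.rid.label}: negative intensities")

    t_max = float(t.max())
    scale = float(np.max(np.abs(y))) or 1.0
    best = None
    for k0 in (1e-6, 1e-5, 1e-4, 1e-3):
        p0 = (max(y[0] - y[-1], 0.1 * scale), k0, y[-1])
        try:
            # plateau bounded at zero: it is residual protonation, and an
            # unbounded C admits a degenerate near-linear solution for slow decays
            popt, pcov = curve_fit(
                _exp_model, t, y, p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_exp_model(t, *popt) - y) ** 2))
        if best is None or sse < best[0] - 1e-15 * scale**2:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError(f"{series.rid.label}: exchange fit did not converge")

    _, popt, pcov = best
    I0, k, C = (float(v) for v in popt)
    k_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    if k * t_max < -math.log(1.0 - CENSOR_DECAY_FRACTION):
        k_bound = -math.log(1.0 - CENSOR_DECAY_FRACTION) / t_max
        return ExchangeFit(series.rid, I0=I0, C=C, k_ex=k_bound, k_err=k_err, censored=True)
    return ExchangeFit(series.rid, I0=I0, C=C, k_ex=k, k_err=k_err, censored=False)


def _arrhenius(ea: float, T: float) -> float:
    return math.exp(-ea / R_KCAL * (1.0 / T - 1.0 / T_REF))


def intrinsic_rate(
    aa: str,
    left: str,
    right: str,
    pD: float = 6.5,
    T: float = T_DEFAULT,
    position: str = "internal",
) -> float:
    """Random-coil exchange rate (s^-1) of the backbone amide of residue ``aa``.

    The rate is the sum of acid-, base- and water-catalysed terms, each the
    poly-DL-alanine reference scaled by log-additive corrections from the
    residue's own side chain and its N-side neighbour ``left``, plus terminal
    corrections when ``position`` is ``nterm`` (the amide following the free
    alpha-amino group) or ``cterm`` (the C-terminal residue).  ``right`` is
    accepted for interface symmetry; the i+1 side chain does not contact the
    amide between i-1 and i and carries no correction in this parameter set.
    """
    if aa == "P":
        raise ValueError("proline has no backbone amide proton")
    for code, name in ((aa, "aa"), (left, "left"), (right, "right")):
        if code not in SIDE_CHAIN_CORRECTIONS:
            raise ValueError(f"unknown residue code {code!r} for {name}")
    if not (1.0 <= pD <= 12.0):
        raise ValueError(f"pD {pD} outside supported range [1, 12]")
    if not (273.0 < T < 373.0):
        raise ValueError(f"temperature {T} K outside supported range")
    if position not in ("nterm", "cterm", "internal"):
        raise ValueError(f"unknown position {position!r}")

    acid_own, _, base_own, _ = SIDE_CHAIN_CORRECTIONS[aa]
    _, acid_left, _, base_left = SIDE_CHAIN_CORRECTIONS[left]
    log_fa = acid_own + acid_left
    log_fb = base_own + base_left
    if position == "nterm":
        log_fa += NTERM_ACID_R
        log_fb += NTERM_BASE_R
    elif position == "cterm":
        log_fa += CTERM_ACID_L
        log_fb += CTERM_BASE_L

    k_acid = 10.0 ** (LOG_KA_REF + log_fa - pD) * _arrhenius(EA_ACID, T)
    k_base = 10.0 ** (LOG_KB_REF + log_fb + pD - PKD) * _arrhenius(EA_BASE, T)
    k_water = 10.0 ** (LOG_KW_REF + log_fb) * _arrhenius(EA_WATER, T)
    return (k_acid + k_base + k_water) / 60.0  # min^-1 -> s^-1


def protection(fit: ExchangeFit, k_rc: float, T: float = T_DEFAULT) -> ProtectionResult:
    """Protection factor and local-unfolding free energy from a fitted rate."""
    if k_rc <= 0:
        raise ValueError(f"{fit.rid.label}: k_rc must be positive")
    if fit.k_ex <= 0:
        raise ValueError(f"{fit.rid.label}: k_prot must be positive")
    P = k_rc / fit.k_ex
    logP = math.log10(P)
    dG = math.log(10.0) * R_KCAL * T * logP
    return ProtectionResult(
        rid=fit.rid, k_rc=k_rc, P=P, logP=logP, dG_local=dG, T=T,
        lower_bound=fit.censored,
    )


def dg_to_logp(dG: float, T: float = T_DEFAULT) -> float:
    """Express a free energy (kcal/mol) on the logP axis: dG / (ln10 * R * T)."""
    return dG / (math.log(10.0) * R_KCAL * T)
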