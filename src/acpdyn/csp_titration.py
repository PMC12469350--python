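"""Chemical-shift perturbation and metal-titration analysis.

The combined amide CSP between two states weights the nitrogen shift change
by a scale factor alpha reflecting the relative 15N dispersion:

    dd = sqrt( 0.5 * [ (ddH)^2 + (alpha * ddN)^2 ] )

with alpha = 0.2 for most residues and 0.14 for glycine.  Residues are
flagged significant when their CSP exceeds the cohort mean plus one sample
standard deviation.

Diamagnetic titrations (Ca2+) are followed as per-residue CSP trajectories
against the zero-concentration reference; paramagnetic titrations (Mn2+) as
normalised intensity ratios, where a peak broadened beyond detection is
assigned ratio 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .io_tables import ResidueID, ShiftRecord

logger = logging.getLogger("acpdyn")

ALPHA_DEFAULT = 0.2
ALPHA_GLYCINE = 0.14


@dataclass(frozen=True)
class CSPRecord:
    rid: ResidueID
    dd: float  # ppm
    significant: bool = False


@dataclass
class TitrationProfile:
    rid: ResidueID
    concentrations: np.ndarray  # M
    values: np.ndarray  # ppm (CSP) or dimensionless (intensity ratio)
    monotonicity: float = float("nan")  # Spearman rho vs concentration


def alpha_for(aa: str) -> float:
    return ALPHA_GLYCINE if aa == "G" else ALPHA_DEFAULT


def csp(ref: ShiftRecord, state: ShiftRecord, half_inside: bool = True) -> CSPRecord:
    """Weighted combined CSP between two states of the same residue.

    ``half_inside`` selects whether the 1/2 averaging factor sits inside the
    square root (the default convention used throughout) or outside it.
    """
    if ref.rid != state.rid:
        raise ValueError(f"residue mismatch: {ref.rid.label} vs {state.rid.label}")
    a = alpha_for(ref.rid.aa)
    ddH = state.dH - ref.dH
    ddN = state.dN - ref.dN
    q = ddH**2 + (a * ddN) ** 2
    dd = float(np.sqrt(0.5 * q)) if half_inside else float(0.5 * np.sqrt(q))
    return CSPRecord(ref.rid, dd)


def significance_flags(records: list[CSPRecord]) -> list[CSPRecord]:
    """Flag residues whose CSP strictly exceeds mean + one sample SD."""
    if len(records) < 3:
        raise ValueError("need >= 3 CSP records to set a significance threshold")
    values = np.array([r.dd for r in records])
    threshold = float(values.mean() + values.std(ddof=1))
    return [CSPRecord(r.rid, r.dd, r.dd > threshold) for r in records]


def csp_threshold(records: list[CSPRecord]) -> float:
    values = np.array([r.dd for r in records])
    return float(values.mean() + values.std(ddof=1))


def paramagnetic_ratio(
    ref: list[ShiftRecord], plus_metal: list[ShiftRecord]
) -> dict[ResidueID, float]:
    """Per-residue intensity ratio I(+metal)/I(reference).

    A residue present in the reference but absent (or without intensity) in
    the metal spectrum has vanished by paramagnetic broadening and receives
    ratio 0.  Residues absent from the reference are excluded with a warning.
    """
    by_rid = {r.rid: r for r in plus_metal}
    ratios: dict[ResidueID, float] = {}
    for r in ref:
        if r.intensity is None or r.intensity <= 0:
            logger.warning("%s: no reference intensity; excluded", r.rid.label)
            continue
        other = by_rid.get(r.rid)
        if other is None or other.intensity is None:
            ratios[r.rid] = 0.0
        else:
            ratios[r.rid] = float(other.intensity / r.intensity)
    return ratios


def titration_trajectory(
    states: list[list[ShiftRecord]], concentrations: list[float]
) -> list[TitrationProfile]:
    """CSP-vs-concentration profiles against the zero-concentration reference.

    The first state must be the reference (concentration 0).  Each residue's
    profile carries a Spearman monotonicity score against concentration.
    """
    if len(states) != len(concentrations):
        raise ValueError("states and concentrations differ in length")
    if concentrations[0] != 0:
        raise ValueError("first state must be the zero-concentration reference")
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must increase")

    ref = {r.rid: r for r in states[0]}
    profiles: list[TitrationProfile] = []
    for rid, r0 in sorted(ref.items()):
        concs, values = [0.0], [0.0]
        for conc, state in zip(concentrations[1:], states[1:]):
            match = next((s for s in state if s.rid == rid), None)
            if match is None:
                continue
            concs.append(float(conc))
            values.append(csp(r0, match).dd)
        if len(concs) < 2:
            continue
        if len(concs) >= 3 and len(set(values)) > 1:
            rho = spearmanr(concs, values).statistic
        else:
            rho = float("nan")
        profiles.append(
            TitrationProfile(rid, np.array(concs), np.array(values), float(rho))
        )
    return profiles
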