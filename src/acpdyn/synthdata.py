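"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator emulates one experiment's observable — mono-exponential
intensity decays, two-state sigmoidal denaturation and melt curves, two-state
DSC excess-heat-capacity peaks, per-residue shift tables with designated
perturbed residues, paramagnetic attenuation profiles, and coordinate series
with switching dihedrals and intermittent hydrogen bonds — and returns the
generated table together with a TruthManifest recording the exact parameters
used, so every analysis stage can be validated by parameter recovery.

Default parameters reproduce the experimental designs of the underlying
holo-ACP study: HDX sampled every 10 min for 1000 min; the printed R1/R2
delay schedules; the Ca2+ (0-30 mM) and Mn2+ (0-0.1 mM) titration ladders;
melting temperatures of 54.5/55.9/65.6/67.4 C for the no-metal/K+/Mg2+/Ca2+
CD conditions; DSC truths (Tm 66.4 C, dH_cal 71.2 kcal/mol, Cp_max 4.47
kcal/mol/K with Ca2+; 57.5 C, 54.5, 3.21 with K+); and a denaturation truth
of dG = 3.83 kcal/mol with midpoint 3.7 M.

Randomness: a single root seed is split into fixed per-stage child streams,
so regenerating one table never perturbs another and the same seed always
reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hdx as _hdx
from . import thermostab as _thermo
from .chemdenat import LEMFit, lem_signal
from .io_tables import ResidueID, SeriesTable, ShiftRecord
from .relaxation import R1_DELAYS, R2_DELAYS
from .thermostab import MeltFit, melt_signal, two_state_cp
from .trajgeom import FrameSeries

#: Mature E. coli ACP sequence, 1-based numbering (Ser36 carries the 4'-PP).
ECACP_SEQUENCE = (
    "STIEERVKKIIGEQLGVKQEEVTNNASFVEDLGADSLDTVELVMALEEEFDTEIPDEEAEKITTVQAAIDYINGHQA"
)

#: Helix boundaries of the solution structure (1-based, inclusive).
HELICES = {"a1": (3, 15), "a2": (36, 50), "a3": (56, 61), "a4": (65, 74)}

#: Fixed per-stage stream keys for seed splitting.
_STAGE_KEYS = {
    "hdx": 1, "denaturation": 2, "melt": 3, "dsc": 4,
    "shifts": 5, "ca_titration": 6, "mn_titration": 7,
    "relaxation": 8, "hnoe": 9, "trajectory": 10,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child RNG for one stage of one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]]))


@dataclass
class TruthManifest:
    seed: int
    stage: str
    truths: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def residue_id(index: int) -> ResidueID:
    return ResidueID(index, ECACP_SEQUENCE[index - 1])


# ---------------------------------------------------------------------------
# H/D exchange
# ---------------------------------------------------------------------------

#: Default local-unfolding free energies (kcal/mol) for the protected
#: (measurable) residues: the helix cohort above the global stability, the
#: two core anchors Ile11 (5.82) and Ile72 (6.01), and a few moderately
#: protected residues below the global value.
DEFAULT_HDX_DG: dict[int, float] = {
    # alpha1 and flanking
    7: 4.3, 8: 4.1, 9: 4.2, 10: 4.6, 11: 5.82, 12: 4.0, 13: 4.1, 14: 4.2, 15: 4.4,
    # alpha1-alpha2 loop anchor
    28: 4.5, 32: 4.0,
    # alpha2
    42: 4.7, 43: 4.9, 44: 4.3, 45: 4.2, 46: 5.0, 47: 4.6, 48: 4.1, 49: 4.0,
    50: 4.8, 52: 4.0,
    # alpha3 (only Ala59 protected) and alpha3-alpha4 loop
    59: 3.6, 62: 4.4,
    # alpha4
    65: 4.3, 66: 4.1, 67: 4.2, 68: 4.4, 69: 4.9, 70: 4.0, 71: 4.5, 72: 6.01, 73: 4.0,
}

#: Default HDX schedule: one HSQC every 10 min for 1000 min (seconds).
HDX_SCHEDULE_S = tuple(float(t) for t in range(0, 60001, 600))


def gen_hdx(
    seed: int,
    dg_truths: dict[int, float] | None = None,
    schedule_s: tuple[float, ...] = HDX_SCHEDULE_S,
    sigma: float = 0.02,
    pD: float = 6.1 + _hdx.PD_METER_CORRECTION,
    T: float = _hdx.T_DEFAULT,
    I0: float = 1.0,
    plateau: float = 0.05,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Per-residue exponential HDX decays with Gaussian noise.

    Each residue's protected rate is k_rc / 10**logP with k_rc computed from
    its real sequence context and logP from the assigned dG_local; rates are
    clipped to the observable window [1e-7, 1e-2] s^-1 and the recorded
    truth reflects the clipped value.
    """
    rng = stage_rng(seed, "hdx")
    dg_truths = DEFAULT_HDX_DG if dg_truths is None else dg_truths
    t = np.asarray(schedule_s, dtype=float)

    rows = []
    truths: dict[str, dict] = {}
    for idx in sorted(dg_truths):
        rid = residue_id(idx)
        left = ECACP_SEQUENCE[idx - 2] if idx > 1 else "A"
        right = ECACP_SEQUENCE[idx] if idx < len(ECACP_SEQUENCE) else "A"
        position = "nterm" if idx == 2 else ("cterm" if idx == len(ECACP_SEQUENCE) else "internal")
        k_rc = _hdx.intrinsic_rate(rid.aa, left, right, pD=pD, T=T, position=position)
        logp = _hdx.dg_to_logp(dg_truths[idx], T)
        k_prot = float(np.clip(k_rc / 10.0**logp, 1e-7, 1e-2))
        logp = math.log10(k_rc / k_prot)
        y = I0 * np.exp(-k_prot * t) + plateau
        if sigma > 0:
            y = y + rng.normal(0.0, sigma * I0, size=t.size)
        y = np.clip(y, 0.0, None)
        for ti, yi in zip(t, y):
            rows.append((idx, rid.aa, ti / 60.0, yi))
        truths[str(idx)] = {
            "aa": rid.aa, "k_rc": k_rc, "k_prot": k_prot, "logP": logp,
            "dG_local": math.log(10.0) * _hdx.R_KCAL * T * logp, "I0": I0, "C": plateau,
        }

    df = pd.DataFrame(rows, columns=["residue", "aa", "t_min", "intensity"])
    manifest = TruthManifest(seed, "hdx", truths=truths,
                             noise={"sigma": sigma, "pD": pD, "T": T})
    return df, manifest


# ---------------------------------------------------------------------------
# Chemical denaturation / thermal melts / DSC
# ---------------------------------------------------------------------------

def gen_denaturation(
    seed: int,
    dG: float = 3.83,
    Cm: float = 3.7,
    baselines: tuple[float, float, float, float] = (-11.5, 0.05, -2.0, 0.1),
    sigma_frac: float = 0.01,
    n_points: int = 20,
    d_max: float = 7.0,
    T: float = _hdx.T_DEFAULT,
) -> tuple[SeriesTable, TruthManifest]:
    """Two-state denaturation curve from the linear extrapolation model."""
    if Cm <= 0 or dG <= 0:
        raise ValueError("dG and Cm must be positive")
    m = dG / Cm
    aN, bN, aU, bU = baselines
    params = LEMFit(dG_H2O=dG, m_value=m, Cm=Cm, aN=aN, bN=bN, aU=aU, bU=bU, T=T)
    D = np.linspace(0.0, d_max, n_points)
    y = lem_signal(D, params)
    rng = stage_rng(seed, "denaturation")
    if sigma_frac > 0:
        span = abs((aU + bU * d_max) - aN)
        y = y + rng.normal(0.0, sigma_frac * span, size=D.size)
    table = SeriesTable(ResidueID(1, "S"), D, y, x_unit="M")
    manifest = TruthManifest(seed, "denaturation",
                             truths={"dG_H2O": dG, "m": m, "Cm": Cm,
                                     "baselines": list(baselines), "T": T},
                             noise={"sigma_frac": sigma_frac})
    return table, manifest


#: CD melting temperatures (K) per metal condition.
MELT_TM_K = {"none": 273.15 + 54.5, "K": 273.15 + 55.9,
             "Mg": 273.15 + 65.6, "Ca": 273.15 + 67.4}


def gen_melt(
    seed: int,
    Tm: float = MELT_TM_K["Ca"],
    dH_vH: float = 60.0,
    baselines: tuple[float, float, float, float] = (-12.0, 0.01, -3.0, 0.02),
    sigma_frac: float = 0.01,
    t_range: tuple[float, float] = (298.15, 373.15),
    n_points: int = 76,
) -> tuple[SeriesTable, TruthManifest]:
    """Two-state CD melt (ellipticity at 222 nm vs temperature in K)."""
    aN, bN, aU, bU = baselines
    fit = MeltFit(Tm=Tm, dH_vH=dH_vH, aN=aN, bN=bN, aU=aU, bU=bU)
    T = np.linspace(*t_range, n_points)
    y = melt_signal(T, fit)
    rng = stage_rng(seed, "melt")
    if sigma_frac > 0:
        span = abs(aU - aN) or 1.0
        y = y + rng.normal(0.0, sigma_frac * span, size=T.size)
    table = SeriesTable(ResidueID(1, "S"), T, y, x_unit="K")
    manifest = TruthManifest(seed, "melt",
                             truths={"Tm": Tm, "dH_vH": dH_vH, "baselines": list(baselines)},
                             noise={"sigma_frac": sigma_frac})
    return table, manifest


#: DSC truths per condition: (Tm K, dH_cal kcal/mol, Cp_max kcal/mol/K).
DSC_TRUTHS = {"Ca": (273.15 + 66.4, 71.2, 4.47), "K": (273.15 + 57.5, 54.5, 3.21)}


def gen_dsc(
    seed: int,
    Tm: float = DSC_TRUTHS["Ca"][0],
    dH_cal: float = DSC_TRUTHS["Ca"][1],
    Cp_max: float | None = DSC_TRUTHS["Ca"][2],
    dH_vH: float | None = None,
    baseline: tuple[float, float] = (0.0, 0.0),
    sigma: float = 0.0,
    t_range: tuple[float, float] = (293.15, 373.15),
    step: float = 0.1,
) -> tuple[SeriesTable, TruthManifest]:
    """Two-state DSC excess-heat-capacity peak on a uniform temperature grid.

    The van 't Hoff enthalpy is taken from ``dH_vH`` if given, otherwise
    derived from the requested peak height via
    Cp_max = dH_cal * dH_vH / (4 R Tm^2).  A linear instrument baseline
    ``a + b*(T - Tm)`` may be added.
    """
    if dH_vH is None:
        if Cp_max is None:
            raise ValueError("give either dH_vH or Cp_max")
        dH_vH = Cp_max * 4.0 * _thermo.R_KCAL * Tm**2 / dH_cal
    T = np.arange(t_range[0], t_range[1] + step / 2, step)
    cp = two_state_cp(T, Tm, dH_vH, dH_cal) + baseline[0] + baseline[1] * (T - Tm)
    rng = stage_rng(seed, "dsc")
    if sigma > 0:
        cp = cp + rng.normal(0.0, sigma, size=T.size)
    table = SeriesTable(ResidueID(1, "S"), T, cp, x_unit="K")
    manifest = TruthManifest(
        seed, "dsc",
        truths={"Tm": Tm, "dH_cal": dH_cal, "dH_vH": dH_vH,
                "Cp_max": dH_cal * dH_vH / (4.0 * _thermo.R_KCAL * Tm**2),
                "baseline": list(baseline)},
        noise={"sigma": sigma},
    )
    return table, manifest


# ---------------------------------------------------------------------------
# Shift tables, CSP and titrations
# ---------------------------------------------------------------------------

def _base_shifts(rng: np.random.Generator) -> list[ShiftRecord]:
    """A full-length reference shift table with realistic amide dispersion."""
    records = []
    for idx, aa in enumerate(ECACP_SEQUENCE, start=1):
        if aa == "P":  # no backbone amide peak
            continue
        records.append(ShiftRecord(
            ResidueID(idx, aa),
            dH=float(rng.normal(8.3, 0.45)),
            dN=float(rng.normal(118.0, 4.0)),
            intensity=float(rng.uniform(0.8e6, 1.2e6)),
        ))
    return records


def gen_shift_tables(
    seed: int,
    site_residues: tuple[int, ...] = (30, 35, 38, 47, 51, 53, 56),
    effect_ppm: tuple[float, float] = (0.06, 0.5),
    noise_ppm: tuple[float, float] = (0.002, 0.02),
) -> tuple[list[ShiftRecord], list[ShiftRecord], TruthManifest]:
    """A reference table and a perturbed state: designated residues shifted.

    ``effect_ppm`` is the (1H, 15N) shift change applied to site residues;
    ``noise_ppm`` the per-dimension Gaussian jitter applied everywhere.
    Glycines are present in the sequence, exercising the alpha = 0.14 weight.
    """
    rng = stage_rng(seed, "shifts")
    ref = _base_shifts(rng)
    state = []
    for rec in ref:
        on_site = rec.rid.index in site_residues
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        dH = rec.dH + (sgn * effect_ppm[0] if on_site else 0.0) + rng.normal(0, noise_ppm[0])
        dN = rec.dN + (sgn * effect_ppm[1] if on_site else 0.0) + rng.normal(0, noise_ppm[1])
        state.append(ShiftRecord(rec.rid, dH, dN, rec.intensity))
    manifest = TruthManifest(seed, "shifts",
                             truths={"site_residues": list(site_residues),
                                     "effect_ppm": list(effect_ppm)},
                             noise={"noise_ppm": list(noise_ppm)})
    return ref, state, manifest


#: Titration ladders (M).
CA_LADDER_M = (0.0, 0.5e-3, 1e-3, 2e-3, 5e-3, 10e-3, 20e-3, 30e-3)
MN_LADDER_M = (0.0, 1e-6, 5e-6, 10e-6, 20e-6, 50e-6, 100e-6)


def gen_ca_titration(
    seed: int,
    site_residues: tuple[int, ...] = (30, 35, 38, 47, 51, 53, 56),
    Kd: float = 2e-3,
    dd_max: tuple[float, float] = (0.08, 0.6),
    ladder: tuple[float, ...] = CA_LADDER_M,
    noise_ppm: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[list[ShiftRecord]], TruthManifest]:
    """Fast-exchange two-site titration: shifts move with the bound fraction.

    Site residues follow dd(c) = dd_max * c/(c + Kd); off-site residues only
    jitter.  Returns one shift table per ladder point (first is the
    reference) plus the truth manifest with the endpoint bound fraction.
    """
    rng = stage_rng(seed, "ca_titration")
    ref = _base_shifts(rng)
    states = [ref]
    for conc in ladder[1:]:
        fb = conc / (conc + Kd)
        state = []
        for rec in ref:
            on_site = rec.rid.index in site_residues
            dH = rec.dH + (dd_max[0] * fb if on_site else 0.0) + rng.normal(0, noise_ppm[0])
            dN = rec.dN + (dd_max[1] * fb if on_site else 0.0) + rng.normal(0, noise_ppm[1])
            state.append(ShiftRecord(rec.rid, dH, dN, rec.intensity))
        states.append(state)
    manifest = TruthManifest(
        seed, "ca_titration",
        truths={"site_residues": list(site_residues), "Kd": Kd,
                "dd_max": list(dd_max), "ladder": list(ladder),
                "endpoint_bound_fraction": ladder[-1] / (ladder[-1] + Kd)},
        noise={"noise_ppm": list(noise_ppm)},
    )
    return states, manifest


def gen_mn_titration(
    seed: int,
    site_residues: tuple[int, ...] = (35, 38, 47, 51, 53, 56),
    near_site_residues: tuple[int, ...] = (14, 15, 16, 17, 30),
    c_half_site: float = 5e-6,
    c_half_near: float = 2e-5,
    c_half_far: float = 5e-3,
    ladder: tuple[float, ...] = MN_LADDER_M,
    vanish_below: float = 0.0,
) -> tuple[list[list[ShiftRecord]], TruthManifest]:
    """Paramagnetic titration: intensities attenuate as exp(-c / c_half).

    Metal-coordinating residues attenuate fastest, near-site residues more
    slowly, and remote residues barely.  Ratios below ``vanish_below`` turn
    the peak absent (intensity None) to emulate broadening beyond detection.
    """
    rng = stage_rng(seed, "mn_titration")
    ref = _base_shifts(rng)
    c_half = {}
    for rec in ref:
        if rec.rid.index in site_residues:
            c_half[rec.rid.index] = c_half_site
        elif rec.rid.index in near_site_residues:
            c_half[rec.rid.index] = c_half_near
        else:
            c_half[rec.rid.index] = c_half_far
    states = [ref]
    for conc in ladder[1:]:
        state = []
        for rec in ref:
            ratio = math.exp(-conc / c_half[rec.rid.index])
            if ratio < vanish_below:
                state.append(ShiftRecord(rec.rid, rec.dH, rec.dN, None))
            else:
                state.append(ShiftRecord(rec.rid, rec.dH, rec.dN, rec.intensity * ratio))
        states.append(state)
    manifest = TruthManifest(
        seed, "mn_titration",
        truths={"site_residues": list(site_residues),
                "near_site_residues": list(near_site_residues),
                "c_half": {str(k): v for k, v in c_half.items()},
                "ladder": list(ladder), "vanish_below": vanish_below},
    )
    return states, manifest


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

#: Default R2 truths (s^-1): a uniform cohort with the two exchange-broadened
#: outliers of the butyryl form, Phe28 (9.86) and Ile54 (8.72).
def default_r2_truths() -> dict[int, float]:
    truths = {}
    for idx, aa in enumerate(ECACP_SEQUENCE, start=1):
        if aa == "P":
            continue
        truths[idx] = 5.0
    truths[28] = 9.86
    truths[54] = 8.72
    truths[1] = truths[77] = 3.0  # mobile termini
    return truths


def default_r1_truths() -> dict[int, float]:
    return {idx: 1.4 for idx, aa in enumerate(ECACP_SEQUENCE, start=1) if aa != "P"}


def gen_relaxation(
    seed: int,
    rates: dict[int, float] | None = None,
    schedule: tuple[float, ...] | None = None,
    kind: str = "R2",
    sigma_frac: float = 0.0,
    I0: float = 1.0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Exponential relaxation decays over the experiment's delay schedule."""
    if rates is None:
        rates = default_r2_truths() if kind == "R2" else default_r1_truths()
    if schedule is None:
        schedule = R2_DELAYS if kind == "R2" else R1_DELAYS
    rng = stage_rng(seed, "relaxation")
    tau = np.asarray(schedule, dtype=float)
    rows = []
    for idx in sorted(rates):
        aa = ECACP_SEQUENCE[idx - 1]
        y = I0 * np.exp(-rates[idx] * tau)
        if sigma_frac > 0:
            y = y + rng.normal(0.0, sigma_frac * I0, size=tau.size)
        for t, yi in zip(tau, y):
            rows.append((idx, aa, t, yi))
    df = pd.DataFrame(rows, columns=["residue", "aa", "delay_s", "intensity"])
    manifest = TruthManifest(seed, "relaxation",
                             truths={"rates": {str(k): v for k, v in rates.items()},
                                     "kind": kind, "schedule": list(schedule), "I0": I0},
                             noise={"sigma_frac": sigma_frac})
    return df, manifest


def gen_hnoe(
    seed: int,
    noes: dict[int, float] | None = None,
    sigma_frac: float = 0.0,
    I0: float = 1.0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Paired saturated/unsaturated intensities realizing given hNOE ratios."""
    if noes is None:
        noes = {idx: 0.80 for idx, aa in enumerate(ECACP_SEQUENCE, start=1) if aa != "P"}
        noes[1] = -0.2  # flexible N-terminus can invert
        noes[2] = 0.3
        noes[77] = 0.1
        noes[19] = noes[20] = 0.86  # rigid loop anchors
    rng = stage_rng(seed, "hnoe")
    rows = []
    for idx in sorted(noes):
        aa = ECACP_SEQUENCE[idx - 1]
        unsat = I0 * (1.0 + (rng.normal(0, sigma_frac) if sigma_frac > 0 else 0.0))
        sat = noes[idx] * I0 + (rng.normal(0, sigma_frac * I0) if sigma_frac > 0 else 0.0)
        rows.append((idx, aa, sat, unsat))
    df = pd.DataFrame(rows, columns=["residue", "aa", "I_sat", "I_unsat"])
    manifest = TruthManifest(seed, "hnoe",
                             truths={"hnoe": {str(k): v for k, v in noes.items()}},
                             noise={"sigma_frac": sigma_frac})
    return df, manifest


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def _place_dihedral_atom(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float):
    """Place a fourth atom at given bond length, bond angle and torsion (NeRF)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return p3 + m @ d


def telegraph_schedule(rng: np.random.Generator, n_frames: int,
                       dwell_fractions: tuple[float, ...],
                       switch_prob: float = 0.02) -> np.ndarray:
    """Markov-chain state labels with the given stationary occupancies."""
    fractions = np.asarray(dwell_fractions, dtype=float)
    if np.any(fractions <= 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("dwell fractions must be positive and sum to 1")
    labels = np.empty(n_frames, dtype=int)
    labels[0] = rng.choice(fractions.size, p=fractions)
    for i in range(1, n_frames):
        if rng.random() < switch_prob:
            labels[i] = rng.choice(fractions.size, p=fractions)
        else:
            labels[i] = labels[i - 1]
    return labels


def gen_trajectory(
    seed: int,
    n_frames: int = 2000,
    chi1_states: tuple[float, ...] = (-70.0, -180.0),
    chi1_dwell: tuple[float, ...] = (0.5, 0.5),
    chi1_schedule: np.ndarray | None = None,
    hbond_dwell: float = 0.40,
    bound_distance: float = 2.9,
    unbound_distance: float = 4.6,
    sigma: float = 0.0,
) -> tuple[FrameSeries, TruthManifest]:
    """Coordinate series with a switching chi1 torsion and a blinking H-bond.

    The Leu42 side-chain chi1 is realised exactly at the scheduled state
    centre each frame; the Gln19(NE2)...Lys8(O) donor-acceptor distance sits
    at ``bound_distance`` in exactly round(hbond_dwell * n_frames) frames and
    ``unbound_distance`` otherwise; a small rigid core provides Rg/COM
    targets including the prosthetic-arm sulfur.
    """
    rng = stage_rng(seed, "trajectory")
    if chi1_schedule is None:
        chi1_schedule = telegraph_schedule(rng, n_frames, chi1_dwell)
    chi1_schedule = np.asarray(chi1_schedule, dtype=int)
    n_frames = chi1_schedule.size

    n_bound = int(round(hbond_dwell * n_frames))
    bound_frames = np.zeros(n_frames, dtype=bool)
    bound_frames[rng.choice(n_frames, size=n_bound, replace=False)] = True

    # Leu42 chi1 quartet N-CA-CB-CG; Gln19 NE2 donor; Lys8 backbone O
    # acceptor; prosthetic sulfur and a compact 6-atom core.
    atoms = [(42, "N"), (42, "CA"), (42, "CB"), (42, "CG"),
             (19, "NE2"), (8, "O"), (36, "S")]
    core = [(100 + i, "CA") for i in range(6)]
    atoms += core
    n_atoms = len(atoms)

    p_n = np.array([0.0, 0.0, 0.0])
    p_ca = np.array([1.46, 0.0, 0.0])
    p_cb = p_ca + np.array([0.53, 1.44, 0.0])
    p_o = np.array([8.0, 0.0, 0.0])
    p_s = np.array([4.0, 6.0, 2.0])
    core_xyz = np.array([[10.0, 10.0, 10.0], [12.0, 10.0, 10.0], [10.0, 12.0, 10.0],
                         [10.0, 10.0, 12.0], [12.0, 12.0, 10.0], [11.0, 11.0, 11.6]])

    coords = np.empty((n_frames, n_atoms, 3))
    states = np.asarray(chi1_states, dtype=float)
    for f in range(n_frames):
        chi = states[chi1_schedule[f]]
        p_cg = _place_dihedral_atom(p_n, p_ca, p_cb, 1.53, 114.0, chi)
        dist = bound_distance if bound_frames[f] else unbound_distance
        p_ne2 = p_o + np.array([dist, 0.0, 0.0])
        frame = np.vstack([p_n, p_ca, p_cb, p_cg, p_ne2, p_o, p_s, core_xyz])
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma, size=frame.shape)
        coords[f] = frame

    transitions = int(np.sum(np.diff(chi1_schedule) != 0))
    occupancies = [float(np.mean(chi1_schedule == s)) for s in range(states.size)]
    series = FrameSeries(times=np.arange(n_frames, dtype=float) * 0.5,
                         atoms=atoms, coords=coords)
    manifest = TruthManifest(
        seed, "trajectory",
        truths={"chi1_states": list(states), "chi1_occupancies": occupancies,
                "chi1_transitions": transitions,
                "hbond_occupancy": n_bound / n_frames,
                "bound_distance": bound_distance,
                "unbound_distance": unbound_distance},
        noise={"sigma": sigma},
    )
    return series, manifest
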