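"""Geometry metrics for coordinate time series from MD trajectories.

Covers the metrics used to characterise acyl-chain accommodation: chi1
side-chain torsions (gating switches), radius of gyration (overall
swelling), centre-of-mass-to-atom distances (chain sequestration depth),
hydrogen-bond occupancy by a distance-only criterion, and assignment of
dihedral series to discrete rotameric states with transition counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Distance cutoff (Angstrom) for hydrogen-bond occupancy.
HBOND_CUTOFF = 3.5

#: Fourth chi1 atom by residue type (chi1 = N-CA-CB-X); Ala/Gly have no chi1.
CHI1_ATOMS: dict[str, str] = {
    "R": "CG", "N": "CG", "D": "CG", "C": "SG", "Q": "CG", "E": "CG",
    "H": "CG", "I": "CG1", "L": "CG", "K": "CG", "M": "CG", "F": "CG",
    "P": "CG", "S": "OG", "T": "OG1", "W": "CG", "Y": "CG", "V": "CG1",
}


@dataclass
class FrameSeries:
    """Time-ordered coordinates for a named atom set.

    ``atoms`` is a list of (residue_index, atom_name); ``coords`` has shape
    (n_frames, n_atoms, 3) in Angstrom; ``masses`` default to unit masses.
    """

    times: np.ndarray  # ns
    atoms: list[tuple[int, str]]
    coords: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.ones(len(self.atoms))
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    def atom_index(self, residue: int, name: str) -> int:
        try:
            return self.atoms.index((residue, name))
        except ValueError:
            raise KeyError(f"atom {name} of residue {residue} not found") from None


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees on (-180, 180], IUPAC sign convention.

    Computed from the projection of the bond vectors onto the plane normal
    to the central bond (the numerically stable atan2 formulation).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError("consecutive points coincide")
    n1 = np.linalg.norm(b1)
    if (np.linalg.norm(np.cross(b0, b1)) < 1e-10 * np.linalg.norm(b0) * n1
            or np.linalg.norm(np.cross(b1, b2)) < 1e-10 * n1 * np.linalg.norm(b2)):
        raise ValueError("collinear atom triple; dihedral undefined")
    u = b1 / n1
    v = b0 - np.dot(b0, u) * u
    w = b2 - np.dot(b2, u) * u
    ang = np.degrees(np.arctan2(np.dot(np.cross(u, v), w), np.dot(v, w)))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def chi1(frame: FrameSeries, frame_index: int, residue: int, aa: str) -> float:
    """chi1 torsion (N-CA-CB-Xgamma) of one residue in one frame."""
    if aa in ("A", "G"):
        raise ValueError(f"{aa}{residue}: no chi1 torsion (no gamma atom)")
    if aa not in CHI1_ATOMS:
        raise ValueError(f"unknown residue type {aa!r}")
    names = ("N", "CA", "CB", CHI1_ATOMS[aa])
    pts = [frame.coords[frame_index, frame.atom_index(residue, n)] for n in names]
    return dihedral(*pts)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None,
                       mass_weighted: bool = True) -> float:
    """Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ) in Angstrom."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("expected an (n_atoms, 3) frame")
    if masses is None or not mass_weighted:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / total))


def com_distance(coords: np.ndarray, selection: np.ndarray, atom_b: np.ndarray,
                 masses: np.ndarray | None = None) -> float:
    """Distance between the mass-weighted COM of ``selection`` rows and a point."""
    sel = np.asarray(coords, dtype=float)[np.asarray(selection, dtype=int)]
    if sel.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(sel.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * sel).sum(axis=0) / masses.sum()
    return float(np.linalg.norm(com - np.asarray(atom_b, dtype=float)))


def hbond_occupancy(series: FrameSeries, donor: tuple[int, str],
                    acceptor: tuple[int, str], cutoff: float = HBOND_CUTOFF) -> float:
    """Fraction of frames with donor-acceptor distance <= cutoff (no angle term)."""
    if series.coords.shape[0] == 0:
        raise ValueError("empty frame series")
    i = series.atom_index(*donor)
    j = series.atom_index(*acceptor)
    d = np.linalg.norm(series.coords[:, i] - series.coords[:, j], axis=1)
    return float(np.mean(d <= cutoff))


def _circular_diff(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def switch_detect(angles: np.ndarray, states: list[float], tolerance: float
                  ) -> tuple[np.ndarray, int]:
    """Assign each frame's dihedral to the nearest state centre on the circle.

    Frames farther than ``tolerance`` from every centre stay unassigned (-1).
    Transitions are counted between consecutive assigned frames whose labels
    differ, skipping unassigned frames in between.  State windows must not
    overlap (centres separated by more than twice the tolerance).
    """
    states_arr = np.asarray(states, dtype=float)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            if _circular_diff(states_arr[i], states_arr[j]) <= 2 * tolerance:
                raise ValueError(f"state windows {states[i]} and {states[j]} overlap")

    angles = np.asarray(angles, dtype=float)
    dists = _circular_diff(angles[:, None], states_arr[None, :])
    labels = np.argmin(dists, axis=1)
    labels[dists[np.arange(angles.size), labels] > tolerance] = -1

    assigned = labels[labels >= 0]
    transitions = int(np.sum(np.diff(assigned) != 0)) if assigned.size else 0
    return labels, transitions


# -- frame input -------------------------------------------------------------

def read_frames_pdb(path: str | Path) -> FrameSeries:
    """Read a multi-model PDB (MODEL/ENDMDL records) into a FrameSeries."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atoms = [(int(a.resid), str(a.name)) for a in u.atoms]
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    times = np.arange(coords.shape[0], dtype=float)
    try:
        masses = u.atoms.masses.copy()
    except Exception:
        masses = None
    return FrameSeries(times=times, atoms=atoms, coords=coords, masses=masses)


def read_frames_table(path: str | Path) -> FrameSeries:
    """Read a whitespace table with columns (frame, residue, atom, x, y, z)."""
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["frame", "residue", "atom", "x", "y", "z"])
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    atoms = [(int(r.residue), str(r.atom)) for r in first.itertuples()]
    coords = np.empty((len(frames), len(atoms), 3))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != len(atoms):
            raise ValueError(f"frame {f}: atom count differs from first frame")
        coords[fi] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    return FrameSeries(times=np.asarray(frames, dtype=float), atoms=atoms, coords=coords)
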