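"""MM-PBSA end-state free-energy bookkeeping and trajectory geometry checks.

The binding free energy of an inhibitor-protein complex is assembled from
per-frame energy components of three species (complex, protein, inhibitor):

.. math::

    \\Delta G_{bind} &= \\Delta H - T\\Delta S \\\\
    \\Delta H &= \\Delta E_{MM} + \\Delta G_{solv} \\\\
    \\Delta E_{MM} &= \\Delta E_{elec} + \\Delta E_{vdW} \\\\
    \\Delta G_{solv} &= \\Delta G_{PB} + \\Delta G_{NP} \\\\
    \\Delta G_{NP} &= \\gamma \\cdot SASA + \\beta

with the AMBER default surface-tension parameters gamma = 0.005420
kcal/mol/A^2 and beta = -1.008 kcal/mol.  Every delta is
``complex - (protein + inhibitor)`` per frame; summary statistics are means
with standard errors over frames.  The entropy penalty ``-T dS`` (from
normal-mode analysis) enters as a given value, not a computation.

The module also provides geometric hydrogen-bond detection (donor-acceptor
distance <= 3.5 A and donor-H-acceptor angle >= 120 deg by default) and
minimum ligand-to-residue contact distances over trajectory frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._text import parse_number

__all__ = [
    "GAMMA_DEFAULT",
    "BETA_DEFAULT",
    "SPECIES",
    "Measured",
    "FrameEnergyTable",
    "EnergySummary",
    "HBondCriterion",
    "HBond",
    "nonpolar_term",
    "frame_deltas",
    "summarize",
    "summary_from_means",
    "detect_hbonds",
    "min_contact_distance",
]

GAMMA_DEFAULT = 0.005420   # kcal mol^-1 A^-2
BETA_DEFAULT = -1.008000   # kcal mol^-1
SPECIES = ("complex", "protein", "inhibitor")
COMPONENTS = ("E_vdW", "E_elec", "G_PB", "SASA")


class Measured(NamedTuple):
    """A value with its standard error of the mean."""

    value: float
    sem: float


def nonpolar_term(sasa: float, gamma: float = GAMMA_DEFAULT,
                  beta: float = BETA_DEFAULT) -> float:
    """Nonpolar solvation energy gamma * SASA + beta (kcal/mol)."""
    sasa = np.asarray(sasa, dtype=float)
    if np.any(sasa < 0):
        raise ValueError("SASA must be non-negative")
    out = gamma * sasa + beta
    return float(out) if out.ndim == 0 else out


@dataclass
class FrameEnergyTable:
    """Per-frame energy components for complex, protein and inhibitor.

    ``data`` is a long-format DataFrame with columns frame, species, E_vdW,
    E_elec, G_PB (kcal/mol) and SASA (A^2); each species must cover the same
    frames.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = {"frame", "species", *COMPONENTS} - set(self.data.columns)
        if missing:
            raise ValueError(f"frame table missing columns: {sorted(missing)}")
        bad = set(self.data["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species: {sorted(bad)}")
        if not np.isfinite(self.data[list(COMPONENTS)].to_numpy()).all():
            raise ValueError("non-finite energy component")
        frames = {s: set(g["frame"]) for s, g in self.data.groupby("species")}
        if len(frames) != 3 or len(set(map(frozenset, frames.values()))) != 1:
            raise ValueError("complex/protein/inhibitor must cover identical frames")

    @property
    def n_frames(self) -> int:
        return self.data["frame"].nunique()

    @classmethod
    def from_csv(cls, path: str) -> "FrameEnergyTable":
        df = pd.read_csv(path)
        for col in COMPONENTS:
            if df[col].dtype == object:  # tolerate typographic minus signs
                df[col] = df[col].map(parse_number)
        return cls(df)


def frame_deltas(table: FrameEnergyTable, gamma: float = GAMMA_DEFAULT,
                 beta: float = BETA_DEFAULT) -> pd.DataFrame:
    """Per-frame binding deltas: each component as complex - protein - inhibitor.

    Returns a DataFrame indexed by frame with columns dE_vdW, dE_elec, dG_PB
    and dG_NP, where dG_NP applies the nonpolar term to each species' SASA
    before differencing (so one beta offset survives: gamma*dSASA - beta).
    """
    wide = {s: g.set_index("frame").sort_index() for s, g in table.data.groupby("species")}
    cx, pr, inh = (wide[s] for s in SPECIES)
    out = pd.DataFrame(index=cx.index)
    for comp in ("E_vdW", "E_elec", "G_PB"):
        out["d" + comp] = cx[comp] - pr[comp] - inh[comp]
    np_each = {s: nonpolar_term(wide[s]["SASA"].to_numpy(), gamma, beta) for s in SPECIES}
    out["dG_NP"] = np_each["complex"] - np_each["protein"] - np_each["inhibitor"]
    return out


@dataclass
class EnergySummary:
    """Mean +- SEM of every MM-PBSA row, satisfying the sum identities exactly.

    ``entropy_term`` is the entropy penalty -T dS in kcal/mol (positive for
    unfavorable entropy), so ``dG = dH + entropy_term``.
    """

    dE_vdW: Measured
    dE_elec: Measured
    dE_MM_gas: Measured
    dG_PB: Measured
    dG_elec_tot: Measured
    dG_NP: Measured
    dG_solv: Measured
    dH: Measured
    entropy_term: Measured
    dG: Measured
    n_frames: int = 0
    sem_mode: str = "quadrature"

    def as_dict(self) -> dict:
        rows = {}
        for name in ("dE_vdW", "dE_elec", "dE_MM_gas", "dG_PB", "dG_elec_tot",
                     "dG_NP", "dG_solv", "dH", "entropy_term", "dG"):
            m: Measured = getattr(self, name)
            rows[name] = {"value": m.value, "sem": m.sem}
        rows["n_frames"] = self.n_frames
        return rows


def _sem(series: np.ndarray) -> float:
    return float(np.std(series, ddof=1) / np.sqrt(len(series)))


def summarize(deltas: pd.DataFrame, entropy_term: float, entropy_sem: float = 0.0,
              sem_mode: str = "quadrature") -> EnergySummary:
    """Aggregate per-frame deltas into the MM-PBSA summary table.

    Parameters
    ----------
    deltas : DataFrame
        Output of :func:`frame_deltas` (columns dE_vdW, dE_elec, dG_PB, dG_NP).
    entropy_term : float
        The entropy penalty -T dS in kcal/mol (a given, e.g. from
        normal-mode analysis).
    entropy_sem : float
        Its standard error.
    sem_mode : {'quadrature', 'entropy_only'}
        How the dG standard error combines the dH and entropy SEMs:
        independent-error quadrature (default) or the entropy SEM alone.

    Component SEMs are sd/sqrt(n_frames) of the per-frame series; derived
    rows (dE_MM_gas, dG_solv, dH, dG_elec_tot) are summed per frame first,
    so their means satisfy the sum identities exactly.
    """
    if len(deltas) < 2:
        raise ValueError("need at least 2 frames for a standard error")
    if sem_mode not in ("quadrature", "entropy_only"):
        raise ValueError(f"unknown sem_mode {sem_mode!r}")
    series = {
        "dE_vdW": deltas["dE_vdW"].to_numpy(),
        "dE_elec": deltas["dE_elec"].to_numpy(),
        "dG_PB": deltas["dG_PB"].to_numpy(),
        "dG_NP": deltas["dG_NP"].to_numpy(),
    }
    series["dE_MM_gas"] = series["dE_vdW"] + series["dE_elec"]
    series["dG_solv"] = series["dG_PB"] + series["dG_NP"]
    series["dG_elec_tot"] = series["dE_elec"] + series["dG_PB"]
    series["dH"] = series["dE_MM_gas"] + series["dG_solv"]
    m = {k: Measured(float(v.mean()), _sem(v)) for k, v in series.items()}
    dh = m["dH"]
    dg_val = dh.value + entropy_term
    dg_sem = (np.hypot(dh.sem, entropy_sem) if sem_mode == "quadrature" else entropy_sem)
    return EnergySummary(
        dE_vdW=m["dE_vdW"], dE_elec=m["dE_elec"], dE_MM_gas=m["dE_MM_gas"],
        dG_PB=m["dG_PB"], dG_elec_tot=m["dG_elec_tot"], dG_NP=m["dG_NP"],
        dG_solv=m["dG_solv"], dH=dh,
        entropy_term=Measured(float(entropy_term), float(entropy_sem)),
        dG=Measured(float(dg_val), float(dg_sem)),
        n_frames=len(deltas), sem_mode=sem_mode,
    )


def summary_from_means(dE_vdW: float, dE_elec: float, dG_PB: float, dG_NP: float,
                       entropy_term: float, dG_solv: float | None = None) -> EnergySummary:
    """Assemble the summary directly from component *means* (no SEMs).

    Useful for checking a printed summary table: the derived rows are
    recomputed from the component means via the sum identities.  ``dG_solv``
    may be overridden to audit a table whose printed dG_solv disagrees with
    dG_PB + dG_NP (the downstream rows then follow the printed value).
    """
    dE_MM = dE_vdW + dE_elec
    solv = dG_PB + dG_NP if dG_solv is None else dG_solv
    dH = dE_MM + solv
    z = lambda v: Measured(float(v), 0.0)
    return EnergySummary(
        dE_vdW=z(dE_vdW), dE_elec=z(dE_elec), dE_MM_gas=z(dE_MM),
        dG_PB=z(dG_PB), dG_elec_tot=z(dE_elec + dG_PB), dG_NP=z(dG_NP),
        dG_solv=z(solv), dH=z(dH), entropy_term=z(entropy_term),
        dG=z(dH + entropy_term), n_frames=0,
    )


# ---------------------------------------------------------------------------
# trajectory geometry


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition (distance in A, angle in degrees)."""

    distance_cutoff: float = 3.5
    angle_cutoff: float = 120.0

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(coords, donors, acceptors,
                  crit: HBondCriterion = HBondCriterion()) -> list[HBond]:
    """Detect hydrogen bonds in one frame of coordinates.

    Parameters
    ----------
    coords : array of shape (n_atoms, 3), Angstrom
    donors : sequence of (donor_index, hydrogen_index) pairs
    acceptors : sequence of acceptor atom indices

    An event requires donor-acceptor distance <= ``crit.distance_cutoff``
    AND donor-hydrogen-acceptor angle >= ``crit.angle_cutoff``.
    """
    coords = np.asarray(coords, dtype=float)
    events = []
    for d_idx, h_idx in donors:
        if h_idx is None or h_idx < 0 or h_idx >= len(coords):
            raise ValueError(f"donor {d_idx} has no valid hydrogen atom")
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            # 1e-9 guards keep geometries exactly at a cutoff on the
            # inclusive side despite floating-point round-off
            if dist > crit.distance_cutoff + 1e-9:
                continue
            ang = _angle_deg(coords[d_idx], coords[h_idx], coords[a_idx])
            if ang >= crit.angle_cutoff - 1e-9:
                events.append(HBond(d_idx, h_idx, a_idx, dist, ang))
    return events


def min_contact_distance(frames, group_a, target_atom: int) -> tuple[float, float]:
    """Mean +- sd (over frames) of the minimum group-to-atom distance.

    For each frame the minimum Euclidean distance from any atom in
    ``group_a`` to ``target_atom`` is taken; the per-frame minima are then
    averaged (population sd, so a single frame reports sd 0).
    """
    group_a = list(group_a)
    if not group_a:
        raise ValueError("empty atom group")
    mins = []
    for frame in frames:
        frame = np.asarray(frame, dtype=float)
        d = np.linalg.norm(frame[group_a] - frame[target_atom], axis=1)
        mins.append(float(d.min()))
    mins = np.asarray(mins)
    return float(mins.mean()), float(mins.std())
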