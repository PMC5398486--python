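"""Synthetic data generators with known ground truth for every pipeline stage.

Real inputs to this pipeline — a few-thousand-compound HTS descriptor matrix,
MM-PBSA per-frame component tables, fluorescence titrations, trajectory
snapshots — are large, licensed, or produced by software outside this
package's scope.  These generators emulate each one at desk scale and emit
the planted truth alongside, so the whole pipeline is testable end to end.

The standing classification benchmark (``DEFAULT_SPEC``) emulates a labeled
descriptor matrix with cluster structure, class-informative columns,
redundant (duplicated) columns and label noise: n=600 compounds, p=120
descriptors, 10 informative + 10 redundant, 5 clusters, 46% actives, 10%
label noise, seed 42.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingCurve, quadratic_isotherm
from .descriptors import DescriptorMatrix
from .mmpbsa import BETA_DEFAULT, GAMMA_DEFAULT, FrameEnergyTable

__all__ = [
    "SyntheticSpec",
    "DEFAULT_SPEC",
    "make_classification_set",
    "make_energy_frames",
    "energy_frames_for_deltas",
    "make_binding_curves",
    "make_hb_frame",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic labeled descriptor matrix.

    ``separation`` is the class effect size in within-cluster standard
    deviations added to each informative column for actives; 3.0 is a
    strongly separated planted signal, appropriate for a benchmark whose
    point is to test the pipeline machinery rather than the limits of the
    classifiers.
    """

    n_compounds: int = 600
    n_descriptors: int = 120
    n_informative: int = 10
    n_redundant: int = 10
    n_clusters: int = 5
    class_balance: float = 0.46
    separation: float = 3.0
    label_noise: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if min(self.n_compounds, self.n_descriptors, self.n_informative,
               self.n_redundant, self.n_clusters) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_descriptors:
            raise ValueError("informative + redundant exceeds descriptor count")
        if not 0 <= self.class_balance <= 1 or not 0 <= self.label_noise <= 1:
            raise ValueError("class_balance and label_noise must be in [0, 1]")


DEFAULT_SPEC = SyntheticSpec()


def make_classification_set(spec: SyntheticSpec = DEFAULT_SPEC
                            ) -> tuple[DescriptorMatrix, pd.Series, dict]:
    """Generate (descriptor matrix, observed labels, ground truth).

    Compounds fall into ``n_clusters`` Gaussian clusters (centers sd 2,
    within-cluster sd 1 per column).  Active compounds (an exact
    ``round(class_balance * n)`` of them) are shifted by ``separation`` on
    each informative column; redundant columns are informative columns plus
    N(0, 0.1) noise; the rest carry only cluster structure.  Observed labels
    flip independently with probability ``label_noise``.

    ``ground_truth`` records informative/redundant column names, true
    cluster ids and the noise-free labels.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    ids = [f"cmpd{i + 1:04d}" for i in range(n)]
    names = [f"d{j + 1:03d}" for j in range(p)]

    centers = rng.normal(0.0, 2.0, size=(spec.n_clusters, p))
    cluster = rng.integers(0, spec.n_clusters, size=n)
    X = centers[cluster] + rng.normal(0.0, 1.0, size=(n, p))

    n_active = int(round(spec.class_balance * n))
    true_active = np.zeros(n, dtype=bool)
    true_active[rng.permutation(n)[:n_active]] = True

    informative = list(range(spec.n_informative))
    redundant = list(range(spec.n_informative, spec.n_informative + spec.n_redundant))
    X[np.ix_(true_active, informative)] += spec.separation
    for r_pos, r_col in enumerate(redundant):
        src = informative[r_pos % max(len(informative), 1)] if informative else 0
        X[:, r_col] = X[:, src] + rng.normal(0.0, 0.1, size=n)

    flips = rng.random(n) < spec.label_noise
    observed = true_active ^ flips
    labels = pd.Series(np.where(observed, "active", "inactive"), index=ids, name="label")

    D = DescriptorMatrix(values=pd.DataFrame(X, index=ids, columns=names))
    ground_truth = {
        "informative": [names[j] for j in informative],
        "redundant": [names[j] for j in redundant],
        "cluster": pd.Series(cluster, index=ids),
        "true_labels": pd.Series(np.where(true_active, "active", "inactive"), index=ids),
        "flipped": pd.Series(flips, index=ids),
    }
    return D, labels, ground_truth


def make_energy_frames(n_frames: int, means: dict, sds: dict, seed: int = 0
                       ) -> FrameEnergyTable:
    """I.i.d. Gaussian per-frame energy components for the three species.

    ``means`` and ``sds`` map species -> {E_vdW, E_elec, G_PB, SASA}.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for species in ("complex", "protein", "inhibitor"):
        m, s = means[species], sds[species]
        block = pd.DataFrame({
            "frame": np.arange(n_frames),
            "species": species,
        })
        for comp in ("E_vdW", "E_elec", "G_PB", "SASA"):
            block[comp] = rng.normal(m[comp], s[comp], size=n_frames)
        if (block["SASA"] < 0).any():
            block["SASA"] = block["SASA"].clip(lower=0.0)
        rows.append(block)
    return FrameEnergyTable(pd.concat(rows, ignore_index=True))


def energy_frames_for_deltas(delta_means: dict, delta_sds: dict, n_frames: int,
                             seed: int = 0) -> FrameEnergyTable:
    """Frames whose per-frame deltas center on the requested component means.

    ``delta_means``/``delta_sds`` have keys dE_vdW, dE_elec, dG_PB, dG_NP.
    Protein and inhibitor get fixed baseline components; the complex absorbs
    the delta and all the frame-to-frame variance.  The nonpolar delta is
    realized through SASA: dSASA = (dG_NP + beta) / gamma.
    """
    base_p = {"E_vdW": -800.0, "E_elec": -5000.0, "G_PB": -2500.0, "SASA": 9000.0}
    base_i = {"E_vdW": -30.0, "E_elec": -80.0, "G_PB": -40.0, "SASA": 700.0}
    d_sasa = (delta_means["dG_NP"] + BETA_DEFAULT) / GAMMA_DEFAULT
    sd_sasa = delta_sds.get("dG_NP", 0.0) / GAMMA_DEFAULT
    means = {
        "protein": base_p,
        "inhibitor": base_i,
        "complex": {
            "E_vdW": base_p["E_vdW"] + base_i["E_vdW"] + delta_means["dE_vdW"],
            "E_elec": base_p["E_elec"] + base_i["E_elec"] + delta_means["dE_elec"],
            "G_PB": base_p["G_PB"] + base_i["G_PB"] + delta_means["dG_PB"],
            "SASA": base_p["SASA"] + base_i["SASA"] + d_sasa,
        },
    }
    zero = {c: 0.0 for c in ("E_vdW", "E_elec", "G_PB", "SASA")}
    sds = {
        "protein": zero, "inhibitor": zero,
        "complex": {
            "E_vdW": delta_sds.get("dE_vdW", 0.0),
            "E_elec": delta_sds.get("dE_elec", 0.0),
            "G_PB": delta_sds.get("dG_PB", 0.0),
            "SASA": sd_sasa,
        },
    }
    return make_energy_frames(n_frames, means, sds, seed=seed)


def make_binding_curves(Kd: float, P0: float, L_grid, dF_max: float = 100.0,
                        noise: float = 0.0, n_replicates: int = 1, seed: int = 0
                        ) -> list[BindingCurve]:
    """Titration replicates from the quadratic isotherm, with multiplicative
    Gaussian noise of relative sd ``noise``."""
    rng = np.random.default_rng(seed)
    L = np.asarray(L_grid, dtype=float)
    curves = []
    for rep in range(n_replicates):
        ideal = quadratic_isotherm(L, P0, Kd, dF_max)
        jitter = 1.0 + noise * rng.standard_normal(len(L)) if noise > 0 else 1.0
        curves.append(BindingCurve(P0=P0, L=L, dF=ideal * jitter, replicate=rep))
    return curves


def make_hb_frame(d_DA: float, angle_deg: float, dh_bond: float = 1.0,
                  rigid_seed: int | None = None) -> tuple[np.ndarray, list, list]:
    """A 3-atom frame (donor, hydrogen, acceptor) with requested geometry.

    The donor sits at the origin, the hydrogen ``dh_bond`` A along x, and the
    acceptor is placed so that dist(D, A) = ``d_DA`` and the D-H-A angle is
    ``angle_deg``.  With ``rigid_seed`` the frame is additionally subjected
    to a random rigid rotation + translation (hydrogen-bond detection must
    be invariant to it).

    Returns ``(coords, donors, acceptors)`` ready for ``detect_hbonds``.
    """
    theta = np.radians(angle_deg)
    s = np.sin(theta)
    if d_DA < dh_bond * abs(s):
        raise ValueError("requested geometry is unrealizable")
    r = dh_bond * np.cos(theta) + np.sqrt(d_DA ** 2 - (dh_bond * s) ** 2)
    D = np.array([0.0, 0.0, 0.0])
    H = np.array([dh_bond, 0.0, 0.0])
    A = H + r * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords = np.vstack([D, H, A])
    if rigid_seed is not None:
        rng = np.random.default_rng(rigid_seed)
        M = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(M)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        coords = coords @ Q.T + rng.uniform(-20, 20, size=3)
    return coords, [(0, 1)], [2]
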