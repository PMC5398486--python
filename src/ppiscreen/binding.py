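"""Binding-assay curve fitting: quadratic Kd isotherm, Scatchard, 4PL.

Fluorescence titrations at fixed protein concentration P0 (comparable to the
Kd, so ligand depletion matters) are fitted with the single-site quadratic
("tight-binding", Morrison) isotherm

.. math::

    \\Delta F(L) = \\Delta F_{max}
        \\frac{(P_0 + L + K_d) - \\sqrt{(P_0 + L + K_d)^2 - 4 P_0 L}}{2 P_0}

Scatchard linearization (bound/free vs bound) provides the binding-site
stoichiometry n from the x-intercept, and a four-parameter logistic handles
sigmoidal dose-response data (IC50 for inhibition, LC50 for viability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BindingCurve",
    "KdFit",
    "ScatchardResult",
    "DoseResponseFit",
    "quadratic_isotherm",
    "fit_quadratic_binding",
    "fit_replicate_curves",
    "scatchard",
    "logistic4",
    "fit_dose_response",
]


@dataclass
class BindingCurve:
    """One titration: ligand concentrations (uM) and fluorescence changes."""

    P0: float                      # protein concentration, uM
    L: np.ndarray                  # ligand concentrations, uM, ascending
    dF: np.ndarray                 # fluorescence change, arbitrary units
    replicate: int = 0

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.dF = np.asarray(self.dF, dtype=float)
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        if len(self.L) != len(self.dF) or len(self.L) < 4:
            raise ValueError("need matched L/dF arrays of length >= 4")
        if np.any(self.L < 0):
            raise ValueError("ligand concentrations must be non-negative")


@dataclass
class KdFit:
    """Fitted dissociation constant with diagnostics."""

    Kd: float                      # uM
    dF_max: float
    residual_norm: float
    Kd_sem: float | None = None
    n_sites: float | None = None
    per_replicate: list[float] = field(default_factory=list)


def quadratic_isotherm(L, P0: float, Kd: float, dF_max: float):
    """Model fluorescence change at ligand concentration(s) L.

    Real for all physical inputs (the discriminant (P0+L+Kd)^2 - 4 P0 L
    equals (P0 - L + Kd)^2 + 4 L Kd >= 0) and bounded by dF_max.
    """
    L = np.asarray(L, dtype=float)
    s = P0 + L + Kd
    disc = s * s - 4.0 * P0 * L
    return dF_max * (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P0)


def fit_quadratic_binding(curve: BindingCurve) -> KdFit:
    """Least-squares fit of the quadratic isotherm to one titration.

    Trust-region-reflective least squares with positivity bounds;
    initialization Kd = median(L), dF_max = max(dF).
    """

    def resid(theta):
        kd, dfmax = theta
        return quadratic_isotherm(curve.L, curve.P0, kd, dfmax) - curve.dF

    x0 = [max(float(np.median(curve.L)), 1e-6), max(float(curve.dF.max()), 1e-6)]
    sol = optimize.least_squares(resid, x0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                 method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(
            f"Kd fit did not converge: {sol.message}; last theta={sol.x}, "
            f"residual={np.linalg.norm(sol.fun):.3g}")
    kd, dfmax = sol.x
    return KdFit(Kd=float(kd), dF_max=float(dfmax),
                 residual_norm=float(np.linalg.norm(sol.fun)))


def fit_replicate_curves(curves: list[BindingCurve]) -> KdFit:
    """Fit each replicate independently; report mean +- SEM across replicates."""
    fits = [fit_quadratic_binding(c) for c in curves]
    kds = np.array([f.Kd for f in fits])
    sem = float(kds.std(ddof=1) / np.sqrt(len(kds))) if len(kds) > 1 else None
    return KdFit(Kd=float(kds.mean()),
                 dF_max=float(np.mean([f.dF_max for f in fits])),
                 residual_norm=float(np.mean([f.residual_norm for f in fits])),
                 Kd_sem=sem, per_replicate=[float(k) for k in kds])


@dataclass
class ScatchardResult:
    slope: float            # -1/Kd, uM^-1
    intercept: float
    n_sites: float          # x-intercept / P0
    r_squared: float
    n_points_used: int


def scatchard(curve: BindingCurve, fit: KdFit) -> ScatchardResult:
    """Scatchard analysis: regress bound/free on bound.

    Bound ligand is dF/dF_max * P0; free is L - bound.  Points with free or
    bound <= 0 carry no information on the ratio and are excluded with a
    warning.  For one-site data the slope is -1/Kd and the x-intercept gives
    n * P0, so ``n_sites`` estimates the binding stoichiometry.
    """
    bound = curve.dF / fit.dF_max * curve.P0
    free = curve.L - bound
    ok = (free > 0) & (bound > 0)
    if not ok.all():
        warnings.warn(f"excluded {int((~ok).sum())} Scatchard point(s) with "
                      "non-positive bound or free concentration")
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable Scatchard points")
    x = bound[ok]
    y = bound[ok] / free[ok]
    reg = stats.linregress(x, y)
    x_intercept = -reg.intercept / reg.slope
    return ScatchardResult(slope=float(reg.slope), intercept=float(reg.intercept),
                           n_sites=float(x_intercept / curve.P0),
                           r_squared=float(reg.rvalue ** 2), n_points_used=int(ok.sum()))


def logistic4(x, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic; y(ec50) is the asymptote midpoint."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


@dataclass
class DoseResponseFit:
    ec50: float             # uM; reported as IC50 or LC50 per direction
    hill: float
    top: float
    bottom: float
    direction: str
    residual_norm: float

    @property
    def label(self) -> str:
        return {"inhibition": "IC50", "viability": "LC50"}[self.direction]


def fit_dose_response(conc, response, direction: str = "inhibition") -> DoseResponseFit:
    """Fit a 4PL curve to percent responses at positive concentrations (uM).

    Needs >= 5 concentrations.  Constant responses are rejected (no signal to
    place an EC50); non-monotone data beyond noise draws a warning but the
    fit is still attempted.
    """
    if direction not in ("inhibition", "viability"):
        raise ValueError(f"unknown direction {direction!r}")
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(conc) < 5:
        raise ValueError("need at least 5 concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.ptp(response) < 1e-9:
        raise ValueError("constant response: no EC50 is defined")
    rho = stats.spearmanr(conc, response).statistic
    if abs(rho) < 0.5:
        warnings.warn("dose-response data look non-monotone; fitting anyway")

    lo, hi = float(response.min()), float(response.max())
    rising = rho >= 0

    def resid(theta):
        return logistic4(conc, *theta) - response

    x0 = [lo, hi, float(np.exp(np.mean(np.log(conc)))), -1.0 if rising else 1.0]
    sol = optimize.least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                 bounds=([-np.inf, -np.inf, 1e-9, -np.inf],
                                         [np.inf, np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"dose-response fit failed: {sol.message}")
    bottom, top, ec50, hill = sol.x
    return DoseResponseFit(ec50=float(ec50), hill=float(hill), top=float(top),
                           bottom=float(bottom), direction=direction,
                           residual_norm=float(np.linalg.norm(sol.fun)))
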