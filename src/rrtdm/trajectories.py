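"""From fitted covariance components to the reported genetic parameters.

A coefficient covariance matrix K induces a covariance function over the
lactation, σ(t₁,t₂) = φ(t₁)' K φ(t₂).  This module evaluates the additive,
permanent-environment and residual variance trajectories, heritability and
repeatability by DIM, and genetic/phenotypic correlation surfaces on a DIM
grid.  Residuals are independent across test days, so they contribute only
to same-day phenotypic variance, never to between-day covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSpec, legendre_matrix
from .tdm_data import assign_residual_class, residual_class_bins

#: DIM grid used for reporting correlation surfaces
DEFAULT_GRID = (35, 65, 95, 125, 155, 185, 215, 245, 275, 305)

#: representative DIM of each residual class used for per-bin reporting
BIN_MIDPOINTS = tuple(20 + 30 * i for i in range(10))


def variance_at(t, M: np.ndarray, spec: BasisSpec):
    """σ²(t) = φ(t)' M φ(t) for one DIM or a vector of DIMs."""
    Phi = legendre_matrix(np.atleast_1d(t), spec)
    out = np.einsum("ri,ij,rj->r", Phi, np.asarray(M, dtype=float), Phi)
    return out if np.ndim(t) else float(out[0])


def heritability_at(sigma2_a: float, sigma2_pe: float, sigma2_e: float) -> float:
    """h² = σ²a / (σ²a + σ²pe + σ²e)."""
    total = sigma2_a + sigma2_pe + sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    if min(sigma2_a, sigma2_pe, sigma2_e) < 0:
        raise ValueError("variances must be nonnegative")
    return sigma2_a / total


def repeatability_at(sigma2_a: float, sigma2_pe: float, sigma2_e: float) -> float:
    """r = (σ²a + σ²pe) / (σ²a + σ²pe + σ²e); upper bound for h²."""
    total = sigma2_a + sigma2_pe + sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return (sigma2_a + sigma2_pe) / total


def trajectory_table(vc, spec_a: BasisSpec, spec_pe: BasisSpec | None = None,
                     dims=BIN_MIDPOINTS) -> pd.DataFrame:
    """Variance components, h² and repeatability evaluated at the given DIMs
    (default: the residual-class midpoints 20, 50, …, 290)."""
    dims = np.asarray(dims)
    s2a = variance_at(dims, vc.K_a, spec_a)
    if vc.kpe:
        s2pe = variance_at(dims, vc.K_pe, spec_pe or BasisSpec(vc.kpe, spec_a.scale, spec_a.normalized))
    else:
        s2pe = np.zeros_like(s2a)
    cls = np.asarray(assign_residual_class(dims))
    s2e = vc.sigma2_e[cls - 1]
    tot = s2a + s2pe + s2e
    bins = residual_class_bins()
    return pd.DataFrame(
        {
            "dim": dims,
            "dim_bin": [f"{bins[c - 1][0]}-{bins[c - 1][1]}" for c in cls],
            "sigma2_a": s2a,
            "sigma2_pe": s2pe,
            "sigma2_e": s2e,
            "h2": s2a / tot,
            "repeatability": (s2a + s2pe) / tot,
        }
    )


@dataclass
class CorrelationSurface:
    grid: np.ndarray
    genetic: np.ndarray
    phenotypic: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Combined layout: genetic below the diagonal, phenotypic above."""
        m = np.where(
            np.tri(len(self.grid), k=-1, dtype=bool), self.genetic, self.phenotypic
        )
        np.fill_diagonal(m, 1.0)
        labels = [str(int(t)) for t in self.grid]
        return pd.DataFrame(m, index=labels, columns=labels)


def correlation_surface(vc, spec_a: BasisSpec, spec_pe: BasisSpec | None = None,
                        grid=DEFAULT_GRID) -> CorrelationSurface:
    """Genetic and phenotypic correlations between yields at the grid DIMs.

    Phenotypic between-day covariance = additive + permanent-environment
    covariance; residual variance enters the same-day denominators only.
    """
    grid = np.asarray(grid, dtype=float)
    Phi_a = legendre_matrix(grid, spec_a)
    C_a = Phi_a @ vc.K_a @ Phi_a.T
    if vc.kpe:
        sp = spec_pe or BasisSpec(vc.kpe, spec_a.scale, spec_a.normalized)
        Phi_p = legendre_matrix(grid, sp)
        C_pe = Phi_p @ vc.K_pe @ Phi_p.T
    else:
        C_pe = np.zeros_like(C_a)
    cls = np.asarray(assign_residual_class(grid))
    C_ph = C_a + C_pe + np.diag(vc.sigma2_e[cls - 1])
    va, vp = np.diag(C_a), np.diag(C_ph)
    if np.any(va <= 0) or np.any(vp <= 0):
        bad = grid[(va <= 0) | (vp <= 0)]
        raise ValueError(f"zero variance at grid DIM(s) {bad}")
    rg = C_a / np.sqrt(np.outer(va, va))
    rp = C_ph / np.sqrt(np.outer(vp, vp))
    np.fill_diagonal(rg, 1.0)
    np.fill_diagonal(rp, 1.0)
    return CorrelationSurface(grid=grid, genetic=rg, phenotypic=rp)


def lactation_summary(vc, spec_a: BasisSpec, spec_pe: BasisSpec | None = None) -> dict:
    """Whole-lactation summary (method: daily-mean): unweighted means of the
    daily h² and repeatability over DIM 5–305.  A reporting convention of
    this package — not comparable to any particular published 'overall'
    value without knowing how that value averaged the trajectory."""
    dims = np.arange(int(spec_a.scale.t_min), int(spec_a.scale.t_max) + 1)
    tab = trajectory_table(vc, spec_a, spec_pe, dims=dims)
    return {
        "method": "daily-mean",
        "h2": float(tab["h2"].mean()),
        "repeatability": float(tab["repeatability"].mean()),
    }
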