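"""Legendre-polynomial basis over the lactation trajectory.

Days in milk (DIM) are mapped linearly onto [−1, 1] and the random
regressions are carried by Legendre polynomials of that standardized time.
By default the basis is orthonormalized, φ_n(x) = √((2n+1)/2)·P_n(x),
the usual convention for covariance functions in test-day models; the plain
P_n alternative is kept behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg


@dataclass(frozen=True)
class DimScale:
    """DIM support of the model, default the retained window 5–305 d."""

    t_min: float = 5.0
    t_max: float = 305.0

    def __post_init__(self):
        if not (self.t_min < self.t_max):
            raise ValueError("t_min must be < t_max")
        if not (1 <= self.t_min <= 400 and 1 <= self.t_max <= 400):
            raise ValueError("DIM scale endpoints must lie in [1, 400]")


@dataclass(frozen=True)
class BasisSpec:
    """order = number of coefficients k (polynomial degrees 0..k−1)."""

    order: int
    scale: DimScale = field(default_factory=DimScale)
    normalized: bool = True

    def __post_init__(self):
        if not (1 <= self.order <= 10):
            raise ValueError("basis order must be in 1..10")


def standardize_dim(t, scale: DimScale) -> np.ndarray | float:
    """Map t in [t_min, t_max] onto [−1, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < scale.t_min) or np.any(t > scale.t_max):
        raise ValueError(
            f"DIM outside [{scale.t_min}, {scale.t_max}]: "
            f"{np.atleast_1d(t)[(np.atleast_1d(t) < scale.t_min) | (np.atleast_1d(t) > scale.t_max)][:5]}"
        )
    x = 2.0 * (t - scale.t_min) / (scale.t_max - scale.t_min) - 1.0
    return x if x.ndim else float(x)


def norm_constants(order: int) -> np.ndarray:
    """√((2n+1)/2) for n = 0..order−1."""
    n = np.arange(order)
    return np.sqrt((2 * n + 1) / 2.0)


def legendre_matrix(t, spec: BasisSpec) -> np.ndarray:
    """Rows φ_0..φ_{k−1} evaluated at each t (shape (len(t), order))."""
    x = np.atleast_1d(standardize_dim(t, spec.scale))
    V = npleg.legvander(x, spec.order - 1)
    if spec.normalized:
        V = V * norm_constants(spec.order)
    return V


def legendre_row(t: float, spec: BasisSpec) -> np.ndarray:
    """Basis row at a single DIM."""
    return legendre_matrix([t], spec)[0]
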