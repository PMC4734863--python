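"""BIC-based choice of the Legendre orders (ka, kpe).

Candidate models differ only in the orders of the additive and
permanent-environment random regressions; BIC = −2l + K·log n ranks them.
Two parameter-counting rules are provided:

``true_count``
    free covariance parameters actually estimated:
    ka(ka+1)/2 + kpe(kpe+1)/2 + n residual classes (the package default).
``paper_compat``
    n_classes + 3·(ka+kpe), the rule back-derived from a published
    Iranian-Holstein milking-frequency analysis whose printed tables this
    package can reproduce; it does not count the free elements of
    unstructured K matrices and is flagged as nonstandard.

The published tables are likewise consistent with base-10 logs in the BIC
penalty, so base 10 is the reporting default; standard natural-log BIC is
available via ``base="e"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .mme import ModelSpec, build_design
from .reml import RemlOptions, fit_reml

DEFAULT_GRID = tuple(
    (ka, kpe) for ka in range(1, 6) for kpe in range(1, ka + 1)
)


def count_parameters(ka: int, kpe: int, n_classes: int = 10,
                     mode: str = "true_count") -> int:
    """Number of estimated (co)variance parameters K for the BIC penalty."""
    if mode == "true_count":
        return ka * (ka + 1) // 2 + kpe * (kpe + 1) // 2 + n_classes
    if mode == "paper_compat":
        return n_classes + 3 * (ka + kpe)
    raise ValueError(f"unknown parameter-count mode {mode!r}")


def bic(l: float, K: int, n: int, base: str | int = 10) -> float:
    """Schwarz criterion −2l + K·log n, log base 10 or e."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if base in (10, "10"):
        logn = math.log10(n)
    elif base in ("e", math.e):
        logn = math.log(n)
    else:
        raise ValueError("base must be 10 or 'e'")
    return -2.0 * l + K * logn


@dataclass
class GridOptions:
    base: str | int = 10
    count_mode: str = "true_count"
    reml: RemlOptions = field(default_factory=RemlOptions)
    template: ModelSpec | None = None   # fixed-part settings shared by all fits


def grid_select(records: pd.DataFrame, ped, grid=None,
                opts: GridOptions | None = None):
    """Fit every (ka, kpe) in the grid and rank by BIC.

    Returns (table, best_spec).  Rows are ordered by (ka, kpe) as in the
    published tables; non-converged fits stay in the table, flagged, and
    are excluded from the argmin.  Ties break toward smaller K, then
    smaller ka.
    """
    opts = opts or GridOptions()
    grid = sorted(set(DEFAULT_GRID if grid is None else grid))
    if not grid:
        raise ValueError("empty model grid")
    template = opts.template or ModelSpec(ka=1, kpe=1)
    n = len(records)
    rows = []
    fits = {}
    for ka, kpe in grid:
        if not (1 <= kpe <= ka):
            raise ValueError(f"grid entry ({ka}, {kpe}) violates 1 <= kpe <= ka")
        spec = replace(template, ka=ka, kpe=kpe)
        design = build_design(records, spec, ped)
        fit = fit_reml(design, opts=opts.reml)
        K = count_parameters(ka, kpe, spec.n_residual_classes, opts.count_mode)
        rows.append(
            dict(ka=ka, kpe=kpe, K=K, loglik=fit.loglik,
                 bic=bic(fit.loglik, K, n, opts.base), converged=fit.converged)
        )
        fits[(ka, kpe)] = (spec, fit)
    table = pd.DataFrame(rows)
    best_spec, best_fit = fits[select_best(table)]
    table["selected"] = (table["ka"] == best_spec.ka) & (table["kpe"] == best_spec.kpe)
    return table, best_spec, best_fit


def select_best(table: pd.DataFrame) -> tuple[int, int]:
    """Argmin-BIC (ka, kpe) among converged rows; ties break toward
    smaller K, then smaller ka."""
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no converged fit in the model grid")
    row = ok.sort_values(["bic", "K", "ka"]).iloc[0]
    return int(row["ka"]), int(row["kpe"])
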