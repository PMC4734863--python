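"""Design matrices and Henderson's mixed-model equations (MME).

The model for a test-day yield is

    y = HTD + Σ_n b_n·age^n + Σ_n c_n·dim^n + Σ_n α_n φ_n(dim) + Σ_n γ_n φ_n(dim) + e

with herd-test-date (HTD) contemporary groups and fixed age/DIM regressions
as fixed effects, per-animal additive regression coefficients α (covariance
A ⊗ K_a over animals) and per-cow permanent-environment coefficients γ
(I ⊗ K_pe), and residuals heteroskedastic over ten 30-day DIM classes.

HTD incidence carries the intercept (the model has no global mean), so the
fixed block is full rank without dropping a level.  Fixed-regression
covariates are standardized to [−1, 1] before raising to powers; raw powers
are available behind ``raw_fixed_powers`` for literal fidelity but are
numerically hostile.

Solving strategy: the permanent-environment equations are block-diagonal
per cow, so they are absorbed into a dense Schur complement over
[fixed | additive].  That factorization also yields, cheaply, the pieces of
the inverse coefficient matrix that REML needs (additive block, per-cow PE
blocks, per-record quadratic forms).  A full sparse assembly is retained
for oracle tests and export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse

from .basis import BasisSpec, DimScale, legendre_matrix
from .pedigree import Pedigree, a_inverse, log_det_a
from .tdm_data import N_RESIDUAL_CLASSES, assign_residual_class


@dataclass(frozen=True)
class ModelSpec:
    """Orders of the random regressions and the fixed part of the model.

    ka/kpe are numbers of coefficients (k coefficients = degrees 0..k−1);
    kpe = 0 drops the permanent-environment term entirely.
    """

    ka: int
    kpe: int
    age_fixed_order: int = 3
    dim_fixed_order: int = 3
    n_residual_classes: int = N_RESIDUAL_CLASSES
    scale: DimScale = field(default_factory=DimScale)
    normalized: bool = True
    use_inbreeding: bool = True
    raw_fixed_powers: bool = False

    def __post_init__(self):
        if self.ka < 1:
            raise ValueError("ka must be >= 1")
        if self.kpe < 0:
            raise ValueError("kpe must be >= 0")
        if not (0 <= self.age_fixed_order <= 5 and 0 <= self.dim_fixed_order <= 5):
            raise ValueError("fixed regression orders must be in 0..5")

    @property
    def basis_a(self) -> BasisSpec:
        return BasisSpec(self.ka, self.scale, self.normalized)

    @property
    def basis_pe(self) -> BasisSpec:
        return BasisSpec(self.kpe, self.scale, self.normalized) if self.kpe else None


class DesignError(ValueError):
    pass


@dataclass
class Design:
    """Prepared matrices for one parity × frequency analysis group."""

    spec: ModelSpec
    ped: Pedigree
    y: np.ndarray
    X: sparse.csr_matrix
    fixed_names: list[str]
    n_htd: int
    htd_levels: list
    phi_a: np.ndarray
    rec_animal: np.ndarray
    phi_pe: np.ndarray | None
    rec_cow: np.ndarray
    cows: list[str]
    rclass0: np.ndarray
    a_inv: sparse.csr_matrix
    logdet_a: float

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.ped.n

    @property
    def n_cows(self) -> int:
        return len(self.cows)

    @cached_property
    def Z_a(self) -> sparse.csr_matrix:
        return _coef_incidence(self.phi_a, self.rec_animal, self.q)

    @cached_property
    def Z_pe(self) -> sparse.csr_matrix | None:
        if self.phi_pe is None:
            return None
        return _coef_incidence(self.phi_pe, self.rec_cow, self.n_cows)

    @cached_property
    def a_lu(self):
        """Sparse LU of A⁻¹ (to apply A = (A⁻¹)⁻¹ to score vectors)."""
        return sparse.linalg.splu(sparse.csc_matrix(self.a_inv))

    @cached_property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.rclass0, minlength=self.spec.n_residual_classes)

    def rinv(self, sigma2_e: np.ndarray) -> np.ndarray:
        """Diagonal of R⁻¹ (per-record inverse residual variance)."""
        return 1.0 / np.asarray(sigma2_e)[self.rclass0]


def _coef_incidence(phi: np.ndarray, owner: np.ndarray, n_owner: int) -> sparse.csr_matrix:
    n, k = phi.shape
    rows = np.repeat(np.arange(n), k)
    cols = (owner[:, None] * k + np.arange(k)).ravel()
    return sparse.csr_matrix((phi.ravel(), (rows, cols)), shape=(n, n_owner * k))


def build_design(records: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> Design:
    """Build fixed/random design matrices for edited records.

    Every record's cow must be in the pedigree.  HTD levels are the
    distinct (herd, test_date) pairs within this dataset.
    """
    df = records.reset_index(drop=True)
    missing = sorted(set(df["cow"]) - set(ped.order_index))
    if missing:
        raise DesignError(f"cows absent from pedigree: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
    n = len(df)
    if n == 0:
        raise DesignError("no records")

    y = df["milk"].to_numpy(dtype=float)
    dim = df["dim"].to_numpy(dtype=float)

    # --- fixed block: HTD incidence then age and DIM power regressions
    htd_key = list(zip(df["herd"], df["test_date"]))
    htd_levels = sorted(set(htd_key))
    htd_index = {h: j for j, h in enumerate(htd_levels)}
    htd_col = np.array([htd_index[h] for h in htd_key])
    n_htd = len(htd_levels)
    X_htd = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), htd_col)), shape=(n, n_htd)
    )
    fixed_names = [f"htd:{h}/{d}" for h, d in htd_levels]

    cols = [X_htd]
    age = df["age_months"].to_numpy(dtype=float)
    x_age = age if spec.raw_fixed_powers else _unit_interval(age)
    age_order = spec.age_fixed_order if np.ptp(age) > 0 else 0
    for k in range(1, age_order + 1):
        cols.append(sparse.csr_matrix(x_age[:, None] ** k))
        fixed_names.append(f"age^{k}")
    x_dim = dim if spec.raw_fixed_powers else np.asarray(
        2.0 * (dim - spec.scale.t_min) / (spec.scale.t_max - spec.scale.t_min) - 1.0
    )
    for k in range(1, spec.dim_fixed_order + 1):
        cols.append(sparse.csr_matrix(x_dim[:, None] ** k))
        fixed_names.append(f"dim^{k}")
    X = sparse.hstack(cols, format="csr")

    # --- random blocks
    phi_a = legendre_matrix(dim, spec.basis_a)
    rec_animal = np.array([ped.order_index[c] for c in df["cow"]])
    if spec.kpe:
        phi_pe = legendre_matrix(dim, spec.basis_pe)
    else:
        phi_pe = None
    cows = sorted(set(df["cow"]))
    cow_index = {c: j for j, c in enumerate(cows)}
    rec_cow = np.array([cow_index[c] for c in df["cow"]])

    if spec.n_residual_classes == 1:
        rclass0 = np.zeros(n, dtype=int)
    else:
        rclass0 = np.asarray(assign_residual_class(df["dim"].to_numpy())) - 1

    return Design(
        spec=spec, ped=ped, y=y, X=X, fixed_names=fixed_names,
        n_htd=n_htd, htd_levels=htd_levels,
        phi_a=phi_a, rec_animal=rec_animal,
        phi_pe=phi_pe, rec_cow=rec_cow, cows=cows,
        rclass0=rclass0,
        a_inv=a_inverse(ped, use_inbreeding=spec.use_inbreeding),
        logdet_a=log_det_a(ped, use_inbreeding=spec.use_inbreeding),
    )


def _unit_interval(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return 2.0 * (v - lo) / (hi - lo) - 1.0


# --------------------------------------------------------------------------
# full sparse assembly (oracle/export path)

@dataclass
class MMESystem:
    matrix: sparse.csc_matrix
    rhs: np.ndarray
    block_index: dict[str, slice]


def assemble_full(design: Design, vc, a_inv: sparse.spmatrix | None = None) -> MMESystem:
    """Full sparse symmetric MME coefficient matrix and right-hand side."""
    a_inv = design.a_inv if a_inv is None else a_inv
    spec = design.spec
    rinv = design.rinv(vc.sigma2_e)
    blocks = [design.X, design.Z_a] + ([design.Z_pe] if spec.kpe else [])
    W = sparse.hstack(blocks, format="csr")
    D = sparse.diags(rinv)
    p = design.p
    na = spec.ka * design.q
    Ga_inv = sparse.kron(a_inv, np.linalg.inv(vc.K_a))
    gblocks = [sparse.csr_matrix((p, p)), Ga_inv]
    idx = {"fixed": slice(0, p), "additive": slice(p, p + na)}
    if spec.kpe:
        gblocks.append(sparse.kron(sparse.eye(design.n_cows), np.linalg.inv(vc.K_pe)))
        idx["pe"] = slice(p + na, p + na + spec.kpe * design.n_cows)
    M = (W.T @ D @ W + sparse.block_diag(gblocks)).tocsc()
    rhs = W.T @ (rinv * design.y)
    return MMESystem(matrix=M, rhs=rhs, block_index=idx)


# --------------------------------------------------------------------------
# absorbed factorization

def _block_diag_sparse(blocks: np.ndarray) -> sparse.csr_matrix:
    """Sparse block-diagonal matrix from a (m, k, k) stack."""
    m, k, _ = blocks.shape
    base = np.arange(m)[:, None, None] * k
    rows, cols = np.broadcast_arrays(
        base + np.arange(k)[None, :, None], base + np.arange(k)[None, None, :]
    )
    return sparse.csr_matrix(
        (blocks.ravel(), (rows.ravel(), cols.ravel())), shape=(m * k, m * k)
    )


class SingularFixedBlock(np.linalg.LinAlgError):
    pass


class MMEFactor:
    """Factorized MME for one (design, variance components) pair.

    Permanent-environment equations (block-diagonal per cow) are absorbed;
    the dense Cholesky of the Schur complement over [fixed | additive]
    provides solves, the log-determinant, and the inverse blocks needed by
    EM/AI-REML.
    """

    def __init__(self, design: Design, vc):
        self.design = design
        self.vc = vc
        spec = design.spec
        d = design
        rinv = d.rinv(vc.sigma2_e)
        self.rinv = rinv
        self.Ka_inv = _pd_inverse(vc.K_a, "K_a")
        W1 = sparse.hstack([d.X, d.Z_a], format="csr")
        self.W1 = W1
        self.n1 = W1.shape[1]
        DW1 = W1.multiply(rinv[:, None]).tocsr()
        M11 = (W1.T @ DW1).toarray()
        Ga_inv = sparse.kron(d.a_inv, self.Ka_inv).toarray()
        M11[d.p:, d.p:] += Ga_inv
        self.rhs1 = W1.T @ (rinv * d.y)

        if spec.kpe:
            self.Kpe_inv = _pd_inverse(vc.K_pe, "K_pe")
            kpe = spec.kpe
            m22 = np.zeros((d.n_cows, kpe, kpe))
            np.add.at(
                m22, d.rec_cow,
                rinv[:, None, None] * d.phi_pe[:, :, None] * d.phi_pe[:, None, :],
            )
            m22 += self.Kpe_inv
            self.M22_blocks = m22
            self.M22inv_blocks = np.linalg.inv(m22)
            sign, logdet22 = np.linalg.slogdet(m22)
            if np.any(sign <= 0):
                raise SingularFixedBlock("permanent-environment block not PD")
            self.logdet_M22 = float(logdet22.sum())
            M21 = (d.Z_pe.T @ DW1).tocsr()
            M22inv_sp = _block_diag_sparse(self.M22inv_blocks)
            self.G2 = (M22inv_sp @ M21).tocsr()
            self.M22inv_sp = M22inv_sp
            S = M11 - (M21.T @ self.G2).toarray()
            self.rhs2 = d.Z_pe.T @ (rinv * d.y)
        else:
            self.logdet_M22 = 0.0
            self.G2 = None
            S = M11
            self.rhs2 = None

        try:
            self.cho = sla.cho_factor(S, lower=True)
        except np.linalg.LinAlgError as err:
            raise SingularFixedBlock(_singular_message(err, design)) from err
        self.logdet_S = 2.0 * float(np.sum(np.log(np.diag(self.cho[0]))))

    # -- linear algebra primitives ----------------------------------------

    @property
    def logdet_M(self) -> float:
        return self.logdet_S + self.logdet_M22

    def solve(self, g1: np.ndarray | None = None, g2: np.ndarray | None = None):
        """Solve the MME for a (block-1, block-2) right-hand side.

        Defaults to the data right-hand side, giving the BLUE/BLUP solution.
        """
        if g1 is None:
            g1, g2 = self.rhs1, self.rhs2
        if self.G2 is None:
            return sla.cho_solve(self.cho, g1), None
        x1 = sla.cho_solve(self.cho, g1 - self.G2.T @ g2)
        x2 = self.M22inv_sp @ g2 - self.G2 @ x1
        return x1, x2

    @cached_property
    def S_inv(self) -> np.ndarray:
        return sla.cho_solve(self.cho, np.eye(self.n1))

    @cached_property
    def C_aa4(self) -> np.ndarray:
        """Additive block of the inverse coefficient matrix, as (q, ka, q, ka)."""
        d = self.design
        ka = d.spec.ka
        return self.S_inv[d.p:, d.p:].reshape(d.q, ka, d.q, ka)

    @cached_property
    def C_pp_blocks(self) -> np.ndarray | None:
        """Per-cow kpe×kpe diagonal blocks of the inverse coefficient matrix."""
        if self.G2 is None:
            return None
        d = self.design
        kpe = d.spec.kpe
        H = self.G2 @ self.S_inv                      # n2 × n1 dense
        full = (self.G2 @ H.T).T                      # G2 S⁻¹ G2'
        n2 = H.shape[0]
        blk = full.reshape(d.n_cows, kpe, d.n_cows, kpe)
        diag = blk[np.arange(d.n_cows), :, np.arange(d.n_cows), :]
        return self.M22inv_blocks + diag

    @cached_property
    def record_quadforms(self) -> np.ndarray:
        """w_r' C w_r per record (C = inverse coefficient matrix)."""
        d = self.design
        if self.G2 is None:
            V = self.W1
            q2 = 0.0
        else:
            V = (self.W1 - d.Z_pe @ self.G2).tocsr()
            q2 = np.einsum(
                "ri,rij,rj->r", d.phi_pe, self.M22inv_blocks[d.rec_cow], d.phi_pe
            )
        VS = V @ self.S_inv
        q1 = np.asarray(V.multiply(VS).sum(axis=1)).ravel()
        return q1 + q2

    def fitted(self, x1: np.ndarray, x2: np.ndarray | None) -> np.ndarray:
        d = self.design
        f = self.W1 @ x1
        if x2 is not None:
            f = f + d.Z_pe @ x2
        return f


def _pd_inverse(K: np.ndarray, name: str) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    try:
        c = sla.cho_factor(K, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} is not positive definite") from err
    return sla.cho_solve(c, np.eye(K.shape[0]))


def _singular_message(err, design: Design) -> str:
    msg = str(err)
    hint = ""
    import re

    m = re.search(r"minor of order (\d+)", msg)
    if m:
        k = int(m.group(1)) - 1
        if k < design.p:
            hint = f" (fixed column {design.fixed_names[k]!r} confounded)"
        else:
            hint = " (additive-coefficient block)"
    return f"singular mixed-model equations: {msg}{hint}"


# --------------------------------------------------------------------------
# solution container

@dataclass
class SolutionSet:
    """BLUE/BLUP solutions of the MME at fixed variance components."""

    htd: pd.Series
    age_coef: np.ndarray
    dim_coef: np.ndarray
    alpha: np.ndarray        # (q, ka) additive coefficients per pedigree animal
    gamma: np.ndarray | None  # (n_cows, kpe) permanent-environment coefficients
    residuals: np.ndarray
    fitted: np.ndarray
    design: Design = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        d = self.design
        for (h, t), v in self.htd.items():
            rows.append(("htd", f"{h}/{t}", 0, v))
        for k, v in enumerate(self.age_coef, start=1):
            rows.append(("age_regression", "b", k, v))
        for k, v in enumerate(self.dim_coef, start=1):
            rows.append(("dim_regression", "c", k, v))
        for u, aid in enumerate(d.ped.ids):
            for j in range(d.spec.ka):
                rows.append(("additive", aid, j, self.alpha[u, j]))
        if self.gamma is not None:
            for c, cid in enumerate(d.cows):
                for j in range(d.spec.kpe):
                    rows.append(("pe", cid, j, self.gamma[c, j]))
        return pd.DataFrame(rows, columns=["block", "level", "coef", "estimate"])


def assemble_and_solve(design: Design, vc, a_inv=None) -> SolutionSet:
    """Solve Henderson's MME at the given variance components."""
    if a_inv is not None:
        design = _with_a_inv(design, a_inv)
    fac = MMEFactor(design, vc)
    x1, x2 = fac.solve()
    return solution_from_vector(design, fac, x1, x2)


def _with_a_inv(design: Design, a_inv) -> Design:
    from dataclasses import replace

    lu = sparse.linalg.splu(sparse.csc_matrix(a_inv))
    logdet = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    return replace(design, a_inv=sparse.csr_matrix(a_inv), logdet_a=logdet)


def solution_from_vector(design: Design, fac: MMEFactor, x1, x2) -> SolutionSet:
    d = design
    spec = d.spec
    n_age = sum(1 for s in d.fixed_names if s.startswith("age^"))
    htd = pd.Series(x1[: d.n_htd], index=pd.MultiIndex.from_tuples(d.htd_levels))
    age_coef = x1[d.n_htd: d.n_htd + n_age]
    dim_coef = x1[d.n_htd + n_age: d.p]
    alpha = x1[d.p:].reshape(d.q, spec.ka)
    gamma = x2.reshape(d.n_cows, spec.kpe) if x2 is not None else None
    fitted = fac.fitted(x1, x2)
    return SolutionSet(
        htd=htd, age_coef=age_coef, dim_coef=dim_coef, alpha=alpha,
        gamma=gamma, residuals=d.y - fitted, fitted=fitted, design=d,
    )
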