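"""REML estimation of the covariance components of the test-day model.

Free parameters: the additive coefficient covariance K_a (ka×ka), the
permanent-environment coefficient covariance K_pe (kpe×kpe), and ten
residual variances (one per 30-day DIM class).  The restricted
log-likelihood is, up to its usual constant,

    −2l = log|R| + log|G| + log|C| + y'Py

evaluated through the mixed-model-equation factorization (the dense V is
never formed outside oracle tests).

Two update schemes are provided.  EM uses the conditional expectations of
the coefficient cross-products and residual sums of squares; each exact EM
step cannot decrease l.  AI uses the average-information approximation to
the Hessian with analytic gradients; AI steps that leave the
positive-definite cone or decrease l fall back to an EM step, so the
default ``ai-em`` method produces a monotone likelihood sequence with
near-quadratic terminal convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import sparse

from .mme import Design, MMEFactor


@dataclass
class VarianceComponents:
    """K_a, K_pe (kg² on the coefficient scale) and class residual variances."""

    K_a: np.ndarray
    K_pe: np.ndarray | None
    sigma2_e: np.ndarray

    def __post_init__(self):
        self.K_a = np.atleast_2d(np.asarray(self.K_a, dtype=float))
        if self.K_pe is not None:
            self.K_pe = np.atleast_2d(np.asarray(self.K_pe, dtype=float))
            if self.K_pe.size == 0:
                self.K_pe = None
        self.sigma2_e = np.asarray(self.sigma2_e, dtype=float)

    @property
    def ka(self) -> int:
        return self.K_a.shape[0]

    @property
    def kpe(self) -> int:
        return 0 if self.K_pe is None else self.K_pe.shape[0]

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            self.K_a.copy(),
            None if self.K_pe is None else self.K_pe.copy(),
            self.sigma2_e.copy(),
        )

    def is_valid(self) -> bool:
        if np.any(self.sigma2_e <= 0):
            return False
        for K in (self.K_a, self.K_pe):
            if K is None:
                continue
            try:
                sla.cho_factor(K)
            except (np.linalg.LinAlgError, ValueError):
                return False
        return True

    # ---- flat parameter vector (lower-triangle packing) -----------------

    def to_vector(self) -> np.ndarray:
        parts = [self.K_a[np.tril_indices(self.ka)]]
        if self.K_pe is not None:
            parts.append(self.K_pe[np.tril_indices(self.kpe)])
        parts.append(self.sigma2_e)
        return np.concatenate(parts)

    def with_vector(self, v: np.ndarray) -> "VarianceComponents":
        ka, kpe = self.ka, self.kpe
        na = ka * (ka + 1) // 2
        npe = kpe * (kpe + 1) // 2
        K_a = _unpack_sym(v[:na], ka)
        K_pe = _unpack_sym(v[na:na + npe], kpe) if kpe else None
        return VarianceComponents(K_a, K_pe, v[na + npe:].copy())


def _unpack_sym(v: np.ndarray, k: int) -> np.ndarray:
    K = np.zeros((k, k))
    K[np.tril_indices(k)] = v
    return K + np.tril(K, -1).T


@dataclass
class RemlOptions:
    method: str = "ai-em"          # one of em, ai, ai-em
    tol: float = 1e-6              # max relative parameter change
    max_iter: int = 200
    em_burnin: int = 2             # EM steps before the first AI attempt
    jitter_sd: float = 0.0         # optional relative jitter of the init
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.method not in ("em", "ai", "ai-em"):
            raise ValueError(f"unknown REML method {self.method!r}")


@dataclass
class FitResult:
    vc: VarianceComponents
    loglik: float
    n_iter: int
    converged: bool
    spec: object
    n_obs: int
    loglik_path: list[float] = field(default_factory=list)
    method: str = "ai-em"

    def to_json(self) -> str:
        payload = {
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "method": self.method,
            "ka": self.vc.ka,
            "kpe": self.vc.kpe,
            "K_a_rowmajor": self.vc.K_a.ravel().tolist(),
            "K_pe_rowmajor": (
                [] if self.vc.K_pe is None else self.vc.K_pe.ravel().tolist()
            ),
            "sigma2_e": self.vc.sigma2_e.tolist(),
            "loglik_path": self.loglik_path,
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def variance_components_from_json(text: str) -> VarianceComponents:
        d = json.loads(text)
        ka, kpe = d["ka"], d["kpe"]
        K_a = np.array(d["K_a_rowmajor"]).reshape(ka, ka)
        K_pe = np.array(d["K_pe_rowmajor"]).reshape(kpe, kpe) if kpe else None
        return VarianceComponents(K_a, K_pe, np.array(d["sigma2_e"]))


# --------------------------------------------------------------------------
# restricted log-likelihood

def restricted_loglik(design: Design, vc: VarianceComponents,
                      factor: MMEFactor | None = None) -> float:
    """Restricted log-likelihood l (with its (n−p)·log 2π constant)."""
    if not vc.is_valid():
        raise ValueError("variance components not positive definite")
    fac = factor if factor is not None else MMEFactor(design, vc)
    return _loglik_from_factor(fac)[0]


def _loglik_from_factor(fac: MMEFactor):
    d = fac.design
    vc = fac.vc
    x1, x2 = fac.solve()
    ypy = float(d.y @ (fac.rinv * d.y)) - float(fac.rhs1 @ x1)
    if x2 is not None:
        ypy -= float(fac.rhs2 @ x2)
    counts = d.class_counts
    logdet_r = float(counts @ np.log(vc.sigma2_e))
    logdet_g = d.spec.ka * d.logdet_a + d.q * _logdet(vc.K_a)
    if vc.kpe:
        logdet_g += d.n_cows * _logdet(vc.K_pe)
    const = (d.n - d.p) * np.log(2 * np.pi)
    l = -0.5 * (logdet_r + logdet_g + fac.logdet_M + ypy + const)
    return l, (x1, x2)


def _logdet(K: np.ndarray) -> float:
    sign, v = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("matrix not positive definite")
    return float(v)


# --------------------------------------------------------------------------
# per-iteration statistics shared by EM, gradient and AI

class _IterState:
    def __init__(self, fac: MMEFactor):
        self.fac = fac
        d = fac.design
        self.l, (self.x1, self.x2) = _loglik_from_factor(fac)
        self.ehat = d.y - fac.fitted(self.x1, self.x2)
        self.py = fac.rinv * self.ehat
        ka = d.spec.ka
        self.alpha = self.x1[d.p:].reshape(d.q, ka)
        self.gamma = (
            None if self.x2 is None else self.x2.reshape(d.n_cows, d.spec.kpe)
        )
        # score accumulators
        Ta = np.zeros((d.q, ka))
        np.add.at(Ta, d.rec_animal, d.phi_a * self.py[:, None])
        self.T_a = Ta
        self.U = d.a_lu.solve(Ta).reshape(d.q, ka)    # U = A @ T_a
        if d.spec.kpe:
            Tp = np.zeros((d.n_cows, d.spec.kpe))
            np.add.at(Tp, d.rec_cow, d.phi_pe * self.py[:, None])
            self.T_pe = Tp
        else:
            self.T_pe = None
        # gathered inverse blocks weighted by A⁻¹:
        # Tmat[i, j] = Σ_uv (A⁻¹)_uv C_aa[(u,i),(v,j)]
        coo = sparse.coo_matrix(d.a_inv)
        gathered = fac.C_aa4[coo.row, :, coo.col, :]
        self.Tmat_a = np.tensordot(coo.data, gathered, axes=1)
        self.Tpp_sum = None if fac.C_pp_blocks is None else fac.C_pp_blocks.sum(axis=0)

    # ---- EM update -----------------------------------------------------

    def em_update(self) -> VarianceComponents:
        fac, d = self.fac, self.fac.design
        vc = fac.vc
        Ainv = d.a_inv
        quad_a = self.alpha.T @ (Ainv @ self.alpha)
        K_a = (quad_a + self.Tmat_a) / d.q
        K_a = 0.5 * (K_a + K_a.T)
        if d.spec.kpe:
            K_pe = (self.gamma.T @ self.gamma + self.Tpp_sum) / d.n_cows
            K_pe = 0.5 * (K_pe + K_pe.T)
        else:
            K_pe = None
        qf = fac.record_quadforms
        s2 = vc.sigma2_e.copy()
        for c in range(d.spec.n_residual_classes):
            mask = d.rclass0 == c
            nc = int(mask.sum())
            if nc:
                s2[c] = (self.ehat[mask] @ self.ehat[mask] + qf[mask].sum()) / nc
        return VarianceComponents(K_a, K_pe, s2)

    # ---- analytic gradient --------------------------------------------

    def gradient(self) -> np.ndarray:
        fac, d = self.fac, self.fac.design
        vc = fac.vc
        g = []
        M1 = self.T_a.T @ self.U
        Kai = fac.Ka_inv
        for i, j in zip(*np.tril_indices(vc.ka)):
            E = _sym_unit(vc.ka, i, j)
            Wm = Kai @ E @ Kai
            tr = d.q * np.trace(E @ Kai) - np.trace(Wm @ self.Tmat_a)
            quad = M1[i, j] + M1[j, i] if i != j else M1[i, i]
            g.append(-0.5 * (tr - quad))
        if vc.kpe:
            M1p = self.T_pe.T @ self.T_pe
            Kpi = fac.Kpe_inv
            for i, j in zip(*np.tril_indices(vc.kpe)):
                E = _sym_unit(vc.kpe, i, j)
                Wm = Kpi @ E @ Kpi
                tr = d.n_cows * np.trace(E @ Kpi) - np.trace(Wm @ self.Tpp_sum)
                quad = M1p[i, j] + M1p[j, i] if i != j else M1p[i, i]
                g.append(-0.5 * (tr - quad))
        qf = fac.record_quadforms
        for c in range(d.spec.n_residual_classes):
            mask = d.rclass0 == c
            nc = int(mask.sum())
            s2 = vc.sigma2_e[c]
            tr = nc / s2 - qf[mask].sum() / s2**2
            quad = float(self.py[mask] @ self.py[mask])
            g.append(-0.5 * (tr - quad))
        return np.array(g)

    # ---- average-information matrix ------------------------------------

    def ai_matrix(self) -> np.ndarray:
        fac, d = self.fac, self.fac.design
        vc = fac.vc
        fs = []
        for i, j in zip(*np.tril_indices(vc.ka)):
            E = _sym_unit(vc.ka, i, j)
            coef = (self.U @ E)[d.rec_animal]
            fs.append(np.einsum("rk,rk->r", d.phi_a, coef))
        if vc.kpe:
            for i, j in zip(*np.tril_indices(vc.kpe)):
                E = _sym_unit(vc.kpe, i, j)
                coef = (self.T_pe @ E)[d.rec_cow]
                fs.append(np.einsum("rk,rk->r", d.phi_pe, coef))
        for c in range(d.spec.n_residual_classes):
            fs.append(np.where(d.rclass0 == c, self.py, 0.0))
        F = np.column_stack(fs)
        PF = np.empty_like(F)
        Zpe = d.Z_pe
        for k in range(F.shape[1]):
            f = F[:, k]
            g1 = fac.W1.T @ (fac.rinv * f)
            g2 = None if Zpe is None else Zpe.T @ (fac.rinv * f)
            x1, x2 = fac.solve(g1, g2)
            PF[:, k] = fac.rinv * (f - fac.fitted(x1, x2))
        AI = 0.5 * (F.T @ PF)
        return 0.5 * (AI + AI.T)


def _sym_unit(k: int, i: int, j: int) -> np.ndarray:
    E = np.zeros((k, k))
    E[i, j] += 1.0
    E[j, i] += 1.0
    if i == j:
        E[i, i] = 1.0
    return E


def reml_gradient(design: Design, vc: VarianceComponents) -> np.ndarray:
    """Analytic ∂l/∂θ for θ = (vech K_a, vech K_pe, σ²e) — small-instance
    diagnostic; off-diagonal entries differentiate the symmetric pair."""
    return _IterState(MMEFactor(design, vc)).gradient()


# --------------------------------------------------------------------------
# the fit driver

def default_init(design: Design) -> VarianceComponents:
    """Heuristic start: K = 0.2·Var(y)·I on the basis scale, σ²e = 0.6·Var(y)."""
    vp = float(np.var(design.y, ddof=1))
    spec = design.spec
    K_a = 0.2 * vp * np.eye(spec.ka)
    K_pe = 0.2 * vp * np.eye(spec.kpe) if spec.kpe else None
    s2 = np.full(spec.n_residual_classes, 0.6 * vp)
    return VarianceComponents(K_a, K_pe, s2)


def fit_reml(design: Design, init: VarianceComponents | None = None,
             opts: RemlOptions | None = None) -> FitResult:
    """Iterate EM / AI updates until the largest relative parameter change
    drops below ``opts.tol`` or ``opts.max_iter`` is hit.

    Non-convergence is reported in the result, not raised.  The likelihood
    sequence recorded in ``loglik_path`` is non-decreasing for the em and
    ai-em methods.
    """
    opts = opts or RemlOptions()
    if design.n <= design.p:
        raise ValueError(
            f"degenerate design: {design.n} records for {design.p} fixed effects"
        )
    vc = init.copy() if init is not None else default_init(design)
    if opts.jitter_sd > 0:
        rng = np.random.default_rng(opts.seed)
        v = vc.to_vector()
        vc = vc.with_vector(v * (1 + opts.jitter_sd * rng.standard_normal(v.size)))
    if not vc.is_valid():
        raise ValueError("initial variance components not positive definite")

    state = _IterState(MMEFactor(design, vc))
    path = [state.l]
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        use_ai = opts.method in ("ai", "ai-em") and n_iter > opts.em_burnin
        new_state = None
        if use_ai:
            for cand in _ai_candidates(state):
                cand_state = _IterState(MMEFactor(design, cand))
                if opts.method == "ai" or cand_state.l >= state.l:
                    new_state = cand_state
                    break
        if new_state is None:
            vc_em = state.em_update()
            new_state = _IterState(MMEFactor(design, vc_em))
        delta = _max_rel_change(state.fac.vc.to_vector(), new_state.fac.vc.to_vector())
        if opts.verbose:
            print(f"iter {n_iter}: l = {new_state.l:.6f}  max rel change = {delta:.3e}")
        state = new_state
        path.append(state.l)
        if delta < opts.tol:
            converged = True
            break

    return FitResult(
        vc=state.fac.vc, loglik=state.l, n_iter=n_iter, converged=converged,
        spec=design.spec, n_obs=design.n, loglik_path=path, method=opts.method,
    )


def _ai_candidates(state: _IterState):
    """Projected AI-step candidates at decreasing step fractions.

    Candidates outside the positive-definite cone are projected back by
    eigenvalue clipping rather than discarded, so the iteration can move
    along the boundary when a component heads to (near-)singularity."""
    vc = state.fac.vc
    try:
        grad = state.gradient()
        AI = state.ai_matrix()
        ridge = 1e-8 * max(1.0, np.abs(np.diag(AI)).max())
        step = np.linalg.solve(AI + ridge * np.eye(AI.shape[0]), grad)
    except np.linalg.LinAlgError:
        return
    theta = vc.to_vector()
    for frac in (1.0, 0.25, 0.05):
        cand = _project_pd(vc.with_vector(theta + frac * step))
        if cand.is_valid():
            yield cand


def _project_pd(vc: VarianceComponents, rel_floor: float = 1e-6) -> VarianceComponents:
    """Clip K eigenvalues and residual variances to small positive floors."""
    def clip(K):
        if K is None:
            return None
        w, V = np.linalg.eigh(K)
        floor = rel_floor * max(np.max(np.abs(w)), 1e-6)
        return (V * np.maximum(w, floor)) @ V.T

    s2 = np.maximum(vc.sigma2_e, rel_floor * max(np.max(vc.sigma2_e), 1e-6))
    return VarianceComponents(clip(vc.K_a), clip(vc.K_pe), s2)


def _max_rel_change(old: np.ndarray, new: np.ndarray) -> float:
    scale = np.maximum(np.abs(old), 1e-8)
    return float(np.max(np.abs(new - old) / scale))
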