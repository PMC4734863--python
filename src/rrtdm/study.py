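"""Simulation studies: parameter recovery and order selection.

One replicate = simulate a herd-book under known (K_a, K_pe, σ²e), apply
the data edits, and REML-fit candidate models.  The study conditions are
fixed here: 500 cows in 25 paternal half-sib families across 5 herds,
about six monthly records each (~3,000 test-day records), truth of order
ka = kpe = 2 giving mid-lactation h² ≈ 0.2.  Used by the analysis drivers
and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mme import ModelSpec, build_design
from .model_selection import bic, count_parameters
from .reml import FitResult, RemlOptions, fit_reml
from .synthetic_data import SimConfig, simulate_tddata
from .tdm_data import apply_edits

STUDY_TRUTH = SimConfig(
    n_herds=5,
    cows_per_herd=100,
    n_sires=25,
    parities=(1,),
    freq_split=0.0,
    records_per_cow=(4, 8),
)

STUDY_REML = RemlOptions(method="ai-em", tol=1e-5, max_iter=60)


def parameter_names(ka: int, kpe: int, n_classes: int = 10) -> list[str]:
    names = [f"K_a[{i},{j}]" for i, j in zip(*np.tril_indices(ka))]
    names += [f"K_pe[{i},{j}]" for i, j in zip(*np.tril_indices(kpe))]
    names += [f"sigma2_e[{c + 1}]" for c in range(n_classes)]
    return names


@dataclass
class StudyResult:
    truth: np.ndarray
    param_names: list[str]
    estimates: np.ndarray          # (n_replicates, n_params)
    bic_true_order: np.ndarray     # BIC at (2,2) per replicate
    bic_low_order: np.ndarray      # BIC at (1,1) per replicate
    logliks: dict = field(default_factory=dict)
    loglik_paths: list = field(default_factory=list)
    n_records: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Replicate mean vs truth, with Monte-Carlo standard errors."""
        mean = self.estimates.mean(axis=0)
        sd = self.estimates.std(axis=0, ddof=1)
        se = sd / np.sqrt(self.estimates.shape[0])
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "truth": self.truth,
                "mean_estimate": mean,
                "mc_sd": sd,
                "mc_se": se,
                "z": (mean - self.truth) / se,
            }
        )

    def prefer_true_order_fraction(self) -> float:
        return float(np.mean(self.bic_true_order < self.bic_low_order))

    def paths_monotone(self, rel_tol: float = 1e-9) -> bool:
        return all(_is_monotone(p, rel_tol) for p in self.loglik_paths)


def _is_monotone(path, rel_tol: float = 1e-9) -> bool:
    p = np.asarray(path)
    return bool(np.all(np.diff(p) >= -rel_tol * np.abs(p[:-1])))


def run_replicate(seed: int, reml_opts: RemlOptions = STUDY_REML,
                  cfg: SimConfig = STUDY_TRUTH) -> dict:
    """Simulate one herd-book and fit the (1,1) and (2,2) models."""
    cfg = replace(cfg, seed=int(seed))
    sim = simulate_tddata(cfg)
    records, _ = apply_edits(sim.records)
    n = len(records)
    out = {"n_records": n, "fits": {}}
    for ka, kpe in ((2, 2), (1, 1)):
        spec = ModelSpec(ka=ka, kpe=kpe)
        design = build_design(records, spec, sim.pedigree)
        fit = fit_reml(design, opts=reml_opts)
        K = count_parameters(ka, kpe, spec.n_residual_classes, "true_count")
        out["fits"][(ka, kpe)] = fit
        out[f"bic_{ka}{kpe}"] = bic(fit.loglik, K, n, base=10)
    return out


def recovery_study(n_replicates: int = 20, seed: int = 0,
                   reml_opts: RemlOptions = STUDY_REML,
                   cfg: SimConfig = STUDY_TRUTH) -> StudyResult:
    """Run the full replicate study under the fixed truth."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    truth_vc_vec = np.concatenate(
        [
            np.asarray(cfg.K_a_true)[np.tril_indices(cfg.ka)],
            np.asarray(cfg.K_pe_true)[np.tril_indices(cfg.kpe)],
            np.asarray(cfg.sigma2_e_true, dtype=float),
        ]
    )
    estimates, b22, b11, paths, nrec = [], [], [], [], []
    logliks = {}
    for r, s in enumerate(rep_seeds):
        rep = run_replicate(int(s), reml_opts, cfg)
        fit22: FitResult = rep["fits"][(2, 2)]
        estimates.append(fit22.vc.to_vector())
        b22.append(rep["bic_22"])
        b11.append(rep["bic_11"])
        paths.append(fit22.loglik_path)
        paths.append(rep["fits"][(1, 1)].loglik_path)
        nrec.append(rep["n_records"])
        logliks[r] = {k: f.loglik for k, f in rep["fits"].items()}
    return StudyResult(
        truth=truth_vc_vec,
        param_names=parameter_names(cfg.ka, cfg.kpe),
        estimates=np.asarray(estimates),
        bic_true_order=np.asarray(b22),
        bic_low_order=np.asarray(b11),
        logliks=logliks,
        loglik_paths=paths,
        n_records=nrec,
    )


def em_monotonicity_run(seed: int = 0, n_iter: int = 12,
                        cfg: SimConfig = STUDY_TRUTH) -> list[float]:
    """Pure-EM iteration path on one replicate (for the monotonicity check)."""
    cfg = replace(cfg, seed=int(seed))
    sim = simulate_tddata(cfg)
    records, _ = apply_edits(sim.records)
    design = build_design(records, ModelSpec(ka=2, kpe=2), sim.pedigree)
    fit = fit_reml(design, opts=RemlOptions(method="em", max_iter=n_iter, tol=0.0))
    return fit.loglik_path
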