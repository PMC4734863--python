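import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import dense_restricted_loglik
from rrtdm.mme import ModelSpec, build_design
from rrtdm.pedigree import relationship_matrix, sort_and_validate
from rrtdm.reml import (
    RemlOptions,
    VarianceComponents,
    default_init,
    fit_reml,
    reml_gradient,
    restricted_loglik,
)
from rrtdm.synthetic_data import SimConfig, simulate_tddata
from rrtdm.tdm_data import apply_edits


def one_way_dataset(n_cows=40, m=6, mu=30.0, s_b=4.0, s_e=9.0, seed=11):
    """Balanced one-way repeatability layout: unrelated cows, m records each,
    one contemporary group, one DIM (so the basis is the constant φ0)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s_b), n_cows)
    rows = []
    for c in range(n_cows):
        for j in range(m):
            rows.append((f"C{c:03d}", "H1", "t1", 1, 26.0, "3X", 100,
                         mu + u[c] + rng.normal(0, np.sqrt(s_e))))
    rec = pd.DataFrame(rows, columns=["cow", "herd", "test_date", "parity",
                                      "age_months", "freq", "dim", "milk"])
    ped = sort_and_validate([(f"C{c:03d}", "0", "0") for c in range(n_cows)])
    return rec, ped


def anova_reml(rec, m):
    """Closed-form balanced one-way REML (= ANOVA) variance components."""
    y = rec.pivot_table(index="cow", values="milk", aggfunc="mean")["milk"]
    grand = rec["milk"].mean()
    msb = m * ((y - grand) ** 2).sum() / (len(y) - 1)
    msw = ((rec["milk"] - rec.groupby("cow")["milk"].transform("mean")) ** 2).sum() / (
        len(rec) - len(y)
    )
    return (msb - msw) / m, msw


class TestRestrictedLoglik:
    def test_matches_dense_formula(self, small_instance):
        sim, _, design, vc = small_instance
        A = relationship_matrix(sim.pedigree)
        l_dense = dense_restricted_loglik(design, vc, A)
        assert restricted_loglik(design, vc) == pytest.approx(l_dense, abs=1e-6)

    def test_scale_equivariance(self, small_instance):
        """Scaling y and all variances by c² shifts l by −(n−p)·log c."""
        sim, rec, design, vc = small_instance
        c2 = 4.0
        rec2 = rec.copy()
        rec2["milk"] = rec2["milk"] * np.sqrt(c2)
        d2 = build_design(rec2, design.spec, sim.pedigree)
        vc2 = VarianceComponents(vc.K_a * c2, vc.K_pe * c2, vc.sigma2_e * c2)
        expected_shift = -0.5 * (design.n - design.p) * np.log(c2)
        got = restricted_loglik(d2, vc2) - restricted_loglik(design, vc)
        assert got == pytest.approx(expected_shift, abs=1e-8)

    def test_duplicated_data_lowers_loglik(self, small_instance):
        sim, rec, design, vc = small_instance
        doubled = pd.concat([rec, rec], ignore_index=True)
        d2 = build_design(doubled, design.spec, sim.pedigree)
        assert restricted_loglik(d2, vc) < restricted_loglik(design, vc)

    def test_invalid_components_rejected(self, small_instance):
        *_, design, vc = small_instance
        bad = VarianceComponents(-np.eye(2), vc.K_pe, vc.sigma2_e)
        with pytest.raises(ValueError):
            restricted_loglik(design, bad)


ONE_WAY_SPEC = ModelSpec(ka=1, kpe=0, age_fixed_order=0, dim_fixed_order=0,
                         n_residual_classes=1)


class TestFitReml:
    def test_one_way_closed_form(self):
        """Additive-only fit on unrelated cows equals ANOVA REML exactly."""
        rec, ped = one_way_dataset()
        s_b, s_e = anova_reml(rec, m=6)
        d = build_design(rec, ONE_WAY_SPEC, ped)
        fit = fit_reml(d, opts=RemlOptions(tol=1e-10, max_iter=300))
        assert fit.converged
        assert fit.vc.K_a[0, 0] / 2 == pytest.approx(s_b, rel=1e-4)  # φ0² = 1/2
        assert fit.vc.sigma2_e[0] == pytest.approx(s_e, rel=1e-4)

    def test_one_way_confounded_sum(self):
        """With additive and PE both present and no pedigree links, only
        their sum is identified; it equals the ANOVA between-cow component."""
        rec, ped = one_way_dataset(seed=12)
        s_b, s_e = anova_reml(rec, m=6)
        spec = dataclasses.replace(ONE_WAY_SPEC, kpe=1)
        fit = fit_reml(build_design(rec, spec, ped),
                       opts=RemlOptions(tol=1e-8, max_iter=300))
        total = (fit.vc.K_a[0, 0] + fit.vc.K_pe[0, 0]) / 2
        assert total == pytest.approx(s_b, rel=1e-3)
        assert fit.vc.sigma2_e[0] == pytest.approx(s_e, rel=1e-3)

    def test_fixed_point_at_optimum(self):
        """Initialized at the REML optimum, the iteration stops immediately."""
        rec, ped = one_way_dataset()
        s_b, s_e = anova_reml(rec, m=6)
        d = build_design(rec, ONE_WAY_SPEC, ped)
        init = VarianceComponents(np.array([[2 * s_b]]), None, np.array([s_e]))
        fit = fit_reml(d, init=init, opts=RemlOptions(method="em", tol=1e-6, max_iter=10))
        assert fit.converged and fit.n_iter <= 2
        assert fit.vc.K_a[0, 0] == pytest.approx(2 * s_b, rel=1e-4)

    def test_em_loglik_monotone(self, small_instance):
        *_, design, vc = small_instance
        fit = fit_reml(design, opts=RemlOptions(method="em", tol=0.0, max_iter=12))
        path = np.asarray(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-9 * np.abs(path[:-1]))

    def test_gradient_matches_numerical(self, small_instance):
        *_, design, vc = small_instance
        g = reml_gradient(design, vc)
        th = vc.to_vector()
        num = np.empty_like(th)
        for k in range(th.size):
            e = np.zeros_like(th)
            e[k] = 1e-5 * max(1.0, abs(th[k]))
            num[k] = (
                restricted_loglik(design, vc.with_vector(th + e))
                - restricted_loglik(design, vc.with_vector(th - e))
            ) / (2 * e[k])
        assert np.abs(g - num).max() < 1e-4

    def test_gradient_small_at_convergence(self):
        rec, ped = one_way_dataset(n_cows=25, m=4, seed=21)
        d = build_design(rec, ONE_WAY_SPEC, ped)
        fit = fit_reml(d, opts=RemlOptions(tol=1e-10, max_iter=300))
        assert fit.converged
        assert np.abs(reml_gradient(d, fit.vc)).max() < 1e-3

    def test_cow_relabelling_invariance(self):
        rec, ped = one_way_dataset(n_cows=15, m=4, seed=31)
        fit1 = fit_reml(build_design(rec, ONE_WAY_SPEC, ped),
                        opts=RemlOptions(tol=1e-8))
        relabel = {c: f"X{c[::-1]}" for c in rec["cow"].unique()}
        rec2 = rec.assign(cow=rec["cow"].map(relabel))
        ped2 = sort_and_validate([(relabel[c], "0", "0") for c in rec["cow"].unique()])
        fit2 = fit_reml(build_design(rec2, ONE_WAY_SPEC, ped2),
                        opts=RemlOptions(tol=1e-8))
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
        assert fit1.vc.K_a[0, 0] == pytest.approx(fit2.vc.K_a[0, 0], abs=1e-8)

    def test_nonconvergence_reported_not_raised(self, small_instance):
        *_, design, vc = small_instance
        fit = fit_reml(design, opts=RemlOptions(method="em", tol=1e-12, max_iter=2))
        assert not fit.converged and fit.n_iter == 2

    def test_degenerate_design_rejected(self):
        rec, ped = one_way_dataset(n_cows=3, m=1)
        rec = rec.copy()
        rec["test_date"] = [f"t{i}" for i in range(len(rec))]  # p == n
        d = build_design(rec, ONE_WAY_SPEC, ped)
        with pytest.raises(ValueError, match="degenerate"):
            fit_reml(d)

    def test_parameter_recovery_moderate(self):
        """Single moderate herd-book: estimates land near truth (loose check;
        the replicated study lives in the acceptance suite)."""
        cfg = SimConfig(n_herds=3, cows_per_herd=80, n_sires=12, parities=(1,),
                        freq_split=0.0, records_per_cow=(5, 8), seed=2024)
        sim = simulate_tddata(cfg)
        rec, _ = apply_edits(sim.records)
        d = build_design(rec, ModelSpec(ka=2, kpe=2), sim.pedigree)
        fit = fit_reml(d, opts=RemlOptions(tol=1e-5, max_iter=60))
        assert fit.vc.sigma2_e.min() > 0
        # smoke bound on a single replicate; the calibrated 3-SE recovery
        # check over 20 replicates lives in the acceptance suite
        rel = np.abs(fit.vc.sigma2_e - np.array(cfg.sigma2_e_true)) / np.array(cfg.sigma2_e_true)
        assert rel.max() < 0.5
        total_mid = (fit.vc.K_a[0, 0] + fit.vc.K_pe[0, 0]) / 2
        assert total_mid == pytest.approx(14.0, rel=0.35)

    def test_serialization_roundtrip(self, small_instance):
        *_, design, vc = small_instance
        fit = fit_reml(design, opts=RemlOptions(method="em", tol=1e-2, max_iter=3))
        from rrtdm.reml import FitResult

        back = FitResult.variance_components_from_json(fit.to_json())
        assert np.allclose(back.K_a, fit.vc.K_a)
        assert np.allclose(back.K_pe, fit.vc.K_pe)
        assert np.allclose(back.sigma2_e, fit.vc.sigma2_e)
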