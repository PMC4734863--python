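import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_CFG, dense_gls_blup
from rrtdm.mme import (
    DesignError,
    ModelSpec,
    assemble_and_solve,
    assemble_full,
    build_design,
)
from rrtdm.pedigree import relationship_matrix, sort_and_validate
from rrtdm.reml import VarianceComponents
from rrtdm.synthetic_data import simulate_tddata
from rrtdm.tdm_data import apply_edits


def _records(rows):
    return pd.DataFrame(
        rows, columns=["cow", "herd", "test_date", "parity", "age_months", "freq", "dim", "milk"]
    )


@pytest.fixture
def one_cow():
    ped = sort_and_validate([("C1", "0", "0")])
    rec = _records([
        ("C1", "H1", "t1", 1, 26.0, "3X", 50, 31.0),
        ("C1", "H1", "t2", 1, 26.0, "3X", 80, 33.0),
        ("C1", "H1", "t3", 1, 26.0, "3X", 120, 32.0),
    ])
    return ped, rec


class TestBuildDesign:
    def test_single_record_intercept_basis(self):
        ped = sort_and_validate([("C1", "0", "0")])
        rec = _records([("C1", "H1", "t1", 1, 26.0, "3X", 50, 31.0)])
        spec = ModelSpec(ka=1, kpe=1, age_fixed_order=1, dim_fixed_order=1)
        d = build_design(rec, spec, ped)
        assert d.n_htd == 1
        # age has zero range in a one-record file, so the age column drops
        assert d.X.shape[1] == 1 + 0 + 1
        assert d.Z_a.toarray()[0, 0] == pytest.approx(0.7071068, abs=1e-7)

    def test_shared_animal_block_distinct_htd(self, one_cow):
        ped, rec = one_cow
        d = build_design(rec, ModelSpec(ka=1, kpe=1), ped)
        assert d.n_htd == 3
        Za = d.Z_a.toarray()
        assert Za.shape == (3, 1)           # one animal block shared by all rows
        assert np.all(Za != 0)

    def test_block_dimension_formula(self):
        sim = simulate_tddata(SMALL_CFG)
        rec, _ = apply_edits(sim.records)
        spec = ModelSpec(ka=3, kpe=2)
        d = build_design(rec, spec, sim.pedigree)
        vc = VarianceComponents(np.eye(3), np.eye(2), np.full(10, 5.0))
        system = assemble_full(d, vc)
        expect = d.p + spec.ka * d.q + spec.kpe * d.n_cows
        assert system.matrix.shape == (expect, expect)
        assert d.p == d.n_htd + spec.age_fixed_order + spec.dim_fixed_order
        # coefficient matrix is symmetric
        assert abs(system.matrix - system.matrix.T).max() < 1e-12

    def test_missing_cow_rejected(self, one_cow):
        ped, rec = one_cow
        rec = rec.copy()
        rec.loc[0, "cow"] = "GHOST"
        with pytest.raises(DesignError, match="GHOST"):
            build_design(rec, ModelSpec(ka=1, kpe=1), ped)


class TestAssembleAndSolve:
    def test_degenerate_mean_case(self, one_cow):
        """With vanishing random variances and a single contemporary group
        the GLS solution collapses to the arithmetic mean."""
        ped, rec = one_cow
        rec = rec.copy()
        rec["test_date"] = "t1"       # one HTD level
        spec = ModelSpec(ka=1, kpe=0, age_fixed_order=0, dim_fixed_order=0,
                         n_residual_classes=1)
        d = build_design(rec, spec, ped)
        vc = VarianceComponents(np.array([[1e-12]]), None, np.array([4.0]))
        sol = assemble_and_solve(d, vc)
        assert sol.htd.iloc[0] == pytest.approx(rec["milk"].mean(), abs=1e-6)

    def test_matches_dense_gls_blup(self, small_instance):
        """Sparse MME solutions equal the explicit V-based GLS/BLUP."""
        sim, rec, design, vc = small_instance
        sol = assemble_and_solve(design, vc)
        A = relationship_matrix(sim.pedigree)
        b, u, *_ = dense_gls_blup(design, vc, A)
        got_fixed = np.concatenate([sol.htd.to_numpy(), sol.age_coef, sol.dim_coef])
        assert np.abs(got_fixed - b).max() < 1e-8
        assert np.abs(sol.alpha.ravel() - u["additive"]).max() < 1e-8
        assert np.abs(sol.gamma.ravel() - u["pe"]).max() < 1e-8

    def test_duplicate_records_scaling_invariance(self, small_instance):
        """Duplicating every record while doubling the residual variances
        leaves the normal equations — hence all solutions — unchanged."""
        sim, rec, design, vc = small_instance
        sol1 = assemble_and_solve(design, vc)
        doubled = pd.concat([rec, rec], ignore_index=True)
        d2 = build_design(doubled, design.spec, sim.pedigree)
        vc2 = VarianceComponents(vc.K_a, vc.K_pe, 2.0 * vc.sigma2_e)
        sol2 = assemble_and_solve(d2, vc2)
        assert np.abs(sol1.alpha - sol2.alpha).max() < 1e-8
        assert np.abs(sol1.htd.to_numpy() - sol2.htd.to_numpy()).max() < 1e-8

    def test_normal_equations_residual_orthogonality(self, small_instance):
        _, _, design, vc = small_instance
        sol = assemble_and_solve(design, vc)
        rinv = design.rinv(vc.sigma2_e)
        assert np.abs(design.X.T @ (rinv * sol.residuals)).max() < 1e-8

    def test_pedigree_permutation_invariance(self, small_instance):
        sim, rec, design, vc = small_instance
        sol1 = assemble_and_solve(design, vc)
        rng = np.random.default_rng(3)
        entries = [
            (sim.pedigree.ids[i],
             sim.pedigree.ids[sim.pedigree.sire[i]] if sim.pedigree.sire[i] >= 0 else "0",
             sim.pedigree.ids[sim.pedigree.dam[i]] if sim.pedigree.dam[i] >= 0 else "0")
            for i in rng.permutation(sim.pedigree.n)
        ]
        ped2 = sort_and_validate(entries)
        d2 = build_design(rec, design.spec, ped2)
        sol2 = assemble_and_solve(d2, vc)
        for aid in sim.pedigree.ids:
            a1 = sol1.alpha[sim.pedigree.order_index[aid]]
            a2 = sol2.alpha[ped2.order_index[aid]]
            assert np.abs(a1 - a2).max() < 1e-8

    def test_solution_export_frame(self, small_instance):
        _, _, design, vc = small_instance
        sol = assemble_and_solve(design, vc)
        frame = sol.to_frame()
        assert set(frame["block"]) == {"htd", "age_regression", "dim_regression",
                                       "additive", "pe"}
        assert len(frame) == design.p + design.q * 2 + design.n_cows * 2
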