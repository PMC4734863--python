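import dataclasses

import numpy as np
import pytest

from rrtdm.mme import ModelSpec, build_design
from rrtdm.pedigree import sort_and_validate
from rrtdm.reml import VarianceComponents
from rrtdm.synthetic_data import SimConfig, simulate_tddata
from rrtdm.tdm_data import apply_edits


@pytest.fixture
def trio_pedigree():
    """Sire S, dam D (unrelated founders), offspring O."""
    return sort_and_validate([("O", "S", "D"), ("S", "0", "0"), ("D", "0", "0")])


@pytest.fixture
def fullsib_mating_pedigree():
    """Full sibs X, Y mated to produce inbred Z."""
    return sort_and_validate(
        [("S", "0", "0"), ("D", "0", "0"), ("X", "S", "D"), ("Y", "S", "D"), ("Z", "X", "Y")]
    )


SMALL_CFG = SimConfig(
    n_herds=2, cows_per_herd=3, n_sires=2, parities=(1,), freq_split=0.0,
    records_per_cow=(4, 5), seed=42,
)


@pytest.fixture(scope="session")
def small_instance():
    """~30-record simulated instance with its design and true components
    (the workhorse for dense-oracle comparisons)."""
    sim = simulate_tddata(SMALL_CFG)
    records, _ = apply_edits(sim.records)
    spec = ModelSpec(ka=2, kpe=2, age_fixed_order=1, dim_fixed_order=2)
    design = build_design(records, spec, sim.pedigree)
    vc = VarianceComponents(
        np.array(SMALL_CFG.K_a_true),
        np.array(SMALL_CFG.K_pe_true),
        np.array(SMALL_CFG.sigma2_e_true),
    )
    return sim, records, design, vc


def random_pedigree(rng: np.random.Generator, n: int):
    """Layered random pedigree of n animals (possibly inbred, cycle-free)."""
    entries = []
    for i in range(n):
        name = f"A{i:04d}"
        if i < 5 or rng.random() < 0.2:
            entries.append((name, "0", "0"))
        else:
            s, d = rng.integers(0, i, size=2)
            sire = f"A{s:04d}"
            dam = f"A{d:04d}" if d != s else "0"
            if rng.random() < 0.15:
                dam = "0"
            entries.append((name, sire, dam))
    perm = rng.permutation(n)
    return sort_and_validate([entries[j] for j in perm])


def dense_gls_blup(design, vc, A):
    """Textbook GLS/BLUP from the explicit V = ZGZ' + R (oracle path)."""
    Ga = np.kron(A, vc.K_a)
    Za = design.Z_a.toarray()
    X = design.X.toarray()
    R = np.diag(vc.sigma2_e[design.rclass0])
    V = Za @ Ga @ Za.T + R
    parts = [("additive", Ga, Za)]
    if vc.kpe:
        Gp = np.kron(np.eye(design.n_cows), vc.K_pe)
        Zp = design.Z_pe.toarray()
        V += Zp @ Gp @ Zp.T
        parts.append(("pe", Gp, Zp))
    Vi = np.linalg.inv(V)
    y = design.y
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    u = {name: G @ Z.T @ Vi @ resid for name, G, Z in parts}
    return b, u, V, Vi, resid


def dense_restricted_loglik(design, vc, A):
    """Textbook REML log-likelihood from the explicit V (oracle path)."""
    _, _, V, Vi, resid = dense_gls_blup(design, vc, A)
    X = design.X.toarray()
    n, p = design.n, design.p
    ld_v = np.linalg.slogdet(V)[1]
    ld_x = np.linalg.slogdet(X.T @ Vi @ X)[1]
    return -0.5 * (ld_v + ld_x + resid @ Vi @ resid + (n - p) * np.log(2 * np.pi))
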