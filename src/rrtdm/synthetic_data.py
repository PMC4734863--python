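"""Synthetic herds with the statistical structure the analysis assumes.

The generator draws paternal half-sib families, puts cows on a monthly
herd test calendar, and builds yields exactly under the fitted model:
herd-test-date effects, a fixed lactation curve (polynomial in
standardized DIM) scaled by milking-frequency group, a linear age-at-
calving effect, per-animal additive Legendre coefficients with covariance
A ⊗ K_a (sampled by pedigree-ordered Mendelian recursion), per-cow
permanent-environment coefficients with I ⊗ K_pe, and residuals whose
variance follows the ten 30-day DIM classes.

Everything is driven by one integer seed; the same seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSpec, DimScale, legendre_matrix
from .pedigree import Pedigree, mendelian_variances, sort_and_validate, write_pedigree_csv
from .tdm_data import COLUMNS, assign_residual_class, write_records_csv

#: default truth: ka = kpe = 2 on the normalized basis, calibrated so that
#: mid-lactation h² ≈ 0.2 with the default residual ladder
DEFAULT_K_A = ((10.0, -1.0), (-1.0, 2.0))
DEFAULT_K_PE = ((18.0, -2.0), (-2.0, 4.0))
DEFAULT_SIGMA2_E = (14.0, 12.0, 11.0, 10.5, 10.0, 9.5, 9.0, 9.0, 8.5, 8.0)

#: gently rising-then-falling cubic on standardized DIM (no constant term;
#: the mean level travels through the herd-test-date effects)
DEFAULT_CURVE = {1: (-2.0, -3.0, 1.0), 2: (-3.0, -4.5, 1.5)}
DEFAULT_BASE = {1: 32.0, 2: 36.0}


@dataclass
class SimConfig:
    n_herds: int = 6
    cows_per_herd: int = 80
    n_sires: int = 25
    parities: tuple = (1, 2)
    freq_split: float = 0.15          # fraction of cows milked 4X
    K_a_true: tuple = DEFAULT_K_A
    K_pe_true: tuple = DEFAULT_K_PE
    sigma2_e_true: tuple = DEFAULT_SIGMA2_E
    htd_sd: float = 2.0               # kg, herd-test-date effect SD
    base_yield: dict = field(default_factory=lambda: dict(DEFAULT_BASE))
    fixed_curve: dict = field(default_factory=lambda: dict(DEFAULT_CURVE))
    age_effect: float = 0.5           # kg per unit of standardized age
    freq_multiplier: float = 1.12     # 4X/3X mean-yield ratio
    test_interval: int = 30           # days between herd test dates
    interval_jitter: int = 3          # uniform jitter of each test date
    records_per_cow: tuple = (4, 10)
    age_range: tuple = (20.0, 36.0)   # months, age at first calving
    scale: DimScale = field(default_factory=DimScale)
    normalized: bool = True
    dams_in_pedigree: bool = False    # explicit founder dams vs unknown
    seed: int = 0

    def __post_init__(self):
        if self.n_sires < 1:
            raise ValueError("n_sires must be >= 1")
        if not (0.0 <= self.freq_split <= 1.0):
            raise ValueError("freq_split must be in [0, 1]")
        if self.freq_multiplier <= 0:
            raise ValueError("freq_multiplier must be positive")
        for name in ("K_a_true", "K_pe_true"):
            K = np.asarray(getattr(self, name), dtype=float)
            if K.size and np.any(np.linalg.eigvalsh(K) < -1e-12):
                raise ValueError(f"{name} must be positive semidefinite")

    @property
    def n_cows(self) -> int:
        return self.n_herds * self.cows_per_herd

    @property
    def ka(self) -> int:
        return np.atleast_2d(np.asarray(self.K_a_true)).shape[0]

    @property
    def kpe(self) -> int:
        K = np.asarray(self.K_pe_true, dtype=float)
        return 0 if K.size == 0 else np.atleast_2d(K).shape[0]


@dataclass
class SimOutput:
    pedigree: Pedigree
    records: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree_csv(self.pedigree, outdir / "pedigree.csv")
        write_records_csv(self.records, outdir / "records.csv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True)
        )


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Founder sires (and optionally dams) plus one cow per slot, sires
    assigned at random — paternal half-sib families."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sires = [f"S{i + 1:04d}" for i in range(cfg.n_sires)]
    entries = [(s, None, None) for s in sires]
    sire_of = rng.integers(0, cfg.n_sires, size=cfg.n_cows)
    for c in range(cfg.n_cows):
        cow = f"C{c + 1:05d}"
        dam = None
        if cfg.dams_in_pedigree:
            dam = f"D{c + 1:05d}"
            entries.append((dam, None, None))
        entries.append((cow, sires[sire_of[c]], dam))
    return sort_and_validate(entries)


def _sample_additive(ped: Pedigree, K_a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Coefficient vectors jointly N(0, A ⊗ K_a), by Mendelian recursion."""
    ka = K_a.shape[0]
    L = np.linalg.cholesky(K_a + 1e-12 * np.eye(ka))
    d = mendelian_variances(ped, use_inbreeding=True)
    a = np.zeros((ped.n, ka))
    z = rng.standard_normal((ped.n, ka))
    for i in range(ped.n):
        mean = np.zeros(ka)
        s, t = ped.sire[i], ped.dam[i]
        if s >= 0:
            mean += 0.5 * a[s]
        if t >= 0:
            mean += 0.5 * a[t]
        a[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return a


def simulate_tddata(cfg: SimConfig, ped: Pedigree | None = None) -> SimOutput:
    """Generate the pedigree (unless given) and a test-day record file,
    plus a truth dictionary with all parameters and coefficient draws."""
    rng = np.random.default_rng(cfg.seed)
    if ped is None:
        ped = simulate_pedigree(cfg, rng)
    K_a = np.atleast_2d(np.asarray(cfg.K_a_true, dtype=float))
    kpe = cfg.kpe
    K_pe = np.atleast_2d(np.asarray(cfg.K_pe_true, dtype=float)) if kpe else None
    s2e = np.asarray(cfg.sigma2_e_true, dtype=float)

    cows = sorted(a for a in ped.ids if a.startswith("C"))
    n_cows = len(cows)
    alpha = _sample_additive(ped, K_a, rng)
    if kpe:
        Lpe = np.linalg.cholesky(K_pe + 1e-12 * np.eye(kpe))
        gamma = rng.standard_normal((n_cows, kpe)) @ Lpe.T
    else:
        gamma = np.zeros((n_cows, 0))

    # cow attributes
    herd_of = np.repeat(np.arange(cfg.n_herds), cfg.cows_per_herd)[:n_cows]
    parities = np.asarray(sorted(cfg.parities))
    parity_of = rng.choice(parities, size=n_cows)
    freq_of = np.where(rng.random(n_cows) < cfg.freq_split, "4X", "3X")
    age_first = np.round(rng.uniform(*cfg.age_range, size=n_cows), 1)
    calving_day = rng.integers(0, 331, size=n_cows)
    target_n = rng.integers(cfg.records_per_cow[0], cfg.records_per_cow[1] + 1,
                            size=n_cows)

    # herd test calendars, long enough to cover every lactation window
    horizon = 330 + int(cfg.scale.t_max) + cfg.test_interval
    calendars = []
    for h in range(cfg.n_herds):
        start = int(rng.integers(0, cfg.test_interval))
        days = np.arange(start, horizon, cfg.test_interval)
        days = days + rng.integers(-cfg.interval_jitter, cfg.interval_jitter + 1,
                                   size=days.size)
        calendars.append(np.unique(days))
    htd_effects: dict[tuple[int, int], float] = {}

    basis_a = BasisSpec(cfg.ka, cfg.scale, cfg.normalized)
    basis_pe = BasisSpec(kpe, cfg.scale, cfg.normalized) if kpe else None

    rows = []
    t_min, t_max = cfg.scale.t_min, cfg.scale.t_max
    for c, cow in enumerate(cows):
        h = herd_of[c]
        par = int(parity_of[c])
        freq = str(freq_of[c])
        age = age_first[c] if par == 1 else round(age_first[c] + 12.0, 1)
        x_age = (age_first[c] - np.mean(cfg.age_range)) / (np.ptp(cfg.age_range) / 2)
        cal = calendars[h]
        dims = cal - calving_day[c]
        ok = (dims >= t_min) & (dims <= t_max)
        eligible = np.flatnonzero(ok)
        if eligible.size > target_n[c]:
            # missed visits: keep a random subset of the herd's test dates
            keep = np.sort(rng.choice(eligible, size=target_n[c], replace=False))
        else:
            keep = eligible
        test_days = cal[keep]
        dims = dims[keep]
        if dims.size == 0:
            continue
        phi_a = legendre_matrix(dims.astype(float), basis_a)
        mean_curve = np.polyval(
            np.append(np.asarray(cfg.fixed_curve[par], dtype=float)[::-1], 0.0),
            2.0 * (dims - t_min) / (t_max - t_min) - 1.0,
        )
        base = cfg.base_yield[par] * (cfg.freq_multiplier if freq == "4X" else 1.0)
        y = base + mean_curve + cfg.age_effect * x_age + phi_a @ alpha[ped.order_index[cow]]
        if kpe:
            phi_pe = legendre_matrix(dims.astype(float), basis_pe)
            y = y + phi_pe @ gamma[c]
        for t_day, dim, mu in zip(test_days, dims, y):
            key = (h, int(t_day))
            if key not in htd_effects:
                htd_effects[key] = float(rng.normal(0.0, cfg.htd_sd))
            cls = assign_residual_class(int(dim))
            e = rng.normal(0.0, np.sqrt(s2e[cls - 1]))
            rows.append(
                (cow, f"H{h + 1:02d}", f"d{int(t_day):04d}", par, age, freq,
                 int(dim), round(float(mu + htd_effects[key] + e), 4))
            )

    records = pd.DataFrame(rows, columns=COLUMNS)
    truth = {
        "K_a": K_a.tolist(),
        "K_pe": K_pe.tolist() if kpe else [],
        "sigma2_e": s2e.tolist(),
        "htd_sd": cfg.htd_sd,
        "freq_multiplier": cfg.freq_multiplier,
        "seed": cfg.seed,
        "alpha": {ped.ids[i]: alpha[i].tolist() for i in range(ped.n)},
        "gamma": {cow: gamma[c].tolist() for c, cow in enumerate(cows)},
    }
    return SimOutput(pedigree=ped, records=records, truth=truth)
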