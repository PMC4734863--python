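"""Pedigree handling for the additive-genetic ("animal") effect.

The additive genetic covariance between animals is proportional to the
numerator relationship matrix A, built from sire/dam links.  Mixed-model
equations never need A itself, only its sparse inverse, which Henderson's
rules construct directly from Mendelian-sampling variances.  The dense
tabular A is kept as well: it is the natural oracle for the sparse inverse
and is used when simulating breeding values or forming dense-matrix checks.

Unknown parents are coded "0" in files and ``None`` internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

#: sentinel used in pedigree files for an unknown parent
UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically sorted pedigree (every parent precedes its offspring).

    Attributes
    ----------
    ids : list of animal identifiers in sorted order
    sire, dam : integer position of each animal's parent, -1 if unknown
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    order_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.order_index:
            self.order_index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0 and self.dam[i] < 0


def sort_and_validate(raw_entries) -> Pedigree:
    """Validate (animal, sire, dam) triples and topologically sort them.

    Parents referenced but never defined are auto-inserted as founders with
    a warning.  Duplicate animal rows and ancestry cycles raise
    :class:`PedigreeError`.
    """
    entries = []
    seen = set()
    for animal, sire, dam in raw_entries:
        animal = str(animal).strip()
        if not animal or animal == UNKNOWN:
            raise PedigreeError(f"invalid animal id {animal!r}")
        if animal in seen:
            raise PedigreeError(f"duplicate pedigree entry for animal {animal!r}")
        seen.add(animal)
        entries.append((animal, _norm_parent(sire), _norm_parent(dam)))

    phantoms = []
    for _, s, d in entries:
        for p in (s, d):
            if p is not None and p not in seen:
                seen.add(p)
                phantoms.append(p)
    if phantoms:
        warnings.warn(
            f"{len(phantoms)} parent(s) never defined as animals; "
            f"inserted as founders: {sorted(phantoms)[:10]}",
            stacklevel=2,
        )
        entries = [(p, None, None) for p in sorted(phantoms)] + entries

    parents = {a: (s, d) for a, s, d in entries}

    # depth-first topological sort with cycle detection
    order: list[str] = []
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(a: str) -> None:
        stack = [(a, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            st = state.get(node)
            if st == 2:
                continue
            if st == 1:
                raise PedigreeError(f"pedigree cycle detected involving animal {node!r}")
            state[node] = 1
            stack.append((node, True))
            for p in parents[node]:
                if p is not None and state.get(p) != 2:
                    if state.get(p) == 1:
                        raise PedigreeError(
                            f"pedigree cycle detected involving animal {p!r}"
                        )
                    stack.append((p, False))

    for a, _, _ in entries:
        if state.get(a) != 2:
            visit(a)

    index = {a: i for i, a in enumerate(order)}
    sire = np.full(len(order), -1, dtype=np.int64)
    dam = np.full(len(order), -1, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = index[a]
        if s is not None:
            sire[i] = index[s]
        if d is not None:
            dam[i] = index[d]
    return Pedigree(ids=order, sire=sire, dam=dam, order_index=index)


def _norm_parent(p) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in ("", UNKNOWN) else p


def _check_sorted(ped: Pedigree) -> None:
    idx = np.arange(ped.n)
    if np.any(ped.sire >= idx) or np.any(ped.dam >= idx):
        raise PedigreeError("pedigree is not sorted parents-first; use sort_and_validate")


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    A[i, i] = 1 + F_i with F_i = ½·A[sire_i, dam_i]; off-diagonals average
    the parent relationships; unknown parents contribute zero.  O(n²) time
    and memory — intended for oracles, simulation and moderate pedigrees.
    """
    _check_sorted(ped)
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        A[i, :i] = A[:i, i] = 0.5 * row
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    return np.diag(relationship_matrix(ped)) - 1.0


def mendelian_variances(ped: Pedigree, use_inbreeding: bool = True) -> np.ndarray:
    """Per-animal Mendelian-sampling variances d_i (in A-scale units).

    d = ½ − ¼(F_s + F_d) with both parents known, ¾ − ¼F_p with one, 1 with
    none; ignoring inbreeding gives the classical ½ / ¾ / 1 pattern.
    Note ∏ d_i = |A|, used for the REML log-determinant.
    """
    _check_sorted(ped)
    F = inbreeding(ped) if use_inbreeding else np.zeros(ped.n)
    d = np.ones(ped.n)
    for i in range(ped.n):
        s, t = ped.sire[i], ped.dam[i]
        if s >= 0 and t >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[t])
        elif s >= 0 or t >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, t)]
    return d


def a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules.

    For each animal i with Mendelian variance d_i, add 1/d_i to (i,i),
    −1/(2d_i) to (i, parent) and 1/(4d_i) to every known-parent pair.
    """
    _check_sorted(ped)
    d = mendelian_variances(ped, use_inbreeding=use_inbreeding)
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        b = 1.0 / d[i]
        par = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(b)
        for p in par:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * b, -0.5 * b]
        for p in par:
            for q in par:
                rows.append(p); cols.append(q); vals.append(0.25 * b)
    n = ped.n
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def log_det_a(ped: Pedigree, use_inbreeding: bool = True) -> float:
    """log|A| = Σ log d_i (Cholesky of A has unit off-diagonal structure)."""
    return float(np.sum(np.log(mendelian_variances(ped, use_inbreeding))))


# ---------------------------------------------------------------- file I/O

def read_pedigree_csv(path) -> Pedigree:
    """Read ``animal,sire,dam`` CSV ("0" = unknown parent) and sort it."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["animal", "sire", "dam"]
    if list(df.columns[:3]) != expected:
        raise PedigreeError(f"pedigree CSV must have header {expected}, got {list(df.columns)}")
    return sort_and_validate(df[expected].itertuples(index=False, name=None))


def write_pedigree_csv(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        {
            "animal": ped.ids,
            "sire": [ped.ids[s] if s >= 0 else UNKNOWN for s in ped.sire],
            "dam": [ped.ids[d] if d >= 0 else UNKNOWN for d in ped.dam],
        }
    )
    df.to_csv(path, index=False)
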