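"""Pedigree containers, validation, inbreeding and additive-relationship matrices.

The numerator relationship matrix A and its sparse inverse are the backbone of
both conventional (pedigree) BLUP and the pedigree part of single-step BLUP.
A-inverse is assembled by Henderson's rules with inbreeding, inbreeding
coefficients come from a Meuwissen-Luo style single pass, and the dense
tabular method serves as the reference construction for submatrices (A22).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"
#: accepted encodings of "parent unknown" on input
_UNKNOWN_CODES = {"", "0", ".", "NA", "nan", None}


class PedigreeError(ValueError):
    """Structural problem in a pedigree."""


class CycleError(PedigreeError):
    """An animal is its own ancestor."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Parents are stored as integer positions into the record order
    (-1 = unknown), so every known parent has a smaller position than its
    offspring.  Ids are opaque strings.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    flock: np.ndarray
    birth_year: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise PedigreeError("duplicate animal ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def parent_ids(self, animal: str) -> tuple[str, str]:
        i = self.index[animal]
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else UNKNOWN, self.ids[d] if d >= 0 else UNKNOWN)

    def copy(self) -> "Pedigree":
        return Pedigree(
            list(self.ids), self.sire.copy(), self.dam.copy(), self.sex.copy(),
            self.flock.copy(), self.birth_year.copy(), dict(self.index),
        )

    def to_frame(self) -> pd.DataFrame:
        sire_ids = [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire]
        dam_ids = [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam]
        return pd.DataFrame(
            {"animal": self.ids, "sire": sire_ids, "dam": dam_ids,
             "sex": self.sex, "flock": self.flock, "birth_year": self.birth_year}
        )


def _norm_parent(code) -> str | None:
    if code is None:
        return None
    s = str(code).strip()
    return None if s in _UNKNOWN_CODES else s


def sort_and_validate(records) -> Pedigree:
    """Build a validated, topologically sorted :class:`Pedigree`.

    ``records`` is an iterable of tuples ``(animal, sire, dam[, sex[, flock
    [, birth_year]]])`` (or a DataFrame with those columns) in any order.
    Parents referenced but never listed as animals are inserted as founder
    records.  Exact duplicate rows are collapsed; conflicting duplicates and
    ancestry cycles raise.
    """
    if isinstance(records, pd.DataFrame):
        cols = ["animal", "sire", "dam", "sex", "flock", "birth_year"]
        rows = [tuple(r) for r in records[[c for c in cols if c in records.columns]].itertuples(index=False)]
    else:
        rows = [tuple(r) for r in records]

    info: dict[str, tuple] = {}
    for row in rows:
        animal = str(row[0]).strip()
        s = _norm_parent(row[1]) if len(row) > 1 else None
        d = _norm_parent(row[2]) if len(row) > 2 else None
        sex = str(row[3]).strip().upper()[:1] if len(row) > 3 and str(row[3]).strip() else "U"
        flock = str(row[4]) if len(row) > 4 else "F0"
        by = int(row[5]) if len(row) > 5 and str(row[5]).strip() not in ("", "nan") else 0
        rec = (s, d, sex, flock, by)
        if animal in info:
            if info[animal] != rec:
                raise PedigreeError(f"conflicting duplicate records for animal {animal!r}")
            continue
        info[animal] = rec

    # insert phantom founder records for parents never listed as animals
    for animal, (s, d, *_rest) in list(info.items()):
        for p, psex in ((s, "M"), (d, "F")):
            if p is not None and p not in info:
                info[p] = (None, None, psex, "F0", 0)

    # Kahn topological sort (stable on insertion order)
    children: dict[str, list[str]] = {a: [] for a in info}
    indeg = {a: 0 for a in info}
    for a, (s, d, *_rest) in info.items():
        for p in (s, d):
            if p is not None:
                if p == a:
                    raise CycleError(f"animal {a!r} is recorded as its own parent")
                children[p].append(a)
                indeg[a] += 1
    order: list[str] = []
    queue = [a for a in info if indeg[a] == 0]
    while queue:
        nxt: list[str] = []
        for a in queue:
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != len(info):
        stuck = next(a for a in info if indeg[a] > 0)
        raise CycleError(f"pedigree contains an ancestry cycle involving {stuck!r}")

    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.empty(n, dtype=object)
    flock = np.empty(n, dtype=object)
    by = np.zeros(n, dtype=np.int64)
    for a, i in index.items():
        s, d, sx, fl, b = info[a]
        sire[i] = index[s] if s is not None else -1
        dam[i] = index[d] if d is not None else -1
        sex[i] = sx
        flock[i] = fl
        by[i] = b
    # sex consistency: animals used as sires must not be female, dams not male
    for i in range(n):
        for p, want in ((sire[i], "M"), (dam[i], "F")):
            if p >= 0:
                if sex[p] == "U":
                    sex[p] = want
                elif sex[p] != want:
                    raise PedigreeError(
                        f"animal {order[p]!r} is used as {'sire' if want == 'M' else 'dam'} "
                        f"but recorded sex is {sex[p]!r}"
                    )
    return Pedigree(order, sire, dam, sex, flock, by, index)


def mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Per-animal Mendelian-sampling variance d_i (in units of sigma2_a).

    d = 1 (both parents unknown), 0.75 - 0.25 F_p (one known),
    0.5 - 0.25 (F_s + F_d) (both known); unknown parents are base draws.
    """
    n = ped.n
    d = np.ones(n)
    s_known = ped.sire >= 0
    d_known = ped.dam >= 0
    Fs = np.where(s_known, F[np.clip(ped.sire, 0, None)], 0.0)
    Fd = np.where(d_known, F[np.clip(ped.dam, 0, None)], 0.0)
    both = s_known & d_known
    one_s = s_known & ~d_known
    one_d = d_known & ~s_known
    d[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    d[one_s] = 0.75 - 0.25 * Fs[one_s]
    d[one_d] = 0.75 - 0.25 * Fd[one_d]
    return d


def inbreeding_array(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients, position-aligned with the pedigree order.

    Single forward pass; for each animal the additive relationship of its
    parents is accumulated over the ancestor graph with path coefficients
    (Meuwissen-Luo style), giving F = 0.5 a(sire, dam).
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian variance weights, filled as we go
    coef = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
            continue
        if s < 0 or d < 0:
            p = s if s >= 0 else d
            D[i] = 0.75 - 0.25 * F[p]
            continue
        D[i] = 0.5 - 0.25 * (F[s] + F[d])
        # A_kk of a dummy progeny of (s, d) via weighted ancestor traversal
        heap: list[int] = []

        def push(j: int, c: float) -> None:
            if coef[j] == 0.0:
                heapq.heappush(heap, -j)
            coef[j] += c

        push(s, 0.5)
        push(d, 0.5)
        akk = D[i]
        while heap:
            j = -heapq.heappop(heap)
            c = coef[j]
            coef[j] = 0.0
            if c == 0.0:
                continue
            akk += c * c * D[j]
            if sire[j] >= 0:
                push(sire[j], 0.5 * c)
            if dam[j] >= 0:
                push(dam[j], 0.5 * c)
        F[i] = akk - 1.0
    return F


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients as a Series indexed by animal id."""
    return pd.Series(inbreeding_array(ped), index=ped.ids, name="F")


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix A by the tabular (recursive) method.

    O(n^2) memory; intended as the oracle construction and for desk-scale
    submatrices, not for national-scale pedigrees.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def a_inverse(ped: Pedigree, F: pd.Series | np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson rules).

    Accounts for inbreeding through the Mendelian-sampling variances.
    ``F`` may be omitted (computed internally), given position-aligned, or as
    a Series indexed by id.
    """
    if F is None:
        Fa = inbreeding_array(ped)
    elif isinstance(F, pd.Series):
        missing = [a for a in ped.ids if a not in F.index]
        if missing:
            raise PedigreeError(f"inbreeding coefficient missing for {missing[0]!r}")
        Fa = F.reindex(ped.ids).to_numpy(dtype=float)
    else:
        Fa = np.asarray(F, dtype=float)
        if Fa.shape[0] != ped.n:
            raise PedigreeError("inbreeding vector length does not match pedigree")
    d = mendelian_variances(ped, Fa)
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        s, de = ped.sire[i], ped.dam[i]
        add(i, i, alpha)
        for p in (s, de):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
                add(p, p, alpha / 4.0)
        if s >= 0 and de >= 0:
            add(s, de, alpha / 4.0)
            add(de, s, alpha / 4.0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def ancestor_closure(ped: Pedigree, positions) -> np.ndarray:
    """Sorted positions of the given animals plus all their ancestors."""
    seen = set()
    stack = list(positions)
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0 and p not in seen:
                stack.append(p)
    return np.array(sorted(seen), dtype=np.int64)


def subset_pedigree(ped: Pedigree, positions: np.ndarray) -> Pedigree:
    """Restriction of the pedigree to ``positions`` (must be ancestor-closed)."""
    pos = np.asarray(sorted(positions), dtype=np.int64)
    remap = {int(p): k for k, p in enumerate(pos)}
    sire = np.array([remap.get(int(ped.sire[p]), -1) if ped.sire[p] >= 0 else -1 for p in pos])
    dam = np.array([remap.get(int(ped.dam[p]), -1) if ped.dam[p] >= 0 else -1 for p in pos])
    return Pedigree(
        [ped.ids[p] for p in pos], sire, dam,
        ped.sex[pos].copy(), ped.flock[pos].copy(), ped.birth_year[pos].copy(),
    )


def relationship_submatrix(ped: Pedigree, ids: list[str]) -> np.ndarray:
    """Additive relationship among ``ids`` (A22), consistent with the full A.

    Runs the tabular method on the ancestor-restricted pedigree and extracts
    the requested rows/columns in the requested order.
    """
    try:
        want = [ped.index[a] for a in ids]
    except KeyError as e:
        raise PedigreeError(f"unknown animal id {e.args[0]!r}") from e
    closure = ancestor_closure(ped, want)
    sub = subset_pedigree(ped, closure)
    A = tabular_relationship(sub)
    pos = [sub.index[a] for a in ids]
    return A[np.ix_(pos, pos)]
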