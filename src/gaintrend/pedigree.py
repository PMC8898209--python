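"""Pedigree validation, inbreeding, and numerator relationship matrix algebra.

The additive (numerator) relationship matrix ``A`` gives the expected
additive genetic covariance between individuals implied by a pedigree;
its diagonal is ``1 + F`` where ``F`` is the inbreeding coefficient.
``A`` (or its sparse inverse, assembled directly from the pedigree by
Henderson's rules) parameterizes the genotype covariance of the animal
model used in stage-2 breeding-value estimation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = None

_NA_TOKENS = {"", "na", "n/a", ".", "0", "unknown", "none", "nan"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered trio records (individual, sire, dam).

    Unknown parents are ``None`` and are treated as unrelated, non-inbred
    founders.  Every parent precedes its offspring in ``records``.
    """

    records: list[tuple[str, Optional[str], Optional[str]]]
    cohort_year: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {rec[0]: i for i, rec in enumerate(self.records)}

    @property
    def ids(self) -> list[str]:
        return [rec[0] for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def index_of(self, item: str) -> int:
        return self._index[item]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of parent row indices, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s is not None:
                out[i, 0] = self._index[s]
            if d is not None:
                out[i, 1] = self._index[d]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r[0] for r in self.records],
                "sire": [r[1] for r in self.records],
                "dam": [r[2] for r in self.records],
                "year_of_origin": [self.cohort_year.get(r[0]) for r in self.records],
            }
        )


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix for an ordered subset of genotypes."""

    ids: list[str]
    values: np.ndarray
    F: dict[str, float]

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self._index[g] for g in ids]
        return RelationshipMatrix(
            list(ids), self.values[np.ix_(idx, idx)], {g: self.F[g] for g in ids}
        )


def _norm_parent(tok) -> Optional[str]:
    if tok is None:
        return None
    if isinstance(tok, float) and np.isnan(tok):
        return None
    s = str(tok).strip()
    if s.lower() in _NA_TOKENS:
        return None
    return s


def load_and_sort_pedigree(
    records: Iterable[Sequence],
    cohort_year: Optional[Mapping[str, float]] = None,
) -> Pedigree:
    """Validate raw trio records and return a topologically sorted pedigree.

    Parents that never appear as individuals are appended as founders.
    Duplicate ids and parent cycles are fatal; a cycle error names the
    offending path.
    """
    trios: list[tuple[str, Optional[str], Optional[str]]] = []
    seen: set[str] = set()
    for rec in records:
        ind = str(rec[0]).strip()
        if not ind or ind.lower() in _NA_TOKENS:
            raise PedigreeError(f"invalid individual id: {rec[0]!r}")
        if ind in seen:
            raise PedigreeError(f"duplicate id in pedigree: {ind!r}")
        seen.add(ind)
        sire = _norm_parent(rec[1]) if len(rec) > 1 else None
        dam = _norm_parent(rec[2]) if len(rec) > 2 else None
        if sire == ind or dam == ind:
            raise PedigreeError(f"cycle detected: {ind} -> {ind} (self-parent)")
        trios.append((ind, sire, dam))

    # implicit founders: parents never listed as individuals
    implicit = []
    for _, s, d in trios:
        for p in (s, d):
            if p is not None and p not in seen:
                seen.add(p)
                implicit.append((p, None, None))
    trios = implicit + trios

    parents = {ind: tuple(p for p in (s, d) if p is not None) for ind, s, d in trios}

    # Kahn topological sort; stable w.r.t. input order
    order: list[str] = []
    indeg = {ind: len(ps) for ind, ps in parents.items()}
    children: dict[str, list[str]] = {ind: [] for ind in parents}
    for ind, ps in parents.items():
        for p in ps:
            children[p].append(ind)
    queue = [ind for ind, _, _ in trios if indeg[ind] == 0]
    qpos = 0
    while qpos < len(queue):
        ind = queue[qpos]
        qpos += 1
        order.append(ind)
        for ch in children[ind]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(order) != len(trios):
        cyc = _find_cycle(parents, set(seen) - set(order))
        raise PedigreeError("cycle detected: " + " -> ".join(cyc))

    bytrio = {ind: (ind, s, d) for ind, s, d in trios}
    cohort = dict(cohort_year) if cohort_year else {}
    return Pedigree([bytrio[ind] for ind in order], cohort)


def _find_cycle(parents: Mapping[str, tuple], candidates: set[str]) -> list[str]:
    # DFS over the parent relation restricted to unresolved nodes
    state: dict[str, int] = {}
    stack_path: list[str] = []

    def dfs(node: str):
        state[node] = 1
        stack_path.append(node)
        for p in parents.get(node, ()):
            if state.get(p) == 1:
                i = stack_path.index(p)
                return stack_path[i:] + [p]
            if state.get(p, 0) == 0:
                found = dfs(p)
                if found:
                    return found
        state[node] = 2
        stack_path.pop()
        return None

    for start in candidates:
        if state.get(start, 0) == 0:
            found = dfs(start)
            if found:
                return found
    return ["<unresolved>"]


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV with columns ``id,sire,dam,year_of_origin``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns: {sorted(missing)}")
    cohort = {}
    if "year_of_origin" in df.columns:
        for _, row in df.iterrows():
            tok = str(row["year_of_origin"]).strip()
            if tok and tok.lower() not in _NA_TOKENS:
                cohort[str(row["id"]).strip()] = float(tok)
    recs = df[["id", "sire", "dam"]].itertuples(index=False, name=None)
    return load_and_sort_pedigree(recs, cohort)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def compute_inbreeding(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficients by the Meuwissen–Luo recursion.

    ``F(x) = a(sire, dam) / 2`` is evaluated via the Cholesky identity
    ``1 + F_i = sum_j L_ij^2 D_jj`` over the ancestors ``j`` of ``i``,
    processed youngest-first.  Founders (and individuals with both parents
    unknown) have ``F = 0``.  Cost is O(n * pedigree depth).
    """
    par = ped.parent_indices()
    n = len(ped)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = par[i]
        # within-family (Mendelian-sampling) variance fraction
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # traverse ancestors of i, youngest first
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        acc = 0.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            lj = L.pop(j)
            acc += lj * lj * D[j]
            for p in par[j]:
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
        F[i] = acc - 1.0
    return {ped.records[i][0]: float(F[i]) for i in range(n)}


def build_a_matrix(ped: Pedigree, ids: Optional[Sequence[str]] = None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    The matrix is always built over the *full* pedigree and only then
    subset to ``ids``: pruning connecting ancestors first would change
    the relationships among the survivors.
    """
    if ids is not None:
        missing = [g for g in ids if g not in ped]
        if missing:
            raise PedigreeError(f"ids not in pedigree: {missing}")
    par = ped.parent_indices()
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    F = {ped.records[i][0]: float(A[i, i] - 1.0) for i in range(n)}
    full = RelationshipMatrix(ped.ids, A, F)
    if ids is None:
        return full
    return full.subset(ids)


def build_a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Uses the Mendelian-sampling variance fraction
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (Quaas modification), so the result
    is the exact inverse of the tabular A for inbred pedigrees too.
    Unknown parents contribute through the known side only.
    """
    Fmap = compute_inbreeding(ped)
    par = ped.parent_indices()
    n = len(ped)
    F = np.array([Fmap[g] for g in ped.ids])
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            di = 0.75 - 0.25 * F[max(s, d)]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * alpha)
            add(d, s, 0.25 * alpha)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
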