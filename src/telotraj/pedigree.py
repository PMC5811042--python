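"""Pedigree container and numerator-relationship-matrix algebra.

The additive genetic covariance between animals is ``A * sigma2_a`` where A is
the numerator relationship matrix implied by the pedigree.  The mixed model
equations only need the sparse inverse of A, assembled by Henderson's rules
with inbreeding coefficients from the Meuwissen & Luo recursion; the dense A
itself (tabular method) is materialized on demand for small pedigrees and for
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["Pedigree", "PedigreeError"]

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents always precede offspring.

    ``sire`` and ``dam`` hold positional indices into ``ids`` (-1 = unknown
    parent, treated as an unrelated founder).  ``generation`` is an optional
    per-animal label recorded by the simulator.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        # topological invariant: parent index < animal index
        idx = np.arange(self.n)
        for par in (self.sire, self.dam):
            bad = (par >= idx) & (par != UNKNOWN)
            if np.any(bad):
                raise PedigreeError(
                    f"pedigree not topologically ordered at animal "
                    f"{self.ids[int(np.nonzero(bad)[0][0])]!r}; validate/reorder first"
                )

    # ---------------------------------------------------------------- basics
    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise PedigreeError(f"animal {animal_id!r} not in pedigree") from None

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    @classmethod
    def from_triples(
        cls, triples: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from (animal, sire, dam) strings; "0"/None/"" = unknown.

        Parents that never appear as animals are auto-added as founders.
        Raises on duplicate animals and on cycles (an animal its own ancestor).
        """

        def norm(v) -> str | None:
            if v is None:
                return None
            v = str(v).strip()
            return None if v in ("0", "", "NA", "na", ".") else v

        seen: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for a, s, d in triples:
            a = norm(a)
            if a is None:
                raise PedigreeError("animal id missing in pedigree row")
            if a in seen:
                raise PedigreeError(f"duplicate pedigree entry for animal {a!r}")
            seen[a] = (norm(s), norm(d))
            order.append(a)
        # closure: unknown parents become founders
        for a in list(order):
            for p in seen[a]:
                if p is not None and p not in seen:
                    seen[p] = (None, None)
                    order.append(p)
        # Kahn topological sort (deterministic: follows declaration order)
        children: dict[str, list[str]] = {a: [] for a in order}
        indeg = {a: 0 for a in order}
        for a in order:
            for p in seen[a]:
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        ready = [a for a in order if indeg[a] == 0]
        topo: list[str] = []
        while ready:
            a = ready.pop(0)
            topo.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(topo) != len(order):
            stuck = next(a for a in order if indeg[a] > 0)
            raise PedigreeError(
                f"pedigree contains a cycle: animal {stuck!r} is its own ancestor"
            )
        pos = {a: i for i, a in enumerate(topo)}
        sire = np.array(
            [pos[seen[a][0]] if seen[a][0] is not None else UNKNOWN for a in topo],
            dtype=np.int64,
        )
        dam = np.array(
            [pos[seen[a][1]] if seen[a][1] is not None else UNKNOWN for a in topo],
            dtype=np.int64,
        )
        return cls(ids=topo, sire=sire, dam=dam)

    def triples(self) -> list[tuple[str, str, str]]:
        """(animal, sire, dam) with '0' for unknown — the on-disk convention."""
        out = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] != UNKNOWN else "0"
            d = self.ids[self.dam[i]] if self.dam[i] != UNKNOWN else "0"
            out.append((a, s, d))
        return out

    # ------------------------------------------------------------- inbreeding
    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i of A = T D T'.

        d_i = 0.5 - 0.25 (F_s + F_d), with F = -1 for an unknown parent
        (equivalently d = 1 for founders, 0.75 - 0.25 F_s with one known
        parent).  Computed alongside Meuwissen-Luo inbreeding.
        """
        return self._ml()[1]

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen & Luo recursion."""
        return self._ml()[0]

    def _ml(self) -> tuple[np.ndarray, np.ndarray]:
        if getattr(self, "_ml_cache", None) is not None:
            return self._ml_cache
        n = self.n
        F = np.zeros(n)
        D = np.zeros(n)
        sire, dam = self.sire, self.dam
        L = np.zeros(n)
        for i in range(n):
            s, d = sire[i], dam[i]
            fs = F[s] if s != UNKNOWN else -1.0
            fd = F[d] if d != UNKNOWN else -1.0
            D[i] = 0.5 - 0.25 * (fs + fd)
            if s == UNKNOWN or d == UNKNOWN:
                F[i] = 0.0
                continue
            # a_ii = sum_j L_ij^2 d_j over ancestors j of i; F_i = a_ii - 1
            L[: i + 1] = 0.0
            L[i] = 1.0
            aii = 0.0
            for j in range(i, -1, -1):
                lj = L[j]
                if lj == 0.0:
                    continue
                if sire[j] != UNKNOWN:
                    L[sire[j]] += 0.5 * lj
                if dam[j] != UNKNOWN:
                    L[dam[j]] += 0.5 * lj
                aii += lj * lj * D[j]
            F[i] = aii - 1.0
        self._ml_cache = (F, D)
        return self._ml_cache

    # ----------------------------------------------------------------- A, A^-1
    def amatrix(self) -> np.ndarray:
        """Dense numerator relationship matrix by the tabular method."""
        n = self.n
        A = np.zeros((n, n))
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * A[s, :i]
            if d != UNKNOWN:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
            asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
            A[i, i] = 1.0 + 0.5 * asd
        return A

    def ainverse(self) -> sparse.csr_matrix:
        """Sparse A^-1 by Henderson's rules with Meuwissen-Luo inbreeding."""
        _, D = self._ml()
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []

        def add(r: int, c: int, v: float) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for i in range(self.n):
            s, d = self.sire[i], self.dam[i]
            alpha = 1.0 / D[i]
            add(i, i, alpha)
            for p in (s, d):
                if p != UNKNOWN:
                    add(i, p, -0.5 * alpha)
                    add(p, i, -0.5 * alpha)
                    add(p, p, 0.25 * alpha)
            if s != UNKNOWN and d != UNKNOWN:
                add(s, d, 0.25 * alpha)
                add(d, s, 0.25 * alpha)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n)
        )

    def ainverse_triplets(self) -> "pd.DataFrame":
        """Lower-triangle A^-1 entries as a (row, col, value) table.

        Rows/cols are animal ids; the on-disk exchange format for breeding
        software that consumes relationship inverses directly.
        """
        import pandas as pd

        M = sparse.tril(self.ainverse().tocoo())
        return pd.DataFrame(
            {
                "row": [self.ids[i] for i in M.row],
                "col": [self.ids[j] for j in M.col],
                "value": M.data,
            }
        )

    def log_det_a(self) -> float:
        """log |A| = sum log d_i from the A = T D T' factorization."""
        return float(np.sum(np.log(self._ml()[1])))

    # --------------------------------------------------- A times dense matrix
    def a_dot(self, x: np.ndarray) -> np.ndarray:
        """Compute A @ x without forming A, via the T D T' recursions.

        T' x is a backward accumulation (each animal pushes half its value to
        its parents), scaling by D, then T forward (each animal receives half
        the parental values).
        """
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        w = np.array(x, ndmin=2, copy=True)
        if squeeze:
            w = x[:, None].copy()
        sire, dam = self.sire, self.dam
        # w <- T' x  (process youngest first)
        for i in range(self.n - 1, -1, -1):
            if sire[i] != UNKNOWN:
                w[sire[i]] += 0.5 * w[i]
            if dam[i] != UNKNOWN:
                w[dam[i]] += 0.5 * w[i]
        w *= self._ml()[1][:, None]
        # w <- T w  (oldest first)
        for i in range(self.n):
            if sire[i] != UNKNOWN:
                w[i] += 0.5 * w[sire[i]]
            if dam[i] != UNKNOWN:
                w[i] += 0.5 * w[dam[i]]
        return w[:, 0] if squeeze else w
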