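"""Declarative model structures for sequence Markov random fields.

Two structure kinds are supported:

``moral_bn``
    A moral Bayesian network over the ``L`` sequence positions: each position
    ``l`` has an ordered parent set ``Pa(l)``, every pair of parents of a node
    must itself be linked (morality), and the induced log-linear features are
    the indicators ``f(x) = 1[x_l = b, pa(l, x) = a]``.  Position weight
    matrices (order 0), weight array matrices (order 1), higher-order Markov
    models and Bayesian trees are all special cases.

``pairwise_mrf``
    A general pairwise Markov random field with one indicator feature per
    unordered position pair and symbol pair, ``f(x) = 1[x_l1 = b1, x_l2 = b2]``,
    optionally augmented with single-position indicator blocks.

Both kinds share one flat feature layout per class, organised in *groups*.
A group is the set of features that, for the equivalent conditional-probability
parameterization, would live on one simplex: the symbol block of one
``(l, parent realization)`` context for moral BNs, or the ``S**2`` block of one
position pair for pairwise MRFs.  Exactly one feature of every group is active
on any sequence, and the last feature of every group is the *anchor* fixed to
zero in the natural (lambda) parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ModelStructure",
    "FeatureIndex",
    "make_markov_structure",
    "make_pwm_structure",
    "make_pairwise_mrf_structure",
    "count_free_parameters",
    "check_morality",
]


@dataclass(frozen=True)
class ModelStructure:
    """Dependency structure of one sequence model.

    Parameters use 0-based positions internally; user-facing messages and
    dumps report 1-based positions.
    """

    kind: str  # "moral_bn" | "pairwise_mrf"
    L: int
    S: int
    parents: tuple[tuple[int, ...], ...] | None = None
    pairs: tuple[tuple[int, int], ...] | None = None
    include_singletons: bool = False
    components: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("moral_bn", "pairwise_mrf"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.S < 2:
            raise ValueError("alphabet size S must be >= 2")
        if self.components < 1:
            raise ValueError("components must be >= 1")
        if self.kind == "moral_bn":
            if self.parents is None or len(self.parents) != self.L:
                raise ValueError("moral_bn structure needs one parent set per position")
            for ell, pa in enumerate(self.parents):
                if ell in pa:
                    raise ValueError(f"position {ell + 1} cannot be its own parent")
                if len(set(pa)) != len(pa):
                    raise ValueError(f"duplicate parents at position {ell + 1}")
                if any(p < 0 or p >= self.L for p in pa):
                    raise ValueError(f"parent out of range at position {ell + 1}")
            self.topological_order()  # raises on cycles
        else:
            if self.pairs is None:
                raise ValueError("pairwise_mrf structure needs a pair list")
            for l1, l2 in self.pairs:
                if not (0 <= l1 < l2 < self.L):
                    raise ValueError(f"pair ({l1 + 1},{l2 + 1}) not canonical (l1 < l2)")
            if len(set(self.pairs)) != len(self.pairs):
                raise ValueError("duplicate pairs")

    # ------------------------------------------------------------------
    def topological_order(self) -> tuple[int, ...]:
        """Topological ordering of the positions under the parent DAG."""
        if self.kind != "moral_bn":
            raise ValueError("topological order is defined for moral_bn structures only")
        ts: TopologicalSorter = TopologicalSorter()
        for ell in range(self.L):
            ts.add(ell, *self.parents[ell])
        try:
            return tuple(ts.static_order())
        except CycleError as exc:  # pragma: no cover - guarded at construction
            raise ValueError("parent graph contains a cycle") from exc

    @property
    def is_markov_chain(self) -> bool:
        """True iff parents are contiguous immediately-preceding windows."""
        if self.kind != "moral_bn":
            return False
        orders = [len(pa) for pa in self.parents]
        k = max(orders, default=0)
        for ell, pa in enumerate(self.parents):
            if pa != tuple(range(max(0, ell - k), ell)):
                return False
        return True

    @property
    def markov_order(self) -> int:
        if not self.is_markov_chain:
            raise ValueError("structure is not an order-k Markov chain")
        return max(len(pa) for pa in self.parents)  # type: ignore[union-attr]

    def feature_index(self) -> "FeatureIndex":
        return FeatureIndex.for_structure(self)

    def describe(self) -> str:
        """Human-readable structure dump (1-based positions)."""
        lines = [f"{self.kind}: L={self.L} S={self.S} components={self.components}"]
        if self.kind == "moral_bn":
            for ell, pa in enumerate(self.parents):  # type: ignore[union-attr]
                pa_str = ",".join(str(p + 1) for p in pa) or "-"
                lines.append(f"  Pa({ell + 1}) = {{{pa_str}}}")
        else:
            lines.append(f"  pairs: {[(a + 1, b + 1) for a, b in self.pairs]}")  # type: ignore[union-attr]
            if self.include_singletons:
                lines.append("  single-position blocks included")
        return "\n".join(lines)


@dataclass(frozen=True)
class FeatureIndex:
    """Flat per-class layout of lambda features with zero-anchoring groups.

    ``groups`` is a list of ``(start, size)`` slices into the flat feature
    vector; the anchored (fixed to zero) entry of every group is its last one.
    ``group_meta`` records what each group is: ``("pos", l, a_code)`` for a
    moral-BN context, ``("pair", l1, l2)`` or ``("single", l)`` for MRFs.
    """

    structure: ModelStructure
    groups: tuple[tuple[int, int], ...]
    group_meta: tuple[tuple, ...]
    n_features: int
    pos_offsets: tuple[int, ...] = field(default=(), repr=False)

    @staticmethod
    def for_structure(structure: ModelStructure) -> "FeatureIndex":
        groups: list[tuple[int, int]] = []
        meta: list[tuple] = []
        offset = 0
        pos_offsets: list[int] = []
        S = structure.S
        if structure.kind == "moral_bn":
            for ell in range(structure.L):
                pos_offsets.append(offset)
                n_ctx = S ** len(structure.parents[ell])  # type: ignore[index]
                for a_code in range(n_ctx):
                    groups.append((offset, S))
                    meta.append(("pos", ell, a_code))
                    offset += S
        else:
            for l1, l2 in structure.pairs:  # type: ignore[union-attr]
                pos_offsets.append(offset)
                groups.append((offset, S * S))
                meta.append(("pair", l1, l2))
                offset += S * S
            if structure.include_singletons:
                for ell in range(structure.L):
                    groups.append((offset, S))
                    meta.append(("single", ell))
                    offset += S
        return FeatureIndex(
            structure=structure,
            groups=tuple(groups),
            group_meta=tuple(meta),
            n_features=offset,
            pos_offsets=tuple(pos_offsets),
        )

    # ------------------------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_free(self) -> int:
        return self.n_features - self.n_groups

    def anchor_indices(self) -> np.ndarray:
        return np.array([start + size - 1 for start, size in self.groups], dtype=np.intp)

    def free_mask(self) -> np.ndarray:
        mask = np.ones(self.n_features, dtype=bool)
        mask[self.anchor_indices()] = False
        return mask

    def group_slices(self) -> Iterator[slice]:
        for start, size in self.groups:
            yield slice(start, start + size)

    def group_of_feature(self) -> np.ndarray:
        """Group id for every flat feature index."""
        out = np.empty(self.n_features, dtype=np.intp)
        for g, (start, size) in enumerate(self.groups):
            out[start : start + size] = g
        return out

    # ------------------------------------------------------------------
    def parent_code(self, x: np.ndarray, ell: int) -> int:
        """Big-endian code of the parent realization of position ``ell``."""
        code = 0
        for p in self.structure.parents[ell]:  # type: ignore[index]
            code = code * self.structure.S + int(x[p])
        return code

    def active_features(self, x: np.ndarray) -> np.ndarray:
        """Indices of active features on ``x``, exactly one per group.

        For moral-BN structures only the group matching the realized parent
        context at each position is hit; all other groups of that position
        contribute no active feature, so the returned array has one entry per
        position (moral BN) or per pair/singleton group (pairwise MRF).
        """
        st = self.structure
        S = st.S
        if st.kind == "moral_bn":
            out = np.empty(st.L, dtype=np.intp)
            for ell in range(st.L):
                a_code = self.parent_code(x, ell)
                out[ell] = self.pos_offsets[ell] + a_code * S + int(x[ell])
            return out
        parts = [
            off + int(x[l1]) * S + int(x[l2])
            for off, (l1, l2) in zip(self.pos_offsets, st.pairs)  # type: ignore[arg-type]
        ]
        if st.include_singletons:
            base = len(st.pairs) * S * S  # type: ignore[arg-type]
            parts.extend(base + ell * S + int(x[ell]) for ell in range(st.L))
        return np.asarray(parts, dtype=np.intp)

    def activation_matrix(self, sequences: np.ndarray) -> np.ndarray:
        """Active-feature index matrix for a batch of encoded sequences.

        ``sequences`` is an ``(N, L)`` integer array; the result is an
        ``(N, n_active)`` index matrix with one column per active group.
        """
        st = self.structure
        S = st.S
        X = np.asarray(sequences, dtype=np.intp)
        if X.ndim != 2 or X.shape[1] != st.L:
            raise ValueError(f"expected (N, {st.L}) sequence array, got {X.shape}")
        cols = []
        if st.kind == "moral_bn":
            for ell in range(st.L):
                code = np.zeros(len(X), dtype=np.intp)
                for p in st.parents[ell]:  # type: ignore[index]
                    code = code * S + X[:, p]
                cols.append(self.pos_offsets[ell] + code * S + X[:, ell])
        else:
            for off, (l1, l2) in zip(self.pos_offsets, st.pairs):  # type: ignore[arg-type]
                cols.append(off + X[:, l1] * S + X[:, l2])
            if st.include_singletons:
                base = len(st.pairs) * S * S  # type: ignore[arg-type]
                for ell in range(st.L):
                    cols.append(base + ell * S + X[:, ell])
        return np.stack(cols, axis=1)


# ----------------------------------------------------------------------
# Constructors
# ----------------------------------------------------------------------

def make_markov_structure(L: int, order: int, S: int = 4, components: int = 1) -> ModelStructure:
    """Inhomogeneous order-``k`` Markov model structure.

    ``order=0`` yields the PWM model (all parent sets empty), ``order=1`` the
    WAM model; in general ``Pa(l)`` is the window of the ``order`` immediately
    preceding positions, clipped at the sequence start.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order >= L:
        raise ValueError(f"order {order} must be smaller than sequence length {L}")
    parents = tuple(tuple(range(max(0, ell - order), ell)) for ell in range(L))
    return ModelStructure(kind="moral_bn", L=L, S=S, parents=parents, components=components)


def make_pwm_structure(L: int, S: int = 4, components: int = 1) -> ModelStructure:
    return make_markov_structure(L, 0, S, components)


def make_pairwise_mrf_structure(
    L: int, S: int = 4, include_singletons: bool = False, components: int = 1,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> ModelStructure:
    """Pairwise MRF with one ``S**2`` indicator block per unordered position pair.

    By default all ``L*(L-1)/2`` pairs are included (the full pairwise model
    used for donor-site classification: ``C(7,2) * 16 = 336`` indicators for
    DNA 7-mers).  ``pairs`` restricts the model to selected position pairs.
    """
    if L < 2:
        raise ValueError("pairwise MRF needs L >= 2")
    if pairs is None:
        pairs = tuple(combinations(range(L), 2))
    else:
        pairs = tuple(tuple(sorted(p)) for p in pairs)  # type: ignore[misc]
    return ModelStructure(
        kind="pairwise_mrf", L=L, S=S, pairs=tuple(pairs),
        include_singletons=include_singletons, components=components,
    )


# ----------------------------------------------------------------------
# Queries
# ----------------------------------------------------------------------

def count_free_parameters(structure: ModelStructure, C: int) -> int:
    """Free parameters of the C-class model: one anchor per group is fixed.

    ``(C - 1)`` free class parameters plus, per class, the features minus one
    anchor per group; for a moral BN this is ``sum_l (S - 1) * S**|Pa(l)|``.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    fi = structure.feature_index()
    return (C - 1) + C * fi.n_free


def check_morality(structure: ModelStructure) -> tuple[bool, list[tuple[int, int, int]]]:
    """Check that every pair of parents of every node is itself linked.

    Returns ``(is_moral, violations)`` where each violation is a 1-based
    ``(p1, p2, child)`` triple.
    """
    if structure.kind != "moral_bn":
        raise ValueError("morality is defined for moral_bn structures")
    violations: list[tuple[int, int, int]] = []
    for ell, pa in enumerate(structure.parents):  # type: ignore[arg-type]
        for p1, p2 in combinations(sorted(pa), 2):
            linked = p2 in structure.parents[p1] or p1 in structure.parents[p2]  # type: ignore[index]
            if not linked:
                violations.append((p1 + 1, p2 + 1, ell + 1))
    return (not violations, violations)
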