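"""Sequence-classifier likelihoods in conditional-probability and natural
parameterizations.

The joint model over a class ``c`` and a fixed-length sequence ``x`` is the
log-linear (Markov random field) form

    p(x, c | lambda) = exp(lambda_c + sum_i lambda_{c,i} f_{c,i}(x)) / Z(lambda)

with binary indicator features ``f`` determined by the model structure and a
global normalization constant ``Z`` summing over all classes and sequences.
For moral Bayesian-network structures the same distribution has an equivalent
conditional-probability (theta) parameterization

    p(x, c | theta) = theta_c * prod_l theta_{c, l, x_l, pa(l, x)}

and the two are linked by a bijection between anchored lambda vectors (one
entry per group fixed to zero) and strictly positive theta.

All probability arithmetic is carried out in the log domain; partition
constants for order-k Markov structures are computed by a position-wise
sum-product recursion, and for general structures by exhaustive enumeration
guarded at ``S**L <= 2**20`` states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .seqdata import LabeledDataset, Alphabet, DNA
from .structures import FeatureIndex, ModelStructure

__all__ = [
    "IntractableModelError",
    "LambdaParameters",
    "ThetaParameters",
    "MixtureParameters",
    "PartitionStats",
    "lambda_zeros",
    "log_score",
    "log_partition",
    "log_joint",
    "class_log_posterior",
    "lambda_to_theta",
    "theta_to_lambda",
    "theta_log_joint",
    "mixture_log_joint",
    "mixture_class_log_posterior",
    "partition_stats",
    "sample_sequences",
]

#: Enumeration guard: exhaustive sums over sequence space are refused beyond
#: this many states (covers the DNA 7-mer pairwise MRF, 4**7 = 16384, with a
#: wide margin).
ENUMERATION_GUARD = 2 ** 20


class IntractableModelError(ValueError):
    """Raised when an exact partition sum would exceed the enumeration guard."""


def _normalize_structures(structures, C: int | None = None):
    if isinstance(structures, ModelStructure):
        if C is None:
            raise ValueError("C required when passing a single shared structure")
        return (structures,) * C
    return tuple(structures)


# ======================================================================
# Parameter containers
# ======================================================================

@dataclass
class LambdaParameters:
    """Natural parameters of the joint classifier.

    ``class_values[c]`` is ``lambda_c`` (last class anchored to 0) and
    ``values[c]`` the flat per-class feature vector aligned with the class
    structure's :class:`FeatureIndex` (last entry of every group anchored to 0).
    """

    structures: tuple[ModelStructure, ...]
    class_values: np.ndarray
    values: list[np.ndarray]
    _indices: tuple[FeatureIndex, ...] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.structures = tuple(self.structures)
        self.class_values = np.asarray(self.class_values, dtype=float)
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if self._indices is None:
            self._indices = tuple(st.feature_index() for st in self.structures)
        if len(self.values) != self.C or len(self.structures) != self.C:
            raise ValueError("need one structure and one value vector per class")
        for c, (fi, v) in enumerate(zip(self._indices, self.values)):
            if v.shape != (fi.n_features,):
                raise ValueError(f"class {c + 1}: expected {fi.n_features} features, got {v.shape}")
        if not np.all(np.isfinite(self.class_values)) or not all(
            np.all(np.isfinite(v)) for v in self.values
        ):
            raise ValueError("lambda values must be finite")

    @property
    def C(self) -> int:
        return len(self.class_values)

    @property
    def feature_indices(self) -> tuple[FeatureIndex, ...]:
        return self._indices

    def copy(self) -> "LambdaParameters":
        return LambdaParameters(self.structures, self.class_values.copy(),
                                [v.copy() for v in self.values], self._indices)

    # ------------------------------------------------------------------
    # Anchoring and free-vector packing
    # ------------------------------------------------------------------
    def check_anchored(self, atol: float = 0.0) -> None:
        if abs(self.class_values[-1]) > atol:
            raise ValueError("class anchor lambda_C must be 0")
        for c, fi in enumerate(self._indices):
            anchors = self.values[c][fi.anchor_indices()]
            if np.max(np.abs(anchors), initial=0.0) > atol:
                raise ValueError(f"class {c + 1}: group anchors must be 0")

    def to_free_vector(self) -> np.ndarray:
        parts = [self.class_values[:-1]]
        parts.extend(self.values[c][fi.free_mask()] for c, fi in enumerate(self._indices))
        return np.concatenate(parts) if parts else np.zeros(0)

    @staticmethod
    def from_free_vector(structures, C: int, vec: np.ndarray) -> "LambdaParameters":
        structures = _normalize_structures(structures, C)
        indices = tuple(st.feature_index() for st in structures)
        vec = np.asarray(vec, dtype=float)
        class_values = np.zeros(C)
        class_values[: C - 1] = vec[: C - 1]
        pos = C - 1
        values = []
        for fi in indices:
            v = np.zeros(fi.n_features)
            mask = fi.free_mask()
            v[mask] = vec[pos : pos + fi.n_free]
            pos += fi.n_free
            values.append(v)
        if pos != len(vec):
            raise ValueError(f"free vector has wrong length ({len(vec)} != {pos})")
        return LambdaParameters(structures, class_values, values, indices)


def lambda_zeros(structures, C: int | None = None) -> LambdaParameters:
    """All-zero (uniform-distribution) natural parameters."""
    structures = _normalize_structures(structures, C)
    C = len(structures)
    indices = tuple(st.feature_index() for st in structures)
    return LambdaParameters(structures, np.zeros(C),
                            [np.zeros(fi.n_features) for fi in indices], indices)


@dataclass
class ThetaParameters:
    """Conditional-probability parameters of a moral-BN classifier.

    ``values[c]`` shares the flat layout of the lambda features: the slice of
    group ``(l, a)`` holds the simplex ``theta_{c, l, ., a}``.
    """

    structures: tuple[ModelStructure, ...]
    class_probs: np.ndarray
    values: list[np.ndarray]
    _indices: tuple[FeatureIndex, ...] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.structures = tuple(self.structures)
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if self._indices is None:
            self._indices = tuple(st.feature_index() for st in self.structures)
        for st in self.structures:
            if st.kind != "moral_bn":
                raise ValueError("theta parameters are defined for moral_bn structures")
        if abs(self.class_probs.sum() - 1.0) > 1e-9 or (self.class_probs < 0).any():
            raise ValueError("class probabilities must form a simplex")
        for c, (fi, v) in enumerate(zip(self._indices, self.values)):
            if v.shape != (fi.n_features,):
                raise ValueError(f"class {c + 1}: wrong theta vector length")
            if (v < -1e-12).any():
                raise ValueError("theta entries must be non-negative")
            for sl in fi.group_slices():
                if abs(v[sl].sum() - 1.0) > 1e-8:
                    raise ValueError(f"class {c + 1}: a conditional block does not sum to 1")

    @property
    def C(self) -> int:
        return len(self.class_probs)

    @property
    def feature_indices(self) -> tuple[FeatureIndex, ...]:
        return self._indices


@dataclass
class MixtureParameters:
    """Per-class mixtures of class-conditional sequence models.

    The joint model is ``p(x, c) = p(c) * sum_m w_{c,m} p_m(x | c)``: each
    class mixes the same ``M`` components' class-``c`` sequence models (their
    feature blocks, normalized per class), with per-class weights given by
    the row-wise softmax of ``weight_logits`` (shape ``(C, M)``, last column
    anchored) and class probabilities by the softmax of ``class_logits``
    (length ``C``, last entry anchored).  The components' own class-value
    blocks play no role (they cancel in the per-class normalization).
    ``M = 1`` collapses exactly to a single model.
    """

    components: list[LambdaParameters]
    weight_logits: np.ndarray
    class_logits: np.ndarray

    def __post_init__(self) -> None:
        self.weight_logits = np.asarray(self.weight_logits, dtype=float)
        self.class_logits = np.asarray(self.class_logits, dtype=float)
        if not self.components:
            raise ValueError("need at least one component")
        C = self.components[0].C
        if self.weight_logits.shape != (C, self.M):
            raise ValueError(f"weight_logits must have shape ({C}, {self.M})")
        if self.class_logits.shape != (C,):
            raise ValueError(f"class_logits must have length {C}")
        for comp in self.components:
            if comp.C != C:
                raise ValueError("components disagree on the number of classes")

    @staticmethod
    def from_single(lam: LambdaParameters) -> "MixtureParameters":
        """Wrap a single joint model as an M=1 mixture with identical joint."""
        stats = partition_stats(lam)
        return MixtureParameters(
            components=[lam.copy()],
            weight_logits=np.zeros((lam.C, 1)),
            class_logits=stats.class_log_probs - stats.class_log_probs[-1],
        )

    @property
    def M(self) -> int:
        return len(self.components)

    @property
    def C(self) -> int:
        return self.components[0].C

    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights())

    def log_weights(self) -> np.ndarray:
        return self.weight_logits - logsumexp(self.weight_logits, axis=1, keepdims=True)

    def class_log_probs(self) -> np.ndarray:
        return self.class_logits - logsumexp(self.class_logits)


# ======================================================================
# Scores and partition constants
# ======================================================================

def _encode(x) -> np.ndarray:
    return np.asarray(x, dtype=np.intp)


def log_score(lam: LambdaParameters, x, c: int) -> float:
    """Unnormalized log mass ``lambda_c + sum_i lambda_{c,i} f_{c,i}(x)``."""
    x = _encode(x)
    st = lam.structures[c]
    if len(x) != st.L:
        raise ValueError(f"sequence length {len(x)} does not match structure length {st.L}")
    fi = lam.feature_indices[c]
    return float(lam.class_values[c] + lam.values[c][fi.active_features(x)].sum())


def _position_blocks(fi: FeatureIndex, vals: np.ndarray) -> list[np.ndarray]:
    """Per-position (n_contexts, S) matrices of a moral-BN feature vector."""
    st = fi.structure
    S = st.S
    blocks = []
    for ell in range(st.L):
        n_ctx = S ** len(st.parents[ell])  # type: ignore[index]
        off = fi.pos_offsets[ell]
        blocks.append(vals[off : off + n_ctx * S].reshape(n_ctx, S))
    return blocks


def _chain_forward_backward(st: ModelStructure, fi: FeatureIndex, vals: np.ndarray):
    """Sum-product recursion along an order-k chain.

    Returns ``(log_z_seq, F, B, blocks)`` where ``F[l]`` are forward log
    messages over the parent-state space of position ``l`` and ``B[l]`` the
    matching backward messages (``B[L]`` trivial).
    """
    S, L, k = st.S, st.L, st.markov_order
    blocks = _position_blocks(fi, vals)
    F: list[np.ndarray] = [np.zeros(1)]
    for ell in range(L):
        m = min(ell, k)
        M = F[ell][:, None] + blocks[ell]  # (S**m, S)
        flat = M.reshape(-1)
        if m < k:
            F.append(flat.copy())
        else:
            F.append(logsumexp(flat.reshape(S, S ** k), axis=0))
    # Backward messages: B[l][state before l]
    B: list[np.ndarray | None] = [None] * (L + 1)
    B[L] = np.zeros(S ** min(L, k))
    for ell in range(L - 1, -1, -1):
        m = min(ell, k)
        nxt = B[ell + 1]
        if m < k:
            Bmat = nxt.reshape(S ** m, S)
        else:
            Bmat = np.tile(nxt.reshape(S ** (k - 1), S), (S, 1)) if k >= 1 else nxt.reshape(1, 1)
        B[ell] = logsumexp(blocks[ell] + Bmat, axis=1)
    log_z_seq = float(B[0][0])
    return log_z_seq, F, B, blocks


def _chain_expectations(st: ModelStructure, fi: FeatureIndex, vals: np.ndarray):
    """Per-class feature expectations E[f_i | c] for an order-k chain."""
    S, L, k = st.S, st.L, st.markov_order
    log_z_seq, F, B, blocks = _chain_forward_backward(st, fi, vals)
    probs = np.zeros(fi.n_features)
    for ell in range(L):
        m = min(ell, k)
        nxt = B[ell + 1]
        if m < k:
            Bmat = nxt.reshape(S ** m, S)
        else:
            Bmat = np.tile(nxt.reshape(S ** (k - 1), S), (S, 1)) if k >= 1 else nxt.reshape(1, 1)
        G = F[ell][:, None] + blocks[ell] + Bmat - log_z_seq
        off = fi.pos_offsets[ell]
        probs[off : off + G.size] = np.exp(G).reshape(-1)
    return log_z_seq, probs


def _guard_enumeration(st: ModelStructure) -> None:
    if st.S ** st.L > ENUMERATION_GUARD:
        raise IntractableModelError(
            f"exact enumeration over S**L = {st.S}**{st.L} states exceeds the "
            f"guard of {ENUMERATION_GUARD}; only order-k Markov structures admit "
            "the sum-product recursion"
        )


def _logscore_tensor(st: ModelStructure, fi: FeatureIndex, vals: np.ndarray) -> np.ndarray:
    """Dense ``(S,)*L`` tensor of per-sequence log scores (no class term)."""
    _guard_enumeration(st)
    S, L = st.S, st.L
    T = np.zeros((S,) * L)
    for (start, size), meta in zip(fi.groups, fi.group_meta):
        block = vals[start : start + size]
        if meta[0] == "pos":
            ell, a_code = meta[1], meta[2]
            pa = st.parents[ell]  # type: ignore[index]
            # fix the parent axes to this context, broadcast block along axis ell
            idx: list = [slice(None)] * L
            rem = a_code
            for p in reversed(pa):
                idx[p] = rem % S
                rem //= S
            free_axes = [d for d in range(L) if isinstance(idx[d], slice)]
            shape = [S if d == ell else 1 for d in free_axes]
            T[tuple(idx)] += block.reshape(shape)
        elif meta[0] == "pair":
            l1, l2 = meta[1], meta[2]
            shape = [1] * L
            shape[l1] = S
            shape[l2] = S
            T += block.reshape(S, S).reshape(shape)
        else:  # single
            ell = meta[1]
            shape = [1] * L
            shape[ell] = S
            T += block.reshape(shape)
    return T


def _class_partition(st: ModelStructure, fi: FeatureIndex, vals: np.ndarray,
                     want_expectations: bool):
    """(log Z_seq, E[f | c] or None) for one class's feature vector."""
    if st.kind == "moral_bn" and st.is_markov_chain:
        if want_expectations:
            return _chain_expectations(st, fi, vals)
        log_z_seq, _, _, _ = _chain_forward_backward(st, fi, vals)
        return log_z_seq, None
    T = _logscore_tensor(st, fi, vals)
    log_z_seq = float(logsumexp(T.reshape(-1)))
    if not want_expectations:
        return log_z_seq, None
    p = np.exp(T - log_z_seq)
    probs = np.zeros(fi.n_features)
    L, S = st.L, st.S
    if st.kind == "moral_bn":
        for ell in range(L):
            pa = st.parents[ell]  # type: ignore[index]
            axes = tuple(sorted(set(range(L)) - set(pa) - {ell}))
            marg = p.sum(axis=axes) if axes else p
            # marg axes are sorted(pa + (ell,)); reorder to (pa..., ell)
            kept = sorted(set(pa) | {ell})
            perm = [kept.index(q) for q in list(pa) + [ell]]
            marg = np.transpose(marg, perm)
            off = fi.pos_offsets[ell]
            probs[off : off + marg.size] = marg.reshape(-1)
        return log_z_seq, probs
    for (start, size), meta in zip(fi.groups, fi.group_meta):
        if meta[0] == "pair":
            l1, l2 = meta[1], meta[2]
            axes = tuple(q for q in range(L) if q not in (l1, l2))
            marg = p.sum(axis=axes)
            probs[start : start + size] = marg.reshape(-1)
        else:
            ell = meta[1]
            axes = tuple(q for q in range(L) if q != ell)
            probs[start : start + size] = p.sum(axis=axes)
    return log_z_seq, probs


@dataclass
class PartitionStats:
    """Partition constant and model moments of a joint classifier."""

    log_z: float
    log_z_seq: np.ndarray          # per class, sequence-space partition
    class_log_probs: np.ndarray    # log p(c)
    expectations: list[np.ndarray] | None  # per class, E[f_i | c]


def partition_stats(lam: LambdaParameters, want_expectations: bool = False) -> PartitionStats:
    log_z_seq = np.empty(lam.C)
    exps: list[np.ndarray] = []
    for c, st in enumerate(lam.structures):
        z, e = _class_partition(st, lam.feature_indices[c], lam.values[c], want_expectations)
        log_z_seq[c] = z
        if want_expectations:
            exps.append(e)
    class_terms = lam.class_values + log_z_seq
    log_z = float(logsumexp(class_terms))
    return PartitionStats(
        log_z=log_z,
        log_z_seq=log_z_seq,
        class_log_probs=class_terms - log_z,
        expectations=exps if want_expectations else None,
    )


def log_partition(lam: LambdaParameters) -> float:
    """``log Z(lambda)``: log-sum-exp over all classes and sequences."""
    return partition_stats(lam).log_z


def log_joint(lam: LambdaParameters, x, c: int) -> float:
    """Normalized ``log p(x, c | lambda)``."""
    return log_score(lam, x, c) - log_partition(lam)


def class_log_posterior(lam: LambdaParameters, x) -> np.ndarray:
    """``log p(c | x, lambda)`` for every class; the partition cancels."""
    scores = np.array([log_score(lam, x, c) for c in range(lam.C)])
    return scores - logsumexp(scores)


# ======================================================================
# theta <-> lambda
# ======================================================================

def lambda_to_theta(lam: LambdaParameters) -> ThetaParameters:
    """Map natural parameters to conditional probabilities by marginalization.

    ``theta_c`` is the marginal class probability of ``p_lambda`` and
    ``theta_{c,l,b,a}`` the conditional probability of symbol ``b`` at ``l``
    given parent realization ``a`` under ``p_lambda(. | c)``.
    """
    for st in lam.structures:
        if st.kind != "moral_bn":
            raise ValueError("lambda_to_theta requires moral_bn structures")
    stats = partition_stats(lam, want_expectations=True)
    values = []
    for c, fi in enumerate(lam.feature_indices):
        probs = stats.expectations[c]  # type: ignore[index]
        out = np.empty_like(probs)
        for sl in fi.group_slices():
            mass = probs[sl].sum()
            if mass <= 0:
                raise ValueError(
                    "a parent realization has zero marginal mass; cannot condition")
            out[sl] = probs[sl] / mass
        values.append(out)
    return ThetaParameters(lam.structures, np.exp(stats.class_log_probs), values,
                           lam.feature_indices)


def theta_log_joint(theta: ThetaParameters, x, c: int) -> float:
    """Directed factorization ``log theta_c + sum_l log theta_{c,l,x_l,pa}``."""
    x = _encode(x)
    fi = theta.feature_indices[c]
    return float(np.log(theta.class_probs[c])
                 + np.log(theta.values[c][fi.active_features(x)]).sum())


def _theta_to_lambda_construct(theta: ThetaParameters) -> LambdaParameters:
    C = theta.C
    class_values = np.log(theta.class_probs.copy())
    values = []
    for c, st in enumerate(theta.structures):
        fi = theta.feature_indices[c]
        v = np.log(theta.values[c].copy())
        order = st.topological_order()
        S = st.S
        meta_by_pos: dict[int, list[tuple[int, int, int]]] = {}
        for (start, size), meta in zip(fi.groups, fi.group_meta):
            meta_by_pos.setdefault(meta[1], []).append((start, size, meta[2]))
        pos_in_order = {p: i for i, p in enumerate(order)}
        for ell in reversed(order):
            pa = st.parents[ell]  # type: ignore[index]
            for start, size, a_code in meta_by_pos[ell]:
                d = v[start + size - 1]
                v[start : start + size] -= d
                if d == 0.0:
                    continue
                if not pa:
                    class_values[c] += d
                    continue
                # decode the context symbols of this group
                ctx = {}
                rem = a_code
                for p in reversed(pa):
                    ctx[p] = rem % S
                    rem //= S
                # absorb into the topologically-last parent's blocks
                p_last = max(pa, key=lambda p: pos_in_order[p])
                others = [p for p in pa if p != p_last]
                pa_p = st.parents[p_last]  # type: ignore[index]
                if any(q not in pa_p for q in others):
                    raise ValueError("structure is not moral; cannot re-anchor")
                slot = {q: i for i, q in enumerate(pa_p)}
                kp = len(pa_p)
                for start_p, size_p, ap_code in meta_by_pos[p_last]:
                    digits = []
                    rem = ap_code
                    for _ in range(kp):
                        digits.append(rem % S)
                        rem //= S
                    digits.reverse()
                    if all(digits[slot[q]] == ctx[q] for q in others):
                        v[start_p + ctx[p_last]] += d
        values.append(v)
    class_values -= class_values[-1]
    return LambdaParameters(theta.structures, class_values, values, theta.feature_indices)


def _theta_free_vector(theta: ThetaParameters) -> np.ndarray:
    parts = [theta.class_probs[:-1]]
    parts.extend(theta.values[c][fi.free_mask()]
                 for c, fi in enumerate(theta.feature_indices))
    return np.concatenate(parts)


def _theta_to_lambda_solve(theta: ThetaParameters) -> LambdaParameters:
    from scipy.optimize import least_squares

    target = _theta_free_vector(theta)
    structures, C = theta.structures, theta.C

    def residual(vec):
        lam = LambdaParameters.from_free_vector(structures, C, vec)
        return _theta_free_vector(lambda_to_theta(lam)) - target

    x0 = _theta_to_lambda_construct(theta).to_free_vector()
    # start from zero to keep the route independent of the constructive path
    sol = least_squares(residual, np.zeros_like(x0), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return LambdaParameters.from_free_vector(structures, C, sol.x)


def theta_to_lambda(theta: ThetaParameters, method: str = "construct") -> LambdaParameters:
    """Unique anchored natural parameters with ``p_lambda = p_theta``.

    Strictly positive ``theta`` is required (boundary values have no finite
    natural-parameter image).  The default constructive route takes within-
    group log-ratios and absorbs each group's anchor value into the blocks of
    the topologically last parent, walking the DAG in reverse topological
    order; ``method="solve"`` solves the marginalization map numerically
    instead.
    """
    for c in range(theta.C):
        if (theta.values[c] <= 0).any() or (theta.class_probs <= 0).any():
            raise ValueError(
                "theta has zero entries; no finite lambda image exists "
                "(use a positive prior / pseudo-counts)")
    if method == "construct":
        return _theta_to_lambda_construct(theta)
    if method == "solve":
        return _theta_to_lambda_solve(theta)
    raise ValueError(f"unknown method {method!r}")


# ======================================================================
# Mixtures
# ======================================================================

def component_class_log_joint(mix: MixtureParameters, x, c: int, m: int) -> float:
    """``log [p(c) w_{c,m} p_m(x | c)]`` for one component."""
    comp = mix.components[m]
    st = comp.structures[c]
    fi = comp.feature_indices[c]
    x = _encode(x)
    if len(x) != st.L:
        raise ValueError(f"sequence length {len(x)} does not match structure length {st.L}")
    log_z_seq, _ = _class_partition(st, fi, comp.values[c], False)
    s = float(comp.values[c][fi.active_features(x)].sum()) - log_z_seq
    return float(mix.class_log_probs()[c] + mix.log_weights()[c, m] + s)


def mixture_log_joint(mix: MixtureParameters, x, c: int) -> float:
    """``log [p(c) sum_m w_{c,m} p_m(x | c)]`` via log-sum-exp.

    At ``M = 1`` (constructed via :meth:`MixtureParameters.from_single`) this
    reduces exactly to :func:`log_joint` of the wrapped model.
    """
    terms = [component_class_log_joint(mix, x, c, m) for m in range(mix.M)]
    return float(logsumexp(terms))


def mixture_class_log_posterior(mix: MixtureParameters, x) -> np.ndarray:
    vals = np.array([mixture_log_joint(mix, x, c) for c in range(mix.C)])
    return vals - logsumexp(vals)


# ======================================================================
# Sampling
# ======================================================================

def _ancestral_sample(theta: ThetaParameters, c: int, rng: np.random.Generator) -> np.ndarray:
    st = theta.structures[c]
    fi = theta.feature_indices[c]
    S = st.S
    x = np.zeros(st.L, dtype=np.int8)
    for ell in st.topological_order():
        a_code = fi.parent_code(x, ell)
        off = fi.pos_offsets[ell] + a_code * S
        probs = theta.values[c][off : off + S]
        x[ell] = rng.choice(S, p=probs / probs.sum())
    return x


def _sample_class_lambda(lam: LambdaParameters, c: int, n: int,
                         rng: np.random.Generator) -> list[np.ndarray]:
    st = lam.structures[c]
    if st.kind == "moral_bn":
        theta = lambda_to_theta(lam)
        return [_ancestral_sample(theta, c, rng) for _ in range(n)]
    fi = lam.feature_indices[c]
    T = _logscore_tensor(st, fi, lam.values[c])
    flat = T.reshape(-1)
    p = np.exp(flat - logsumexp(flat))
    draws = rng.choice(len(flat), size=n, p=p / p.sum())
    return [np.array(np.unravel_index(d, T.shape), dtype=np.int8) for d in draws]


def sample_sequences(params, n: int, seed: int, alphabet: Alphabet = DNA) -> LabeledDataset:
    """Draw ``n`` i.i.d. ``(x, c)`` pairs from the joint model.

    Moral-BN models are sampled ancestrally; general MRFs by exact categorical
    draws over the enumerated sequence space (subject to the guard).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(params, ThetaParameters):
        C = params.C
        classes = rng.choice(C, size=n, p=params.class_probs / params.class_probs.sum())
        seqs = [_ancestral_sample(params, int(c), rng) for c in classes]
        return LabeledDataset(seqs, classes.astype(np.intp), alphabet, C)
    if isinstance(params, LambdaParameters):
        stats = partition_stats(params)
        C = params.C
        class_p = np.exp(stats.class_log_probs)
        classes = rng.choice(C, size=n, p=class_p / class_p.sum())
        seqs: list[np.ndarray] = [None] * n  # type: ignore[list-item]
        for c in range(C):
            idx = np.flatnonzero(classes == c)
            if len(idx) == 0:
                continue
            drawn = _sample_class_lambda(params, c, len(idx), rng)
            for i, s in zip(idx, drawn):
                seqs[i] = s
        return LabeledDataset(seqs, classes.astype(np.intp), alphabet, C)
    if isinstance(params, MixtureParameters):
        C, M = params.C, params.M
        mass = (np.exp(params.class_log_probs())[:, None] * params.weights()).reshape(-1)
        mass = mass / mass.sum()  # index c * M + m
        draws = rng.choice(C * M, size=n, p=mass)
        seqs = [None] * n  # type: ignore[list-item]
        classes = (draws // M).astype(np.intp)
        for c in range(C):
            for m in range(M):
                idx = np.flatnonzero(draws == c * M + m)
                if len(idx) == 0:
                    continue
                drawn = _sample_class_lambda(params.components[m], c, len(idx), rng)
                for i, s in zip(idx, drawn):
                    seqs[i] = s
        return LabeledDataset(seqs, classes, alphabet, C)
    raise TypeError(f"cannot sample from {type(params).__name__}")
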