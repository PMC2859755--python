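"""Synthetic benchmark generators emulating the two case-study data shapes.

``tfbs_like`` mimics a transcription-factor binding-site study: a small set
of aligned fixed-length motif occurrences (default 257 sites of 16 bp, the
scale of a typical TFBS collection) against background windows cut from
longer genomic-like sequences (default 680 100-mers from a higher-order
homogeneous Markov chain with mild composition bias, chunked into motif-length
windows).

``splice_like`` mimics a donor-splice-site study: short highly conserved
sites (default 7 bp) whose distribution mixes latent subclasses and carries
*non-adjacent* pairwise dependencies, generated from planted pairwise MRFs;
the background is an order-1 Markov chain emitted directly as windows.

The planted generating models are returned alongside the data so parameter-
recovery and model-mismatch experiments can compare against ground truth.
All generation is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .models import (
    LambdaParameters,
    MixtureParameters,
    ThetaParameters,
    lambda_zeros,
    sample_sequences,
    theta_to_lambda,
)
from .seqdata import DNA, Alphabet, LabeledDataset, chunk_sequences
from .structures import make_pairwise_mrf_structure, make_pwm_structure

__all__ = [
    "ScenarioSpec",
    "MarkovBackground",
    "make_planted_model",
    "generate_benchmark",
]

#: non-adjacent position pairs carrying planted dependencies in splice_like
DEFAULT_COUPLED_PAIRS = ((0, 4), (1, 5), (2, 6))


@dataclass
class ScenarioSpec:
    """Shape and effect-size knobs of one synthetic benchmark.

    ``divergence`` is the mean per-position Kullback-Leibler divergence (nats)
    of the planted foreground symbol distributions from uniform — roughly the
    per-position information content of the motif.  ``n_bg`` counts raw
    background sequences of length ``bg_len`` before windowing.
    """

    scenario: str = "tfbs_like"
    L_fg: int | None = None
    n_fg: int | None = None
    n_bg: int | None = None
    bg_len: int | None = None
    bg_order: int | None = None
    divergence: float | None = None
    subclasses: int | None = None
    coupling: float = 3.0
    coupled_pairs: tuple[tuple[int, int], ...] = DEFAULT_COUPLED_PAIRS
    seed: int = 0
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        defaults = {
            "tfbs_like": dict(L_fg=16, n_fg=257, n_bg=680, bg_len=100,
                              bg_order=3, divergence=0.4, subclasses=2),
            "splice_like": dict(L_fg=7, n_fg=4000, n_bg=8000, bg_len=None,
                                bg_order=1, divergence=0.4, subclasses=2),
        }
        if self.scenario not in defaults:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        d = defaults[self.scenario]
        for key, val in d.items():
            if getattr(self, key) is None:
                setattr(self, key, val)
        if self.bg_len is None:
            self.bg_len = self.L_fg
        if self.n_fg <= 0 or self.n_bg <= 0:
            raise ValueError("n_fg and n_bg must be positive")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.subclasses < 1:
            raise ValueError("subclasses must be >= 1")
        for l1, l2 in self.coupled_pairs:
            if not (0 <= l1 < l2 < self.L_fg):
                raise ValueError("coupled pair outside the motif")


# ----------------------------------------------------------------------
# Effect-size calibration
# ----------------------------------------------------------------------

def _consensus_profile(kappa: float, S: int) -> np.ndarray:
    """Mean of Dirichlet(kappa e_b + 1): consensus mass (kappa+1)/(kappa+S)."""
    p = np.full(S, 1.0 / (kappa + S))
    p[0] = (kappa + 1.0) / (kappa + S)
    return p


def _solve_kappa(divergence: float, S: int) -> float:
    """Concentration giving the requested KL-from-uniform of the mean profile."""
    if divergence <= 0:
        return 0.0
    max_kl = np.log(S) * 0.999

    def f(kappa):
        p = _consensus_profile(kappa, S)
        return float((p * np.log(p * S)).sum()) - min(divergence, max_kl)

    return float(brentq(f, 0.0, 1e6))


# ----------------------------------------------------------------------
# Background model
# ----------------------------------------------------------------------

@dataclass
class MarkovBackground:
    """Homogeneous order-``r`` Markov chain over the alphabet.

    ``transitions[m]`` (for ``m = 0..r``) is the ``(S**m, S)`` conditional
    table used at position ``m`` (the order-``r`` table is reused from
    position ``r`` onward).  Context codes are big-endian in the preceding
    symbols.
    """

    order: int
    S: int
    transitions: list[np.ndarray]

    @staticmethod
    def random(order: int, S: int, rng: np.random.Generator,
               bias: float = 1.0) -> "MarkovBackground":
        """Draw a chain with mild composition bias.

        A global composition is drawn close to uniform and per-context
        transition rows around it; ``bias=0`` yields the exactly uniform
        chain (used by null scenarios).
        """
        if bias == 0.0:
            tables = [np.full((S ** m, S), 1.0 / S) for m in range(order + 1)]
            return MarkovBackground(order, S, tables)
        comp = rng.dirichlet(np.full(S, 30.0 / bias))
        tables = []
        for m in range(order + 1):
            rows = rng.dirichlet(8.0 * S * comp, size=S ** m)
            tables.append(rows)
        return MarkovBackground(order, S, tables)

    def sample(self, length: int, n: int, rng: np.random.Generator) -> list[np.ndarray]:
        X = np.zeros((n, length), dtype=np.int8)
        codes = np.zeros(n, dtype=np.intp)  # big-endian code of the last min(pos, order) symbols
        for pos in range(length):
            m = min(pos, self.order)
            rows = self.transitions[m][codes]
            u = rng.random(n)
            X[:, pos] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
            if self.order > 0:
                codes = (codes * self.S + X[:, pos]) % (self.S ** self.order)
        return list(X)

    def conditional(self, context: Sequence[int]) -> np.ndarray:
        m = min(len(context), self.order)
        code = 0
        for sym in list(context)[-m:]:
            code = code * self.S + int(sym)
        return self.transitions[m][code]


# ----------------------------------------------------------------------
# Planted foreground models
# ----------------------------------------------------------------------

def _planted_pwm_theta(spec: ScenarioSpec, rng: np.random.Generator) -> ThetaParameters:
    S = spec.alphabet.size
    st = make_pwm_structure(spec.L_fg, S)
    kappa = _solve_kappa(spec.divergence, S)
    vals = np.empty(st.feature_index().n_features)
    for ell in range(spec.L_fg):
        if kappa == 0.0:
            p = np.full(S, 1.0 / S)
        else:
            consensus = rng.integers(S)
            a = np.ones(S)
            a[consensus] += kappa
            p = rng.dirichlet(a)
            p = np.clip(p, 1e-6, None)
            p /= p.sum()
        vals[ell * S : (ell + 1) * S] = p
    return ThetaParameters((st,), np.array([1.0]), [vals])


def _planted_splice_lambda(spec: ScenarioSpec, consensus: np.ndarray,
                           component: int) -> LambdaParameters:
    """One subclass of the planted donor-like motif.

    The subclasses emulate the compensation structure reported for donor-site
    subpopulations: they share the overall consensus and one non-adjacent
    coupled pair (the first planted pair), but each subclass (i) is strongly
    conserved at the alternating interior positions 2, 4, 6 with a consensus
    *shifted* by the subclass index, and (ii) couples a different one of the
    remaining planted pairs, leaving the others independent.  A single
    pairwise model sees only diluted couplings and averaged conservation,
    while a mixture recovers the per-subclass structure.
    """
    S = spec.alphabet.size
    st = make_pairwise_mrf_structure(
        spec.L_fg, S, include_singletons=True, pairs=spec.coupled_pairs)
    lam = lambda_zeros(st, 1)
    fi = lam.feature_indices[0]
    kappa = _solve_kappa(spec.divergence, S)
    p_cons = (kappa + 1.0) / (kappa + S)
    f_shared = float(np.log(p_cons / ((1.0 - p_cons) / (S - 1)))) if kappa > 0 else 0.0
    f_strong = float(np.log(0.85 / (0.15 / (S - 1)))) if spec.divergence > 0 else 0.0
    subclass_positions = {p for p in range(1, spec.L_fg, 2)}
    v = lam.values[0]
    n_pairs = len(spec.coupled_pairs)
    own = 1 + component % max(1, n_pairs - 1) if n_pairs > 1 else 0
    pair_no = 0
    coupling_matrix = spec.coupling * np.eye(S)
    for (start, size), meta in zip(fi.groups, fi.group_meta):
        if meta[0] == "pair":
            if pair_no == 0 or pair_no == own:
                v[start : start + size] = coupling_matrix.reshape(-1)
            pair_no += 1
        elif meta[1] in subclass_positions:
            v[start + (consensus[meta[1]] + component) % S] = f_strong
        else:  # shared consensus field
            v[start + consensus[meta[1]]] = f_shared
    return lam


def make_planted_model(spec: ScenarioSpec):
    """Generating models of one scenario: ``(foreground, background)``.

    The foreground is a single-class model (or a mixture of ``subclasses``
    equally weighted components); the background is a homogeneous Markov
    chain of order ``bg_order``.  Same seed, same models.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.alphabet.size
    if spec.scenario == "tfbs_like":
        comps = [_planted_pwm_theta(spec, rng) for _ in range(spec.subclasses)]
        fg = comps[0] if spec.subclasses == 1 else MixtureParameters(
            components=[theta_to_lambda(t) for t in comps],
            weight_logits=np.zeros((1, spec.subclasses)),
            class_logits=np.zeros(1))
    else:
        consensus = rng.integers(S, size=spec.L_fg)
        comps_l = [_planted_splice_lambda(spec, consensus, m)
                   for m in range(spec.subclasses)]
        fg = comps_l[0] if spec.subclasses == 1 else MixtureParameters(
            components=comps_l, weight_logits=np.zeros((1, spec.subclasses)),
            class_logits=np.zeros(1))
    bg = MarkovBackground.random(spec.bg_order, S, rng,
                                 bias=0.0 if spec.divergence == 0 else 1.0)
    return fg, bg


def generate_benchmark(spec: ScenarioSpec
                       ) -> tuple[LabeledDataset, LabeledDataset, dict]:
    """Sample one benchmark: foreground sites, background windows, and truth.

    Background sequences of length ``bg_len`` are cut into non-overlapping
    motif-length windows.  The returned truth dictionary carries the planted
    models for parameter-recovery tests.
    """
    fg_model, bg_model = make_planted_model(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]).generate_state(1)[0])
    fg_data = sample_sequences(fg_model, spec.n_fg,
                               seed=int(rng.integers(2 ** 31)), alphabet=spec.alphabet)
    fg_data = LabeledDataset(fg_data.sequences, np.zeros(len(fg_data), dtype=np.intp),
                             spec.alphabet, 2)
    raw_bg = bg_model.sample(spec.bg_len, spec.n_bg, rng)
    bg_data = LabeledDataset(raw_bg, np.ones(len(raw_bg), dtype=np.intp),
                             spec.alphabet, 2)
    if spec.bg_len != spec.L_fg:
        bg_data = chunk_sequences(bg_data, spec.L_fg)
    truth = {
        "spec": spec,
        "foreground_model": fg_model,
        "background_model": bg_model,
        "coupled_pairs": spec.coupled_pairs if spec.scenario == "splice_like" else (),
    }
    return fg_data, bg_data, truth
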