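"""MAP and MSP training of MRF sequence classifiers under the shared prior.

Both learning principles maximize (prior x likelihood); they differ in the
likelihood term:

* MAP (generative): joint likelihood of sequences and labels.  With the
  conjugate transformed-Dirichlet prior and a moral-BN structure the optimum
  is available in closed form as smoothed relative frequencies; all other
  cases (general MRFs, mixtures) are optimized by quasi-Newton ascent with
  analytic gradients.
* MSP (discriminative): conditional likelihood of the labels given the
  sequences.  The data term is partition-free (the normalization constant
  cancels in the class posterior); only the prior contributes model
  expectations to the gradient.

Mixtures are trained by direct gradient ascent on the (supervised) posterior
rather than EM, so MAP and MSP share one optimization path.  Gradients
returned by the objective functions are in the packed free-parameter
coordinates (anchored entries excluded), matching what the optimizer sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .models import (
    LambdaParameters,
    MixtureParameters,
    ThetaParameters,
    _class_partition,
    lambda_zeros,
    partition_stats,
    theta_to_lambda,
)
from .priors import HyperParameters, bdeu_hyperparameters
from .seqdata import CountTable, LabeledDataset, count_statistics
from .structures import ModelStructure

__all__ = [
    "TrainingConfig",
    "Classifier",
    "map_objective",
    "map_closed_form",
    "msp_objective",
    "train",
    "decision_scores",
    "posterior_matrix",
]


@dataclass
class TrainingConfig:
    """Settings of one training run.

    ``ess`` is the per-class equivalent sample size (scalar = same for all
    classes).  ``restarts=None`` picks the default: one run for single models,
    four jittered runs for mixtures.
    """

    principle: str = "MAP"
    ess: float | Sequence[float] = 4.0
    tolerance: float = 1e-6
    max_iterations: int = 5000
    restarts: int | None = None
    init_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.principle not in ("MAP", "MSP"):
            raise ValueError("principle must be 'MAP' or 'MSP'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.restarts is not None and self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class Classifier:
    """A trained classifier: structures, fitted parameters, and provenance."""

    structures: tuple[ModelStructure, ...]
    params: LambdaParameters | MixtureParameters
    hyper: HyperParameters
    principle: str
    training_log: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def C(self) -> int:
        return self.params.C

    def decision_scores(self, dataset: LabeledDataset) -> np.ndarray:
        return decision_scores(self.params, dataset)


# ======================================================================
# Objectives
# ======================================================================

def _prior_terms(lam: LambdaParameters, hyper: HyperParameters, stats):
    """Value and per-entry gradient of the prior given partition stats."""
    value = float(hyper.ess @ lam.class_values)
    for c in range(lam.C):
        value += float(hyper.alpha[c] @ lam.values[c])
    value -= hyper.total * stats.log_z
    p_c = np.exp(stats.class_log_probs)
    g_class = hyper.ess - hyper.total * p_c
    g_vals = [hyper.alpha[c] - hyper.total * p_c[c] * stats.expectations[c]
              for c in range(lam.C)]
    return value, g_class, g_vals


def _pack_grad(lam: LambdaParameters, g_class: np.ndarray,
               g_vals: list[np.ndarray]) -> np.ndarray:
    parts = [g_class[:-1]]
    parts.extend(g_vals[c][fi.free_mask()] for c, fi in enumerate(lam.feature_indices))
    return np.concatenate(parts)


def map_objective(lam: LambdaParameters, counts: CountTable, hyper: HyperParameters
                  ) -> tuple[float, np.ndarray]:
    """Log posterior (up to a constant) and its free-coordinate gradient.

    ``value = sum_i (n_i + alpha_i) lambda_i - (N + alpha) log Z(lambda)``;
    the gradient entries are ``(n_i + alpha_i) - (N + alpha) E_p[f_i]`` with
    model expectations from sum-product or enumeration.
    """
    stats = partition_stats(lam, want_expectations=True)
    post = hyper.shifted_by_counts(counts)
    value, g_class, g_vals = _prior_terms(lam, post, stats)
    return value, _pack_grad(lam, g_class, g_vals)


def map_closed_form(counts: CountTable, hyper: HyperParameters) -> ThetaParameters:
    """Smoothed relative frequencies: the exact MAP optimum for moral BNs.

    ``theta_c = (N_c + alpha_c) / (N + alpha)`` and
    ``theta_{c,l,b,a} = (n_{c,l,b,a} + alpha_{c,l,b,a}) / sum_b' (...)``.
    Positivity of the hyper-parameters guarantees a strictly positive result.
    """
    class_probs = (counts.class_counts + hyper.ess) / (counts.N + hyper.total)
    values = []
    for c, st in enumerate(counts.structures):
        if st.kind != "moral_bn":
            raise ValueError("closed-form MAP requires moral_bn structures")
        fi = st.feature_index()
        smoothed = counts.feature_counts[c] + hyper.alpha[c]
        out = np.empty_like(smoothed)
        for sl in fi.group_slices():
            out[sl] = smoothed[sl] / smoothed[sl].sum()
        values.append(out)
    return ThetaParameters(counts.structures, class_probs, values)


def _activation_matrices(lam_structures, indices, dataset: LabeledDataset):
    X = dataset.as_matrix()
    return [fi.activation_matrix(X) for fi in indices]


def _score_matrix(lam: LambdaParameters, acts: list[np.ndarray]) -> np.ndarray:
    N = acts[0].shape[0]
    S = np.empty((N, lam.C))
    for c in range(lam.C):
        S[:, c] = lam.class_values[c] + lam.values[c][acts[c]].sum(axis=1)
    return S


def msp_objective(lam: LambdaParameters, dataset: LabeledDataset,
                  hyper: HyperParameters) -> tuple[float, np.ndarray]:
    """Log supervised posterior and its free-coordinate gradient.

    ``value = sum_n log p(c_n | x_n, lambda) + log h(lambda | alpha)``; the
    data part of the gradient is the usual softmax residual (partition-free),
    the prior part contributes ``alpha_i - alpha E_p[f_i]``.
    """
    acts = _activation_matrices(lam.structures, lam.feature_indices, dataset)
    S = _score_matrix(lam, acts)
    lse = logsumexp(S, axis=1)
    data_value = float(S[np.arange(len(S)), dataset.labels].sum() - lse.sum())
    W = -np.exp(S - lse[:, None])
    W[np.arange(len(S)), dataset.labels] += 1.0
    stats = partition_stats(lam, want_expectations=True)
    p_value, g_class, g_vals = _prior_terms(lam, hyper, stats)
    g_class = g_class + W.sum(axis=0)
    for c in range(lam.C):
        g = np.bincount(acts[c].ravel(),
                        weights=np.repeat(W[:, c], acts[c].shape[1]),
                        minlength=len(g_vals[c]))
        g_vals[c] = g_vals[c] + g
    return data_value + p_value, _pack_grad(lam, g_class, g_vals)


# ======================================================================
# Mixture packing and objectives
# ======================================================================

def _mix_pack(mix: MixtureParameters) -> np.ndarray:
    """Free vector: class logits, weight logits, per-component feature blocks."""
    parts = [mix.class_logits[:-1], mix.weight_logits[:, :-1].reshape(-1)]
    for comp in mix.components:
        parts.extend(comp.values[c][fi.free_mask()]
                     for c, fi in enumerate(comp.feature_indices))
    return np.concatenate(parts)


def _mix_unpack(structures, C: int, M: int, vec: np.ndarray) -> MixtureParameters:
    class_logits = np.zeros(C)
    class_logits[: C - 1] = vec[: C - 1]
    pos = C - 1
    logits = np.zeros((C, M))
    logits[:, : M - 1] = vec[pos : pos + C * (M - 1)].reshape(C, M - 1)
    pos += C * (M - 1)
    indices = tuple(st.feature_index() for st in structures)
    comps = []
    for _ in range(M):
        values = []
        for fi in indices:
            v = np.zeros(fi.n_features)
            v[fi.free_mask()] = vec[pos : pos + fi.n_free]
            pos += fi.n_free
            values.append(v)
        comps.append(LambdaParameters(structures, np.zeros(C), values, indices))
    if pos != len(vec):
        raise ValueError("mixture free vector has wrong length")
    return MixtureParameters(components=comps, weight_logits=logits,
                             class_logits=class_logits)


def _mixture_objective(vec: np.ndarray, structures, C: int, M: int,
                       acts: list[np.ndarray], labels: np.ndarray,
                       hyper: HyperParameters, principle: str,
                       weight_alpha: np.ndarray) -> tuple[float, np.ndarray]:
    """(Supervised) posterior of a per-class mixture and its packed gradient.

    The joint is ``p(x, c) = p(c) sum_m w_{c,m} p_m(x | c)`` with per-class
    normalized component models.  MAP sums ``log p(x_n, c_n)``, MSP the label
    posteriors.  The prior is the class-block transformed Dirichlet on the
    class logits, the per-class Eq.-style conjugate prior on every component
    (full per-class ESS each), and symmetric Dirichlet(alpha_c / M) weights.
    """
    mix = _mix_unpack(structures, C, M, vec)
    N = acts[0].shape[0]
    logw = mix.log_weights()
    w = np.exp(logw)
    log_pc = mix.class_log_probs()
    p_class = np.exp(log_pc)

    # per-component, per-class sequence partitions and expectations
    log_z = np.empty((M, C))
    exps: list[list[np.ndarray]] = []
    sj = np.empty((M, N, C))
    for m, comp in enumerate(mix.components):
        row = []
        for c, st in enumerate(structures):
            z, e = _class_partition(st, comp.feature_indices[c], comp.values[c], True)
            log_z[m, c] = z
            row.append(e)
            sj[m, :, c] = comp.values[c][acts[c]].sum(axis=1) - z
        exps.append(row)
    smix = logsumexp(sj + logw.T[:, None, :], axis=0)  # (N, C): log sum_m w p_m(x|c)
    score = smix + log_pc[None, :]                      # log p(x, c)

    n_class = np.bincount(labels, minlength=C).astype(float)
    if principle == "MAP":
        value = float(score[np.arange(N), labels].sum())
        W = np.zeros((N, C))
        W[np.arange(N), labels] = 1.0
        g_class_data = n_class - N * p_class
    else:
        lse = logsumexp(score, axis=1)
        value = float(score[np.arange(N), labels].sum() - lse.sum())
        W = -np.exp(score - lse[:, None])
        W[np.arange(N), labels] += 1.0
        g_class_data = W.sum(axis=0)

    # priors: class block + weights
    alpha_tot = hyper.total
    value += float(hyper.ess @ log_pc) + float((weight_alpha[:, None] * logw).sum())
    g_class = g_class_data + hyper.ess - alpha_tot * p_class

    r = np.exp(sj + logw.T[:, None, :] - smix[None, :, :])  # resp. within class

    grad_parts = [g_class[:-1]]
    g_logits = np.einsum("nc,mnc->cm", W, r) - (W.sum(axis=0)[:, None] * w)
    g_logits += weight_alpha[:, None] * (1.0 - M * w)
    grad_parts.append(g_logits[:, : M - 1].reshape(-1))

    for m, comp in enumerate(mix.components):
        Wm = W * r[m]  # (N, C)
        col_tot = Wm.sum(axis=0)
        for c in range(C):
            # component prior: sum_i alpha_i lambda_i - alpha_c log Z_seq_c
            value += float(hyper.alpha[c] @ comp.values[c]) - hyper.ess[c] * log_z[m, c]
            g = np.bincount(acts[c].ravel(),
                            weights=np.repeat(Wm[:, c], acts[c].shape[1]),
                            minlength=len(comp.values[c]))
            g += hyper.alpha[c] - (col_tot[c] + hyper.ess[c]) * exps[m][c]
            grad_parts.append(g[comp.feature_indices[c].free_mask()])
    return value, np.concatenate(grad_parts)


def _mixture_init(structures, C: int, M: int, data: LabeledDataset,
                  hyper: HyperParameters, rng: np.random.Generator) -> np.ndarray:
    """Data-driven mixture start: random hard split, moment-matched blocks.

    Each class's sequences are partitioned uniformly at random into ``M``
    parts; component ``m`` starts from group-wise smoothed log relative
    frequencies of its part (the exact conditional estimate for moral-BN
    blocks, a moment-matching surrogate for MRF blocks).  This breaks the
    label-swap symmetry with structure present in the data rather than with
    isotropic noise, which plain jitter often fails to escape.
    """
    indices = tuple(st.feature_index() for st in structures)
    comp_vecs: list[np.ndarray] = [[] for _ in range(M)]
    assign = rng.integers(M, size=len(data))
    X = data.as_matrix()
    for m in range(M):
        parts = []
        for c, fi in enumerate(indices):
            sel = (data.labels == c) & (assign == m)
            counts = np.zeros(fi.n_features)
            if sel.any():
                act = fi.activation_matrix(X[sel])
                counts = np.bincount(act.ravel(), minlength=fi.n_features).astype(float)
            smoothed = counts + hyper.alpha[c]
            v = np.zeros(fi.n_features)
            for sl in fi.group_slices():
                block = np.log(smoothed[sl] / smoothed[sl].sum())
                v[sl] = block - block[-1]
            parts.append(v[fi.free_mask()])
        comp_vecs[m] = np.concatenate(parts)
    head = np.zeros((C - 1) + C * (M - 1))
    return np.concatenate([head] + comp_vecs)


# ======================================================================
# Training driver
# ======================================================================

def _as_structures(structure, C: int) -> tuple[ModelStructure, ...]:
    if isinstance(structure, ModelStructure):
        return (structure,) * C
    return tuple(structure)


def _run_optimizer(fun_grad, x0: np.ndarray, config: TrainingConfig):
    trace: list[float] = []

    def neg(v):
        val, grad = fun_grad(v)
        trace.append(max(val, trace[-1]) if trace else val)  # best-so-far
        return -val, -grad

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.max_iterations,
                            "gtol": config.tolerance, "ftol": 1e-13})
    return res.x, -float(res.fun), bool(res.success), trace, res.nit


def train(config: TrainingConfig, structure, train_data: LabeledDataset) -> Classifier:
    """Fit a classifier by the configured principle.

    MAP with a single moral-BN model uses the closed form (smoothed relative
    frequencies mapped to natural parameters); every other combination runs
    the quasi-Newton optimizer from seeded initializations and keeps the best
    restart.  Identical config, seed and data give bit-identical results.
    """
    C = train_data.n_classes
    structures = _as_structures(structure, C)
    M = structures[0].components
    if any(st.components != M for st in structures):
        raise ValueError("all class structures must agree on mixture components")
    hyper = bdeu_hyperparameters(structures, config.ess, C=C)
    counts = count_statistics(train_data, structures)

    all_moral = all(st.kind == "moral_bn" for st in structures)
    if config.principle == "MAP" and M == 1 and all_moral:
        theta = map_closed_form(counts, hyper)
        lam = theta_to_lambda(theta)
        value, _ = map_objective(lam, counts, hyper)
        log = [{"restart": 0, "objective": value, "iterations": 0,
                "method": "closed_form"}]
        return Classifier(structures, lam, hyper, config.principle, log, True)

    restarts = config.restarts if config.restarts is not None else (4 if M > 1 else 1)
    rng = np.random.default_rng(config.seed)
    acts = [fi.activation_matrix(train_data.as_matrix())
            for fi in (st.feature_index() for st in structures)]
    labels = train_data.labels
    weight_alpha = hyper.ess / M

    if M == 1:
        if config.principle == "MAP":
            def fun_grad(vec):
                lam = LambdaParameters.from_free_vector(structures, C, vec)
                return map_objective(lam, counts, hyper)
        else:
            def fun_grad(vec):
                lam = LambdaParameters.from_free_vector(structures, C, vec)
                return msp_objective(lam, train_data, hyper)
        n_par = len(lambda_zeros(structures, C).to_free_vector())
    else:
        def fun_grad(vec):
            return _mixture_objective(vec, structures, C, M, acts, labels,
                                      hyper, config.principle, weight_alpha)
        feat_free = sum(st.feature_index().n_free for st in structures)
        n_par = (C - 1) + C * (M - 1) + M * feat_free

    best = None
    log: list[dict] = []
    for r in range(restarts):
        if M > 1:
            x0 = _mixture_init(structures, C, M, train_data, hyper, rng)
        elif r > 0:
            x0 = rng.normal(scale=config.init_scale, size=n_par)
        else:
            x0 = np.zeros(n_par)
        x, value, success, trace, nit = _run_optimizer(fun_grad, x0, config)
        log.append({"restart": r, "objective": value, "iterations": int(nit),
                    "converged": success, "trace_tail": trace[-5:]})
        if best is None or value > best[1]:
            best = (x, value, success)
    assert best is not None
    x, value, success = best
    if not success:
        import warnings
        warnings.warn("optimizer did not report convergence; returning best iterate",
                      stacklevel=2)
    if M == 1:
        params: LambdaParameters | MixtureParameters = \
            LambdaParameters.from_free_vector(structures, C, x)
    else:
        params = _mix_unpack(structures, C, M, x)
    return Classifier(structures, params, hyper, config.principle, log, success)


# ======================================================================
# Scoring
# ======================================================================

def posterior_matrix(params: LambdaParameters | MixtureParameters,
                     dataset: LabeledDataset) -> np.ndarray:
    """(N, C) matrix of log class posteriors; partitions cancel row-wise."""
    if isinstance(params, LambdaParameters):
        acts = [fi.activation_matrix(dataset.as_matrix())
                for fi in params.feature_indices]
        S = _score_matrix(params, acts)
    else:
        from .models import _class_partition

        comps = params.components
        acts = [fi.activation_matrix(dataset.as_matrix())
                for fi in comps[0].feature_indices]
        logw = params.log_weights()
        parts = []
        for comp in comps:
            sj = np.empty((acts[0].shape[0], params.C))
            for c, st in enumerate(comp.structures):
                z, _ = _class_partition(st, comp.feature_indices[c], comp.values[c], False)
                sj[:, c] = comp.values[c][acts[c]].sum(axis=1) - z
            parts.append(sj)
        S = logsumexp(np.stack(parts) + logw.T[:, None, :], axis=0)
        S = S + params.class_log_probs()[None, :]
    return S - logsumexp(S, axis=1, keepdims=True)


def decision_scores(params: LambdaParameters | MixtureParameters,
                    dataset: LabeledDataset, positive_class: int = 0) -> np.ndarray:
    """Log posterior odds of the positive (foreground) class per sequence."""
    lp = posterior_matrix(params, dataset)
    rest = np.delete(lp, positive_class, axis=1)
    return lp[:, positive_class] - logsumexp(rest, axis=1)
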