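# Methods

## Model family

All classifiers are joint distributions over a class label `c ∈ {1..C}` and a
fixed-length sequence `x ∈ Σ^L` of the log-linear form

    p(x, c | λ) = exp( λ_c + Σ_i λ_{c,i} f_{c,i}(x) ) / Z(λ),

where the `f_{c,i} ∈ {0,1}` are indicator features determined by a
`ModelStructure` and `Z(λ)` sums the numerator over all classes and all
sequences.  Two structure kinds are supported:

* **moral Bayesian networks** — per-position parent sets `Pa(ℓ)` whose
  parents are pairwise linked; features are `1[x_ℓ = b, pa(ℓ,x) = a]`.
  Order-k Markov chains (PWM at k=0, WAM at k=1), and trees, are special
  cases.  These models admit an equivalent conditional-probability (θ)
  parameterization `p(x,c|θ) = θ_c Π_ℓ θ_{c,ℓ,x_ℓ,pa(ℓ,x)}`.
* **pairwise MRFs** — one `S²` indicator block per unordered position pair
  (`C(L,2)·S²` features; 336 for DNA 7-mers), optionally with single-position
  blocks.  Pairwise blocks span single-position effects, so the pure pairwise
  model loses no expressiveness by omitting them; the optional singleton
  block exists for planted-model construction and is off by default so the
  336-feature count of the classical donor-site model is reproduced.

Features are laid out flat per class in *groups* (one conditional context, or
one position pair).  Exactly one feature per group is active on any sequence,
and the last feature of each group is anchored to 0, which makes the map
between θ and anchored λ a bijection on strictly positive θ and gives both
parameterizations the same number of free parameters.

Per-class structures may differ (e.g. PWM foreground, order-2 background);
the same-structure case is the default in tests.

## θ ↔ λ

`lambda_to_theta` marginalizes the joint: `θ_c` is the class marginal and
`θ_{c,ℓ,b,a}` the conditional `P(x_ℓ=b | pa=a, c)` under `p_λ`, computed by a
position-wise sum–product recursion for order-k chains and by exhaustive
enumeration otherwise (guarded at `S^L ≤ 2^20` states; larger general MRFs
raise an explicit error rather than approximate).  `theta_to_lambda` is
constructive: starting from `λ = log θ`, each group's anchor value is
subtracted from the group and absorbed into the blocks of the topologically
last parent (legal exactly when the DAG is moral), walking positions in
reverse topological order; class-block shifts are absorbed by `Z`.  A
numerical least-squares fallback (`method="solve"`) inverts the
marginalization map directly; the two agree to optimizer precision and the
round-trip identity is enforced in tests at 1e-8.

All probability arithmetic is in the log domain via log-sum-exp; partition
constants never appear unlogged in any interface, and the class posterior is
computed from raw scores so the partition cancels exactly.

## The prior

The conjugate prior in λ is, up to a constant,

    log h(λ|α) = Σ_c α_c λ_c + Σ_{c,i} α_{c,i} λ_{c,i} − α log Z(λ).

It is the pushforward of the product-Dirichlet prior through the bijection
whenever the hyper-parameters satisfy the consistency condition (all block
pseudo-counts derive from one joint pseudo-data mass), and it extends
verbatim to arbitrary feature groups.  `pushforward_check` validates the
identity numerically: at random λ points it compares the prior with
`log h_θ(t(λ)|α) + log|det J_t(λ)|`, the Jacobian estimated by central
differences with step `1e-5·(1+|λ|)`; for consistent α the difference is
constant (the dropped normalizer), and the report flags non-constant
differences as consistency violations.  The prior is evaluated unnormalized —
every optimizer touches it only through its value and gradient, so the
constant is irrelevant; validation treats it as a free offset.

Hyper-parameters are constructed by the BDeu rule from per-class equivalent
sample sizes: `α_{c,ℓ,b,a} = α_c/(S·S^{|Pa(ℓ)|})` for moral-BN blocks,
`α_c/S²` per pairwise block entry and `α_c/S` per singleton entry (uniform
pseudo-data restricted to the features' positions — one defensible extension
of the moral-BN rule to arbitrary groups).  Mixtures use the full per-class
ESS for every component's prior plus a symmetric Dirichlet(α_c/M) on the
component weights, preserving the pseudo-data interpretation per component.

## Training

* **MAP, single moral-BN model** — closed form: smoothed relative
  frequencies `(n+α)/Σ(n+α)`, mapped to λ.  The class-independent prior makes
  the objective separate per class.
* **Everything else** — L-BFGS-B ascent with analytic gradients on the free
  coordinates.  Defaults: gradient tolerance 1e-6 (max-abs), at most 5000
  iterations, 1 restart for single models and 4 for mixtures.  Gradients
  combine data terms (softmax residuals for MSP; partition-free) with prior
  terms, which require model expectations `E[f_i]` from the chain recursion
  or the enumerated joint.

* **Mixtures** are per-class: `p(x,c) = p(c) Σ_m w_{c,m} p_m(x|c)` with
  per-class normalized component models, mixture-level class logits, and
  per-class softmax weights.  They are trained by direct gradient ascent on
  the full (supervised) posterior — not EM — so MAP and MSP share one code
  path.  Components are initialized from a random hard split of each class's
  training sequences (group-wise smoothed log relative frequencies per part):
  isotropic jitter around zero reliably fails to break the label-swap
  symmetry for MRF mixtures, whereas the data-driven start does.  Identical
  configuration, seed and data give bit-identical classifiers.

## Performance measures

Scores are foreground posterior log-odds; every metric depends on them only
through ranking (monotone-transform invariance is tested).  AUC-ROC uses
trapezoidal integration with tied scores grouped (equal to the Mann–Whitney
statistic with ties counted ½).  AUC-PR interpolates between achievable
(TP, FP) points with FP linear in TP — the nonlinear PR-space interpolation —
and integrates each segment in closed form,

    ∫ precision d(recall) = [ ΔTP − k·log((TP_b+k)/(TP_a+k)) ] / (P(1+s)),

with `s = ΔFP/ΔTP` and `k = (FP_a − s·TP_a)/(1+s)`; the segment leaving the
origin has constant precision, extending the curve flat toward recall 0 (a
test set with all scores equal therefore integrates to the prevalence).  A
plain trapezoidal variant is available behind a flag for sensitivity
analysis.  Fixed-sensitivity thresholds take the largest threshold with
Sn ≥ target; fixed-specificity the smallest threshold with Sp ≥ target —
finite-sample conventions the underlying definitions leave open, chosen here
and documented rather than inferred.

The repeated stratified-holdout driver partitions each class independently
(test size `floor(h·N+0.5)`), subsamples one training set per fraction shared
by all classifiers, scores all of them on the same held-out test set, and
reports means and standard errors (sample SD/√repeats; presentation layers
may plot 2×SE whiskers).  The fixed-split driver trains a classifier grid on
one pre-partitioned train/test pair.

## Synthetic benchmarks

`tfbs_like` emulates a binding-site study: 257 aligned 16-bp sites against
680 background 100-mers from a homogeneous order-3 Markov chain with mild
composition bias, cut into non-overlapping 16-bp windows (windowing
convention: remainders discarded).  Foreground positions draw their symbol
distributions from Dirichlet(κ·e_consensus + 1), with κ calibrated so the
mean profile's KL divergence from uniform equals the `divergence` knob;
the default 0.4 nats/position (≈0.6 bit) matches typical TFBS information
content.  The default foreground is a two-subclass mixture: real TFBS
collections are heterogeneous, and this mild misspecification of the fitted
PWM family is precisely the regime in which the discriminative principle's
advantage manifests; with a single planted PWM the family is exactly
well-specified and MAP is, correctly, as good as MSP.

`splice_like` emulates a donor-site study: 7-mers with strong consensus,
non-adjacent dependencies and two latent subclasses, against an order-1
background.  Subclasses share the overall consensus and one coupled pair
(default (1,5) in 1-based positions, coupling 3.0 on matching symbols), and
differ in (i) strongly conserved alternating interior positions whose
consensus is shifted by the subclass index and (ii) one exclusive coupled
pair each — the compensation-like structure in which a single pairwise model
sees only diluted couplings and averaged conservation while a mixture
recovers the per-subclass strengths.  Defaults n_fg=4000, n_bg=8000 scale
the reference donor-site study down about twofold rather than tenfold,
because subclass mixtures are only reliably learnable from thousands of
sites (verified on held-out foreground likelihood).  Generation is exact:
ancestral sampling for moral-BN models, categorical draws over the
enumerated joint for MRFs, vectorized chain sampling for backgrounds.

What passing these benchmarks does **not** show: synthetic foregrounds are
draws from the stated model family, so they lack alignment errors,
compositional covariates, strand ambiguity and the long-tailed subclass
structure of curated site collections; absolute metric values are not
comparable to results on real data, only the qualitative orderings are.

## Desk scales and numerical choices

The case-study replications in the test suite run at desk scale: the
binding-site comparison uses 30 holdout repeats over fractions
{0.1, 0.25, 0.5, 1.0} with a PWM foreground and an order-2 background model;
the splice comparison uses 20 data seeds with a fixed-split protocol and a
large freshly sampled test set (4000 + 8000) per seed.  Experiment grids use
optimizer tolerance 1e-2 and one mixture restart — orders of magnitude looser
than the training defaults, with no measurable effect on the resulting
metrics at these scales.  Enumeration is guarded at `2^20` states; boundary
θ (zero entries) has no λ image and raises with a pointer to positive
priors; a Dirichlet density at a boundary point returns ±∞ according to the
block's pseudo-count, flagged rather than silently clipped.

## Known limitations

No approximate inference: general MRFs beyond the enumeration guard are
rejected, not approximated (pseudo-likelihood and MCMC are out of scope).
Variable-length likelihoods, structure learning, position-specific alphabets
and reverse-strand handling are out of scope; users supply both strands if
desired.  The closed-form MAP path requires consistent hyper-parameters;
inconsistent α are accepted by the gradient path but void the pushforward
equivalence (and are flagged by the validator).
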