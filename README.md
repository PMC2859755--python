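# seqmrf

Recognition of short DNA signal sequences — transcription-factor binding
sites, splice sites, and similar motifs — with statistical models from the
Markov-random-field (MRF) family, trained generatively or discriminatively
**under the same prior**.

## The problem

Most motif classifiers are special cases of one log-linear family: position
weight matrices (PWM), weight array matrices (WAM), higher-order
inhomogeneous Markov models, Bayesian trees and moral Bayesian networks, up
to general pairwise MRFs and their mixtures.  Comparative studies of
generative (maximum a-posteriori, MAP) versus discriminative (maximum
supervised posterior, MSP) parameter estimation have traditionally put a
product-Dirichlet prior on the conditional-probability parameterization for
MAP but a Gaussian or Laplace prior on the natural parameterization for MSP —
so observed performance differences conflate the learning principle with the
prior.  This package removes that confound.

## The model and prior

The joint model over a class *c* and a fixed-length sequence *x* is

    p(x, c | λ) = exp( λ_c + Σ_i λ_{c,i} f_{c,i}(x) ) / Z(λ)

with binary indicator features *f* fixed by the model structure, one
anchored-to-zero parameter per simplex-equivalent group, and a global
normalization constant *Z*.  For moral Bayesian-network structures this is a
bijective reparameterization of θ-space (class probabilities and conditional
probability tables), and pushing the product-Dirichlet prior h_θ(θ|α)
through the bijection yields the **transformed Dirichlet prior**

    h(λ | α)  ∝  exp( Σ_c α_c λ_c + Σ_{c,i} α_{c,i} λ_{c,i} )  /  Z(λ)^α ,
    α = Σ_c α_c ,

valid for arbitrary indicator-feature MRFs, conjugate to the likelihood
(posterior = prior with α shifted by the observed feature counts), log-concave,
Gaussian-like near its maximum and Laplace-like in the tails.  Hyper-parameters
come from the BDeu rule — uniform pseudo-data of per-class mass α_c (the
*equivalent sample size*) — giving `α_{c,ℓ,b,a} = α_c / (S · S^{|Pa(ℓ)|})`,
which guarantees likelihood equivalence across equivalent structures.

MAP maximizes prior × joint likelihood (closed form for moral BNs: smoothed
relative frequencies); MSP maximizes prior × conditional label likelihood
(quasi-Newton ascent with analytic gradients).  Both use the same prior, so
observed differences are attributable to the principle alone.

## Worked example

`examples/01_bdeu_prior.py` derives the pseudo-counts of a PWM and a WAM on
the DNA alphabet from one equivalent sample size of 32:

```
equivalent sample size per class: 32
PWM pseudo-count per (position, symbol) entry: 8
WAM pseudo-count, first position:              8
WAM pseudo-count, conditional entries:         2
```

Both tables represent the same pseudo-data: 32 uniform sequences contain each
mono-nucleotide 8 times and each dinucleotide-conditional context 2 times.
The same script probes the log prior along one natural-parameter coordinate
(quadratic near 0, linear in the tails):

```
  lambda =  -20.0  ->    -24.394
  lambda =   -2.0  ->     -6.571
  lambda =   +0.0  ->     -5.545
  lambda =   +2.0  ->     -7.363
  lambda =  +20.0  ->    -60.000
```

`examples/02_map_vs_msp_tfbs.py` runs a stratified-holdout comparison on a
binding-site-shaped synthetic benchmark (257 aligned 16-bp sites), training a
PWM-foreground / order-2-background classifier by MAP and MSP with identical
hyper-parameters (ESS 4 foreground, 1024 background):

```
mean AUC-PR (5 holdout repeats):
classifier    MAP    MSP
fraction
0.1         0.841  0.872
0.5         0.907  0.918
1.0         0.883  0.911
```

The discriminatively trained classifier leads at every training-set size —
a difference now attributable to the principle, not the prior.

`examples/03_splice_mixture_mrf.py` compares an order-1 Markov model, the
full pairwise MRF over 7-mers (336 indicator features) and a 2-component MRF
mixture on donor-site-like data with planted non-adjacent dependencies and
two latent subclasses:

```
  order-1 Markov model     AUC-ROC = 0.9309
  pairwise MRF             AUC-ROC = 0.9763
  2-component MRF mixture  AUC-ROC = 0.9772
```

`examples/04_prior_pushforward.py` validates the change of variables
numerically: the transformed prior equals the product-Dirichlet density of
the mapped parameters times the finite-difference Jacobian determinant, up to
a constant (spread ≈ 1e-10 over random points), and a consistency-violating
hyper-parameter vector is flagged.

## Command line

```sh
seqmrf simulate --scenario tfbs_like --seed 1 --out-dir bench/
seqmrf train    --fg bench/foreground.fa --bg bench/background.fa \
                --principle MSP --order 0 --ess 4 1024 --out clf.json
seqmrf evaluate --classifier clf.json --fg test_fg.fa --bg test_bg.fa --out report.json
seqmrf compare  --fg bench/foreground.fa --bg bench/background.fa \
                --preset tfbs --repeats 100 --seed 1 --out table.tsv
```

`--preset tfbs` runs the MAP-vs-MSP holdout sweep; `--preset splice` runs the
fixed-split grid of MM / mixMM / MRF / mixMRF under both principles.

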