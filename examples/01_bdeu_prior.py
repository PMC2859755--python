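"""BDeu hyper-parameters and the shape of the transformed Dirichlet prior.

Builds PWM and WAM structures on the DNA alphabet, derives their Dirichlet
pseudo-counts from one equivalent sample size, and probes the log prior along
a single natural-parameter coordinate.
"""

import numpy as np

from seqmrf import (
    bdeu_hyperparameters,
    lambda_zeros,
    make_markov_structure,
    make_pwm_structure,
    mrf_log_prior,
)

ESS = 32.0

pwm = make_pwm_structure(L=16, S=4)
wam = make_markov_structure(L=16, order=1, S=4)

h_pwm = bdeu_hyperparameters(pwm, ESS, C=1)
h_wam = bdeu_hyperparameters(wam, ESS, C=1)

print(f"equivalent sample size per class: {ESS:g}")
print(f"PWM pseudo-count per (position, symbol) entry: {h_pwm.alpha[0][0]:g}")
print(f"WAM pseudo-count, first position:              {h_wam.alpha[0][0]:g}")
print(f"WAM pseudo-count, conditional entries:         {h_wam.alpha[0][4]:g}")
# All three derive from one set of uniform pseudo-data of mass 32: 32/4 = 8
# mono-nucleotide counts, 32/16 = 2 dinucleotide-conditional counts.

st = make_pwm_structure(L=1, S=4)
hyper = bdeu_hyperparameters(st, 4.0, C=1)


def log_prior_along_first_coordinate(t: float) -> float:
    lam = lambda_zeros(st, 1)
    lam.values[0][0] = t
    return mrf_log_prior(lam, hyper)


print("\nlog prior along one free coordinate (unnormalized):")
for t in (-20.0, -2.0, 0.0, 2.0, 20.0):
    print(f"  lambda = {t:+6.1f}  ->  {log_prior_along_first_coordinate(t):9.3f}")
# Near 0 the curve is quadratic (Gaussian-like); in the far tails it is
# linear with slopes alpha_i and alpha_i - alpha (Laplace-like).
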