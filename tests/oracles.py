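"""Independent oracles used by the test suite.

These deliberately avoid the library's Monte Carlo path: tail
probabilities come from a semi-analytic integral (the error rate
integrated in closed form conditional on copy number and round count,
the remaining two dimensions by quadrature), and small brute-force
iterations stand in for closed-form inversions.
"""

import math
from itertools import combinations

import numpy as np

G = 16_569
MU_LOW = 2.8e-8
MU_HIGH = 5.6e-7



def rounds_sum_pdf(proliferating, step=0.05):
    """Exact density of Y = X1 + X2 (+ X3), a sum of independent uniforms.

    Inclusion-exclusion formula for the sum of k uniforms on (0, w_i):
    f(t) = sum_S (-1)^|S| (t - sum_{i in S} w_i)_+^{k-1} / ((k-1)! prod w_i),
    evaluated on a grid after shifting by the interval lower bounds.
    """
    bounds = [(10.0, 80.0), (180.0, 380.0)]
    if proliferating:
        bounds.append((81.0, 101.0))
    widths = [hi - lo for lo, hi in bounds]
    shift = sum(lo for lo, _ in bounds)
    total = sum(widths)
    k = len(widths)
    y = np.arange(shift, shift + total + step / 2, step)
    t = y - shift
    f = np.zeros_like(t)
    for r in range(k + 1):
        for sub in combinations(widths, r):
            f += (-1.0) ** r * np.clip(t - sum(sub), 0.0, None) ** (k - 1)
    f /= math.factorial(k - 1) * math.prod(widths)
    return y, f


def tail_ge_analytic(threshold, proliferating=True, n_l=1501, step=0.05):
    """P(B >= threshold) under the reference model, by quadrature.

    Conditional on L and Y, B >= t iff mu >= t / (C 10^L Y) with
    C = G/2, and mu is uniform, so the conditional probability is a
    clipped linear function integrated over L ~ Unif(2,4) and the
    convolution density of Y.
    """
    c = G / 2.0
    y, py = rounds_sum_pdf(proliferating, step)
    l_grid = np.linspace(2.0, 4.0, n_l)
    inner = np.empty(n_l)
    for i, l in enumerate(l_grid):               # keep memory flat
        mu_min = threshold / (c * 10.0 ** l * y)
        p_cond = np.clip((MU_HIGH - mu_min) / (MU_HIGH - MU_LOW), 0.0, 1.0)
        inner[i] = np.trapezoid(p_cond * py, y)  # E over Y given L
    return float(np.trapezoid(inner, l_grid) / 2.0)     # L density = 1/2


def project_iterative(h0, s, n_rounds, convention="halved"):
    """Round-by-round odds update; oracle for the closed-form projection."""
    a = s / 2.0 if convention == "halved" else s
    if h0 in (0.0, 1.0):
        return h0
    odds = h0 / (1.0 - h0)
    for _ in range(n_rounds):
        odds *= 1.0 + a
    return odds / (1.0 + odds)


def rounds_to_threshold_iterative(h0, s, target, convention="halved",
                                  n_max=100_000):
    """Smallest n with the iterative projection >= target."""
    for n in range(n_max + 1):
        if project_iterative(h0, s, n, convention) >= target:
            return n
    raise AssertionError("target unreachable within n_max")
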