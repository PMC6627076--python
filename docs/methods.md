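# Methods

## The model

mtburden models the accumulation of de novo somatic mtDNA mutations per
cell with age. The central assumption is that mutations arise only from
replication errors of the mitochondrial polymerase POLG, so the burden a
cell carries is proportional to the number of times its mtDNA population
has been copied. Per cell,

    B = G · Z · (X1 + X2 + X3) · µ / 2

- **G** — mtDNA genome length, fixed at 16,569 bp (the reference genome).
- **Z** — mtDNA copies per cell; log10 Z ~ Unif(2, 4), i.e. 100–10,000
  copies with geometric mean 1000, reflecting the spread across tissues.
- **µ** — POLG per-base per-replication error rate, uniform on
  [2.8×10⁻⁸, 5.6×10⁻⁷] (one misincorporation per 3.6×10⁷ to 1.8×10⁶
  bases synthesized, with proofreading).
- **X1** — replication rounds during development, Unif(10, 80), mean 45:
  floor(log2 3.72×10¹³) complete doublings from zygote to adult census.
- **X2** — turnover-driven rounds after birth, Unif(180, 380), mean 280
  at age 70: one population-doubling-equivalent per mtDNA half-life
  (default 3 months = 91.3125 days), age·365.25/half-life.
- **X3** — extra rounds in proliferating lineages, Unif(81, 101), mean 91
  at age 70: HSC self-renewal every 40 weeks, age·52.18/cycle. Zero for
  non-proliferating cells.
- **µ/2** — the effective-rate correction: a fresh mutation has a 50%
  chance of being lost, either to the unmutated daughter at division or
  to degradation within one half-life. The halving applies only to the
  burden model B; per-division and birth-burden counts are
  pre-segregation totals and are not halved.

The closed-form expectation uses the **geometric mean** of Z
(E[10^L] would be ~2178 copies, 2.2× the geometric mean; the geometric
mean is the representative copy number under a log-uniform spread):

    E(B) = G · 10^E(log10 Z) · E(µ)/2 · (E(X1)+E(X2)+E(X3))
         = 16,569 · 1000 · 1.47×10⁻⁷ · 416 = 1013.25

The Monte Carlo sample, by contrast, draws Z per cell, so the sample
mean (~2178) sits well above the geometric-mean expectation — both
numbers are correct and the tests assert each against its own oracle.

## Calendar and rounding conventions

Year lengths are fixed at 365.25 days and 52.18 weeks; "3 months" is
365.25/4 = 91.3125 days. These are the unique simple conventions under
which the age-70 round counts print as 280 (3-month half-life), 2131
(12-day), 70 (12-month) and 91 (40-week HSC cycle) simultaneously.

Headline integers are reported through `printed_integer()`: round to one
decimal, then to an integer with .5 ties going away from zero. This is
needed because E(B | µ=2.8×10⁻⁸) = 96.498, which at one-decimal working
precision is 96.5 and prints as 97; plain nearest-integer rounding of
the raw float would give 96. All other headline integers (1013, 1930,
280, 2131, 70, 91) are insensitive to the choice.

The quoted per-division mutation rates 0.5 and 9.2 (and the 22–414 birth
burden derived from them) trace to the exact fidelity reciprocals
1/3.6×10⁷ and 1/1.8×10⁶ (rates 0.460 and 9.205), not to the
two-significant-figure bounds (which give 9.28 → would print 9.3).
`birth_burden_range` therefore defaults its µ bounds to the exact
reciprocals; the burden model B keeps the rounded bounds, whose midpoint
E(µ)/2 = 1.47×10⁻⁷ is exact. `rounding="one_decimal"` reproduces the
tabulated integers (0.5·45 = 22.5 → 22; 9.2·45 = 414) using integer
tenths so float truncation cannot shave a unit.

## Ages other than 70

The reference distributions are stated at age 70 only. The package
scales the X2 and X3 intervals linearly by age/70 (midpoints track the
turnover and HSC arithmetic; half-widths scale in proportion, keeping
each interval's coefficient of variation constant). X1 is age-free.
This recovers the reference intervals exactly at age 70; any other
choice of width growth would be equally consistent with the stated
inputs — this one is the least structured.

## Monte Carlo design

`sample_burden` draws every parameter independently per cell (Z is
population-heterogeneous, not fixed per run), from a single
`numpy.random.default_rng(seed)` in the documented order L, µ, x1, x2,
x3 — one vector per variable — so identical (seed, config) reproduces
samples bit for bit, and a port in another language can match at the
distribution level. Fixed (degenerate) parameters consume no draws;
this makes proliferating and non-proliferating samples at a shared seed
*pairwise coupled* (they differ only by the x3 term), which the
dominance tests exploit.

Default n = 10⁶ draws: the standard error of any tail probability is at
most 0.0005, comfortably inside the ±0.01 reproduction band used for
the reference table, which also absorbs the unknown MC error of the
published values. B is left continuous (it is an expected burden); an
optional Poisson layer (`poisson_counts=True`, count ~ Poisson(B)) is
available but off by default because the reference tail thresholds act
on the continuous quantity.

The test suite checks tail probabilities against a semi-analytic
oracle that never touches the sampling path: conditional on L and
Y = X1+X2+X3, the µ-tail is a clipped linear function integrated in
closed form; Y's density is the exact piecewise-polynomial
(inclusion–exclusion) density of a sum of uniforms; the remaining two
dimensions are handled by trapezoid quadrature (converged to ~10⁻⁸ at
the grids used). Agreement is required within 3 MC standard errors.

## Heteroplasmy projection

A variant at fraction h with a per-round proliferative advantage
multiplies its odds h/(1−h) by (1+a) each replication round:

    odds_n = (h0/(1−h0)) · (1+a)^n,   h_n = odds_n/(1+odds_n)

logistic growth in n, computed in log-odds for stability at large n.
The **convention** maps the stated advantage s to the effective a:
`halved` (a = s/2, the default) reproduces all five reference outcomes
(1%→14.1% at s=2% over 280 rounds; 1%→28.8% over 371; 10%→64.4%;
5%→79.3% at s=20% over 45; 1%→91.0% at s=5%), whereas `full` (a = s)
over-predicts drastically (e.g. 72% instead of 14%). The halved
convention is a reconstruction — the projection formula behind the
published point values is not restated there — and `full` is kept for
sensitivity analysis. `rounds_to_threshold` inverts the projection via
logarithms with a ±1 integer check.

`segregate_stochastic` is a clearly-labelled neutral extension: at each
division the mutant count is resampled Binomial(Z, h) at constant copy
number Z. Mean heteroplasmy is a martingale, variance grows with
divisions at rate governed by 1/Z, and 0/1 are absorbing. No published
calibration exists for this layer; it is excluded from the headline
quantities and validated only through its mathematical properties.

## What the generator does and does not emulate

The simulation draws cells from the stated parameter distributions; it
emulates *parameter uncertainty and between-cell heterogeneity*, not a
mechanistic birth–death process of mtDNA molecules. In particular:
mutation counts are expectations, not realized integer counts (unless
the Poisson layer is enabled); Z is static per cell over life; X1–X3
are independent, though in a real tissue turnover and proliferation are
correlated; selection and drift do not feed back on the burden.
Passing tests show the arithmetic, the sampling and the projections are
faithful to the stated model — they say nothing about whether real
tissues obey it (mtDNA half-life, POLG fidelity in vivo and HSC cycling
rates are all actively debated).

## Numerical choices and degenerate inputs

- Tail ties count for both directions (a draw exactly at a threshold
  satisfies ≤ and ≥); with continuous distributions the empirical
  P(≤x) + P(≥x) = 1 up to ties.
- `reversed_cdf` uses a sort + `searchsorted`, exact and O(n log n).
- h0 = 0 and h0 = 1 short-circuit as absorbing states; projections with
  log-odds above 700 saturate to 1.0 before `exp` can overflow.
- A non-proliferating configuration forces X3 to a point mass at 0 at
  construction; `run()` therefore expects an x3-carrying configuration
  and derives the non-proliferating class from it.
- Problem sizes: the module tests use 2×10⁵-draw session fixtures
  (tail SE ≈ 0.001); the acceptance-scale table check and the
  acceptance script use the default 10⁶.

## Known limitations

Single copy-number distribution across tissues; no apoptosis
accounting (at most one extra development round even under 50% cell
loss, so it is deliberately ignored); no germline bottleneck; no
cell-level competition or fitness feedback; the age scaling of X2/X3
widths is a modelling choice, not a fitted quantity.
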