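"""Somatic mtDNA mutation burden with age: closed forms, simulation, drift.

The model: every mtDNA replication event risks a polymerase (POLG)
misincorporation, so the de novo mutation burden a cell carries at a given
age is set by how many times its mtDNA population has been copied.  Per
proliferating cell the burden is

    B = G * Z * (X1 + X2 + X3) * mu / 2

where G is the mitochondrial genome length (16,569 bp), Z the mtDNA copy
number per cell, mu the per-base per-replication POLG error rate, X1 the
replication rounds during development (zygote to birth), X2 the rounds
driven by mtDNA turnover after birth (relaxed replication), and X3 the
extra rounds in proliferating lineages (e.g. hematopoietic stem cells,
HSCs).  The division by two is the effective-rate correction: a new
mutation has a 50% chance of being lost to segregation at division or to
turnover within one half-life.

Parameters are random variables of the cell: mu uniform on its literature
interval, log10 Z uniform (so the expectation uses the geometric mean of
Z), and the Xi uniform around their age-70 point estimates.  The module is
laid out in the order the method runs:

1. parameter distributions;
2. replication-round and mutation-rate arithmetic (closed forms);
3. the burden model configuration and its expectation;
4. Monte Carlo sampling of per-cell burden, tail tables, reversed CDF;
5. heteroplasmy projection under a proliferative advantage, plus a
   neutral binomial-segregation simulator;
6. configuration files, report writing and the run entry point.

All heteroplasmy values are fractions in [0, 1] internally; the CLI
formats percentages.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParamDistribution",
    "fixed",
    "uniform",
    "log10_uniform",
    "TurnoverParams",
    "BurdenModelConfig",
    "default_config",
    "config_for_age",
    "expected_burden",
    "turnover_rounds",
    "hsc_extra_rounds",
    "divisions_to_cell_count",
    "per_division_mutation_count",
    "birth_burden_range",
    "body_copy_estimate",
    "printed_integer",
    "SimulationConfig",
    "BurdenSample",
    "sample_burden",
    "tail_probabilities",
    "TailTable",
    "reversed_cdf",
    "summarize",
    "DriftParams",
    "project_heteroplasmy",
    "rounds_to_threshold",
    "segregate_stochastic",
    "RunManifest",
    "run",
    "run_from_manifest",
    "load_config",
    "save_config",
    "parse_thresholds",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_DRIFT_SCENARIOS",
    "ConfigurationError",
    "UnsupportedConfigurationError",
    "UnreachableThresholdError",
]

logger = logging.getLogger("mtburden")

# Reference constants of the model.
GENOME_LENGTH_BP = 16_569           # human mtDNA reference length
MU_LOW = 2.8e-8                     # POLG error rate, low literature bound
MU_HIGH = 5.6e-7                    # POLG error rate, high literature bound
# The bounds above are the two-significant-figure forms of the measured
# fidelity, 1 misincorporation per 3.6e7 (resp. 1.8e6) bases synthesized.
MU_LOW_EXACT = 1.0 / 3.6e7
MU_HIGH_EXACT = 1.0 / 1.8e6
DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = 52.18
REFERENCE_AGE_YEARS = 70.0


class ConfigurationError(ValueError):
    """A model or run configuration violates an invariant."""


class UnsupportedConfigurationError(ConfigurationError):
    """A valid configuration that a closed-form operation cannot handle."""


class UnreachableThresholdError(ValueError):
    """A heteroplasmy target that no number of rounds can reach."""


# ---------------------------------------------------------------------------
# 1. Parameter distributions
# ---------------------------------------------------------------------------

_KINDS = ("fixed", "uniform", "log10_uniform")


@dataclass(frozen=True)
class ParamDistribution:
    """A scalar model parameter: a point value or a uniform interval.

    ``kind`` is one of ``fixed`` (degenerate at ``value``), ``uniform``
    (uniform on [lower, upper] on the natural scale) or ``log10_uniform``
    (log10 of the quantity uniform on [lower, upper]; the bounds are
    exponents, so ``log10_uniform(2, 4)`` spans 100 to 10,000).
    """

    kind: str
    value: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None:
                raise ConfigurationError("fixed distribution needs a value")
        else:
            if self.lower is None or self.upper is None:
                raise ConfigurationError(f"{self.kind} needs lower and upper")
            if self.lower > self.upper:
                raise ConfigurationError(
                    f"lower {self.lower} exceeds upper {self.upper}"
                )

    def mean(self) -> float:
        """Expected value; for ``log10_uniform`` the mean of the exponent."""
        if self.kind == "fixed":
            return float(self.value)
        return (self.lower + self.upper) / 2.0

    def geometric_mean(self) -> float:
        """10**mean(exponent) for log10_uniform; the value itself for fixed."""
        if self.kind == "log10_uniform":
            return 10.0 ** ((self.lower + self.upper) / 2.0)
        if self.kind == "fixed":
            return float(self.value)
        raise UnsupportedConfigurationError(
            "geometric mean defined only for fixed and log10_uniform"
        )

    def arithmetic_mean_natural(self) -> float:
        """E of the quantity on the natural scale (integrates out log-uniform)."""
        if self.kind == "log10_uniform":
            # E[10^L], L ~ Unif(lower, upper)
            lo, hi = self.lower, self.upper
            if hi == lo:
                return 10.0 ** lo
            return (10.0 ** hi - 10.0 ** lo) / ((hi - lo) * math.log(10.0))
        return self.mean()

    def support_nonnegative(self) -> bool:
        if self.kind == "fixed":
            return self.value >= 0
        if self.kind == "uniform":
            return self.lower >= 0
        return True  # 10^L > 0 always

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, float(self.value))
        draws = rng.uniform(self.lower, self.upper, n)
        if self.kind == "log10_uniform":
            return 10.0 ** draws
        return draws

    def to_dict(self) -> dict:
        if self.kind == "fixed":
            return {"kind": "fixed", "value": self.value}
        return {"kind": self.kind, "lower": self.lower, "upper": self.upper}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamDistribution":
        return cls(**d)


def fixed(value: float) -> ParamDistribution:
    return ParamDistribution("fixed", value=value)


def uniform(lower: float, upper: float) -> ParamDistribution:
    return ParamDistribution("uniform", lower=lower, upper=upper)


def log10_uniform(lower: float, upper: float) -> ParamDistribution:
    return ParamDistribution("log10_uniform", lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# 2. Replication-round and mutation-rate arithmetic
# ---------------------------------------------------------------------------


def printed_integer(x: float) -> int:
    """Round to the nearest integer at one-decimal working precision.

    Rounds ``x`` to one decimal first, then to an integer, breaking .5 ties
    away from zero.  This is the convention under which the model's
    tabulated point estimates (which are computed at one-decimal working
    precision) come out of the raw closed forms; e.g. 96.498 -> 96.5 -> 97.
    """
    sign = -1.0 if x < 0 else 1.0
    one_dec = math.floor(abs(x) * 10.0 + 0.5) / 10.0
    return int(sign * math.floor(one_dec + 0.5))


def turnover_rounds(
    age_years: float,
    half_life_days: float,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """Replication rounds needed to offset mtDNA turnover by a given age.

    Relaxed replication: mtDNA is degraded continuously even in post-mitotic
    cells, and each half-life the whole population must be replicated once
    just to hold copy number steady — one population-doubling-equivalent per
    half-life.  With the default 3-month half-life (91.3125 days) a
    70-year-old non-dividing cell has accumulated ~280 rounds; a 12-day
    half-life gives ~2131; a 12-month half-life gives 70.
    """
    if half_life_days <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_days}")
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    return age_years * days_per_year / half_life_days


def hsc_extra_rounds(
    age_years: float,
    cycle_weeks: float = 40.0,
    weeks_per_year: float = WEEKS_PER_YEAR,
) -> float:
    """Additional replication rounds from stem-cell self-renewal.

    HSCs self-renew roughly once every 40 weeks, adding ~91 mtDNA
    replication rounds by age 70 on top of the turnover baseline.
    """
    if cycle_weeks <= 0:
        raise ValueError(f"cycle length must be positive, got {cycle_weeks}")
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    return age_years * weeks_per_year / cycle_weeks


def divisions_to_cell_count(n_cells: float) -> int:
    """Complete population doublings achieved within ``n_cells`` cells.

    floor(log2 n): the "at least" convention for counting developmental
    divisions — 3.72e13 cells imply at least 45 doublings from the zygote
    (2**45 ~ 3.52e13 falls just short of the census estimate; the count is
    the last complete doubling).
    """
    if n_cells < 1:
        raise ValueError(f"need at least one cell, got {n_cells}")
    return int(math.floor(math.log2(n_cells)))


def per_division_mutation_count(
    copy_number: float,
    genome_length_bp: int = GENOME_LENGTH_BP,
    error_rate: float = MU_LOW,
) -> float:
    """Expected de novo mtDNA mutations created by one cell division.

    Doubling a population of ``copy_number`` genomes synthesizes
    ``copy_number * genome_length_bp`` bases, each a Bernoulli(error_rate)
    misincorporation opportunity.  This counts mutations created, before
    any segregation or turnover loss, so no halving factor applies.
    At Z=1000 the two POLG bounds give 0.46 and 9.28 per division.
    """
    if copy_number <= 0 or genome_length_bp <= 0:
        raise ValueError("copy number and genome length must be positive")
    if error_rate < 0:
        raise ValueError("error rate must be non-negative")
    return copy_number * genome_length_bp * error_rate


def birth_burden_range(
    copy_number: float = 1000.0,
    genome_length_bp: int = GENOME_LENGTH_BP,
    mu_low: float = MU_LOW_EXACT,
    mu_high: float = MU_HIGH_EXACT,
    divisions: int = 45,
    rounding: str = "none",
) -> tuple[float, float]:
    """De novo mutation count per cell accumulated over development.

    Per-division rate times the number of developmental divisions, at the
    low and high POLG error-rate bounds.  The defaults are the exact
    fidelity reciprocals (1 error per 3.6e7 / 1.8e6 bases): these give
    per-division rates of 0.460 and 9.205, which is where the commonly
    quoted one-decimal figures 0.5 and 9.2 come from (the rounded
    two-significant-figure bound 5.6e-7 gives 9.28, which would print as
    9.3).  ``rounding="one_decimal"`` reproduces the tabulated integers
    by rounding the per-division rate to one decimal before multiplying
    and truncating (0.5*45 = 22.5 -> 22, 9.2*45 -> 414); the default
    ``"none"`` keeps full precision.
    """
    if mu_low > mu_high:
        raise ValueError("mu_low must not exceed mu_high")
    if divisions < 0:
        raise ValueError("divisions must be non-negative")
    if rounding not in ("none", "one_decimal"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    out = []
    for mu in (mu_low, mu_high):
        rate = per_division_mutation_count(copy_number, genome_length_bp, mu)
        if rounding == "one_decimal":
            # integer tenths to keep 9.2 * 45 = 414 exact under truncation
            rate_tenths = math.floor(rate * 10.0 + 0.5)
            out.append(float(rate_tenths * divisions // 10))
        else:
            out.append(rate * divisions)
    return out[0], out[1]


def body_copy_estimate(
    n_cells: float,
    copies_per_cell_low: float,
    copies_per_cell_high: float,
) -> tuple[float, float]:
    """Total mtDNA molecules per individual, as a (low, high) range.

    The product of a whole-body cell census and a per-cell copy-number
    range.  For 3.72e13 cells at 100-10,000 copies this spans 3.72e15 to
    3.72e17 — an order-of-magnitude statement (the commonly quoted range
    is 1e16 to 1e17 copies per adult).
    """
    if n_cells < 0 or copies_per_cell_low < 0 or copies_per_cell_high < 0:
        raise ValueError("cell count and copy numbers must be non-negative")
    return n_cells * copies_per_cell_low, n_cells * copies_per_cell_high


# ---------------------------------------------------------------------------
# 3. The burden model and its closed-form expectation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverParams:
    """Calendar parameters behind X2 and X3.

    half_life_days: mtDNA half-life (default 3 months = 91.3125 days, the
    conservative middle of the published days-to-a-year range).
    hsc_cycle_weeks: stem-cell self-renewal interval (default 40 weeks).
    The year-length conventions are chosen so the age-70 round counts land
    on 280, 2131, 70 and 91 under nearest-integer rounding.
    """

    half_life_days: float = DAYS_PER_YEAR / 4.0  # 3 months
    hsc_cycle_weeks: float = 40.0
    days_per_year: float = DAYS_PER_YEAR
    weeks_per_year: float = WEEKS_PER_YEAR

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be strictly positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BurdenModelConfig:
    """Full parameter set of the per-cell burden model B = G*Z*Y*mu/2.

    Defaults are the age-70 reference setting: mu ~ Unif(2.8e-8, 5.6e-7)
    per base per replication; log10 Z ~ Unif(2, 4) (geometric mean 1000
    copies); X1 ~ Unif(10, 80) developmental rounds; X2 ~ Unif(180, 380)
    turnover rounds; X3 ~ Unif(81, 101) proliferation rounds (zero for
    non-proliferating cells).  ``halving_factor`` converts the raw
    polymerase rate to the effective rate surviving segregation/turnover
    loss (mu/2).
    """

    genome_length_bp: int = GENOME_LENGTH_BP
    copy_number: ParamDistribution = field(
        default_factory=lambda: log10_uniform(2.0, 4.0)
    )
    polg_error_rate: ParamDistribution = field(
        default_factory=lambda: uniform(MU_LOW, MU_HIGH)
    )
    x1: ParamDistribution = field(default_factory=lambda: uniform(10.0, 80.0))
    x2: ParamDistribution = field(default_factory=lambda: uniform(180.0, 380.0))
    x3: ParamDistribution = field(default_factory=lambda: uniform(81.0, 101.0))
    proliferating: bool = True
    halving_factor: float = 2.0
    age_years: float = REFERENCE_AGE_YEARS

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0:
            raise ConfigurationError("genome_length_bp must be positive")
        if self.halving_factor <= 0:
            raise ConfigurationError("halving_factor must be positive")
        if self.age_years < 0:
            raise ConfigurationError("age_years must be non-negative")
        # a non-proliferating cell has no extra proliferation rounds
        if not self.proliferating:
            object.__setattr__(self, "x3", fixed(0.0))
        for name in ("copy_number", "polg_error_rate", "x1", "x2", "x3"):
            dist = getattr(self, name)
            if not isinstance(dist, ParamDistribution):
                raise ConfigurationError(f"{name} must be a ParamDistribution")
            if not dist.support_nonnegative():
                raise ConfigurationError(f"{name} support must be non-negative")

    def expected_rounds(self) -> float:
        """E(Y) = E(X1) + E(X2) + E(X3)."""
        return self.x1.mean() + self.x2.mean() + self.x3.mean()

    def to_dict(self) -> dict:
        d = {
            "genome_length_bp": self.genome_length_bp,
            "proliferating": self.proliferating,
            "halving_factor": self.halving_factor,
            "age_years": self.age_years,
        }
        for name in ("copy_number", "polg_error_rate", "x1", "x2", "x3"):
            d[name] = getattr(self, name).to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BurdenModelConfig":
        kwargs = dict(d)
        for name in ("copy_number", "polg_error_rate", "x1", "x2", "x3"):
            if name in kwargs:
                kwargs[name] = ParamDistribution.from_dict(kwargs[name])
        return cls(**kwargs)


def default_config(proliferating: bool = True) -> BurdenModelConfig:
    """The age-70 reference configuration."""
    return BurdenModelConfig(proliferating=proliferating)


def config_for_age(
    age_years: float,
    proliferating: bool = True,
    turnover: TurnoverParams | None = None,
) -> BurdenModelConfig:
    """Reference configuration rescaled to another age.

    X2 and X3 intervals are the age-70 reference intervals scaled linearly
    by age/70 (midpoints 4*age and ~1.3*age; half-widths in proportion),
    which keeps each interval's coefficient of variation constant and
    recovers the reference intervals exactly at age 70.  X1 (development)
    does not depend on age.  ``turnover`` rescales the X2/X3 midpoints for
    a different half-life or stem-cell cycle before the interval is built.
    """
    if age_years < 0:
        raise ConfigurationError("age_years must be non-negative")
    t = turnover or TurnoverParams()
    x2_mid = turnover_rounds(age_years, t.half_life_days, t.days_per_year)
    x3_mid = hsc_extra_rounds(age_years, t.hsc_cycle_weeks, t.weeks_per_year)
    # reference half-widths at the age-70 midpoints 280 and 91
    x2_half = 100.0 * x2_mid / 280.0
    x3_half = 10.0 * x3_mid / 91.315
    x2 = fixed(0.0) if x2_mid == 0 else uniform(x2_mid - x2_half, x2_mid + x2_half)
    if age_years == REFERENCE_AGE_YEARS and t == TurnoverParams():
        # land exactly on the reference intervals
        x2, x3 = uniform(180.0, 380.0), uniform(81.0, 101.0)
    elif x3_mid == 0:
        x3 = fixed(0.0)
    else:
        x3 = uniform(max(x3_mid - x3_half, 0.0), x3_mid + x3_half)
    return BurdenModelConfig(
        x2=x2, x3=x3, proliferating=proliferating, age_years=age_years
    )


def expected_burden(config: BurdenModelConfig) -> float:
    """Closed-form expected mutation burden per cell.

    E(B) = G * Z~ * E(mu)/halving_factor * (E(X1)+E(X2)+E(X3)), with Z~
    the geometric mean of the copy number (its log is uniform, so the
    geometric mean — not the arithmetic mean, which is ~2.2x larger — is
    the representative copy number).  The reference proliferating setting
    gives 16,569 * 1000 * 1.47e-7 * 416 = 1013.25.

    Raises :class:`UnsupportedConfigurationError` if the copy number is a
    plain (natural-scale) uniform, for which the geometric-mean convention
    is not defined here.
    """
    if config.copy_number.kind == "uniform":
        raise UnsupportedConfigurationError(
            "closed-form expectation requires a fixed or log10_uniform "
            "copy number (geometric-mean convention)"
        )
    z_tilde = config.copy_number.geometric_mean()
    mu_eff = config.polg_error_rate.mean() / config.halving_factor
    return config.genome_length_bp * z_tilde * mu_eff * config.expected_rounds()


# ---------------------------------------------------------------------------
# 4. Monte Carlo simulation of per-cell burden
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings: model, sample size, seed.

    ``poisson_counts=True`` adds an integer sampling layer on top of the
    continuous expected burden (count ~ Poisson(B)); off by default since
    the tail-table thresholds act on the continuous quantity.
    """

    model: BurdenModelConfig = field(default_factory=BurdenModelConfig)
    n_samples: int = 1_000_000
    seed: int = 0
    poisson_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be at least 1")


@dataclass(frozen=True)
class BurdenSample:
    """Per-cell burden draws plus the configuration that produced them."""

    values: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if len(self.values) != self.config.n_samples:
            raise ConfigurationError("sample length must equal n_samples")

    def __len__(self) -> int:
        return len(self.values)


def sample_burden(config: SimulationConfig) -> BurdenSample:
    """Draw per-cell burdens B = G * 10^L * (x1+x2+x3) * mu / halving.

    Each cell gets an independent draw of every parameter — the copy
    number Z = 10^L is redrawn per cell (population heterogeneity), not
    fixed per run.  Draws come from a single seeded generator in the fixed
    order L, mu, x1, x2, x3 (one vector each), so identical (seed, config)
    reproduces the sample bit for bit.
    """
    m = config.model
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    z = m.copy_number.sample(rng, n)      # L drawn first (as 10^L)
    mu = m.polg_error_rate.sample(rng, n)
    x1 = m.x1.sample(rng, n)
    x2 = m.x2.sample(rng, n)
    x3 = m.x3.sample(rng, n)
    b = m.genome_length_bp * z * (x1 + x2 + x3) * mu / m.halving_factor
    if config.poisson_counts:
        b = rng.poisson(b).astype(float)
    return BurdenSample(values=b, config=config)


@dataclass(frozen=True)
class TailTable:
    """Estimated P(B <= t) / P(B >= t) rows for a set of thresholds."""

    rows: tuple[tuple[str, float, float], ...]  # (direction, threshold, prob)

    def __post_init__(self) -> None:
        for direction, _, p in self.rows:
            if direction not in ("le", "ge"):
                raise ValueError(f"direction must be 'le' or 'ge', got {direction!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def probability(self, direction: str, threshold: float) -> float:
        for d, t, p in self.rows:
            if d == direction and t == threshold:
                return p
        raise KeyError((direction, threshold))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["direction", "threshold", "probability"]
        )


def tail_probabilities(
    sample: BurdenSample,
    thresholds: Sequence[tuple[str, float]],
) -> TailTable:
    """Empirical tail probabilities at the given (direction, threshold) rows.

    Ties count for both directions: a draw exactly at the threshold
    satisfies both <= and >=.
    """
    v = sample.values
    if len(v) == 0:
        raise ValueError("empty sample")
    rows = []
    for direction, t in thresholds:
        if direction == "le":
            p = float(np.mean(v <= t))
        elif direction == "ge":
            p = float(np.mean(v >= t))
        else:
            raise ValueError(f"direction must be 'le' or 'ge', got {direction!r}")
        rows.append((direction, float(t), p))
    return TailTable(rows=tuple(rows))


def reversed_cdf(
    sample: BurdenSample, grid: Sequence[float]
) -> list[tuple[float, float]]:
    """P(B >= x) along an ascending grid — the reversed (1-CDF) curve."""
    g = np.asarray(grid, dtype=float)
    if len(g) == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(g) < 0):
        raise ValueError("grid must be sorted ascending")
    v = np.sort(sample.values)
    # count of values >= x via searchsorted on the sorted sample
    n_ge = len(v) - np.searchsorted(v, g, side="left")
    return [(float(x), float(c) / len(v)) for x, c in zip(g, n_ge)]


def summarize(sample: BurdenSample, n_bins: int = 100) -> dict:
    """Mean, sd, standard quantiles and histogram counts of a sample.

    The histogram uses ``n_bins`` equal-width bins spanning the sample
    range; counts sum to n_samples.
    """
    v = sample.values
    if len(v) == 0:
        raise ValueError("empty sample")
    qs = [1, 5, 25, 50, 75, 95, 99]
    counts, edges = np.histogram(v, bins=n_bins)
    return {
        "n": int(len(v)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "quantiles": {
            str(q): float(np.percentile(v, q)) for q in qs
        },
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
    }


# ---------------------------------------------------------------------------
# 5. Heteroplasmy: deterministic projection and stochastic segregation
# ---------------------------------------------------------------------------

_CONVENTIONS = ("halved", "full")


@dataclass(frozen=True)
class DriftParams:
    """A heteroplasmy projection scenario.

    h0: starting mutant fraction; advantage: the stated per-round
    proliferative advantage s (a fraction, e.g. 0.02 for "2%"); n_rounds:
    mtDNA replication rounds; convention: how the stated advantage enters
    the per-round odds multiplier — ``halved`` uses a = s/2 (only the
    replicated half of the population expresses the edge each round, the
    convention that matches the published point projections), ``full``
    uses a = s.
    """

    h0: float
    advantage: float
    n_rounds: int
    convention: str = "halved"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h0 <= 1.0:
            raise ValueError(f"h0 must be in [0, 1], got {self.h0}")
        if self.advantage < 0:
            raise ValueError("advantage must be non-negative")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be non-negative")
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"convention must be one of {_CONVENTIONS}")

    @property
    def effective_advantage(self) -> float:
        return self.advantage / 2.0 if self.convention == "halved" else self.advantage


def project_heteroplasmy(params: DriftParams) -> float:
    """Deterministic mutant fraction after n rounds of biased replication.

    The mutant:wild-type odds grow geometrically, odds_n =
    (h0/(1-h0)) * (1+a)^n with a the effective per-round advantage, and
    the fraction is odds_n/(1+odds_n) — logistic growth in n.  h0 = 0 and
    h0 = 1 are absorbing.  E.g. 1% at a stated 2% advantage reaches ~14%
    after 280 rounds and ~29% after 371; 5% at a stated 20% advantage
    reaches ~79% after 45 rounds.
    """
    h0 = params.h0
    if h0 in (0.0, 1.0):
        return h0
    a = params.effective_advantage
    # work in log-odds to stay stable at large n
    log_odds = math.log(h0 / (1.0 - h0)) + params.n_rounds * math.log1p(a)
    if log_odds > 700.0:
        return 1.0
    odds = math.exp(log_odds)
    return odds / (1.0 + odds)


def rounds_to_threshold(
    h0: float,
    advantage: float,
    target: float,
    convention: str = "halved",
) -> int:
    """Smallest round count at which the projection reaches ``target``.

    Closed-form inversion via logarithms, then an integer check of the
    neighbouring round counts to absorb floating-point edge effects.
    """
    if not 0.0 < h0 < 1.0:
        raise ValueError("h0 must be strictly inside (0, 1)")
    if not 0.0 < target < 1.0:
        raise ValueError("target must be strictly inside (0, 1)")
    if target <= h0:
        return 0
    if advantage <= 0:
        raise UnreachableThresholdError(
            "a neutral variant never reaches a target above h0"
        )
    a = advantage / 2.0 if convention == "halved" else advantage
    need = (math.log(target / (1 - target)) - math.log(h0 / (1 - h0))) / math.log1p(a)
    n = max(int(math.ceil(need)), 0)
    while n > 0 and project_heteroplasmy(
        DriftParams(h0, advantage, n - 1, convention)
    ) >= target:
        n -= 1
    while project_heteroplasmy(DriftParams(h0, advantage, n, convention)) < target:
        n += 1
    return n


def segregate_stochastic(
    h0: float,
    copy_number: int,
    n_divisions: int,
    n_lineages: int,
    seed: int = 0,
) -> np.ndarray:
    """Neutral random segregation of heteroplasmy across cell divisions.

    Each division resamples the mutant count binomially: with Z genome
    copies and current mutant fraction h, the daughter's count is
    Binomial(Z, h)/Z.  Mean heteroplasmy is conserved (a martingale) while
    variance grows until lineages absorb at 0 or 1 — genetic drift of the
    intracellular mtDNA population.  This is a constant-copy-number
    extension of the deterministic model, not a published calibration.

    Returns an (n_lineages, n_divisions+1) trajectory matrix including the
    starting state.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be at least 1")
    if not 0.0 <= h0 <= 1.0:
        raise ValueError("h0 must be in [0, 1]")
    if n_divisions < 0 or n_lineages < 1:
        raise ValueError("n_divisions >= 0 and n_lineages >= 1 required")
    rng = np.random.default_rng(seed)
    traj = np.empty((n_lineages, n_divisions + 1))
    h = np.full(n_lineages, float(h0))
    traj[:, 0] = h
    for k in range(1, n_divisions + 1):
        h = rng.binomial(copy_number, h) / copy_number
        traj[:, k] = h
    return traj


# ---------------------------------------------------------------------------
# 6. Configuration files, reports and the run entry point
# ---------------------------------------------------------------------------

#: Reference tail-table rows (the reporting default).
DEFAULT_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("le", 10.0), ("le", 50.0), ("le", 100.0), ("le", 200.0),
    ("ge", 500.0), ("ge", 1000.0), ("ge", 1500.0),
    ("ge", 2000.0), ("ge", 3000.0), ("ge", 5000.0),
)

#: Reference drift scenarios (h0, stated advantage, rounds).
DEFAULT_DRIFT_SCENARIOS: tuple[tuple[float, float, int], ...] = (
    (0.05, 0.20, 45),    # zygote variant through development
    (0.01, 0.02, 280),   # non-proliferating lineage to age 70
    (0.10, 0.02, 280),
    (0.01, 0.05, 280),
    (0.01, 0.02, 371),   # proliferating (HSC) lineage to age 70
)

_ARTIFACT_VERSION = "0.1.0"


def parse_thresholds(text: str) -> tuple[tuple[str, float], ...]:
    """Parse 'le:10,ge:500,...' into (direction, threshold) rows."""
    rows = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            direction, value = tok.split(":")
            direction = direction.strip()
            if direction not in ("le", "ge"):
                raise ValueError
            rows.append((direction, float(value)))
        except ValueError:
            raise ConfigurationError(
                f"bad threshold {tok!r}: expected le:<num> or ge:<num>"
            ) from None
    if not rows:
        raise ConfigurationError("no thresholds given")
    return tuple(rows)


def save_config(
    config: BurdenModelConfig,
    path: str | Path,
    turnover: TurnoverParams | None = None,
) -> None:
    """Write a flat JSON configuration file (model + calendar parameters)."""
    doc = config.to_dict()
    doc.update((turnover or TurnoverParams()).to_dict())
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_config(path: str | Path) -> tuple[BurdenModelConfig, TurnoverParams]:
    """Read a flat JSON configuration file; see :func:`save_config`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigurationError(
            f"{path}:{e.lineno}:{e.colno}: invalid JSON: {e.msg}"
        ) from None
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a JSON object")
    t_fields = {f.name for f in dataclasses.fields(TurnoverParams)}
    m_fields = {f.name for f in dataclasses.fields(BurdenModelConfig)}
    t_kwargs = {k: v for k, v in doc.items() if k in t_fields}
    m_kwargs = {k: v for k, v in doc.items() if k in m_fields}
    unknown = set(doc) - t_fields - m_fields
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        model = BurdenModelConfig.from_dict(m_kwargs)
        turnover = TurnoverParams(**t_kwargs)
    except (TypeError, ConfigurationError) as e:
        raise ConfigurationError(f"{path}: {e}") from None
    return model, turnover


def _config_hash(doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run: resolved config, seed, outputs."""

    config: dict
    seed: int
    n_samples: int
    convention: str
    cell_class: str
    thresholds: tuple[tuple[str, float], ...]
    version: str
    config_sha256: str
    outputs: tuple[str, ...]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = [list(r) for r in self.thresholds]
        d["outputs"] = list(self.outputs)
        return d


def _meta_header(manifest: RunManifest) -> str:
    return (
        f"# mtburden v{manifest.version}"
        f" seed={manifest.seed} n_samples={manifest.n_samples}"
        f" config_sha256={manifest.config_sha256}\n"
    )


def run(
    outdir: str | Path,
    config: BurdenModelConfig | None = None,
    turnover: TurnoverParams | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
    thresholds: Sequence[tuple[str, float]] = DEFAULT_THRESHOLDS,
    convention: str = "halved",
    drift_scenarios: Sequence[tuple[float, float, int]] = DEFAULT_DRIFT_SCENARIOS,
    n_grid: int = 200,
    cell_class: str = "proliferating",
) -> RunManifest:
    """Run the full analysis and write all reports under ``outdir``.

    Produces: a closed-form expectation report (JSON); the tail table for
    proliferating and non-proliferating cells (TSV + JSON); reversed-CDF
    and histogram exports (TSV, ready for any plotting tool);
    heteroplasmy projections (JSON); and a run manifest.  All tabular
    outputs carry the seed and a configuration hash in a header comment.
    Nothing is written if validation fails.

    ``config`` should carry the x3 distribution (a proliferating
    configuration): both cell classes are derived from it, the
    non-proliferating one by zeroing x3.  ``cell_class`` selects which
    sample the histogram and summary describe.
    """
    config = config or default_config()
    turnover = turnover or TurnoverParams()
    if convention not in _CONVENTIONS:
        raise ConfigurationError(f"convention must be one of {_CONVENTIONS}")
    if cell_class not in ("proliferating", "non_proliferating"):
        raise ConfigurationError(
            "cell_class must be 'proliferating' or 'non_proliferating'"
        )
    thresholds = tuple((d, float(t)) for d, t in thresholds)
    sim_p = SimulationConfig(model=replace(config, proliferating=True),
                             n_samples=n_samples, seed=seed)
    sim_n = SimulationConfig(model=replace(config, proliferating=False),
                             n_samples=n_samples, seed=seed)

    doc = config.to_dict()
    doc.update(turnover.to_dict())
    for key, val in sorted(doc.items()):
        logger.info("resolved parameter %s = %s", key, val)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [
        "expectation_report.json", "tail_table.tsv", "tail_table.json",
        "reversed_cdf.tsv", "histogram.tsv", "summary.json",
        "heteroplasmy.json", "manifest.json",
    ]
    manifest = RunManifest(
        config=doc, seed=seed, n_samples=n_samples, convention=convention,
        cell_class=cell_class,
        thresholds=thresholds, version=_ARTIFACT_VERSION,
        config_sha256=_config_hash(doc), outputs=tuple(outputs),
    )
    header = _meta_header(manifest)

    # -- closed forms ------------------------------------------------------
    cfg_p, cfg_n = sim_p.model, sim_n.model
    mu = config.polg_error_rate
    report = {
        "expected_burden_proliferating": expected_burden(cfg_p),
        "expected_burden_proliferating_int": printed_integer(expected_burden(cfg_p)),
        "expected_burden_non_proliferating": expected_burden(cfg_n),
        "expected_burden_non_proliferating_int": printed_integer(
            expected_burden(cfg_n)
        ),
        "turnover_rounds": turnover_rounds(
            config.age_years, turnover.half_life_days, turnover.days_per_year
        ),
        "hsc_extra_rounds": hsc_extra_rounds(
            config.age_years, turnover.hsc_cycle_weeks, turnover.weeks_per_year
        ),
        "expected_total_rounds": cfg_p.expected_rounds(),
    }
    if mu.kind == "uniform":
        for label, bound in (("low", mu.lower), ("high", mu.upper)):
            cfg_b = replace(cfg_p, polg_error_rate=fixed(bound))
            report[f"expected_burden_mu_{label}"] = expected_burden(cfg_b)
            report[f"expected_burden_mu_{label}_int"] = printed_integer(
                expected_burden(cfg_b)
            )
    (outdir / "expectation_report.json").write_text(
        json.dumps({"seed": seed, "config_sha256": manifest.config_sha256,
                    "report": report}, indent=2) + "\n"
    )

    # -- simulation --------------------------------------------------------
    samp_p, samp_n = sample_burden(sim_p), sample_burden(sim_n)
    tab_p = tail_probabilities(samp_p, thresholds)
    tab_n = tail_probabilities(samp_n, thresholds)
    df = tab_p.to_dataframe().rename(columns={"probability": "p_proliferating"})
    df["p_non_proliferating"] = [p for _, _, p in tab_n.rows]
    with open(outdir / "tail_table.tsv", "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    (outdir / "tail_table.json").write_text(
        json.dumps({"seed": seed, "config_sha256": manifest.config_sha256,
                    "rows": df.to_dict(orient="records")}, indent=2) + "\n"
    )

    hi = float(np.percentile(samp_p.values, 99.5))
    grid = np.linspace(0.0, hi, n_grid)
    curve_p = reversed_cdf(samp_p, grid)
    curve_n = reversed_cdf(samp_n, grid)
    with open(outdir / "reversed_cdf.tsv", "w") as fh:
        fh.write(header)
        fh.write("burden\tp_ge_proliferating\tp_ge_non_proliferating\n")
        for (x, pp), (_, pn) in zip(curve_p, curve_n):
            fh.write(f"{x:.6g}\t{pp:.6g}\t{pn:.6g}\n")

    primary = samp_p if cell_class == "proliferating" else samp_n
    summ = summarize(primary)
    with open(outdir / "histogram.tsv", "w") as fh:
        fh.write(header)
        fh.write(f"# cell_class={cell_class}\n")
        fh.write("bin_left\tbin_right\tcount\n")
        edges, counts = summ["bin_edges"], summ["counts"]
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{left:.6g}\t{right:.6g}\t{c}\n")
    (outdir / "summary.json").write_text(
        json.dumps({"seed": seed, "config_sha256": manifest.config_sha256,
                    "cell_class": cell_class,
                    "proliferating": summarize(samp_p),
                    "non_proliferating": summarize(samp_n)}, indent=2) + "\n"
    )

    # -- heteroplasmy projections -----------------------------------------
    records = []
    for h0, s, n in drift_scenarios:
        p = DriftParams(h0=h0, advantage=s, n_rounds=n, convention=convention)
        records.append({
            "h0": h0, "s": s, "n": n, "convention": convention,
            "h_n": project_heteroplasmy(p),
        })
    (outdir / "heteroplasmy.json").write_text(
        json.dumps({"seed": seed, "config_sha256": manifest.config_sha256,
                    "projections": records}, indent=2) + "\n"
    )

    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2) + "\n"
    )
    return manifest


def run_from_manifest(manifest_path: str | Path, outdir: str | Path) -> RunManifest:
    """Re-run an analysis from its manifest, reproducing outputs exactly."""
    doc = json.loads(Path(manifest_path).read_text())
    t_fields = {f.name for f in dataclasses.fields(TurnoverParams)}
    cfg_doc = doc["config"]
    model = BurdenModelConfig.from_dict(
        {k: v for k, v in cfg_doc.items() if k not in t_fields}
    )
    turnover = TurnoverParams(**{k: v for k, v in cfg_doc.items() if k in t_fields})
    return run(
        outdir, config=model, turnover=turnover, n_samples=doc["n_samples"],
        seed=doc["seed"], thresholds=[tuple(r) for r in doc["thresholds"]],
        convention=doc["convention"], cell_class=doc["cell_class"],
    )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="mtburden",
        description=(
            "Somatic mtDNA mutation burden with age: closed-form "
            "expectations, Monte Carlo burden distributions and "
            "heteroplasmy projections."
        ),
    )
    p.add_argument("--config", type=Path, default=None,
                   help="JSON configuration file (overrides built-in defaults)")
    p.add_argument("--age", type=float, default=None,
                   help="age in years (rescales turnover/proliferation rounds)")
    grp = p.add_mutually_exclusive_group()
    grp.add_argument("--proliferating", dest="proliferating",
                     action="store_true", default=True)
    grp.add_argument("--non-proliferating", dest="proliferating",
                     action="store_false",
                     help="model a post-mitotic cell (X3 = 0)")
    p.add_argument("--half-life-days", type=float, default=None,
                   help="mtDNA half-life in days (default 91.3125 = 3 months)")
    p.add_argument("--hsc-cycle-weeks", type=float, default=None,
                   help="stem-cell self-renewal interval in weeks (default 40)")
    p.add_argument("--n-samples", type=int, default=1_000_000,
                   help="Monte Carlo sample size (default 1e6)")
    p.add_argument("--seed", type=int, default=0, help="RNG seed")
    p.add_argument("--thresholds", type=str, default=None,
                   help="comma list of le:<x>/ge:<x> rows for the tail table")
    p.add_argument("--convention", choices=list(_CONVENTIONS), default="halved",
                   help="how the stated advantage enters the odds multiplier")
    p.add_argument("--outdir", type=Path, default=Path("mtburden_out"),
                   help="output directory")
    p.add_argument("-v", "--verbose", action="store_true",
                   help="log resolved parameters at INFO")
    return p


def main(argv: Sequence[str] | None = None) -> int:
    args = build_parser().parse_args(argv)
    logging.basicConfig(
        level=logging.INFO if args.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    try:
        if args.config is not None:
            model, turnover = load_config(args.config)
        else:
            model, turnover = default_config(), TurnoverParams()
        if args.half_life_days is not None or args.hsc_cycle_weeks is not None:
            turnover = replace(
                turnover,
                **{k: v for k, v in (
                    ("half_life_days", args.half_life_days),
                    ("hsc_cycle_weeks", args.hsc_cycle_weeks),
                ) if v is not None},
            )
        if args.age is not None:
            model = config_for_age(args.age, turnover=turnover)
        thresholds = (
            parse_thresholds(args.thresholds)
            if args.thresholds is not None else DEFAULT_THRESHOLDS
        )
        manifest = run(
            args.outdir, config=model, turnover=turnover,
            n_samples=args.n_samples, seed=args.seed,
            thresholds=thresholds, convention=args.convention,
            cell_class=(
                "proliferating" if args.proliferating else "non_proliferating"
            ),
        )
    except (ConfigurationError, ValueError) as e:
        print(f"error: {e}", file=sys.stderr)
        return 2
    ep = json.loads((args.outdir / "expectation_report.json").read_text())
    r = ep["report"]
    print(f"outputs written to {args.outdir} "
          f"(seed={manifest.seed}, config={manifest.config_sha256})")
    print(f"E(B) proliferating     = {r['expected_burden_proliferating']:.1f}"
          f"  (~{r['expected_burden_proliferating_int']})")
    print(f"E(B) non-proliferating = {r['expected_burden_non_proliferating']:.1f}"
          f"  (~{r['expected_burden_non_proliferating_int']})")
    return 0
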