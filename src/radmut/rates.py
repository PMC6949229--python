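"""Mutation-rate estimation, parental-aging adjustment and Poisson tests.

The per-generation mutation rate is mu = m / (n * G): m mutations over n
offspring, G the analysed diploid genome size (twice the EWC region).  95%
confidence intervals are the exact Poisson (Garwood, chi-square inversion)
bounds, defined at zero counts.  Before/after-exposure count differences are
tested with a two-tailed Monte-Carlo test that draws pairs of Poisson counts
under a common mean; parental-aging adjustments subtract a linear per-week
increment expressed as a fraction of the 8-week baseline count, and the
uncertainty of that subtraction can be propagated into the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateEstimate",
    "AgingModel",
    "AgingRates",
    "AgingUncertainty",
    "PoissonTestResult",
    "poisson_exact_ci",
    "mutation_rate",
    "aging_rate_from_phased_counts",
    "aging_rate_from_two_studies",
    "adjust_count_for_age",
    "poisson_difference_test",
    "extrapolate_per_offspring",
    "region_distribution_test",
]


def poisson_exact_ci(m: int, conf: float = 0.95) -> tuple[float, float]:
    """Garwood (chi-square inversion) interval for a Poisson mean."""
    if m < 0:
        raise ValueError("count must be >= 0")
    alpha = 1.0 - conf
    lo = 0.0 if m == 0 else float(stats.chi2.ppf(alpha / 2, 2 * m) / 2)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * (m + 1)) / 2)
    return lo, hi


@dataclass(frozen=True)
class RateEstimate:
    m: int
    n: int
    G: float  # analysed genome size in bp (diploid: 2 x EWC size)
    mu: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:  # printed the way rate tables are
        return f"{self.mu:.2g} ({self.ci_low:.2g}-{self.ci_high:.2g})"


def mutation_rate(m: int, n: int, G: float, conf: float = 0.95) -> RateEstimate:
    """Per-nucleotide per-generation rate with exact Poisson CI."""
    if m < 0:
        raise ValueError("negative mutation count")
    if n < 1 or G <= 0:
        raise ValueError("need n >= 1 offspring and G > 0")
    denom = n * G
    lo, hi = poisson_exact_ci(m, conf)
    return RateEstimate(m, n, G, m / denom, lo / denom, hi / denom)


@dataclass(frozen=True)
class AgingModel:
    """Linear parental-aging increments as fractions of the baseline count.

    r_paternal / r_maternal: fraction of the total 8-week baseline SNV count
    added per week of paternal / maternal age beyond the reference age.
    """

    r_paternal: float = 0.045
    r_maternal: float = 0.023
    reference_age_weeks: float = 8.0
    delta_weeks_paternal: float = 0.0
    delta_weeks_maternal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r_paternal, self.r_maternal) < 0:
            raise ValueError("aging rates must be >= 0")
        if min(self.delta_weeks_paternal, self.delta_weeks_maternal) < 0:
            raise ValueError("delta weeks must be >= 0")

    @property
    def weekly_total(self) -> float:
        """Expected aging additions per unit baseline count for this comparison."""
        return (
            self.r_paternal * self.delta_weeks_paternal
            + self.r_maternal * self.delta_weeks_maternal
        )


@dataclass(frozen=True)
class AgingRates:
    r_paternal: float
    r_maternal: float
    undefined: frozenset[str] = frozenset()


def aging_rate_from_phased_counts(
    before_paternal: int,
    before_maternal: int,
    after_paternal: int,
    after_maternal: int,
    delta_weeks_paternal: float,
    delta_weeks_maternal: float,
) -> AgingRates:
    """Weekly aging increments from phased counts before/after the age gap.

    Each parent's relative increase is rescaled by that parent's share of the
    phased baseline, giving the increment as a fraction of the *total*
    baseline count:  r = (after/before - 1) * (before/total_before) / dw.
    A zero baseline on one side leaves that rate undefined (NaN, flagged).
    """
    if delta_weeks_paternal <= 0 or delta_weeks_maternal <= 0:
        raise ValueError("age difference must be positive")
    total = before_paternal + before_maternal
    if total == 0:
        raise ValueError("no phased baseline mutations")
    undefined = set()

    def one(before: int, after: int, dw: float, label: str) -> float:
        if before == 0:
            undefined.add(label)
            return float("nan")
        return (after / before - 1.0) * (before / total) / dw

    rp = one(before_paternal, after_paternal, delta_weeks_paternal, "paternal")
    rm = one(before_maternal, after_maternal, delta_weeks_maternal, "maternal")
    return AgingRates(rp, rm, frozenset(undefined))


def aging_rate_from_two_studies(
    mu1: float, mu2: float, age1_weeks: float, age2_weeks: float
) -> float:
    """Weekly fractional SNV increase from two rate estimates at two ages."""
    if age2_weeks <= age1_weeks:
        raise ValueError("age2 must exceed age1")
    if mu1 <= 0:
        raise ValueError("baseline rate must be positive")
    return (mu2 / mu1 - 1.0) / (age2_weeks - age1_weeks)


def adjust_count_for_age(
    observed_after: float, baseline_before: float, model: AgingModel
) -> float:
    """Observed count minus the expected aging additions (may go negative)."""
    return observed_after - baseline_before * model.weekly_total


@dataclass(frozen=True)
class AgingUncertainty:
    """Propagate the sampling noise of the aging subtraction into the test.

    Per replicate the baseline count is re-drawn Poisson; with ``split`` the
    redrawn baseline is divided between parents by a Binomial before the
    per-parent weekly increments are applied.
    """

    baseline: float
    model: AgingModel
    paternal_share: float = 0.5
    split: bool = False

    def draw_subtractions(self, rng: np.random.Generator, reps: int) -> np.ndarray:
        base = rng.poisson(self.baseline, size=reps)
        mdl = self.model
        if not self.split:
            return base * mdl.weekly_total
        bp = rng.binomial(base, self.paternal_share)
        bm = base - bp
        # per-parent increments, rescaled from total-count fractions
        wp = mdl.r_paternal * mdl.delta_weeks_paternal / self.paternal_share
        wm = mdl.r_maternal * mdl.delta_weeks_maternal / (1 - self.paternal_share)
        return bp * wp + bm * wm


@dataclass(frozen=True)
class PoissonTestResult:
    p_two_tailed: float
    reps: int
    seed: int | None
    observed: tuple[float, float]
    aging_propagated: bool


def poisson_difference_test(
    m1: float,
    m2: float,
    reps: int = 100_000,
    seed: int | None = 0,
    aging_uncertainty: AgingUncertainty | None = None,
) -> PoissonTestResult:
    """Two-tailed Monte-Carlo test of a difference between two Poisson counts.

    Under the null both groups share the pooled mean (m1+m2)/2; the p-value
    is the proportion of simulated pairs whose absolute difference reaches
    the observed |m1-m2|.  With `aging_uncertainty`, m2 is an age-adjusted
    count: each replicate draws a raw count around the pooled mean plus the
    expected aging additions, then subtracts a re-drawn aging term.
    """
    if reps < 10_000:
        raise ValueError("need at least 10,000 replicates")
    rng = np.random.default_rng(seed)
    c = (m1 + m2) / 2.0
    if c < 0:
        raise ValueError("pooled mean is negative")
    x = rng.poisson(c, size=reps)
    if aging_uncertainty is None:
        y = rng.poisson(c, size=reps).astype(float)
    else:
        sub_mean = aging_uncertainty.baseline * aging_uncertainty.model.weekly_total
        y_raw = rng.poisson(c + sub_mean, size=reps)
        y = y_raw - aging_uncertainty.draw_subtractions(rng, reps)
    stat = abs(m1 - m2)
    p = float(np.mean(np.abs(x - y) >= stat - 1e-9))
    return PoissonTestResult(p, reps, seed, (m1, m2), aging_uncertainty is not None)


def extrapolate_per_offspring(
    m: float,
    n: int,
    ewc_fraction: float = 0.539,
    reps: int = 1000,
    seed: int | None = 0,
    ci: str = "simulation",
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """Autosome-wide mutations per offspring, extrapolated beyond the EWC region.

    Point estimate m / (n * ewc_fraction).  The interval either rescales the
    exact Poisson bounds (``ci="exact"``) or takes percentiles of Poisson
    re-draws of m (``ci="simulation"``, 1,000 replicates by default).
    """
    if not (0 < ewc_fraction <= 1):
        raise ValueError("ewc_fraction must be in (0, 1]")
    if n < 1 or m < 0:
        raise ValueError("need n >= 1 and m >= 0")
    denom = n * ewc_fraction
    point = m / denom
    if ci == "exact":
        lo, hi = poisson_exact_ci(int(round(m)), conf)
        return point, lo / denom, hi / denom
    if ci != "simulation":
        raise ValueError("ci must be 'exact' or 'simulation'")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(m, size=reps) / denom
    alpha = (1 - conf) / 2
    lo, hi = np.quantile(draws, [alpha, 1 - alpha])
    return point, float(lo), float(hi)


def region_distribution_test(
    observed: "np.typing.ArrayLike", region_fractions: "np.typing.ArrayLike"
) -> tuple[float, float]:
    """Chi-square test of mutation counts against region-size expectations."""
    obs = np.asarray(observed, dtype=float)
    frac = np.asarray(region_fractions, dtype=float)
    if obs.shape != frac.shape or obs.size < 2:
        raise ValueError("need >= 2 region classes with matching fractions")
    frac = frac / frac.sum()
    expected = obs.sum() * frac
    if np.any(expected <= 0):
        raise ValueError("expected count of zero in a region class")
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), float(p)
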