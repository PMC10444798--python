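"""Excess-burden testing, transformation timing and clone growth.

Colony mutation burdens are overdispersed relative to Poisson; the
overdispersion (variance/mean of burdens within an individual at one
timepoint) is modelled on the log scale as a linear function of age. A
clade's mean burden is tested against its age expectation under a negative
binomial with that overdispersion. The age at which a transformed clone
switched on its distinct mutational process is inferred by ABC rejection:
draw an age and a mutation rate, simulate the negative-binomial count of
steady-state mutations accrued by that age, and keep draws matching the
observed trunk count attributable to the steady-state signature. Clone
growth rate is estimated by maximum likelihood under the
exponential-growth coalescent from the clade's coalescence times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, lgamma, log

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ConfigurationError, DataError

__all__ = [
    "OverdispersionModel",
    "estimate_overdispersion",
    "BurdenTestResult",
    "burden_excess_test",
    "TransformationTiming",
    "abc_transformation_age",
    "GrowthFit",
    "fit_clade_growth",
    "growth_to_doubling_time",
    "doubling_time_to_growth",
    "hsc_mutation_influx",
]


# -- overdispersion of colony burdens ------------------------------------


@dataclass
class OverdispersionModel:
    per_timepoint: pd.DataFrame  # individual, age, n, mean, var, od
    intercept: float
    slope: float
    model: object

    def predict(self, age: float) -> tuple[float, tuple[float, float]]:
        """Overdispersion at ``age`` with a 95% prediction interval."""
        X = sm.add_constant(np.array([[age]]), has_constant="add")
        pred = self.model.get_prediction(X)
        frame = pred.summary_frame(alpha=0.05)
        return (
            float(np.exp(frame["mean"].iloc[0])),
            (
                float(np.exp(frame["obs_ci_lower"].iloc[0])),
                float(np.exp(frame["obs_ci_upper"].iloc[0])),
            ),
        )


def estimate_overdispersion(burdens, ages, groups) -> OverdispersionModel:
    """Variance/mean of burdens per timepoint, log-linear in age.

    ``groups`` identifies the individual/timepoint of each colony burden;
    timepoints with a single colony are excluded with a warning. Requires
    at least two usable timepoints at distinct ages.
    """
    df = pd.DataFrame({"burden": np.asarray(burdens, dtype=float),
                       "age": np.asarray(ages, dtype=float),
                       "group": np.asarray(groups)})
    rows = []
    for (grp, age), sub in df.groupby(["group", "age"]):
        if len(sub) < 2:
            warnings.warn(f"timepoint {grp!r} at age {age} has a single colony; excluded")
            continue
        mean = sub["burden"].mean()
        var = sub["burden"].var(ddof=1)
        rows.append({"individual": grp, "age": age, "n": len(sub),
                     "mean": mean, "var": var, "od": var / mean})
    per = pd.DataFrame(rows)
    if len(per) < 2 or per["age"].nunique() < 2:
        raise DataError("need >= 2 timepoints at distinct ages with >= 2 colonies each")
    X = sm.add_constant(per["age"].to_numpy())
    fit = sm.OLS(np.log(per["od"].to_numpy()), X).fit()
    return OverdispersionModel(
        per_timepoint=per,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        model=fit,
    )


# -- negative-binomial excess-burden test --------------------------------


@dataclass
class BurdenTestResult:
    observed: float
    expected_mean: float
    overdispersion: float
    size: float | None  # NB size parameter; None in the Poisson limit
    p_value: float


def _nb_tail_logspace(k0: int, size: float, p_success: float) -> float:
    """P(X >= k0) for NB(size, p) by log-space summation from k0 upward.

    Accumulates pmf terms with the pmf recurrence until they underflow
    relative to the running sum.
    """
    q = 1.0 - p_success
    lp = (
        lgamma(k0 + size) - lgamma(size) - lgamma(k0 + 1)
        + size * log(p_success) + k0 * log(q) if k0 > 0
        else size * log(p_success)
    )
    total = lp
    k = k0
    while True:
        lp = lp + log((k + size) / (k + 1.0)) + log(q)
        k += 1
        total = np.logaddexp(total, lp)
        if lp < total - 40.0 and k > k0 + 10:
            break
    return float(np.exp(min(total, 0.0)))


def burden_excess_test(
    observed: float, expected_mean: float, overdispersion: float
) -> BurdenTestResult:
    """One-sided upper-tail test of a clade's mean burden.

    Under the null the burden is NB with mean ``expected_mean`` and
    variance ``overdispersion`` times the mean (Poisson when the
    overdispersion is exactly 1). Returns P(X >= observed).
    """
    if expected_mean <= 0:
        raise ConfigurationError("expected_mean must be positive")
    if overdispersion < 1:
        raise ConfigurationError("overdispersion < 1 is outside the NB model")
    k0 = int(np.ceil(observed))
    if overdispersion == 1:
        p = float(stats.poisson.sf(k0 - 1, expected_mean))
        return BurdenTestResult(observed, expected_mean, overdispersion, None, p)
    size = expected_mean / (overdispersion - 1.0)
    p_success = size / (size + expected_mean)  # = 1/overdispersion
    p = _nb_tail_logspace(k0, size, p_success)
    return BurdenTestResult(observed, expected_mean, overdispersion, size, p)


# -- ABC timing of transformation ----------------------------------------


@dataclass
class TransformationTiming:
    samples: np.ndarray  # accepted transformation ages (years)
    median: float
    ci95: tuple[float, float]
    acceptance_rate: float
    priors: dict


def abc_transformation_age(
    observed_composite_count: float,
    overdispersion: float = 2.24,
    rate_prior_mean: float = 15.1,
    rate_prior_sd: float = 1.0,
    age_prior: tuple[float, float] = (0.0, 100.0),
    n_sims: int = 1_000_000,
    tolerance: float | None = None,
    seed=None,
) -> TransformationTiming:
    """Rejection-ABC posterior for the age at transformation.

    Steady-state mutations accrued by the transformation age are modelled
    as NB(mean = age x rate, variance = overdispersion x mean) with the
    rate drawn from Normal(rate_prior_mean, rate_prior_sd) and the age
    uniform on ``age_prior``; draws whose simulated count falls within
    ``tolerance`` (default 2% of the observation) of the observed
    composite-signature trunk count are accepted.
    """
    if observed_composite_count <= 0:
        raise ConfigurationError("observed count must be positive")
    lo, hi = age_prior
    if not (hi > lo >= 0):
        raise ConfigurationError("invalid age prior")
    if tolerance is None:
        tolerance = 0.02 * observed_composite_count
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n_sims)
    rates = rng.normal(rate_prior_mean, rate_prior_sd, size=n_sims)
    mean = ages * rates
    valid = mean > 0
    sim = np.zeros(n_sims)
    if overdispersion == 1:
        sim[valid] = rng.poisson(mean[valid])
    else:
        size = mean[valid] / (overdispersion - 1.0)
        sim[valid] = rng.negative_binomial(size, 1.0 / overdispersion)
    accept = valid & (np.abs(sim - observed_composite_count) <= tolerance)
    kept = ages[accept]
    if kept.size == 0:
        raise ConfigurationError(
            "ABC accepted no draws; increase tolerance or n_sims"
        )
    lo95, med, hi95 = np.percentile(kept, [2.5, 50, 97.5])
    return TransformationTiming(
        samples=kept,
        median=float(med),
        ci95=(float(lo95), float(hi95)),
        acceptance_rate=kept.size / n_sims,
        priors={
            "rate": (rate_prior_mean, rate_prior_sd),
            "age": age_prior,
            "overdispersion": overdispersion,
            "tolerance": tolerance,
        },
    )


# -- clone growth from coalescences --------------------------------------


@dataclass
class GrowthFit:
    growth_rate: float  # per year
    ci: tuple[float, float]
    annual_percent: float  # 100 * (e^g - 1)
    annual_percent_ci: tuple[float, float]
    doubling_months: float
    n_present: float  # implied clone size at sampling
    log_likelihood: float


def _growth_profile_loglik(g: float, taus: np.ndarray, n_tips: int,
                           max_log_n: float | None = None) -> tuple[float, float]:
    """Profile log-likelihood over the present clone size N at growth rate g.

    Backwards in time the clone has size N e^{-g tau}... i.e. coalescence
    rate C(k,2) e^{g tau} / N for k extant lineages. Returns (loglik, logN-hat).
    """
    taus = np.sort(taus)
    m = len(taus)  # = n_tips - 1 coalescences
    bounds = np.concatenate([[0.0], taus])
    ks = np.arange(n_tips, 1, -1)
    pairs = np.array([comb(int(k), 2) for k in ks], dtype=float)
    if g <= 0:
        raise ValueError("g must be positive")
    # log A(g), A = sum_k C(k,2) (e^{g b_k} - e^{g a_k}) / g, done in log space
    from scipy.special import logsumexp

    widths = bounds[1:] - bounds[:-1]
    with np.errstate(divide="ignore"):
        log_terms = (
            np.log(pairs) + g * bounds[1:] + np.log1p(-np.exp(-g * widths)) - np.log(g)
        )
    keep = np.isfinite(log_terms)  # zero-width intervals contribute nothing
    logA = float(logsumexp(log_terms[keep]))
    logN = logA - np.log(m)
    if max_log_n is not None and logN > max_log_n:
        logN = max_log_n
    integral = np.exp(min(logA - logN, 700.0))
    ll = float(np.sum(np.log(pairs)) + g * taus.sum() - m * logN - integral)
    return ll, logN


def _growth_conditioned_loglik(g: float, taus: np.ndarray, n_tips: int,
                               span: float) -> float:
    """Log-likelihood of coalescence times for a clone founded ``span`` years
    before sampling by a single cell (N at sampling = e^{g * span}).

    Each inter-coalescent waiting time is conditioned on the event
    happening before the founding, matching the constraint that the whole
    sample descends from the founder cell.
    """
    taus = np.sort(taus)
    bounds = np.concatenate([[0.0], taus])
    ks = np.arange(n_tips, 1, -1)
    pairs = np.array([comb(int(k), 2) for k in ks], dtype=float)
    a, b = bounds[:-1], bounds[1:]
    # integrated rate over (a, b): pairs/g * e^{-g(span-b)} (1 - e^{-g(b-a)})
    I_ab = pairs / g * np.exp(-g * (span - b)) * -np.expm1(-g * (b - a))
    I_a_span = pairs / g * -np.expm1(-g * (span - a))
    log_denom = np.log(-np.expm1(-np.maximum(I_a_span, 1e-300)))
    log_rate = np.log(pairs) - g * (span - b)
    return float(np.sum(log_rate - I_ab - log_denom))


def fit_clade_growth(
    coal_times: np.ndarray,
    n_tips: int | None = None,
    origin_bound: float | None = None,
    sampled_fraction: float = 1.0,
    g_bounds: tuple[float, float] = (1e-3, 200.0),
) -> GrowthFit:
    """ML growth rate of a clone from within-clade coalescence times.

    ``coal_times`` are the clade's coalescence times in years *before
    sampling* (backwards time); with n tips there are n-1 of them. With
    ``origin_bound`` (years before sampling) the clone is modelled as
    founded by a single cell at a time between the oldest coalescence and
    the bound; the founding time is profiled out and every coalescence is
    conditioned to predate the founding, leaving the growth rate as the
    parameter of interest. Without a bound, the rate and the present clone
    size are free and the size is profiled out. ``sampled_fraction``
    (clone fraction of the compartment represented by the sampled
    colonies) only scales the reported present size.
    """
    taus = np.sort(np.asarray(coal_times, dtype=float))
    if len(taus) < 2:
        raise DataError("need >= 2 coalescence events to fit growth")
    if np.allclose(taus, taus[0]):
        raise DataError("all coalescences at identical times: degenerate likelihood")
    if n_tips is None:
        n_tips = len(taus) + 1
    if origin_bound is not None and origin_bound <= taus[-1]:
        raise DataError("origin_bound must predate the oldest coalescence")

    def best_span(g):
        """Profile the founding time within (oldest coalescence, bound]."""
        lo = taus[-1] * (1 + 1e-9) + 1e-12
        hi = origin_bound
        if lo >= hi:  # oldest coalescence essentially at the bound
            return hi, _growth_conditioned_loglik(g, taus, n_tips, hi)
        r = optimize.minimize_scalar(
            lambda s: -_growth_conditioned_loglik(g, taus, n_tips, s),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
        )
        return float(r.x), -float(r.fun)

    def neg(gl):
        g = np.exp(gl)
        if origin_bound is not None:
            return -best_span(g)[1]
        return -_growth_profile_loglik(g, taus, n_tips, None)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(g_bounds[0]), np.log(g_bounds[1])), method="bounded",
        options={"xatol": 1e-6},
    )
    g_hat = float(np.exp(res.x))
    ll_max = -float(res.fun)
    if origin_bound is not None:
        span_hat, _ = best_span(g_hat)
        logN = g_hat * span_hat  # one founding cell at the fitted origin
    else:
        _, logN = _growth_profile_loglik(g_hat, taus, n_tips, None)

    # profile-likelihood 95% CI: 2 * (ll_max - ll(g)) <= 3.84
    cut = ll_max - 1.9207

    def deficit(gl):
        return -neg(gl) - cut

    lo_gl = np.log(g_bounds[0])
    hi_gl = np.log(g_bounds[1])
    g_lo = g_bounds[0] if deficit(lo_gl) > 0 else float(
        np.exp(optimize.brentq(deficit, lo_gl, res.x))
    )
    g_hi = g_bounds[1] if deficit(hi_gl) > 0 else float(
        np.exp(optimize.brentq(deficit, res.x, hi_gl))
    )
    pct = 100.0 * (np.exp(g_hat) - 1.0)
    return GrowthFit(
        growth_rate=g_hat,
        ci=(g_lo, g_hi),
        annual_percent=pct,
        annual_percent_ci=(100.0 * (np.exp(g_lo) - 1.0), 100.0 * (np.exp(g_hi) - 1.0)),
        doubling_months=growth_to_doubling_time(pct),
        n_present=float(np.exp(logN) / sampled_fraction),
        log_likelihood=ll_max,
    )


def growth_to_doubling_time(annual_growth_percent: float) -> float:
    """Doubling time in months for a clone growing by the given % per year."""
    if annual_growth_percent <= 0:
        raise ValueError(
            "doubling time is undefined (infinite) for non-positive growth"
        )
    return 12.0 * log(2.0) / log(1.0 + annual_growth_percent / 100.0)


def doubling_time_to_growth(months: float) -> float:
    """Inverse of :func:`growth_to_doubling_time`: % growth per year."""
    if months <= 0:
        raise ValueError("doubling time must be positive")
    return 100.0 * (2.0 ** (12.0 / months) - 1.0)


def hsc_mutation_influx(
    n_hsc: float = 200_000, mutations_per_year: float = 15.0,
    coding_fraction: float = 0.01,
) -> dict:
    """Mutations entering the HSC pool per year, total and coding.

    With ~50,000-200,000 active HSCs each accruing ~15 SNVs/year, a few
    million somatic mutations enter the pool annually, of which ~1% land
    in coding sequence.
    """
    total = n_hsc * mutations_per_year
    return {"total_per_year": total, "coding_per_year": total * coding_fraction}
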