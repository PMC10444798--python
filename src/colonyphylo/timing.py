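"""Ultrametric calibration of mutation trees in years.

Branch lengths in molecular time (mutation counts) are converted to years
under a Poisson branch model: the observed count on branch j is

    n_j ~ Poisson(duration_j * sensitivity_j * rate + excess_j)

with a single per-individual mutation rate (SNVs/year) and the hard
constraint that every root-to-tip path spans exactly the age at sampling.
Node times are parameterised by per-node stick-breaking fractions so the
age constraint holds by construction in every posterior sample. Internal
nodes are classified as embryonic or postnatal from their molecular
height (the same horizon the clonal-expansion rule uses: a node below
~75 mutations predates birth, since lineages carry ~50-65 mutations by
then); embryonic node times are confined to the development window.
Without this constraint the model is practically unidentifiable at a
single sampling age: stretching embryonic branches over years while
inflating the rate fits the counts almost as well as attributing them to
the developmental excess. An
elevated embryonic mutation rate is modelled as a total excess e spread
over each branch's overlap with the development window (first 0.25 years),
so each lineage receives e expected extra mutations. Inference is
random-walk Metropolis (adaptive during burn-in) over the fractions, the
rate and the excess, with split-Rhat convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceWarning, DataError
from .phylo import MutationTree
from .tree import CladeTree

__all__ = [
    "UltrametricTree",
    "fit_ultrametric",
    "time_mrca",
    "burden_rate_regression",
    "RateRegression",
]


@dataclass
class UltrametricTree:
    """Calibrated tree: node times in years plus posterior samples."""

    tree: CladeTree  # branch lengths = posterior median durations (years)
    node_time: np.ndarray  # posterior median node times
    node_time_samples: np.ndarray  # (n_samples, n_nodes)
    rate_samples: np.ndarray
    excess_samples: np.ndarray
    age: float
    rhat: dict

    @property
    def rate_summary(self) -> tuple[float, float, float]:
        """(median, 2.5%, 97.5%) of the mutation rate in SNVs/year."""
        lo, med, hi = np.percentile(self.rate_samples, [2.5, 50, 97.5])
        return float(med), float(lo), float(hi)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat of a (n_chains, n_draws) array."""
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def fit_ultrametric(
    mtree: MutationTree,
    age: float,
    n_chains: int = 4,
    n_iter: int = 20000,
    seed=None,
    dev_window: float = 0.25,
    max_excess: float = 150.0,
    max_rate: float = 100.0,
    emb_height_threshold: float = 75.0,
    rhat_threshold: float = 1.05,
) -> UltrametricTree:
    """Fit node times (years), mutation rate and embryonic excess by MCMC.

    Uses raw branch counts and branch sensitivities from ``mtree``
    (sensitivity 1 if lengths were never corrected). Priors: rate ~
    U(0, max_rate), excess ~ U(0, max_excess), stick-breaking fractions ~
    U(0, 1). Internal nodes whose molecular height is at most
    ``emb_height_threshold`` mutations are treated as embryonic and their
    times confined to the development window. Set ``max_excess=0`` to
    disable the embryonic excess.
    """
    if age <= 0:
        raise DataError("age at sampling must be positive")
    tree = mtree.tree
    n_nodes = tree.n_nodes
    parent = tree.parent
    counts = mtree.raw_count.astype(float)
    S = (
        mtree.branch_sensitivity
        if mtree.branch_sensitivity is not None
        else np.ones(n_nodes)
    )
    internal = np.array(tree.internal_ids, dtype=int)
    is_tip = np.array([tree.is_tip(i) for i in range(n_nodes)])
    n_int = len(internal)
    w = dev_window
    use_excess = max_excess > 0 and w > 0

    rng = np.random.default_rng(seed)

    heights = mtree.node_heights()
    # embryonic = ancestor-closed set of internal nodes below the horizon
    emb = (heights <= emb_height_threshold) & ~is_tip
    cap = np.where(emb, min(w, age) if w > 0 else age, age)

    frac_idx = np.full(n_nodes, -1)
    frac_idx[internal] = np.arange(n_int)

    def node_times(U: np.ndarray) -> np.ndarray:
        """U: (chains, n_int) fractions -> (chains, n_nodes) times (preorder)."""
        tau = np.empty((U.shape[0], n_nodes))
        for i in range(n_nodes):
            tp = tau[:, parent[i]] if parent[i] >= 0 else 0.0
            if is_tip[i]:
                tau[:, i] = age
            else:
                tau[:, i] = tp + U[:, frac_idx[i]] * (cap[i] - tp)
        return tau

    def log_lik(F, lam, exc) -> np.ndarray:
        """Poisson log-likelihood plus the stick-breaking log-Jacobian.

        The Jacobian term makes the node-time prior flat in *time* over the
        order-constrained region rather than flat in the fractions — a
        uniform-fraction prior would favour configurations where embryonic
        splits crowd the end of the window and bias the excess downward.
        """
        tau = node_times(F)
        tp = np.where(parent >= 0, tau[:, np.clip(parent, 0, None)], 0.0)
        dur = tau - tp
        mean = lam[:, None] * S[None, :] * dur
        if use_excess:
            overlap = np.clip(np.minimum(tau, w) - np.minimum(tp, w), 0.0, None)
            mean = mean + (exc[:, None] / w) * S[None, :] * overlap
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts[None, :] > 0, counts[None, :] * np.log(mean), 0.0)
            term = np.where((mean == 0) & (counts[None, :] > 0), -np.inf, term)
            jac = np.log(np.clip(cap[None, internal] - tp[:, internal], 0.0, None))
        jac = jac.sum(axis=1) if n_int else np.zeros(tau.shape[0])
        return (term - mean).sum(axis=1) + jac

    # over-dispersed initial points
    F = rng.uniform(0.05, 0.95, size=(n_chains, n_int))
    lam = rng.uniform(0.05 * max_rate, 0.6 * max_rate, size=n_chains)
    exc = rng.uniform(0.0, max_excess, size=n_chains) if use_excess else np.zeros(n_chains)

    # components: fractions, rate, excess, plus a joint (rate, excess) ridge
    # move that trades rate against excess at fixed expected tip burden —
    # the two are tightly anti-correlated through rate*age + excess, and
    # single-parameter moves mix very slowly along that valley.
    d = n_int + 1 + (2 if use_excess else 0)
    step = np.full(d, 0.2)
    step[n_int] = 0.1 * max_rate
    if use_excess:
        step[n_int + 1] = 0.1 * max_excess
        step[n_int + 2] = 1.0  # ridge step in rate units
    acc = np.zeros(d)
    tries = np.zeros(d)

    ll = log_lik(F, lam, exc)
    burn = n_iter // 2
    keep_every = max(1, (n_iter - burn) // 500)
    tau_store, lam_store, exc_store = [], [], []
    lam_trace, exc_trace = [], []

    for it in range(n_iter):
        for j in range(d):
            if j < n_int:
                prop = F[:, j] + step[j] * rng.standard_normal(n_chains)
                ok = (prop > 0) & (prop < 1)
                Fp = F.copy()
                Fp[:, j] = np.where(ok, prop, F[:, j])
                llp = log_lik(Fp, lam, exc)
                accept = ok & (np.log(rng.random(n_chains)) < llp - ll)
                F[accept, j] = Fp[accept, j]
            elif j == n_int:
                prop = lam + step[j] * rng.standard_normal(n_chains)
                ok = (prop > 0) & (prop < max_rate)
                lamp = np.where(ok, prop, lam)
                llp = log_lik(F, lamp, exc)
                accept = ok & (np.log(rng.random(n_chains)) < llp - ll)
                lam = np.where(accept, lamp, lam)
            elif j == n_int + 1:
                prop = exc + step[j] * rng.standard_normal(n_chains)
                ok = (prop >= 0) & (prop < max_excess)
                excp = np.where(ok, prop, exc)
                llp = log_lik(F, lam, excp)
                accept = ok & (np.log(rng.random(n_chains)) < llp - ll)
                exc = np.where(accept, excp, exc)
            else:  # ridge move: rate up, excess down by age * delta
                delta = step[j] * rng.standard_normal(n_chains)
                lamp = lam + delta
                excp = exc - age * delta
                ok = (
                    (lamp > 0) & (lamp < max_rate) & (excp >= 0) & (excp < max_excess)
                )
                lamp = np.where(ok, lamp, lam)
                excp = np.where(ok, excp, exc)
                llp = log_lik(F, lamp, excp)
                accept = ok & (np.log(rng.random(n_chains)) < llp - ll)
                lam = np.where(accept, lamp, lam)
                exc = np.where(accept, excp, exc)
            ll = np.where(accept, llp, ll)
            acc[j] += accept.mean()
            tries[j] += 1
        if it < burn and (it + 1) % 50 == 0:  # adapt during burn-in
            rate = acc / np.maximum(tries, 1)
            step *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            acc[:] = 0
            tries[:] = 0
        if it >= burn:
            lam_trace.append(lam.copy())
            if use_excess:
                exc_trace.append(exc.copy())
            if (it - burn) % keep_every == 0:
                tau_store.append(node_times(F))
                lam_store.append(lam.copy())
                exc_store.append(exc.copy())

    tau_samples = np.concatenate(tau_store, axis=0)  # (draws*chains, n_nodes)
    lam_samples = np.concatenate(lam_store)
    exc_samples = np.concatenate(exc_store)

    lam_tr = np.stack(lam_trace, axis=1)  # (chains, draws)
    rhat = {"rate": _split_rhat(lam_tr)}
    if use_excess:
        rhat["excess"] = _split_rhat(np.stack(exc_trace, axis=1))
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > rhat_threshold}
    if bad:
        warnings.warn(
            f"chains may not have converged (split-Rhat {bad}); "
            "increase n_iter or check the tree",
            ConvergenceWarning,
        )

    med_tau = np.median(tau_samples, axis=0)
    med_tau[is_tip] = age  # exact by construction
    durations = np.array(
        [med_tau[i] - (med_tau[parent[i]] if parent[i] >= 0 else 0.0) for i in range(n_nodes)]
    )
    cal = CladeTree(parent, tree.labels, durations)
    return UltrametricTree(
        tree=cal,
        node_time=med_tau,
        node_time_samples=tau_samples,
        rate_samples=lam_samples,
        excess_samples=exc_samples,
        age=age,
        rhat=rhat,
    )


def time_mrca(ult: UltrametricTree, tips) -> tuple[float, tuple[float, float]]:
    """Posterior timing of the MRCA of a clade of colonies.

    Returns (median age in years, central 95% credibility interval). The
    tip set must be exactly a clade of the tree.
    """
    s = frozenset(tips)
    node = ult.tree.mrca(s)
    if ult.tree.clade[node] != s:
        raise DataError("tip set is not monophyletic in the fitted tree")
    samples = ult.node_time_samples[:, node]
    lo, med, hi = np.percentile(samples, [2.5, 50, 97.5])
    return float(med), (float(lo), float(hi))


@dataclass
class RateRegression:
    slope: float
    conf_int: tuple[float, float]
    intercept: float
    per_individual: pd.DataFrame
    excluded: tuple
    model: object


def burden_rate_regression(
    burdens: pd.Series, ages: pd.Series, individuals: pd.Series, exclude=()
) -> RateRegression:
    """Mutation-accumulation rate: OLS of per-individual mean burden on age.

    A deliberately simple two-stage substitute for a mixed-effects model:
    colonies are first averaged within individual (one point per
    individual), then mean burden is regressed on age with an intercept.
    ``exclude`` drops flagged individuals (e.g. a transformed outlier) and
    is recorded on the result.
    """
    df = pd.DataFrame({"burden": burdens, "age": ages, "individual": individuals})
    df = df[~df["individual"].isin(set(exclude))]
    per = df.groupby("individual").agg(burden=("burden", "mean"), age=("age", "mean"))
    if per["age"].nunique() < 2:
        raise DataError("need colonies sampled at >= 2 distinct ages")
    X = sm.add_constant(per["age"].to_numpy())
    fit = sm.OLS(per["burden"].to_numpy(), X).fit()
    ci = fit.conf_int()
    return RateRegression(
        slope=float(fit.params[1]),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(fit.params[0]),
        per_individual=per,
        excluded=tuple(exclude),
        model=fit,
    )
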