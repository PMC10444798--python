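"""Time a malignant transformation and estimate clone growth.

An MDS-like individual: a TP53 clade founded at age 19 (sampling at 25)
whose mutations after transformation arrive 5x faster and are 65%
SBS1-like. The trunk spectrum is decomposed into the steady-state
(composite) and transformation profiles, the composite count is converted
to an age by ABC rejection, and the clade's coalescences give the clone
growth rate.
"""

import numpy as np

import colonyphylo as cp
from colonyphylo.signatures import compute_spectrum, pooled_profile
from colonyphylo.simdata import drop_mutations, simulate_phylogeny

age, origin = 25.0, 19.0
cfg = cp.SimConfig(
    n_colonies=20, age=age, seed=3,
    clades=[cp.CladeConfig(origin_age=origin, n_tips=12, growth_rate=4.0,
                           sbs1_fraction=0.65, rate_multiplier=5.0)],
)
rc, truth = cp.simulate_individual(cfg)

m = truth.mutations
trunk_node = truth.trunk_nodes[0]
trunk = compute_spectrum(m[m["node"] == trunk_node])
end_nodes = [i for i in truth.tree.tip_ids if truth.node_clade[i] == 0]
transformation = compute_spectrum(m[m["node"].isin(end_nodes)]).normalised()

# composite = pooled spectrum of comparator individuals without a clade
comps = []
for j in range(3):
    c = cp.SimConfig(n_colonies=8, age=age, seed=100 + j, n_germline_het_sites=0)
    comps.append(compute_spectrum(drop_mutations(simulate_phylogeny(c), c).mutations))
p_comp, p_trans, cos = cp.decompose_trunk(trunk, pooled_profile(comps), transformation)
print(f"trunk of {trunk.total:.0f} SNVs: {p_comp:.2f} steady-state + "
      f"{p_trans:.2f} transformation (cosine {cos:.3f})")

# excess burden of the clade against the cohort expectation
clade_burden = truth.tip_burden[[truth.tree.labels[i] for i in end_nodes]].mean()
expected = 57.5 + 15.0 * age
r = cp.burden_excess_test(clade_burden, expected, overdispersion=2.24)
print(f"clade burden {clade_burden:.0f} vs expected {expected:.0f}: "
      f"p = {r.p_value:.2e} (NB, variance 2.24x mean)")

composite_count = max(p_comp * trunk.total - 57.5, 1.0)
abc = cp.abc_transformation_age(
    composite_count, overdispersion=2.24, rate_prior_mean=15.1, rate_prior_sd=1.0,
    age_prior=(0.0, age), n_sims=500_000, seed=5,
)
print(f"transformation age: {abc.median:.1f} yr "
      f"(95% CI {abc.ci95[0]:.1f}-{abc.ci95[1]:.1f}; truth {origin})")

coal_tau = age - truth.clade_coalescence_ages(0)
bound = max(age - abc.ci95[0], 1.02 * coal_tau.max())
fit = cp.fit_clade_growth(coal_tau, n_tips=12, origin_bound=bound)
print(f"clone growth: {fit.annual_percent:.0f}%/yr "
      f"(CI {fit.annual_percent_ci[0]:.0f}-{fit.annual_percent_ci[1]:.0f}), "
      f"doubling every {fit.doubling_months:.1f} months "
      f"(truth {100 * (np.exp(4.0) - 1):.0f}%/yr)")
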