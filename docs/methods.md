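# Methods

This note documents the models behind `colonyphylo`, the choices that were
genuinely open, and what the synthetic-data experiments do and do not
establish.

## Observation model and genotype calling

A colony grown from a single diploid cell carries each somatic SNV of its
founder heterozygously, so the expected variant allele fraction (VAF) is
0.5 in a clonal colony, scaled down by the colony's clonality when the
outgrowth is contaminated by unrelated cells. Read counts are modelled as
MTR ~ Binomial(DEP, p) with p the expected VAF at a mutant site and the
per-read error rate (default 0.01) at a wild-type site. The caller
compares the two binomial likelihoods and requires a ratio of at least 20
(ties count as decided); anything less ambiguous is NA, as is any site
with zero depth (the data carry no evidence either way — a stated choice,
not forced by the model). Expected VAF is 0.5 on diploid autosomes and
1/ploidy on X, Y and per-colony copy-number regions; an absent call
inside a colony's LOH interval is overridden to NA because the reference
allele itself may be lost there. Positions and intervals are 1-based and
closed, following VCF conventions for point variants.

Colony QC removes colonies with mean depth strictly below 6x or median
somatic VAF strictly below 0.4 (boundary values are retained). The median
VAF is taken over sites the colony carries — quick genotype call of 1 at
expected VAF 0.5 — restricted to depth ≥ 4, which avoids zero-depth noise;
the carried-site definition is a documented package choice.

## Topology, assignment, sensitivity

Only SNVs inform the topology. Carrier sets (colonies called 1; NAs
ignored per site) are ranked by support and added greedily while they
remain laminar, which yields the perfect phylogeny exactly whenever one
exists; nearest-neighbour-interchange hill climbing on the Fitch
parsimony score (missing entries treated as ambiguous, multifurcations
resolved by sequential intersection) polishes the tree otherwise. The
tree is rooted at the all-absent outgroup profile. This deliberately
replaces large-scale bootstrap parsimony search: colony data at this
scale are conflict-free or nearly so, and the scientific content lies
downstream of the topology.

Each mutation (SNVs and indels) is then hard-assigned to the branch whose
implied carrier clade maximises the product of binomial likelihoods over
colonies, under a uniform prior over branches; the root's stem acts as
the branch carried by every colony. Exact likelihood ties break to the
lowest preorder branch index — deterministic, and favouring the shallower
branch.

Detection sensitivity per colony is the recovered fraction of germline
heterozygous sites, times a clonality correction min(1, median VAF/0.5).
A branch's mutations are discoverable if detected in at least one carrier,
giving branch sensitivity 1 − ∏(1 − s_i·c_i); observed branch counts are
divided by this. The at-least-one-carrier form is our own (the source
tooling does not print its formula); it is validated against the
generator, where corrected burdens are unbiased within Monte-Carlo error.
Copy-number regions present in any colony of an individual are masked in
all of that individual's colonies, and burdens rescaled by
1/(1 − masked fraction of the genome).

## Ultrametric timing

Branch counts follow n_j ~ Poisson(t_j · S_j · λ + e_j): t_j the branch
duration in years, S_j its detection sensitivity, λ a single
per-individual rate (SNVs/year), and e_j an embryonic excess. Node times
are stick-breaking fractions of the remaining time to the tips, so every
root-to-tip path equals the age at sampling exactly in every posterior
sample. Three structural choices matter and are ours:

- **Excess attribution.** The embryonic excess is a single parameter e
  (prior U(0, 150)) spread over each branch's overlap with a fixed
  development window (0, 0.25) years, so each lineage receives e expected
  extra mutations wherever its early branches lie. Attributing e to one
  "earliest segment" per path misallocates load carried by deeper
  pre-birth branches and biases λ upward.
- **Embryonic horizon.** At a single sampling age the model is nearly
  unidentifiable: stretching pre-birth branches over years while
  inflating λ fits the counts almost as well as the excess does. Internal
  nodes are therefore classified by their molecular height — at most 75
  mutations (the same horizon as the expansion rule, since lineages carry
  ~50–65 mutations by birth) means pre-birth — and embryonic node times
  are confined to the development window. A clone genuinely founded
  within the first months of life would be misclassified; at desk scale
  configured clades sit years later.
- **Flat-in-time prior.** The stick-breaking log-Jacobian is added to the
  posterior so the node-time prior is uniform over the order-constrained
  time region. A uniform-fraction prior instead concentrates embryonic
  splits at the end of the window, which systematically deflates e.

Sampling is component-wise random-walk Metropolis, vectorised across
chains, with step sizes adapted to ~0.44 acceptance during the first half
(burn-in), plus a joint (λ, e) proposal moving along the λ·age + e ridge
— the two parameters are tightly anti-correlated through the total burden
and single-parameter moves alone mix poorly along that valley. Priors:
λ ~ U(0, 100) SNVs/yr, e ~ U(0, 150). Chains start over-dispersed;
split-R̂ above 1.05 raises a `ConvergenceWarning`. Defaults are 4 chains ×
20,000 iterations; the recovery experiments in the test suite use 4 ×
2,500–4,000 on 12–20 colonies, a problem size chosen so the whole suite
runs comfortably while λ = 15/yr stays inside the 95% credibility
interval in ≥ 90% of seeded replicates.

MRCA ages of clades are posterior summaries of the corresponding node
time. The cohort mutation rate is a deliberately simple two-stage
substitute for a mixed model: per-individual mean burden, then OLS of
mean burden on age with an intercept; exclusions (e.g. a transformed
outlier individual) are explicit arguments recorded on the result.

## Expansions, drivers, signatures

A post-embryonic clonal expansion is a clade of ≥ 2 colonies whose MRCA
molecular height exceeds 75 mutations strictly; heights use
sensitivity-corrected lengths by default (a flag switches to raw counts —
whether the original analysis corrected first is not stated anywhere we
could verify). Nested qualifying clades report only their outermost
ancestor. The driver screen is purely annotation-based (consequence
tokens × configurable gene list in `data/drivers.yaml`; chr7q/15q LOH
flagged as dosage events); no selection inference is attempted.

Spectra use the standard 96 pyrimidine-strand channels; purine-strand
records are reverse-complemented, and shared mutations can be assigned
once to a random colony to avoid double counting. Refitting fixed
signatures is multinomial maximum likelihood via EM (equal-proportion
initialisation, likelihood-gain tolerance 1e-8); the EM likelihood is
non-decreasing and the fit is invariant to consistent channel
permutation. The packaged reference profiles are *synthetic stand-ins* —
an SBS1-like profile concentrated on NpCpG C>T and a broad
SBSblood-like profile with disjoint dominant channels — chosen so
recovery is well conditioned; they are not the COSMIC vectors, and
analyses of real data should supply the published references instead. The
composite (steady-state) profile for trunk decomposition is the pooled,
normalised spectrum of comparator individuals; pooled-vs-averaged is
irrelevant after normalisation when comparators contribute similar
totals.

## Burden excess, transformation timing, growth

Within-individual burden overdispersion (variance/mean at a timepoint;
single-colony timepoints excluded with a warning) is modelled log-linearly
in age by OLS, with prediction intervals on the natural scale. The
excess-burden test treats a clade as one observation at its mean burden
and computes the NB upper tail with size = mean/(od − 1) (exactly Poisson
at od = 1) by log-space summation of the pmf recurrence until terms
underflow; the implementation agrees with an independent cumulative
oracle to machine precision in log-p.

Transformation age: ABC rejection with age ~ U(lo, hi), rate ~
N(15.1, sd 1) ("variance of 1" is read literally as variance), simulated
count ~ NB(mean = age × rate, variance = 2.24 × mean), acceptance within
a tolerance defaulting to 2% of the observed count (the original
tolerance is not printed; ours is an exposed flag). The observed count
should be the trunk mutations attributable to the steady-state signature
*since birth*; the pipeline subtracts the fitted embryonic excess before
running ABC.

Clone growth uses the exponential-growth coalescent: backwards from
sampling the clone has size N(τ) = N·e^{−gτ} and k lineages coalesce at
rate C(k,2)/N(τ). With an origin bound, the clone is modelled as founded
by one cell at a time profiled between the oldest coalescence and the
bound, and every waiting time is conditioned to predate the founding —
without this conditioning the pure coalescent lets the last lineages
outlive the founder, and fitting unconditioned draws overestimates g.
Without a bound, (g, N) are fit with N profiled analytically.
Profile-likelihood 95% CIs come from the 1.92 log-likelihood drop.
The generator draws clade genealogies from the same conditioned process
by per-step truncated inverse transform, and the recovery experiment
(g = 4/yr, 20 tips) covers the truth in ≥ 90% of replicates. Doubling
time is 12·ln 2 / ln(1 + percent/100) months, undefined (reported as an
explicit error) for non-positive growth.

## The generator, and what passing tests show

`simdata` emulates: clonal colonies (VAF 0.5 × clonality), Poisson depth
around 20x, binomial reads with a 1% error floor, germline-het sites for
sensitivity estimation, embryonic coalescence uniform in the first 0.25
years, per-individual embryonic load uniform on 50–65 spread as an
elevated rate across the window, postnatal accrual at 15 SNVs/yr,
signature-labelled channels (background 12% SBS1-like), and configured
clades with exponential-growth genealogies, optional post-transformation
rate multipliers and a planted annotated driver on the trunk. The
embryonic load is one integer per individual rather than per lineage —
independent per-lineage loads cannot be made consistent on shared
branches.

It does not emulate: mapping or alignment artefacts, indel/SV calling
noise, depth overdispersion beyond Poisson, contamination between
colonies, non-clock mutation processes other than the configured clade
multiplier, or recurrent (non-infinite-sites) mutation. Recovery on these
fixtures therefore demonstrates internal consistency of the estimators
under their stated models at cohort-realistic sizes — not robustness to
the artefact structure of real sequencing data, whose upstream filtering
is out of scope here.

## Degenerate inputs and errors

Empty QC results, all-colony removal, missing germline sites,
zero-sensitivity branches, non-monophyletic tip sets for MRCA timing,
masked fractions ≥ 1, overdispersion < 1, zero-total spectra, zero ABC
acceptances and fully tied coalescence times all raise typed exceptions
(`colonyphylo.errors`) with actionable messages rather than propagating
NaNs.
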