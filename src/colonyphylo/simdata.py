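"""Synthetic individuals: genealogies, mutations and colony read counts.

The generator emulates whole-genome sequencing of single-cell-derived
haematopoietic colonies from one individual. Lineages that are not part of
a configured clonal expansion coalesce within the embryonic window (first
0.25 years); each configured clade is founded at its origin age and its
tips coalesce under the exponential-growth coalescent at the configured
growth rate. Somatic mutations accumulate as a Poisson process along
branches (~15 SNVs/year by default) on top of an embryonic excess of
~50-65 mutations per lineage, each mutation carrying a 96-channel
trinucleotide label drawn from a mixture of a clock-like SBS1-like profile
and a broad HSC-background profile. Read counts then follow the same
binomial observation model the genotype caller assumes: DEP ~
Poisson(mean depth), MTR ~ Binomial(DEP, 0.5 x clonality) for carriers and
Binomial(DEP, error rate) otherwise, plus germline heterozygous sites
(carried by every colony at VAF 0.5) for sensitivity estimation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotype import ReadCountSet
from .signatures import CHANNELS, synthetic_reference_signatures
from .tree import CladeTree

__all__ = [
    "CladeConfig",
    "SimConfig",
    "TruePhylogeny",
    "simulate_phylogeny",
    "drop_mutations",
    "simulate_reads",
    "simulate_individual",
    "write_fixture",
    "sample_growth_coalescent",
]

_AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class CladeConfig:
    """One post-embryonic clonal expansion to plant in the genealogy."""

    origin_age: float  # years; clade founded at this age
    n_tips: int
    growth_rate: float  # per year (exponential clone growth)
    sbs1_fraction: float = 0.65  # SBS1-like channel fraction after transformation
    rate_multiplier: float = 1.0  # post-transformation mutation rate multiplier
    driver_gene: str | None = "TP53"  # annotated driver planted on the trunk
    name: str | None = None


@dataclass
class SimConfig:
    n_colonies: int
    age: float  # years at sampling
    mutation_rate: float = 15.0  # SNVs/year
    embryonic_mutations: tuple[int, int] = (50, 65)  # per-lineage load by birth
    mean_depth: float = 20.0
    error_rate: float = 0.01
    clonality: float = 1.0  # expected somatic VAF = 0.5 * clonality
    clades: list[CladeConfig] = field(default_factory=list)
    background_sbs1_fraction: float = 0.12
    n_germline_het_sites: int = 200
    seed: int = 0
    individual: str = "sim01"
    dev_window: float = 0.25  # years; embryonic coalescence + excess window

    def validate(self) -> None:
        if self.n_colonies < 1:
            raise ConfigurationError("need at least one colony")
        if self.age <= 0:
            raise ConfigurationError("age must be positive")
        if self.mutation_rate < 0 or self.error_rate < 0 or self.mean_depth < 0:
            raise ConfigurationError("rates must be nonnegative")
        if not 0 < self.clonality <= 1:
            raise ConfigurationError("clonality must lie in (0, 1]")
        lo, hi = self.embryonic_mutations
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid embryonic mutation range")
        total = 0
        for i, c in enumerate(self.clades):
            label = c.name or f"clade{i}"
            if not 0 <= c.origin_age < self.age:
                raise ConfigurationError(
                    f"{label}: origin_age {c.origin_age} must lie in [0, age={self.age})"
                )
            if c.n_tips < 1:
                raise ConfigurationError(f"{label}: n_tips must be >= 1")
            if c.growth_rate < 0:
                raise ConfigurationError(f"{label}: growth_rate must be >= 0")
            if c.rate_multiplier < 0:
                raise ConfigurationError(f"{label}: rate_multiplier must be >= 0")
            if not 0 <= c.sbs1_fraction <= 1:
                raise ConfigurationError(f"{label}: sbs1_fraction must lie in [0, 1]")
            total += c.n_tips
        if total > self.n_colonies:
            raise ConfigurationError(
                f"clade tips ({total}) exceed n_colonies ({self.n_colonies})"
            )


@dataclass
class TruePhylogeny:
    """Ground-truth genealogy, with mutations once they have been dropped."""

    tree: CladeTree  # branch lengths in years
    node_time: np.ndarray  # years since conception (root-side of stem = 0)
    age: float
    node_clade: np.ndarray  # clade index per node; -1 = background
    trunk_nodes: dict[int, int]  # clade index -> MRCA node id (owns the trunk branch)
    config: SimConfig
    mutations: pd.DataFrame | None = None  # one row per simulated mutation
    branch_count: np.ndarray | None = None  # per-node assigned mutation counts
    tip_burden: pd.Series | None = None
    embryonic_load: int | None = None

    def clade_coalescence_ages(self, clade_idx: int) -> np.ndarray:
        """Ages (years) of all coalescences within a configured clade."""
        mrca = self.trunk_nodes[clade_idx]
        ages = []
        stack = [mrca]
        while stack:
            i = stack.pop()
            if self.tree.children[i]:
                ages.append(self.node_time[i])
                stack.extend(self.tree.children[i])
        return np.sort(np.asarray(ages))


def sample_growth_coalescent(n_tips: int, growth_rate: float, span: float,
                             rng=None) -> np.ndarray:
    """Coalescence times (backwards from sampling) for an exponentially growing clone.

    The clone is founded by a single cell ``span`` years before sampling and
    grows at rate ``growth_rate`` per year, so looking backwards the
    population is N(tau) = exp(growth_rate * (span - tau)) and k lineages
    coalesce at rate C(k,2)/N(tau). Each waiting time is drawn by inverse
    transform of the time-rescaled exponential, truncated so the event
    falls before the founding — the sample must coalesce fully within
    ``span`` because the clone descends from a single cell (the pure
    coalescent approximation would otherwise let the last few lineages
    outlive the founder). Returns the n-1 times sorted ascending (most
    recent first).
    """
    rng = np.random.default_rng(rng)
    if n_tips < 2:
        return np.array([])
    if span <= 0:
        raise ConfigurationError("span must be positive")
    g = float(growth_rate)
    taus = []
    tau = 0.0
    for k in range(n_tips, 1, -1):
        pairs = comb(k, 2)
        u = rng.random()
        if g == 0:  # constant population of size 1 back to the founding
            e_max = pairs * (span - tau)
            e = -np.log1p(-u * (1.0 - np.exp(-e_max)))
            tau = tau + e / pairs
        else:
            # truncation bound: tau_new < span  <=>  E < e_max
            log_emax = np.log(pairs / g) + np.log1p(-np.exp(-g * (span - tau)))
            e = -np.log1p(-u * -np.expm1(-np.exp(log_emax)))
            tau = np.logaddexp(g * tau, np.log(g * e / pairs) + g * span) / g
        taus.append(min(tau, span * (1 - 1e-12)))
        tau = taus[-1]
    return np.asarray(taus)


class _Node:
    __slots__ = ("time", "children", "label", "clade")

    def __init__(self, time, children=None, label=None, clade=-1):
        self.time = time
        self.children = children or []
        self.label = label
        self.clade = clade


def _clade_subtree(labels, cfg: CladeConfig, clade_idx: int, age: float, rng) -> _Node:
    tips = [_Node(age, label=lab, clade=clade_idx) for lab in labels]
    if len(tips) == 1:
        return tips[0]
    taus = sample_growth_coalescent(len(tips), cfg.growth_rate, age - cfg.origin_age, rng)
    lineages = list(tips)
    for tau in taus:  # ascending backwards time = merges from most recent
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = _Node(age - tau, children=[lineages[i], lineages[j]], clade=clade_idx)
        lineages[i] = node
        del lineages[j]
    return lineages[0]


def simulate_phylogeny(config: SimConfig) -> TruePhylogeny:
    """Draw the true ultrametric genealogy of the configured individual."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    names = [f"c{i:03d}" for i in range(config.n_colonies)]
    pos = 0
    units: list[_Node] = []
    mrca_of_clade: list[_Node | None] = []
    for ci, c in enumerate(config.clades):
        labels = names[pos : pos + c.n_tips]
        pos += c.n_tips
        sub = _clade_subtree(labels, c, ci, config.age, rng)
        mrca_of_clade.append(sub)
        units.append(sub)
    for lab in names[pos:]:
        units.append(_Node(config.age, label=lab))

    if len(units) == 1:
        root = units[0]
    else:
        merge_times = np.concatenate(
            [[0.0], rng.uniform(0.0, config.dev_window, size=len(units) - 2)]
        )
        lineages = list(units)
        for t in np.sort(merge_times)[::-1]:  # deepest merge (t=0) last
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            node = _Node(t, children=[lineages[i], lineages[j]])
            lineages[i] = node
            del lineages[j]
        root = lineages[0]

    # flatten in preorder
    order: list[_Node] = []
    parent_idx: list[int] = []
    stack: list[tuple[_Node, int]] = [(root, -1)]
    while stack:
        node, p = stack.pop()
        idx = len(order)
        order.append(node)
        parent_idx.append(p)
        for ch in reversed(node.children):
            stack.append((ch, idx))
    times = np.array([n.time for n in order])
    lengths = np.array(
        [t - (times[p] if p >= 0 else 0.0) for t, p in zip(times, parent_idx)]
    )
    tree = CladeTree(parent_idx, [n.label for n in order], lengths)
    node_clade = np.array([n.clade for n in order])
    trunk_nodes = {ci: order.index(m) for ci, m in enumerate(mrca_of_clade)}
    # the clade MRCA's own branch is the (mixed) trunk, not the transformed interior
    return TruePhylogeny(
        tree=tree,
        node_time=times,
        age=config.age,
        node_clade=node_clade,
        trunk_nodes=trunk_nodes,
        config=config,
    )


def _channel_fields(channel: str, rng) -> tuple[str, str, str]:
    """Context/ref/alt for a channel, emitted on a random strand."""
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    ctx = five + ref + three
    if rng.random() < 0.5:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ctx = "".join(comp[b] for b in reversed(ctx))
        ref, alt = comp[ref], comp[alt]
    return ctx, ref, alt


def drop_mutations(phylo: TruePhylogeny, config: SimConfig) -> TruePhylogeny:
    """Scatter signature-labelled mutations on the true genealogy.

    Postnatal counts per branch are Poisson(duration x mutation rate); the
    embryonic load (one uniform integer total per individual) is spread as
    an elevated rate over each branch's overlap with the development
    window, so every root-to-tip lineage receives that load in expectation.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    lo, hi = config.embryonic_mutations
    e_total = int(rng.integers(lo, hi + 1))
    w = config.dev_window
    refs = synthetic_reference_signatures()
    prof = {"sbs1": refs["SBS1like"].to_numpy(), "blood": refs["SBSbloodlike"].to_numpy()}

    tree, times = phylo.tree, phylo.node_time
    origin_of = {ci: c.origin_age for ci, c in enumerate(config.clades)}
    sbs1_of = {ci: c.sbs1_fraction for ci, c in enumerate(config.clades)}
    trunk_clade = {node: ci for ci, node in phylo.trunk_nodes.items()}

    chrom_cycle = 0
    pos_counter: dict[str, int] = {c: 0 for c in _AUTOSOMES}
    rows = []
    branch_count = np.zeros(tree.n_nodes, dtype=int)

    def emit(node: int, mtime: float, sbs1_frac: float, gene: str = "",
             consequence: str = "intergenic_variant"):
        nonlocal chrom_cycle
        which = "sbs1" if rng.random() < sbs1_frac else "blood"
        channel = CHANNELS[rng.choice(96, p=prof[which])]
        ctx, ref, alt = _channel_fields(channel, rng)
        chrom = _AUTOSOMES[chrom_cycle % 22]
        chrom_cycle += 1
        pos_counter[chrom] += 1
        rows.append(
            {
                "site_id": f"s{len(rows):06d}",
                "chrom": chrom,
                "pos": 10_000 + 1_000 * pos_counter[chrom],
                "ref": ref,
                "alt": alt,
                "context": ctx,
                "gene": gene,
                "consequence": consequence,
                "channel": channel,
                "node": node,
                "time": mtime,
                "clade": int(phylo.node_clade[node]),
            }
        )
        branch_count[node] += 1

    bg = config.background_sbs1_fraction
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        t_p = times[p] if p >= 0 else 0.0
        t_c = times[i]
        ci = int(phylo.node_clade[i])
        # piecewise-constant mutation process: the trunk switches from the
        # background regime to the transformed regime at the clade origin
        if i in trunk_clade:
            cj = trunk_clade[i]
            o = origin_of[cj]
            segments = []
            if t_p < o:
                segments.append((t_p, min(t_c, o), 1.0, bg))
            if t_c > o:
                segments.append((max(t_p, o), t_c, config.clades[cj].rate_multiplier,
                                 sbs1_of[cj]))
        elif ci >= 0:
            segments = [(t_p, t_c, config.clades[ci].rate_multiplier, sbs1_of[ci])]
        else:
            segments = [(t_p, t_c, 1.0, bg)]
        for lo_t, hi_t, mult, f in segments:
            n = rng.poisson((hi_t - lo_t) * config.mutation_rate * mult)
            for t in np.sort(rng.uniform(lo_t, hi_t, size=n)) if n else []:
                emit(i, float(t), f)
        overlap = max(0.0, min(t_c, w) - min(t_p, w))
        n_emb = rng.poisson(overlap * e_total / w) if w > 0 else 0
        if n_emb:
            for t in rng.uniform(min(t_p, w), min(t_c, w), size=n_emb):
                emit(i, float(t), bg)

    for ci, c in enumerate(config.clades):
        if c.driver_gene:
            node = phylo.trunk_nodes[ci]
            emit(node, times[node], config.background_sbs1_fraction,
                 gene=c.driver_gene, consequence="missense_variant")

    columns = ["site_id", "chrom", "pos", "ref", "alt", "context", "gene",
               "consequence", "channel", "node", "time", "clade"]
    mutations = pd.DataFrame(rows, columns=columns).set_index("site_id")
    heights = tree.node_heights(branch_count.astype(float))
    burden = pd.Series(
        {tree.labels[i]: heights[i] for i in tree.tip_ids}, name="burden"
    ).sort_index()
    return dataclasses.replace(
        phylo,
        mutations=mutations,
        branch_count=branch_count,
        tip_burden=burden,
        embryonic_load=e_total,
    )


def simulate_reads(phylo: TruePhylogeny, config: SimConfig) -> ReadCountSet:
    """Generate MTR/DEP matrices under the binomial observation model."""
    if phylo.mutations is None:
        raise ConfigurationError("drop_mutations must run before simulate_reads")
    rng = np.random.default_rng([int(config.seed), 2])
    tree = phylo.tree
    colonies = sorted(tree.tips)
    col_index = {c: j for j, c in enumerate(colonies)}

    som = phylo.mutations
    n_som, n_col = len(som), len(colonies)
    carrier = np.zeros((n_som, n_col), dtype=bool)
    for r, node in enumerate(som["node"].to_numpy()):
        for lab in tree.clade[node]:
            carrier[r, col_index[lab]] = True

    n_germ = config.n_germline_het_sites
    grows = []
    refs = synthetic_reference_signatures()
    blood = refs["SBSbloodlike"].to_numpy()
    for gidx in range(n_germ):
        channel = CHANNELS[rng.choice(96, p=blood)]
        ctx, ref, alt = _channel_fields(channel, rng)
        chrom = _AUTOSOMES[gidx % 22]
        grows.append(
            {
                "site_id": f"g{gidx:05d}",
                "chrom": chrom,
                "pos": 500_000_000 + 1_000 * (gidx // 22 + 1),
                "ref": ref,
                "alt": alt,
                "context": ctx,
                "gene": "",
                "consequence": "",
                "is_germline": True,
            }
        )
    gsites = pd.DataFrame(grows).set_index("site_id") if grows else None

    ssites = som[["chrom", "pos", "ref", "alt", "context", "gene", "consequence"]].copy()
    ssites["is_germline"] = False
    sites = pd.concat([ssites, gsites]) if gsites is not None else ssites

    n_sites = len(sites)
    dep = rng.poisson(config.mean_depth, size=(n_sites, n_col))
    p = np.full((n_sites, n_col), config.error_rate)
    p[:n_som][carrier] = 0.5 * config.clonality
    p[n_som:] = 0.5  # germline het: every cell carries it regardless of clonality
    mtr = rng.binomial(dep, p)

    mtr_df = pd.DataFrame(mtr, index=sites.index, columns=colonies)
    dep_df = pd.DataFrame(dep, index=sites.index, columns=colonies)
    cdf = pd.DataFrame(index=pd.Index(colonies, name="colony"))
    cdf["individual"] = config.individual
    cdf["age_years"] = config.age
    tip_clade = {tree.labels[i]: int(phylo.node_clade[i]) for i in tree.tip_ids}
    cdf["true_clade"] = [tip_clade[c] for c in colonies]
    return ReadCountSet(mtr_df, dep_df, sites, cdf)


def simulate_individual(config: SimConfig) -> tuple[ReadCountSet, TruePhylogeny]:
    """Full generator: genealogy, mutations, then read counts."""
    phylo = simulate_phylogeny(config)
    phylo = drop_mutations(phylo, config)
    return simulate_reads(phylo, config), phylo


def truth_mutation_tree(phylo: TruePhylogeny):
    """True mutation tree (perfect detection) as a :class:`~colonyphylo.phylo.MutationTree`.

    Bypasses the read-count layer: branch counts are the true simulated
    counts and every mutation is assigned to its true branch, which is the
    natural input for parameter-recovery experiments on the timing model.
    """
    from .phylo import MutationTree

    if phylo.mutations is None:
        raise ConfigurationError("drop_mutations must run first")
    muts = phylo.mutations
    assignments = pd.DataFrame(
        {
            "node": muts["node"].to_numpy(),
            "probability": 1.0,
            "is_snv": True,
        },
        index=muts.index,
    )
    return MutationTree(
        tree=phylo.tree,
        assignments=assignments,
        raw_count=phylo.branch_count.copy(),
        indel_count=np.zeros(phylo.tree.n_nodes, dtype=int),
        sites=muts,
    )


def write_fixture(readcounts: ReadCountSet, phylo: TruePhylogeny, path) -> list[Path]:
    """Write the TSV/Newick fixture layout; byte-identical for a given seed."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in [
        ("mtr.tsv", readcounts.mtr),
        ("dep.tsv", readcounts.dep),
        ("sites.tsv", readcounts.sites),
        ("colonies.tsv", readcounts.colonies),
    ]:
        f = d / name
        df.to_csv(f, sep="\t", lineterminator="\n")
        written.append(f)
    f = d / "truth.nwk"
    f.write_text(phylo.tree.to_newick() + "\n")
    written.append(f)
    f = d / "truth_assignments.tsv"
    cols = ["node", "chrom", "pos", "ref", "alt", "channel", "clade"]
    phylo.mutations[cols].to_csv(f, sep="\t", lineterminator="\n")
    written.append(f)
    return written
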