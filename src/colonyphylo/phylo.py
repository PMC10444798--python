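"""Topology inference, mutation assignment and branch-length correction.

The tree over colonies is inferred by maximum parsimony on the binary SNV
genotype matrix: carrier sets are ranked by support, a greedy laminar
(perfect-phylogeny) family is built, and the resulting tree is refined by
nearest-neighbour-interchange hill climbing on the Fitch parsimony score.
Every mutation (SNV or indel) is then hard-assigned to the branch whose
implied carrier set maximises the binomial read-count likelihood, branch
lengths are corrected for detection sensitivity estimated from germline
heterozygous sites, and copy-number regions can be masked uniformly across
an individual's colonies with burdens rescaled accordingly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import DataError, EmptyResultError
from .genotype import GenotypeMatrix, ReadCountSet, call_genotype
from .tree import CladeTree

__all__ = [
    "MutationTree",
    "SensitivityEstimate",
    "infer_topology",
    "parsimony_score",
    "assign_mutations",
    "estimate_sensitivity",
    "correct_branch_lengths",
    "mask_cna_rescale_burden",
]


@dataclass
class SensitivityEstimate:
    """Per-colony SNV detection sensitivity.

    ``germline_detection`` (s_i) is the fraction of germline heterozygous
    sites called present; ``clonality`` (c_i) = min(1, median somatic
    VAF / 0.5); ``combined`` = s_i * c_i.
    """

    germline_detection: pd.Series
    clonality: pd.Series
    combined: pd.Series


@dataclass
class MutationTree:
    """Rooted colony tree with per-branch mutation assignments.

    Node i owns the branch above it (node 0 owns the stem). ``raw_count``
    counts assigned SNVs per branch; ``corrected_length`` divides by the
    branch detection sensitivity once :func:`correct_branch_lengths` has
    run. ``assignments`` has one row per mutation with its winning node and
    assignment probability.
    """

    tree: CladeTree
    assignments: pd.DataFrame
    raw_count: np.ndarray  # SNVs per branch
    indel_count: np.ndarray
    sites: pd.DataFrame
    branch_sensitivity: np.ndarray | None = None
    corrected_length: np.ndarray | None = None
    sensitivity: SensitivityEstimate | None = None
    burden_scale: float = 1.0  # CNA-mask rescale factor applied to burdens
    masked_sites: frozenset = frozenset()

    @property
    def lengths(self) -> np.ndarray:
        """Corrected branch lengths if available, else raw counts."""
        if self.corrected_length is not None:
            return self.corrected_length
        return self.raw_count.astype(float)

    def node_heights(self) -> np.ndarray:
        return self.tree.node_heights(self.lengths)

    def tip_burdens(self) -> pd.Series:
        """Per-colony mutation burden: root-to-tip sum of branch lengths."""
        h = self.node_heights()
        return pd.Series(
            {self.tree.labels[i]: h[i] * self.burden_scale for i in self.tree.tip_ids},
            name="burden",
        ).sort_index()


def _is_snv(sites: pd.DataFrame) -> pd.Series:
    return (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)


def _laminar_with(s: frozenset, family: list[frozenset]) -> bool:
    return all((s <= t) or (t <= s) or not (s & t) for t in family)


def parsimony_score(tree: CladeTree, geno: pd.DataFrame) -> int:
    """Fitch parsimony score of a 0/1/NA matrix on a rooted tree.

    Missing entries are treated as ambiguous {0,1}; the all-absent outgroup
    is included, so a site whose root state set excludes 0 costs one extra
    change on the stem. Multifurcations are resolved by sequential Fitch
    intersection, an upper bound that is exact on binary trees.
    """
    cols = list(geno.columns)
    n_sites = len(geno)
    masks = {}
    score = np.zeros(n_sites, dtype=int)
    STATE0, STATE1, BOTH = 1, 2, 3
    for i in reversed(range(tree.n_nodes)):
        if tree.is_tip(i):
            v = geno[tree.labels[i]].to_numpy(dtype=float)
            m = np.full(n_sites, BOTH, dtype=np.int8)
            m[v == 0.0] = STATE0
            m[v == 1.0] = STATE1
            masks[i] = m
        else:
            acc = None
            for c in tree.children[i]:
                if acc is None:
                    acc = masks[c].copy()
                else:
                    inter = acc & masks[c]
                    union = acc | masks[c]
                    empty = inter == 0
                    score += empty
                    acc = np.where(empty, union, inter).astype(np.int8)
                del masks[c]
            masks[i] = acc
    root = masks[0]
    score += (root & STATE0) == 0  # change on the stem towards the all-absent outgroup
    return int(score.sum())


def infer_topology(genotypes: GenotypeMatrix | pd.DataFrame, nni: bool = True,
                   max_rounds: int = 10) -> CladeTree:
    """Maximum-parsimony topology from a binary genotype matrix.

    Pass SNV rows only. If the matrix (NAs ignored per site) admits a
    perfect phylogeny it is returned exactly; otherwise carrier sets are
    added greedily in order of support and the tree is polished by NNI
    hill climbing on the parsimony score.
    """
    geno = genotypes.data if isinstance(genotypes, GenotypeMatrix) else genotypes
    tips = list(geno.columns)
    if len(tips) < 2:
        raise EmptyResultError("need at least two colonies to build a tree")
    support: dict[frozenset, int] = {}
    arr = geno.to_numpy(dtype=float)
    for r in range(arr.shape[0]):
        carriers = frozenset(np.asarray(tips)[arr[r] == 1.0])
        if 2 <= len(carriers) <= len(tips) - 1:
            support[carriers] = support.get(carriers, 0) + 1
    ranked = sorted(
        support, key=lambda s: (-support[s], -len(s), tuple(sorted(s)))
    )
    accepted: list[frozenset] = []
    for s in ranked:
        if _laminar_with(s, accepted):
            accepted.append(s)
    tree = CladeTree.from_laminar(tips, accepted)
    if not nni:
        return tree
    best = parsimony_score(tree, geno)
    for _ in range(max_rounds):
        improved = False
        for v in range(1, tree.n_nodes):
            if tree.is_tip(v):
                continue
            u = tree.parent[v]
            for a in list(tree.children[v]):
                for b in list(tree.children[u]):
                    if b == v:
                        continue
                    cand = _swap_subtrees(tree, a, b)
                    sc = parsimony_score(cand, geno)
                    if sc < best:
                        tree, best = cand, sc
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return tree


def _swap_subtrees(tree: CladeTree, a: int, b: int) -> CladeTree:
    """New tree with the subtrees rooted at nodes a and b exchanged."""
    parent = tree.parent.copy()
    pa, pb = parent[a], parent[b]
    parent[a], parent[b] = pb, pa
    # rebuild in preorder
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        if parent[i] >= 0:
            children[parent[i]].append(i)
    order = []
    stack = [int(np.where(parent == -1)[0][0])]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    remap = {old: new for new, old in enumerate(order)}
    new_parent = [remap[parent[i]] if parent[i] >= 0 else -1 for i in order]
    new_labels = [tree.labels[i] for i in order]
    return CladeTree(new_parent, new_labels)


def assign_mutations(
    topology: CladeTree,
    readcounts: ReadCountSet,
    expected_vaf: float = 0.5,
    error_rate: float = 0.01,
) -> MutationTree:
    """Hard-assign every somatic mutation to its maximum-likelihood branch.

    For branch b with implied carrier clade S_b, the likelihood of a
    mutation's read counts is the product over colonies of
    Binomial(mtr; dep, expected_vaf) for members of S_b and
    Binomial(mtr; dep, error_rate) otherwise; branches get a uniform prior.
    Ties break to the lowest preorder branch index.
    """
    tips = set(topology.tips)
    if not tips <= set(readcounts.colony_ids):
        raise DataError("topology tips missing from read counts")
    cols = sorted(tips)
    som = readcounts.somatic_ids
    mtr = readcounts.mtr.loc[som, cols].to_numpy()
    dep = readcounts.dep.loc[som, cols].to_numpy()
    with np.errstate(divide="ignore"):
        l1 = stats.binom.logpmf(mtr, dep, expected_vaf)
        l0 = stats.binom.logpmf(mtr, dep, error_rate)
    delta = l1 - l0
    B = np.zeros((topology.n_nodes, len(cols)))
    cidx = {c: j for j, c in enumerate(cols)}
    for i in range(topology.n_nodes):
        for lab in topology.clade[i]:
            B[i, cidx[lab]] = 1.0
    scores = delta @ B.T  # sites x nodes (common l0 term dropped)
    winner = np.argmax(scores, axis=1)  # first max = lowest preorder id
    logZ = logsumexp(scores, axis=1)
    prob = np.exp(scores[np.arange(len(som)), winner] - logZ)
    sites = readcounts.sites.loc[som]
    is_snv = _is_snv(sites)
    assignments = pd.DataFrame(
        {"node": winner, "probability": prob, "is_snv": is_snv.to_numpy()}, index=som
    )
    raw = np.bincount(winner[is_snv.to_numpy()], minlength=topology.n_nodes)
    indel = np.bincount(winner[~is_snv.to_numpy()], minlength=topology.n_nodes)
    return MutationTree(
        tree=topology,
        assignments=assignments,
        raw_count=raw,
        indel_count=indel,
        sites=sites,
    )


def estimate_sensitivity(
    readcounts: ReadCountSet, genotypes: GenotypeMatrix
) -> SensitivityEstimate:
    """Per-colony sensitivity from germline heterozygous site recovery.

    s_i is the fraction of germline het sites called present in colony i;
    the clonality correction c_i = min(1, median somatic VAF / 0.5)
    accounts for colonies whose somatic variants sit below VAF 0.5.
    """
    germ = readcounts.germline_ids
    if len(germ) == 0:
        raise DataError(
            "no germline-flagged heterozygous sites: supply them to estimate sensitivity"
        )
    calls = genotypes.data.loc[germ]
    s = (calls == 1.0).sum(axis=0) / len(germ)
    if "median_vaf" in readcounts.colonies.columns:
        med = readcounts.colonies["median_vaf"]
    else:
        from .genotype import _median_somatic_vaf

        med = pd.Series(
            {c: _median_somatic_vaf(readcounts, c) for c in readcounts.colony_ids}
        )
    c = (med / 0.5).clip(upper=1.0)
    s = s.reindex(readcounts.colony_ids)
    c = c.reindex(readcounts.colony_ids)
    return SensitivityEstimate(
        germline_detection=s, clonality=c, combined=s * c
    )


def correct_branch_lengths(mtree: MutationTree, sens: SensitivityEstimate) -> MutationTree:
    """Divide branch counts by the branch-specific detection sensitivity.

    A mutation on a branch is discoverable if it is detected in at least
    one carrier colony, so the branch sensitivity for carrier clade S is
    1 - prod_{i in S} (1 - s_i c_i).
    """
    tree = mtree.tree
    sc = sens.combined
    branch_sens = np.empty(tree.n_nodes)
    for i in range(tree.n_nodes):
        miss = np.prod([1.0 - sc[lab] for lab in tree.clade[i]])
        branch_sens[i] = 1.0 - miss
    if np.any(branch_sens <= 0):
        bad = [i for i in range(tree.n_nodes) if branch_sens[i] <= 0]
        raise DataError(f"zero detection sensitivity on branches {bad}")
    corrected = mtree.raw_count / branch_sens
    return dataclasses.replace(
        mtree,
        branch_sensitivity=branch_sens,
        corrected_length=corrected,
        sensitivity=sens,
    )


def mask_cna_rescale_burden(
    mtree: MutationTree, cna_regions: pd.DataFrame, genome_size: float = 3.0e9
) -> MutationTree:
    """Mask CNA regions uniformly across the individual and rescale burdens.

    Mutations inside the union of the individual's copy-number regions
    (columns chrom/start/end; 1-based closed) are removed from branch
    counts for every colony, and burdens are multiplied by
    1/(1 - masked fraction of the genome).
    """
    if cna_regions is None or len(cna_regions) == 0:
        return mtree
    merged: dict[str, list[tuple[int, int]]] = {}
    for _, r in cna_regions.iterrows():
        merged.setdefault(str(r["chrom"]), []).append((int(r["start"]), int(r["end"])))
    masked_bases = 0
    union: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in merged.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        union[chrom] = [(s, e) for s, e in out]
        masked_bases += sum(e - s + 1 for s, e in out)
    frac = masked_bases / genome_size
    if frac >= 1:
        raise DataError("masked fraction of the genome is >= 1")

    def in_mask(chrom, pos):
        return any(s <= pos <= e for s, e in union.get(str(chrom), []))

    sites = mtree.sites
    masked_ids = frozenset(
        sid
        for sid, chrom, pos in zip(sites.index, sites["chrom"], sites["pos"])
        if in_mask(chrom, pos)
    )
    keep = ~mtree.assignments.index.isin(masked_ids)
    asg = mtree.assignments[keep]
    raw = np.bincount(
        asg.loc[asg["is_snv"], "node"].to_numpy(), minlength=mtree.tree.n_nodes
    )
    indel = np.bincount(
        asg.loc[~asg["is_snv"], "node"].to_numpy(), minlength=mtree.tree.n_nodes
    )
    out = dataclasses.replace(
        mtree,
        assignments=asg,
        raw_count=raw,
        indel_count=indel,
        burden_scale=mtree.burden_scale / (1.0 - frac),
        masked_sites=masked_ids,
    )
    if mtree.sensitivity is not None:
        out = correct_branch_lengths(out, mtree.sensitivity)
        out = dataclasses.replace(out, burden_scale=mtree.burden_scale / (1.0 - frac))
    return out
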