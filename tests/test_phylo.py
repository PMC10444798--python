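from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonyphylo.errors import DataError
from colonyphylo.phylo import (
    SensitivityEstimate,
    assign_mutations,
    correct_branch_lengths,
    estimate_sensitivity,
    infer_topology,
    mask_cna_rescale_burden,
    parsimony_score,
)
from colonyphylo.tree import CladeTree

from .test_genotype import make_rc


def all_laminar_trees(tips):
    """Every rooted tree over the tips, as laminar clade families."""
    candidates = [
        frozenset(c)
        for size in range(2, len(tips))
        for c in combinations(tips, size)
    ]
    out = []

    def rec(i, family):
        if i == len(candidates):
            out.append(CladeTree.from_laminar(tips, family))
            return
        rec(i + 1, family)
        c = candidates[i]
        if all(c <= f or f <= c or not (c & f) for f in family):
            rec(i + 1, family + [c])

    rec(0, [])
    return out


class TestTopology:
    def test_conflict_free_matrix_matches_exhaustive_search(self):
        """4 colonies: inferred tree is the parsimony optimum over all rooted trees."""
        tips = ["a", "b", "c", "d"]
        geno = pd.DataFrame(
            {
                "a": [1, 1, 1, 0, 1],
                "b": [1, 1, 0, 0, 0],
                "c": [0, 0, 0, 1, 0],
                "d": [0, 0, 0, 1, 0],
            },
            dtype=float,
        )
        tree = infer_topology(geno)
        assert tree.clade_set() == {frozenset("ab"), frozenset("cd")}
        best = min(parsimony_score(t, geno) for t in all_laminar_trees(tips))
        assert parsimony_score(tree, geno) == best

    def test_all_zero_matrix_gives_star_tree(self):
        geno = pd.DataFrame(np.zeros((8, 5)), columns=list("abcde"))
        tree = infer_topology(geno)
        assert tree.clade_set() == set()

    def test_recovers_simulator_truth_on_clean_fixture(self, deep_pipeline):
        cfg, truth, mtree, rc2, gmat = deep_pipeline
        # truth clades supported by >= 1 mutation are exactly recoverable
        supported = {
            truth.tree.clade[i]
            for i in truth.tree.internal_ids
            if i != 0 and truth.branch_count[i] > 0 and len(truth.tree.clade[i]) >= 2
        }
        assert mtree.tree.clade_set() == supported

    def test_single_colony_errors(self):
        with pytest.raises(Exception):
            infer_topology(pd.DataFrame({"a": [1.0, 0.0]}))


class TestAssignment:
    def test_assignments_match_truth_on_clean_fixture(self, deep_pipeline):
        cfg, truth, mtree, rc2, gmat = deep_pipeline
        # compare by carrier clade (node ids differ between trees)
        ok = 0
        for sid, node in zip(mtree.assignments.index, mtree.assignments["node"]):
            true_node = truth.mutations.loc[sid, "node"]
            ok += mtree.tree.clade[node] == truth.tree.clade[true_node]
        assert ok == len(mtree.assignments)

    def test_mutation_in_every_colony_goes_to_stem(self):
        tree = CladeTree.from_laminar(["a", "b", "c"], [frozenset("ab")])
        dep = np.full((1, 3), 30)
        mtr = np.full((1, 3), 15)
        rc = make_rc(mtr, dep)
        rc.mtr.columns = rc.dep.columns = ["a", "b", "c"]
        rc.colonies.index = pd.Index(["a", "b", "c"], name="colony")
        mt = assign_mutations(tree, rc)
        assert mt.assignments["node"].iloc[0] == 0  # the root/stem branch

    def test_assignment_equals_brute_force_likelihood(self):
        """Missing data in one colony: still assigned to the argmax branch."""
        tree = CladeTree.from_laminar(["a", "b", "c"], [frozenset("ab")])
        mtr = np.array([[14, 12, 0]])
        dep = np.array([[30, 28, 2]])  # colony c: nearly no reads at the site
        rc = make_rc(mtr, dep)
        rc.mtr.columns = rc.dep.columns = ["a", "b", "c"]
        rc.colonies.index = pd.Index(["a", "b", "c"], name="colony")
        mt = assign_mutations(tree, rc)
        # oracle: per-branch product of binomial pmfs
        def loglik(carriers):
            ll = 0.0
            for lab, m, d in zip("abc", mtr[0], dep[0]):
                p = 0.5 if lab in carriers else 0.01
                ll += stats.binom.logpmf(m, d, p)
            return ll

        best = max(
            range(tree.n_nodes), key=lambda i: (loglik(tree.clade[i]), -i)
        )
        assert mt.assignments["node"].iloc[0] == best
        assert tree.clade[best] == frozenset("ab")

    def test_conservation_of_assigned_mutations(self, deep_pipeline):
        cfg, truth, mtree, rc2, gmat = deep_pipeline
        assert mtree.raw_count.sum() + mtree.indel_count.sum() == len(mtree.assignments)


class TestSensitivity:
    def test_arithmetic_from_definition(self):
        # 90/100 germline hets detected, median VAF 0.45 -> 0.9 * 0.9 = 0.81
        rng = np.random.default_rng(2)
        dep = np.full((300, 1), 30)
        mtr = rng.binomial(30, 0.45, size=(300, 1))
        rc = make_rc(mtr, dep, germline=100)
        gcalls = pd.DataFrame(
            np.where(np.arange(300)[:, None] < 90, 1.0, 0.0),
            index=rc.sites.index, columns=["c0"],
        )
        from colonyphylo.genotype import GenotypeMatrix

        rc.colonies["median_vaf"] = 0.45
        est = estimate_sensitivity(rc, GenotypeMatrix(gcalls))
        assert est.germline_detection["c0"] == pytest.approx(0.9)
        assert est.clonality["c0"] == pytest.approx(0.9)
        assert est.combined["c0"] == pytest.approx(0.81)

    def test_clonality_capped_at_one(self):
        rc = make_rc(np.array([[5]]), np.array([[10]]), germline=1)
        rc.colonies["median_vaf"] = 0.6
        from colonyphylo.genotype import GenotypeMatrix

        gcalls = pd.DataFrame([[1.0]], index=rc.sites.index, columns=["c0"])
        est = estimate_sensitivity(rc, GenotypeMatrix(gcalls))
        assert est.clonality["c0"] == 1.0
        assert est.combined["c0"] == 1.0

    def test_no_germline_sites_errors(self):
        from colonyphylo.genotype import GenotypeMatrix

        rc = make_rc(np.array([[5]]), np.array([[10]]))
        g = GenotypeMatrix(pd.DataFrame([[1.0]], index=rc.sites.index, columns=["c0"]))
        with pytest.raises(DataError, match="germline"):
            estimate_sensitivity(rc, g)


def _toy_mutation_tree(raw, tips=("a", "b"), clades=()):
    from colonyphylo.phylo import MutationTree

    tree = CladeTree.from_laminar(tips, [frozenset(c) for c in clades])
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, int(np.sum(raw)) + 1) * 10,
            "ref": "C",
            "alt": "T",
        },
        index=pd.Index([f"s{i}" for i in range(int(np.sum(raw)))], name="site_id"),
    )
    nodes = np.repeat(np.arange(len(raw)), raw)
    assignments = pd.DataFrame(
        {"node": nodes, "probability": 1.0, "is_snv": True}, index=sites.index
    )
    return MutationTree(
        tree=tree,
        assignments=assignments,
        raw_count=np.asarray(raw),
        indel_count=np.zeros(len(raw), dtype=int),
        sites=sites,
    )


class TestBranchCorrection:
    def test_perfect_sensitivity_is_identity(self):
        mt = _toy_mutation_tree([0, 10, 12])
        sens = SensitivityEstimate(
            germline_detection=pd.Series(1.0, index=["a", "b"]),
            clonality=pd.Series(1.0, index=["a", "b"]),
            combined=pd.Series(1.0, index=["a", "b"]),
        )
        out = correct_branch_lengths(mt, sens)
        assert np.allclose(out.corrected_length, out.raw_count)

    def test_private_and_shared_branch_formulas(self):
        # private branch s*c=0.8: 10 -> 12.5; two-colony branch: 1-0.2^2=0.96, 24 -> 25
        mt = _toy_mutation_tree([24, 10, 0])
        s = pd.Series(0.8, index=["a", "b"])
        sens = SensitivityEstimate(s, pd.Series(1.0, index=["a", "b"]), s)
        out = correct_branch_lengths(mt, sens)
        assert out.branch_sensitivity[0] == pytest.approx(0.96)
        assert out.corrected_length[0] == pytest.approx(25.0)
        assert out.corrected_length[1] == pytest.approx(12.5)
        assert np.all(out.corrected_length >= out.raw_count)

    def test_corrected_lengths_unbiased_on_simulated_data(self, noisy_fixture):
        cfg, rc, truth = noisy_fixture
        from .conftest import run_pipeline

        mtree, rc2, gmat = run_pipeline(rc)
        est = mtree.tip_burdens()
        true_b = truth.tip_burden.loc[est.index]
        # corrected totals within 5% of the truth on average
        assert abs((est / true_b).mean() - 1.0) < 0.05


class TestCnaMasking:
    def test_no_regions_is_identity(self):
        mt = _toy_mutation_tree([5, 3, 2])
        out = mask_cna_rescale_burden(mt, pd.DataFrame())
        assert out is mt

    def test_masked_fraction_rescales_burden(self):
        # 100 mutations on the stem; mask a region holding 10 of them (10% of genome)
        mt = _toy_mutation_tree([100, 0, 0])
        region = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [100]})
        out = mask_cna_rescale_burden(mt, region, genome_size=1000)
        assert out.raw_count[0] == 90
        assert out.tip_burdens()["a"] == pytest.approx(90 / 0.9)

    def test_masking_applies_to_all_colonies(self):
        mt = _toy_mutation_tree([0, 4, 6])
        region = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [1000]})
        out = mask_cna_rescale_burden(mt, region, genome_size=10000)
        assert out.raw_count.sum() == 0  # every colony's branches masked

    def test_full_mask_errors(self):
        mt = _toy_mutation_tree([1, 0, 0])
        region = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [1000]})
        with pytest.raises(DataError):
            mask_cna_rescale_burden(mt, region, genome_size=1000)
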