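import numpy as np
import pandas as pd
import pytest

from colonyphylo.clones import (
    annotate_drivers,
    detect_expansions,
    load_driver_config,
    summarize_clonality,
)
from colonyphylo.errors import DataError
from colonyphylo.phylo import MutationTree
from colonyphylo.tree import CladeTree


def tree_with_heights(tips, clades, lengths):
    """MutationTree with prescribed corrected branch lengths (node order preorder)."""
    tree = CladeTree.from_laminar(tips, [frozenset(c) for c in clades])
    raw = np.array(lengths, dtype=float)
    sites = pd.DataFrame(
        {"chrom": "1", "pos": [], "ref": [], "alt": []},
        index=pd.Index([], name="site_id"),
    )
    return MutationTree(
        tree=tree,
        assignments=pd.DataFrame(columns=["node", "probability", "is_snv"]),
        raw_count=raw.astype(int),
        indel_count=np.zeros(len(raw), dtype=int),
        sites=sites,
        corrected_length=raw,
    )


class TestExpansionRule:
    @pytest.mark.parametrize("stem,expect", [(74, 0), (75, 0), (76, 1)])
    def test_strictly_after_75_mutations(self, stem, expect):
        # clade (a,b) whose MRCA height equals the stem+trunk length
        mt = tree_with_heights(
            ["a", "b", "c"], [("a", "b")], [0, stem, 40, 40, 120]
        )
        found = detect_expansions(mt, threshold=75)
        assert len(found) == expect
        if expect:
            assert found[0].tips == ("a", "b")
            assert found[0].mrca_height == stem

    def test_star_tree_has_no_expansions(self):
        mt = tree_with_heights(["a", "b", "c"], [], [0, 200, 200, 200])
        assert detect_expansions(mt) == []

    def test_nested_qualifying_clades_report_only_maximal(self):
        # ((a,b),c) with both internal nodes beyond the threshold
        mt = tree_with_heights(
            ["a", "b", "c", "d"], [("a", "b"), ("a", "b", "c")],
            [0, 100, 50, 10, 10, 10, 150],
        )
        found = detect_expansions(mt, threshold=75)
        assert len(found) == 1
        assert found[0].tips == ("a", "b", "c")

    def test_invariant_to_tip_ordering(self, deep_pipeline):
        cfg, truth, mtree, rc2, gmat = deep_pipeline
        found = detect_expansions(mtree)
        tipsets = {e.tips for e in found}
        # rebuild the same tree with clades supplied in reverse order
        clades = sorted(mtree.tree.clade_set(), key=lambda s: tuple(sorted(s)), reverse=True)
        tree2 = CladeTree.from_laminar(mtree.tree.tips, clades)
        # map corrected lengths across by clade identity
        bylen = {mtree.tree.clade[i]: mtree.lengths[i] for i in range(mtree.tree.n_nodes)}
        lengths2 = [bylen[tree2.clade[i]] for i in range(tree2.n_nodes)]
        mt2 = tree_with_heights(
            mtree.tree.tips, [c for c in clades], lengths2
        )
        mt2.tree = tree2
        found2 = detect_expansions(mt2)
        assert {e.tips for e in found2} == tipsets

    def test_detects_planted_clade(self, deep_pipeline):
        cfg, truth, mtree, rc2, gmat = deep_pipeline
        clade_tips = tuple(
            sorted(
                truth.tree.labels[i]
                for i in truth.tree.tip_ids
                if truth.node_clade[i] == 0
            )
        )
        found = detect_expansions(mtree)
        assert any(e.tips == clade_tips for e in found)


class TestDrivers:
    def sites(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "consequence"],
            index=pd.Index([f"s{i}" for i in range(len(rows))], name="site_id"),
        )

    def test_tp53_missense_is_sds_associated_driver(self):
        out = annotate_drivers(self.sites([("TP53", "missense_variant")]))
        assert len(out) == 1
        assert out.iloc[0]["driver_class"] == "SDS-associated"

    def test_synonymous_and_unlisted_genes_excluded(self):
        out = annotate_drivers(
            self.sites(
                [("TP53", "synonymous_variant"), ("GAPDH", "missense_variant"),
                 ("DNMT3A", "frameshift_variant")]
            )
        )
        assert list(out["gene"]) == ["DNMT3A"]
        assert out.iloc[0]["driver_class"] == "CH/cancer gene"

    def test_chr7q_loh_flags_sbds_dosage_driver(self):
        cna = pd.DataFrame(
            {"colony": ["c1"], "chrom": ["7"], "start": [60_000_000], "end": [80_000_000]}
        )
        out = annotate_drivers(self.sites([]), cna_regions=cna)
        assert (out["driver_class"] == "dosage CNA").all()
        assert "SBDS" in set(out["gene"])

    def test_missing_annotation_columns_error(self):
        with pytest.raises(DataError):
            annotate_drivers(pd.DataFrame({"gene": ["TP53"]}))

    def test_config_contains_the_35_gene_screen(self):
        cfg = load_driver_config()
        assert len(set(cfg["ch_cancer"])) == 35
        assert set(cfg["sds_associated"]) == {"TP53", "EIF6", "RPL5", "RPL22", "PRPF8"}


class TestClonalitySummary:
    def toy(self):
        # 10 tips, one 4-tip expansion (e,f,g,h), driver on singleton branch of tip a
        tips = [chr(ord("a") + i) for i in range(10)]
        mt = tree_with_heights(
            tips, [("e", "f", "g", "h")],
            [0] + [100] * 11,
        )
        exp = detect_expansions(mt, threshold=75)
        node_a = next(
            i for i in range(mt.tree.n_nodes) if mt.tree.clade[i] == frozenset("a")
        )
        drivers = pd.DataFrame(
            {"gene": ["TP53"], "driver_class": ["SDS-associated"],
             "consequence": ["missense"], "node": [node_a]},
            index=pd.Index(["s0"], name="site_id"),
        )
        return mt, exp, drivers

    def test_union_and_lineage_count_on_toy_tree(self):
        mt, exp, drivers = self.toy()
        s = summarize_clonality(mt, exp, drivers)
        assert s.n_colonies == 10
        assert s.frac_in_expansion == pytest.approx(0.4)
        assert s.frac_with_driver == pytest.approx(0.1)
        assert s.union_fraction == pytest.approx(0.5)
        assert s.n_expanded_lineages == 2

    def test_empty_inputs_give_zero_fractions(self):
        mt, _, _ = self.toy()
        s = summarize_clonality(mt, [], pd.DataFrame(columns=["node"]))
        assert s.frac_in_expansion == 0
        assert s.frac_with_driver == 0
        assert s.union_fraction == 0
        assert s.n_expanded_lineages == 0

    def test_driver_inside_expansion_counted_once(self):
        mt, exp, _ = self.toy()
        node_e = next(
            i for i in range(mt.tree.n_nodes) if mt.tree.clade[i] == frozenset("e")
        )
        drivers = pd.DataFrame({"node": [node_e]}, index=pd.Index(["s0"]))
        s = summarize_clonality(mt, exp, drivers)
        assert s.union_fraction == pytest.approx(0.4)
        assert s.n_expanded_lineages == 1
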