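import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from colonyphylo.errors import DataError, EmptyResultError
from colonyphylo.genotype import (
    ReadCountSet,
    build_genotype_matrix,
    call_genotype,
    qc_colonies,
)


def make_rc(mtr, dep, chroms=None, loh=None, ploidy=None, germline=0):
    """Small ReadCountSet from raw matrices (rows = sites, cols = colonies)."""
    mtr = np.atleast_2d(mtr)
    dep = np.atleast_2d(dep)
    n_sites, n_col = mtr.shape
    cols = [f"c{j}" for j in range(n_col)]
    sids = [f"s{i}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "C",
            "alt": "T",
            "context": "ACA",
            "gene": "",
            "consequence": "",
            "is_germline": [i < germline for i in range(n_sites)],
        },
        index=pd.Index(sids, name="site_id"),
    )
    colonies = pd.DataFrame(
        {"individual": "ind1", "age_years": 10.0}, index=pd.Index(cols, name="colony")
    )
    kw = {}
    if loh is not None:
        kw["loh_regions"] = pd.DataFrame(loh, columns=["colony", "chrom", "start", "end"])
    if ploidy is not None:
        kw["ploidy_regions"] = pd.DataFrame(
            ploidy, columns=["colony", "chrom", "start", "end", "ploidy"]
        )
    return ReadCountSet(
        pd.DataFrame(mtr, index=sites.index, columns=cols),
        pd.DataFrame(dep, index=sites.index, columns=cols),
        sites,
        colonies,
        **kw,
    )


class TestCallGenotype:
    @pytest.mark.parametrize(
        "mtr,dep,vaf,expected",
        [
            (10, 20, 0.5, 1.0),  # clean heterozygous site
            (0, 20, 0.5, 0.0),  # clean absence
            (1, 4, 0.5, np.nan),  # ambiguous: neither ratio reaches 20
            (0, 0, 0.5, np.nan),  # no reads, no call
        ],
    )
    def test_frozen_examples(self, mtr, dep, vaf, expected):
        got = call_genotype(mtr, dep, vaf)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_agrees_with_direct_pmf_oracle(self):
        """Exhaustive check against scipy binomial pmfs for dep <= 30."""
        for dep in range(0, 31):
            for mtr in range(0, dep + 1):
                l1 = stats.binom.pmf(mtr, dep, 0.5)
                l0 = stats.binom.pmf(mtr, dep, 0.01)
                if dep == 0:
                    want = np.nan
                elif l1 >= 20 * l0:
                    want = 1.0
                elif l0 >= 20 * l1:
                    want = 0.0
                else:
                    want = np.nan
                got = call_genotype(mtr, dep, 0.5)
                assert (np.isnan(got) and np.isnan(want)) or got == want, (mtr, dep)

    @given(dep=st.integers(1, 60))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_mtr(self, dep):
        """As mtr grows at fixed dep the call moves 0 -> NA -> 1, never back."""
        calls = [call_genotype(m, dep, 0.5) for m in range(dep + 1)]
        codes = [0 if c == 0.0 else (2 if c == 1.0 else 1) for c in calls]
        assert codes == sorted(codes)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            call_genotype(1, 2, 0.0)
        with pytest.raises(ValueError):
            call_genotype(3, 2, 0.5)


class TestQC:
    def test_low_depth_colony_removed(self):
        rng = np.random.default_rng(0)
        dep = np.column_stack([rng.poisson(5.9, 400).clip(min=0), rng.poisson(20, 400)])
        mtr = rng.binomial(dep, 0.5)
        rc = make_rc(mtr, dep)
        kept, report = qc_colonies(rc)
        if report.loc["c0", "mean_depth"] < 6:  # realized mean below threshold
            assert not report.loc["c0", "kept"]
        assert report.loc["c1", "kept"]

    def test_vaf_boundary_is_kept_strictly_below_removed(self):
        dep = np.full((500, 2), 30)
        rng = np.random.default_rng(1)
        mtr = np.column_stack(
            [rng.binomial(30, 0.30, 500), rng.binomial(30, 0.5, 500)]
        )
        rc = make_rc(mtr, dep)
        kept, report = qc_colonies(rc)
        assert not report.loc["c0", "kept"]
        assert "median VAF" in report.loc["c0", "reason"]
        assert report.loc["c1", "kept"]

    def test_all_removed_raises(self):
        rc = make_rc(np.zeros((10, 1), int), np.full((10, 1), 2))
        with pytest.raises(EmptyResultError):
            qc_colonies(rc)


class TestGenotypeMatrix:
    def test_expected_vaf_rules(self):
        # 12/40 reads: present at VAF 0.5 but absent under VAF 1.0 (ploidy 1)
        mtr = np.array([[12], [12]])
        dep = np.array([[40], [40]])
        rc = make_rc(mtr, dep, chroms=["1", "1"],
                     ploidy=[("c0", "1", 150, 250, 1)])  # second site in ploidy-1 region
        g = build_genotype_matrix(rc)
        assert g.data.iloc[0, 0] == 1.0
        assert g.data.iloc[1, 0] == 0.0

    def test_sex_chromosome_uses_haploid_vaf(self):
        mtr = np.array([[12]])
        dep = np.array([[40]])
        rc = make_rc(mtr, dep, chroms=["X"])
        g = build_genotype_matrix(rc)
        assert g.data.iloc[0, 0] == 0.0  # 12/40 inconsistent with VAF 1.0

    def test_loh_override_sets_absent_to_missing(self):
        mtr = np.array([[0], [0]])
        dep = np.array([[30], [30]])
        rc = make_rc(mtr, dep, loh=[("c0", "1", 150, 250)])
        g = build_genotype_matrix(rc)
        assert g.data.iloc[0, 0] == 0.0  # outside LOH: confident absence
        assert np.isnan(g.data.iloc[1, 0])  # inside LOH: overridden to NA

    def test_contradictory_ploidy_intervals_raise(self):
        mtr = np.array([[5]])
        dep = np.array([[20]])
        rc = make_rc(mtr, dep, ploidy=[("c0", "1", 50, 150, 1), ("c0", "1", 90, 120, 3)])
        with pytest.raises(DataError, match="ploidy"):
            build_genotype_matrix(rc)

    def test_error_free_deep_matrix_equals_truth(self, deep_fixture):
        cfg, rc, truth = deep_fixture
        g = build_genotype_matrix(rc)
        som = rc.sites.index[~rc.sites["is_germline"]]
        carrier = {
            (sid, lab): True
            for sid, node in zip(truth.mutations.index, truth.mutations["node"])
            for lab in truth.tree.clade[node]
        }
        vals = g.data.loc[som]
        for sid in som:
            for lab in rc.colony_ids:
                want = 1.0 if carrier.get((sid, lab)) else 0.0
                assert vals.loc[sid, lab] == want

    def test_determinism(self, deep_fixture):
        cfg, rc, truth = deep_fixture
        a = build_genotype_matrix(rc)
        b = build_genotype_matrix(rc)
        assert a.data.equals(b.data)
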