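import pytest

from colonyphylo import (
    CladeConfig,
    SimConfig,
    assign_mutations,
    build_genotype_matrix,
    correct_branch_lengths,
    estimate_sensitivity,
    infer_topology,
    qc_colonies,
    simulate_individual,
)


@pytest.fixture(scope="session")
def deep_fixture():
    """Error-free, deeply sequenced individual: genotypes recover truth exactly."""
    cfg = SimConfig(
        n_colonies=12,
        age=20,
        seed=11,
        mean_depth=80,
        error_rate=0.0,
        clades=[CladeConfig(origin_age=5, n_tips=4, growth_rate=2.0)],
    )
    rc, truth = simulate_individual(cfg)
    return cfg, rc, truth


@pytest.fixture(scope="session")
def noisy_fixture():
    """Realistic individual: 20x depth, 1% error, one expanded clade."""
    cfg = SimConfig(
        n_colonies=15,
        age=25,
        seed=23,
        clades=[CladeConfig(origin_age=6, n_tips=5, growth_rate=3.0, sbs1_fraction=0.65)],
    )
    rc, truth = simulate_individual(cfg)
    return cfg, rc, truth


def run_pipeline(rc):
    """QC -> genotypes -> topology -> assignment -> sensitivity correction."""
    rc, _ = qc_colonies(rc)
    gmat = build_genotype_matrix(rc)
    snv = rc.sites.index[
        ~rc.sites["is_germline"]
        & (rc.sites["ref"].str.len() == 1)
        & (rc.sites["alt"].str.len() == 1)
    ]
    topo = infer_topology(gmat.data.loc[snv])
    mtree = assign_mutations(topo, rc)
    sens = estimate_sensitivity(rc, gmat)
    return correct_branch_lengths(mtree, sens), rc, gmat


@pytest.fixture(scope="session")
def deep_pipeline(deep_fixture):
    cfg, rc, truth = deep_fixture
    mtree, rc2, gmat = run_pipeline(rc)
    return cfg, truth, mtree, rc2, gmat
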