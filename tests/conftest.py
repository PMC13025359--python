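import pytest

import lcrqc as L

SEED = 1234


@pytest.fixture(scope="session")
def batch_cohort():
    """Default four-batch exome scenario (229/117/117/126x, 10 samples
    per batch, 200 planted systematic-dropout intervals per batch)."""
    return L.simulate_cohort(L.batch_effect_scenario(seed=SEED))


@pytest.fixture(scope="session")
def batch_callsets(batch_cohort):
    return [L.call_lcrs(p, batch_cohort.universe) for p in batch_cohort.profiles]


@pytest.fixture(scope="session")
def batch_matrix(batch_callsets):
    return L.build_binary_matrix(batch_callsets)


@pytest.fixture(scope="session")
def batch_ztables(batch_cohort):
    ids = sorted({p.batch_id for p in batch_cohort.profiles})
    return [
        L.batch_zscores(batch_cohort.profiles_for(batch_id=b), batch_cohort.universe)
        for b in ids
    ]


@pytest.fixture(scope="session")
def paired_cohort():
    """Paired ES/GS scenario: 14 donors, disjoint assay-specific planted
    dropout, assay-specific GC depression."""
    return L.simulate_cohort(L.paired_assay_scenario(seed=SEED))


@pytest.fixture(scope="session")
def paired_callsets(paired_cohort):
    es = {p.sample_id: L.call_lcrs(p, paired_cohort.universe)
          for p in paired_cohort.profiles_for(assay="ES")}
    gs = {p.sample_id: L.call_lcrs(p, paired_cohort.universe)
          for p in paired_cohort.profiles_for(assay="GS")}
    return es, gs


@pytest.fixture(scope="session")
def paired_matrix(paired_callsets):
    es, gs = paired_callsets
    return L.build_binary_matrix(list(es.values()) + list(gs.values()))


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-batch cohort for annotation-heavy tests."""
    cfg = L.SimConfig(
        n_intervals=400,
        n_chromosomes=4,
        batches=(
            L.BatchSpec("b1", 3, 120.0, assay="ES", n_planted=25),
            L.BatchSpec("b2", 3, 60.0, assay="GS", n_planted=15),
        ),
        n_planted_shared=5,
        seed=SEED,
    )
    return L.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_annotation(small_cohort):
    return L.simulate_gene_annotation(small_cohort)


@pytest.fixture(scope="session")
def small_annotation_dir(small_annotation, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("annotation")
    return L.write_annotation(small_annotation, outdir)
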