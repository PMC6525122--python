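import pytest

from mhchap import deconvolve, fixture, haplotyper, synth


@pytest.fixture(scope="session")
def db():
    return fixture.fixture_database()


@pytest.fixture(scope="session")
def panel(db):
    return fixture.fixture_panel(db)


@pytest.fixture(scope="session")
def assay_map():
    return fixture.fixture_assays()


@pytest.fixture(scope="session")
def assays():
    return fixture.default_genotyping_assays()


def genotype_cohort(cohort, db, assay_map):
    """Deconvolve every observation of a simulated cohort."""
    return {
        ind: {
            name: deconvolve.call_genotype(obs, db, assay_map[name])
            for name, obs in obs_by_assay.items()
        }
        for ind, obs_by_assay in cohort.observations.items()
    }


def simulate_and_infer(panel, db, assays, assay_map, n, seed, **sim_kwargs):
    """Simulate a cohort and run the full inference; returns (cohort, table, result)."""
    cfg = synth.SimConfig(
        frequencies=[1.0 / len(panel.labels)] * len(panel.labels),
        n=n, seed=seed, **sim_kwargs,
    )
    cohort = synth.simulate_cohort(panel, db, assays, cfg)
    table = genotype_cohort(cohort, db, assay_map)
    result = haplotyper.infer_haplotypes(table, db, assays)
    return cohort, table, result


@pytest.fixture(scope="session")
def inference_run(panel, db, assays, assay_map):
    """One mid-sized noise-free cohort shared by several tests."""
    return simulate_and_infer(panel, db, assays, assay_map, n=250, seed=11)
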