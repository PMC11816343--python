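import pytest

import tka


@pytest.fixture(scope="session")
def catalog() -> tka.TargetCatalog:
    return tka.load_packaged_catalog()


@pytest.fixture(scope="session")
def sets(catalog) -> tka.GeneSetCatalog:
    return catalog.gene_sets()


@pytest.fixture(scope="session")
def fixture_cohort(catalog):
    return tka.load_fixture_cohort(catalog)


@pytest.fixture(scope="session")
def event_mode_result(catalog, fixture_cohort) -> tka.AssessmentResult:
    """Assessment of the packaged cohort from its transcribed events."""
    return tka.assess_events(
        catalog,
        fixture_cohort.manifest,
        fixture_cohort.event_frame(),
        reference_counts=fixture_cohort.reference_counts,
    )


@pytest.fixture(scope="session")
def raw_mode_result(catalog, fixture_cohort) -> tka.AssessmentResult:
    """Assessment of the packaged cohort via back-generated numeric tables,
    exercising the amplification/overexpression/mutation/fusion callers."""
    raw = tka.build_raw_cohort(fixture_cohort, catalog, seed=0)
    return tka.assess_cohort(
        catalog,
        raw.manifest,
        mutations=raw.mutations,
        cnvs=raw.cnvs,
        expression=raw.expression,
        fusions=raw.fusions,
        reference_counts=fixture_cohort.reference_counts,
    )
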