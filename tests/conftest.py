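"""Shared fixtures: small hand-built inputs and cached pipeline runs."""

from __future__ import annotations

import pytest

from sicompre import (
    FixtureConfig,
    LatticeConfig,
    ReferenceComplexSet,
    build_model,
    generate_fixture,
    refine_pipeline,
    run_simulation,
)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle: 10 planted complexes, 100 decoys."""
    return generate_fixture(FixtureConfig())


@pytest.fixture(scope="session")
def default_model(default_bundle):
    b = default_bundle
    return build_model(b.ppi, b.ddi, b.domains, b.abundance, b.annotations)


@pytest.fixture(scope="session")
def default_scs(default_model):
    """Two-run simulation of the default model under the default settings."""
    return run_simulation(default_model, LatticeConfig(seed=0))


@pytest.fixture(scope="session")
def default_refined(default_scs):
    return refine_pipeline(default_scs)


@pytest.fixture(scope="session")
def default_reference(default_bundle):
    return ReferenceComplexSet(default_bundle.reference, source="planted")


def make_model(proteins: dict[str, tuple[float, list[str]]], rules):
    """Hand-build an IntegratedModel for simulator unit tests.

    proteins: id -> (abundance_raw, domain slots); rules: tuples
    (protein_a, domain_a, protein_b, domain_b).
    """
    from sicompre.model import (
        KNOWN_DDI,
        CoverageStats,
        IntegratedModel,
        InteractionRule,
        ProteinSpec,
        transform_abundance,
    )

    specs = {
        pid: ProteinSpec(pid, ab, transform_abundance(ab), list(slots))
        for pid, (ab, slots) in proteins.items()
    }
    rule_objs = [InteractionRule(pa, pb, da, db, KNOWN_DDI).canonical()
                 for pa, da, pb, db in rules]
    cov = CoverageStats(len(rule_objs), len(specs), len(specs), len(rule_objs), 1.0, 1.0)
    return IntegratedModel(proteins=specs, rules=rule_objs, coverage=cov)
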