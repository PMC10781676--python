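import pytest

from ecotoxkit.synth import (
    FixtureSpec,
    generate_annotation_fixture,
    generate_ecotox_fixture,
    generate_qsar_fixture,
)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One seeded fixture set shared by the whole session: the synthetic
    release archive, companion inputs, annotation catalog, QSAR exports,
    and their ground-truth manifests."""
    d = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(seed=FIXTURE_SEED)
    manifests = {
        "ecotox": generate_ecotox_fixture(spec, d),
        "annotations": generate_annotation_fixture(spec, d),
        "qsar": generate_qsar_fixture(spec, d),
    }
    return d, manifests
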