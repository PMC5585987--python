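import pytest
from hypothesis import settings

from genefam.catalog import load_catalog
from genefam.duplication import GeneAnnotation
from genefam.simulate import FamilySimConfig, simulate_family

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic family bundle, shared across the suite."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_family(FamilySimConfig(seed=BUNDLE_SEED), outdir)


@pytest.fixture(scope="session")
def bundle_records(bundle):
    return load_catalog(bundle.paths["genome"], bundle.paths["annotation"],
                        bundle.paths["cds"], bundle.paths["proteins"])


@pytest.fixture(scope="session")
def bundle_annotation(bundle):
    return GeneAnnotation.from_gff3(bundle.paths["annotation"])
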