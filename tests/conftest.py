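import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from snvaa import fixtures
from snvaa.gene_model import TranscriptModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mini_bundle():
    """Canonical smoke-test bundle: seed 1, 20 transcripts, 80 variants."""
    return fixtures.generate_bundle(seed=1, n_transcripts=20, n_variants=80)


@pytest.fixture(scope="session")
def mini_bundle_dir(mini_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("mini_bundle")
    paths = fixtures.write_bundle(mini_bundle, str(out))
    return paths


@pytest.fixture
def demo_transcript():
    """Worked example: plus strand, exons [100,200)+[250,400), CDS [150,350)."""
    return TranscriptModel(
        ucsc_id="uc_demo.1",
        chromosome="chr1",
        strand="+",
        tx_start=100,
        tx_end=400,
        cds_start=150,
        cds_end=350,
        exons=[(100, 200), (250, 400)],
    )


@pytest.fixture
def demo_transcript_minus(demo_transcript):
    t = demo_transcript
    return TranscriptModel(
        ucsc_id="uc_demo_m.1",
        chromosome=t.chromosome,
        strand="-",
        tx_start=t.tx_start,
        tx_end=t.tx_end,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
        exons=list(t.exons),
    )
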