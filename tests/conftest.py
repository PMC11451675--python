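from pathlib import Path

import pytest
from hypothesis import settings

from gwaspar import VariantRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"
ANCESTRIES = ["EUR", "AFR", "EAS", "AMR"]


def make_record(**overrides) -> VariantRecord:
    base = dict(
        variant_id="rs1",
        chrom="1",
        pos=100,
        effect_allele="A",
        other_allele="G",
        beta=0.3,
        se=0.05,
        p_value=1e-8,
        eaf=0.2,
        locus="LOC1",
        ancestry="EUR",
    )
    base.update(overrides)
    return VariantRecord(**base)


@pytest.fixture
def fixture_dir() -> Path:
    return FIXTURE_DIR
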