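import numpy as np
import pandas as pd
import pytest

from sfsflow.demography import get_model
from sfsflow.engine import EngineConfig
from sfsflow.simulate import fixture_vcf
from sfsflow.vcf_filters import read_popmap


#: moderate-accuracy engine settings used by tests that fit models
FAST_ENGINE = EngineConfig(dt_fac=0.05, order_buffer=3)


@pytest.fixture(scope="session")
def filter_fixture(tmp_path_factory):
    """The hand-designed filter-rule VCF, its popmap and manifest."""
    d = tmp_path_factory.mktemp("fixture")
    vcf = d / "fixture.vcf"
    pop = d / "popmap.tsv"
    manifest = fixture_vcf(vcf, pop)
    return {"vcf": vcf, "popmap": read_popmap(pop), "popmap_path": pop,
            "manifest": manifest}


@pytest.fixture()
def small_site_table():
    return pd.DataFrame({
        "scaffold": ["s1", "s1", "s2"],
        "pos": [100, 600, 50],
        "anc": ["A", "C", "G"],
        "der": ["G", "T", "A"],
        "d1": [1, 2, 0],
        "c1": [4, 4, 2],
        "d2": [0, 1, 2],
        "c2": [2, 4, 2],
    })


@pytest.fixture(scope="session")
def im_model():
    return get_model("e1ms")
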