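import pandas as pd
import pytest

from cfmeth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-group cohort shared by read-only tests."""
    return generate_cohort(SimConfig(seed=7, n_regions=40,
                                     n_fragments_per_sample=3000))


@pytest.fixture()
def toy_fragments():
    """Ten high-quality fragments, two with the CCCA end motif."""
    motifs = ["CCCA", "CCCA"] + ["AAAA", "ACGT", "TTTA", "GGGC", "CATG",
                                 "TGCA", "GTAC", "AGTC"]
    return pd.DataFrame({
        "sample_id": "s1",
        "fragment_id": [f"f{i}" for i in range(10)],
        "chrom": "chrS",
        "start": range(0, 1000, 100),
        "end": [s + 166 for s in range(0, 1000, 100)],
        "mapq": 60,
        "motif5p": motifs,
        "gc": 0.5,
    })
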