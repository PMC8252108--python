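import numpy as np
import pandas as pd
import pytest

from aacsia import generate_dataset, paper_preset
from aacsia.registry import MEASURED_13


@pytest.fixture(scope="session")
def preset_dataset():
    """One preset dataset (6 plankton samples so LDA classes are viable)."""
    config = paper_preset(n_plankton=6)
    table, truth = generate_dataset(config, seed=11)
    return config, table, truth


def make_long_frame(sample_specs, aa_codes=None, elements=("C", "N"), base=-20.0):
    """Small deterministic long-format frame for IO tests.

    sample_specs: list of (sample_id, fraction, treatment).
    """
    aa_codes = list(aa_codes or MEASURED_13)
    rows = []
    for si, (sid, fraction, treatment) in enumerate(sample_specs):
        for ei, element in enumerate(elements):
            for ai, aa in enumerate(aa_codes):
                rows.append(
                    {
                        "sample_id": sid,
                        "fraction": fraction,
                        "treatment": treatment,
                        "study": "unit",
                        "genet": None,
                        "amino_acid": aa,
                        "element": element,
                        "delta": base + 10.0 * ei + ai + 0.1 * si,
                        "sd": 0.2 + 0.01 * ai,
                        "n_rep": 3,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def two_sample_frame():
    return make_long_frame(
        [("s1", "host", "L-NF"), ("s2", "symbiont", "L-NF")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
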