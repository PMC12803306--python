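import numpy as np
import pandas as pd
import pytest

from phenorisk.features import FeatureMap, PhenotypeFeature


def make_events(rows):
    """Build a diagnosis DataFrame from (patient, code, version, iso_date) tuples."""
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "icd_code": [r[1] for r in rows],
            "icd_version": [r[2] for r in rows],
            "event_date": pd.to_datetime([r[3] for r in rows]),
        }
    )


@pytest.fixture
def simple_fmap():
    """Three features over a handful of codes (both ICD versions)."""
    return FeatureMap(
        "toy_disease",
        [
            PhenotypeFeature(
                "hf", "Heart failure", frozenset({("I509", 10), ("I500", 10), ("4280", 9)})
            ),
            PhenotypeFeature("cts", "Carpal tunnel", frozenset({("G560", 10), ("3540", 9)})),
            PhenotypeFeature("pn", "Polyneuropathy", frozenset({("G629", 10)})),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
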