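import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import kinovuln as kv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_screen_params():
    """A 24-gene, 2-plate screen that exercises every layout branch."""
    return kv.ScreenSimParams(n_genes=24, sirnas_per_gene=3,
                              sample_wells_per_plate=40, controls_per_plate=3,
                              seed=42)


@pytest.fixture
def tiny_wells():
    """One hand-built plate: three controls (mean 1.0) and two samples."""
    return pd.DataFrame(
        {
            "plate_id": ["P1"] * 5,
            "well": ["A1", "A2", "A3", "B1", "B2"],
            "sirna_id": ["c1", "c2", "c3", "g1_si1", "g2_si1"],
            "gene": [None, None, None, "G1", "G2"],
            "role": ["control"] * 3 + ["sample"] * 2,
            "absorbance": [0.8, 1.0, 1.2, 0.5, 1.5],
        }
    )


@pytest.fixture
def clean_fit():
    """An exactly-known 4PL curve (bottom 0, top 100, IC50 200, hill 1)."""
    return kv.FourPLFit(bottom=0.0, top=100.0, ic50=200.0, hill=1.0,
                        rss=0.0, converged=True)
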