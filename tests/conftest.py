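import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_panel():
    """Two-population panel with one planted shared sweep (no noise)."""
    import rohscan as rs

    cfg = rs.SimConfig(
        seed=7,
        n_chrom=2,
        snps_per_chrom=1_500,
        chrom_length_bp=15_000_000,
        populations=[("pet", 25, 0.02), ("show", 25, 0.05)],
        het_error_rate=0.0,
        missing_rate=0.0,
        planted_segments=[
            rs.PlantedSegment(1, 3_000_000, 5_000_000, {"show": 0.8}, "shared_sweep")
        ],
    )
    return rs.simulate_panel(cfg)
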