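import numpy as np
import pandas as pd
import pytest

import sig2screen as s2s
from sig2screen import simulate
from sig2screen.screen import ProbePanel, ScreenTable


@pytest.fixture(scope="session")
def small_screen():
    """A small screen with strong spiked hits and plate batch effects."""
    cfg = simulate.ScreenSimConfig(
        n_compounds=60,
        n_hits=6,
        hit_log2fc=-1.5,
        replicates_per_compound=3,
        wells_per_plate=72,
        n_dmso_per_plate=8,
        n_probes=40,
        n_stable=33,
        seed=11,
    )
    table, truth = simulate.gen_screen(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def toy_panel():
    """Four 12-nt probes, two of them stable; distances between probes >= 6."""
    return ProbePanel(
        pd.DataFrame(
            {
                "probe_id": ["P1", "P2", "P3", "P4"],
                "sequence": ["ACGTACGTACGT", "TTTTGGGGCCCC", "AAAACCCCGGGG", "GTCAGTCAGTCA"],
                "gene": ["CXCL1", "CXCL2", "STB001", "STB002"],
                "is_stable": [False, False, True, True],
            }
        )
    )


@pytest.fixture(scope="session")
def sc_pair():
    """Reference and query single-cell cohorts from the default generator."""
    ref, _ = simulate.gen_scrna(simulate.ScSimConfig(n_patients=10, cells_per_patient=150, seed=5))
    query, truth = simulate.gen_scrna(
        simulate.ScSimConfig(n_patients=10, cells_per_patient=150, seed=6)
    )
    for ad in (ref, query):
        s2s.sc.lognormalize(ad)
    return ref, query, truth
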