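import numpy as np
import pytest

import minisplice as ms


@pytest.fixture(scope="session")
def ref():
    """Full-size (1.2 kb) three-exon reference."""
    return ms.generate_reference(seed=1)


@pytest.fixture(scope="session")
def ref_small():
    """Short reference for fast structural tests."""
    return ms.generate_reference(
        exon_lengths=(60, 90, 80), intron_lengths=(50, 40), orf_start=10, seed=2
    )


@pytest.fixture(scope="session")
def small_screen(ref):
    """A small simulated screen: library, truth and two replicate count tables."""
    cfg = ms.SimConfig(n_variants=250, n_wt=60, seed=11, coverage_mean=250)
    library, truth = ms.generate_library(ref, cfg)
    tables = ms.simulate_isoform_counts(library, truth, cfg)
    return cfg, library, truth, tables
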