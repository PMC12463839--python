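import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sequence_family():
    """A small simulated 16S family shared by matching tests."""
    from rhizoscreen.simdata import SequenceSimConfig, simulate_sequences

    return simulate_sequences(SequenceSimConfig(
        seed=42, n_isolates=8, n_asvs=15, divergence_range=(0.0, 0.04)))


def reference_records(sim):
    """Reference SequenceRecords for a simulated family."""
    from rhizoscreen.matching import SequenceRecord

    return [SequenceRecord(id=f"{iso}|{region}", residues=seq,
                           region=region, isolate_id=iso)
            for region, entries in sim.regions.items()
            for iso, seq in entries.items()]
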