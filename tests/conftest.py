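"""Shared fixtures: a small asymmetric scheme and a reference panel."""

import numpy as np
import pytest

import amplikit as ak


@pytest.fixture(scope="session")
def scheme():
    """6x6 asymmetric dual-UMI scheme with a full well map."""
    return ak.default_scheme(6, 6, seed=1)


@pytest.fixture(scope="session")
def refs(scheme):
    """Six COI-like references, one carrying an 11-bp thymine tract."""
    return ak.generate_references(
        6, homopolymer_spec=[("T", 11, "mid")], seed=2
    )


@pytest.fixture(scope="session")
def ref648():
    """Single 648-bp reference with a mid-sequence 11-bp T tract."""
    return ak.generate_references(
        1, length_range=(648, 648), homopolymer_spec=[("T", 11, 0.5)], seed=9
    )[0]


@pytest.fixture
def noise_free():
    """Simulation parameters with every error channel switched off."""
    return ak.SimulationParams(
        sub_rate=0.0,
        indel_rate=0.0,
        erosion_rate=0.0,
        rc_prob=0.0,
        pcr_error_rate=0.0,
        mean_reads_per_well=8,
        seed=3,
    )


def perfect_read(sequence, read_id="r1", qv=90):
    """A CCSRead with uniform QVs."""
    return ak.CCSRead(read_id, sequence, np.full(len(sequence), qv, dtype=np.int64))


@pytest.fixture
def make_read():
    return perfect_read
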