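"""Shared synthetic datasets; generated once per session at the study defaults."""
from __future__ import annotations

import logging

import numpy as np
import pytest

from radtas import (
    KineticScheme,
    neat_solvent_matrix,
    simulate_ta_matrix,
    solution_matrix,
)

logging.getLogger("radtas").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def neat_matrix():
    """Seeded neat-solvent picosecond matrix (bilinear mode)."""
    return neat_solvent_matrix(seed=7)


@pytest.fixture(scope="session")
def neat_shifting():
    """Seeded neat-solvent matrix with the moving visible band."""
    return neat_solvent_matrix(seed=3, mode="shifting")


@pytest.fixture(scope="session")
def neat_noiseless():
    return simulate_ta_matrix(KineticScheme(), noise_sd=0.0)


@pytest.fixture(scope="session")
def shifting_noiseless():
    return simulate_ta_matrix(KineticScheme(), mode="shifting", noise_sd=0.0)


@pytest.fixture(scope="session")
def solution_03():
    """Seeded 0.3 M solution matrix on the picosecond window."""
    return solution_matrix(0.3, seed=11)


@pytest.fixture(scope="session")
def neat_reference():
    """Independent neat reference for subtraction/frozen-spectra analyses."""
    return neat_solvent_matrix(seed=911)
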