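"""Shared fixtures: synthetic datasets reused across test modules."""

import numpy as np
import pytest

from thermoscreen import (
    ScreenSimConfig,
    TimelapseSimConfig,
    average_replicates,
    call_count_hits,
    score_screen,
    simulate_screen,
    simulate_timelapse,
)
from thermoscreen.condensation import analyze_embryo


@pytest.fixture(scope="session")
def planted_screen():
    """Screen with planted temperature effect classes plus ground truth."""
    cfg = ScreenSimConfig(
        n_plates=4,
        frac_17_specific=0.05,
        frac_27_specific=0.03,
        frac_both=0.03,
        frac_enhancer=0.02,
        seed=7,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def scored_screen(planted_screen):
    return score_screen(planted_screen.wells)


@pytest.fixture(scope="session")
def hit_table(scored_screen):
    return call_count_hits(average_replicates(scored_screen))


@pytest.fixture(scope="session")
def null_screen():
    """Screen with no planted effects (all amplicons null)."""
    return simulate_screen(ScreenSimConfig(n_plates=4, seed=11))


@pytest.fixture(scope="session")
def peripheral_sim():
    return simulate_timelapse(TimelapseSimConfig(n_nuclei=4, mode="peripheral", seed=1))


@pytest.fixture(scope="session")
def internal_sim():
    return simulate_timelapse(TimelapseSimConfig(n_nuclei=4, mode="internal", seed=2))


@pytest.fixture(scope="session")
def peripheral_analysis(peripheral_sim):
    return analyze_embryo(peripheral_sim.stack, peripheral_sim.metaphase_timepoint)


@pytest.fixture(scope="session")
def internal_analysis(internal_sim):
    return analyze_embryo(internal_sim.stack, internal_sim.metaphase_timepoint)


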