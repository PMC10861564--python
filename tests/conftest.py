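import numpy as np
import pytest

from isoscope.chem import (
    ADDUCTS,
    TRACER_13C,
    TRACER_15N,
    enumerate_isotopologues,
    parse_formula,
)
from isoscope.nacorrect import build_correction_matrix
from isoscope.synthetic import NoiseModel, default_panel, emit_feature_table

DUAL_TRACERS = [TRACER_13C, TRACER_15N]


@pytest.fixture(scope="session")
def glutamine_grid():
    """The 18-point dual-tracer grid of glutamine (C5, N2), deprotonated."""
    return enumerate_isotopologues(
        parse_formula("C5H10N2O3"), DUAL_TRACERS, ADDUCTS["[M-H]-"], "glutamine"
    )


@pytest.fixture(scope="session")
def glutamine_correction(glutamine_grid):
    return build_correction_matrix(glutamine_grid, mode="resolved")


@pytest.fixture(scope="session")
def dual_panel_data():
    """Default synthetic dual + lipid panel at default noise, seed 0."""
    return emit_feature_table(
        default_panel(),
        {"glutamine": DUAL_TRACERS, "PC(36:4)": [TRACER_13C]},
        times_h=(0, 2, 4, 6, 8),
        replicates=4,
        noise=NoiseModel(),
        seed=0,
    )
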