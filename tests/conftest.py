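import numpy as np
import pandas as pd
import pytest

from autoflux.flux_model import FluxDesign, LaneQuant


def make_design(cells: dict[tuple[str, bool], float] | dict, replicates=("R1",), noise=0.0, seed=0):
    """Build a FluxDesign directly from per-cell values.

    ``cells`` maps (condition, inhibitor) to the cell value; optional
    multiplicative lognormal noise is applied per replicate and cell.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in replicates:
        for (cond, inh), v in cells.items():
            f = rng.lognormal(0, noise) if noise > 0 else 1.0
            rows.append(
                {"replicate_id": rep, "condition": cond, "inhibitor": inh, "value": v * f}
            )
    return FluxDesign(data=pd.DataFrame(rows), scheme="lc3ii_over_control")


@pytest.fixture
def four_cell_lanes():
    """One replicate of the canonical 2x2 design, raw band intensities."""
    return [
        LaneQuant("R1", "EXP-", False, lc3ii=100, loading_control=100),
        LaneQuant("R1", "EXP-", True, lc3ii=150, loading_control=100),
        LaneQuant("R1", "EXP+", False, lc3ii=150, loading_control=100),
        LaneQuant("R1", "EXP+", True, lc3ii=200, loading_control=100),
    ]


@pytest.fixture
def simple_design():
    return make_design(
        {("EXP-", False): 100, ("EXP-", True): 150, ("EXP+", False): 150, ("EXP+", True): 200}
    )
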