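import numpy as np
import pytest

from blipta.library import (
    CombinationSpec,
    ComboRegimen,
    CompoundEntry,
    ModelLibrary,
    PKPDTarget,
    load_model_library,
    synthetic_library_path,
)
from blipta.pta import PTAEngine
from blipta.synthetic import make_onecpt_fixture, make_twocpt_fixture


@pytest.fixture(scope="session")
def onecpt():
    return make_onecpt_fixture()


@pytest.fixture(scope="session")
def twocpt():
    return make_twocpt_fixture()


@pytest.fixture(scope="session")
def synlib():
    return load_model_library(synthetic_library_path())


@pytest.fixture(scope="session")
def engine(synlib):
    """Shared small-population engine over the synthetic library."""
    return PTAEngine(synlib, n=400, seed=11)


@pytest.fixture(scope="session")
def degenerate_library(onecpt):
    """Zero-IIV single-compound library whose BLI target is trivially met.

    The BL and BLI are the same deterministic 1-compartment compound; the BLI
    carries an always-attained %fT>C_T target (threshold far below any
    concentration), so combined attainment must equal BL attainment exactly.
    """
    bl = CompoundEntry(
        key="refbl",
        model=onecpt.model,
        penetration=onecpt.penetration,
        target=onecpt.target,
    )
    bli = CompoundEntry(
        key="refbli",
        model=onecpt.model.model_copy(update={"compound_name": "refdrug1b"}),
        penetration=onecpt.penetration,
        target=PKPDTarget(
            metric="ft_above_ct",
            c_t_mg_per_L=1e-9,
            tier_magnitudes={"EUCAST": 1e-6, "Severe": 2e-6, "Aggressive": 3e-6},
        ),
    )
    reg = ComboRegimen(bl=onecpt.regimen, bli=onecpt.regimen)
    combo = CombinationSpec(
        name="REF",
        bl=bl,
        bli=bli,
        regimens={"bacteraemia": reg, "HAP/VAP": reg},
        mic_grid_mg_per_L=[1.0, 2.0, 4.0, 8.0],
    )
    return ModelLibrary(compounds={"refbl": bl, "refbli": bli}, combinations={"REF": combo})


@pytest.fixture(scope="session")
def reallib():
    from blipta.library import default_library_path

    return load_model_library(default_library_path())
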