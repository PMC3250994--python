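import numpy as np
import pytest

import pgpkin as pk


@pytest.fixture(scope="session")
def schedule():
    return pk.default_schedule()


@pytest.fixture(scope="session")
def fine_t(schedule):
    return pk.fine_grid(schedule)


@pytest.fixture(scope="session")
def wt1_truth():
    """The first wild-type parameter set: K1=0.054 mL/cc/min, k2=0.190 /min."""
    return pk.KineticParams(K1=0.054, k2=0.190, vB=0.03)


@pytest.fixture(scope="session")
def wt1_curves(wt1_truth):
    """Noise-free reference curves generated from the WT-1 ground truth."""
    gt = pk.GroundTruth(kinetics={"brain": wt1_truth}, group="WT-saline")
    return gt.curves()


@pytest.fixture(scope="session")
def wt1_inputs(wt1_curves):
    """(parent input, whole-blood InputFunction) on the true fine grid."""
    wb = pk.InputFunction(wt1_curves["times_s"], wt1_curves["whole_blood"])
    return wt1_curves["input_function"], wb
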