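import numpy as np
import pytest

import metcycle as mc
from metcycle.synthetic_data import StudyDesign


@pytest.fixture(scope="session")
def pop():
    """Packaged final population model (both groups, IIV, residual error)."""
    return mc.default_population()


@pytest.fixture(scope="session")
def control(pop):
    return pop.theta


@pytest.fixture(scope="session")
def zdf(pop):
    return pop.group_rates(1)


@pytest.fixture(scope="session")
def small_study(pop):
    """A small two-group synthetic study (8/group) with a fixed seed."""
    return mc.generate_study(mc.default_design(), pop, seed=20180210)


def random_rates(rng, stiff=True):
    """Random strictly-positive rate constants, log-uniform over a wide
    physiologic-ish range; K_SS optionally large to keep the system stiff."""
    draw = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return mc.RatePars(
        K_CM=draw(0.01, 10), K_MC=draw(0.01, 10), K_MS=draw(0.05, 10),
        K_SS=draw(100, 5000) if stiff else draw(0.1, 10),
        K_EL=draw(0.05, 5), K_SH=draw(1, 50), K_HM=draw(0.5, 50),
        K_HC=draw(0.1, 50), K_HP=draw(1, 200), K_PH=draw(0.01, 10),
        Vc=draw(0.05, 1.0))
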