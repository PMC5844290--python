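import warnings

import numpy as np
import pytest

from fluctassay.data import CultureSet
from fluctassay.exceptions import FewCulturesWarning
from fluctassay.simulate import simulate_cultureset
from fluctassay.data import StrainSpec


@pytest.fixture(autouse=True)
def _quiet_small_experiments():
    """Unit tests routinely use tiny culture sets; silence the size warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FewCulturesWarning)
        yield


def make_cultureset(counts, strain_id="S", reporter="CanR", Nt=1e8, plated_fraction=1.0):
    return CultureSet(
        strain_id=strain_id,
        reporter=reporter,
        counts=np.asarray(counts),
        Nt=Nt,
        plated_fraction=plated_fraction,
    )


def simulate_set(m, n_cultures, seed, strain_id="S", reporter="CanR", Nt=1e8):
    """Simulated culture set with a given expected event count m."""
    n0 = 1e3
    spec = StrainSpec(
        strain_id=strain_id,
        reporter=reporter,
        mu=m / (Nt - n0),
        Nt=Nt,
        N0=n0,
        n_cultures=n_cultures,
    )
    return simulate_cultureset(spec, seed)


@pytest.fixture
def wt_set():
    return simulate_set(3.0, 18, seed=11, strain_id="WT")
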