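import numpy as np
import pytest

from kappab.circuit import CircuitParams
from kappab.ssa import estimate_sspd, ssa_reduced


@pytest.fixture(scope="session")
def defaults() -> CircuitParams:
    return CircuitParams()


#: horizons chosen so each run collects ~1e6 events (event rates differ by kd)
_SSA_T_END = {1e-3: 8.0e6, 2e-3: 1.4e7, 3e-3: 3.6e7}


@pytest.fixture(scope="session")
def reduced_runs(defaults):
    """Long reduced-SSA runs and their stationary histograms at the three
    reference degradation rates (monostable / bistable / monostable)."""
    out = {}
    for i, (kd, t_end) in enumerate(_SSA_T_END.items()):
        tr = ssa_reduced(defaults.replace(kd=kd), t_end, seed=1000 + i)
        hist = estimate_sspd(tr, burn_in=0.05 * t_end)
        out[kd] = (tr, hist)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
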