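"""Hill responses, vector fields and equilibrium finding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kappab.circuit import (
    CircuitParams,
    CircuitState,
    find_equilibria,
    hill_activation,
    hill_repression,
    rhs_full,
    rhs_qssa,
)


@pytest.mark.parametrize(
    "N, Km1, nH1, expected",
    [
        (12.0, 12.0, 1.0, 0.5),          # half-saturation symmetry
        (100.0, 12.0, 1.0, 100.0 / 112.0),
        (0.0, 12.0, 4.0, 0.0),
    ],
)
def test_hill_activation_values(N, Km1, nH1, expected):
    assert hill_activation(N, Km1, nH1) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "I, Km2, nH2, expected, tol",
    [
        (12.0, 12.0, 4.0, 0.5, 1e-12),
        (0.0, 12.0, 4.0, 1.0, 1e-12),
        (29.50876, 12.0, 4.0, 0.02662, 5e-6),  # repression at the upper equilibrium
    ],
)
def test_hill_repression_values(I, Km2, nH2, expected, tol):
    assert hill_repression(I, Km2, nH2) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("bad", [dict(Km1=0.0), dict(nH1=-1.0)])
def test_hill_activation_domain_errors(bad):
    kw = dict(N=10.0, Km1=12.0, nH1=1.0)
    kw.update(bad)
    with pytest.raises(ValueError):
        hill_activation(**kw)


@settings(max_examples=50, derandomize=True)
@given(
    n1=st.floats(0.0, 1e4),
    n2=st.floats(0.0, 1e4),
    km=st.floats(0.1, 100.0),
    nh=st.floats(0.2, 6.0),
)
def test_hill_monotonicity_and_range(n1, n2, km, nh):
    fa1, fa2 = hill_activation(n1, km, nh), hill_activation(n2, km, nh)
    fr1, fr2 = hill_repression(n1, km, nh), hill_repression(n2, km, nh)
    assert 0.0 <= fa1 <= 1.0 and 0.0 <= fr1 <= 1.0
    if n1 <= n2:
        assert fa1 <= fa2 + 1e-12   # activation non-decreasing
        assert fr1 >= fr2 - 1e-12   # repression non-increasing


def test_rhs_full_vanishes_at_printed_equilibrium(defaults):
    dG, dI = rhs_full(CircuitState(0.90796, 29.50876), defaults)
    assert abs(dG) < 1e-5 and abs(dI) < 1e-5


def test_rhs_full_direct_substitutions(defaults):
    # fully active gene, no protein: deactivation at full rate, production kP
    dG, dI = rhs_full(CircuitState(1.0, 0.0), defaults)
    assert dG == pytest.approx(-3.4) and dI == pytest.approx(0.065)
    # absorbing origin without NF-κB
    dG0, dI0 = rhs_full(CircuitState(0.0, 0.0), defaults.replace(N=0.0))
    assert dG0 == 0.0 and dI0 == 0.0


def test_rhs_qssa_signs_and_equilibrium(defaults):
    assert abs(rhs_qssa(29.50876, defaults)) < 1e-6
    assert rhs_qssa(0.0, defaults) > 0.0            # net production at I = 0
    assert rhs_qssa(10.0 * defaults.I_ceiling, defaults) < 0.0


def test_find_equilibria_default_set(defaults):
    eqs = find_equilibria(defaults)
    assert len(eqs) == 3
    stabilities = [e.stability for e in eqs]
    assert stabilities == ["stable", "saddle", "stable"]
    upper = eqs[-1]
    assert upper.I == pytest.approx(29.50876, abs=5e-5)
    assert upper.Gstar == pytest.approx(0.90796, abs=5e-5)
    for e in eqs:
        # residual refinement and the algebraic slaving G* = kd I / kP
        assert abs(rhs_qssa(e.I, defaults)) < 1e-10
        if e.I > 0:
            assert e.Gstar == pytest.approx(defaults.kd * e.I / defaults.kP, rel=1e-10)


def test_find_equilibria_no_activation():
    eqs = find_equilibria(CircuitParams(N=0.0))
    assert len(eqs) == 1
    assert eqs[0].I == pytest.approx(0.0, abs=1e-12)
    assert eqs[0].stability == "stable"


def test_find_equilibria_three_roots_near_fold(defaults):
    eqs = find_equilibria(defaults.replace(kd=0.00226))
    assert len(eqs) == 3
    assert [e.stability for e in eqs] == ["stable", "saddle", "stable"]


def test_find_equilibria_matches_dense_scan_oracle(defaults, rng):
    """Root set equals the sign-change set of a 1e5-point brute-force scan."""
    for _ in range(50):
        p = defaults.replace(
            k1=float(rng.uniform(0.2, 3.0)),
            k2=float(rng.uniform(0.5, 6.0)),
            kd=float(rng.uniform(5e-4, 5e-3)),
            N=float(rng.uniform(10.0, 300.0)),
            nH2=float(rng.uniform(1.0, 6.0)),
        )
        grid = np.linspace(0.0, 1.05 * p.I_ceiling, 100_001)
        vals = rhs_qssa(grid, p)
        n_oracle = int(np.sum(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0))
        assert len(find_equilibria(p)) == n_oracle


def test_ode_trajectories_stay_in_box(defaults):
    """The instantaneous system leaves [0,1] x [0, inf) invariant."""
    from kappab.ddesim import DelayConfig, integrate_dde

    for g0, i0 in [(0.0, 0.0), (1.0, 60.0), (0.5, 5.0)]:
        cfg = DelayConfig(T=0.0, t_end=500.0, history=CircuitState(g0, i0))
        r = integrate_dde(defaults, cfg)
        assert np.all(r.Gstar_series >= -1e-9) and np.all(r.Gstar_series <= 1 + 1e-9)
        assert np.all(r.I_series >= -1e-9)


def test_params_validation():
    with pytest.raises(ValueError):
        CircuitParams(kd=0.0)
    with pytest.raises(ValueError):
        CircuitParams(N=-1.0)
    with pytest.raises(ValueError):
        CircuitParams.from_dict({"kd": 0.002, "bogus": 1.0})
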