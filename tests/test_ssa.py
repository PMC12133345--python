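"""Stochastic kinetics: exactness, seeding, OU statistics, coloured scheme."""

import numpy as np
import pytest

from kappab.circuit import CircuitParams, s_plus
from kappab.ssa import (
    OUParams,
    Trajectory,
    estimate_sspd,
    generate_ou_path,
    ou_step,
    spawn_seeds,
    ssa_colored,
    ssa_full,
    ssa_reduced,
)


def test_seed_reproducibility_bitwise(defaults):
    a = ssa_reduced(defaults, 1e5, seed=7)
    b = ssa_reduced(defaults, 1e5, seed=7)
    assert np.array_equal(a.times, b.times) and np.array_equal(a.I_series, b.I_series)
    c = ssa_colored(defaults, OUParams(D=0.5, tau=5.0), 1e5, seed=7)
    d = ssa_colored(defaults, OUParams(D=0.5, tau=5.0), 1e5, seed=7)
    assert np.array_equal(c.times, d.times) and np.array_equal(c.epsilon_series, d.epsilon_series)


def test_reduced_counts_never_negative_and_unit_steps(defaults):
    tr = ssa_reduced(defaults.replace(kd=3e-3), 5e5, seed=3)
    assert np.min(tr.I_series) >= 0
    assert set(np.unique(np.diff(tr.I_series))) <= {-1, 1}
    assert np.all(np.diff(tr.times) > 0)


def test_no_production_without_activator():
    tr = ssa_full(CircuitParams(N=0.0), 1e4, seed=1, g0=0, i0=0)
    assert np.all(tr.I_series == 0)


def test_full_scheme_gene_states_binary(defaults):
    tr = ssa_full(defaults, 2e5, seed=9)
    assert set(np.unique(tr.Gstar_series)) <= {0, 1}


def test_reduced_matches_birth_death_product_form(reduced_runs, defaults):
    """Empirical stationary law vs the exact product-form solution.

    For a 1-D birth-death chain the stationary distribution is
    π(I) ∝ Π_{i<=I} S+(i-1)/S-(i); a χ² test on decorrelated samples
    must not reject it.
    """
    from scipy.stats import chisquare

    from kappab.spectra import resample_uniform

    p = defaults.replace(kd=3e-3)
    tr, _ = reduced_runs[3e-3]
    i_max = 140
    logpi = np.zeros(i_max + 1)
    for i in range(1, i_max + 1):
        logpi[i] = logpi[i - 1] + np.log(s_plus(i - 1.0, p)) - np.log(p.kd * i)
    pi = np.exp(logpi - logpi.max())
    pi /= pi.sum()
    samples = resample_uniform(tr, 1500.0, burn_in=0.05 * tr.t_end).astype(int)
    obs = np.bincount(np.clip(samples, 0, i_max), minlength=i_max + 1)
    exp = pi * len(samples)
    merge = exp >= 5
    o = np.append(obs[merge], obs[~merge].sum())
    e = np.append(exp[merge], exp[~merge].sum())
    res = chisquare(o, e * o.sum() / e.sum())
    assert res.pvalue > 0.01


def test_sspd_histogram_two_state_oracle():
    """Time-weighted occupancy of a deterministic two-state path equals the
    holding-time ratio exactly."""
    times = np.concatenate([[0.0], np.cumsum(np.tile([1.0, 3.0], 50))])[:-1]
    states = np.tile([0, 1], 50)
    tr = Trajectory(times, states, seed=0, scheme="reduced", t_end=float(times[-1] + 3.0))
    dg = estimate_sspd(tr, burn_in=0.0)
    assert dg.density[0] == pytest.approx(0.25, abs=1e-12)
    assert dg.density[1] == pytest.approx(0.75, abs=1e-12)
    assert np.sum(dg.density) * 1.0 == pytest.approx(1.0, abs=1e-12)


def test_sspd_histogram_normalization(reduced_runs):
    _, hist = reduced_runs[2e-3]
    assert np.sum(hist.density) * 1.0 == pytest.approx(1.0, abs=1e-12)


def test_sspd_modes_near_deterministic_equilibria(reduced_runs, defaults):
    """Bistable histogram puts its two modes near the stable fixed points
    (the chemical-FPE mode sits 1-2 molecules below the drift zero)."""
    from kappab.circuit import find_equilibria

    _, hist = reduced_runs[2e-3]
    stable = [e.I for e in find_equilibria(defaults) if e.stability == "stable"]
    assert len(hist.modes) == 2
    for I_eq in stable:
        assert min(abs(m[0] - I_eq) for m in hist.modes) < 2.5


def test_ou_step_stationary_limit(rng):
    ou = OUParams(D=2.0, tau=10.0)
    draws = np.array([ou_step(5.0, 1e6, ou, rng) for _ in range(4000)])
    sd = ou.stationary_std
    assert abs(draws.mean()) < 3 * sd / np.sqrt(len(draws))
    assert draws.var() == pytest.approx(sd**2, rel=0.15)


def test_ou_step_deterministic_decay(rng):
    ou = OUParams(D=0.0, tau=4.0)
    assert ou_step(2.0, 8.0, ou, rng) == pytest.approx(2.0 * np.exp(-2.0), rel=1e-12)


def test_ou_lag_correlator(rng):
    """Sample correlator matches (D/τ) e^{-Δ/τ} at five lags within 3 SE."""
    ou = OUParams(D=2.0, tau=10.0)
    dt = 1.0
    n_paths = 60
    lags = [2, 5, 10, 20, 40]
    per_path = np.empty((n_paths, len(lags)))
    for k in range(n_paths):
        _, eps = generate_ou_path(ou, 4000.0, dt, rng)
        eps = eps[200:]  # discard the ε(0)=0 transient
        for j, lag in enumerate(lags):
            per_path[k, j] = np.mean(eps[:-lag] * eps[lag:])
    mean = per_path.mean(axis=0)
    sem = per_path.std(axis=0, ddof=1) / np.sqrt(n_paths)
    expected = (ou.D / ou.tau) * np.exp(-np.array(lags) * dt / ou.tau)
    assert np.all(np.abs(mean - expected) < 3 * sem)


def test_colored_with_zero_noise_matches_reduced(defaults):
    """D = 0 colouring is statistically indistinguishable from the plain
    birth-death scheme (KS on decorrelated stationary samples)."""
    from scipy.stats import ks_2samp

    from kappab.spectra import resample_uniform

    p = defaults.replace(kd=3e-3)
    a = resample_uniform(ssa_colored(p, OUParams(D=0.0, tau=1.0), 2e6, 99), 1000.0, 1e4)[::2]
    b = resample_uniform(ssa_reduced(p, 2e6, 123), 1000.0, 1e4)[::2]
    assert ks_2samp(a, b).pvalue > 0.01


def test_colored_histogram_agrees_with_ucna_density(defaults):
    """Coloured-SSA stationary histograms track the UCNA closed form at
    moderate noise (normalized sup-norm under 0.2)."""
    from kappab.density import sspd_ucna

    p = defaults.replace(kd=1e-3)
    for D, tau, t_end in ((10.0, 10.0, 3e6), (200.0, 1000.0, 4e6)):
        ou = OUParams(D=D, tau=tau)
        dg = sspd_ucna(p, ou)
        tr = ssa_colored(p, ou, t_end, seed=21)
        h = estimate_sspd(tr, burn_in=0.05 * t_end)
        on_grid = np.interp(h.I_grid, dg.I_grid, dg.density)
        assert np.max(np.abs(h.density - on_grid)) < 0.2


def test_usage_errors(defaults):
    with pytest.raises(ValueError):
        ssa_reduced(defaults, -1.0, seed=0)
    with pytest.raises(ValueError):
        OUParams(D=-1.0, tau=1.0)
    with pytest.raises(ValueError):
        OUParams(D=1.0, tau=0.0)


def test_spawn_seeds_deterministic_and_bounded():
    s1 = spawn_seeds(42, 8)
    s2 = spawn_seeds(42, 8)
    assert np.array_equal(s1, s2)
    assert np.all(s1 >= 0) and np.all(s1 < 2**31)
    assert len(np.unique(s1)) == 8
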