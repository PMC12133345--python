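"""Closed-form stationary densities: FPE, UCNA, modes and contours."""

import numpy as np
import pytest

from kappab.circuit import find_equilibria
from kappab.density import DensityGrid, find_modes, pmax_contour, sspd_ucna, sspd_white
from kappab.ssa import OUParams


def test_white_density_normalized_and_nonnegative(defaults):
    for kd in (1e-3, 2e-3, 3e-3):
        dg = sspd_white(defaults.replace(kd=kd))
        assert dg.integral() == pytest.approx(1.0, abs=1e-8)
        assert np.all(dg.density >= 0.0)


def test_white_density_mode_counts_track_bistability(defaults):
    assert len(sspd_white(defaults.replace(kd=1e-3)).modes) == 1
    assert len(sspd_white(defaults.replace(kd=2e-3)).modes) == 2
    assert len(sspd_white(defaults.replace(kd=3e-3)).modes) == 1


def test_white_density_modes_near_stable_equilibria(defaults):
    """Density maxima sit within ~2 molecules of the stable fixed points
    (the finite-number skew of the chemical FPE shifts them slightly down)."""
    for kd in (1e-3, 2e-3, 3e-3):
        p = defaults.replace(kd=kd)
        dg = sspd_white(p)
        stable = [e.I for e in find_equilibria(p) if e.stability == "stable"]
        assert len(dg.modes) == len(stable)
        for I_eq in stable:
            assert min(abs(m[0] - I_eq) for m in dg.modes) < 2.5


def test_white_density_requires_activation(defaults):
    with pytest.raises(ValueError):
        sspd_white(defaults.replace(N=0.0))


def test_fpe_matches_reduced_ssa_histogram(reduced_runs, defaults):
    """'Fair correlation' between the closed-form FPE density and the
    time-weighted Gillespie histogram at all three reference kd."""
    for kd, (_, hist) in reduced_runs.items():
        dg = sspd_white(defaults.replace(kd=kd))
        on_grid = np.interp(hist.I_grid, dg.I_grid, dg.density)
        assert np.max(np.abs(on_grid - hist.density)) < 0.15
        assert len(hist.modes) == len(dg.modes)


def test_ucna_reduces_to_its_z1_reference_as_tau_shrinks(defaults):
    """τ → 0 sends the UCNA correction Z → 1; the density converges to the
    white-extrinsic reference monotonically along the ladder."""
    for kd in (1e-3, 2e-3):
        p = defaults.replace(kd=kd)
        ref = sspd_ucna(p, OUParams(D=0.5, tau=1.0), force_Z1=True)
        sups = []
        for tau in (1.0, 0.1, 0.01):
            dg = sspd_ucna(p, OUParams(D=0.5, tau=tau))
            sups.append(float(np.max(np.abs(dg.density - ref.density))))
        assert sups[0] > sups[1] > sups[2]


def test_ucna_reduces_to_intrinsic_limit_as_D_shrinks(defaults):
    """D → 0 removes the extrinsic diffusion channel; the density converges
    monotonically to the UCNA functional's own D = 0 limit."""
    for kd in (1e-3, 2e-3):
        p = defaults.replace(kd=kd)
        ref = sspd_ucna(p, OUParams(D=1e-10, tau=0.01))
        sups = []
        for D in (0.5, 0.05, 0.005):
            dg = sspd_ucna(p, OUParams(D=D, tau=0.01))
            sups.append(float(np.max(np.abs(dg.density - ref.density))))
        assert sups[0] > sups[1] > sups[2]


def test_ucna_small_noise_corner_close_to_white_fpe(defaults):
    """At D → 0, τ → 0 the UCNA density differs from the chemical-FPE form
    only through its prefactor; the shapes are close in sup-norm."""
    for kd in (1e-3, 2e-3, 3e-3):
        p = defaults.replace(kd=kd)
        w = sspd_white(p)
        u = sspd_ucna(p, OUParams(D=1e-10, tau=0.01))
        on_w = np.interp(w.I_grid, u.I_grid, u.density)
        assert np.max(np.abs(on_w - w.density)) < 0.05


def test_noise_induced_bimodality(defaults):
    """Strong slow extrinsic noise makes the monostable kd = 1e-3 system
    bimodal while the intrinsic-only density stays unimodal."""
    p = defaults.replace(kd=1e-3)
    assert len(sspd_white(p).modes) == 1
    dg = sspd_ucna(p, OUParams(D=1000.0, tau=1000.0))
    assert len(dg.modes) == 2


def test_correlation_time_sharpens_density(defaults):
    """Increasing τ at fixed D shrinks the inter-quartile width."""
    p = defaults.replace(kd=1e-3)

    def iqw(dg: DensityGrid) -> float:
        cdf = np.cumsum(dg.density)
        cdf /= cdf[-1]
        lo = dg.I_grid[np.searchsorted(cdf, 0.25)]
        hi = dg.I_grid[np.searchsorted(cdf, 0.75)]
        return float(hi - lo)

    widths = [iqw(sspd_ucna(p, OUParams(D=100.0, tau=tau))) for tau in (1.0, 10.0, 100.0, 1000.0)]
    assert all(a >= b for a, b in zip(widths, widths[1:]))


def test_find_modes_synthetic_shapes():
    x = np.linspace(0.0, 10.0, 2001)
    gauss = np.exp(-0.5 * ((x - 5.0) / 0.8) ** 2)
    dg = DensityGrid(x, gauss / np.trapezoid(gauss, x), 1.0)
    modes = find_modes(dg)
    assert len(modes) == 1
    assert modes[0][0] == pytest.approx(5.0, abs=0.01)

    double = np.exp(-0.5 * ((x - 3.0) / 0.5) ** 2) + np.exp(-0.5 * ((x - 7.0) / 0.5) ** 2)
    dg2 = DensityGrid(x, double / np.trapezoid(double, x), 1.0)
    modes2 = find_modes(dg2)
    assert len(modes2) == 2
    assert modes2[0][1] == pytest.approx(modes2[1][1], rel=1e-6)  # symmetric bumps


def test_pmax_contour_limits_and_bimodal_region(defaults):
    p = defaults.replace(kd=1e-3)
    D_range = np.array([1e-9, 300.0, 1500.0])
    tau_range = np.array([1.0, 1000.0])
    P, M, F = pmax_contour(p, D_range, tau_range)
    # D -> 0 column matches the intrinsic white-noise result
    w = sspd_white(p)
    assert P[0, 0] == pytest.approx(w.pmax, rel=0.05)
    # bimodality appears in the high-(D, τ) corner; Pmax drops with D there
    assert M[1, 2] == 2
    assert P[1, 2] < P[1, 0]
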