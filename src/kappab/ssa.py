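"""Exact-event stochastic kinetics of the circuit.

Three schemes are provided:

* ``ssa_full`` — Gillespie direct method on the four elementary reactions
  (gene activation/deactivation, protein production, protein decay) with a
  single binary gene copy;
* ``ssa_reduced`` — two-channel birth-death walk on I alone with the QSSA
  propensities S+(I) and S-(I) = kd I;
* ``ssa_colored`` — the reduced scheme with the degradation rate modulated
  by an Ornstein-Uhlenbeck process, kd -> kd (1 + ε(t)), simulated with a
  next-reaction method whose degradation hazard is integrated
  piecewise-constant over a fine OU grid (a time-dependent-propensity
  variant of Anderson's modified next reaction method).

The OU process has zero mean and stationary correlator (D/τ) e^{-|Δ|/τ};
its stationary variance is therefore D/τ and ``ou_step`` performs the
exact Gaussian update over an arbitrary time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import ssa_colored_kernel, ssa_full_kernel, ssa_reduced_kernel
from .circuit import CircuitParams, hill_activation

__all__ = [
    "OUParams",
    "Trajectory",
    "ou_step",
    "generate_ou_path",
    "ssa_full",
    "ssa_reduced",
    "ssa_colored",
    "estimate_sspd",
    "spawn_seeds",
]

_DEFAULT_MAX_EVENTS = 20_000_000


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck noise on the degradation rate.

    D : noise strength; the stationary variance of ε is D/τ
    tau : correlation time (min)
    epsilon0 : initial noise value
    """

    D: float = 0.0
    tau: float = 1.0
    epsilon0: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def stationary_std(self) -> float:
        return float(np.sqrt(self.D / self.tau))

    def grid_dt(self) -> float:
        """OU discretization step: τ/50 capped at 0.1 min."""
        return min(self.tau / 50.0, 0.1)


@dataclass
class Trajectory:
    """An event-time series of the protein count (and gene/noise state)."""

    times: np.ndarray
    I_series: np.ndarray
    seed: int
    scheme: str  # 'full' | 'reduced' | 'reduced-colored'
    t_end: float
    Gstar_series: np.ndarray | None = None
    epsilon_series: np.ndarray | None = None
    n_clamped: int = 0


def ou_step(epsilon: float, dt: float, ou: OUParams, rng: np.random.Generator) -> float:
    """Exact OU update over dt: mean-reverting decay plus Gaussian kick."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt / ou.tau)
    sd = ou.stationary_std * np.sqrt(1.0 - decay * decay)
    return float(epsilon * decay + sd * rng.standard_normal())


def generate_ou_path(ou: OUParams, t_end: float, dt: float, rng: np.random.Generator):
    """An OU sample path on a uniform grid (vectorized exact recursion)."""
    n = int(np.ceil(t_end / dt))
    decay = np.exp(-dt / ou.tau)
    sd = ou.stationary_std * np.sqrt(1.0 - decay * decay)
    kicks = sd * rng.standard_normal(n)
    eps = np.empty(n + 1)
    eps[0] = ou.epsilon0
    for i in range(n):
        eps[i + 1] = eps[i] * decay + kicks[i]
    return np.arange(n + 1) * dt, eps


def _check_times(t_end: float) -> None:
    if t_end <= 0:
        raise ValueError("t_end must be positive")


def ssa_full(
    p: CircuitParams,
    t_end: float,
    seed: int,
    g0: int = 1,
    i0: int = 0,
    max_events: int = _DEFAULT_MAX_EVENTS,
) -> Trajectory:
    """Gillespie direct method on the full four-reaction scheme."""
    _check_times(t_end)
    k1fa = p.k1 * hill_activation(p.N, p.Km1, p.nH1)
    t, I, g = ssa_full_kernel(
        k1fa, p.k2, p.kP, p.kd, p.Km2, p.nH2, g0, i0, t_end, max_events, seed
    )
    return Trajectory(t, I, seed, "full", t_end, Gstar_series=g)


def ssa_reduced(
    p: CircuitParams,
    t_end: float,
    seed: int,
    i0: int = 0,
    max_events: int = _DEFAULT_MAX_EVENTS,
) -> Trajectory:
    """Two-channel birth-death SSA with the QSSA propensities."""
    _check_times(t_end)
    k1fa = p.k1 * hill_activation(p.N, p.Km1, p.nH1)
    t, I = ssa_reduced_kernel(
        k1fa, p.k2, p.kP, p.kd, p.Km2, p.nH2, i0, t_end, max_events, seed
    )
    return Trajectory(t, I, seed, "reduced", t_end)


def ssa_colored(
    p: CircuitParams,
    ou: OUParams,
    t_end: float,
    seed: int,
    i0: int = 0,
    max_events: int = _DEFAULT_MAX_EVENTS,
) -> Trajectory:
    """Next-reaction SSA with OU-modulated degradation propensity.

    The modulated rate kd (1 + ε) is clamped at zero when the noise
    excursion would make it negative; the number of clamped evaluations is
    recorded on the trajectory (negligible for D/τ « 1).
    """
    _check_times(t_end)
    k1fa = p.k1 * hill_activation(p.N, p.Km1, p.nH1)
    t, I, eps, n_clamp = ssa_colored_kernel(
        k1fa,
        p.k2,
        p.kP,
        p.kd,
        p.Km2,
        p.nH2,
        i0,
        t_end,
        max_events,
        seed,
        ou.D,
        ou.tau,
        ou.grid_dt(),
        ou.epsilon0,
    )
    return Trajectory(t, I, seed, "reduced-colored", t_end, epsilon_series=eps, n_clamped=int(n_clamp))


def estimate_sspd(
    trajectories: list[Trajectory] | Trajectory,
    burn_in: float = 0.0,
    bin_width: float = 1.0,
):
    """Time-weighted occupancy histogram over I, normalized as a density.

    Each visited state is weighted by its holding time (the span between
    successive events), so the estimate is the exact stationary occupancy
    of the sampled path rather than an event-count histogram.
    """
    from .density import DensityGrid, _attach_modes

    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    i_max = int(max(np.max(tr.I_series) for tr in trajectories))
    n_bins = int(np.floor(i_max / bin_width)) + 1
    weights = np.zeros(n_bins)
    span = 0.0
    for tr in trajectories:
        t_stop = tr.t_end if np.isfinite(tr.t_end) else tr.times[-1]
        hold = np.diff(np.append(tr.times, t_stop))
        keep = tr.times + hold > burn_in
        hold = hold[keep].copy()
        tt = tr.times[keep]
        if len(tt) and tt[0] < burn_in:
            hold[0] = tt[0] + hold[0] - burn_in
        idx = (tr.I_series[keep] / bin_width).astype(np.int64)
        np.add.at(weights, idx, hold)
        span += float(np.sum(hold))
    if span <= 0:
        raise ValueError("no post-burn-in span in the trajectories")
    centers = (np.arange(n_bins) + 0.5) * bin_width
    density = weights / (span * bin_width)
    return _attach_modes(DensityGrid(centers, density, 1.0 / span))


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive n independent kernel seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 1)).astype(np.int64)
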