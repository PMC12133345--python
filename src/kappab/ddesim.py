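"""Fixed-step RK4 integration of the delayed circuit and its phenomenology.

The delay is rounded to the nearest multiple of the step (error at most
h/2, i.e. 5e-4 min at the default h = 0.001 min), so delayed lookups are
exact grid reads; the intermediate RK4 stages reuse the same delayed value,
which is O(h^4)-consistent only for the non-delayed part of the right-hand
side.  Histories are constant states on [-T, 0], matching how initial
conditions such as IC1 = (0.8, 30.0) and IC2 = (0.1, 5.0) are specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._kernels import rk4_dde
from .circuit import CircuitParams, CircuitState, hill_activation

__all__ = [
    "DelayConfig",
    "DelaySimResult",
    "IC1",
    "IC2",
    "integrate_dde",
    "classify_attractor",
    "oscillation_metrics",
    "basin_scan",
    "dde_oscillation_boundary_kd",
]

#: the two initial histories used throughout: IC1 targets the upper branch,
#: IC2 the lower one.
IC1 = CircuitState(0.8, 30.0)
IC2 = CircuitState(0.1, 5.0)


@dataclass(frozen=True)
class DelayConfig:
    """Integration settings for one delayed run."""

    T: float = 2.5
    h_step: float = 0.001
    t_end: float = 5000.0
    transient_fraction: float = 0.5
    history: CircuitState = IC1
    record_every: int = 10  # store every k-th step (default dt = 0.01 min)

    def __post_init__(self) -> None:
        if self.h_step <= 0:
            raise ValueError("h_step must be positive")
        if self.T < 0:
            raise ValueError("delay T must be >= 0")
        if self.T > 0 and self.t_end <= 10 * self.T:
            raise ValueError("t_end must exceed 10*T")
        if not 0 < self.transient_fraction < 1:
            raise ValueError("transient_fraction must lie in (0, 1)")


@dataclass
class DelaySimResult:
    times: np.ndarray
    Gstar_series: np.ndarray
    I_series: np.ndarray
    attractor: str  # 'steady' | 'oscillatory'
    amplitude: float
    period: float
    frequency: float
    config: DelayConfig = field(repr=False, default=None)


#: relative peak-to-trough range below which a trajectory counts as steady
OSCILLATION_THRESHOLD = 1e-3


def integrate_dde(p: CircuitParams, cfg: DelayConfig) -> DelaySimResult:
    """Integrate the delayed system and classify the post-transient attractor."""
    h = cfg.h_step
    lag = int(round(cfg.T / h))
    k = max(cfg.record_every, 1)
    n_steps = int(np.ceil(cfg.t_end / (h * k))) * k
    b = p.k1 * hill_activation(p.N, p.Km1, p.nH1)
    G, I = rk4_dde(
        b, p.k2, p.kP, p.kd, p.Km2, p.nH2, n_steps, h, lag, cfg.history.Gstar, cfg.history.I, k
    )
    # Unlike the instantaneous system, the delayed equations do not preserve
    # the box 0 <= G* <= 1: deep in the oscillatory regime the gene variable
    # makes large excursions outside it (a real feature of the delayed model,
    # stable under step refinement), so only blow-up is treated as an error.
    if not (np.all(np.isfinite(I)) and np.all(np.isfinite(G))):
        raise RuntimeError("integration diverged; reduce h_step")
    times = np.arange(len(I)) * (h * k)
    att = classify_attractor(times, I, transient_fraction=cfg.transient_fraction)
    if att == "oscillatory":
        amp, per, freq = oscillation_metrics(times, I, transient_fraction=cfg.transient_fraction)
    else:
        amp, per, freq = 0.0, np.nan, np.nan
    return DelaySimResult(times, G, I, att, amp, per, freq, cfg)


def _post_transient(times, series, transient_fraction):
    i0 = int(len(times) * transient_fraction)
    return times[i0:], series[i0:]


def _regular_peaks(t, x):
    rng = np.ptp(x)
    if rng == 0.0:
        return np.array([], dtype=int)
    pk, _ = find_peaks(x, prominence=0.25 * rng)
    return pk


def classify_attractor(
    times: np.ndarray,
    I_series: np.ndarray,
    threshold: float = OSCILLATION_THRESHOLD,
    transient_fraction: float = 0.5,
) -> str:
    """'oscillatory' iff the late window keeps a finite swing with >= 5 regular peaks.

    The peak-to-trough range of the final fifth of the trajectory must
    exceed ``threshold`` times the mean level (a decaying ring-down fails
    this), and the post-transient window must contain at least five peaks
    whose spacing has a coefficient of variation under 5%.
    """
    t, x = _post_transient(times, I_series, transient_fraction)
    if len(t) < 100:
        raise ValueError("post-transient window too short to classify")
    mean = float(np.mean(x))
    tail = x[int(0.8 * len(x)):]
    if np.ptp(tail) < threshold * max(abs(mean), 1e-12):
        return "steady"
    pk = _regular_peaks(t, x)
    if len(pk) < 5:
        return "steady"
    gaps = np.diff(t[pk])
    if np.std(gaps) / np.mean(gaps) > 0.05:
        return "steady"
    return "oscillatory"


def oscillation_metrics(
    times: np.ndarray,
    I_series: np.ndarray,
    transient_fraction: float = 0.5,
) -> tuple[float, float, float]:
    """(amplitude, period, frequency) of a sustained oscillation.

    Peaks and troughs are discrete local extrema refined to sub-grid
    accuracy by a quadratic fit through the three samples around each
    extremum; amplitude is (mean peak - mean trough)/2 and the period is
    the mean peak-to-peak spacing.
    """
    t, x = _post_transient(times, I_series, transient_fraction)
    pk = _regular_peaks(t, x)
    tr = _regular_peaks(t, -x)
    if len(pk) < 2 or len(tr) < 1:
        raise ValueError("oscillation_metrics requires an oscillatory series")
    t_pk, v_pk = _refine_extrema(t, x, pk)
    _, v_tr = _refine_extrema(t, x, tr)
    period = float(np.mean(np.diff(t_pk)))
    amplitude = float((np.mean(v_pk) - np.mean(v_tr)) / 2.0)
    return amplitude, period, 1.0 / period


def _refine_extrema(t, x, idx):
    """Quadratic sub-grid refinement of extremum locations and values."""
    idx = idx[(idx > 0) & (idx < len(x) - 1)]
    tt = np.empty(len(idx))
    vv = np.empty(len(idx))
    dt = t[1] - t[0]
    for k, i in enumerate(idx):
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        tt[k] = t[i] + delta * dt
        vv[k] = y1 - 0.25 * (y0 - y2) * delta
    return tt, vv


def basin_scan(
    p: CircuitParams,
    T: float,
    Gstar0_grid: np.ndarray,
    I0_grid: np.ndarray,
    t_end: float = 1500.0,
    h_step: float = 0.001,
) -> np.ndarray:
    """Attractor class per constant-history cell; shape (len(I0), len(G0)).

    Entries are 'steady' or 'oscillatory'.
    """
    out = np.empty((len(I0_grid), len(Gstar0_grid)), dtype=object)
    for j, i0 in enumerate(I0_grid):
        for i, g0 in enumerate(Gstar0_grid):
            cfg = DelayConfig(
                T=T, h_step=h_step, t_end=t_end, history=CircuitState(float(g0), float(i0))
            )
            out[j, i] = integrate_dde(p, cfg).attractor
    return out


def dde_oscillation_boundary_kd(
    p: CircuitParams,
    T: float,
    history: CircuitState,
    kd_lo: float,
    kd_hi: float,
    t_end: float = 40000.0,
    h_step: float = 0.001,
    abs_tol: float = 2e-6,
) -> float:
    """Bisect the kd boundary between oscillatory and steady DDE runs.

    The run at kd_lo must be oscillatory and the run at kd_hi steady.  The
    default horizon is long because close to a fold the escape from the
    saddle-node ghost is slow (the escape time diverges like the inverse
    square root of the parameter distance), and a run still in the
    bottleneck would be misread as steady; the attractor is judged on the
    final quarter of the run.
    """

    def is_osc(kd: float) -> bool:
        cfg = DelayConfig(
            T=T,
            h_step=h_step,
            t_end=t_end,
            history=history,
            transient_fraction=0.75,
            record_every=100,
        )
        return integrate_dde(p.replace(kd=kd), cfg).attractor == "oscillatory"

    lo, hi = kd_lo, kd_hi
    if not is_osc(lo):
        raise ValueError("kd_lo must be oscillatory")
    if is_osc(hi):
        raise ValueError("kd_hi must be steady")
    while (hi - lo) > abs_tol:
        mid = 0.5 * (lo + hi)
        if is_osc(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
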