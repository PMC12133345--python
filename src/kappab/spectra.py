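"""Stationary autocovariance and power spectra of protein-number fluctuations.

The spectrum is the Fourier transform of the stationary autocovariance
with kernel e^{-2πiωt} (Wiener-Khinchin with ω an ordinary frequency in
cycles/min, not angular).  SSA paths are piecewise constant, so they are
first resampled onto a uniform grid by zero-order hold; the autocovariance
uses the biased (1/n) lag-product estimator, which keeps the implied
spectrum positive semidefinite, averaged over an ensemble of
independently seeded trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParams
from .ssa import OUParams, Trajectory, spawn_seeds, ssa_colored, ssa_reduced

__all__ = [
    "SpectrumResult",
    "resample_uniform",
    "autocorrelation",
    "psd",
    "ensemble_psd",
]


@dataclass
class SpectrumResult:
    lags: np.ndarray      # time lags (min)
    autocov: np.ndarray   # <δz(t) δz(0)> (molecules^2)
    freqs: np.ndarray     # ordinary frequency (cycles / min)
    S: np.ndarray         # spectral density (molecules^2 · min)
    n_traj: int


def resample_uniform(traj: Trajectory, dt: float, burn_in: float = 0.0) -> np.ndarray:
    """Zero-order-hold sampling of a piecewise-constant SSA path.

    Grid points take the value of the most recent event at or before them.
    """
    t_stop = traj.t_end
    n = int(np.floor((t_stop - burn_in) / dt))
    if n < 1000:
        raise ValueError("trajectory span must cover at least 1000 samples")
    grid = burn_in + np.arange(n) * dt
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.times) - 1)
    return traj.I_series[idx].astype(float)


def autocorrelation(series_ensemble: list[np.ndarray], max_lag: int) -> np.ndarray:
    """Ensemble-averaged biased autocovariance at lags 0..max_lag.

    Each series is mean-subtracted individually; the per-series estimator
    is c_k = (1/n) Σ_t x_t x_{t+k}, computed by FFT.
    """
    if not series_ensemble:
        raise ValueError("empty ensemble")
    n_min = min(len(x) for x in series_ensemble)
    if max_lag > n_min // 10:
        raise ValueError("max_lag must not exceed a tenth of the series length")
    acc = np.zeros(max_lag + 1)
    for x in series_ensemble:
        x = np.asarray(x, dtype=float)
        x = x - x.mean()
        n = len(x)
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        X = np.fft.rfft(x, nfft)
        c = np.fft.irfft(X * np.conj(X), nfft)[: max_lag + 1] / n
        acc += c
    return acc / len(series_ensemble)


def psd(autocov: np.ndarray, dt: float) -> SpectrumResult:
    """One-sided spectrum: DFT of the evenly extended autocovariance."""
    m = len(autocov) - 1
    ext = np.concatenate([autocov, autocov[-2:0:-1]])  # even extension, length 2m
    S_full = np.real(np.fft.fft(ext)) * dt
    freqs = np.fft.fftfreq(len(ext), d=dt)
    keep = slice(0, m + 1)
    return SpectrumResult(
        lags=np.arange(m + 1) * dt,
        autocov=autocov,
        freqs=freqs[keep],
        S=S_full[keep],
        n_traj=1,
    )


def ensemble_psd(
    p: CircuitParams,
    ou: OUParams | None,
    n_traj: int,
    t_end: float,
    master_seed: int,
    dt: float = 1.0,
    max_lag: int | None = None,
    burn_in: float | None = None,
    i0: int = 0,
) -> SpectrumResult:
    """Full pipeline resample -> autocovariance -> spectrum over an ensemble.

    ``ou=None`` runs the intrinsic-only reduced scheme; otherwise the
    coloured scheme.  Seeds are spawned deterministically from the master.
    """
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    if burn_in is None:
        burn_in = 0.2 * t_end
    seeds = spawn_seeds(master_seed, n_traj)
    series = []
    for s in seeds:
        if ou is None or ou.D == 0.0:
            tr = ssa_reduced(p, t_end, int(s), i0=i0)
        else:
            tr = ssa_colored(p, ou, t_end, int(s), i0=i0)
        series.append(resample_uniform(tr, dt, burn_in=burn_in))
    n_min = min(len(x) for x in series)
    if max_lag is None:
        max_lag = n_min // 10
    ac = autocorrelation(series, max_lag)
    out = psd(ac, dt)
    out.n_traj = n_traj
    return out
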