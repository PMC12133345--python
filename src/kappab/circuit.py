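"""Core circuit model: parameters, Hill responses, vector fields and equilibria.

The circuit is a single-copy gene encoding the inhibitor protein IκBα,
switched on by the transcription factor NF-κB (level ``N``, held constant)
and switched off through IκBα binding.  State variables are the active-gene
fraction ``G*`` (the gene copy is either on or off, so deterministically
``G + G* = 1``) and the IκBα copy number ``I``:

    dG*/dt = k1 fA(N) (1 - G*) - k2 fR(I) G*
    dI/dt  = kP G* - kd I

with Hill responses fA(N) = N^nH1 / (Km1^nH1 + N^nH1) and
fR(I) = Km2^nH2 / (Km2^nH2 + I^nH2).  When gene switching is fast compared
with protein turnover the gene variable can be eliminated (quasi-steady-state
approximation), leaving a scalar equation for I whose production term
S+(I) = k1 kP fA / (k1 fA + k2 fR(I)) also drives the stochastic layers.

Time is measured in minutes and molecule numbers are continuous,
non-negative reals in this deterministic layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CircuitParams",
    "CircuitState",
    "EquilibriumPoint",
    "hill_activation",
    "hill_repression",
    "hill_repression_deriv",
    "rhs_full",
    "rhs_qssa",
    "rhs_qssa_deriv",
    "s_plus",
    "s_minus",
    "jacobian_full",
    "find_equilibria",
]

PARAM_NAMES = ("k1", "k2", "kP", "kd", "Km1", "Km2", "nH1", "nH2", "N")


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of the circuit; the single source of truth.

    k1 : gene-activation rate (min^-1)
    k2 : gene-deactivation rate (min^-1)
    kP : protein production rate per active gene (molecules min^-1)
    kd : protein degradation rate (min^-1)
    Km1, Km2 : half-saturation constants of NF-κB / IκBα binding (molecules)
    nH1, nH2 : Hill coefficients of NF-κB / IκBα binding
    N : NF-κB level (molecules), a constant input
    """

    k1: float = 1.0
    k2: float = 3.4
    kP: float = 0.065
    kd: float = 0.002
    Km1: float = 12.0
    Km2: float = 12.0
    nH1: float = 1.0
    nH2: float = 4.0
    N: float = 100.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:-1]:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.N < 0:
            raise ValueError("N must be non-negative")

    def replace(self, **kwargs: float) -> "CircuitParams":
        return replace(self, **kwargs)

    @property
    def I_ceiling(self) -> float:
        """Absolute ceiling of stationary protein number, kP/kd."""
        return self.kP / self.kd

    def fA(self) -> float:
        return hill_activation(self.N, self.Km1, self.nH1)

    def fR(self, I):
        return hill_repression(I, self.Km2, self.nH2)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CircuitState:
    """Active-gene fraction and IκBα copy number."""

    Gstar: float
    I: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.Gstar <= 1 + 1e-12):
            raise ValueError(f"Gstar={self.Gstar} outside [0, 1]")
        if self.I < -1e-12:
            raise ValueError(f"I={self.I} negative")


@dataclass(frozen=True)
class EquilibriumPoint:
    """A fixed point with its full-system eigenvalues and stability class."""

    state: CircuitState
    eigenvalues: tuple
    stability: str  # 'stable' | 'unstable' | 'saddle'

    @property
    def I(self) -> float:
        return self.state.I

    @property
    def Gstar(self) -> float:
        return self.state.Gstar


def hill_activation(N, Km1: float, nH1: float):
    """Activating Hill response fA(N) = N^n / (Km^n + N^n)."""
    if Km1 <= 0 or nH1 <= 0:
        raise ValueError("Km1 and nH1 must be strictly positive")
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be non-negative")
    x = (N / Km1) ** nH1
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def hill_repression(I, Km2: float, nH2: float):
    """Repressing Hill response fR(I) = Km^n / (Km^n + I^n)."""
    if Km2 <= 0 or nH2 <= 0:
        raise ValueError("Km2 and nH2 must be strictly positive")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("I must be non-negative")
    x = (I / Km2) ** nH2
    out = 1.0 / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def hill_repression_deriv(I, Km2: float, nH2: float):
    """d fR / dI, which is <= 0 everywhere."""
    I = np.asarray(I, dtype=float)
    x = (I / Km2) ** nH2
    with np.errstate(invalid="ignore"):
        out = np.where(I > 0, -nH2 * x / (I * (1.0 + x) ** 2), 0.0)
    # nH2 == 1 has a finite nonzero derivative at I = 0
    if nH2 == 1:
        out = np.where(I == 0, -1.0 / Km2, out)
    return float(out) if out.ndim == 0 else out


def rhs_full(state: CircuitState, p: CircuitParams) -> tuple:
    """Time derivatives (dG*/dt, dI/dt) of the two-variable system."""
    fa = p.fA()
    fr = p.fR(state.I)
    dG = p.k1 * fa * (1.0 - state.Gstar) - p.k2 * fr * state.Gstar
    dI = p.kP * state.Gstar - p.kd * state.I
    return dG, dI


def s_plus(I, p: CircuitParams):
    """QSSA production propensity S+(I) = k1 kP fA / (k1 fA + k2 fR(I))."""
    fa = p.fA()
    fr = p.fR(I)
    return p.k1 * p.kP * fa / (p.k1 * fa + p.k2 * fr)


def s_minus(I, p: CircuitParams):
    """Degradation propensity S-(I) = kd I."""
    return p.kd * np.asarray(I, dtype=float) if np.ndim(I) else p.kd * I


def rhs_qssa(I, p: CircuitParams):
    """dI/dt of the gene-eliminated (QSSA) dynamics, S+(I) - kd I."""
    fa = p.fA()
    if fa == 0.0:
        return -p.kd * np.asarray(I, dtype=float) if np.ndim(I) else -p.kd * I
    return s_plus(I, p) - p.kd * np.asarray(I, dtype=float)


def rhs_qssa_deriv(I, p: CircuitParams):
    """d/dI of the QSSA drift (analytic)."""
    fa = p.fA()
    if fa == 0.0:
        return -p.kd * np.ones_like(np.asarray(I, dtype=float))
    fr = p.fR(I)
    dfr = hill_repression_deriv(I, p.Km2, p.nH2)
    denom = p.k1 * fa + p.k2 * fr
    return -p.k1 * p.kP * fa * p.k2 * dfr / denom**2 - p.kd


def s_plus_deriv(I, p: CircuitParams):
    """d S+/dI (analytic); positive because fR decreases with I."""
    fa = p.fA()
    fr = p.fR(I)
    dfr = hill_repression_deriv(I, p.Km2, p.nH2)
    denom = p.k1 * fa + p.k2 * fr
    return -p.k1 * p.kP * fa * p.k2 * dfr / denom**2


def jacobian_full(state: CircuitState, p: CircuitParams) -> np.ndarray:
    """2x2 Jacobian of the full (non-delayed) system at a state."""
    fa = p.fA()
    fr = p.fR(state.I)
    dfr = hill_repression_deriv(state.I, p.Km2, p.nH2)
    return np.array(
        [
            [-(p.k1 * fa + p.k2 * fr), -p.k2 * dfr * state.Gstar],
            [p.kP, -p.kd],
        ]
    )


def _classify(eigvals: np.ndarray) -> str:
    re = np.real(eigvals)
    if np.all(np.abs(np.imag(eigvals)) < 1e-14) and re[0] * re[1] < 0:
        return "saddle"
    if np.all(re < 0):
        return "stable"
    return "unstable"


def find_equilibria(
    p: CircuitParams,
    I_max: float | None = None,
    n_grid: int = 4096,
) -> list[EquilibriumPoint]:
    """All equilibria on [0, I_max], sorted by increasing I.

    A bracketing scan over a uniform grid followed by Brent refinement; the
    fixed-point equation is scalar and smooth with at most three roots for
    this circuit, so a dense scan is robust against fold structure.  Each
    root is refined to |residual| < 1e-10 and carries the eigenvalues of the
    full-system Jacobian (G* = kd I / kP at equilibrium).
    """
    if I_max is None:
        I_max = 1.05 * p.I_ceiling
    grid = np.linspace(0.0, I_max, n_grid + 1)
    vals = rhs_qssa(grid, p)
    roots: list[float] = []
    for i in range(n_grid):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(
                brentq(lambda I: rhs_qssa(I, p), grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15)
            )
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    out = []
    for I in roots:
        if abs(rhs_qssa(I, p)) > 1e-10:
            continue
        G = p.kd * I / p.kP
        st = CircuitState(min(max(G, 0.0), 1.0), max(I, 0.0))
        ev = np.linalg.eigvals(jacobian_full(st, p))
        ev = tuple(sorted(ev, key=lambda z: (z.real, z.imag)))
        out.append(EquilibriumPoint(st, ev, _classify(np.asarray(ev))))
    out.sort(key=lambda e: e.I)
    return out


def equilibria_to_frame(eqs: Iterable[EquilibriumPoint]):
    """Equilibria as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = [
        {
            "Gstar": e.Gstar,
            "I": e.I,
            "re_lambda1": e.eigenvalues[0].real,
            "im_lambda1": e.eigenvalues[0].imag,
            "re_lambda2": e.eigenvalues[1].real,
            "im_lambda2": e.eigenvalues[1].imag,
            "stability": e.stability,
        }
        for e in eqs
    ]
    return pd.DataFrame(rows, columns=["Gstar", "I", "re_lambda1", "im_lambda1", "re_lambda2", "im_lambda2", "stability"])
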