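"""Closed-form stationary densities of the IκBα copy number.

White (intrinsic) noise: the chemical Fokker-Planck equation built from
the birth-death jump moments a1 = S+ + S- (diffusion) and a2 = S+ - S-
(drift) has the stationary solution

    P(I) ∝ (1 / a1) exp( 2 ∫ a2 / a1 dI ).

Coloured (extrinsic) noise on the degradation rate, kd -> kd (1 + ε) with
ε an Ornstein-Uhlenbeck process of strength D and correlation time τ, is
treated with the unified coloured noise approximation (UCNA): with drift
h = a2, coloured coupling g1 = -S-, intrinsic diffusion source g2 = a1 and
combined noise field g² = D g1² + g2 / 2, the adiabatic elimination of ε
gives the correction factor

    Z(I) = 1 + τ ( h g1' / g1 - h' )

and the stationary density

    P(I) ∝ (1 / g̃²) exp( ∫ (h̃ + g̃ g̃') / g̃² dI ),   h̃ = h/Z, g̃ = g/Z.

The ∫ g̃ g̃'/g̃² term is a logarithm, so the density is evaluated as
log P = -log g̃ + ∫ h Z / g² dI (identical analytically, better behaved
numerically); the exponent is accumulated by cumulative trapezoid and
shifted by its maximum before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.signal import find_peaks, peak_prominences

from .circuit import CircuitParams, s_plus, s_plus_deriv
from .ssa import OUParams

__all__ = [
    "DensityGrid",
    "UCNAFields",
    "sspd_white",
    "sspd_ucna",
    "find_modes",
    "pmax_contour",
]


@dataclass
class DensityGrid:
    """A normalized stationary density P(I) on a uniform grid."""

    I_grid: np.ndarray
    density: np.ndarray
    Q: float  # normalization constant applied to the unnormalized shape
    modes: list = field(default_factory=list)  # (I, P) maxima, P descending
    ucna_valid_fraction: float = 1.0
    warning: str | None = None

    def integral(self) -> float:
        return float(trapezoid(self.density, self.I_grid))

    @property
    def pmax(self) -> float:
        return self.modes[0][1] if self.modes else float(np.max(self.density))

    @property
    def mode_location(self) -> float:
        return self.modes[0][0] if self.modes else float(self.I_grid[np.argmax(self.density)])


@dataclass(frozen=True)
class UCNAFields:
    """The UCNA field functions evaluated on a grid."""

    I: np.ndarray
    h: np.ndarray      # drift a2 = S+ - S-
    g1: np.ndarray     # coloured coupling -S-
    g2: np.ndarray     # intrinsic diffusion source a1 = S+ + S-
    Z: np.ndarray      # UCNA correction factor
    g_sq: np.ndarray   # D g1^2 + g2/2


def _normalize(I, shape) -> tuple[np.ndarray, float]:
    total = trapezoid(shape, I)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate density: non-normalizable shape")
    return shape / total, 1.0 / total


def _attach_modes(dg: DensityGrid, prominence_fraction: float = 0.05) -> DensityGrid:
    dg.modes = find_modes(dg, prominence_fraction)
    return dg


def sspd_white(p: CircuitParams, I_max: float | None = None, n_grid: int = 4000) -> DensityGrid:
    """Stationary density of the intrinsic-noise (chemical FPE) model."""
    if p.fA() == 0.0:
        raise ValueError("N = 0 gives a1(0) = 0: the density degenerates at the origin")
    if n_grid < 1000:
        raise ValueError("n_grid must be >= 1000")
    if I_max is None:
        I_max = 1.5 * p.I_ceiling
    I = np.linspace(0.0, I_max, n_grid)
    sp = s_plus(I, p)
    sm = p.kd * I
    a1 = sp + sm
    a2 = sp - sm
    expo = 2.0 * cumulative_trapezoid(a2 / a1, I, initial=0.0)
    logP = expo - np.log(a1)
    logP -= np.max(logP)
    density, Q = _normalize(I, np.exp(logP))
    return _attach_modes(DensityGrid(I, density, Q))


def ucna_fields(p: CircuitParams, ou: OUParams, I: np.ndarray) -> UCNAFields:
    """Evaluate h, g1, g2, Z and g² on a grid (I > 0 required for Z)."""
    sp = s_plus(I, p)
    sm = p.kd * I
    h = sp - sm
    g1 = -sm
    g2 = sp + sm
    hp = s_plus_deriv(I, p) - p.kd  # h'
    # h g1'/g1 = h (-kd)/(-kd I) = h / I
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = 1.0 + ou.tau * (h / I - hp)
    g_sq = ou.D * g1**2 + g2 / 2.0
    return UCNAFields(I=I, h=h, g1=g1, g2=g2, Z=Z, g_sq=g_sq)


def sspd_ucna(
    p: CircuitParams,
    ou: OUParams,
    I_max: float | None = None,
    n_grid: int = 4000,
    force_Z1: bool = False,
) -> DensityGrid:
    """Stationary density under UCNA for OU-modulated degradation.

    Grid points with Z <= 0 (outside the UCNA validity region) are
    excluded; if they exceed 5% of the support the result carries a
    warning flag rather than failing.  ``force_Z1`` evaluates the same
    functional with Z ≡ 1 (the τ -> 0 reference).
    """
    if p.fA() == 0.0:
        raise ValueError("N = 0 gives a degenerate density at the origin")
    if n_grid < 1000:
        raise ValueError("n_grid must be >= 1000")
    if I_max is None:
        I_max = 1.5 * p.I_ceiling
    # open grid: Z(I) ~ tau*h(0)/I diverges at I = 0
    I = np.linspace(I_max / n_grid, I_max, n_grid)
    f = ucna_fields(p, ou, I)
    Z = np.ones_like(I) if force_Z1 else f.Z
    valid = Z > 0
    frac = float(np.mean(valid))
    warning = None
    if frac < 0.95:
        warning = f"UCNA validity: Z <= 0 on {100 * (1 - frac):.1f}% of the grid"
    Iv = I[valid]
    Zv = Z[valid]
    g_sq = f.g_sq[valid]
    h = f.h[valid]
    g_t = np.sqrt(g_sq) / Zv
    # log P = -log g̃ + ∫ h Z / g² dI  (the g̃ g̃' term integrates to log g̃)
    expo = cumulative_trapezoid(h * Zv / g_sq, Iv, initial=0.0)
    logP = expo - np.log(g_t)
    logP -= np.max(logP)
    density, Q = _normalize(Iv, np.exp(logP))
    return _attach_modes(
        DensityGrid(Iv, density, Q, ucna_valid_fraction=frac, warning=warning)
    )


def find_modes(dg: DensityGrid, prominence_fraction: float = 0.05) -> list:
    """Local density maxima with prominence >= fraction of the global max.

    Returns (I, P) pairs sorted by P descending; a maximum at the grid
    boundary counts as a mode.
    """
    y = dg.density
    pk, _ = find_peaks(y)
    if len(pk):
        prom = peak_prominences(y, pk)[0]
        pk = pk[prom >= prominence_fraction * np.max(y)]
    pk = list(pk)
    # boundary maxima are invisible to find_peaks
    if len(y) > 1 and y[0] > y[1] and y[0] >= prominence_fraction * np.max(y):
        pk.insert(0, 0)
    if len(y) > 1 and y[-1] > y[-2] and y[-1] >= prominence_fraction * np.max(y):
        pk.append(len(y) - 1)
    modes = [(float(dg.I_grid[i]), float(y[i])) for i in pk]
    modes.sort(key=lambda m: -m[1])
    return modes


def pmax_contour(
    p: CircuitParams,
    D_range: np.ndarray,
    tau_range: np.ndarray,
    n_grid: int = 2000,
):
    """Pmax and mode count of the UCNA density over a (D, τ) grid.

    Returns (Pmax, n_modes, flags) arrays of shape (len(tau), len(D));
    flags marks cells where the UCNA validity region was incomplete.
    """
    P = np.empty((len(tau_range), len(D_range)))
    M = np.empty_like(P, dtype=int)
    F = np.zeros_like(M)
    for j, tau in enumerate(tau_range):
        for i, D in enumerate(D_range):
            dg = sspd_ucna(p, OUParams(D=float(D), tau=float(tau)), n_grid=n_grid)
            P[j, i] = dg.pmax
            M[j, i] = len(dg.modes)
            F[j, i] = int(dg.warning is not None)
    return P, M, F
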