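"""Linear stability of the delayed circuit: Hopf boundaries in (kd, T).

With a delay T in gene activation (the NF-κB:IκBα complex releases free
NF-κB only after a lag), linearizing about an equilibrium (G*, I*) gives a
transcendental characteristic equation

    (λ + a + b e^{-λT})(λ + kd) - q kP = 0

with a = k2 fR(I*), b = k1 fA(N) and q = k2 |fR'(I*)| G* > 0.  Writing it
as P(λ) + Q(λ) e^{-λT} = 0 with P(λ) = (λ + a)(λ + kd) - q kP and
Q(λ) = b (λ + kd), purely imaginary roots λ = iω require
|P(iω)| = |Q(iω)|, a quadratic in ω², and each admissible ω carries a
ladder of critical delays T_mj = (θ(ω) + 2πj)/ω fixed by the phase of
e^{-iωT} = -P(iω)/Q(iω).  The smallest such delay, TH, is where the
equilibrium first loses stability through a Hopf bifurcation.

The sign of the q kP term is not taken on trust: ``linearize_delayed``
verifies that at T = 0 the characteristic roots reduce to the eigenvalues
of the non-delayed Jacobian.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .circuit import (
    CircuitParams,
    EquilibriumPoint,
    find_equilibria,
    hill_activation,
    hill_repression,
    hill_repression_deriv,
    rhs_full,
)

__all__ = [
    "DelayCharacteristic",
    "HopfBranchPoint",
    "BranchNotFoundError",
    "linearize_delayed",
    "select_branch",
    "hopf_boundary",
    "min_hopf_delay",
    "hopf_kd_at_T",
    "stability_map_kd_T",
]


class BranchNotFoundError(ValueError):
    """The requested equilibrium branch does not exist at these parameters."""


@dataclass(frozen=True)
class DelayCharacteristic:
    """Coefficients of the delay characteristic equation at an equilibrium.

    a : instantaneous gene-relaxation coefficient k2 fR(I*)  (min^-1)
    b : delayed coefficient k1 fA(N)                          (min^-1)
    q : protein-to-gene coupling k2 |fR'(I*)| G*              (min^-1)
    kd : protein degradation rate                             (min^-1)
    """

    a: float
    b: float
    q: float
    kd: float
    kP: float
    equilibrium: EquilibriumPoint

    def char(self, lam: complex, T: float) -> complex:
        """Value of (λ + a + b e^{-λT})(λ + kd) - q kP."""
        return (lam + self.a + self.b * cmath.exp(-lam * T)) * (lam + self.kd) - self.q * self.kP

    def roots_T0(self) -> np.ndarray:
        """Characteristic roots at T = 0 (quadratic; equals Jacobian spectrum)."""
        s = self.a + self.b + self.kd
        d = (self.a + self.b) * self.kd - self.q * self.kP
        return np.roots([1.0, s, d])


@dataclass(frozen=True)
class HopfBranchPoint:
    """One solution (ω, T_mj) of the characteristic equation on λ = iω."""

    omega: float  # Hopf frequency (rad min^-1)
    T_mj: float   # critical delay (min)
    j: int        # branch index


def linearize_delayed(p: CircuitParams, eq: EquilibriumPoint) -> DelayCharacteristic:
    """Characteristic-equation coefficients at an equilibrium of the circuit.

    Raises if ``eq`` is not an equilibrium (residual above 1e-10) or if the
    T = 0 roots fail to match the non-delayed Jacobian eigenvalues.
    """
    res = rhs_full(eq.state, p)
    if max(abs(res[0]), abs(res[1])) > 1e-10:
        raise ValueError(f"state {eq.state} is not an equilibrium (residual {res})")
    a = p.k2 * hill_repression(eq.I, p.Km2, p.nH2)
    b = p.k1 * hill_activation(p.N, p.Km1, p.nH1)
    q = p.k2 * abs(hill_repression_deriv(eq.I, p.Km2, p.nH2)) * eq.Gstar
    dc = DelayCharacteristic(a=a, b=b, q=q, kd=p.kd, kP=p.kP, equilibrium=eq)
    lam0 = np.sort_complex(dc.roots_T0())
    lam_jac = np.sort_complex(np.asarray(eq.eigenvalues))
    if not np.allclose(lam0, lam_jac, atol=1e-8):
        raise AssertionError(
            "T=0 characteristic roots disagree with the Jacobian eigenvalues; "
            "sign convention broken"
        )
    return dc


def select_branch(p: CircuitParams, branch: str) -> EquilibriumPoint:
    """Pick the upper or lower equilibrium branch.

    With three equilibria the largest-I and smallest-I roots are the upper
    and lower branch (the middle one is the saddle).  With a single
    equilibrium the branch label follows the active-gene fraction: the
    upper branch has G* > 1/2, the lower G* < 1/2.
    """
    if branch not in ("upper", "lower"):
        raise ValueError("branch must be 'upper' or 'lower'")
    eqs = find_equilibria(p)
    non_saddle = [e for e in eqs if e.stability != "saddle"] or eqs
    if len(non_saddle) >= 2:
        return non_saddle[-1] if branch == "upper" else non_saddle[0]
    e = non_saddle[0]
    label = "upper" if e.Gstar > 0.5 else "lower"
    if label != branch:
        raise BranchNotFoundError(
            f"the {branch} branch does not exist at these parameters "
            f"(single equilibrium with G*={e.Gstar:.3f})"
        )
    return e


def hopf_frequencies(dc: DelayCharacteristic) -> list[float]:
    """Positive ω with |P(iω)| = |Q(iω)| (candidate Hopf frequencies).

    |P|² - |Q|² is a quadratic in u = ω²; its positive roots are returned
    in decreasing order.
    """
    A = dc.a * dc.kd - dc.q * dc.kP
    B = (dc.a + dc.kd) ** 2 - 2.0 * A - dc.b**2
    C = A * A - dc.b**2 * dc.kd**2
    disc = B * B - 4.0 * C
    if disc < 0:
        return []
    out = []
    for u in ((-B + np.sqrt(disc)) / 2.0, (-B - np.sqrt(disc)) / 2.0):
        if u > 0:
            out.append(float(np.sqrt(u)))
    return sorted(set(out), reverse=True)


def hopf_boundary(dc: DelayCharacteristic, j_max: int = 10) -> list[HopfBranchPoint]:
    """All Hopf branch points T_mj for j = 0..j_max, sorted by T_mj.

    Empty when no positive-ω root exists (delay-independent stability),
    e.g. when the delayed coefficient b vanishes.
    """
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    if dc.b == 0.0:
        return []
    points = []
    for w in hopf_frequencies(dc):
        P = (1j * w + dc.a) * (1j * w + dc.kd) - dc.q * dc.kP
        Q = dc.b * (1j * w + dc.kd)
        ratio = -P / Q  # = e^{-i ω T} on the Hopf boundary
        theta = float(np.mod(-np.angle(ratio), 2.0 * np.pi))
        for j in range(j_max + 1):
            T = (theta + 2.0 * np.pi * j) / w
            points.append(HopfBranchPoint(omega=w, T_mj=T, j=j))
    points.sort(key=lambda h: h.T_mj)
    return points


def min_hopf_delay(p: CircuitParams, branch: str = "upper") -> float | None:
    """Minimal Hopf delay TH = min T_mj on the chosen branch, or None.

    None means the branch equilibrium is stable for every delay.
    """
    eq = select_branch(p, branch)
    dc = linearize_delayed(p, eq)
    pts = hopf_boundary(dc, j_max=0)
    if not pts:
        return None
    # only crossings that destabilize a branch stable at T=0 count; for this
    # circuit the smallest T_mj is the first stability loss
    return pts[0].T_mj


def _oscillatory_at(p: CircuitParams, kd: float, T: float, branch: str) -> bool:
    try:
        TH = min_hopf_delay(p.replace(kd=kd), branch)
    except BranchNotFoundError:
        return False
    return TH is not None and T >= TH


def hopf_kd_at_T(
    p: CircuitParams,
    T: float,
    branch: str = "upper",
    kd_lo: float = 5e-4,
    kd_hi: float = 5e-3,
    rel_tol: float = 1e-6,
) -> float:
    """The kd where the branch flips oscillatory -> stable at fixed delay T.

    Along the upper branch TH(kd) grows with kd and the branch itself ends
    at a fold; the oscillation boundary at fixed T is therefore either the
    TH(kd) = T crossing or the fold, whichever comes first.  Located by
    bisection on the oscillatory/stable classification.
    """
    lo, hi = kd_lo, kd_hi
    if not _oscillatory_at(p, lo, T, branch):
        raise ValueError("kd_lo must lie in the oscillatory zone")
    if _oscillatory_at(p, hi, T, branch):
        raise ValueError("kd_hi must lie in the stable zone")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _oscillatory_at(p, mid, T, branch):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stability_map_kd_T(
    p: CircuitParams,
    branch: str,
    kd_range: tuple[float, float],
    T_range: tuple[float, float],
    resolution: int = 100,
):
    """Classify a (kd, T) grid as 'stable' / 'oscillatory' / 'missing'.

    Returns (kd_grid, T_grid, labels) with labels of shape (len(T), len(kd)).
    Cells where the branch does not exist are 'missing', not errors.
    """
    kd_grid = np.linspace(*kd_range, resolution)
    T_grid = np.linspace(*T_range, resolution)
    labels = np.full((resolution, resolution), "stable", dtype=object)
    for i, kd in enumerate(kd_grid):
        try:
            TH = min_hopf_delay(p.replace(kd=float(kd)), branch)
        except BranchNotFoundError:
            labels[:, i] = "missing"
            continue
        if TH is None:
            continue
        labels[T_grid >= TH, i] = "oscillatory"
    return kd_grid, T_grid, labels


def hopf_curve_kd(
    p: CircuitParams,
    branch: str,
    kd_range: tuple[float, float],
    n: int = 100,
):
    """TH(kd) along a branch; NaN where the branch or the Hopf is absent."""
    kd_grid = np.linspace(*kd_range, n)
    TH = np.full(n, np.nan)
    for i, kd in enumerate(kd_grid):
        try:
            v = min_hopf_delay(p.replace(kd=float(kd)), branch)
        except BranchNotFoundError:
            continue
        if v is not None:
            TH[i] = v
    return kd_grid, TH
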