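"""Equilibrium continuation: saddle-node folds, two-parameter loci, cusps.

Because the fixed-point problem is scalar in I, continuation is done by
dense per-parameter root enumeration with nearest-neighbour branch
stitching rather than pseudo-arclength: full enumeration is cheap and
immune to fold turning-point failures.  Folds are refined by bisection on
the change of root count; two-parameter saddle-node loci are traced by
bisection in the second parameter per column and polished with a Newton
solve of (f, df/dI) = (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .circuit import (
    CircuitParams,
    find_equilibria,
    rhs_qssa,
    rhs_qssa_deriv,
)

__all__ = [
    "BifurcationBranch",
    "TwoParamMap",
    "scan_branch_1d",
    "saddle_node_locus",
    "count_stable_states",
]


@dataclass
class BifurcationBranch:
    """One-parameter diagram: equilibria and fold (saddle-node) points."""

    parameter_name: str
    points: list  # (parameter value, I, stability), ordered by parameter
    sn_points: list  # (parameter value, I) at folds


@dataclass
class TwoParamMap:
    """Saddle-node locus in a parameter plane, with detected cusp points."""

    x_name: str
    y_name: str
    sn_curves: list = field(default_factory=list)  # list of (n, 2) arrays
    cusp_points: list = field(default_factory=list)  # (x, y) pairs
    sn_points: list = field(default_factory=list)  # (x, y, I) fold triples


def _check_param(name: str) -> None:
    from .circuit import PARAM_NAMES

    if name not in PARAM_NAMES:
        raise ValueError(f"{name!r} is not a circuit parameter; choose from {PARAM_NAMES}")


def _roots(p: CircuitParams) -> list[float]:
    return [e.I for e in find_equilibria(p)]


def count_stable_states(p: CircuitParams) -> int:
    """Number of stable equilibria (1 in monostable, 2 in bistable zones)."""
    return sum(1 for e in find_equilibria(p) if e.stability == "stable")


def _bisect_fold(p: CircuitParams, name: str, lo: float, hi: float, n_lo: int, rel_tol: float = 1e-6):
    """Refine a parameter value where the equilibrium count changes."""
    while (hi - lo) > rel_tol * max(abs(hi), abs(lo), 1e-300):
        mid = 0.5 * (lo + hi)
        if len(_roots(p.replace(**{name: mid}))) == n_lo:
            lo = mid
        else:
            hi = mid
    # fold protein level: the pair of roots closest together on the 3-root side
    side = lo if len(_roots(p.replace(**{name: lo}))) >= 3 else hi
    rs = _roots(p.replace(**{name: side}))
    if len(rs) >= 2:
        gaps = np.diff(rs)
        i = int(np.argmin(gaps))
        I_fold = 0.5 * (rs[i] + rs[i + 1])
    else:
        I_fold = rs[0]
    return 0.5 * (lo + hi), I_fold


def scan_branch_1d(
    p: CircuitParams,
    parameter_name: str,
    lo: float,
    hi: float,
    n_steps: int = 200,
) -> BifurcationBranch:
    """One-parameter bifurcation diagram by dense equilibrium enumeration."""
    _check_param(parameter_name)
    if not lo < hi:
        raise ValueError("need lo < hi")
    if n_steps < 50:
        raise ValueError("n_steps must be >= 50")
    values = np.linspace(lo, hi, n_steps + 1)
    # N = 0 is legal for scans over N; other parameters must stay positive
    if parameter_name != "N":
        values = values[values > 0]

    points = []
    counts = []
    for v in values:
        eqs = find_equilibria(p.replace(**{parameter_name: float(v)}))
        counts.append(len(eqs))
        for e in eqs:
            points.append((float(v), e.I, e.stability))

    sn_points = []
    for i in range(len(values) - 1):
        if counts[i] != counts[i + 1]:
            n_folds = abs(counts[i] - counts[i + 1]) // 2
            v_fold, I_fold = _bisect_fold(
                p, parameter_name, float(values[i]), float(values[i + 1]), counts[i]
            )
            for _ in range(max(n_folds, 1)):
                sn_points.append((v_fold, I_fold))
    return BifurcationBranch(parameter_name, points, sn_points)


def _sn_condition(p: CircuitParams, y_name: str):
    def fun(z):
        I, y = z
        q = p.replace(**{y_name: float(max(y, 1e-12))})
        return [rhs_qssa(float(max(I, 0.0)), q), rhs_qssa_deriv(float(max(I, 0.0)), q)]

    return fun


def _sn_y_values(p: CircuitParams, y_name: str, y_grid: np.ndarray) -> list[tuple[float, float]]:
    """(y, I) saddle-node points along one column, by root-count bisection."""
    counts = [len(_roots(p.replace(**{y_name: float(y)}))) for y in y_grid]
    out = []
    for i in range(len(y_grid) - 1):
        if counts[i] != counts[i + 1]:
            y_fold, I_fold = _bisect_fold(
                p, y_name, float(y_grid[i]), float(y_grid[i + 1]), counts[i], rel_tol=1e-9
            )
            # Newton polish on (f, f') = (0, 0)
            sol, info, ier, _ = fsolve(
                _sn_condition(p, y_name), [I_fold, y_fold], full_output=True, xtol=1e-13
            )
            if ier == 1:
                I_fold, y_fold = float(sol[0]), float(sol[1])
            out.append((y_fold, I_fold))
    out.sort()
    return out


def saddle_node_locus(
    p: CircuitParams,
    x_name: str,
    y_name: str,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    resolution: int = 60,
) -> TwoParamMap:
    """Saddle-node curves in the (x, y) plane and their cusp meeting points.

    For each x-column the fold y-values are located by bisection on the
    equilibrium count and polished on (f, df/dI) = (0, 0).  A cusp is
    reported where the pair of fold branches merges: the column-to-column
    gap between paired folds shrinks below grid tolerance, refined by
    bisection on the existence of a fold pair.
    """
    _check_param(x_name)
    _check_param(y_name)
    if resolution < 50:
        raise ValueError("resolution must be >= 50 per axis")
    x_grid = np.linspace(*x_range, resolution)
    if x_name != "N":
        x_grid = x_grid[x_grid > 0]
    y_grid = np.linspace(*y_range, resolution)
    if y_name != "N":
        y_grid = y_grid[y_grid > 0]

    columns: list[list[tuple[float, float]]] = []
    for x in x_grid:
        px = p.replace(**{x_name: float(x)})
        columns.append(_sn_y_values(px, y_name, y_grid))

    # assemble curves: k-th fold (ordered by y) per column joins branch k
    n_branch = max((len(c) for c in columns), default=0)
    curves = []
    triples = []
    for k in range(n_branch):
        pts = [(float(x_grid[i]), c[k][0]) for i, c in enumerate(columns) if len(c) > k]
        if pts:
            curves.append(np.asarray(pts))
    for i, c in enumerate(columns):
        for y, I in c:
            triples.append((float(x_grid[i]), y, I))

    # cusp: adjacent columns where a fold pair appears/disappears
    cusps = []
    pair_count = [len(c) // 2 for c in columns]
    for i in range(len(x_grid) - 1):
        if (len(columns[i]) >= 2) != (len(columns[i + 1]) >= 2):
            lo, hi = float(x_grid[i]), float(x_grid[i + 1])
            has_lo = len(columns[i]) >= 2
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                folds = _sn_y_values(p.replace(**{x_name: mid}), y_name, y_grid)
                if (len(folds) >= 2) == has_lo:
                    lo = mid
                else:
                    hi = mid
            side = lo if has_lo else hi
            folds = _sn_y_values(p.replace(**{x_name: side}), y_name, y_grid)
            if len(folds) >= 2:
                ys = [f[0] for f in folds]
                gaps = np.diff(ys)
                j = int(np.argmin(gaps))
                cusps.append((0.5 * (lo + hi), 0.5 * (ys[j] + ys[j + 1])))
    _ = pair_count
    return TwoParamMap(x_name, y_name, curves, cusps, triples)


def branch_to_frame(branch: BifurcationBranch):
    import pandas as pd

    return pd.DataFrame(branch.points, columns=[branch.parameter_name, "I", "stability"])


def locus_to_frame(m: TwoParamMap):
    import pandas as pd

    rows = []
    for bid, curve in enumerate(m.sn_curves):
        for x, y in curve:
            rows.append({m.x_name: x, m.y_name: y, "branch_id": bid})
    return pd.DataFrame(rows, columns=[m.x_name, m.y_name, "branch_id"])
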