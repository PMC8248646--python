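"""Deterministic slow-fast dynamics: ODE integration, equilibrium surfaces
over parameter planes, and Monte-Carlo basin-of-attraction estimates.

The mean-field limit is the singularly perturbed system

    dx/dtau   = B_x - D_x
    eps*dq_A/dtau = B_A - D_A
    eps*dq_I/dtau = B_I - D_I

whose equilibria are the roots of S'(x) = log(<B_x>/<D_x>) with the marks at
quasi-steady state.  ``estimate_Poff`` measures the relative size of the
basin of attraction of the low-expression (OFF) equilibrium by integrating
from initial conditions sampled uniformly in the (x, q_A) plane, with q_I
started at its QSS value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .landscape import compute_landscape, refine_sprime_roots
from .model import (
    ModelParams,
    StateVars,
    _rates_A_arrays,
    _rates_I_arrays,
    _rates_tf_arrays,
    default_x_grid,
    mark_root_sets,
    qss_marks,
)

__all__ = [
    "Equilibrium",
    "BasinEstimate",
    "EquilibriumSheet",
    "equilibria",
    "off_state",
    "integrate_meanfield",
    "equilibrium_sheet",
    "estimate_Poff",
]


@dataclass(frozen=True)
class Equilibrium:
    x: float
    q_A: float
    q_I: float
    stable: bool


def _rhs(t, y, params: ModelParams, eps: float):
    x, qA, qI = y
    x = max(x, 0.0)
    qA = min(max(qA, 0.0), params.rho_A)
    qI = min(max(qI, 0.0), params.rho_I)
    Bx, Dx = _rates_tf_arrays(x, qA, qI, params)
    BA, DA = _rates_A_arrays(x, qA, params)
    BI, DI = _rates_I_arrays(x, qI, params)
    return [float(Bx - Dx), float(BA - DA) / eps, float(BI - DI) / eps]


def equilibria(params: ModelParams, x_grid: np.ndarray | None = None,
               refine: bool = True) -> list[Equilibrium]:
    """Mean-field equilibria (x*, q_A*(x*), q_I*(x*)) with stability tags.

    Roots of S' with S' crossing + to - are stable (the drift B_x - D_x
    changes sign downwards).
    """
    if x_grid is None:
        x_grid = default_x_grid(params)
    qss = qss_marks(params, x_grid)
    B, D = _rates_tf_arrays(x_grid, qss.qA_star, qss.qI_star, params)
    sp = np.log(B / D)
    s = np.sign(sp)
    s[s == 0] = 1
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    roots = []
    for i in idx:
        w = sp[i] / (sp[i] - sp[i + 1])
        roots.append((float(x_grid[i] + w * (x_grid[i + 1] - x_grid[i])), sp[i] > 0))
    if refine and roots:
        xs = refine_sprime_roots(params, np.array([r for r, _ in roots]))
        roots = [(float(x), st) for x, (_, st) in zip(xs, roots)]
    out = []
    for x, stable in roots:
        qA, qI = mark_root_sets(params, x)
        out.append(Equilibrium(x=x, q_A=float(qA[0]), q_I=float(qI[0]), stable=stable))
    return out


def off_state(params: ModelParams) -> StateVars:
    """The stable equilibrium with the lowest x (OFF), as a state point."""
    eqs = [e for e in equilibria(params) if e.stable]
    if not eqs:
        raise RuntimeError("no stable mean-field equilibrium found on the grid")
    e = min(eqs, key=lambda e: e.x)
    return StateVars(x=e.x, q_A=e.q_A, q_I=e.q_I)


def integrate_meanfield(params: ModelParams, init: StateVars, eps: float = 0.1,
                        t_max: float = 200.0, rtol: float = 1e-8, atol: float = 1e-10,
                        eqs: list[Equilibrium] | None = None, delta: float = 1e-3):
    """Integrate the slow-fast ODEs and classify the terminal state.

    Returns (solution, outcome) with outcome in {"ON", "OFF", "undecided"}.
    ON/OFF is decided by comparing the terminal x with the unstable
    (separatrix) root when the system is bistable, else by the nearest
    equilibrium; terminal points within ``delta`` of the unstable root are
    "undecided".
    """
    if not eps > 0:
        raise ValueError("eps must be > 0")
    init.validate(params)
    sol = solve_ivp(_rhs, (0.0, t_max), [init.x, init.q_A, init.q_I],
                    args=(params, eps), method="LSODA", rtol=rtol, atol=atol)
    if eqs is None:
        eqs = equilibria(params)
    xT = float(sol.y[0, -1])
    stable = sorted([e.x for e in eqs if e.stable])
    unstable = [e.x for e in eqs if not e.stable]
    if not stable:
        return sol, "undecided"
    if unstable:
        xs = unstable[0]
        if abs(xT - xs) <= delta:
            return sol, "undecided"
        return sol, ("OFF" if xT < xs else "ON")
    # monostable: require actual convergence to the single attractor
    if abs(xT - stable[0]) > 100 * delta * max(1.0, stable[0]):
        return sol, "undecided"
    return sol, ("OFF" if stable[0] < np.sqrt(1 + params.C1) / params.C2 else "ON")


@dataclass
class EquilibriumSheet:
    """Equilibrium x values with stability on a 2-parameter grid."""

    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    equilibria: list            # [i][j] -> list of (x, stable)
    bistable: np.ndarray        # bool, shape (len(grid_x), len(grid_y))

    def to_frame(self):
        """Long-format table: one row per (node, equilibrium)."""
        import pandas as pd
        rows = []
        for i, vx in enumerate(self.grid_x):
            for j, vy in enumerate(self.grid_y):
                for x_eq, stable in self.equilibria[i][j]:
                    rows.append({self.param_x: vx, self.param_y: vy,
                                 "x_eq": x_eq, "stable": stable,
                                 "bistable": bool(self.bistable[i, j])})
        return pd.DataFrame(rows)


def _set_param(params: ModelParams, name: str, value: float) -> ModelParams:
    from .model import THETA_KEYS
    if name in THETA_KEYS:
        return params.with_theta(**{name: value})
    if hasattr(params, name) and name not in ("theta",):
        return params.with_constants(**{name: value})
    raise ValueError(f"unknown parameter {name!r}")


def equilibrium_sheet(params: ModelParams, param_x: str, param_y: str,
                      ranges, resolution: int = 25, n_grid: int = 200) -> EquilibriumSheet:
    """Scan a 2-parameter plane for the mean-field equilibrium structure.

    At each node the roots of S' are counted; three roots (two stable, one
    unstable) flag bistability.  The bistable region's boundary approximates
    the saddle-node curves.
    """
    (lo_x, hi_x), (lo_y, hi_y) = ranges
    gx = np.linspace(lo_x, hi_x, resolution)
    gy = np.linspace(lo_y, hi_y, resolution)
    eq_table = []
    bist = np.zeros((resolution, resolution), dtype=bool)
    for i, vx in enumerate(gx):
        row = []
        for j, vy in enumerate(gy):
            p = _set_param(_set_param(params, param_x, float(vx)), param_y, float(vy))
            eqs = equilibria(p, x_grid=default_x_grid(p, n=n_grid), refine=False)
            row.append([(e.x, e.stable) for e in eqs])
            n_stable = sum(e.stable for e in eqs)
            bist[i, j] = len(eqs) == 3 and n_stable == 2
        eq_table.append(row)
    return EquilibriumSheet(param_x=param_x, param_y=param_y, grid_x=gx,
                            grid_y=gy, equilibria=eq_table, bistable=bist)


@dataclass(frozen=True)
class BasinEstimate:
    """Monte-Carlo estimate of the relative OFF-basin size (P_off + P_on = 1)."""

    P_off: float
    P_on: float
    n_samples: int
    ci_halfwidth: float
    n_undecided: int = 0


def estimate_Poff(params: ModelParams, eps: float = 0.1, n_samples: int = 1000,
                  seed: int = 0, sampling_domain=None, t_max: float = 150.0,
                  rtol: float = 1e-5, atol: float = 1e-8,
                  max_undecided_frac: float = 0.05) -> BasinEstimate:
    """Monte-Carlo relative size of the OFF basin of attraction.

    Initial (x, q_A) pairs are uniform on the sampling domain (default
    x in [0, 1.2*x_ON], q_A in [0, rho_A]); q_I starts at its QSS value
    q_I*(x0).  Trivially returns P_off in {0, 1} for monostable parameters.
    """
    rng = np.random.default_rng(seed)
    eqs = equilibria(params)
    stable = sorted([e.x for e in eqs if e.stable])
    if not stable:
        raise RuntimeError("no stable equilibrium; cannot define basins")
    if len(stable) == 1:
        p_off = 1.0 if stable[0] < np.sqrt(1 + params.C1) / params.C2 else 0.0
        return BasinEstimate(P_off=p_off, P_on=1.0 - p_off, n_samples=n_samples,
                             ci_halfwidth=0.0)
    x_on = stable[-1]
    if sampling_domain is None:
        sampling_domain = ((0.0, 1.2 * x_on), (0.0, params.rho_A))
    (xlo, xhi), (alo, ahi) = sampling_domain
    n_off = n_on = n_und = 0
    for _ in range(n_samples):
        x0 = rng.uniform(xlo, xhi)
        qA0 = rng.uniform(alo, ahi)
        _, qI_roots = mark_root_sets(params, x0)
        init = StateVars(x=x0, q_A=qA0, q_I=float(qI_roots[0]))
        _, outcome = integrate_meanfield(params, init, eps=eps, t_max=t_max,
                                         rtol=rtol, atol=atol, eqs=eqs)
        if outcome == "OFF":
            n_off += 1
        elif outcome == "ON":
            n_on += 1
        else:
            n_und += 1
    if n_und > max_undecided_frac * n_samples:
        raise RuntimeError(
            f"{n_und}/{n_samples} undecided outcomes; increase t_max")
    n_eff = n_off + n_on
    p = n_off / n_eff
    ci = 1.959964 * np.sqrt(p * (1 - p) / n_eff)
    return BasinEstimate(P_off=p, P_on=1.0 - p, n_samples=n_samples,
                         ci_halfwidth=float(ci), n_undecided=n_und)
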