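"""Epigenetic (Waddington) landscape of the reduced switch.

From the WKB treatment of the slow TF variable, the stationary density is

    phi_x(x) = N_x * exp(-Omega_T * U(x, Omega_T)),
    U = -S + [log<B_x> + log<D_x>] / (2*Omega_T),
    S = int_0^x log(<B_x>/<D_x>) ds,

with <B_x>, <D_x> the TF rates evaluated at the quasi-steady-state mark
curves.  Zeros of S' are the mean-field equilibria; zeros of U' are the modes
of phi_x at finite system size.  A parameter set is classified by the two
root counts:

    BISTABLE       S' and U' both have 3 positive roots
    NOISE_INDUCED  U' has 3 roots but S' only 1 (bimodality exists only at
                   finite Omega_T)
    HIGH_GE/LOW_GE both counts 1, split by the modal point against x_THR

Barriers dU0 (from the low-expression well) and dU1 (from the high well) are
potential differences between the saddle and each minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .model import (
    ModelParams,
    QSSCurves,
    _rates_A_arrays,
    _rates_I_arrays,
    _rates_tf_arrays,
    default_x_grid,
    mark_root_sets,
    qss_marks,
)

__all__ = [
    "Landscape",
    "action_S",
    "potential_U",
    "stationary_pdf",
    "wkb_mark_pdf",
    "find_critical_points",
    "classify_theta",
    "compute_landscape",
    "sprime_at",
    "refine_sprime_roots",
]

CLASS_LABELS = ("LOW_GE", "HIGH_GE", "BISTABLE", "NOISE_INDUCED", "UNCLASSIFIED")


@dataclass
class Landscape:
    """Landscape functions and their critical-point summary for one theta."""

    x_grid: np.ndarray
    S: np.ndarray
    U: np.ndarray
    phi_x: np.ndarray
    roots_Sprime: np.ndarray
    roots_Uprime: np.ndarray
    modes: np.ndarray              # minima of U (maxima of phi_x)
    dU0: float | None
    dU1: float | None
    class_label: str
    Omega_T: int
    qss: QSSCurves | None = None

    @property
    def x_star(self) -> float:
        """Dominant mode (global minimum of U among the detected modes)."""
        if len(self.modes) == 0:
            raise ValueError("no modes detected")
        Uspl = CubicSpline(self.x_grid, self.U)
        return float(self.modes[np.argmin(Uspl(self.modes))])


def _mean_rates(params: ModelParams, qss: QSSCurves):
    """<B_x>(x), <D_x>(x): TF rates at the QSS mark curves."""
    return _rates_tf_arrays(qss.x_grid, qss.qA_star, qss.qI_star, params)


def action_S(params: ModelParams, qss: QSSCurves) -> np.ndarray:
    """Action S(x) = int_0^x log(<B_x>/<D_x>) ds on the QSS grid.

    The integrand diverges like -log(c*s) for s -> 0 (integrable); the piece
    on [0, x_min] is added analytically using that local form, the rest by
    cumulative trapezoid.
    """
    x = qss.x_grid
    B, D = _mean_rates(params, qss)
    if np.any(D <= 0):
        raise FloatingPointError("<D_x> vanished on the grid; start the grid at x > 0")
    integrand = np.log(B / D)
    if not np.all(np.isfinite(integrand)):
        raise FloatingPointError("log(<B_x>/<D_x>) not finite on the grid")
    # head: integrand ~ -log(c s) with c matched at x_min =>
    # int_0^xmin = x_min * (1 + log(B/D)(x_min))
    head = x[0] * (1.0 + integrand[0])
    return head + cumulative_trapezoid(integrand, x, initial=0.0)


def potential_U(params: ModelParams, qss: QSSCurves, Omega_T: int | None = None) -> np.ndarray:
    """Effective potential U = -S + [log<B_x> + log<D_x>]/(2*Omega_T)."""
    Omega_T = int(Omega_T if Omega_T is not None else params.Omega_T)
    if Omega_T <= 0:
        raise ValueError("Omega_T must be a positive integer")
    S = action_S(params, qss)
    B, D = _mean_rates(params, qss)
    return -S + (np.log(B) + np.log(D)) / (2.0 * Omega_T)


def stationary_pdf(U: np.ndarray, Omega_T: int, x_grid: np.ndarray) -> np.ndarray:
    """phi_x proportional to exp(-Omega_T U), unit trapezoidal integral."""
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("U must be finite on the grid")
    w = np.exp(-Omega_T * (U - U.min()))
    Z = trapezoid(w, x_grid)
    if Z <= 0 or not np.isfinite(Z):
        raise ValueError("density vanished after exponentiation; grid does not cover support")
    return w / Z


def wkb_mark_pdf(params: ModelParams, x: float, residue: str, Omega_S: int | None = None,
                 n_grid: int = 800):
    """WKB conditional density of one mark variable at frozen TF level x.

    phi_J(p|x) ~ exp(-Omega_S * int_0^p log(D_J/B_J) ds) / sqrt(B_J D_J),
    J in {A, I}.  Returns (p_grid, density) with unit trapezoidal integral.
    The mode sits at the QSS root where B_J = D_J.
    """
    Omega_S = int(Omega_S if Omega_S is not None else params.Omega_S)
    if residue == "A":
        hi = params.rho_A
        rates = lambda q: _rates_A_arrays(x, q, params)
    elif residue == "I":
        hi = params.rho_I
        rates = lambda q: _rates_I_arrays(x, q, params)
    else:
        raise ValueError("residue must be 'A' or 'I'")
    # stay off the absorbing endpoints where B or D vanish
    p = np.linspace(hi * 1e-4, hi * (1 - 1e-4), n_grid)
    B, D = rates(p)
    if np.any(B <= 0) or np.any(D <= 0):
        raise FloatingPointError("B_J or D_J vanished inside the mark domain")
    expo = cumulative_trapezoid(np.log(D / B), p, initial=0.0)
    logphi = -Omega_S * expo - 0.5 * (np.log(B) + np.log(D))
    w = np.exp(logphi - logphi.max())
    Z = trapezoid(w, p)
    if Z <= 0:
        raise ValueError("mark density vanished after exponentiation")
    return p, w / Z


def find_critical_points(f_prime_grid: np.ndarray, x_grid: np.ndarray):
    """Roots of a gridded derivative, with min/max stability tags.

    Sign-change brackets are refined with brentq on a cubic-spline
    interpolant.  Returns (roots, tags) with tags 'min' (f' crosses - to +
    going... here f' crossing + to - means a local max of f).  More than 5
    roots signals grid artefacts (the model admits at most 3) and raises.
    """
    f = np.asarray(f_prime_grid, dtype=float)
    x = np.asarray(x_grid, dtype=float)
    s = np.sign(f)
    s[s == 0] = 1
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if len(idx) > 5:
        raise RuntimeError(f"{len(idx)} sign changes of the derivative: grid artefacts "
                           "(the model admits at most 3 critical points)")
    spl = CubicSpline(x, f)
    roots, tags = [], []
    for i in idx:
        r = brentq(spl, x[i], x[i + 1], xtol=1e-12, rtol=1e-12)
        roots.append(float(r))
        tags.append("max" if f[i] > 0 else "min")
    return np.array(roots), tags


def phi_mode_visibility(landscape: "Landscape") -> float:
    """Prominence of the second-highest mode of phi_x, relative to its max.

    0 when phi_x is unimodal on the grid; used to rank how observable a
    (noise-induced) bimodality would be in simulation.
    """
    from scipy.signal import find_peaks
    phi = landscape.phi_x
    if phi.max() <= 0:
        return 0.0
    padded = np.concatenate([[0.0], phi, [0.0]])
    _, props = find_peaks(padded, prominence=0.0)
    pr = np.sort(props["prominences"])[::-1]
    if len(pr) < 2:
        return 0.0
    return float(pr[1] / phi.max())


def sprime_at(params: ModelParams, x: float) -> float:
    """S'(x) = log(<B_x>/<D_x>) with marks solved at QSS (scalar, accurate)."""
    qA_roots, qI_roots = mark_root_sets(params, x)
    B, D = _rates_tf_arrays(x, qA_roots[0], qI_roots[0], params)
    return float(np.log(B / D))


def refine_sprime_roots(params: ModelParams, roots: np.ndarray, rel_bracket: float = 0.02):
    """Polish gridded S' roots with scalar brentq on the exact S' (1e-12)."""
    out = []
    for r in roots:
        a, b = r * (1 - rel_bracket), r * (1 + rel_bracket)
        fa, fb = sprime_at(params, a), sprime_at(params, b)
        k = 0
        while fa * fb > 0 and k < 6:
            a *= 1 - rel_bracket
            b *= 1 + rel_bracket
            fa, fb = sprime_at(params, a), sprime_at(params, b)
            k += 1
        if fa * fb > 0:
            out.append(float(r))
            continue
        out.append(float(brentq(lambda xx: sprime_at(params, xx), a, b,
                                xtol=1e-12, rtol=1e-14)))
    return np.array(out)


def compute_landscape(params: ModelParams, Omega_T: int | None = None,
                      x_grid: np.ndarray | None = None, x_THR: float | None = None,
                      qss: QSSCurves | None = None, refine: bool = False) -> Landscape:
    """Full landscape pipeline: QSS -> S, U, phi_x -> critical points -> label.

    ``x_THR`` splits monostable parameter sets into HIGH_GE/LOW_GE; if None,
    a geometric-mean split of the two deterministic well positions
    sqrt(1+C1)/C2 is used (the ensemble module recomputes a data-driven
    threshold from the modal distribution).
    """
    Omega_T = int(Omega_T if Omega_T is not None else params.Omega_T)
    if x_grid is None:
        x_grid = default_x_grid(params)
    if qss is None:
        qss = qss_marks(params, x_grid)
    if x_THR is None:
        x_THR = np.sqrt(1.0 + params.C1) / params.C2

    x = qss.x_grid
    B, D = _mean_rates(params, qss)
    Sp = np.log(B / D)                       # S' is known analytically
    S = action_S(params, qss)
    U = -S + (np.log(B) + np.log(D)) / (2.0 * Omega_T)
    Up = -Sp + np.gradient(np.log(B) + np.log(D), x) / (2.0 * Omega_T)
    phi = stationary_pdf(U, Omega_T, x)

    roots_S, tags_S = find_critical_points(Sp, x)
    roots_U, tags_U = find_critical_points(Up, x)
    if refine and len(roots_S):
        roots_S = refine_sprime_roots(params, roots_S)

    modes = np.array([r for r, t in zip(roots_U, tags_U) if t == "min"])

    nS, nU = len(roots_S), len(roots_U)
    dU0 = dU1 = None
    Uspl = CubicSpline(x, U)
    if nU == 3 and tags_U == ["min", "max", "min"]:
        saddle = roots_U[1]
        dU0 = float(Uspl(saddle) - Uspl(roots_U[0]))
        dU1 = float(Uspl(saddle) - Uspl(roots_U[2]))

    if nS == 3 and nU == 3 and tags_U == ["min", "max", "min"]:
        label = "BISTABLE"
    elif nS == 1 and nU == 3 and tags_U == ["min", "max", "min"]:
        label = "NOISE_INDUCED"
    elif nU == 1 and tags_U == ["min"] and nS in (1, 3):
        # nS == 3 with a single phi_x mode is mean-field bistability erased
        # by finite-size fluctuations; phenotypically monostable
        label = "HIGH_GE" if modes[0] >= x_THR else "LOW_GE"
    else:
        label = "UNCLASSIFIED"

    return Landscape(x_grid=x, S=S, U=U, phi_x=phi, roots_Sprime=roots_S,
                     roots_Uprime=roots_U, modes=modes, dU0=dU0, dU1=dU1,
                     class_label=label, Omega_T=Omega_T, qss=qss)


def classify_theta(params: ModelParams, x_THR: float | None = None,
                   Omega_T: int | None = None, x_grid: np.ndarray | None = None) -> Landscape:
    """Classify one parameter set into a landscape-topography sub-ensemble."""
    return compute_landscape(params, Omega_T=Omega_T, x_grid=x_grid, x_THR=x_THR)
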