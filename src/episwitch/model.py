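"""Core model: rate laws of the reduced bivalent-chromatin switch and their
quasi-steady-state (QSS) analysis.

The reduced model tracks three variables: the concentration ``x`` of a
monomeric, self-regulating transcription factor (TF, the slow variable) and
the concentrations ``q_A`` (H3K4me3, activating mark) and ``q_I`` (H3K27me3,
repressive mark), which evolve on a faster time scale set by
``eps2 = Omega_S / Omega_T < 1``.

TF birth/death::

    B_x = rho * [1 + (C1 + C4*q_I) * h],   D_x = rho * [C2*x + C4*q_I * h]

with the shared occupancy fraction ``h = q_A*x / (lambda_x*q_I + q_A*x)``.
Note the drift identity ``B_x - D_x = rho*(1 + C1*h - C2*x)``: the C4 terms
cancel in the mean but add to the fluctuation intensity, which is how the
repressive mark shapes the finite-size (noise-induced) behaviour.

Mark addition follows total quasi-steady-state Michaelis--Menten kinetics with
linear feedback of marks and TF on enzyme recruitment; mark removal is plain
Michaelis--Menten::

    B_A = Lambda_A*(rho_A - q_A)*(A1 + q_A*x)*(A3 + q_A*x)
          / [(rho_A - q_A)*(A1 + q_A*x) + B2 + K2*q_A*x]
    D_A = Lambda_A*lambda_A*K6*q_A / (q_A + K5)
    B_I = Lambda_I*(rho_I - q_I)*(A7 + q_I)*(A9 + q_I)
          / [(rho_I - q_I)*(A7 + q_I) + B8 + (K8*x + K9)*q_I]
    D_I = Lambda_I*lambda_I*K12*q_I / (q_I + K11)

The 16 sampled kinetic constants form the parameter vector theta; the
remaining symbols are fixed constants of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "THETA_KEYS",
    "ModelParams",
    "StateVars",
    "QSSCurves",
    "HillFit",
    "rates_tf",
    "rates_marks",
    "qss_marks",
    "mark_root_sets",
    "response_curve",
    "effective_hill",
    "fit_hill_exponent",
    "default_x_grid",
]

#: Canonical ordering of the sampled kinetic constants.
THETA_KEYS = (
    "A1", "A3", "B2", "K2", "K5", "K6", "lambda_A", "lambda_x",
    "A7", "A9", "B8", "K8", "K9", "K11", "K12", "lambda_I",
)


@dataclass(frozen=True)
class ModelParams:
    """All rate constants of the reduced model.

    Parameters
    ----------
    theta
        Mapping with exactly the 16 keys of :data:`THETA_KEYS`; all values
        non-negative (dimensionless, rescaled units).
    rho
        Overall TF transcription rate scale (> 0).
    C1, C2, C4
        TF production/degradation coupling constants (>= 0).
    Lambda_A, Lambda_I
        Mark-turnover rate scales (> 0).
    rho_A, rho_I
        Total (maximal) concentrations of H3K4 / H3K27 residues (> 0).
    Omega_T, Omega_S
        TF and histone-residue system sizes; ``Omega_S/Omega_T`` must be < 1
        (slow-fast assumption).
    """

    theta: Mapping[str, float]
    rho: float = 1.0
    C1: float = 9.0
    C2: float = 1.0
    C4: float = 1.0
    Lambda_A: float = 1.0
    Lambda_I: float = 1.0
    rho_A: float = 1.0
    rho_I: float = 1.0
    Omega_T: int = 200
    Omega_S: int = 20

    def __post_init__(self):
        keys = set(self.theta)
        expected = set(THETA_KEYS)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"theta must contain exactly the 16 named constants; "
                f"missing={missing}, unexpected={extra}"
            )
        bad = {k: v for k, v in self.theta.items() if not (v >= 0.0) or not math.isfinite(v)}
        if bad:
            raise ValueError(f"theta components must be finite and >= 0: {bad}")
        object.__setattr__(self, "theta", dict(self.theta))
        for name in ("rho", "Lambda_A", "Lambda_I", "rho_A", "rho_I"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("C1", "C2", "C4"):
            if not (getattr(self, name) >= 0):
                raise ValueError(f"{name} must be >= 0")
        if not (self.Omega_T > 0 and self.Omega_S > 0):
            raise ValueError("Omega_T and Omega_S must be positive integers")
        if not self.Omega_S / self.Omega_T < 1:
            raise ValueError(
                f"slow-fast assumption violated: eps2 = Omega_S/Omega_T = "
                f"{self.Omega_S / self.Omega_T:g} must be < 1"
            )

    @property
    def eps2(self) -> float:
        """Time-scale separation ratio Omega_S / Omega_T."""
        return self.Omega_S / self.Omega_T

    def theta_array(self) -> np.ndarray:
        """theta as a vector in :data:`THETA_KEYS` order."""
        return np.array([self.theta[k] for k in THETA_KEYS], dtype=float)

    def with_theta(self, **updates: float) -> "ModelParams":
        """Copy with some theta components replaced."""
        unknown = set(updates) - set(THETA_KEYS)
        if unknown:
            raise ValueError(f"unknown theta components: {sorted(unknown)}")
        return replace(self, theta={**self.theta, **updates})

    def with_constants(self, **updates) -> "ModelParams":
        return replace(self, **updates)


@dataclass(frozen=True)
class StateVars:
    """A point (x, q_A, q_I) of the reduced state space."""

    x: float
    q_A: float
    q_I: float

    def validate(self, params: ModelParams) -> "StateVars":
        if not (self.x >= 0 and math.isfinite(self.x)):
            raise ValueError(f"x must be finite and >= 0, got {self.x}")
        if not (0 <= self.q_A <= params.rho_A):
            raise ValueError(f"q_A must lie in [0, rho_A={params.rho_A}], got {self.q_A}")
        if not (0 <= self.q_I <= params.rho_I):
            raise ValueError(f"q_I must lie in [0, rho_I={params.rho_I}], got {self.q_I}")
        return self


def _hill_fraction(x, q_A, q_I, lambda_x):
    """Shared occupancy fraction h = q_A x / (lambda_x q_I + q_A x).

    The 0/0 point (x*q_A = 0 and q_I = 0) is defined as 0 by continuity from
    x -> 0 at q_I > 0 (no marks and no TF means basal rates only).
    """
    num = np.asarray(q_A * x, dtype=float)
    den = np.asarray(lambda_x * q_I + num, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return h


def rates_tf(state: StateVars, params: ModelParams):
    """TF birth and death rates (B_x, D_x) at a state point."""
    state.validate(params)
    B, D = _rates_tf_arrays(state.x, state.q_A, state.q_I, params)
    return float(B), float(D)


def _rates_tf_arrays(x, q_A, q_I, params: ModelParams):
    h = _hill_fraction(x, q_A, q_I, params.theta["lambda_x"])
    B = params.rho * (1.0 + (params.C1 + params.C4 * np.asarray(q_I)) * h)
    D = params.rho * (params.C2 * np.asarray(x, dtype=float) + params.C4 * np.asarray(q_I) * h)
    if np.any(~np.isfinite(B)) or np.any(~np.isfinite(D)):
        raise FloatingPointError("non-finite TF rate; check parameter values")
    return B, D


def rates_marks(state: StateVars, params: ModelParams):
    """Mark addition/removal rates (B_A, D_A, B_I, D_I) at a state point."""
    state.validate(params)
    BA, DA = _rates_A_arrays(state.x, state.q_A, params)
    BI, DI = _rates_I_arrays(state.x, state.q_I, params)
    return float(BA), float(DA), float(BI), float(DI)


def _rates_A_arrays(x, q_A, params: ModelParams):
    t = params.theta
    x = np.asarray(x, dtype=float)
    q_A = np.asarray(q_A, dtype=float)
    w = q_A * x
    num = params.Lambda_A * (params.rho_A - q_A) * (t["A1"] + w) * (t["A3"] + w)
    den = (params.rho_A - q_A) * (t["A1"] + w) + t["B2"] + t["K2"] * w
    if np.any(den <= 0):
        raise ZeroDivisionError(
            "B_A denominator vanished: (rho_A-q_A)*(A1+q_A*x) + B2 + K2*q_A*x = 0; "
            f"A1={t['A1']}, B2={t['B2']}, K2={t['K2']} jointly too small"
        )
    BA = num / den
    den_D = q_A + t["K5"]
    with np.errstate(invalid="ignore", divide="ignore"):
        DA = np.where(
            q_A > 0,
            params.Lambda_A * t["lambda_A"] * t["K6"] * q_A / np.where(den_D > 0, den_D, 1.0),
            0.0,
        )
    if np.any(~np.isfinite(BA)) or np.any(~np.isfinite(DA)):
        raise FloatingPointError("non-finite H3K4me3 rate")
    return BA, DA


def _rates_I_arrays(x, q_I, params: ModelParams):
    t = params.theta
    x = np.asarray(x, dtype=float)
    q_I = np.asarray(q_I, dtype=float)
    num = params.Lambda_I * (params.rho_I - q_I) * (t["A7"] + q_I) * (t["A9"] + q_I)
    den = (params.rho_I - q_I) * (t["A7"] + q_I) + t["B8"] + (t["K8"] * x + t["K9"]) * q_I
    if np.any(den <= 0):
        raise ZeroDivisionError(
            "B_I denominator vanished: (rho_I-q_I)*(A7+q_I) + B8 + (K8*x+K9)*q_I = 0; "
            f"A7={t['A7']}, B8={t['B8']}, K9={t['K9']} jointly too small"
        )
    BI = num / den
    den_D = q_I + t["K11"]
    with np.errstate(invalid="ignore", divide="ignore"):
        DI = np.where(
            q_I > 0,
            params.Lambda_I * t["lambda_I"] * t["K12"] * q_I / np.where(den_D > 0, den_D, 1.0),
            0.0,
        )
    if np.any(~np.isfinite(BI)) or np.any(~np.isfinite(DI)):
        raise FloatingPointError("non-finite H3K27me3 rate")
    return BI, DI


@dataclass
class QSSCurves:
    """Quasi-steady-state mark concentrations tabulated on an x grid.

    ``qA_star[i]`` is the smallest root of B_A - D_A = 0 in [0, rho_A] at
    ``x_grid[i]`` (similarly ``qI_star``).  ``rootsA_count``/``rootsI_count``
    give the number of roots found at each x; any count > 1 sets
    ``multistable`` and disqualifies the parameter set from the ensemble
    acceptance filter.
    """

    x_grid: np.ndarray
    qA_star: np.ndarray
    qI_star: np.ndarray
    rootsA_count: np.ndarray
    rootsI_count: np.ndarray
    crossover_x: float | None = None

    @property
    def multistable(self) -> bool:
        return bool(np.any(self.rootsA_count > 1) or np.any(self.rootsI_count > 1))


def _vectorised_roots(resid_fn, x_grid, q_hi, n_scan=512, n_bisect=60):
    """Roots of resid_fn(x, q) = 0 in q over [0, q_hi], for every x at once.

    resid_fn must broadcast over arrays. Returns (first_root, root_count).
    A sign-change scan on an ``n_scan``-point uniform q grid brackets roots;
    each first bracket is then refined by vectorised bisection.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    qs = np.linspace(0.0, q_hi, n_scan)
    R = resid_fn(x_grid[:, None], qs[None, :])
    sign = np.sign(R)
    # treat exact zeros as positive on the left of a crossing so a tabulated
    # root is detected once
    sign[sign == 0] = 1.0
    flips = sign[:, :-1] * sign[:, 1:] < 0
    count = flips.sum(axis=1)

    lo = np.zeros_like(x_grid)
    hi = np.full_like(x_grid, q_hi)
    has = count > 0
    first = np.argmax(flips, axis=1)
    lo[has] = qs[first[has]]
    hi[has] = qs[first[has] + 1]
    left_sign = np.take_along_axis(sign, np.minimum(first, n_scan - 1)[:, None], 1)[:, 0]
    # no interior sign change: residual one-signed; the root sits at an
    # endpoint (resid >= 0 everywhere => root at q_hi, e.g. demethylation off)
    no = ~has
    if np.any(no):
        endpoint = np.where(R[no, -1] >= 0, q_hi, 0.0)
        lo[no] = endpoint
        hi[no] = endpoint
        count = count + no.astype(int)  # endpoint root counts as one root

    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        rm = resid_fn(x_grid, mid)
        neg = np.sign(rm) == left_sign
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi), count


def qss_marks(params: ModelParams, x_grid: Sequence[float], tol: float = 1e-8,
              n_scan: int = 512) -> QSSCurves:
    """Solve B_A = D_A and B_I = D_I for the QSS mark curves on ``x_grid``.

    Raises if any tabulated point violates the residual tolerance ``tol``.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.ndim != 1 or len(x_grid) < 2 or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be strictly increasing with >= 2 points")
    if np.any(x_grid < 0):
        raise ValueError("x_grid must be non-negative")
    if not tol > 0:
        raise ValueError("tol must be > 0")

    def residA(x, q):
        B, D = _rates_A_arrays(x, q, params)
        return B - D

    def residI(x, q):
        B, D = _rates_I_arrays(x, q, params)
        return B - D
    qA, nA = _vectorised_roots(residA, x_grid, params.rho_A, n_scan=n_scan)
    qI, nI = _vectorised_roots(residI, x_grid, params.rho_I, n_scan=n_scan)

    rA = np.abs(residA(x_grid, qA))
    rI = np.abs(residI(x_grid, qI))
    # endpoint roots (e.g. q = rho_A with demethylation off) are exact
    if rA.max() > tol or rI.max() > tol:
        i = int(np.argmax(np.maximum(rA, rI)))
        raise RuntimeError(
            f"QSS residual exceeds tol={tol:g} at x={x_grid[i]:g}: "
            f"|B_A-D_A|={rA[i]:.3g}, |B_I-D_I|={rI[i]:.3g}"
        )

    diff = qA - qI
    crossover = None
    s = np.sign(diff)
    s[s == 0] = 1
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if len(idx):
        i = idx[0]
        # linear interpolation of the crossing
        w = diff[i] / (diff[i] - diff[i + 1])
        crossover = float(x_grid[i] + w * (x_grid[i + 1] - x_grid[i]))
    return QSSCurves(x_grid=x_grid, qA_star=qA, qI_star=qI,
                     rootsA_count=nA, rootsI_count=nI, crossover_x=crossover)


def mark_root_sets(params: ModelParams, x: float, n_scan: int = 2048):
    """All QSS roots of both mark equations at a single x (diagnostic)."""
    out = {}
    for label, fn, hi in (
        ("q_A", lambda q: _rates_A_arrays(x, q, params)[0] - _rates_A_arrays(x, q, params)[1],
         params.rho_A),
        ("q_I", lambda q: _rates_I_arrays(x, q, params)[0] - _rates_I_arrays(x, q, params)[1],
         params.rho_I),
    ):
        qs = np.linspace(0.0, hi, n_scan)
        r = fn(qs)
        roots = []
        s = np.sign(r)
        s[s == 0] = 1
        for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
            roots.append(brentq(fn, qs[i], qs[i + 1], xtol=1e-13))
        if not roots:
            roots = [hi if r[-1] >= 0 else 0.0]
        out[label] = np.array(roots)
    return out["q_A"], out["q_I"]


def response_curve(params: ModelParams, qss: QSSCurves) -> np.ndarray:
    """TF production response R(x) = rho * (1 + C1 * h(x)) at QSS marks."""
    h = _hill_fraction(qss.x_grid, qss.qA_star, qss.qI_star, params.theta["lambda_x"])
    return params.rho * (1.0 + params.C1 * h)


@dataclass(frozen=True)
class HillFit:
    """Effective Hill description R(x) ~ rho*(1 + C_eff x^n_eff/(lambda_eff + x^n_eff))."""

    n_eff: float
    C_eff: float
    lambda_eff: float
    fit_residual: float


def effective_hill(params: ModelParams, qss: QSSCurves, h_margin: float = 1e-4) -> HillFit:
    """Effective cooperativity of the response curve.

    n_eff is the maximum logit slope d log[h/(1-h)] / d log x over the
    interior subgrid where h is strictly between its bounds; this estimator is
    exact for true Hill functions of any order.  C_eff and lambda_eff then
    come from a least-squares fit of the Hill form at fixed n_eff.
    """
    x = qss.x_grid
    h = _hill_fraction(x, qss.qA_star, qss.qI_star, params.theta["lambda_x"])
    mask = (h > h_margin) & (h < 1.0 - h_margin) & (x > 0)
    if mask.sum() < 5 or np.ptp(h[mask]) < 1e-10:
        raise ValueError("response curve is degenerate (h constant or out of range); "
                         "n_eff undefined")
    logit = np.log(h[mask]) - np.log1p(-h[mask])
    lx = np.log(x[mask])
    slope = np.gradient(logit, lx)
    n_eff = float(np.max(slope))

    R = params.rho * (1.0 + params.C1 * h)

    def hill(xv, C_eff, lam):
        xn = xv ** n_eff
        return params.rho * (1.0 + C_eff * xn / (lam + xn))

    x50 = float(np.interp(0.5 * (h[mask].min() + h[mask].max()), h[mask], x[mask]))
    p0 = (params.C1 * h.max(), max(x50, 1e-6) ** n_eff)
    try:
        popt, _ = curve_fit(hill, x[mask], R[mask], p0=p0, maxfev=20000)
        C_eff, lam = float(popt[0]), float(abs(popt[1]))
        resid = float(np.sqrt(np.mean((hill(x[mask], *popt) - R[mask]) ** 2)))
    except RuntimeError:
        C_eff, lam = p0
        resid = float("inf")
    return HillFit(n_eff=n_eff, C_eff=C_eff, lambda_eff=lam, fit_residual=resid)


def fit_hill_exponent(params: ModelParams, qss: QSSCurves) -> HillFit:
    """Unconstrained least-squares Hill fit of the response curve.

    Unlike :func:`effective_hill` (whose logit-slope estimator is a sharp
    local measure, bounded below by 1 for monotone mark curves), this fits
    all three Hill parameters (C_eff, lambda_eff, n_eff) to R(x) globally --
    the exponent the response-curve definition itself uses -- so it can
    relax to 1 as the mark feedback flattens.
    """
    x = qss.x_grid
    R = response_curve(params, qss)
    rho, C1 = params.rho, params.C1
    mask = (R > rho * 1.001) & (R < rho * (1 + C1) * 0.999) & (x > 0)
    if mask.sum() < 8:
        raise ValueError("response curve degenerate; Hill exponent undefined")

    def hill(xv, C_eff, lam, n):
        xn = xv ** n
        return rho * (1.0 + C_eff * xn / (lam + xn))

    popt, _ = curve_fit(hill, x[mask], R[mask], p0=(C1, 0.3, 1.5), maxfev=50000)
    resid = float(np.sqrt(np.mean((hill(x[mask], *popt) - R[mask]) ** 2)))
    return HillFit(n_eff=float(popt[2]), C_eff=float(popt[0]),
                   lambda_eff=float(abs(popt[1])), fit_residual=resid)


def default_x_grid(params: ModelParams, n: int = 400, x_min: float = 1e-3) -> np.ndarray:
    """Log-spaced grid [x_min, 10*(1+C1)/C2] covering both expression wells.

    Because h <= 1, every mean-field equilibrium satisfies x <= (1+C1)/C2, so
    ten times that bound covers the support of phi_x with margin; log spacing
    resolves the near-singular region at small x.
    """
    if params.C2 <= 0:
        raise ValueError("C2 must be > 0 to bound the x grid")
    x_max = 10.0 * (1.0 + params.C1) / params.C2
    return np.geomspace(x_min, x_max, n)
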