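"""Exact stochastic simulation of the reduced three-variable switch.

The master equation is simulated in count space: the state is
``(n_x, n_A, n_I)`` with concentrations ``x = n_x/Omega_T``,
``q = n/Omega_S``.  All six channels carry propensity ``Omega_T * rate``
(the 1/eps2 acceleration of the mark channels combines with their Omega_S
prefactor to Omega_S/eps2 = Omega_T), with unit count increments.  Mark
addition vanishes at the carrying capacity by construction, so counts never
exceed ``rho_J * Omega_S``.

The inner loop is JIT-compiled with numba; a pure-Python fallback (the same
function, uncompiled) is used when numba is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .model import ModelParams, StateVars

__all__ = [
    "SSAConfig",
    "SSATrajectory",
    "gillespie_run",
    "occupation_histogram",
    "count_modes",
    "scan_system_size",
]


@dataclass(frozen=True)
class SSAConfig:
    """Simulation settings (time in units of the slow TF time scale tau)."""

    t_max: float
    seed: int
    burn_in: float = 0.0
    record_stride: float = 0.1
    Omega_T: int | None = None   # default: taken from the ModelParams
    Omega_S: int | None = None

    def __post_init__(self):
        if not self.t_max > 0:
            raise ValueError("t_max must be > 0")
        if not 0 <= self.burn_in < self.t_max:
            raise ValueError("burn_in must satisfy 0 <= burn_in < t_max")
        if not self.record_stride > 0:
            raise ValueError("record_stride must be > 0")


@dataclass
class SSATrajectory:
    """Stride-sampled trajectory of counts; concentrations are derived views."""

    times: np.ndarray
    n_x: np.ndarray
    n_A: np.ndarray
    n_I: np.ndarray
    Omega_T: int
    Omega_S: int
    absorbed: bool = False

    @property
    def x(self) -> np.ndarray:
        return self.n_x / self.Omega_T

    @property
    def q_A(self) -> np.ndarray:
        return self.n_A / self.Omega_S

    @property
    def q_I(self) -> np.ndarray:
        return self.n_I / self.Omega_S


def _ssa_kernel(th, co, Omega_T, Omega_S, capA, capI, n_x, n_A, n_I,
                t_max, stride, n_rec, rng, freeze_x):
    """Count-space Gillespie loop.  th: theta in THETA_KEYS order; co:
    (rho, C1, C2, C4, Lambda_A, Lambda_I, rho_A, rho_I)."""
    A1 = th[0]; A3 = th[1]; B2 = th[2]; K2 = th[3]; K5 = th[4]; K6 = th[5]
    lamA = th[6]; lamx = th[7]; A7 = th[8]; A9 = th[9]; B8 = th[10]
    K8 = th[11]; K9 = th[12]; K11 = th[13]; K12 = th[14]; lamI = th[15]
    rho = co[0]; C1 = co[1]; C2 = co[2]; C4 = co[3]
    LA = co[4]; LI = co[5]; rhoA = co[6]; rhoI = co[7]

    out_x = np.empty(n_rec, dtype=np.int64)
    out_A = np.empty(n_rec, dtype=np.int64)
    out_I = np.empty(n_rec, dtype=np.int64)
    t = 0.0
    irec = 0
    absorbed = False
    while irec < n_rec:
        x = n_x / Omega_T
        qA = n_A / Omega_S
        qI = n_I / Omega_S

        num = qA * x
        den = lamx * qI + num
        h = num / den if den > 0.0 else 0.0
        Bx = rho * (1.0 + (C1 + C4 * qI) * h)
        Dx = rho * (C2 * x + C4 * qI * h)

        w = qA * x
        BA = LA * (rhoA - qA) * (A1 + w) * (A3 + w) / ((rhoA - qA) * (A1 + w) + B2 + K2 * w)
        DA = LA * lamA * K6 * qA / (qA + K5) if n_A > 0 else 0.0
        BI = LI * (rhoI - qI) * (A7 + qI) * (A9 + qI) / (
            (rhoI - qI) * (A7 + qI) + B8 + (K8 * x + K9) * qI)
        DI = LI * lamI * K12 * qI / (qI + K11) if n_I > 0 else 0.0

        if freeze_x:
            a = Omega_T * (BA + DA + BI + DI)
        else:
            a = Omega_T * (Bx + Dx + BA + DA + BI + DI)
        if a <= 0.0:
            absorbed = True
            while irec < n_rec:
                out_x[irec] = n_x; out_A[irec] = n_A; out_I[irec] = n_I
                irec += 1
            break
        dt = -np.log(rng.random()) / a
        t_new = t + dt
        # record stride samples passed during the holding interval
        while irec < n_rec and irec * stride < t_new:
            out_x[irec] = n_x; out_A[irec] = n_A; out_I[irec] = n_I
            irec += 1
        t = t_new
        u = rng.random() * a
        if freeze_x:
            c = Omega_T * BA
            if u < c:
                if n_A < capA: n_A += 1
            elif u < c + Omega_T * DA:
                if n_A > 0: n_A -= 1
            elif u < c + Omega_T * (DA + BI):
                if n_I < capI: n_I += 1
            else:
                if n_I > 0: n_I -= 1
        else:
            c1 = Omega_T * Bx
            c2 = c1 + Omega_T * Dx
            c3 = c2 + Omega_T * BA
            c4 = c3 + Omega_T * DA
            c5 = c4 + Omega_T * BI
            if u < c1:
                n_x += 1
            elif u < c2:
                if n_x > 0: n_x -= 1
            elif u < c3:
                if n_A < capA: n_A += 1
            elif u < c4:
                if n_A > 0: n_A -= 1
            elif u < c5:
                if n_I < capI: n_I += 1
            else:
                if n_I > 0: n_I -= 1
    return out_x, out_A, out_I, absorbed


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _ssa_kernel_jit = njit(cache=False)(_ssa_kernel)
except ImportError:  # pragma: no cover
    _ssa_kernel_jit = _ssa_kernel


def gillespie_run(params: ModelParams, cfg: SSAConfig,
                  init: StateVars | None = None, freeze_x: bool = False) -> SSATrajectory:
    """Exact SSA run; identical seed gives an identical trajectory.

    ``init`` defaults to the state (x, q_A, q_I) = (1/C2 at basal production,
    QSS marks there), i.e. near the OFF/low-expression well.  With
    ``freeze_x`` the TF count is held fixed and only the mark channels fire
    (used to validate the conditional WKB mark densities).
    """
    Omega_T = int(cfg.Omega_T or params.Omega_T)
    Omega_S = int(cfg.Omega_S or params.Omega_S)
    if not Omega_S / Omega_T < 1:
        raise ValueError("eps2 = Omega_S/Omega_T must be < 1")
    capA = int(round(params.rho_A * Omega_S))
    capI = int(round(params.rho_I * Omega_S))
    if init is None:
        from .meanfield import off_state
        init = off_state(params)
    init.validate(params)
    n_x = int(round(init.x * Omega_T))
    n_A = min(int(round(init.q_A * Omega_S)), capA)
    n_I = min(int(round(init.q_I * Omega_S)), capI)

    n_rec = int(np.floor(cfg.t_max / cfg.record_stride)) + 1
    rng = np.random.default_rng(cfg.seed)
    co = np.array([params.rho, params.C1, params.C2, params.C4,
                   params.Lambda_A, params.Lambda_I, params.rho_A, params.rho_I])
    out_x, out_A, out_I, absorbed = _ssa_kernel_jit(
        params.theta_array(), co, Omega_T, Omega_S, capA, capI,
        n_x, n_A, n_I, float(cfg.t_max), float(cfg.record_stride), n_rec, rng,
        freeze_x)
    times = np.arange(n_rec) * cfg.record_stride
    return SSATrajectory(times=times, n_x=out_x, n_A=out_A, n_I=out_I,
                         Omega_T=Omega_T, Omega_S=Omega_S, absorbed=bool(absorbed))


def occupation_histogram(traj: SSATrajectory, burn_in: float = 0.0,
                         n_bins: int = 60, x_max: float | None = None):
    """Time-weighted stationary histogram of the TF concentration.

    Recorded samples are equally spaced in time, so equal weights estimate
    the occupation measure.  Returns (bin_edges, density) normalised to unit
    integral over x.
    """
    keep = traj.times >= burn_in
    if keep.sum() < 100:
        raise ValueError("post-burn-in window covers fewer than 100 recorded points")
    xs = traj.x[keep]
    hi = x_max if x_max is not None else xs.max() * 1.05 + 1.0 / traj.Omega_T
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, edges = np.histogram(xs, bins=edges)
    widths = np.diff(edges)
    density = counts / counts.sum() / widths
    return edges, density


def count_modes(density: np.ndarray, min_prominence: float = 0.05) -> int:
    """Number of local maxima with prominence >= min_prominence * max(density).

    The density is zero-padded so modes at the domain boundary are counted.
    """
    d = np.asarray(density, dtype=float)
    if d.max() <= 0:
        return 0
    padded = np.concatenate([[0.0], d, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * d.max())
    return int(len(peaks))


def scan_system_size(params: ModelParams, omega_list, cfg: SSAConfig,
                     replicates: int = 3, seed: int = 0, n_bins: int = 40,
                     min_prominence: float = 0.05, smooth: int = 3):
    """Majority-vote SSA mode count per system size (descending Omega_T).

    Omega_S is scaled with Omega_T to keep eps2 fixed.  Returns a dict with
    per-Omega mode counts and, when the count crosses 1 -> 2 as Omega_T
    decreases, the bracketing pair; a non-monotone majority pattern is
    reported as inconclusive rather than raised.
    """
    omega_list = list(omega_list)
    if any(omega_list[i] < omega_list[i + 1] for i in range(len(omega_list) - 1)):
        raise ValueError("omega_list must be sorted descending")
    eps2 = params.eps2
    results = {}
    for k, OT in enumerate(omega_list):
        OS = max(2, int(round(eps2 * OT)))
        votes = []
        for r in range(replicates):
            c = SSAConfig(t_max=cfg.t_max, seed=seed + 1000 * k + r,
                          burn_in=cfg.burn_in, record_stride=cfg.record_stride,
                          Omega_T=OT, Omega_S=OS)
            traj = gillespie_run(params, c)
            _, dens = occupation_histogram(traj, burn_in=c.burn_in, n_bins=n_bins)
            if smooth > 1:
                kern = np.ones(smooth) / smooth
                dens = np.convolve(dens, kern, mode="same")
            votes.append(count_modes(dens, min_prominence=min_prominence))
        results[OT] = int(np.median(votes))
    counts = [results[o] for o in omega_list]
    crossing = None
    inconclusive = False
    for i in range(len(counts) - 1):
        if counts[i] == 1 and counts[i + 1] >= 2:
            crossing = (omega_list[i], omega_list[i + 1])
            break
    mono = all(counts[i] <= counts[i + 1] for i in range(len(counts) - 1))
    if not mono and crossing is None:
        inconclusive = True
    return {"mode_counts": results, "crossing": crossing, "inconclusive": inconclusive}
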