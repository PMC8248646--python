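"""Sub-ensemble statistics and in-silico epigenetic-drug screens.

Drugs against chromatin modifiers are emulated as multiplicative
perturbations of the corresponding Michaelis--Menten parameters: a protocol
maps theta components to fold-change functions of a dose-like factor nu
(identity, nu, or f(nu) = 2 - nu for counter-scaled combinations).  The
screen rescales every bistable theta, re-classifies its landscape, and
reports the fraction rendered monostable as a function of nu, the
operational measure of how well a strategy overcomes ensemble heterogeneity.

Enzyme-activity proxies map the four mark fluxes onto the enzymes that
catalyse them: B_A -> MLL2 (H3K4 methyltransferase), D_A -> KDM5 (H3K4
demethylase), B_I -> EZH2 (H3K27 methyltransferase), D_I -> UTX (H3K27
demethylase).  The proxy is the maximum over the mark level q of the
phi_x-average of the flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.stats import ks_2samp, pearsonr, spearmanr

from .landscape import Landscape, compute_landscape
from .model import THETA_KEYS, ModelParams, default_x_grid

__all__ = [
    "ENZYME_FLUXES",
    "TherapyProtocol",
    "ResponseCurve",
    "ks_compare",
    "correlation_matrix",
    "activity_proxies",
    "apply_therapy",
]

#: enzyme name -> which flux proxies its activity
ENZYME_FLUXES = {"MLL2": "B_A", "KDM5": "D_A", "EZH2": "B_I", "UTX": "D_I"}

_SCALINGS = {
    "identity": lambda nu: 1.0,
    "nu": lambda nu: nu,
    "two_minus_nu": lambda nu: 2.0 - nu,
}


@dataclass(frozen=True)
class TherapyProtocol:
    """Mapping of theta components to fold-change rules over a nu grid.

    ``scalings`` values are rule names: "nu" scales the parameter by nu,
    "two_minus_nu" by f(nu) = 2 - nu (counter-scaled combination partner),
    "identity" leaves it unchanged.  Every rule is the identity at nu = 1.
    """

    name: str
    scalings: dict
    nu_grid: tuple = tuple(np.round(np.arange(0.1, 2.0, 0.1), 10))

    def __post_init__(self):
        for k, rule in self.scalings.items():
            if k not in THETA_KEYS:
                raise ValueError(f"unknown theta component {k!r}")
            if rule not in _SCALINGS:
                raise ValueError(f"unknown scaling rule {rule!r}")
        if not all(nu > 0 for nu in self.nu_grid):
            raise ValueError("nu grid must be positive")

    def feasible(self, nu: float) -> bool:
        return all(_SCALINGS[r](nu) >= 0 for r in self.scalings.values())

    def apply(self, theta: dict, nu: float) -> dict:
        if not self.feasible(nu):
            raise ValueError(f"protocol {self.name} infeasible at nu={nu} "
                             "(negative fold change)")
        out = dict(theta)
        for k, rule in self.scalings.items():
            out[k] = theta[k] * _SCALINGS[rule](nu)
        return out


def single_parameter_protocol(param: str, nu_grid=None) -> TherapyProtocol:
    kw = {} if nu_grid is None else {"nu_grid": tuple(nu_grid)}
    return TherapyProtocol(name=param, scalings={param: "nu"}, **kw)


def combination_protocol(param_up: str, param_down: str, nu_grid=None) -> TherapyProtocol:
    """Combined protocol: param_up -> nu * p, param_down -> (2 - nu) * p."""
    kw = {} if nu_grid is None else {"nu_grid": tuple(nu_grid)}
    return TherapyProtocol(name=f"{param_up}-{param_down}",
                           scalings={param_up: "nu", param_down: "two_minus_nu"}, **kw)


def ks_compare(ensemble_A: pd.DataFrame, ensemble_B: pd.DataFrame,
               component_list=THETA_KEYS):
    """Two-sample KS p-value for each theta component's marginal.

    Returns a DataFrame (component, statistic, p_value, low_power) where
    low_power flags sub-ensembles smaller than 20.
    """
    if len(ensemble_A) == 0 or len(ensemble_B) == 0:
        raise ValueError("both sub-ensembles must be non-empty")
    low_power = min(len(ensemble_A), len(ensemble_B)) < 20
    rows = []
    for c in component_list:
        res = ks_2samp(ensemble_A[c].to_numpy(), ensemble_B[c].to_numpy())
        rows.append({"component": c, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "low_power": low_power})
    return pd.DataFrame(rows)


def correlation_matrix(sub_ensemble: pd.DataFrame, component_list=THETA_KEYS,
                       alpha_bands=(0.05, 0.5), method: str = "pearson"):
    """Pairwise linear correlations with p-values, banded into three classes:
    p < alpha_bands[0] (correlated), intermediate, and p > alpha_bands[1]
    (uncorrelated).

    Returns (r, p, bands) DataFrames indexed by component; zero-variance
    components yield NaN entries for their pairs.
    """
    if len(sub_ensemble) < 3:
        raise ValueError("need at least 3 records for correlations")
    corr = pearsonr if method == "pearson" else spearmanr
    k = len(component_list)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i, a in enumerate(component_list):
        xa = sub_ensemble[a].to_numpy()
        for j, b in enumerate(component_list):
            if j < i:
                continue
            xb = sub_ensemble[b].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            res = corr(xa, xb)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    lo, hi = alpha_bands
    bands = np.where(np.isnan(p), "undefined",
                     np.where(p < lo, "correlated",
                              np.where(p > hi, "uncorrelated", "weak")))
    idx = list(component_list)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(bands, index=idx, columns=idx))


def activity_proxies(params: ModelParams, landscape: Landscape,
                     n_q: int = 200) -> dict:
    """Chromatin-modifier activity proxies.

    activity(J) = max over the mark level q of  int J(x, q) phi_x(x) dx,
    for J in {B_A, D_A, B_I, D_I} mapped to {MLL2, KDM5, EZH2, UTX}.
    """
    from .model import _rates_A_arrays, _rates_I_arrays
    x = landscape.x_grid
    phi = landscape.phi_x
    qA = np.linspace(0.0, params.rho_A, n_q)
    qI = np.linspace(0.0, params.rho_I, n_q)
    BA, DA = _rates_A_arrays(x[None, :], qA[:, None], params)
    BI, DI = _rates_I_arrays(x[None, :], qI[:, None], params)
    out = {}
    for name, mat in (("MLL2", BA), ("KDM5", DA), ("EZH2", BI), ("UTX", DI)):
        avg = trapezoid(mat * phi[None, :], x, axis=1)
        out[name] = float(avg.max())
    return out


@dataclass
class ResponseCurve:
    """Fractions of an initially bistable sub-ensemble re-classified at each nu."""

    protocol: str
    nu_grid: np.ndarray
    fraction_monostable: np.ndarray
    fraction_noise_induced: np.ndarray
    fraction_still_bistable: np.ndarray
    n_bistable_input: int
    infeasible: np.ndarray            # bool per nu
    activities: pd.DataFrame | None = None   # long format: nu, enzyme, value


def apply_therapy(bistable_thetas: list[dict], protocol: TherapyProtocol,
                  constants: dict | None = None, Omega_T: int = 200,
                  x_THR: float | None = None, n_grid: int = 200,
                  with_activities: bool = True) -> ResponseCurve:
    """Rescale every bistable theta per protocol at each nu and re-classify.

    Counts NOISE_INDUCED outcomes separately from monostable ones so either
    reading of "becomes monostable" is recoverable.  A nu where a fold
    change would be negative is marked infeasible, never clipped.
    """
    if not bistable_thetas:
        raise ValueError("no bistable records supplied")
    from .ensemble import mark_averages  # noqa: F401  (module coupling kept explicit)
    nus = np.asarray(protocol.nu_grid, dtype=float)
    n = len(bistable_thetas)
    f_mono = np.zeros(len(nus))
    f_ni = np.zeros(len(nus))
    f_bi = np.zeros(len(nus))
    infeasible = np.zeros(len(nus), dtype=bool)
    act_rows = []
    if x_THR is None:
        p0 = ModelParams(theta=bistable_thetas[0], **(constants or {}))
        x_THR = float(np.sqrt(1 + p0.C1) / p0.C2)
    for i, nu in enumerate(nus):
        if not protocol.feasible(nu):
            infeasible[i] = True
            f_mono[i] = f_ni[i] = f_bi[i] = np.nan
            continue
        counts = {"mono": 0, "ni": 0, "bi": 0}
        for theta in bistable_thetas:
            th = protocol.apply(theta, nu)
            params = ModelParams(theta=th, **(constants or {}))
            L = compute_landscape(params, Omega_T=Omega_T, x_THR=x_THR,
                                  x_grid=default_x_grid(params, n=n_grid))
            if L.class_label in ("LOW_GE", "HIGH_GE"):
                counts["mono"] += 1
            elif L.class_label == "NOISE_INDUCED":
                counts["ni"] += 1
            elif L.class_label == "BISTABLE":
                counts["bi"] += 1
            else:  # UNCLASSIFIED: conservatively still counted as bistable
                counts["bi"] += 1
            if with_activities:
                for enz, v in activity_proxies(params, L).items():
                    act_rows.append({"nu": nu, "enzyme": enz, "value": v})
        f_mono[i] = counts["mono"] / n
        f_ni[i] = counts["ni"] / n
        f_bi[i] = counts["bi"] / n
    acts = pd.DataFrame(act_rows) if with_activities else None
    return ResponseCurve(protocol=protocol.name, nu_grid=nus,
                         fraction_monostable=f_mono, fraction_noise_induced=f_ni,
                         fraction_still_bistable=f_bi, n_bistable_input=n,
                         infeasible=infeasible, activities=acts)
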