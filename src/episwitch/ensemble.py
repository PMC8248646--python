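"""Parameter-ensemble machinery: uniform prior sampling, the mark-
monostability acceptance filter, per-theta classification and summaries,
persistence, and the seeded reference-parameter (fixture) search.

Every accepted theta is classified by its landscape topography at a common
system size, yielding the four sub-ensembles LOW_GE, HIGH_GE, BISTABLE and
NOISE_INDUCED.  Per-theta summaries include the phi_x-weighted mark averages
<q_J|theta>_x, the chromatin-modifier activity proxies, the potential
barriers and a methylation-status label mirroring ChIP-seq classifications
(unmarked / K4-dominant / K27-dominant / bivalent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.stats import gaussian_kde

from .landscape import Landscape, compute_landscape
from .model import THETA_KEYS, ModelParams, QSSCurves, default_x_grid, qss_marks

__all__ = [
    "PriorRanges",
    "EnsembleRecord",
    "Ensemble",
    "sample_prior",
    "acceptance_filter",
    "mark_averages",
    "methylation_status",
    "split_threshold",
    "build_record",
    "build_ensemble",
    "find_reference_params",
]

METHYLATION_LABELS = ("UNMARKED", "K4_DOMINANT", "K27_DOMINANT", "BIVALENT")


@dataclass(frozen=True)
class PriorRanges:
    """Closed uniform-prior interval for each of the 16 theta components."""

    ranges: dict

    def __post_init__(self):
        keys = set(self.ranges)
        if keys != set(THETA_KEYS):
            raise ValueError(
                f"prior ranges must cover exactly the 16 theta components; "
                f"missing={sorted(set(THETA_KEYS) - keys)}, "
                f"unexpected={sorted(keys - set(THETA_KEYS))}")
        for k, (lo, hi) in self.ranges.items():
            if not (0 <= lo < hi):
                raise ValueError(f"invalid range for {k}: [{lo}, {hi}]")
        object.__setattr__(self, "ranges", {k: (float(lo), float(hi))
                                            for k, (lo, hi) in self.ranges.items()})

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in
                ((kk, self.ranges[kk]) for kk in THETA_KEYS)}


def sample_prior(ranges: PriorRanges, n: int, seed: int | np.random.Generator) -> list[dict]:
    """n independent uniform draws of theta; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [ranges.sample(rng) for _ in range(n)]


def acceptance_filter(theta: dict, constants: dict | None = None,
                      n_x: int = 64, n_scan: int = 512):
    """Accept theta iff both mark equations are monostable in their own
    variable at every TF level on a reference grid.

    Returns (accepted, reason); reason is "" when accepted.
    """
    params = ModelParams(theta=theta, **(constants or {}))
    grid = default_x_grid(params, n=n_x)
    qss = qss_marks(params, grid, n_scan=n_scan)
    if np.any(qss.rootsA_count > 1):
        return False, "qA multistable"
    if np.any(qss.rootsI_count > 1):
        return False, "qI multistable"
    return True, ""


def mark_averages(params: ModelParams, landscape: Landscape):
    """phi_x-weighted QSS mark averages (<q_A|theta>_x, <q_I|theta>_x)."""
    qss = landscape.qss
    if qss is None:
        qss = qss_marks(params, landscape.x_grid)
    qA = float(trapezoid(qss.qA_star * landscape.phi_x, landscape.x_grid))
    qI = float(trapezoid(qss.qI_star * landscape.phi_x, landscape.x_grid))
    return qA, qI


def methylation_status(qA_avg: float, qI_avg: float,
                       thresholds=(0.05, 0.8, 5.0)) -> str:
    """Sequential methylation-status rule (boundary ties go to the earlier
    rule): unmarked if <q_A> < t0; K4-dominant if <q_I> < t1; K27-dominant if
    <q_I>/<q_A> < t2; else bivalent.

    The published rule is applied verbatim; note the K27-dominant ratio
    direction looks inverted relative to its name, so the thresholds are
    configurable.
    """
    t0, t1, t2 = thresholds
    if qA_avg <= t0:
        return "UNMARKED"
    if qI_avg <= t1:
        return "K4_DOMINANT"
    if qI_avg / qA_avg <= t2:
        return "K27_DOMINANT"
    return "BIVALENT"


def split_threshold(x_modes) -> float:
    """Data-driven x_THR: the KDE minimum of log10(x_*) between the two main
    peaks of the monostable modal distribution (which is bimodal)."""
    x_modes = np.asarray(x_modes, dtype=float)
    x_modes = x_modes[x_modes > 0]
    if len(x_modes) < 10:
        raise ValueError("need >= 10 monostable modes to place the threshold")
    lx = np.log10(x_modes)
    kde = gaussian_kde(lx)
    grid = np.linspace(lx.min(), lx.max(), 512)
    d = kde(grid)
    from scipy.signal import find_peaks
    peaks, props = find_peaks(d, prominence=0.02 * d.max())
    if len(peaks) < 2:
        raise ValueError("modal distribution not bimodal; supply x_THR explicitly")
    # two most prominent peaks
    order = np.argsort(props["prominences"])[::-1][:2]
    i, j = sorted(peaks[order])
    k = i + int(np.argmin(d[i:j + 1]))
    return float(10 ** grid[k])


@dataclass
class EnsembleRecord:
    """One accepted theta with its classification and summaries."""

    theta: dict
    class_label: str
    x_modes: np.ndarray
    x_star: float
    dU0: float | None
    dU1: float | None
    qA_avg: float
    qI_avg: float
    activities: dict
    methylation: str

    def to_row(self) -> dict:
        row = {k: self.theta[k] for k in THETA_KEYS}
        row.update(class_label=self.class_label, x_star=self.x_star,
                   n_modes=len(self.x_modes),
                   dU0=np.nan if self.dU0 is None else self.dU0,
                   dU1=np.nan if self.dU1 is None else self.dU1,
                   qA_avg=self.qA_avg, qI_avg=self.qI_avg,
                   methylation=self.methylation,
                   **{f"activity_{k}": v for k, v in self.activities.items()})
        return row


def build_record(theta: dict, constants: dict | None = None,
                 Omega_T: int | None = None, x_THR: float | None = None,
                 n_grid: int = 200) -> EnsembleRecord:
    """Classify one accepted theta and fill every summary field."""
    from .therapy import activity_proxies
    params = ModelParams(theta=theta, **(constants or {}))
    L = compute_landscape(params, Omega_T=Omega_T,
                          x_grid=default_x_grid(params, n=n_grid), x_THR=x_THR)
    # near-saddle-node wiggles can confuse the coarse grid; retry finer
    n_retry = n_grid
    while L.class_label == "UNCLASSIFIED" and n_retry < 8 * n_grid:
        n_retry *= 2
        L = compute_landscape(params, Omega_T=Omega_T,
                              x_grid=default_x_grid(params, n=n_retry), x_THR=x_THR)
    qA_avg, qI_avg = mark_averages(params, L)
    acts = activity_proxies(params, L)
    return EnsembleRecord(theta=dict(theta), class_label=L.class_label,
                          x_modes=L.modes,
                          x_star=L.x_star if len(L.modes) else np.nan,
                          dU0=L.dU0, dU1=L.dU1, qA_avg=qA_avg, qI_avg=qI_avg,
                          activities=acts, methylation=methylation_status(qA_avg, qI_avg))


@dataclass
class Ensemble:
    """Accepted-theta table plus the metadata to reproduce it exactly."""

    records: pd.DataFrame
    metadata: dict

    @property
    def class_tally(self) -> dict:
        return self.records["class_label"].value_counts().to_dict()

    def subset(self, label: str) -> pd.DataFrame:
        return self.records[self.records["class_label"] == label]

    def thetas(self, label: str | None = None) -> list[dict]:
        df = self.records if label is None else self.subset(label)
        return [{k: float(r[k]) for k in THETA_KEYS} for _, r in df.iterrows()]

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(d / "ensemble.csv", index=False)
        with open(d / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "Ensemble":
        d = Path(directory)
        records = pd.read_csv(d / "ensemble.csv")
        with open(d / "metadata.json") as fh:
            metadata = json.load(fh)
        return cls(records=records, metadata=metadata)


def build_ensemble(ranges: PriorRanges, constants: dict | None = None,
                   n_target_accepted: int = 500, Omega_T: int = 200,
                   x_THR: float | None = None, seed: int = 0,
                   max_draws: int | None = None, n_grid: int = 200,
                   min_acceptance: float = 1e-4) -> Ensemble:
    """Sample until ``n_target_accepted`` thetas pass the monostability
    filter, classify each and return the ensemble with its class tally.

    When ``x_THR`` is None the high/low split threshold is recomputed from
    the kernel-density minimum of the monostable modal distribution
    (geometric-mean fallback when that distribution is not bimodal).
    """
    rng = np.random.default_rng(seed)
    max_draws = max_draws or max(100_000, 50 * n_target_accepted)
    accepted, n_rejected, n_draws = [], 0, 0
    rejected_reasons: dict[str, int] = {}
    while len(accepted) < n_target_accepted:
        if n_draws >= max_draws:
            raise RuntimeError(
                f"only {len(accepted)} acceptances in {n_draws} draws; "
                f"prior ranges may be too wide (rejections: {rejected_reasons})")
        theta = ranges.sample(rng)
        n_draws += 1
        ok, reason = acceptance_filter(theta, constants)
        if not ok:
            n_rejected += 1
            rejected_reasons[reason] = rejected_reasons.get(reason, 0) + 1
            if n_draws >= 100_000 and len(accepted) / n_draws < min_acceptance:
                raise RuntimeError(
                    f"acceptance rate {len(accepted)/n_draws:.2e} below "
                    f"{min_acceptance}; rejections: {rejected_reasons}")
            continue
        accepted.append(theta)

    records = [build_record(t, constants, Omega_T=Omega_T, x_THR=np.inf,
                            n_grid=n_grid) for t in accepted]
    # second pass for the HIGH/LOW split when no threshold was supplied
    if x_THR is None:
        mono = [r.x_star for r in records if r.class_label in ("LOW_GE", "HIGH_GE")]
        params0 = ModelParams(theta=accepted[0], **(constants or {}))
        try:
            x_THR = split_threshold(mono)
        except ValueError:
            x_THR = float(np.sqrt(1 + params0.C1) / params0.C2)
    for r in records:
        if r.class_label in ("LOW_GE", "HIGH_GE"):
            r.class_label = "HIGH_GE" if r.x_star >= x_THR else "LOW_GE"

    df = pd.DataFrame([r.to_row() for r in records])
    unclassified = (df["class_label"] == "UNCLASSIFIED").mean()
    metadata = {
        "constants": constants or {}, "ranges": ranges.ranges, "seed": seed,
        "Omega_T": Omega_T, "x_THR": x_THR, "n_grid": n_grid,
        "n_accepted": len(accepted), "n_rejected": n_rejected,
        "n_draws": n_draws, "unclassified_rate": float(unclassified),
        "rejection_reasons": rejected_reasons,
    }
    return Ensemble(records=df, metadata=metadata)


def find_reference_params(constants: dict | None = None,
                          ranges: PriorRanges | None = None,
                          classes_wanted=("LOW_GE", "HIGH_GE", "BISTABLE", "NOISE_INDUCED"),
                          seed: int = 0, budget: int = 4000,
                          Omega_T: int = 200, x_THR: float | None = None,
                          min_barrier: float = 0.01,
                          min_visibility: float = 0.02) -> dict:
    """Seeded search for one exemplar theta per requested class.

    All exemplars come from prior sampling.  The bistable pick prefers
    shallow, balanced potential barriers, so that both wells are visited and
    visible in stochastic simulations on simulable time scales.  The
    NOISE_INDUCED pick maximises the visibility (second-mode prominence) of
    phi_x among sampled noise-induced thetas; if none reaches
    ``min_visibility``, a continuation fallback drives a bistable theta
    through its lower saddle-node by scaling B2 down.  Raises if a requested
    class cannot be found within budget (draws).
    """
    from .reference import DEFAULT_PRIOR_RANGES
    if ranges is None:
        ranges = PriorRanges(DEFAULT_PRIOR_RANGES)
    if x_THR is None:
        p0 = ModelParams(theta=ranges.sample(np.random.default_rng(0)),
                         **(constants or {}))
        x_THR = float(np.sqrt(1 + p0.C1) / p0.C2)
    from .landscape import phi_mode_visibility
    rng = np.random.default_rng(seed)
    found: dict[str, dict] = {}
    bistables: list[tuple[dict, float, float]] = []
    ni_best: tuple[float, dict | None] = (0.0, None)
    for _ in range(budget):
        theta = ranges.sample(rng)
        ok, _ = acceptance_filter(theta, constants)
        if not ok:
            continue
        params = ModelParams(theta=theta, **(constants or {}))
        try:
            L = compute_landscape(params, Omega_T=Omega_T, x_THR=x_THR)
        except Exception:
            continue
        lab = L.class_label
        if lab == "BISTABLE":
            bistables.append((theta, L.dU0, L.dU1))
        elif lab == "NOISE_INDUCED":
            Lf = compute_landscape(params, Omega_T=Omega_T, x_THR=x_THR,
                                   x_grid=default_x_grid(params, n=800))
            vis = phi_mode_visibility(Lf)
            if vis >= ni_best[0]:
                ni_best = (vis, theta)
        elif lab in classes_wanted and lab not in found:
            found[lab] = theta
    if bistables and "BISTABLE" in classes_wanted:
        # prefer shallow, balanced barriers: both wells then remain visible
        # and reachable in stochastic simulations at Omega_T ~ 100-200
        feasible = [b for b in bistables
                    if min_barrier <= min(b[1], b[2]) <= 3 * min_barrier]
        if feasible:
            theta_bi = min(feasible, key=lambda b: abs(b[1] - b[2]))[0]
        else:
            theta_bi = max(bistables, key=lambda b: min(b[1], b[2]))[0]
        found["BISTABLE"] = theta_bi

    if "NOISE_INDUCED" in classes_wanted:
        if ni_best[1] is not None and ni_best[0] >= min_visibility:
            found["NOISE_INDUCED"] = ni_best[1]
        elif bistables:
            seed_theta = max(bistables, key=lambda b: min(b[1], b[2]))[0]
            for scale_param in ("B2", "K11", "B8"):
                found_ni = _noise_induced_by_continuation(
                    seed_theta, constants, Omega_T, x_THR, scale_param=scale_param)
                if found_ni is not None:
                    found["NOISE_INDUCED"] = found_ni
                    break
        if "NOISE_INDUCED" not in found and ni_best[1] is not None:
            found["NOISE_INDUCED"] = ni_best[1]

    missing = set(classes_wanted) - set(found)
    if missing:
        raise RuntimeError(f"classes not found within budget: {sorted(missing)}; "
                           f"found {sorted(found)}")
    return {k: found[k] for k in classes_wanted}


def _classify(theta, constants, Omega_T, x_THR):
    params = ModelParams(theta=theta, **(constants or {}))
    return compute_landscape(params, Omega_T=Omega_T, x_THR=x_THR)


def _noise_induced_by_continuation(theta_bi: dict, constants, Omega_T, x_THR,
                                   scale_param: str = "B2", n_scan: int = 80):
    """Scale one parameter down through the lower saddle-node and keep the
    NOISE_INDUCED point with the deepest induced well."""
    lo, hi = 0.3, 1.0
    # bracket the saddle-node: find largest factor where S' has 1 root
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        th = dict(theta_bi, **{scale_param: theta_bi[scale_param] * mid})
        try:
            L = _classify(th, constants, Omega_T, x_THR)
        except Exception:
            lo = mid
            continue
        if len(L.roots_Sprime) >= 3:
            hi = mid
        else:
            lo = mid
    best, best_score = None, 0.0
    for f in np.linspace(lo * 0.95, lo, n_scan):
        th = dict(theta_bi, **{scale_param: theta_bi[scale_param] * f})
        try:
            L = _classify(th, constants, Omega_T, x_THR)
        except Exception:
            continue
        if L.class_label == "NOISE_INDUCED":
            score = min(L.dU0, L.dU1)
            if score > best_score:
                best, best_score = th, score
    return best
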