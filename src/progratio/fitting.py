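"""Joint nonlinear least-squares estimation of (T0, k, a, δ).

The running-rate and overall-rate equations are fitted simultaneously to a
rat's per-ratio rate data by minimising the unweighted combined sum of
squared errors

    SSE = Σ_i (R_RUN,obs,i − R_RUN,pred,i)² + Σ_i (R_OVL,obs,i − R_OVL,pred,i)²

over the usable ratios (the first ratio and incomplete ratios are never
fitted).  Two prediction modes are provided:

``conditioned`` (default)
    each ratio's predictions use the *observed* previous total
    inter-reinforcement time, the direct reading of the rate equations;
``recursive``
    predictions use the model's own forward recursion, seeded with the
    observed total time of the (excluded) first ratio when available.

Goodness of the combined fit is expressed as R² = 1 − SSE/SST with SST, by
default, the sum over both rate series of squared deviations about each
series' own mean (a pooled grand-mean convention is selectable).

The objective is smooth but mildly nonconvex, so the optimiser is restarted
from seeded Latin-hypercube draws across the parameter bounds (log-spaced
for a and δ) plus one data-driven start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import ArgumentError, ConvergenceError, FitError, UndefinedR2Error
from .extract import prepare_fit_table
from .model import ParamSet

#: Generous physical bounds (seconds where dimensional): T0, k, a, delta.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t0": (0.0, 60.0),
    "k": (0.0, 2.0),
    "a": (0.1, 3600.0),
    "delta": (0.01, 10.0),
}

_PARAM_ORDER = ("t0", "k", "a", "delta")
_LOG_SCALED = ("a", "delta")  # sampled log-uniformly for multistart


@dataclass
class FitResult:
    """Estimated parameters plus goodness-of-fit and diagnostics."""

    params: ParamSet
    r2: float
    sse: float
    n_points: int
    mode: str
    converged: bool
    multistart_dispersion: float
    at_bounds: tuple[str, ...] = ()
    sst_convention: str = "per_series"

    def to_dict(self) -> dict:
        return {
            "t0": self.params.t0,
            "k": self.params.k,
            "a": self.params.a,
            "delta": self.params.delta,
            "r2": self.r2,
            "sse": self.sse,
            "n_points": self.n_points,
            "mode": self.mode,
            "converged": self.converged,
        }


def goodness_r2(
    obs_series: Sequence[np.ndarray],
    pred_series: Sequence[np.ndarray],
    sst: str = "per_series",
) -> float:
    """Combined R² = 1 − SSE/SST over several observed/predicted series.

    ``sst="per_series"``: SST sums squared deviations of each series about
    its own mean; ``sst="pooled"``: about the grand mean of all points.
    """
    if len(obs_series) != len(pred_series):
        raise ArgumentError("obs and pred must have the same number of series")
    obs = [np.asarray(o, dtype=float) for o in obs_series]
    pred = [np.asarray(p, dtype=float) for p in pred_series]
    for o, p in zip(obs, pred):
        if o.shape != p.shape:
            raise ArgumentError("each obs/pred series pair must have equal length")
    if sum(o.size for o in obs) < 2:
        raise ArgumentError("need at least 2 points")
    sse = sum(float(np.sum((o - p) ** 2)) for o, p in zip(obs, pred))
    if sst == "per_series":
        tot = sum(float(np.sum((o - o.mean()) ** 2)) for o in obs)
    elif sst == "pooled":
        grand = np.mean(np.concatenate(obs))
        tot = sum(float(np.sum((o - grand) ** 2)) for o in obs)
    else:
        raise ArgumentError(f"unknown sst convention {sst!r}")
    if tot == 0:
        raise UndefinedR2Error("total sum of squares is zero; R^2 undefined")
    return 1.0 - sse / tot


def _conditioned_predictions(
    theta: np.ndarray, n: np.ndarray, tp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    t0, k, a, d = theta
    factor = 1.0 + tp / a
    r_run = 1.0 / (d * factor)
    t_tot = t0 + k * tp + n * d * factor
    return r_run, n / t_tot


def _recursive_predictions(
    theta: np.ndarray, n: np.ndarray, t_seed: float
) -> tuple[np.ndarray, np.ndarray]:
    t0, k, a, d = theta
    r_run = np.empty_like(n, dtype=float)
    r_ovl = np.empty_like(n, dtype=float)
    t_state = t_seed
    for i in range(n.size):
        factor = 1.0 + t_state / a
        r_run[i] = 1.0 / (d * factor)
        t_tot = t0 + k * t_state + n[i] * d * factor
        r_ovl[i] = n[i] / t_tot
        t_state = t_tot
    return r_run, r_ovl


def _heuristic_start(table: pd.DataFrame, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    usable = table[table["usable"]]
    delta0 = 1.0 / float(np.nanmax(usable["r_run"]))
    a0 = float(np.nanmedian(usable["ttot_prev_s"]))
    prp = usable["prp_s"] if "prp_s" in usable else pd.Series([1.0])
    t00 = float(np.nanmin(prp)) if np.isfinite(prp).any() else 1.0
    x0 = np.array([t00, 0.5, a0, delta0])
    return np.clip(x0, lo, hi)


def _lhs_starts(
    n_starts: int, lo: np.ndarray, hi: np.ndarray, seed: int | None
) -> np.ndarray:
    if n_starts <= 0:
        return np.empty((0, 4))
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n_starts)
    starts = np.empty_like(u)
    for j, name in enumerate(_PARAM_ORDER):
        if name in _LOG_SCALED:
            starts[:, j] = np.exp(np.log(lo[j]) + u[:, j] * (np.log(hi[j]) - np.log(lo[j])))
        else:
            starts[:, j] = lo[j] + u[:, j] * (hi[j] - lo[j])
    return starts


def fit(
    table: pd.DataFrame,
    mode: str = "conditioned",
    bounds: Mapping[str, tuple[float, float]] | None = None,
    multistart: int = 16,
    seed: int | None = None,
    sst: str = "per_series",
) -> FitResult:
    """Fit the four-parameter model to one rat×condition's rate table.

    ``table`` comes from :func:`progratio.extract.prepare_fit_table`.  At
    least five usable points are required (more points than parameters).
    Returns the lowest-SSE solution over all starts; exact SSE ties are
    broken toward the lowest a.
    """
    if mode not in ("conditioned", "recursive"):
        raise ArgumentError(f"unknown fit mode {mode!r}")
    if multistart < 1:
        raise ArgumentError("multistart must be >= 1")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[p][0] for p in _PARAM_ORDER])
    hi = np.array([b[p][1] for p in _PARAM_ORDER])

    usable = table[table["usable"]].sort_values("ratio_index")
    if len(usable) < 5:
        raise FitError(f"need at least 5 usable points, got {len(usable)}")
    n = usable["n"].to_numpy(dtype=float)
    tp = usable["ttot_prev_s"].to_numpy(dtype=float)
    obs_run = usable["r_run"].to_numpy(dtype=float)
    obs_ovl = usable["r_overall"].to_numpy(dtype=float)

    if mode == "recursive":
        if usable["ratio_index"].duplicated().any():
            raise ArgumentError("recursive mode requires one point per ratio index")
        first = table[table["ratio_index"] == 1]
        t_seed = float(first["ttot_s"].iloc[0]) if len(first) and np.isfinite(
            first["ttot_s"].iloc[0]
        ) else 0.0

        def predict(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return _recursive_predictions(theta, n, t_seed)

    else:

        def predict(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return _conditioned_predictions(theta, n, tp)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pr, po = predict(theta)
        return np.concatenate((obs_run - pr, obs_ovl - po))

    starts = [_heuristic_start(table, lo, hi)]
    starts.extend(_lhs_starts(multistart - 1, lo, hi, seed))
    solutions: list[tuple[float, np.ndarray]] = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if np.all(np.isfinite(res.x)) and np.isfinite(res.cost):
            solutions.append((float(np.sum(res.fun**2)), res.x))
    if not solutions:
        raise ConvergenceError(
            f"all {len(starts)} optimisation starts failed (mode={mode}, n_points={len(usable)})"
        )
    best_sse = min(s for s, _ in solutions)
    near = [x for s, x in solutions if s <= best_sse * (1 + 1e-9) + 1e-15]
    x_best = min(near, key=lambda x: x[2])  # tie-break: lowest a
    sse_best = float(np.sum(residuals(x_best) ** 2))

    top = [x for s, x in solutions if s <= best_sse * 1.01 + 1e-12]
    top_arr = np.array(top)
    denom = np.maximum(np.abs(x_best), 1e-12)
    dispersion = float(np.max((top_arr.max(axis=0) - top_arr.min(axis=0)) / denom))

    at_bounds = tuple(
        name
        for j, name in enumerate(_PARAM_ORDER)
        if (x_best[j] - lo[j]) <= 1e-3 * max(lo[j], 1e-9) and lo[j] > 0
        or (hi[j] - x_best[j]) <= 1e-3 * hi[j]
    )
    pr, po = predict(x_best)
    try:
        r2 = goodness_r2([obs_run, obs_ovl], [pr, po], sst=sst)
    except UndefinedR2Error:
        r2 = np.nan
    params = ParamSet(t0=max(x_best[0], 0.0), k=max(x_best[1], 0.0), a=x_best[2], delta=x_best[3])
    return FitResult(
        params=params,
        r2=float(r2),
        sse=sse_best,
        n_points=int(2 * len(usable)),
        mode=mode,
        converged=True,
        multistart_dispersion=dispersion,
        at_bounds=at_bounds,
        sst_convention=sst,
    )


def fit_per_rat(
    records: pd.DataFrame,
    last_n_sessions: int = 10,
    method: str = "average",
    mode: str = "conditioned",
    bounds: Mapping[str, tuple[float, float]] | None = None,
    multistart: int = 16,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit every rat×condition in a multi-session record table.

    ``records`` comes from :func:`progratio.extract.extract_sessions`.
    Returns one row per rat×condition with the estimated parameters, R²,
    SSE and fit metadata.  Per-fit optimiser seeds derive deterministically
    from ``seed``.
    """
    keys = records[["rat_id", "group", "condition"]].drop_duplicates()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(keys)) % (2**31)
    rows = []
    for (rat, group, cond), fit_seed in zip(
        keys.itertuples(index=False, name=None), child_seeds
    ):
        sub = records[(records["rat_id"] == rat) & (records["condition"] == cond)]
        table = prepare_fit_table(sub, last_n_sessions=last_n_sessions, method=method)
        result = fit(
            table, mode=mode, bounds=bounds, multistart=multistart, seed=int(fit_seed)
        )
        rows.append(
            {"rat_id": rat, "group": group, "condition": cond, **result.to_dict()}
        )
    return pd.DataFrame(rows)
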