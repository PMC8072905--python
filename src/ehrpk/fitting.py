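"""Per-subject maximum-likelihood estimation and AIC model selection.

The observation model is proportional: C_obs = C_pred(theta) * (1 + eps),
eps ~ N(0, sigma^2). For one subject with n quantifiable observations

    -2LL(theta, sigma) = sum_j [ log(2 pi sigma^2 C_pred_j^2)
                                 + (C_obs_j - C_pred_j)^2 / (sigma^2 C_pred_j^2) ]

sigma is profiled analytically: given residuals, the ML value is
sigma_hat^2 = mean(((C_obs - C_pred)/C_pred)^2), subject to a small floor
(default 1e-6 proportional CV) that keeps the objective bounded on
noise-free data. Structural parameters are optimized on the log scale
(positivity, conditioning) from multiple seeded start points; BLQ records
are excluded from the likelihood.

AIC = -2LL + 2p counts every estimated structural parameter plus sigma;
fixed design quantities (n_transit, t_lag, released_fraction, dose) are not
counted. Model selection uses the "reduction of AIC >= 2 is significant"
rule: the lowest-AIC candidate is selected only when it beats the runner-up
by at least 2; otherwise the candidates are flagged indistinguishable and
the most parsimonious of the near-tied set is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import SubjectDataset
from .model import (FREE_PARAMETERS, ModelParams, ModelStructureError, Route,
                    SolverConfig, ehr_fraction, reference_params,
                    simulate_profile)

__all__ = ["FitConfig", "FitResult", "StartRecord", "SelectionResult",
           "neg2_loglik", "profiled_sigma", "fit_subject", "fit_pooled",
           "aic", "select_model", "scan_transit_number", "summarize_cohort"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitConfig:
    """Controls one maximum-likelihood fit.

    fixed           structural parameters to hold at a given value (by flat
                    name); they are removed from the estimated set and from
                    the AIC parameter count
    bounds          (lower, upper) on every free parameter's natural scale
    n_starts        number of start points: the initial guess plus seeded
                    log-uniform perturbations of it by up to x/÷ perturb_factor
    tol             objective tolerance passed to the optimizer
    sigma_floor     lower bound on the profiled proportional SD
    polish          refine the best start with a Nelder-Mead pass
    """

    n_starts: int = 10
    perturb_factor: float = 3.0
    bounds: tuple[float, float] = (1e-4, 1e4)
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    sigma_floor: float = 1e-6
    fixed: dict[str, float] = field(default_factory=dict)
    polish: bool = True
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError("bounds must be positive with lower < upper")


@dataclass(frozen=True)
class StartRecord:
    """Outcome of one optimization start."""
    start_index: int
    x0: tuple[float, ...]
    objective: float
    success: bool
    message: str
    n_evaluations: int


@dataclass
class FitResult:
    """Best maximum-likelihood fit for one subject."""

    subject_id: str
    route: Route
    params: ModelParams          # includes the fitted (profiled) sigma
    neg2ll: float
    aic: float
    p: int                       # estimated parameter count incl. sigma
    n_obs: int
    converged: bool
    predictions: pd.DataFrame    # time_h, observed, predicted, iwres
    free_names: tuple[str, ...]
    starts: list[StartRecord] = field(default_factory=list, repr=False)
    best_start: int = 0
    data_checksum: str = ""

    def estimates(self) -> dict[str, float]:
        out = {name: self.params.get(name) for name in self.free_names}
        out["sigma"] = self.params.sigma
        return out


def profiled_sigma(observed: np.ndarray, predicted: np.ndarray,
                   floor: float = 1e-6) -> float:
    """Closed-form joint-ML proportional SD given residuals (floored)."""
    rel = (observed - predicted) / predicted
    return float(max(np.sqrt(np.mean(rel ** 2)), floor))


def _neg2ll_terms(observed: np.ndarray, predicted: np.ndarray,
                  sigma: float) -> float:
    s2 = sigma * sigma
    rel2 = ((observed - predicted) / predicted) ** 2
    return float(np.sum(_LOG_2PI + np.log(s2 * predicted ** 2) + rel2 / s2))


def neg2_loglik(params: ModelParams, data: SubjectDataset,
                sigma: float | str = "profile",
                solver: SolverConfig | None = None,
                sigma_floor: float = 1e-6) -> float:
    """-2 log-likelihood of the quantifiable records under the proportional
    error model.

    ``sigma="profile"`` (default) plugs in the analytic joint-ML value;
    a float fixes sigma; ``None`` uses ``params.sigma``. Returns +inf when
    any prediction at an observation time is nonpositive (optimizer-safe).
    """
    obs_df = data.observed()
    times = obs_df["time_h"].to_numpy()
    observed = obs_df["conc_ng_ml"].to_numpy()
    if times.size == 0:
        raise ValueError("no quantifiable observations to fit")
    predicted = simulate_profile(params, data.schedule, times, solver)
    if not np.all(np.isfinite(predicted)) or np.any(predicted <= 0):
        return math.inf
    if sigma == "profile":
        s = profiled_sigma(observed, predicted, sigma_floor)
    elif sigma is None:
        s = params.sigma
    else:
        s = float(sigma)
    if s <= 0:
        raise ValueError("sigma must be > 0")
    return _neg2ll_terms(observed, predicted, s)


def aic(neg2ll: float, p: int) -> float:
    """Akaike information criterion, -2LL + 2p (p >= 1)."""
    if p < 1:
        raise ValueError("parameter count p must be >= 1")
    return neg2ll + 2 * p


def _free_names(route: Route, fixed: dict[str, float]) -> tuple[str, ...]:
    names = [n for n in FREE_PARAMETERS[Route(route)] if n not in fixed]
    return tuple(names)


def _build_params(base: ModelParams, names: tuple[str, ...],
                  x_nat: np.ndarray) -> ModelParams:
    return base.with_values(**dict(zip(names, x_nat)))


def _group_predictions(params: ModelParams, groups, solver):
    """Predictions per group; subjects sharing (dose, times) share one
    simulation (replicate designs are common in pooled fits)."""
    cache: dict[tuple, np.ndarray] = {}
    preds = []
    for data, times, _ in groups:
        key = (data.dose_mg_kg, times.tobytes())
        if key not in cache:
            cache[key] = simulate_profile(params, data.schedule, times,
                                          solver)
        preds.append(cache[key])
    return preds


def _make_objective(base: ModelParams, names: tuple[str, ...],
                    groups: list[tuple[SubjectDataset, np.ndarray, np.ndarray]],
                    cfg: FitConfig):
    """Objective over log-parameters; ``groups`` holds (data, times, obs)
    per subject, pooled with a common profiled sigma."""
    observed = np.concatenate([g[2] for g in groups])

    def objective(x_log: np.ndarray) -> float:
        try:
            params = _build_params(base, names, np.exp(x_log))
            preds = _group_predictions(params, groups, cfg.solver)
        except Exception:
            return math.inf
        predicted = np.concatenate(preds)
        if not np.all(np.isfinite(predicted)) or np.any(predicted <= 0):
            return math.inf
        s = profiled_sigma(observed, predicted, cfg.sigma_floor)
        return _neg2ll_terms(observed, predicted, s)

    return objective


def _optimize(objective, x0: np.ndarray, cfg: FitConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, float, list[StartRecord]]:
    lo, hi = np.log(cfg.bounds[0]), np.log(cfg.bounds[1])
    bounds = [(lo, hi)] * x0.size
    starts = [x0]
    spread = math.log(cfg.perturb_factor)
    for _ in range(cfg.n_starts - 1):
        starts.append(np.clip(x0 + rng.uniform(-spread, spread, x0.size),
                              lo, hi))
    records: list[StartRecord] = []
    best_x, best_f = x0, math.inf
    for i, xs in enumerate(starts):
        res = minimize(objective, xs, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": cfg.max_iter, "ftol": cfg.tol,
                                "gtol": 1e-10})
        f = float(res.fun)
        records.append(StartRecord(i, tuple(xs), f, bool(res.success),
                                   str(res.message), int(res.nfev)))
        if f < best_f:
            best_f, best_x = f, res.x
    if cfg.polish and np.isfinite(best_f):
        res = minimize(objective, best_x, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10,
                                "fatol": cfg.tol})
        if float(res.fun) < best_f:
            best_f, best_x = float(res.fun), res.x
        res2 = minimize(objective, best_x, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": cfg.max_iter, "ftol": cfg.tol,
                                 "gtol": 1e-12})
        if float(res2.fun) < best_f:
            best_f, best_x = float(res2.fun), res2.x
    return np.asarray(best_x), best_f, records


def _finalize(subject_id: str, route: Route, base: ModelParams,
              names: tuple[str, ...], x_log: np.ndarray, cfg: FitConfig,
              groups, checksum: str) -> FitResult:
    params = _build_params(base, names, np.exp(x_log))
    all_rows = []
    all_obs, all_pred = [], []
    preds_by_group = _group_predictions(params, groups, cfg.solver)
    for (data, times, observed), pred in zip(groups, preds_by_group):
        all_obs.append(observed)
        all_pred.append(pred)
        all_rows.append(pd.DataFrame({
            "subject_id": data.subject_id, "time_h": times,
            "observed": observed, "predicted": pred}))
    observed = np.concatenate(all_obs)
    predicted = np.concatenate(all_pred)
    sigma_hat = profiled_sigma(observed, predicted, cfg.sigma_floor)
    params = replace(params, sigma=sigma_hat)
    preds = pd.concat(all_rows, ignore_index=True)
    preds["iwres"] = (preds["observed"] - preds["predicted"]) / (
        sigma_hat * preds["predicted"])
    n2ll = _neg2ll_terms(observed, predicted, sigma_hat)
    p = len(names) + 1
    return FitResult(subject_id=subject_id, route=Route(route), params=params,
                     neg2ll=n2ll, aic=aic(n2ll, p), p=p, n_obs=observed.size,
                     converged=True, predictions=preds, free_names=names,
                     data_checksum=checksum)


def _prepare_groups(datasets: list[SubjectDataset], route: Route):
    groups = []
    for data in datasets:
        if Route(data.route) is not Route(route):
            raise ModelStructureError(
                f"subject {data.subject_id} is {data.route}, expected {route}")
        obs = data.observed()
        groups.append((data, obs["time_h"].to_numpy(),
                       obs["conc_ng_ml"].to_numpy()))
    return groups


def fit_subject(data: SubjectDataset, route: Route | None = None,
                cfg: FitConfig | None = None,
                init: ModelParams | None = None) -> FitResult:
    """Maximum-likelihood fit of one subject's EHR model.

    Optimizes the profiled -2LL over log-scale parameters from
    ``cfg.n_starts`` start points (the initial guess plus seeded
    perturbations); the reported fit is the best start after polishing.
    Deterministic given ``cfg.seed`` and the data.
    """
    route = Route(route) if route is not None else Route(data.route)
    cfg = cfg or FitConfig()
    base = init if init is not None else reference_params(route)
    if Route(base.route) is not route:
        raise ModelStructureError("init params route mismatch")
    if cfg.fixed:
        base = base.with_values(**cfg.fixed)
    names = _free_names(route, cfg.fixed)
    p = len(names) + 1
    if data.n_observed < p:
        raise ValueError(
            f"subject {data.subject_id}: {data.n_observed} quantifiable "
            f"points cannot identify {p} parameters")
    groups = _prepare_groups([data], route)
    objective = _make_objective(base, names, groups, cfg)
    x0 = np.log([base.get(n) for n in names])
    rng = np.random.default_rng(cfg.seed)
    x_best, f_best, records = _optimize(objective, x0, cfg, rng)
    if not math.isfinite(f_best):
        statuses = "; ".join(f"start {r.start_index}: {r.message}"
                             for r in records)
        raise RuntimeError(f"no start converged for {data.subject_id}: "
                           f"{statuses}")
    result = _finalize(data.subject_id, route, base, names, x_best, cfg,
                       groups, data.checksum())
    result.starts = records
    result.best_start = int(np.argmin([r.objective for r in records]))
    result.converged = any(r.success for r in records)
    return result


def fit_pooled(datasets: list[SubjectDataset], route: Route | None = None,
               cfg: FitConfig | None = None,
               init: ModelParams | None = None) -> FitResult:
    """Naive pooled fit: one parameter vector for all subjects, residuals
    pooled under a single profiled sigma."""
    if not datasets:
        raise ValueError("no datasets")
    route = Route(route) if route is not None else Route(datasets[0].route)
    cfg = cfg or FitConfig()
    base = init if init is not None else reference_params(route)
    if cfg.fixed:
        base = base.with_values(**cfg.fixed)
    names = _free_names(route, cfg.fixed)
    p = len(names) + 1
    groups = _prepare_groups(datasets, route)
    n_obs = sum(g[2].size for g in groups)
    if n_obs < p:
        raise ValueError("fewer pooled observations than parameters")
    objective = _make_objective(base, names, groups, cfg)
    x0 = np.log([base.get(n) for n in names])
    rng = np.random.default_rng(cfg.seed)
    x_best, f_best, records = _optimize(objective, x0, cfg, rng)
    if not math.isfinite(f_best):
        raise RuntimeError("no start converged for pooled fit")
    checksum = "+".join(d.checksum() for d in datasets)
    result = _finalize("pooled", route, base, names, x_best, cfg, groups,
                       checksum)
    result.starts = records
    result.converged = any(r.success for r in records)
    return result


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of AIC-based model selection on one subject's data."""
    ranking: tuple[str, ...]        # labels, best AIC first
    aics: dict[str, float]
    selected: str
    significant: bool               # best beat the runner-up by >= 2
    delta_aic: float                # runner-up AIC minus best AIC


def select_model(candidates: dict[str, FitResult]) -> SelectionResult:
    """Rank candidate fits of the *same* data by AIC.

    The lowest-AIC candidate is selected when it beats the runner-up by at
    least 2 (a significant reduction); otherwise the near-tied candidates
    (within 2 of the best) are indistinguishable and the one with the
    fewest parameters is selected.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    checksums = {fit.data_checksum for fit in candidates.values()}
    if len(checksums) != 1:
        raise ModelStructureError(
            "candidates were fitted on different data")
    order = sorted(candidates, key=lambda k: candidates[k].aic)
    best, runner = order[0], order[1]
    delta = candidates[runner].aic - candidates[best].aic
    if delta >= 2.0:
        selected, significant = best, True
    else:
        near = [k for k in order
                if candidates[k].aic - candidates[best].aic < 2.0]
        selected = min(near, key=lambda k: (candidates[k].p,
                                            candidates[k].aic))
        significant = False
    return SelectionResult(ranking=tuple(order),
                           aics={k: candidates[k].aic for k in order},
                           selected=selected, significant=significant,
                           delta_aic=delta)


def scan_transit_number(data: SubjectDataset, route: Route | None = None,
                        n_values: range | list[int] = range(1, 11),
                        cfg: FitConfig | None = None,
                        init: ModelParams | None = None
                        ) -> tuple[pd.DataFrame, int | None]:
    """Refit with the transit-compartment count fixed at each value.

    Returns the per-n table (n_transit, neg2ll, aic, converged, error) and
    the AIC-argmin n (None if every fit failed). Individual fit failures
    are recorded without aborting the scan.
    """
    route = Route(route) if route is not None else Route(data.route)
    if route is Route.IV:
        raise ModelStructureError("IV model has no transit absorption")
    cfg = cfg or FitConfig()
    base = init if init is not None else reference_params(route)
    rows = []
    for n in n_values:
        row = {"n_transit": int(n), "neg2ll": np.nan, "aic": np.nan,
               "converged": False, "error": ""}
        try:
            b = replace(base, absorp=replace(base.absorp, n_transit=int(n)))
            fit = fit_subject(data, route, cfg, init=b)
            row.update(neg2ll=fit.neg2ll, aic=fit.aic,
                       converged=fit.converged)
        except Exception as exc:  # noqa: BLE001 - per-n failures recorded
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["aic"].notna().any():
        best_n = int(table.loc[table["aic"].idxmin(), "n_transit"])
    else:
        best_n = None
    return table, best_n


def summarize_cohort(fits: list[FitResult]) -> pd.DataFrame:
    """Mean +/- sample SD of the estimates across one route's subjects.

    EHR%% is computed per animal and then averaged. Rows: each estimated
    parameter, sigma, ehr_pct, neg2ll, aic; columns: mean, sd, n.
    A single subject yields sd 0.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    routes = {f.route for f in fits}
    if len(routes) != 1:
        raise ModelStructureError("cannot summarize mixed routes")
    rows: dict[str, list[float]] = {}
    for f in fits:
        est = f.estimates()
        est["ehr_pct"] = ehr_fraction(f.params)
        est["neg2ll"] = f.neg2ll
        est["aic"] = f.aic
        for k, v in est.items():
            rows.setdefault(k, []).append(v)
    out = []
    for name, vals in rows.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out.append({"parameter": name, "mean": float(np.mean(arr)),
                    "sd": sd, "n": arr.size})
    return pd.DataFrame(out).set_index("parameter")
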