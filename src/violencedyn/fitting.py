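"""Two-stage least-squares calibration of the base model.

Stage 1 fits the uncoupled aggressor logistic (``r_A``, ``k_A`` and the
initial level ``A0``) to the aggressor target series using the closed
form.  Stage 2 freezes those and estimates the remaining six rates
(``r_S, k_S, beta_M, beta_F, alpha_M, alpha_F``) together with the
initial conditions of the coupled compartments by trust-region
nonlinear least squares on the integrated trajectory, with the victim
death rates bounded above (by 1, by default) to exclude degenerate
solutions with extreme mortality.

Residual blocks (susceptibles and the two victim series) are normalized
by each block's data mean by default, so the ~0.1-million victim series
are not drowned by the ~50-million susceptible series.  The last
observation year (2023 for the national dataset) is excluded from the
objective and used for holdout validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import ScenarioSeries
from .model import IntegrationError, ModelParams, StateVec, TimeGrid, aggressor_closed_form, integrate

__all__ = [
    "FitConfig",
    "AggressorFit",
    "FitResult",
    "FitError",
    "fit_aggressor_logistic",
    "fit_full_model",
    "validate_holdout",
    "compare_fit_quality",
]

_PENALTY = 1e6
_STAGE2_PARAMS = ("r_S", "k_S", "beta_M", "beta_F", "alpha_M", "alpha_F")


class FitError(RuntimeError):
    """Raised when the optimizer cannot produce any converged fit."""


@dataclass(frozen=True)
class FitConfig:
    """Options for the two-stage estimation.

    ``bounds`` maps parameter names to ``(lower, upper)`` and overrides
    the defaults; ``alpha_upper`` caps both death rates (the published
    analysis bounds them at 1/year).  ``residual_blocks`` selects which
    observed series enter the stage-2 objective and ``normalization``
    how each block is scaled (``none`` raw, ``mean`` by the block data
    mean, ``std`` by its standard deviation).  ``multistart`` counts the
    optimizer starts (the first is a data-driven heuristic, the rest
    Latin-hypercube draws seeded by ``seed``).
    """

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    alpha_upper: float = 1.0
    optimize_initial_conditions: bool = True
    residual_blocks: tuple[str, ...] = ("S", "V_M", "V_F")
    normalization: str = "mean"
    multistart: int = 8
    seed: int = 0
    ic_bracket: tuple[float, float] = (0.25, 4.0)
    rtol: float = 1e-10
    atol: float = 1e-12
    max_nfev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.normalization not in ("none", "mean", "std"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        bad = set(self.residual_blocks) - {"S", "V_M", "V_F"}
        if bad:
            raise ValueError(f"unknown residual blocks: {sorted(bad)}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        if not 0 < self.alpha_upper <= 1.0 + 1e-12:
            # the bound exists to exclude extreme death rates; allow <= 1
            raise ValueError("alpha_upper must be in (0, 1]")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class AggressorFit:
    """Stage-1 logistic fit of the aggressor series."""

    r_A: float
    k_A: float
    A0: float
    rmse: float
    identifiable: bool = True
    diagnostics: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters, optimized initial state and fit metrics.

    ``rmse_blocks`` holds per-block RMSE on the fit years in data units
    (millions); ``rmse_blocks_normalized`` the same after the block
    normalization used in the objective.  ``holdout`` is populated by
    :func:`validate_holdout` (relative error per compartment at each
    held-out year).
    """

    params: ModelParams
    state0: StateVec
    t0: float
    fit_years: tuple[int, ...]
    rmse_blocks: dict
    rmse_blocks_normalized: dict
    aggressor_fit: AggressorFit
    diagnostics: dict = field(compare=False, default_factory=dict)
    holdout: Optional[dict] = None

    @property
    def victim_rmse_normalized(self) -> float:
        """Root mean square of the stacked normalized victim residuals."""
        vals = [self.rmse_blocks_normalized[b] for b in ("V_M", "V_F")
                if b in self.rmse_blocks_normalized]
        return float(np.sqrt(np.mean(np.square(vals))))

    def with_holdout(self, holdout: dict) -> "FitResult":
        return dataclasses.replace(self, holdout=holdout)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "state0": {"A": self.state0.A, "S": self.state0.S,
                       "V_M": self.state0.V_M, "V_F": self.state0.V_F},
            "t0": self.t0,
            "fit_years": list(self.fit_years),
            "rmse_blocks": self.rmse_blocks,
            "rmse_blocks_normalized": self.rmse_blocks_normalized,
            "aggressor_fit": {"r_A": self.aggressor_fit.r_A,
                              "k_A": self.aggressor_fit.k_A,
                              "A0": self.aggressor_fit.A0,
                              "rmse": self.aggressor_fit.rmse,
                              "identifiable": self.aggressor_fit.identifiable},
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool))},
            "holdout": self.holdout,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FitResult":
        payload = json.loads(Path(path).read_text())
        holdout = payload.get("holdout")
        if holdout and "relative_error" in holdout:
            # JSON stringifies the integer year keys
            holdout["relative_error"] = {
                int(y): v for y, v in holdout["relative_error"].items()
            }
        agg = payload["aggressor_fit"]
        return cls(
            params=ModelParams.from_mapping(payload["params"]),
            state0=StateVec(**payload["state0"]),
            t0=float(payload["t0"]),
            fit_years=tuple(payload["fit_years"]),
            rmse_blocks=payload["rmse_blocks"],
            rmse_blocks_normalized=payload["rmse_blocks_normalized"],
            aggressor_fit=AggressorFit(r_A=agg["r_A"], k_A=agg["k_A"],
                                       A0=agg["A0"], rmse=agg["rmse"],
                                       identifiable=agg["identifiable"]),
            diagnostics=payload.get("diagnostics", {}),
            holdout=holdout,
        )


# ---------------------------------------------------------------------------
# stage 1


def fit_aggressor_logistic(series: ScenarioSeries, cfg: FitConfig) -> AggressorFit:
    """Least-squares logistic fit ``(r_A, k_A, A0)`` to the aggressor targets.

    A constant series is a degenerate logistic (any growth rate fits at
    ``A0 = k_A``); it is detected and returned with ``identifiable=False``
    and ``r_A = 0``.
    """
    frame = series.fit_frame
    if len(frame) < 3:
        raise FitError("aggressor fit needs at least 3 fit years")
    years = frame.index.to_numpy(dtype=float)
    obs = frame["A_obs"].to_numpy(dtype=float)
    t = years - years[0]

    mean = float(np.mean(obs))
    if mean <= 0:
        raise FitError("aggressor series must be positive")
    if float(np.std(obs)) / mean < 1e-12:
        return AggressorFit(r_A=0.0, k_A=mean, A0=mean, rmse=0.0,
                            identifiable=False,
                            diagnostics={"message": "constant series: r_A unidentifiable"})

    def residual(x: np.ndarray) -> np.ndarray:
        p = ModelParams(r_A=x[0], k_A=x[1], r_S=0, k_S=1,
                        beta_F=0, beta_M=0, alpha_F=0, alpha_M=0)
        return aggressor_closed_form(x[2], p, t) - obs

    # crude growth-rate guess from the end-to-end log ratio
    r0 = max(np.log(obs[-1] / obs[0]) / max(t[-1], 1.0), 1e-3)
    lo = np.array([1e-6, obs.max() * 0.5, obs[0] * 0.1])
    hi = np.array([2.0, obs.max() * 50.0, obs[0] * 10.0])
    starts = [np.array([r0, 2.0 * obs.max(), obs[0]])]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.multistart - 1):
        u = rng.random(3)
        starts.append(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))

    best = None
    for x0 in starts:
        sol = least_squares(residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                            method="trf", x_scale="jac",
                            ftol=1e-15, xtol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.status <= 0:
        raise FitError(f"aggressor fit did not converge: {best and best.message}")
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    return AggressorFit(
        r_A=float(best.x[0]), k_A=float(best.x[1]), A0=float(best.x[2]),
        rmse=rmse,
        diagnostics={"cost": float(best.cost), "nfev": int(best.nfev),
                     "status": int(best.status), "message": best.message},
    )


# ---------------------------------------------------------------------------
# stage 2


def _default_bounds(series: ScenarioSeries, cfg: FitConfig) -> dict[str, tuple[float, float]]:
    frame = series.fit_frame
    s_max = float(frame["S_obs"].max())
    bounds = {
        "r_S": (1e-6, 2.0),
        "k_S": (s_max * 0.5, s_max * 50.0),
        "beta_M": (1e-10, 1e-1),
        "beta_F": (1e-10, 1e-1),
        "alpha_M": (1e-6, cfg.alpha_upper),
        "alpha_F": (1e-6, cfg.alpha_upper),
    }
    bounds.update(cfg.bounds)
    return bounds


def _heuristic_start(series: ScenarioSeries, agg: AggressorFit,
                     bounds: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Data-driven initial guess.

    k_S slightly above the largest observed susceptible level, r_S at the
    aggressor growth rate (both compartments track percentages of the
    same population so their growth rates are comparable), death rates
    at mid-bound, and the betas from the quasi-equilibrium balance
    ``beta_i ~ alpha_i * mean(V_i) / mean(A * S)``.
    """
    frame = series.fit_frame
    a = frame["A_obs"].to_numpy()
    s = frame["S_obs"].to_numpy()
    contact = float(np.mean(a * s))
    alpha0 = 0.5 * bounds["alpha_M"][1]
    start = {
        "r_S": max(agg.r_A, 1e-3),
        "k_S": 1.2 * float(s.max()),
        "beta_M": alpha0 * float(frame["V_M_obs"].mean()) / contact,
        "beta_F": alpha0 * float(frame["V_F_obs"].mean()) / contact,
        "alpha_M": alpha0,
        "alpha_F": alpha0,
    }
    return {k: float(np.clip(v, *bounds[k])) for k, v in start.items()}


def fit_full_model(
    series: ScenarioSeries,
    aggressor_fit: AggressorFit,
    cfg: Optional[FitConfig] = None,
) -> FitResult:
    """Stage-2 trust-region least squares for the coupled compartments.

    ``r_A``, ``k_A`` and the aggressor initial level are frozen at the
    stage-1 values.  The decision vector holds the six remaining rates
    plus, by default, the initial S, V_M and V_F levels, bracketed to
    ``ic_bracket`` x the first observation.  Integration failures during
    a trial are penalized, not fatal; the best of ``multistart`` starts
    wins.  Fits are deterministic given (config, seed).
    """
    cfg = cfg or FitConfig()
    frame = series.fit_frame
    years = frame.index.to_numpy(dtype=float)
    grid = TimeGrid(t0=years[0], times=tuple(years))
    bounds = _default_bounds(series, cfg)

    obs = {
        "S": frame["S_obs"].to_numpy(dtype=float),
        "V_M": frame["V_M_obs"].to_numpy(dtype=float),
        "V_F": frame["V_F_obs"].to_numpy(dtype=float),
    }
    norms = {}
    for block in cfg.residual_blocks:
        if cfg.normalization == "mean":
            norms[block] = max(float(np.mean(np.abs(obs[block]))), 1e-300)
        elif cfg.normalization == "std":
            norms[block] = max(float(np.std(obs[block])), 1e-300)
        else:
            norms[block] = 1.0

    first = frame.iloc[0]
    ic_names: tuple[str, ...] = ()
    ic_bounds: list[tuple[float, float]] = []
    if cfg.optimize_initial_conditions:
        # A0 stays frozen at the stage-1 estimate: the aggressor series is
        # not part of the stage-2 objective, so re-optimizing A0 here would
        # leave it unconstrained (beta can absorb any rescaling of A)
        lo_f, hi_f = cfg.ic_bracket
        ic_names = ("S0", "V_M0", "V_F0")
        firsts = {"S0": first["S_obs"],
                  "V_M0": first["V_M_obs"], "V_F0": first["V_F_obs"]}
        ic_bounds = [(lo_f * firsts[n], hi_f * firsts[n]) for n in ic_names]

    names = _STAGE2_PARAMS + ic_names
    lo = np.array([bounds[n][0] for n in _STAGE2_PARAMS] + [b[0] for b in ic_bounds])
    hi = np.array([bounds[n][1] for n in _STAGE2_PARAMS] + [b[1] for b in ic_bounds])

    n_fail = 0

    def unpack(x: np.ndarray) -> tuple[ModelParams, StateVec]:
        kv = dict(zip(names, x))
        params = ModelParams(
            r_A=aggressor_fit.r_A, k_A=aggressor_fit.k_A,
            r_S=kv["r_S"], k_S=kv["k_S"],
            beta_F=kv["beta_F"], beta_M=kv["beta_M"],
            alpha_F=kv["alpha_F"], alpha_M=kv["alpha_M"],
        )
        if cfg.optimize_initial_conditions:
            state0 = StateVec(aggressor_fit.A0, kv["S0"], kv["V_M0"], kv["V_F0"])
        else:
            state0 = StateVec(aggressor_fit.A0, first["S_obs"],
                              first["V_M_obs"], first["V_F_obs"])
        return params, state0

    n_res = len(cfg.residual_blocks) * len(years)

    def residual(x: np.ndarray) -> np.ndarray:
        nonlocal n_fail
        params, state0 = unpack(x)
        try:
            traj = integrate("base", state0, params, grid,
                             rtol=cfg.rtol, atol=cfg.atol)
        except (IntegrationError, ValueError):
            n_fail += 1
            return np.full(n_res, _PENALTY)
        parts = [(traj[b].to_numpy() - obs[b]) / norms[b]
                 for b in cfg.residual_blocks]
        return np.concatenate(parts)

    # multistart: heuristic first, then log-space Latin hypercube
    heur = _heuristic_start(series, aggressor_fit, bounds)
    x0_heur = np.array([heur[n] for n in _STAGE2_PARAMS]
                       + [0.5 * (b[0] + b[1]) for b in ic_bounds])
    if cfg.optimize_initial_conditions:
        firsts_arr = np.array([first["S_obs"], first["V_M_obs"], first["V_F_obs"]])
        x0_heur[len(_STAGE2_PARAMS):] = np.clip(firsts_arr, lo[len(_STAGE2_PARAMS):],
                                                hi[len(_STAGE2_PARAMS):])
    starts = [np.clip(x0_heur, lo, hi)]
    if cfg.multistart > 1:
        rng = np.random.default_rng(cfg.seed)
        n_extra = cfg.multistart - 1
        # stratified (Latin hypercube) sample in log space per coordinate
        log_lo, log_hi = np.log(np.maximum(lo, 1e-300)), np.log(hi)
        u = np.empty((n_extra, len(names)))
        for d in range(len(names)):
            u[:, d] = (rng.permutation(n_extra) + rng.random(n_extra)) / n_extra
        for j in range(n_extra):
            starts.append(np.exp(log_lo + u[j] * (log_hi - log_lo)))

    best = None
    history: list[float] = []
    for x0 in starts:
        sol = least_squares(residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                            method="trf", x_scale=np.maximum(np.abs(x0_heur), 1e-8),
                            ftol=1e-14, xtol=1e-14, gtol=1e-14,
                            max_nfev=cfg.max_nfev)
        history.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)) or best.cost >= 0.5 * n_res * _PENALTY ** 2:
        raise FitError("all stage-2 starts failed (integration penalties everywhere)")

    params, state0 = unpack(best.x)
    traj = integrate("base", state0, params, grid, rtol=cfg.rtol, atol=cfg.atol)
    rmse_raw = {}
    rmse_norm = {}
    for block in ("S", "V_M", "V_F"):
        err = traj[block].to_numpy() - obs[block]
        rmse_raw[block] = float(np.sqrt(np.mean(err ** 2)))
        norm = norms.get(block)
        if norm is None:
            norm = max(float(np.mean(np.abs(obs[block]))), 1e-300) \
                if cfg.normalization != "std" else max(float(np.std(obs[block])), 1e-300)
        rmse_norm[block] = rmse_raw[block] / (norm if cfg.normalization != "none" else 1.0)

    diagnostics = {
        "objective": float(best.cost),
        "nfev": int(best.nfev),
        "status": int(best.status),
        "converged": bool(best.success),
        "message": str(best.message),
        "n_integration_failures": int(n_fail),
        "start_costs": history,
        "optimality": float(best.optimality),
    }
    return FitResult(
        params=params, state0=state0, t0=float(years[0]),
        fit_years=tuple(int(y) for y in years),
        rmse_blocks=rmse_raw, rmse_blocks_normalized=rmse_norm,
        aggressor_fit=aggressor_fit, diagnostics=diagnostics,
    )


def validate_holdout(result: FitResult, series: ScenarioSeries) -> dict:
    """Forward-validate a fit on the held-out years (no refitting).

    Integrates the fitted base model from the fitted initial state to
    each holdout year and reports the relative error per compartment,
    plus the victim-block RMSE over holdout years.  Relative errors are
    unit-free (invariant to expressing populations in other units).
    """
    if not series.holdout_years:
        raise ValueError("scenario has no holdout years")
    missing = set(series.holdout_years) - set(series.data.index)
    if missing:
        raise ValueError(f"holdout years missing from data: {sorted(missing)}")
    hold = series.holdout_frame
    times = tuple(float(y) for y in series.holdout_years)
    grid = TimeGrid(t0=result.t0, times=times)
    traj = integrate("base", result.state0, result.params, grid)

    per_year: dict[int, dict[str, float]] = {}
    sq = []
    for year in series.holdout_years:
        row = {}
        for block, col in (("A", "A_obs"), ("S", "S_obs"),
                           ("V_M", "V_M_obs"), ("V_F", "V_F_obs")):
            observed = float(hold.loc[year, col])
            predicted = float(traj.loc[float(year), block])
            row[block] = (predicted - observed) / observed if observed != 0 else np.inf
        per_year[int(year)] = row
        sq.extend([(traj.loc[float(year), "V_M"] - hold.loc[year, "V_M_obs"]) ** 2,
                   (traj.loc[float(year), "V_F"] - hold.loc[year, "V_F_obs"]) ** 2])
    return {
        "relative_error": per_year,
        "victim_rmse": float(np.sqrt(np.mean(sq))),
    }


def compare_fit_quality(results: Mapping[str, FitResult]) -> pd.DataFrame:
    """Rank fits by normalized victim-block RMSE (smaller is better).

    Returns one row per label with the normalized victim RMSE, a dense
    rank, and a tie flag (equal RMSE to within 1e-12 relative).
    """
    if not results:
        raise ValueError("no fit results to compare")
    rows = {label: res.victim_rmse_normalized for label, res in results.items()}
    frame = pd.DataFrame({"victim_rmse_normalized": pd.Series(rows)})
    frame = frame.sort_values("victim_rmse_normalized")
    frame["rank"] = frame["victim_rmse_normalized"].rank(method="dense").astype(int)
    vals = frame["victim_rmse_normalized"].to_numpy()
    tied = np.zeros(len(vals), dtype=bool)
    for i in range(len(vals)):
        for j in range(len(vals)):
            if i != j and np.isclose(vals[i], vals[j], rtol=1e-12, atol=1e-15):
                tied[i] = True
    frame["tied"] = tied
    frame.index.name = "label"
    return frame
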