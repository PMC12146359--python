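"""Long-run projections and recovery-intervention experiments.

The base model is projected forward (default horizon 2034) from a
calibrated fit.  Interventions are modelled as a hard regime switch: the
base dynamics govern the system from the fit origin up to a *recovery
year*, after which the female-recovery (``gamma_F > 0``) or complete
(``gamma_F, delta_A > 0``) dynamics take over from the handed-over
state.  The central policy question — can female and male victim counts
be equalized? — is answered two ways: by bisecting the recovery rate
needed to reach ``V_F <= V_M`` within a finite horizon, and by the
asymptotic closed form obtained from the equilibrium ratio

    V_F*/V_M* = beta_F alpha_M / (beta_M (alpha_F + gamma_F)),

which equals 1 at ``gamma_F* = alpha_M beta_F / beta_M - alpha_F``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .model import ModelParams, StateVec, TimeGrid, integrate

__all__ = [
    "RecoverySchedule",
    "ProjectionReport",
    "EqualityThresholdResult",
    "project",
    "project_with_recovery",
    "sweep",
    "equality_threshold",
]

DEFAULT_HORIZON = 2034.0
_STEP = 0.1  # years between projection samples


@dataclass(frozen=True)
class RecoverySchedule:
    """When the intervention starts and how strong it is.

    ``recovery_year`` is the calendar year at which the recovery terms
    switch on (published experiments use 2020-2023); ``gamma_F`` the
    female-victim recovery rate and ``delta_A`` the aggressor
    rehabilitation rate (0 for the female-only mechanism), both 1/year.
    """

    recovery_year: float
    gamma_F: float
    delta_A: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_F < 0 or self.delta_A < 0:
            raise ValueError("recovery rates must be >= 0")


@dataclass(frozen=True)
class ProjectionReport:
    """A projected trajectory with its gender-gap summary.

    ``gap`` is the equality gap g(t) = V_F(t)/V_M(t) (1 means parity);
    ``min_gap``/``min_gap_year`` locate its minimum over the horizon and
    ``terminal`` holds the final state.
    """

    trajectory: pd.DataFrame
    gap: pd.Series = field(compare=False)
    min_gap: float
    min_gap_year: float
    terminal: StateVec
    schedule: Optional[RecoverySchedule] = None

    @property
    def terminal_year(self) -> float:
        return float(self.trajectory.index[-1])


def _make_report(traj: pd.DataFrame,
                 schedule: Optional[RecoverySchedule] = None) -> ProjectionReport:
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = traj["V_F"] / traj["V_M"]
    finite = gap.replace([np.inf, -np.inf], np.nan).dropna()
    if len(finite):
        min_gap = float(finite.min())
        min_gap_year = float(finite.idxmin())
    else:
        min_gap, min_gap_year = np.nan, np.nan
    last = traj.iloc[-1]
    terminal = StateVec(float(last["A"]), float(last["S"]),
                        float(last["V_M"]), float(last["V_F"]))
    return ProjectionReport(trajectory=traj, gap=gap, min_gap=min_gap,
                            min_gap_year=min_gap_year, terminal=terminal,
                            schedule=schedule)


def project(
    params: ModelParams,
    state0: StateVec,
    horizon: float = DEFAULT_HORIZON,
    t0: float = 2010.0,
    step: float = _STEP,
) -> ProjectionReport:
    """Project the base model from ``t0`` to ``horizon``.

    ``horizon == t0`` degenerates to a single-row report equal to the
    initial state.
    """
    if horizon < t0:
        raise ValueError(f"horizon {horizon} precedes t0 {t0}")
    if horizon == t0:
        traj = pd.DataFrame([state0.to_array()], columns=["A", "S", "V_M", "V_F"],
                            index=pd.Index([t0], name="year"))
        return _make_report(traj)
    grid = TimeGrid.fine(t0, horizon, step)
    traj = integrate("base", state0, params, grid)
    return _make_report(traj)


def project_with_recovery(
    fit: FitResult,
    schedule: RecoverySchedule,
    horizon: float = DEFAULT_HORIZON,
    step: float = _STEP,
) -> ProjectionReport:
    """Base dynamics to the recovery year, then recovery dynamics.

    The state at the switch is handed over exactly (the trajectory is
    continuous; only the vector field jumps).  ``delta_A = 0`` selects
    the female-only mechanism, otherwise the complete model runs.  With
    both rates zero the result coincides with :func:`project`.
    """
    t0 = fit.t0
    t_switch = float(schedule.recovery_year)
    if not t0 <= t_switch <= horizon:
        raise ValueError(
            f"recovery year {t_switch} outside the projection window [{t0}, {horizon}]"
        )
    params = fit.params.replace(gamma_F=schedule.gamma_F, delta_A=schedule.delta_A)

    if t_switch == t0:
        pre = None
        state_switch = fit.state0
    else:
        pre_grid = TimeGrid.fine(t0, t_switch, step)
        pre = integrate("base", fit.state0, fit.params, pre_grid)
        state_switch = StateVec.from_array(pre.iloc[-1].to_numpy())

    rhs = "female_recovery" if schedule.delta_A == 0 else "complete_recovery"
    if t_switch == horizon:
        post = pd.DataFrame([state_switch.to_array()],
                            columns=["A", "S", "V_M", "V_F"],
                            index=pd.Index([t_switch], name="year"))
    else:
        post_grid = TimeGrid.fine(t_switch, horizon, step)
        post = integrate(rhs, state_switch, params, post_grid)

    if pre is not None:
        traj = pd.concat([pre.iloc[:-1], post])
    else:
        traj = post
    traj.index.name = "year"
    return _make_report(traj, schedule)


def sweep(
    fit: FitResult,
    gammas: Sequence[float],
    deltas: Sequence[float],
    recovery_years: Sequence[float],
    horizon: float = DEFAULT_HORIZON,
) -> tuple[dict[tuple[float, float, float], ProjectionReport], pd.DataFrame]:
    """Grid of recovery projections over (gamma_F, delta_A, recovery_year).

    Returns the full report per grid cell plus a tidy summary table with
    columns ``gamma_F, delta_A, recovery_year, terminal_V_F,
    terminal_V_M, min_gap, gap_year``.
    """
    if not (len(gammas) and len(deltas) and len(recovery_years)):
        raise ValueError("sweep grids must be nonempty")
    reports: dict[tuple[float, float, float], ProjectionReport] = {}
    rows = []
    for g, d, y in itertools.product(gammas, deltas, recovery_years):
        rep = project_with_recovery(
            fit, RecoverySchedule(recovery_year=y, gamma_F=g, delta_A=d), horizon
        )
        reports[(g, d, y)] = rep
        rows.append({"gamma_F": g, "delta_A": d, "recovery_year": y,
                     "terminal_V_F": rep.terminal.V_F,
                     "terminal_V_M": rep.terminal.V_M,
                     "min_gap": rep.min_gap, "gap_year": rep.min_gap_year})
    return reports, pd.DataFrame(rows)


@dataclass(frozen=True)
class EqualityThresholdResult:
    """Smallest female recovery rate that closes the victim gender gap.

    ``gamma_F`` / ``multiplier`` (gamma_F as a multiple of alpha_F) give
    the finite-horizon bisection answer (``achieved=False`` when even the
    top of the search bracket cannot close the gap within the horizon);
    ``gamma_asymptotic`` is the closed-form rate at which the equilibrium
    victim ratio reaches 1, independent of horizon.
    """

    achieved: bool
    gamma_F: Optional[float]
    multiplier: Optional[float]
    gamma_asymptotic: float
    multiplier_asymptotic: float
    horizon_years: float
    recovery_year: float


def asymptotic_equality_gamma(params: ModelParams) -> float:
    """Closed-form gamma_F for asymptotic parity, clamped at 0.

    From V_F*/V_M* = beta_F alpha_M / (beta_M (alpha_F + gamma_F)):
    parity requires gamma_F >= alpha_M beta_F / beta_M - alpha_F.
    """
    if params.beta_M == 0:
        raise ValueError("beta_M = 0: male victims vanish, parity undefined")
    return max(0.0, params.alpha_M * params.beta_F / params.beta_M - params.alpha_F)


def equality_threshold(
    fit: FitResult,
    recovery_year: float = 2023.0,
    horizon_years: float = 10.0,
    max_multiplier: float = 1e4,
    tol: float = 1e-3,
) -> EqualityThresholdResult:
    """Bisect the minimal gamma_F achieving V_F <= V_M within a horizon.

    Only the female-recovery mechanism is considered (``delta_A = 0``).
    gamma_F is parametrized as a multiple of the fitted alpha_F; the
    search bracket is [0, max_multiplier].  If even the bracket top
    leaves V_F > V_M everywhere within ``horizon_years`` after the
    switch, the result is reported as not achievable rather than raised.
    """
    alpha_F = fit.params.alpha_F
    if alpha_F <= 0:
        raise ValueError("fitted alpha_F must be positive")
    horizon = recovery_year + horizon_years

    def gap_closed(mult: float) -> bool:
        rep = project_with_recovery(
            fit, RecoverySchedule(recovery_year, gamma_F=mult * alpha_F), horizon
        )
        after = rep.trajectory.loc[rep.trajectory.index >= recovery_year]
        return bool((after["V_F"] <= after["V_M"]).any())

    g_star = asymptotic_equality_gamma(fit.params)
    m_star = g_star / alpha_F

    if gap_closed(0.0):
        return EqualityThresholdResult(True, 0.0, 0.0, g_star, m_star,
                                       horizon_years, recovery_year)
    if not gap_closed(max_multiplier):
        return EqualityThresholdResult(False, None, None, g_star, m_star,
                                       horizon_years, recovery_year)
    lo, hi = 0.0, max_multiplier
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if gap_closed(mid):
            hi = mid
        else:
            lo = mid
    return EqualityThresholdResult(True, hi * alpha_F, hi, g_star, m_star,
                                   horizon_years, recovery_year)
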