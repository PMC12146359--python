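"""Core compartmental models of gender-segregated violence.

The population is split into four compartments: aggressors ``A``,
susceptibles ``S``, male victims ``V_M`` and female victims ``V_F``,
all measured in millions of people, with time in calendar years.

Three nested systems are provided:

* the **base model** — aggressors and susceptibles each follow logistic
  growth; mass-action contact between aggressors and susceptibles moves
  susceptibles into the gender-specific victim compartments, which are
  depleted at per-capita removal (death) rates::

      dA/dt   = r_A A (1 - A/k_A)
      dS/dt   = r_S S (1 - S/k_S) - (beta_M + beta_F) A S
      dV_M/dt = beta_M A S - alpha_M V_M
      dV_F/dt = beta_F A S - alpha_F V_F

* the **female-recovery model** — adds a return flow ``gamma_F V_F``
  from female victims back to the susceptible compartment;
* the **complete-recovery model** — additionally moves aggressors back
  to the susceptible compartment at rate ``delta_A``.

The aggressor equation is uncoupled, so its solution is the classical
logistic curve (:func:`aggressor_closed_form`); this is used both as the
first stage of parameter estimation and as an integration oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "StateVec",
    "TimeGrid",
    "IntegrationError",
    "base_rhs",
    "female_recovery_rhs",
    "complete_recovery_rhs",
    "aggressor_closed_form",
    "integrate",
    "trajectory_to_csv",
]

#: numerical floor: components in [-NEG_FLOOR, 0) are treated as exact zeros,
#: anything more negative is an error (protects the mass-action terms from
#: spurious sign flips without hiding genuine solver failures)
NEG_FLOOR = 1e-10

_PARAM_FIELDS = (
    "r_A", "k_A", "r_S", "k_S",
    "beta_F", "beta_M", "alpha_F", "alpha_M",
    "gamma_F", "delta_A",
)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a valid trajectory."""


@dataclass(frozen=True)
class ModelParams:
    """Rates and capacities of the violence model.

    Parameters
    ----------
    r_A, r_S
        Logistic growth rates of aggressors / susceptibles (1/year).
    k_A, k_S
        Carrying capacities of aggressors / susceptibles (millions).
    beta_F, beta_M
        Mass-action victimization rates producing female / male victims
        (1/(million * year)).
    alpha_F, alpha_M
        Per-capita removal (death) rates of female / male victims (1/year).
    gamma_F
        Recovery rate of female victims back to susceptibles (1/year);
        0 disables the female-recovery mechanism.
    delta_A
        Recovery rate of aggressors back to susceptibles (1/year);
        0 disables aggressor rehabilitation.

    One parameter object serves all three model variants: the base model
    is the special case ``gamma_F = delta_A = 0``.
    """

    r_A: float
    k_A: float
    r_S: float
    k_S: float
    beta_F: float
    beta_M: float
    alpha_F: float
    alpha_M: float
    gamma_F: float = 0.0
    delta_A: float = 0.0

    def __post_init__(self) -> None:
        for name in _PARAM_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")

    def replace(self, **changes: float) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _PARAM_FIELDS}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParams":
        unknown = set(mapping) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParams":
        """Load parameters from a flat YAML or JSON key/value file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of parameter names")
        return cls.from_mapping(data)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class StateVec:
    """Compartment sizes (millions of people) at one instant."""

    A: float
    S: float
    V_M: float
    V_F: float

    def __post_init__(self) -> None:
        for name in ("A", "S", "V_M", "V_F"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"state component {name} must be finite")
            if value < 0:
                raise ValueError(f"state component {name} must be >= 0, got {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.A, self.S, self.V_M, self.V_F], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVec":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise ValueError(f"state array must have shape (4,), got {arr.shape}")
        # tolerate tiny negative undershoot from the integrator
        if np.any(arr < -NEG_FLOOR):
            raise ValueError(f"state components below the -{NEG_FLOOR} floor: {arr}")
        return cls(*np.maximum(arr, 0.0))


@dataclass(frozen=True)
class TimeGrid:
    """Evaluation times for a trajectory, in calendar years.

    ``t0`` is the integration start (the first observation year, 2010.0
    for the national dataset); ``times`` are the strictly increasing
    output times, with ``times[0] >= t0``.
    """

    t0: float
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if not times:
            raise ValueError("TimeGrid requires at least one evaluation time")
        if times[0] < self.t0:
            raise ValueError(f"times[0]={times[0]} precedes t0={self.t0}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def annual(cls, start: float, end: float) -> "TimeGrid":
        """Integer-year grid from ``start`` to ``end`` inclusive."""
        return cls(t0=float(start), times=tuple(np.arange(start, end + 0.5)))

    @classmethod
    def fine(cls, start: float, end: float, step: float = 0.1) -> "TimeGrid":
        n = int(round((end - start) / step))
        return cls(t0=float(start), times=tuple(start + step * np.arange(n + 1)))


# ---------------------------------------------------------------------------
# right-hand sides


def _deriv(y: np.ndarray, p: ModelParams) -> np.ndarray:
    """Complete-recovery derivative on a raw state array (no validation).

    The base and female-recovery systems are the gamma_F = delta_A = 0
    and delta_A = 0 special cases, so a single kernel serves all three.
    Negative components (solver undershoot) are clamped to zero before
    the mass-action product is formed.
    """
    A, S, V_M, V_F = np.maximum(y, 0.0)
    contact = (p.beta_M + p.beta_F) * A * S
    dA = p.r_A * A * (1.0 - A / p.k_A) - p.delta_A * A
    dS = p.r_S * S * (1.0 - S / p.k_S) - contact + p.gamma_F * V_F + p.delta_A * A
    dVM = p.beta_M * A * S - p.alpha_M * V_M
    dVF = p.beta_F * A * S - p.alpha_F * V_F - p.gamma_F * V_F
    return np.array([dA, dS, dVM, dVF])


def _checked_state(state: StateVec) -> np.ndarray:
    y = state.to_array()
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("state components must be finite and nonnegative")
    return y


def base_rhs(state: StateVec, params: ModelParams) -> np.ndarray:
    """Time derivative of the base model, as ``(dA, dS, dV_M, dV_F)``.

    Any recovery rates on ``params`` are ignored: this is the pure
    logistic + mass-action system.
    """
    y = _checked_state(state)
    p = params if params.gamma_F == 0 and params.delta_A == 0 else params.replace(
        gamma_F=0.0, delta_A=0.0
    )
    return _deriv(y, p)


def female_recovery_rhs(state: StateVec, params: ModelParams) -> np.ndarray:
    """Base model plus the female-victim recovery flow ``gamma_F * V_F``.

    The flow leaves ``dS + dV_F`` unchanged (pure mass transfer).
    ``delta_A`` on ``params`` is ignored.
    """
    y = _checked_state(state)
    p = params if params.delta_A == 0 else params.replace(delta_A=0.0)
    return _deriv(y, p)


def complete_recovery_rhs(state: StateVec, params: ModelParams) -> np.ndarray:
    """Female recovery plus aggressor rehabilitation ``delta_A * A``."""
    return _deriv(_checked_state(state), params)


_RHS_BY_NAME: dict[str, Callable[[StateVec, ModelParams], np.ndarray]] = {
    "base": base_rhs,
    "female_recovery": female_recovery_rhs,
    "complete_recovery": complete_recovery_rhs,
}


def aggressor_closed_form(
    A0: float, params: ModelParams, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Logistic solution of the uncoupled aggressor equation.

    Returns ``k_A A0 e^{r_A t} / (k_A + A0 (e^{r_A t} - 1))`` evaluated
    at elapsed time ``t`` (years since the initial condition), computed
    in the overflow-safe form ``k_A / (1 + ((k_A - A0)/A0) e^{-r_A t})``.
    Requires ``delta_A = 0`` (with rehabilitation the aggressor equation
    is a shifted logistic and this formula does not apply).
    """
    if params.delta_A != 0:
        raise ValueError("closed form requires delta_A = 0")
    if A0 < 0:
        raise ValueError(f"A0 must be >= 0, got {A0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if A0 == 0:
        return np.zeros_like(t) if t.ndim else 0.0
    if params.r_A == 0:
        out = np.full_like(t, A0)
        return out if t.ndim else float(A0)
    ratio = (params.k_A - A0) / A0
    out = params.k_A / (1.0 + ratio * np.exp(-params.r_A * t))
    return out if t.ndim else float(out)


def integrate(
    rhs: Union[str, Callable[[StateVec, ModelParams], np.ndarray]],
    state0: StateVec,
    params: ModelParams,
    grid: TimeGrid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> pd.DataFrame:
    """Integrate one model variant over a time grid.

    Parameters
    ----------
    rhs
        ``"base"``, ``"female_recovery"``, ``"complete_recovery"`` or one
        of the rhs functions from this module.
    state0
        Initial compartment sizes at ``grid.t0``.
    grid
        Output times (calendar years).
    rtol, atol, method
        Passed to :func:`scipy.integrate.solve_ivp`. Defaults are tight
        enough that the aggressor component agrees with
        :func:`aggressor_closed_form` to better than 1e-8 relative over
        multi-decade horizons.

    Returns
    -------
    pandas.DataFrame
        Columns ``A, S, V_M, V_F`` (millions), indexed by ``year``.

    Raises
    ------
    IntegrationError
        If the solver reports failure or the trajectory undershoots the
        negativity floor; never returns silent NaNs.
    """
    if isinstance(rhs, str):
        try:
            rhs_fn = _RHS_BY_NAME[rhs]
        except KeyError:
            raise ValueError(
                f"unknown rhs {rhs!r}; expected one of {sorted(_RHS_BY_NAME)}"
            ) from None
    else:
        rhs_fn = rhs

    # route through the shared kernel with the variant's rate masking
    if rhs_fn is base_rhs:
        p = params.replace(gamma_F=0.0, delta_A=0.0)
    elif rhs_fn is female_recovery_rhs:
        p = params.replace(delta_A=0.0)
    else:
        p = params

    if rhs_fn in (base_rhs, female_recovery_rhs, complete_recovery_rhs):
        def fun(t: float, y: np.ndarray) -> np.ndarray:
            return _deriv(y, p)
    else:  # user-supplied callable
        def fun(t: float, y: np.ndarray) -> np.ndarray:
            return np.asarray(
                rhs_fn(StateVec.from_array(np.maximum(y, 0.0)), p), dtype=float
            )

    y0 = state0.to_array()
    times = np.asarray(grid.times)
    sol = solve_ivp(
        fun,
        (grid.t0, times[-1]),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise IntegrationError("ODE solver produced non-finite values")
    if np.any(y < -NEG_FLOOR):
        raise IntegrationError(
            f"trajectory undershoots the negativity floor (min {y.min():.3e})"
        )
    y = np.maximum(y, 0.0)
    return pd.DataFrame(y, columns=["A", "S", "V_M", "V_F"],
                        index=pd.Index(times, name="year"))


def trajectory_to_csv(trajectory: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trajectory as ``year,A,S,V_M,V_F`` with 6 significant digits."""
    trajectory.to_csv(path, float_format="%.6g")
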