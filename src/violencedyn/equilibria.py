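"""Fixed points, local stability and long-run saturation values.

For the base model (no recovery) the positive equilibrium is available
in closed form: the aggressor logistic saturates at ``A* = k_A``, the
susceptible compartment settles at

    S* = k_S (1 - (beta_M + beta_F) k_A / r_S)          (or 0 if negative)

and the victim compartments balance inflow against removal,

    V_M* = beta_M k_A S* / alpha_M
    V_F* = beta_F k_A S* / (alpha_F + gamma_F).

With aggressor rehabilitation (``delta_A > 0``) the aggressor fixed
point shifts to ``k_A (1 - delta_A/r_A)`` and the susceptible steady
state is the root of a scalar balance equation solved numerically.
Saturation values are how the long-run victim burden is reported: for
the national family-violence calibration they are on the order of 1e4
male and 1.5e5 female victims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .model import ModelParams, StateVec, complete_recovery_rhs

__all__ = [
    "EquilibriumReport",
    "DegenerateParameterError",
    "susceptible_equilibrium",
    "victim_equilibria",
    "recovery_equilibrium",
    "stability",
    "jacobian",
]

_RESIDUAL_TOL = 1e-10


class DegenerateParameterError(ValueError):
    """A parameter combination for which the equilibrium is undefined."""


@dataclass(frozen=True)
class EquilibriumReport:
    """A fixed point of one model variant with its local linearization.

    Starred populations are in millions; ``eigenvalues`` are the four
    eigenvalues of the Jacobian at the fixed point (1/year) and
    ``stable`` is True when every real part is negative.  ``residual``
    is the max-norm of the rhs at the starred state (should be < 1e-10),
    ``diagnostic`` carries a message when the numerical root search had
    to fall back.
    """

    A_star: float
    S_star: float
    V_M_star: float
    V_F_star: float
    eigenvalues: tuple[complex, complex, complex, complex]
    stable: bool
    residual: float
    diagnostic: str = ""

    @property
    def state(self) -> StateVec:
        return StateVec(self.A_star, self.S_star, self.V_M_star, self.V_F_star)

    def as_dict(self) -> dict:
        return {
            "A_star_millions": self.A_star,
            "S_star_millions": self.S_star,
            "V_M_star_millions": self.V_M_star,
            "V_F_star_millions": self.V_F_star,
            "V_M_star_individuals": self.V_M_star * 1e6,
            "V_F_star_individuals": self.V_F_star * 1e6,
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "stable": self.stable,
            "residual": self.residual,
            "diagnostic": self.diagnostic,
        }


def susceptible_equilibrium(params: ModelParams) -> float:
    """Closed-form susceptible steady state of the base model (millions).

    Valid only without recovery flows (``gamma_F = delta_A = 0``).  The
    expression ``k_S (1 - (beta_M+beta_F) k_A / r_S)`` is clamped at 0:
    when mass-action drain at aggressor saturation exceeds the logistic
    growth the susceptible population is driven extinct.
    """
    if params.gamma_F != 0 or params.delta_A != 0:
        raise ValueError("susceptible_equilibrium requires gamma_F = delta_A = 0")
    if params.r_S == 0:
        raise DegenerateParameterError("r_S = 0: susceptible equilibrium undefined")
    s = params.k_S * (1.0 - (params.beta_M + params.beta_F) * params.k_A / params.r_S)
    return max(s, 0.0)


def victim_equilibria(params: ModelParams) -> tuple[float, float]:
    """Steady-state victim populations ``(V_M*, V_F*)`` in millions.

    Uses ``A* = k_A`` (requires ``delta_A = 0``) and the closed-form
    ``S*``; each victim compartment balances mass-action inflow against
    removal (plus recovery for females).
    """
    if params.delta_A != 0:
        raise ValueError("victim_equilibria requires delta_A = 0")
    s_star = susceptible_equilibrium(params.replace(gamma_F=0.0))
    inflow_m = params.beta_M * params.k_A * s_star
    inflow_f = params.beta_F * params.k_A * s_star
    if params.alpha_M == 0 and inflow_m > 0:
        raise DegenerateParameterError("alpha_M = 0 with positive inflow: V_M unbounded")
    denom_f = params.alpha_F + params.gamma_F
    if denom_f == 0 and inflow_f > 0:
        raise DegenerateParameterError("alpha_F + gamma_F = 0 with positive inflow: V_F unbounded")
    v_m = inflow_m / params.alpha_M if inflow_m > 0 else 0.0
    v_f = inflow_f / denom_f if inflow_f > 0 else 0.0
    return v_m, v_f


def _susceptible_balance(s: float, a_star: float, p: ModelParams) -> float:
    # steady-state S equation of the complete-recovery model, with
    # V_F* eliminated via V_F*(S) = beta_F A* S / (alpha_F + gamma_F)
    v_f = p.beta_F * a_star * s / (p.alpha_F + p.gamma_F) if (p.alpha_F + p.gamma_F) > 0 else 0.0
    return (
        p.r_S * s * (1.0 - s / p.k_S)
        - (p.beta_M + p.beta_F) * a_star * s
        + p.gamma_F * v_f
        + p.delta_A * a_star
    )


def recovery_equilibrium(params: ModelParams) -> EquilibriumReport:
    """Nontrivial fixed point of the complete-recovery model.

    ``A* = max(0, k_A (1 - delta_A/r_A))``; ``S*`` is found by bracketed
    bisection of the scalar balance equation on ``[0, 2 k_S]`` (sign
    scan over 1000 points, tolerance 1e-12); victims follow from the
    inflow/removal balance.  Reduces exactly to the closed forms when
    ``gamma_F = delta_A = 0``.
    """
    p = params
    if p.r_A == 0 and p.delta_A == 0:
        raise DegenerateParameterError(
            "r_A = delta_A = 0: every aggressor level is stationary"
        )
    a_star = max(0.0, p.k_A * (1.0 - p.delta_A / p.r_A)) if p.r_A > 0 else 0.0

    diagnostic = ""
    if a_star == 0.0:
        # aggressors extinct: susceptibles relax to pure logistic capacity
        s_star = p.k_S
        v_m = v_f = 0.0
    elif p.delta_A == 0 and p.gamma_F == 0:
        s_star = susceptible_equilibrium(p)
        v_m, v_f = victim_equilibria(p)
    elif p.delta_A == 0:
        if p.r_S == 0:
            raise DegenerateParameterError("r_S = 0: susceptible equilibrium undefined")
        # S = 0 always solves the balance when delta_A = 0; the nontrivial
        # root comes from factoring S out (recovery feeds back a fraction
        # gamma_F/(alpha_F+gamma_F) of the female mass-action drain)
        b = p.beta_M + p.beta_F
        feedback = (p.gamma_F * p.beta_F / (p.alpha_F + p.gamma_F)
                    if (p.alpha_F + p.gamma_F) > 0 else 0.0)
        s_star = max(0.0, p.k_S * (1.0 - (b - feedback) * a_star / p.r_S))
        denom_f = p.alpha_F + p.gamma_F
        v_f = p.beta_F * a_star * s_star / denom_f if denom_f > 0 else 0.0
        v_m = p.beta_M * a_star * s_star / p.alpha_M if p.alpha_M > 0 else 0.0
    else:
        # sign-change scan over [0, 2 k_S]; a strong rehabilitation inflow
        # (delta_A A* large vs r_S k_S) can push S* above that, so the
        # bracket is doubled as needed (noted in the diagnostic)
        s_star = None
        upper = 2.0 * p.k_S
        while s_star is None and upper <= 1024.0 * p.k_S:
            grid = np.linspace(0.0, upper, 1001)
            vals = np.array([_susceptible_balance(s, a_star, p) for s in grid])
            for i in range(len(grid) - 1):
                lo, hi = vals[i], vals[i + 1]
                if lo == 0.0:
                    s_star = grid[i]
                    break
                if lo * hi < 0:
                    s_star = bisect(_susceptible_balance, grid[i], grid[i + 1],
                                    args=(a_star, p), xtol=1e-12)
                    break
            if s_star is None:
                upper *= 2.0
        if s_star is not None and upper > 2.0 * p.k_S:
            diagnostic = f"susceptible balance root found beyond 2 k_S (bracket {upper:g})"
        if s_star is None:
            diagnostic = "FAILED: no sign change of the susceptible balance up to 1024 k_S"
            s_star = 0.0
        denom_f = p.alpha_F + p.gamma_F
        v_f = p.beta_F * a_star * s_star / denom_f if denom_f > 0 else 0.0
        v_m = p.beta_M * a_star * s_star / p.alpha_M if p.alpha_M > 0 else 0.0

    state = StateVec(a_star, s_star, v_m, v_f)
    residual = float(np.max(np.abs(complete_recovery_rhs(state, p))))
    if diagnostic.startswith("FAILED"):
        eig = (complex(np.nan),) * 4
        return EquilibriumReport(a_star, s_star, v_m, v_f, eig, False,
                                 residual, diagnostic)
    eig, stable = stability(p, state)
    return EquilibriumReport(a_star, s_star, v_m, v_f, tuple(eig), stable,
                             residual, diagnostic)


def jacobian(params: ModelParams, state: StateVec) -> np.ndarray:
    """Analytic 4x4 Jacobian of the complete-recovery rhs at ``state``.

    Row/column order is (A, S, V_M, V_F).  With ``delta_A = 0`` the
    aggressor row has a single nonzero (diagonal) entry, reflecting the
    uncoupled logistic.
    """
    p = params
    A, S = state.A, state.S
    b = p.beta_M + p.beta_F
    return np.array([
        [p.r_A * (1.0 - 2.0 * A / p.k_A) - p.delta_A, 0.0, 0.0, 0.0],
        [-b * S + p.delta_A, p.r_S * (1.0 - 2.0 * S / p.k_S) - b * A, 0.0, p.gamma_F],
        [p.beta_M * S, p.beta_M * A, -p.alpha_M, 0.0],
        [p.beta_F * S, p.beta_F * A, 0.0, -(p.alpha_F + p.gamma_F)],
    ])


def stability(
    params: ModelParams, state_star: StateVec, rhs_tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Eigenvalues of the Jacobian at a fixed point and a stability flag.

    Raises ``ValueError`` if ``state_star`` is not actually a fixed point
    (rhs max-norm >= ``rhs_tol``).  Stability is strict: all real parts
    negative.
    """
    residual = float(np.max(np.abs(complete_recovery_rhs(state_star, params))))
    if residual >= rhs_tol:
        raise ValueError(
            f"state is not a fixed point (rhs max-norm {residual:.3e} >= {rhs_tol})"
        )
    eig = np.linalg.eigvals(jacobian(params, state_star))
    return eig, bool(np.all(eig.real < 0))
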