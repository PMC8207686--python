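"""Stationary-state solving for the QC niche models.

The model read-out is the promoter activity at the stationary state, so
everything downstream depends on finding stable fixed points reliably.  Two
independent routes are provided:

* :func:`solve_stationary` — root-finding on the algebraic stationary
  equations (a modification of Powell's hybrid method), with seeded
  multistart to detect multistability;
* :func:`integrate_to_steady` — explicit time integration from the all-zero
  state until the flow settles.  This is the canonical solution (the basin
  of the developmental "switch-on" initial condition) and serves as an
  independent oracle: when the two routes disagree beyond tolerance the
  integration endpoint wins and a warning is recorded.

Clamped (knocked-out) variables are removed from the solved system and from
the stability Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .parameters import GenotypeSpec

__all__ = [
    "SolverOptions",
    "SteadyState",
    "SolverError",
    "solve_stationary",
    "integrate_to_steady",
    "is_stable",
    "solve_two_variable_fast",
]


class SolverError(RuntimeError):
    """No stationary state found within budget; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SolverOptions:
    """Numerical policy for stationary solving.

    residual_tol   — absolute tolerance on max |dX/dt| at the solution,
                     on the per-component scale max(|X|, 1);
    steady_tol     — settling threshold for the integration oracle;
    t_chunk        — integration chunk length; the horizon doubles per chunk
                     until the flow settles or max_chunks is exhausted;
    multistart     — number of seeded random root-finder starts used to
                     detect multistability (0 disables detection);
    verify_with_integration — cross-check the root against the integration
                     endpoint (the canonical basin) on every solve.
    """

    residual_tol: float = 1e-10
    steady_tol: float = 1e-8
    t_chunk: float = 100.0
    max_chunks: int = 24
    multistart: int = 8
    seed: int = 0
    verify_with_integration: bool = True
    agreement_rtol: float = 1e-6

    def __post_init__(self):
        if self.residual_tol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SteadyState:
    """A converged stationary state with its promoter read-outs."""

    state: np.ndarray
    pB: float
    pW: float
    residual_norm: float
    stable: bool
    provenance: str  # 'root_find' or 'integration'
    genotype: str
    multistable: bool = False
    messages: tuple = ()

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)


def _free_indices(model, g: GenotypeSpec) -> np.ndarray:
    return np.where(~model.clamp_mask(g))[0]


def _make_free_rhs(model, g: GenotypeSpec):
    """RHS restricted to unclamped components, tolerant of negative probes.

    Root-finder trial points may dip below zero where the promoter functions
    are undefined; those probes are evaluated at the clipped state with a
    linear push-back term so no root can sit at a negative value.
    """
    idx = _free_indices(model, g)
    n = model.n_species

    def f(xfree: np.ndarray) -> np.ndarray:
        xc = np.maximum(xfree, 0.0)
        full = np.zeros(n)
        full[idx] = xc
        r = model.rhs(full, g)[idx]
        return r + (xc - xfree)

    return f, idx


def _residual_norm(model, g, state) -> float:
    scale = np.maximum(np.abs(state), 1.0)
    return float(np.max(np.abs(model.rhs(state, g)) / scale))


def _full_state(model, idx, xfree) -> np.ndarray:
    full = np.zeros(model.n_species)
    full[idx] = np.maximum(xfree, 0.0)
    return full


def jacobian_free(model, g: GenotypeSpec, state: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian of the RHS on unclamped variables."""
    idx = _free_indices(model, g)
    state = np.asarray(state, dtype=float)
    m = len(idx)
    J = np.empty((m, m))
    for j, col in enumerate(idx):
        h = 1e-6 * max(abs(state[col]), 1.0)
        up = state.copy()
        dn = state.copy()
        up[col] += h
        dn[col] = max(dn[col] - h, 0.0)
        span = up[col] - dn[col]
        J[:, j] = (model.rhs(up, g)[idx] - model.rhs(dn, g)[idx]) / span
    return J


def is_stable(model, g: GenotypeSpec, state, opts: SolverOptions | None = None) -> bool:
    """Linear stability of a stationary state (clamped variables excluded).

    True iff every eigenvalue of the finite-difference Jacobian at the state
    has negative real part.  Raises if the state is not stationary within
    tolerance.
    """
    opts = opts or SolverOptions()
    state = np.asarray(state, dtype=float)
    res = _residual_norm(model, g, state)
    if res > max(opts.residual_tol, 1e-8) * 10:
        raise ValueError(
            f"state is not stationary (residual {res:.3g} above tolerance)"
        )
    idx = _free_indices(model, g)
    if len(idx) == 0:
        return True
    eig = np.linalg.eigvals(jacobian_free(model, g, state))
    return bool(np.all(eig.real < 0))


def integrate_to_steady(
    model, g: GenotypeSpec, opts: SolverOptions | None = None
) -> SteadyState:
    """Integrate the dynamics from the all-zero state until it settles.

    The horizon grows geometrically; failure to settle within the budget
    signals an oscillation or a very slow mode and raises.
    """
    opts = opts or SolverOptions()
    idx = _free_indices(model, g)
    n_free = len(idx)
    state = np.zeros(model.n_species)
    if n_free == 0:
        pB, pW = model.promoter_activities(state, g)
        return SteadyState(state, pB, pW, 0.0, True, "integration", g.id)

    def f(t, xfree):
        full = _full_state(model, idx, xfree)
        return model.rhs(full, g)[idx]

    x = np.zeros(n_free)
    t_chunk = opts.t_chunk
    for _ in range(opts.max_chunks):
        sol = solve_ivp(
            f,
            (0.0, t_chunk),
            x,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed for genotype {g.id}: {sol.message}",
                {"genotype": g.id},
            )
        x = np.maximum(sol.y[:, -1], 0.0)
        deriv = np.abs(f(0.0, x))
        scale = np.maximum(np.abs(x), 1.0)
        if np.max(deriv / scale) < opts.steady_tol:
            break
        t_chunk *= 2.0
    else:
        raise SolverError(
            f"integration did not settle for genotype {g.id} "
            f"(max horizon {t_chunk:.3g} exhausted)",
            {"genotype": g.id, "last_state": x},
        )
    full = _full_state(model, idx, x)
    pB, pW = model.promoter_activities(full, g)
    return SteadyState(
        full,
        pB,
        pW,
        _residual_norm(model, g, full),
        True,
        "integration",
        g.id,
    )


def _polish_root(model, g, guess_free):
    """Powell-hybrid root polish; returns (full_state, success)."""
    f, idx = _make_free_rhs(model, g)
    if len(idx) == 0:
        return np.zeros(model.n_species), True
    sol = root(f, np.asarray(guess_free, dtype=float), method="hybr", tol=1e-12)
    return _full_state(model, idx, sol.x), bool(sol.success)


def solve_stationary(
    model, g: GenotypeSpec, opts: SolverOptions | None = None
) -> SteadyState:
    """Find the canonical stable stationary state for one genotype.

    Strategy: integrate from the all-zero state to locate the canonical
    basin, polish with Powell's hybrid root-finder, and accept the root only
    if it agrees with the integration endpoint; otherwise the endpoint wins
    and a warning is recorded.  Seeded multistart root searches flag (never
    hide) multistability.
    """
    opts = opts or SolverOptions()
    idx = _free_indices(model, g)
    messages: list[str] = []

    if opts.verify_with_integration:
        anchor = integrate_to_steady(model, g, opts)
        guess = anchor.state[idx]
    else:
        anchor = None
        guess = 0.5 * model.state_scale(g)[idx]

    polished, ok = _polish_root(model, g, guess)
    provenance = "root_find"
    if anchor is not None:
        scale = np.maximum(np.abs(anchor.state), 1.0)
        # The polish starts at the endpoint, so any drift beyond ~1e-4 on the
        # state scale means it jumped basins; the endpoint then wins.
        agree = ok and bool(np.max(np.abs(polished - anchor.state) / scale) < 1e-4)
        if not agree:
            messages.append(
                "root-finder disagreed with the integration endpoint; "
                "integration endpoint used"
            )
            warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)
            polished = anchor.state
            provenance = "integration"
    elif not ok:
        # no anchor available: fall back to the integration oracle outright
        anchor = integrate_to_steady(model, g, opts)
        polished = anchor.state
        provenance = "integration"

    res = _residual_norm(model, g, polished)
    if res > max(opts.residual_tol, opts.steady_tol):
        raise SolverError(
            f"no converged stationary state for genotype {g.id} (residual {res:.3g})",
            {"genotype": g.id, "state": polished},
        )

    try:
        stable = is_stable(model, g, polished, opts)
    except ValueError:
        stable = False

    multistable = False
    if opts.multistart > 0 and len(idx) > 0:
        rng = np.random.default_rng(opts.seed)
        scale_free = model.state_scale(g)[idx]
        found = [polished[idx]]
        for _ in range(opts.multistart):
            start = rng.uniform(0.0, 1.5, size=len(idx)) * scale_free
            cand, ok2 = _polish_root(model, g, start)
            if not ok2:
                continue
            if _residual_norm(model, g, cand) > max(opts.residual_tol, opts.steady_tol):
                continue
            try:
                if not is_stable(model, g, cand, opts):
                    continue
            except ValueError:
                continue
            cf = cand[idx]
            if all(
                np.max(np.abs(cf - other) / np.maximum(np.abs(other), 1.0)) > 1e-5
                for other in found
            ):
                found.append(cf)
        if len(found) > 1:
            multistable = True
            messages.append(
                f"multistability detected for genotype {g.id}: "
                f"{len(found)} distinct stable roots"
            )
            warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)

    pB, pW = model.promoter_activities(polished, g)
    return SteadyState(
        polished,
        pB,
        pW,
        res,
        stable,
        provenance,
        g.id,
        multistable=multistable,
        messages=tuple(messages),
    )


# ---------------------------------------------------------------------------
# Fast bracketed path for the two-variable models
#
# The stationary equations are monotone in a nested sense: at fixed W the
# BRAVO balance alpha*A0 + P_B(B,W) - d_B*B is strictly decreasing in B
# (eps_B < 1), so B(W) is a unique bracketed root; substituting B(W) into the
# WOX5 balance leaves one bounded scalar equation in W.  This gives a
# deterministic, derivative-free solve that the calibration and exploration
# loops use heavily.


def _bravo_balance_root(model, g: GenotypeSpec, W: float) -> float:
    p = model.params
    if g.clamp_B:
        return 0.0
    from .promoters import promoter_bravo

    def h(B):
        return p.alpha * g.A0 + promoter_bravo(B, W, p) - p.d_B * B

    hi = (p.alpha * g.A0 + p.alpha * max(1.0, p.eps_W)) / p.d_B + 1.0
    if h(hi) >= 0:  # numerical safety; h(hi) < 0 analytically
        return hi
    return brentq(h, 0.0, hi, xtol=1e-14, rtol=1e-15)


def solve_two_variable_fast(model, g: GenotypeSpec) -> np.ndarray:
    """Stationary (B, W) of a two-variable model by nested bracketed roots."""
    p = model.params
    if g.clamp_W:
        return np.array([_bravo_balance_root(model, g, 0.0), 0.0])

    gmax = p.gamma * (1.0 + p.B1) if model.variant == "activation" else p.gamma
    w_hi = (p.gamma * g.G0 + gmax) / p.d_W + 1.0

    def wox5_balance(W):
        B = _bravo_balance_root(model, g, W)
        return p.gamma * g.G0 + model._pw(B, W) - p.d_W * W

    if wox5_balance(w_hi) >= 0:
        W = w_hi
    else:
        W = brentq(wox5_balance, 0.0, w_hi, xtol=1e-14, rtol=1e-15)
    return np.array([_bravo_balance_root(model, g, W), W])
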