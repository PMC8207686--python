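"""Calibration of the two-variable models against experimental promoter
fold-changes.

The reporter data fix two numbers — the pBRAVO fold-change in the wox5
knockout (~0.5) and the pWOX5 fold-change in the bravo knockout (~0.8) —
plus the direction of the remaining ratios and the ordering "WT BRAVO
expression below WT WOX5 expression".  With alpha and gamma pinned at their
control-medium values the remaining kinetic constants are fitted by a
derivative-free multistart search minimizing squared error on log ratios,
with inequality targets as hinge penalties.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import TwoVariableModel, get_model
from .panel import FoldChangeTable, genotype_panel
from .parameters import ParameterSet, ValidationError
from .solver import SolverError, SolverOptions, solve_stationary, solve_two_variable_fast

__all__ = [
    "CalibrationTarget",
    "CalibrationTargets",
    "default_targets",
    "FoldChangeCalibration",
    "CalibrationResult",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """No feasible parameter set found; carries best-found diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CalibrationTarget:
    """One fold-change constraint: ratio of a promoter in a genotype vs WT."""

    genotype: str
    promoter: str  # 'pB' or 'pW'
    relation: str  # 'equals' | 'greater_than' | 'less_than'
    value: float
    weight: float = 1.0

    def __post_init__(self):
        if self.relation not in ("equals", "greater_than", "less_than"):
            raise ValidationError(f"unknown relation {self.relation!r}")
        if self.value <= 0:
            raise ValidationError("target ratios must be positive")


@dataclass(frozen=True)
class CalibrationTargets:
    """A target set; requires at least one equality target.  The WT ordering
    constraint (stationary B below stationary W) is always enforced."""

    targets: tuple = ()
    require_wt_ordering: bool = True

    def __post_init__(self):
        if not any(t.relation == "equals" for t in self.targets):
            raise ValidationError("at least one equality target is required")


def default_targets() -> CalibrationTargets:
    """The experimental fold-change constraints.

    Two measured ratios (equality, heavily weighted) and the observed
    directions of the others, encoded as inequalities: pBRAVO rises in the
    bravo mutant, pWOX5 rises in wox5 and in the double mutant, pBRAVO falls
    in the double mutant, pBRAVO rises under WOX5 overexpression and pWOX5
    stays at or slightly above WT under BRAVO overexpression.
    """
    return CalibrationTargets(
        targets=(
            CalibrationTarget("wox5", "pB", "equals", 0.5, weight=10.0),
            CalibrationTarget("bravo", "pW", "equals", 0.8, weight=10.0),
            CalibrationTarget("bravo", "pB", "greater_than", 1.0),
            CalibrationTarget("wox5", "pW", "greater_than", 1.0),
            CalibrationTarget("bravo_wox5", "pW", "greater_than", 1.0),
            CalibrationTarget("bravo_wox5", "pB", "less_than", 1.0),
            CalibrationTarget("WOX5_OE", "pB", "greater_than", 1.0),
            CalibrationTarget("BRAVO_OE", "pW", "greater_than", 1.0, weight=0.2),
        )
    )


# free parameters and their broad positive search ranges (log-uniform starts)
_FREE_BOUNDS = {
    "eps_B": (0.05, 0.95),
    "eps_W": (1.1, 10.0),
    "K_B": (0.05, 20.0),
    "K_W": (0.01, 5.0),
    "W0": (0.5, 50.0),
    "B0": (0.05, 10.0),
    "B1": (0.1, 10.0),
    "d_B": (0.2, 5.0),
    "d_W": (0.2, 5.0),
}
_FREE_NAMES = tuple(_FREE_BOUNDS)


def _to_vector(p: ParameterSet) -> np.ndarray:
    return np.array([np.log(getattr(p, n)) for n in _FREE_NAMES])


def _from_vector(v: np.ndarray, alpha: float, gamma: float) -> ParameterSet:
    vals = {}
    for n, x in zip(_FREE_NAMES, v):
        lo, hi = _FREE_BOUNDS[n]
        vals[n] = float(np.clip(np.exp(x), lo, hi))
    return ParameterSet(alpha=alpha, gamma=gamma, **vals)


@dataclass
class CalibrationResult:
    """Best feasible parameter set with the achieved fold-change panel.

    ``params`` is the calibrated :class:`ParameterSet`; ``achieved`` the
    genotype panel it produces; ``objective`` the final penalized loss;
    ``target_errors`` the relative error on each equality target.
    """

    params: ParameterSet
    achieved: FoldChangeTable
    objective: float
    targets: CalibrationTargets
    target_errors: dict
    n_starts: int
    seed: int
    wt_state: np.ndarray

    def summary(self) -> str:
        lines = [
            "Fold-change calibration",
            "=" * 55,
            f"model: {self.achieved.model}   starts: {self.n_starts}   seed: {self.seed}",
            f"objective: {self.objective:.3e}",
            "",
            "calibrated parameters:",
        ]
        for n in ParameterSet.field_names():
            lines.append(f"  {n:7s} = {getattr(self.params, n):.6g}")
        lines.append("")
        lines.append(f"{'target':28s} {'wanted':>10s} {'achieved':>10s} {'rel.err':>8s}")
        for t in self.targets.targets:
            got = self.achieved.ratio(t.genotype, t.promoter)
            rel = (got - t.value) / t.value
            want = {"equals": "=", "greater_than": ">", "less_than": "<"}[t.relation]
            lines.append(
                f"{t.genotype + ' ' + t.promoter:28s} {want}{t.value:<9.3g} "
                f"{got:10.4f} {rel:8.1%}"
            )
        b, w = self.wt_state
        lines.append("")
        lines.append(f"WT stationary expressions: B = {b:.4g} < W = {w:.4g}")
        return "\n".join(lines)


class FoldChangeCalibration:
    """Fit the free kinetic constants of a two-variable model to the
    experimental fold-change targets.

    Parameters
    ----------
    model : str
        'alleviation' or 'activation'.
    targets : CalibrationTargets, optional
        Defaults to the experimental target set (:func:`default_targets`).
    alpha, gamma : float
        Basal production rates, fixed at their control-medium values and not
        fitted.
    """

    #: hinge margin on log-ratios for inequality targets
    margin = 0.05

    def __init__(
        self,
        model: str = "alleviation",
        targets: CalibrationTargets | None = None,
        alpha: float = 0.3,
        gamma: float = 25.0,
    ):
        if model not in ("alleviation", "activation"):
            raise ValidationError("calibration applies to the two-variable models")
        self.model = model
        self.targets = targets or default_targets()
        self.alpha = alpha
        self.gamma = gamma

    # -- objective -----------------------------------------------------

    def _loss(self, v: np.ndarray) -> float:
        try:
            p = _from_vector(v, self.alpha, self.gamma)
            table = genotype_panel(self.model, p)
        except (ValidationError, SolverError, ValueError):
            return 1e6
        loss = 0.0
        for t in self.targets.targets:
            r = table.ratio(t.genotype, t.promoter)
            if r <= 0 or not np.isfinite(r):
                return 1e6
            lr, lt = np.log(r), np.log(t.value)
            if t.relation == "equals":
                loss += t.weight * (lr - lt) ** 2
            elif t.relation == "greater_than":
                loss += t.weight * max(0.0, lt + self.margin - lr) ** 2
            else:
                loss += t.weight * max(0.0, lr - lt + self.margin) ** 2
        if self.targets.require_wt_ordering:
            model = get_model(self.model, _from_vector(v, self.alpha, self.gamma))
            from .parameters import GENOTYPES

            B, W = solve_two_variable_fast(model, GENOTYPES["WT"])
            loss += max(0.0, np.log(max(B, 1e-12)) - np.log(max(W, 1e-12)) + self.margin) ** 2
        return float(loss)

    def _initial_points(self, rng: np.random.Generator, n: int) -> list[np.ndarray]:
        pts = []
        center = ParameterSet(alpha=self.alpha, gamma=self.gamma)
        pts.append(_to_vector(center))
        for _ in range(n - 1):
            v = np.array(
                [
                    rng.uniform(np.log(lo), np.log(hi))
                    for lo, hi in _FREE_BOUNDS.values()
                ]
            )
            pts.append(v)
        return pts

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        n_starts: int = 8,
        maxiter: int = 600,
        tolerance: float = 0.10,
    ) -> CalibrationResult:
        """Multistart Nelder-Mead on log-parameters.

        Raises :class:`CalibrationError` unless every equality target is met
        within ``tolerance`` relative and the WT ordering holds.
        """
        rng = np.random.default_rng(seed)
        best_v, best_loss = None, np.inf
        for v0 in self._initial_points(rng, n_starts):
            res = minimize(
                self._loss,
                v0,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-12},
            )
            if res.fun < best_loss:
                best_v, best_loss = res.x, float(res.fun)
        params = _from_vector(best_v, self.alpha, self.gamma)

        # verify the winning set on the full (integration-anchored) solver
        model = get_model(self.model, params)
        opts = SolverOptions(multistart=0)
        table_fast = genotype_panel(self.model, params, check_saturation=True)
        from .parameters import GENOTYPES

        wt = solve_stationary(model, GENOTYPES["WT"], opts)
        fast_wt = solve_two_variable_fast(model, GENOTYPES["WT"])
        if np.max(np.abs(wt.state - fast_wt) / np.maximum(np.abs(wt.state), 1.0)) > 1e-6:
            raise CalibrationError(
                "fast stationary path disagrees with the canonical solver at the optimum",
                {"fast": fast_wt, "canonical": wt.state},
            )

        errors = {}
        for t in self.targets.targets:
            if t.relation != "equals":
                continue
            got = table_fast.ratio(t.genotype, t.promoter)
            errors[(t.genotype, t.promoter)] = abs(got - t.value) / t.value
        infeasible = {k: e for k, e in errors.items() if e > tolerance}
        B, W = wt.state
        if infeasible or not B < W:
            raise CalibrationError(
                "calibration infeasible within multistart budget",
                {
                    "errors": errors,
                    "objective": best_loss,
                    "params": params.to_dict(),
                    "wt_state": (B, W),
                },
            )
        return CalibrationResult(
            params=params,
            achieved=table_fast,
            objective=best_loss,
            targets=self.targets,
            target_errors=errors,
            n_starts=n_starts,
            seed=seed,
            wt_state=wt.state,
        )
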