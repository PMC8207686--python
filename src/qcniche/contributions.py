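"""Decomposition of divided-QC frequencies into BRAVO-, WOX5- and jointly
mediated contributions.

The observed fraction of roots with a divided QC in genotype g is modelled
as ``F^g = F0 / (1 + sum of the contributions active in g)``: a positive
contribution represses QC division, a negative one promotes it.  In a single
knockout the other factor's contribution persists attenuated by a factor q
(``T_W^bravo = qW * T_W^WT``, ``T_B^wox5 = qB * T_B^WT``), and in the double
mutant no contribution remains, so ``F^dm = F0``.  Equating the model to the
four observed frequencies (a, b, c, d for WT, bravo, wox5, double mutant)
gives closed forms:

    F0   = d
    T_B  = (1/qB) (d/c - 1)
    T_W  = (1/qW) (d/b - 1)
    T_BW = d/a - 1 - T_B - T_W

Errors on the frequencies are Bernoulli standard deviations sqrt(p(1-p)/N)
and are propagated analytically assuming independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "bernoulli_error",
    "DivisionData",
    "AttenuationFactors",
    "ContributionEstimate",
    "solve_contributions",
    "predict_frequencies",
    "sweep_qB",
    "monte_carlo_errors",
    "QCDivisionModel",
    "ContributionResult",
    "OBSERVED_DIVISION_DATA",
]


def bernoulli_error(p: float, n: int) -> float:
    """Standard deviation of a sample proportion: sqrt(p(1-p)/n)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"count must be >= 1, got {n}")
    return math.sqrt(p * (1.0 - p) / n)


@dataclass(frozen=True)
class DivisionData:
    """Divided-QC frequencies for WT (a), bravo (b), wox5 (c) and the double
    mutant (d), with Bernoulli errors at an effective root count N_eff.

    N_eff defaults to the conservative 15 used for the published error bars;
    the deltas are recomputed from (p, N_eff) on construction.
    """

    a: float
    b: float
    c: float
    d: float
    n_eff: int = 15
    delta_a: float = field(init=False)
    delta_b: float = field(init=False)
    delta_c: float = field(init=False)
    delta_d: float = field(init=False)

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"frequency {name} must lie in (0, 1), got {v}")
        for name in "abcd":
            object.__setattr__(
                self, f"delta_{name}", bernoulli_error(getattr(self, name), self.n_eff)
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


#: measured divided-QC frequencies (WT, bravo, wox5, bravo wox5)
OBSERVED_DIVISION_DATA = DivisionData(a=0.3939, b=0.8732, c=0.8070, d=0.8846)


@dataclass(frozen=True)
class AttenuationFactors:
    """Multiplicative change of one factor's contribution in the other's
    knockout: qW_bravo for the WOX5-mediated term in bravo (estimate 0.8 from
    the pWOX5 fold-change), qB_wox5 for the BRAVO-mediated term in wox5
    (estimate 0.5 from the pBRAVO fold-change, swept over a grid)."""

    qW_bravo: float = 0.8
    qB_wox5: float = 0.5

    def __post_init__(self):
        if self.qW_bravo <= 0 or self.qB_wox5 <= 0:
            raise ValueError("attenuation factors must be positive")


@dataclass(frozen=True)
class ContributionEstimate:
    """Point estimates and propagated errors of the three contributions.

    Positive values repress QC division, negative values promote it.  F0 is
    the baseline division frequency with every contribution absent (the
    double-mutant condition).
    """

    T_B: float
    T_W: float
    T_BW: float
    delta_T_B: float
    delta_T_W: float
    delta_T_BW: float
    F0: float
    q: AttenuationFactors

    def envelope_excludes_zero(self) -> dict:
        return {
            "T_B": abs(self.T_B) > self.delta_T_B,
            "T_W": abs(self.T_W) > self.delta_T_W,
            "T_BW": abs(self.T_BW) > self.delta_T_BW,
        }


def solve_contributions(
    data: DivisionData, q: AttenuationFactors | None = None
) -> ContributionEstimate:
    """Closed-form contributions from the four observed frequencies.

    Negative contributions are meaningful (activation of QC division), never
    an error.  The errors follow first-order propagation of the independent
    Bernoulli deltas through the closed forms.
    """
    q = q or AttenuationFactors()
    a, b, c, d = data.as_tuple()
    da, db, dc, dd = data.delta_a, data.delta_b, data.delta_c, data.delta_d
    qB, qW = q.qB_wox5, q.qW_bravo

    F0 = d
    T_B = (d / c - 1.0) / qB
    T_W = (d / b - 1.0) / qW
    T_BW = d / a - 1.0 - T_B - T_W

    delta_T_B = math.sqrt((dd / c) ** 2 + (d / c**2) ** 2 * dc**2) / qB
    delta_T_W = math.sqrt((dd / b) ** 2 + (d / b**2) ** 2 * db**2) / qW
    delta_T_BW = math.sqrt(
        dd**2 * (1.0 / a - 1.0 / (qB * c) - 1.0 / (qW * b)) ** 2
        + (d / a**2) ** 2 * da**2
        + (d / (qW * b**2)) ** 2 * db**2
        + (d / (qB * c**2)) ** 2 * dc**2
    )
    return ContributionEstimate(
        T_B=T_B,
        T_W=T_W,
        T_BW=T_BW,
        delta_T_B=delta_T_B,
        delta_T_W=delta_T_W,
        delta_T_BW=delta_T_BW,
        F0=F0,
        q=q,
    )


def predict_frequencies(
    F0: float,
    T_B: float,
    T_W: float,
    T_BW: float,
    q: AttenuationFactors | None = None,
) -> tuple[float, float, float, float]:
    """Forward model: (F^WT, F^bravo, F^wox5, F^dm) from the contributions.

    F^WT = F0/(1+T_B+T_W+T_BW); in each single knockout only the other
    factor's attenuated contribution remains; F^dm = F0.  The algebraic
    inverse of :func:`solve_contributions`.
    """
    q = q or AttenuationFactors()
    denoms = {
        "WT": 1.0 + T_B + T_W + T_BW,
        "bravo": 1.0 + T_W * q.qW_bravo,
        "wox5": 1.0 + T_B * q.qB_wox5,
        "dm": 1.0,
    }
    for g, den in denoms.items():
        if den <= 0:
            raise ValueError(
                f"contribution sum makes the {g} frequency undefined (1+sum={den:.4g})"
            )
    return (
        F0 / denoms["WT"],
        F0 / denoms["bravo"],
        F0 / denoms["wox5"],
        F0 / denoms["dm"],
    )


def sweep_qB(
    data: DivisionData,
    qW: float = 0.8,
    qB_grid=None,
) -> pd.DataFrame:
    """Contribution estimates across a grid of the BRAVO attenuation factor.

    Default grid: 50 log-spaced points in [0.05, 1.5].  Per grid point the
    table carries the point estimates, the +-delta envelopes, and whether
    each contribution's envelope excludes zero.
    """
    if qB_grid is None:
        qB_grid = np.geomspace(0.05, 1.5, 50)
    rows = []
    for qB in np.asarray(qB_grid, dtype=float):
        if qB <= 0:
            raise ValueError("qB grid values must be positive")
        est = solve_contributions(data, AttenuationFactors(qW_bravo=qW, qB_wox5=qB))
        excl = est.envelope_excludes_zero()
        rows.append(
            {
                "qB_wox5": qB,
                "qW_bravo": qW,
                "F0": est.F0,
                "T_B": est.T_B,
                "T_W": est.T_W,
                "T_BW": est.T_BW,
                "delta_T_B": est.delta_T_B,
                "delta_T_W": est.delta_T_W,
                "delta_T_BW": est.delta_T_BW,
                "T_B_excludes_zero": excl["T_B"],
                "T_W_excludes_zero": excl["T_W"],
                "T_BW_excludes_zero": excl["T_BW"],
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_errors(
    data: DivisionData,
    q: AttenuationFactors | None = None,
    n_draws: int = 10**6,
    seed: int = 0,
    scale: float = 0.01,
) -> dict:
    """Monte-Carlo estimate of the propagated contribution errors.

    Draws independent Gaussian perturbations of (a, b, c, d) with the
    Bernoulli deltas scaled by ``scale`` and rescales the resulting spreads,
    i.e. it samples the delta-method (first-order) propagation that the
    analytic formulas implement.  At ``scale = 1`` the T_BW spread is
    dominated by the heavy tail of d/a (the WT frequency sits within ~3 of
    its delta from zero) and no longer reflects first-order propagation;
    small ``scale`` probes the linear-response regime.
    """
    q = q or AttenuationFactors()
    a, b, c, d = data.as_tuple()
    rng = np.random.default_rng(seed)
    A = a + rng.normal(0.0, data.delta_a * scale, n_draws)
    B = b + rng.normal(0.0, data.delta_b * scale, n_draws)
    C = c + rng.normal(0.0, data.delta_c * scale, n_draws)
    D = d + rng.normal(0.0, data.delta_d * scale, n_draws)
    T_B = (D / C - 1.0) / q.qB_wox5
    T_W = (D / B - 1.0) / q.qW_bravo
    T_BW = D / A - 1.0 - T_B - T_W
    return {
        "delta_T_B": float(T_B.std() / scale),
        "delta_T_W": float(T_W.std() / scale),
        "delta_T_BW": float(T_BW.std() / scale),
    }


# ---------------------------------------------------------------------------
# Model/Results wrappers


@dataclass
class ContributionResult:
    """Fit result of :class:`QCDivisionModel`: the contribution estimates,
    their propagated errors and the fitted frequencies (which reproduce the
    observations exactly — the decomposition is an algebraic inverse)."""

    estimate: ContributionEstimate
    data: DivisionData
    fitted: tuple

    def predict(self, q: AttenuationFactors | None = None):
        e = self.estimate
        return predict_frequencies(e.F0, e.T_B, e.T_W, e.T_BW, q or e.q)

    def sweep_qb(self, qB_grid=None) -> pd.DataFrame:
        return sweep_qB(self.data, qW=self.estimate.q.qW_bravo, qB_grid=qB_grid)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "QC division contribution decomposition",
            "=" * 55,
            f"observed frequencies (WT, bravo, wox5, dm): "
            f"{self.data.a:.4f}, {self.data.b:.4f}, {self.data.c:.4f}, {self.data.d:.4f}",
            f"Bernoulli errors at N_eff = {self.data.n_eff}: "
            f"{self.data.delta_a:.4f}, {self.data.delta_b:.4f}, "
            f"{self.data.delta_c:.4f}, {self.data.delta_d:.4f}",
            f"attenuation factors: qW_bravo = {e.q.qW_bravo}, qB_wox5 = {e.q.qB_wox5}",
            "",
            f"{'term':6s} {'estimate':>10s} {'+-delta':>10s} {'excl. 0':>8s}",
        ]
        for name, val, err in (
            ("F0", e.F0, float("nan")),
            ("T_B", e.T_B, e.delta_T_B),
            ("T_W", e.T_W, e.delta_T_W),
            ("T_BW", e.T_BW, e.delta_T_BW),
        ):
            mark = ""
            if name != "F0":
                mark = "yes" if abs(val) > err else "no"
            err_s = f"{err:10.4f}" if np.isfinite(err) else " " * 10
            lines.append(f"{name:6s} {val:10.4f} {err_s} {mark:>8s}")
        lines.append("")
        lines.append("positive = repression of QC division, negative = activation")
        return "\n".join(lines)


class QCDivisionModel:
    """Contribution decomposition as a fitted model.

    Built from :class:`DivisionData` (defaults to the measured frequencies)
    and :class:`AttenuationFactors`; ``fit()`` returns a
    :class:`ContributionResult` carrying estimates, propagated errors and a
    ``summary()`` table.
    """

    def __init__(
        self,
        data: DivisionData | None = None,
        q: AttenuationFactors | None = None,
    ):
        self.data = data or OBSERVED_DIVISION_DATA
        self.q = q or AttenuationFactors()

    @classmethod
    def from_counts(
        cls,
        n_divided: dict,
        n_roots: dict,
        n_eff: int | None = None,
        q: AttenuationFactors | None = None,
    ) -> "QCDivisionModel":
        """Build from per-genotype divided/total root counts.

        ``n_eff`` overrides the error-bar root count (defaults to the
        conservative 15 rather than the actual counts).
        """
        freqs = {}
        for g in ("WT", "bravo", "wox5", "bravo_wox5"):
            freqs[g] = n_divided[g] / n_roots[g]
        data = DivisionData(
            a=freqs["WT"],
            b=freqs["bravo"],
            c=freqs["wox5"],
            d=freqs["bravo_wox5"],
            n_eff=n_eff if n_eff is not None else 15,
        )
        return cls(data=data, q=q)

    def fit(self) -> ContributionResult:
        est = solve_contributions(self.data, self.q)
        fitted = predict_frequencies(est.F0, est.T_B, est.T_W, est.T_BW, self.q)
        return ContributionResult(estimate=est, data=self.data, fitted=fitted)
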