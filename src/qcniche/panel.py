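"""Genotype panels of stationary promoter fold-changes and the
parameter-space robustness exploration.

The comparable quantity between model and reporter data is the fold-change:
the stationary promoter activity in a perturbed genotype over its WT value
(GFP scale is arbitrary, so only ratios are meaningful).  All genotypes in a
panel share one parameter set — mutants change nothing but the clamp.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ComplexFormationModel, TwoVariableModel, get_model
from .parameters import (
    ComplexParameterSet,
    GENOTYPES,
    GenotypeSpec,
    MediumCondition,
    ParameterSet,
    ValidationError,
    medium_condition_params,
)
from .solver import (
    SolverError,
    SolverOptions,
    SteadyState,
    solve_stationary,
    solve_two_variable_fast,
)

__all__ = [
    "FoldChangeTable",
    "ExplorationConfig",
    "ExplorationResult",
    "genotype_panel",
    "explore_parameter_space",
    "single_parameter_sensitivity",
    "sweep_medium",
    "compare_model_robustness",
]

# canonical panel order; aliases follow the superscript shorthand
PANEL_GENOTYPES = ("WT", "bravo", "wox5", "bravo_wox5", "BRAVO_OE", "WOX5_OE")
_ALIASES = {"dm": "bravo_wox5", "Boe": "BRAVO_OE", "Woe": "WOX5_OE"}

# complex model: degradation rates and unbinding coefficients drive redundant
# stationary outcomes, so the exploration holds them fixed
COMPLEX_FROZEN = (
    "d_B",
    "d_W",
    "d_S",
    "d_BW",
    "d_BS",
    "d_WS",
    "mu_BW",
    "mu_BS",
    "mu_WS",
)


@dataclass
class FoldChangeTable:
    """Stationary promoter activities and their mutant/WT ratios.

    ``raw`` maps genotype id -> (pB, pW); ``ratios`` holds pB^g/pB^WT and
    pW^g/pW^WT per genotype (WT rows equal 1 by construction).
    """

    raw: dict
    model: str

    def __post_init__(self):
        wt_pB, wt_pW = self.raw["WT"]
        if wt_pB <= 0 or wt_pW <= 0:
            raise ValidationError("WT promoter activities must be positive")

    def _resolve(self, genotype: str) -> str:
        return _ALIASES.get(genotype, genotype)

    def pB(self, genotype: str) -> float:
        return self.raw[self._resolve(genotype)][0]

    def pW(self, genotype: str) -> float:
        return self.raw[self._resolve(genotype)][1]

    def ratio(self, genotype: str, promoter: str) -> float:
        """Fold-change pX^genotype / pX^WT with promoter in {'pB', 'pW'}."""
        g = self._resolve(genotype)
        i = {"pB": 0, "pW": 1}[promoter]
        return self.raw[g][i] / self.raw["WT"][i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, (pB, pW) in self.raw.items():
            rows.append(
                {
                    "genotype": g,
                    "pB": pB,
                    "pW": pW,
                    "pB_ratio": pB / self.raw["WT"][0],
                    "pW_ratio": pW / self.raw["WT"][1],
                }
            )
        return pd.DataFrame(rows)


class SaturationError(RuntimeError):
    """Overexpression read-out failed to saturate after escalation budget."""


def _solve_state(model, g: GenotypeSpec, opts: SolverOptions, fast: bool):
    if fast and isinstance(model, TwoVariableModel):
        state = solve_two_variable_fast(model, g)
        pB, pW = model.promoter_activities(state, g)
        return state, pB, pW
    ss = solve_stationary(model, g, opts)
    return ss.state, ss.pB, ss.pW


def _solve_oe_saturated(model, g: GenotypeSpec, opts, fast, check_saturation):
    """Solve an overexpression genotype, escalating A0/G0 x10 until the
    regulated read-out changes by < 1% (max 6 escalations)."""
    state, pB, pW = _solve_state(model, g, opts, fast)
    if not check_saturation:
        return state, pB, pW
    monitored = pW if g.A0 > 0 else pB  # read-out of the regulated factor
    for _ in range(6):
        g_up = dataclasses.replace(g, A0=g.A0 * 10, G0=g.G0 * 10)
        state_up, pB_up, pW_up = _solve_state(model, g_up, opts, fast)
        monitored_up = pW_up if g.A0 > 0 else pB_up
        if abs(monitored_up - monitored) <= 0.01 * max(abs(monitored), 1e-300):
            return state, pB, pW
        g, state, pB, pW, monitored = g_up, state_up, pB_up, pW_up, monitored_up
    raise SaturationError(
        f"overexpression read-out did not saturate for genotype {g.id}"
    )


def genotype_panel(
    model_or_name,
    params: ParameterSet | None = None,
    opts: SolverOptions | None = None,
    fast: bool = True,
    check_saturation: bool = False,
) -> FoldChangeTable:
    """Solve all six genotypes at stationarity (one shared parameter set)
    and tabulate promoter fold-changes relative to WT.

    ``fast`` uses the bracketed nested-root path for the two-variable models;
    ``check_saturation`` enables the overexpression-extent escalation check.
    Solver failures are re-raised annotated with the genotype id.
    """
    model = (
        get_model(model_or_name, params) if isinstance(model_or_name, str) else model_or_name
    )
    opts = opts or SolverOptions(verify_with_integration=False, multistart=0)
    raw = {}
    for gid in PANEL_GENOTYPES:
        g = GENOTYPES[gid]
        try:
            if g.A0 > 0 or g.G0 > 0:
                _, pB, pW = _solve_oe_saturated(model, g, opts, fast, check_saturation)
            else:
                _, pB, pW = _solve_state(model, g, opts, fast)
        except (SolverError, SaturationError) as e:
            raise SolverError(f"genotype {gid}: {e}", {"genotype": gid}) from e
        raw[gid] = (pB, pW)
    return FoldChangeTable(raw=raw, model=model.name)


# ---------------------------------------------------------------------------
# Parameter-space exploration


@dataclass(frozen=True)
class ExplorationConfig:
    """Sampling protocol: each non-frozen parameter drawn uniformly in
    [P0/2, 2*P0] around its default P0 (intersected with the validity domain
    of eps_B < 1 and eps_W > 1)."""

    n_runs: int = 1000
    range_factor: float = 2.0
    seed: int = 0
    frozen: tuple = ()
    max_failure_rate: float = 0.05

    def __post_init__(self):
        if self.n_runs < 0:
            raise ValidationError("n_runs must be >= 0")
        if self.range_factor <= 1.0:
            raise ValidationError("range_factor must exceed 1")


@dataclass
class ExplorationResult:
    """Raw ensemble plus the distribution summary of a robustness run."""

    ensemble: pd.DataFrame  # one row per run x genotype x promoter
    summary: pd.DataFrame
    n_failures: int
    config: ExplorationConfig

    def fraction_above_one(self, genotype: str, promoter: str) -> float:
        s = self.summary
        row = s[(s.genotype == _ALIASES.get(genotype, genotype)) & (s.promoter == promoter)]
        return float(row["frac_gt_1"].iloc[0])


def _sample_bounds(name: str, p0: float, factor: float) -> tuple[float, float]:
    lo, hi = p0 / factor, p0 * factor
    if name == "eps_B":
        hi = min(hi, 1.0 - 1e-9)
    elif name == "eps_W":
        lo = max(lo, 1.0 + 1e-9)
    if lo >= hi:
        raise ValidationError(
            f"empty sampling range for {name} around {p0} (validity-domain clipped)"
        )
    return lo, hi


def _sampled_names(base: ParameterSet, frozen) -> list[str]:
    names = [n for n in base.field_names() if n not in frozen]
    unknown = set(frozen) - set(base.field_names())
    if unknown:
        raise ValidationError(f"unknown frozen parameters: {sorted(unknown)}")
    return names


def _draw_params(base: ParameterSet, names, rng, factor) -> ParameterSet:
    updates = {}
    for n in names:
        lo, hi = _sample_bounds(n, getattr(base, n), factor)
        updates[n] = rng.uniform(lo, hi)
    return base.replace(**updates)


def explore_parameter_space(
    model_name: str,
    base: ParameterSet,
    cfg: ExplorationConfig | None = None,
) -> ExplorationResult:
    """Robustness exploration: N seeded parameter draws, full genotype panel
    per draw, boxplot-style summary per mutant/WT ratio.

    Draws whose panel fails to solve are recorded and excluded; a failure
    rate above ``cfg.max_failure_rate`` aborts with diagnostics.
    """
    cfg = cfg or ExplorationConfig()
    if isinstance(base, ComplexParameterSet) and not cfg.frozen:
        cfg = dataclasses.replace(cfg, frozen=COMPLEX_FROZEN)
    names = _sampled_names(base, cfg.frozen)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    n_failures = 0
    for run in range(cfg.n_runs):
        try:
            p = _draw_params(base, names, rng, cfg.range_factor)
            table = genotype_panel(model_name, p)
        except (SolverError, ValidationError):
            n_failures += 1
            continue
        pvals = {f"param_{n}": getattr(p, n) for n in names}
        for gid in PANEL_GENOTYPES[1:]:
            for promoter in ("pB", "pW"):
                value = table.pB(gid) if promoter == "pB" else table.pW(gid)
                wt_value = table.pB("WT") if promoter == "pB" else table.pW("WT")
                rows.append(
                    {
                        "run": run,
                        "genotype": gid,
                        "promoter": promoter,
                        "value": value,
                        "wt_value": wt_value,
                        "ratio": table.ratio(gid, promoter),
                        **pvals,
                    }
                )
    if cfg.n_runs > 0 and n_failures > cfg.max_failure_rate * cfg.n_runs:
        raise SolverError(
            f"exploration aborted: {n_failures}/{cfg.n_runs} draws failed to solve"
        )
    ensemble = pd.DataFrame(rows)
    summary = summarize_ensemble(ensemble)
    return ExplorationResult(ensemble, summary, n_failures, cfg)


def summarize_ensemble(ensemble: pd.DataFrame) -> pd.DataFrame:
    """Per-ratio median, quartiles, Tukey whiskers and fraction above 1."""
    if ensemble.empty:
        return pd.DataFrame(
            columns=[
                "genotype",
                "promoter",
                "n",
                "median",
                "q1",
                "q3",
                "whisker_lo",
                "whisker_hi",
                "frac_gt_1",
            ]
        )
    rows = []
    for (gid, promoter), grp in ensemble.groupby(["genotype", "promoter"], sort=False):
        r = grp["ratio"].to_numpy()
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "genotype": gid,
                "promoter": promoter,
                "n": len(r),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": q1 - 1.5 * iqr,
                "whisker_hi": q3 + 1.5 * iqr,
                "frac_gt_1": float(np.mean(r > 1.0)),
            }
        )
    return pd.DataFrame(rows)


def single_parameter_sensitivity(
    model_name: str,
    base: ParameterSet,
    parameter: str,
    cfg: ExplorationConfig | None = None,
) -> pd.DataFrame:
    """Same protocol as the full exploration but varying one parameter only."""
    cfg = cfg or ExplorationConfig()
    if isinstance(base, ComplexParameterSet) and not cfg.frozen:
        cfg = dataclasses.replace(cfg, frozen=COMPLEX_FROZEN)
    if parameter not in base.field_names():
        raise ValidationError(f"unknown parameter {parameter!r}")
    if parameter in cfg.frozen:
        raise ValidationError(f"parameter {parameter!r} is frozen in this exploration")
    sub = dataclasses.replace(cfg, frozen=tuple(
        n for n in base.field_names() if n != parameter
    ))
    result = explore_parameter_space(model_name, base, sub)
    return result.ensemble


def sweep_medium(
    model_name: str,
    base: ParameterSet,
    x_values,
) -> pd.DataFrame:
    """Genotype panels across medium conditions.

    Per x, alpha and gamma are overridden by the medium-condition functions
    (alpha = 0.3/x, gamma = 250x/(x+9)); all other parameters stay fixed.
    The output flags whether each mutant/WT ratio keeps the same side of 1
    across the sweep (column ``side_of_1_stable``, identical in all rows of
    one genotype x promoter).
    """
    rows = []
    for x in x_values:
        alpha, gamma = medium_condition_params(MediumCondition(float(x)))
        p = base.replace(alpha=alpha, gamma=gamma)
        table = genotype_panel(model_name, p)
        for gid in PANEL_GENOTYPES[1:]:
            for promoter in ("pB", "pW"):
                rows.append(
                    {
                        "x": float(x),
                        "alpha": alpha,
                        "gamma": gamma,
                        "genotype": gid,
                        "promoter": promoter,
                        "ratio": table.ratio(gid, promoter),
                    }
                )
    df = pd.DataFrame(rows)
    stable = (
        df.assign(above=df.ratio > 1.0)
        .groupby(["genotype", "promoter"])["above"]
        .transform(lambda s: s.all() or (~s).all())
    )
    df["side_of_1_stable"] = stable
    return df


def compare_model_robustness(
    base_alleviation: ParameterSet,
    base_activation: ParameterSet,
    cfg: ExplorationConfig | None = None,
) -> dict:
    """Fraction of exploration draws in which each two-variable model shows
    the experimentally observed increase of WOX5 promoter activity in the
    double mutant (ratio >= 1).  Reported, not asserted: the alleviation
    model is expected to be the more robust one.
    """
    cfg = cfg or ExplorationConfig()
    out = {}
    for name, base in (
        ("alleviation", base_alleviation),
        ("activation", base_activation),
    ):
        res = explore_parameter_space(name, base, cfg)
        ens = res.ensemble
        sel = ens[(ens.genotype == "bravo_wox5") & (ens.promoter == "pW")]
        out[name] = float(np.mean(sel["ratio"].to_numpy() >= 1.0)) if len(sel) else float("nan")
    return out
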