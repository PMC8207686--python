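"""Model classes: two-variable effective-regulation models and the
six-species complex-formation model.

Each model exposes a right-hand side ``rhs(state, genotype)``, the clamp
pattern a genotype imposes, and the stationary promoter read-outs
``promoter_activities`` (the endogenous production terms pB, pW evaluated at
a state — the quantity compared with reporter GFP).  Steady states are
obtained through :mod:`qcniche.solver`.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    ComplexParameterSet,
    GenotypeSpec,
    ParameterSet,
    ValidationError,
)
from . import promoters as prom

__all__ = ["TwoVariableModel", "ComplexFormationModel", "get_model", "MODEL_NAMES"]

MODEL_NAMES = ("alleviation", "activation", "complex")


class TwoVariableModel:
    """dB/dt = alpha*A0 + P_B(B,W) - d_B B ; dW/dt = gamma*G0 + P_W(B,W) - d_W W.

    ``variant`` selects the WOX5 promoter: 'alleviation' (BRAVO weakens WOX5
    self-repression) or 'activation' (BRAVO activates the WOX5 promoter).
    Knockout genotypes clamp an expression to zero at all times; the clamped
    variable's derivative is forced to zero and its value is treated as zero
    inside the promoter functions.
    """

    n_species = 2
    species = ("B", "W")

    def __init__(self, variant: str, params: ParameterSet):
        if variant not in ("alleviation", "activation"):
            raise ValidationError(
                f"unknown model variant {variant!r}; expected 'alleviation' or 'activation'"
            )
        self.variant = variant
        self.params = params

    def with_params(self, params: ParameterSet) -> "TwoVariableModel":
        return TwoVariableModel(self.variant, params)

    @property
    def name(self) -> str:
        return self.variant

    def clamp_mask(self, g: GenotypeSpec) -> np.ndarray:
        return np.array([g.clamp_B, g.clamp_W], dtype=bool)

    def _pw(self, B, W):
        if self.variant == "alleviation":
            return prom.promoter_wox5_alleviation(B, W, self.params)
        return prom.promoter_wox5_activation(B, W, self.params)

    def apply_clamps(self, state: np.ndarray, g: GenotypeSpec) -> np.ndarray:
        state = np.array(state, dtype=float)
        state[self.clamp_mask(g)] = 0.0
        return state

    def promoter_activities(self, state, g: GenotypeSpec) -> tuple[float, float]:
        """Endogenous promoter activities (pB, pW) at a state.

        Overexpression terms alpha*A0 / gamma*G0 are production from the
        transgene, not the endogenous promoter, and are excluded.
        """
        B, W = self.apply_clamps(state, g)
        return float(prom.promoter_bravo(B, W, self.params)), float(self._pw(B, W))

    def rhs(self, state, g: GenotypeSpec) -> np.ndarray:
        p = self.params
        B, W = self.apply_clamps(state, g)
        dB = p.alpha * g.A0 + prom.promoter_bravo(B, W, p) - p.d_B * B
        dW = p.gamma * g.G0 + self._pw(B, W) - p.d_W * W
        out = np.array([dB, dW], dtype=float)
        out[self.clamp_mask(g)] = 0.0
        return out

    def state_scale(self, g: GenotypeSpec) -> np.ndarray:
        """Upper bounds on the stationary values, used for brackets/scaling."""
        p = self.params
        b_max = p.alpha * (g.A0 + max(1.0, p.eps_W)) / p.d_B
        gmax = p.gamma * (1.0 + p.B1) if self.variant == "activation" else p.gamma
        w_max = (p.gamma * g.G0 + gmax) / p.d_W
        return np.array([b_max, w_max])


class ComplexFormationModel:
    """Mass-action model of free BRAVO (B), WOX5 (W) and competitor S plus
    the pairwise heterodimers C_BW, C_BS, C_WS.

    Production of B follows the BRAVO promoter logic evaluated on the free
    proteins; production of W carries only WOX5 self-repression; S is
    produced at the constant rate beta.  Heterodimers form with rate
    lambda_XY, unbind with mu_XY, decay with d_XY, and are transcriptionally
    inert.  Knockouts clamp the free protein and every complex containing it
    (their only source term vanishes).
    """

    n_species = 6
    species = ("B", "W", "S", "C_BW", "C_BS", "C_WS")
    name = "complex"

    def __init__(self, params: ComplexParameterSet):
        if not isinstance(params, ComplexParameterSet):
            raise ValidationError("complex model requires a ComplexParameterSet")
        self.params = params

    def with_params(self, params: ComplexParameterSet) -> "ComplexFormationModel":
        return ComplexFormationModel(params)

    def clamp_mask(self, g: GenotypeSpec) -> np.ndarray:
        mask = np.zeros(6, dtype=bool)
        if g.clamp_B:
            mask[[0, 3, 4]] = True  # B, C_BW, C_BS
        if g.clamp_W:
            mask[[1, 3, 5]] = True  # W, C_BW, C_WS
        return mask

    def apply_clamps(self, state: np.ndarray, g: GenotypeSpec) -> np.ndarray:
        state = np.array(state, dtype=float)
        state[self.clamp_mask(g)] = 0.0
        return state

    def promoter_activities(self, state, g: GenotypeSpec) -> tuple[float, float]:
        B, W = self.apply_clamps(state, g)[:2]
        p = self.params
        return (
            float(prom.promoter_bravo(B, W, p)),
            float(prom.promoter_wox5_selfrepression(W, p)),
        )

    def rhs(self, state, g: GenotypeSpec) -> np.ndarray:
        p = self.params
        B, W, S, C_BW, C_BS, C_WS = self.apply_clamps(state, g)
        PB = prom.promoter_bravo(B, W, p)
        PW = prom.promoter_wox5_selfrepression(W, p)
        dB = (
            p.alpha * g.A0
            + PB
            - p.lambda_BW * B * W
            + p.mu_BW * C_BW
            - p.lambda_BS * B * S
            + p.mu_BS * C_BS
            - p.d_B * B
        )
        dW = (
            p.gamma * g.G0
            + PW
            - p.lambda_BW * B * W
            + p.mu_BW * C_BW
            - p.lambda_WS * W * S
            + p.mu_WS * C_WS
            - p.d_W * W
        )
        dS = (
            p.beta
            - p.lambda_BS * B * S
            + p.mu_BS * C_BS
            - p.lambda_WS * W * S
            + p.mu_WS * C_WS
            - p.d_S * S
        )
        dC_BW = p.lambda_BW * B * W - (p.mu_BW + p.d_BW) * C_BW
        dC_BS = p.lambda_BS * B * S - (p.mu_BS + p.d_BS) * C_BS
        dC_WS = p.lambda_WS * W * S - (p.mu_WS + p.d_WS) * C_WS
        out = np.array([dB, dW, dS, dC_BW, dC_BS, dC_WS], dtype=float)
        out[self.clamp_mask(g)] = 0.0
        return out

    def state_scale(self, g: GenotypeSpec) -> np.ndarray:
        p = self.params
        b_max = p.alpha * (g.A0 + max(1.0, p.eps_W)) / p.d_B
        w_max = (p.gamma * g.G0 + p.gamma) / p.d_W
        s_max = p.beta / p.d_S if p.beta > 0 else 1.0
        return np.array(
            [
                b_max,
                w_max,
                s_max,
                max(b_max * w_max, 1.0),
                max(b_max * s_max, 1.0),
                max(w_max * s_max, 1.0),
            ]
        )


def free_fraction_report(steady) -> dict:
    """Free vs bound BRAVO and WOX5 at a converged complex-model steady state.

    Total BRAVO counts free B plus the complexes containing it (C_BW, C_BS);
    total WOX5 counts free W plus C_BW and C_WS.  Input must be a converged
    six-species :class:`~qcniche.solver.SteadyState`.
    """
    state = np.asarray(steady.state, dtype=float)
    if state.shape != (6,):
        raise ValueError("free_fraction_report requires a six-species steady state")
    if not getattr(steady, "stable", False) and steady.residual_norm > 1e-6:
        raise ValueError("steady state has not converged")
    B, W, S, C_BW, C_BS, C_WS = state
    total_B = B + C_BW + C_BS
    total_W = W + C_BW + C_WS
    return {
        "free_B": B,
        "free_W": W,
        "total_B": total_B,
        "total_W": total_W,
        "free_fraction_B": B / total_B if total_B > 0 else 1.0,
        "free_fraction_W": W / total_W if total_W > 0 else 1.0,
    }


def get_model(name: str, params: ParameterSet):
    """Instantiate a model by name ('alleviation', 'activation', 'complex')."""
    if name in ("alleviation", "activation"):
        return TwoVariableModel(name, params)
    if name == "complex":
        return ComplexFormationModel(params)
    raise ValidationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
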