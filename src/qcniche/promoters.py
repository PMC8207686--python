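"""Promoter-activity functions (Hill-type effective regulations, exponent 2).

All intermediate translational/post-translational steps are absorbed into
these production terms.  The BRAVO promoter carries a basal rate alpha,
self-inhibition (floor eps_B < 1) and activation by WOX5 (ceiling eps_W > 1).
The two WOX5 promoter variants share WOX5 self-repression (threshold W0) and
differ in what BRAVO does:

* alleviation — BRAVO weakens the WOX5 self-repression.  The repression
  strength factor is ``B1*B0^2/(B^2+B0^2) + 1``: it equals ``1 + B1`` with no
  BRAVO (maximal repression) and decays to 1 at high BRAVO, so B1 sets the
  maximum alleviation and B0 its BRAVO threshold.
* activation — BRAVO multiplies the promoter by ``1 + B1*B^2/(B^2+B0^2)``,
  a WOX5-independent activation of maximum strength B1.

The complex-formation model's WOX5 production keeps only the self-repression
factor.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "promoter_bravo",
    "promoter_wox5_alleviation",
    "promoter_wox5_activation",
    "promoter_wox5_selfrepression",
]


def _check_nonnegative(B, W) -> None:
    if np.any(np.asarray(B) < 0) or np.any(np.asarray(W) < 0):
        raise ValueError("expressions must be non-negative")


def promoter_bravo(B, W, p: ParameterSet):
    """BRAVO promoter activity P_B(B, W).

    ``alpha * [1 + eps_B (K_B B)^2]/[1 + (K_B B)^2]
            * [1 + eps_W (K_W W)^2]/[1 + (K_W W)^2]``

    Equals alpha at (0, 0), decreases to alpha*eps_B at high BRAVO and rises
    to alpha*eps_W at high WOX5.
    """
    _check_nonnegative(B, W)
    b2 = (p.K_B * np.asarray(B, dtype=float)) ** 2
    w2 = (p.K_W * np.asarray(W, dtype=float)) ** 2
    return p.alpha * (1 + p.eps_B * b2) / (1 + b2) * (1 + p.eps_W * w2) / (1 + w2)


def promoter_wox5_alleviation(B, W, p: ParameterSet):
    """WOX5 promoter activity, alleviation variant.

    ``gamma * W0^2 / (W0^2 + W^2 * [B1*B0^2/(B^2+B0^2) + 1]^2)``

    Basal rate gamma at (0, 0); in the absence of BRAVO the self-repression
    factor is maximal, (1+B1)^2, and high BRAVO alleviates it back to 1.
    """
    _check_nonnegative(B, W)
    B = np.asarray(B, dtype=float)
    W = np.asarray(W, dtype=float)
    repression = p.B1 * p.B0**2 / (B**2 + p.B0**2) + 1.0
    return p.gamma * p.W0**2 / (p.W0**2 + W**2 * repression**2)


def promoter_wox5_activation(B, W, p: ParameterSet):
    """WOX5 promoter activity, activation variant.

    ``gamma * [W0^2/(W0^2 + W^2)] * [1 + B1*B^2/(B^2+B0^2)]``
    """
    _check_nonnegative(B, W)
    B = np.asarray(B, dtype=float)
    W = np.asarray(W, dtype=float)
    return (
        p.gamma
        * p.W0**2
        / (p.W0**2 + W**2)
        * (1.0 + p.B1 * B**2 / (B**2 + p.B0**2))
    )


def promoter_wox5_selfrepression(W, p: ParameterSet):
    """WOX5 production of the complex-formation model: self-repression only."""
    if np.any(np.asarray(W) < 0):
        raise ValueError("expressions must be non-negative")
    W = np.asarray(W, dtype=float)
    return p.gamma * p.W0**2 / (p.W0**2 + W**2)
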