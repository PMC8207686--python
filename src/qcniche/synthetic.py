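"""Synthetic observations with the statistical structure the analysis
assumes: per-root GFP reporter intensities (lognormal, genotype-specific
mean fold-changes) and per-root binary divided/non-divided QC observations
(Bernoulli trials).

These generators emulate the quantification of reporter images and QC
division counts; they make every pipeline stage testable end-to-end with no
external data.  The intensity scale is arbitrary — only fold-changes carry
information — and the defaults (WT mean 100 a.u., coefficient of variation
0.3) are stand-ins for unpublished per-root dispersion, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import FoldChangeTable

__all__ = [
    "GfpSample",
    "DivisionObservations",
    "generate_gfp",
    "estimate_foldchanges_from_gfp",
    "generate_division_observations",
]


@dataclass(frozen=True)
class GfpSample:
    """Per-root reporter intensities for one genotype and reporter."""

    genotype: str
    reporter: str  # 'pBRAVO' or 'pWOX5'
    intensities: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or len(arr) < 1:
            raise ValueError("need at least one intensity per (genotype, reporter)")
        if np.any(arr <= 0):
            raise ValueError("intensities must be positive")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class DivisionObservations:
    """Binary divided-QC counts for one genotype."""

    genotype: str
    n_roots: int
    n_divided: int

    def __post_init__(self):
        if not 0 <= self.n_divided <= self.n_roots:
            raise ValueError("need 0 <= n_divided <= n_roots")

    @property
    def frequency(self) -> float:
        return self.n_divided / self.n_roots


_REPORTER_KEY = {"pBRAVO": "pB", "pWOX5": "pW"}


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    # mean/cv parametrization: sigma^2 = ln(1+cv^2), mu = ln(mean) - sigma^2/2
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_gfp(
    foldchanges,
    wt_mean: float = 100.0,
    cv: float = 0.3,
    n_roots: int = 30,
    seed: int = 0,
) -> list[GfpSample]:
    """Draw per-root reporter intensities per genotype.

    ``foldchanges`` is either a :class:`~qcniche.panel.FoldChangeTable` or a
    mapping ``{(genotype, reporter): fold-change}``.  Intensities follow a
    lognormal law with group mean ``wt_mean * fold-change`` and coefficient
    of variation ``cv`` (multiplicative biological scatter, positive
    support).  ``cv = 0`` degenerates to every intensity equal to its group
    mean.  Fully reproducible under a fixed seed.
    """
    if wt_mean <= 0:
        raise ValueError("wt_mean must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")

    if isinstance(foldchanges, FoldChangeTable):
        fc_map = {
            (g, rep): foldchanges.ratio(g, key)
            for g in foldchanges.raw
            for rep, key in _REPORTER_KEY.items()
        }
    else:
        fc_map = dict(foldchanges)

    rng = np.random.default_rng(seed)
    samples = []
    for (genotype, reporter), fc in sorted(fc_map.items()):
        if fc <= 0:
            raise ValueError(
                f"fold-change for ({genotype}, {reporter}) must be positive, got {fc}"
            )
        mean = wt_mean * fc
        if cv == 0:
            vals = np.full(n_roots, mean)
        else:
            mu, sigma = _lognormal_params(mean, cv)
            vals = rng.lognormal(mu, sigma, size=n_roots)
        samples.append(GfpSample(genotype, reporter, vals))
    return samples


def estimate_foldchanges_from_gfp(samples: list[GfpSample]) -> pd.DataFrame:
    """Fold-changes of group-mean intensity vs WT, with propagated errors.

    Per reporter, the ratio is mean(mutant)/mean(WT); the error is
    ``sqrt((dm/w)^2 + (m*dw/w^2)^2)`` with each group's standard deviation
    as its delta — the same propagation applied to the measured GFP data.
    """
    rows = []
    by_reporter: dict[str, dict[str, GfpSample]] = {}
    for s in samples:
        by_reporter.setdefault(s.reporter, {})[s.genotype] = s
    for reporter, groups in sorted(by_reporter.items()):
        if "WT" not in groups:
            raise ValueError(f"missing WT group for reporter {reporter}")
        w = float(np.mean(groups["WT"].intensities))
        dw = float(np.std(groups["WT"].intensities, ddof=1)) if len(
            groups["WT"].intensities
        ) > 1 else 0.0
        for genotype, s in sorted(groups.items()):
            m = float(np.mean(s.intensities))
            dm = float(np.std(s.intensities, ddof=1)) if len(s.intensities) > 1 else 0.0
            ratio = m / w
            err = float(np.sqrt((dm / w) ** 2 + (m * dw / w**2) ** 2))
            rows.append(
                {
                    "genotype": genotype,
                    "reporter": reporter,
                    "n": len(s.intensities),
                    "mean": m,
                    "sd": dm,
                    "ratio": ratio,
                    "ratio_error": err,
                }
            )
    return pd.DataFrame(rows)


def generate_division_observations(
    frequencies: dict,
    n_roots,
    seed: int = 0,
) -> list[DivisionObservations]:
    """Binomial divided-QC counts per genotype.

    ``frequencies`` maps genotype -> division probability in [0, 1];
    ``n_roots`` is an int (shared) or a per-genotype mapping.
    """
    rng = np.random.default_rng(seed)
    out = []
    for genotype, p in sorted(frequencies.items()):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency for {genotype} must lie in [0, 1], got {p}")
        n = n_roots[genotype] if isinstance(n_roots, dict) else int(n_roots)
        if n < 1:
            raise ValueError("n_roots must be >= 1")
        out.append(DivisionObservations(genotype, n, int(rng.binomial(n, p))))
    return out
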