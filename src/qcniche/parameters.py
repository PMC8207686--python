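"""Parameter sets, genotypes and medium conditions for the QC niche models.

The two-variable models track total *BRAVO* (B) and total *WOX5* (W)
expression in the stem cell niche.  The complex-formation model tracks free
BRAVO, WOX5 and a competitor protein S plus the three pairwise heterodimers.
Genotypes are in-silico perturbations: knockouts clamp an expression to zero
at all times (the promoter is still evaluated at the clamped state), and
overexpression adds a constant production term on top of the endogenous
promoter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "ComplexParameterSet",
    "GenotypeSpec",
    "MediumCondition",
    "medium_condition_params",
    "GENOTYPES",
    "genotype",
    "save_params",
    "load_params",
    "default_parameters",
]


class ValidationError(ValueError):
    """A parameter set or genotype violates a model-class invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic/regulatory constants of the two-variable models.

    Attributes
    ----------
    alpha : float
        Basal BRAVO promoter rate (expression/time).
    gamma : float
        Basal WOX5 promoter rate (expression/time).
    eps_B : float
        BRAVO self-inhibition floor; must satisfy ``eps_B < 1``.
    eps_W : float
        WOX5->BRAVO activation ceiling; must satisfy ``eps_W > 1``.
    K_B, K_W : float
        Inverse regulation thresholds (1/expression) of the BRAVO
        self-inhibition and the WOX5->BRAVO activation.
    W0 : float
        WOX5 self-repression threshold (expression).
    B0 : float
        BRAVO alleviation/activation threshold (expression).
    B1 : float
        Maximum alleviation (or activation) strength (dimensionless).
    d_B, d_W : float
        Linear decay rates (1/time).
    """

    alpha: float = 0.3
    gamma: float = 25.0
    eps_B: float = 0.5
    eps_W: float = 2.0
    K_B: float = 1.0
    K_W: float = 0.5
    W0: float = 10.0
    B0: float = 0.5
    B1: float = 1.0
    d_B: float = 1.0
    d_W: float = 1.0

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")
        if not self.eps_B < 1:
            raise ValidationError(
                f"eps_B must be < 1 (self-inhibition), got {self.eps_B}"
            )
        if not self.eps_W > 1:
            raise ValidationError(f"eps_W must exceed 1 (activation), got {self.eps_W}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        unknown = set(d) - set(cls.field_names())
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class ComplexParameterSet(ParameterSet):
    """Parameters of the six-species complex-formation model.

    Extends :class:`ParameterSet` with the competitor-protein production rate
    ``beta``, pairwise mass-action binding (``lambda_XY``), unbinding
    (``mu_XY``) and heterodimer decay (``d_XY``) rates, and the free-S decay
    ``d_S``.  In this model the WOX5 production term carries only WOX5
    self-repression, so ``B0``/``B1`` are unused.  ``beta = 0`` together with
    all binding rates zero recovers the two-variable submodel.
    """

    W0: float = 1.0
    beta: float = 10.0
    lambda_BW: float = 5.0
    lambda_BS: float = 2.0
    lambda_WS: float = 2.0
    mu_BW: float = 0.2
    mu_BS: float = 1.0
    mu_WS: float = 1.0
    d_BW: float = 0.2
    d_BS: float = 1.0
    d_WS: float = 1.0
    d_S: float = 1.0

    _NONNEG = ("beta", "lambda_BW", "lambda_BS", "lambda_WS")

    def _validate(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not isinstance(v, (int, float)):
                raise ValidationError(f"{name} must be numeric, got {v!r}")
            if name in self._NONNEG:
                if v < 0:
                    raise ValidationError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if not self.eps_B < 1:
            raise ValidationError(f"eps_B must be < 1, got {self.eps_B}")
        if not self.eps_W > 1:
            raise ValidationError(f"eps_W must exceed 1, got {self.eps_W}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(
            f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")
        )


@dataclass(frozen=True)
class GenotypeSpec:
    """An in-silico genotype: clamps and/or additive overexpression.

    Knockouts hold the mutated gene's expression at zero at all times while
    the promoter activity is still evaluated (at the clamped state);
    parameter values are never changed in mutants.  Overexpression adds
    ``alpha*A0`` (BRAVO) or ``gamma*G0`` (WOX5) to the production term.
    """

    id: str
    clamp_B: bool = False
    clamp_W: bool = False
    A0: float = 0.0
    G0: float = 0.0

    def __post_init__(self) -> None:
        if self.A0 < 0 or self.G0 < 0:
            raise ValidationError("overexpression extents must be non-negative")
        if self.clamp_B and self.A0 > 0:
            raise ValidationError("cannot clamp and overexpress BRAVO simultaneously")
        if self.clamp_W and self.G0 > 0:
            raise ValidationError("cannot clamp and overexpress WOX5 simultaneously")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeSpec":
        return cls(**d)


# A0/G0 default: high enough that the regulated read-out is saturated; the
# solver-side saturation check escalates x10 if it is not (see panel module).
DEFAULT_OE_EXTENT = 100.0

GENOTYPES: dict[str, GenotypeSpec] = {
    "WT": GenotypeSpec("WT"),
    "bravo": GenotypeSpec("bravo", clamp_B=True),
    "wox5": GenotypeSpec("wox5", clamp_W=True),
    "bravo_wox5": GenotypeSpec("bravo_wox5", clamp_B=True, clamp_W=True),
    "BRAVO_OE": GenotypeSpec("BRAVO_OE", A0=DEFAULT_OE_EXTENT),
    "WOX5_OE": GenotypeSpec("WOX5_OE", G0=DEFAULT_OE_EXTENT),
}


def genotype(gid: str) -> GenotypeSpec:
    """Look up one of the six canonical genotypes by id."""
    try:
        return GENOTYPES[gid]
    except KeyError:
        raise ValidationError(
            f"unknown genotype {gid!r}; expected one of {sorted(GENOTYPES)}"
        ) from None


@dataclass(frozen=True)
class MediumCondition:
    """Growth-medium control parameter; x = 1 is control, larger x mimics BL."""

    x: float = 1.0

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValidationError(f"medium parameter x must be positive, got {self.x}")


def medium_condition_params(m: MediumCondition | float) -> tuple[float, float]:
    """Basal production rates (alpha, gamma) as functions of the medium.

    alpha = 0.3/x decreases and gamma = 250x/(x+9) increases with x, so x
    controls the disparity between the basal BRAVO and WOX5 production;
    x = 1 gives the control-medium values (0.3, 25).
    """
    x = m.x if isinstance(m, MediumCondition) else float(m)
    if x <= 0:
        raise ValidationError(f"medium parameter x must be positive, got {x}")
    return 0.3 / x, 250.0 * x / (x + 9.0)


# ---------------------------------------------------------------------------
# Config (YAML) serialization


def save_params(p: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to a YAML config with exact field names."""
    payload = {
        "kind": type(p).__name__,
        "parameters": p.to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_params(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` or :class:`ComplexParameterSet` from YAML."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "parameters" not in payload:
        raise ValidationError(f"{path}: expected a mapping with a 'parameters' key")
    kind = payload.get("kind", "ParameterSet")
    cls = {"ParameterSet": ParameterSet, "ComplexParameterSet": ComplexParameterSet}.get(
        kind
    )
    if cls is None:
        raise ValidationError(f"{path}: unknown parameter kind {kind!r}")
    return cls.from_dict(payload["parameters"])


_DATA_DIR = Path(__file__).parent / "data"

_DEFAULT_FILES = {
    "alleviation": "alleviation_calibrated.yaml",
    "activation": "activation_calibrated.yaml",
    "complex": "complex_default.yaml",
}


def default_parameters(model: str) -> ParameterSet:
    """Shipped default parameter set for a model variant.

    The two-variable defaults were produced by the calibration pipeline
    against the experimental promoter fold-changes (alpha and gamma fixed at
    their control-medium values); the complex-model defaults are chosen so
    that the BRAVO-WOX5 heterodimer is a non-trivial fraction of total WOX5
    in the WT.
    """
    try:
        fname = _DEFAULT_FILES[model]
    except KeyError:
        raise ValidationError(
            f"unknown model {model!r}; expected one of {sorted(_DEFAULT_FILES)}"
        ) from None
    return load_params(_DATA_DIR / fname)
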