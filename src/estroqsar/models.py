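"""Linear QSAR models of antioxidant potency.

The response throughout is −log₁₀(IC50) with IC50 in molar units, so larger
values mean a more potent inhibitor of lipid peroxidation.  The module
ships the eight published equations relating that response to subsets of
{BDE, SI_k1, SA, logP, HOMO} for ~70 estradiol-related polycyclic phenols,
and provides prediction plus classification of a candidate as more or less
potent than a reference compound (17β-estradiol, E2, in the original
application).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector


class MissingDescriptorError(KeyError):
    """A model requires a descriptor value the vector does not supply."""


@dataclass(frozen=True)
class Coefficient:
    value: float
    stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error must be >= 0")


@dataclass
class LinearQSARModel:
    """−log(IC50) = intercept + Σ coefficient·descriptor, with the fit
    statistics reported for the training regression."""

    name: str
    intercept: Coefficient
    coefficients: dict[str, Coefficient]  # ordered, descriptor name -> coef
    r: Optional[float] = None  # multiple correlation coefficient
    F: Optional[float] = None  # ANOVA variance ratio
    p: Optional[float] = None
    n: Optional[int] = None  # training-set size

    def __post_init__(self) -> None:
        for name in self.coefficients:
            if name not in DESCRIPTOR_NAMES:
                raise ValueError(f"unknown descriptor {name!r} in {self.name}")
        if self.r is not None and not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if self.F is not None and self.F < 0:
            raise ValueError("F must be >= 0")

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    # ------------------------------------------------------------ serialise
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": {"value": self.intercept.value, "stderr": self.intercept.stderr},
            "coefficients": {
                k: {"value": c.value, "stderr": c.stderr}
                for k, c in self.coefficients.items()
            },
            "r": self.r,
            "F": self.F,
            "p": self.p,
            "n": self.n,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearQSARModel":
        return cls(
            name=d["name"],
            intercept=Coefficient(**d["intercept"]),
            coefficients={k: Coefficient(**c) for k, c in d["coefficients"].items()},
            r=d.get("r"),
            F=d.get("F"),
            p=d.get("p"),
            n=d.get("n"),
        )

    @classmethod
    def from_json(cls, s: str) -> "LinearQSARModel":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PotencyPrediction:
    neglog_ic50: float  # −log10 of molar IC50
    ic50: float  # molar
    model: str
    descriptors: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PotencyClass:
    """Outcome of comparing a candidate with a reference compound;
    ``margin`` is the difference in predicted −log(IC50)."""

    label: str  # more_potent | less_potent | tie
    margin: float


def published_models() -> list[LinearQSARModel]:
    """The eight reported regression equations, with coefficients, standard
    errors and fit statistics exactly as printed.

    p-values were reported significant (< 0.001) for all models; only the
    first equation prints the bound explicitly, so ``p`` carries that bound
    for Eq1 and ``None`` elsewhere.
    """

    def m(name, intercept, coefs, r, F, p=None, n=70):
        return LinearQSARModel(
            name=name,
            intercept=Coefficient(*intercept),
            coefficients={k: Coefficient(*v) for k, v in coefs.items()},
            r=r,
            F=F,
            p=p,
            n=n,
        )

    return [
        m("Eq1", (13.6, 3.4), {"BDE": (-0.179, 0.042)}, 0.46, 18.11, p=0.001),
        m("Eq2", (-2.69, 0.36), {"SI_k1": (0.118, 0.021)}, 0.55, 29.85),
        m("Eq3", (-3.03, 0.41), {"SA": (0.00728, 0.0031)}, 0.56, 30.97),
        m("Eq4", (-2.27, 0.27), {"logP": (0.295, 0.052)}, 0.57, 32.42),
        m(
            "Eq5",
            (6.48, 3.42),
            {"logP": (0.237, 0.0547), "BDE": (-0.105, 0.041)},
            0.58,
            20.83,
        ),
        m(
            "Eq6",
            (6.23, 2.63),
            {"logP": (0.288, 0.048), "HOMO": (0.988, 0.304)},
            0.64,
            23.78,
        ),
        m(
            "Eq7",
            (2.56, 0.36),
            {"logP": (0.186, 0.102), "SI_k1": (0.0522, 0.0421)},
            0.58,
            17.10,
        ),
        m(
            "Eq8",
            (18.5, 4.3),
            {"logP": (0.209, 0.050), "BDE": (-0.130, 0.037), "HOMO": (1.16, 0.29)},
            0.71,
            22.60,
        ),
    ]


def get_model(name: str) -> LinearQSARModel:
    for model in published_models():
        if model.name == name:
            return model
    raise KeyError(f"no published model named {name!r}")


def predict(model: LinearQSARModel, d: DescriptorVector | Mapping) -> PotencyPrediction:
    """Evaluate the linear model: −log(IC50) = intercept + Σ coeff·value,
    and back-transform to a molar IC50."""
    getter = d.get if hasattr(d, "get") else d.__getitem__
    used = {}
    y = model.intercept.value
    for name, coef in model.coefficients.items():
        value = getter(name)
        if value is None:
            raise MissingDescriptorError(
                f"model {model.name} needs descriptor {name!r}, not supplied"
            )
        used[name] = value
        y += coef.value * value
    return PotencyPrediction(
        neglog_ic50=y, ic50=10.0 ** (-y), model=model.name, descriptors=used
    )


def classify_vs_reference(
    model: LinearQSARModel,
    candidate: DescriptorVector | Mapping,
    reference: DescriptorVector | Mapping,
    tie_tol: float = 1e-9,
) -> PotencyClass:
    """Classify a candidate as more or less potent than the reference by
    comparing the model's predictions for both (predicted-vs-predicted;
    the experimental reference IC50 never enters).

    The margin is candidate − reference in −log(IC50) space: positive
    means the candidate is predicted the stronger antioxidant.
    """
    margin = (
        predict(model, candidate).neglog_ic50
        - predict(model, reference).neglog_ic50
    )
    if margin > tie_tol:
        label = "more_potent"
    elif margin < -tie_tol:
        label = "less_potent"
    else:
        label = "tie"
    return PotencyClass(label=label, margin=margin)
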