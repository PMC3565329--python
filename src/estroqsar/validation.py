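"""Internal and external validation of the potency models.

Internal checks: refitting after randomly leaving out 10% of the training
compounds (coefficient and correlation stability) and y-randomization
(refitting after permuting the responses, to rule out chance correlation).

External check: classify an independent compound set as more or less
potent than a reference compound and tally false positives (observed less
potent, predicted more potent), false negatives (observed more potent,
predicted less potent) and correct predictions — the bookkeeping used to
score the published models against an independently assayed estrogen set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .descriptors import DescriptorVector
from .models import LinearQSARModel, classify_vs_reference
from .regression import FitResult, TrainingTable, fit_ols


@dataclass(frozen=True)
class ExternalCompound:
    id: str
    descriptors: DescriptorVector
    observed_label: str  # more_potent | less_potent (relative to reference)

    def __post_init__(self) -> None:
        if self.observed_label not in ("more_potent", "less_potent"):
            raise ValueError(f"bad label {self.observed_label!r}")


@dataclass
class ValidationReport:
    """Confusion counts for one model over an external set.  Ties are
    counted as incorrect (no tie category exists in the observed labels)
    and reported separately in ``ties``."""

    model_name: str
    false_positives: int
    false_negatives: int
    correct: int
    ties: int = 0

    @property
    def total(self) -> int:
        return self.false_positives + self.false_negatives + self.correct + self.ties

    def rates(self) -> dict[str, float]:
        """Percentages of the external-set size (exact floats; see
        :func:`pool_reports` for display rounding)."""
        t = self.total
        return {
            "correct": 100.0 * self.correct / t,
            "false_positives": 100.0 * self.false_positives / t,
            "false_negatives": 100.0 * self.false_negatives / t,
        }


@dataclass
class LeaveGroupOutResult:
    full_fit: FitResult
    reduced_fit: FitResult
    kept_ids: list[str]
    left_out_ids: list[str]

    @property
    def coefficient_deltas(self) -> dict[str, float]:
        full = self.full_fit.model
        red = self.reduced_fit.model
        deltas = {"intercept": red.intercept.value - full.intercept.value}
        for name, coef in full.coefficients.items():
            deltas[name] = red.coefficients[name].value - coef.value
        return deltas

    @property
    def r_values(self) -> tuple[float, float]:
        return self.full_fit.model.r, self.reduced_fit.model.r


def leave_group_out(
    table: TrainingTable,
    model_spec: Sequence[str],
    fraction: float = 0.10,
    seed: int = 0,
) -> LeaveGroupOutResult:
    """Refit after randomly leaving out a fraction of the training set.

    The left-out count is round(fraction·n) with round-half-to-even, so
    10% of 70 compounds leaves 63 in.  Deterministic given the seed.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = table.n
    n_out = int(round(fraction * n))
    n_kept = n - n_out
    if n_kept < len(model_spec) + 2:
        raise ValueError(
            f"reduced set of {n_kept} rows too small for {len(model_spec)} predictors"
        )
    rng = np.random.default_rng(seed)
    out_idx = set(rng.choice(n, size=n_out, replace=False).tolist())
    keep = [i for i in range(n) if i not in out_idx]
    reduced = TrainingTable(
        ids=[table.ids[i] for i in keep],
        descriptors=table.descriptors.iloc[keep].reset_index(drop=True),
        y=table.y[keep],
    )
    return LeaveGroupOutResult(
        full_fit=fit_ols(table, model_spec),
        reduced_fit=fit_ols(reduced, model_spec),
        kept_ids=[table.ids[i] for i in keep],
        left_out_ids=[table.ids[i] for i in sorted(out_idx)],
    )


@dataclass
class YRandomizationResult:
    null_r: np.ndarray
    null_F: np.ndarray
    real_r: float
    real_F: float

    @property
    def r_quantile(self) -> float:
        """Fraction of permuted fits whose r falls below the real model's."""
        return float(np.mean(self.null_r < self.real_r))


def y_randomization(
    table: TrainingTable,
    model_spec: Sequence[str],
    n_perm: int = 200,
    seed: int = 0,
) -> YRandomizationResult:
    """Null distribution of (r, F) under response permutation.

    A model whose correlation survives y-scrambling near the top of the
    null distribution is unlikely to be a chance correlation.  For the
    signed-r bookkeeping the permuted r keeps the sign of the fitted slope
    when a single predictor is used (multiple-r is non-negative by
    construction, which would fold the null in half).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    real = fit_ols(table, model_spec)
    single = len(model_spec) == 1

    def signed_r(fit: FitResult) -> float:
        r = fit.model.r
        if single:
            slope = next(iter(fit.model.coefficients.values())).value
            return r if slope >= 0 else -r
        return r

    null_r = np.empty(n_perm)
    null_F = np.empty(n_perm)
    for b in range(n_perm):
        permuted = TrainingTable(
            ids=table.ids,
            descriptors=table.descriptors,
            y=rng.permutation(table.y),
        )
        fit = fit_ols(permuted, model_spec)
        null_r[b] = signed_r(fit)
        null_F[b] = fit.F
    return YRandomizationResult(
        null_r=null_r, null_F=null_F, real_r=signed_r(real), real_F=real.F
    )


def external_validation(
    model: LinearQSARModel,
    externals: Iterable[ExternalCompound],
    reference: DescriptorVector,
    tie_tol: float = 1e-9,
) -> ValidationReport:
    """Score a model's more/less-potent-than-reference calls against
    observed labels.  Tie predictions are incorrect by policy and counted
    in ``ties``."""
    externals = list(externals)
    if not externals:
        raise ValueError("external set is empty")
    fp = fn = ok = ties = 0
    for compound in externals:
        pred = classify_vs_reference(model, compound.descriptors, reference, tie_tol)
        if pred.label == "tie":
            ties += 1
        elif pred.label == compound.observed_label:
            ok += 1
        elif pred.label == "more_potent":  # observed less_potent
            fp += 1
        else:  # predicted less_potent, observed more_potent
            fn += 1
    return ValidationReport(
        model_name=model.name,
        false_positives=fp,
        false_negatives=fn,
        correct=ok,
        ties=ties,
    )


@dataclass
class PooledRates:
    """Category rates pooled over several reports; exact rationals kept
    internally, integers (nearest) for display."""

    correct: Fraction
    false_positives: Fraction
    false_negatives: Fraction

    def as_percent(self) -> dict[str, float]:
        return {
            "correct": float(100 * self.correct),
            "false_positives": float(100 * self.false_positives),
            "false_negatives": float(100 * self.false_negatives),
        }

    def rounded(self) -> dict[str, int]:
        return {k: round(v) for k, v in self.as_percent().items()}


def pool_reports(
    reports: Iterable[ValidationReport],
    exclude: Sequence[str] = (),
) -> PooledRates:
    """Pool confusion counts over models (optionally excluding some, e.g.
    models an external comparison failed to validate) and convert to
    percentage rates of the combined total."""
    kept = [r for r in reports if r.model_name not in exclude]
    if not kept:
        raise ValueError("no reports left after exclusion")
    sizes = {r.total for r in kept}
    if len(sizes) > 1:
        raise ValueError(f"external-set sizes differ across reports: {sizes}")
    total = sum(r.total for r in kept)
    return PooledRates(
        correct=Fraction(sum(r.correct for r in kept), total),
        false_positives=Fraction(sum(r.false_positives for r in kept), total),
        false_negatives=Fraction(sum(r.false_negatives for r in kept), total),
    )
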