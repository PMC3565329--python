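"""Ordinary least squares with ANOVA statistics and stepwise descriptor
selection under an overall-F threshold.

The potency response y = −log₁₀(IC50 [M]) is regressed on descriptor
subsets.  Model quality is judged by the ANOVA variance ratio
F = (SSR/k) / (SSE/(n−k−1)) — the explained-to-unexplained variance ratio
for k predictors — and a model enters the selection path only when its
overall F clears the threshold (15 by default, the value used to screen
the published equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import Coefficient, LinearQSARModel


class CollinearityError(ValueError):
    """Design matrix is rank deficient; lists the offending columns."""


@dataclass
class TrainingTable:
    """Compound ids, descriptor matrix and the −log(IC50) response."""

    ids: list[str]
    descriptors: pd.DataFrame  # rows align with ids
    y: np.ndarray  # −log10(IC50 [M])

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(self.descriptors) or len(self.ids) != len(self.y):
            raise ValueError("ids, descriptors and response must align")
        if np.isnan(self.y).any():
            raise ValueError("response contains missing values")

    @property
    def n(self) -> int:
        return len(self.y)

    def candidate_columns(self) -> list[str]:
        """Descriptor columns with no missing entries (partially observed
        columns are excluded from candidacy rather than imputed)."""
        return [c for c in self.descriptors.columns if self.descriptors[c].notna().all()]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        response: str = "neglog_ic50",
        id_column: str = "id",
    ) -> "TrainingTable":
        """Build from a flat table (e.g. read from CSV).  If the response
        column is ``ic50_molar`` it is −log10-transformed."""
        frame = frame.reset_index() if id_column not in frame.columns else frame
        if response == "ic50_molar" or (
            response not in frame.columns and "ic50_molar" in frame.columns
        ):
            y = -np.log10(frame["ic50_molar"].to_numpy(dtype=float))
        else:
            y = frame[response].to_numpy(dtype=float)
        drop = [c for c in (id_column, response, "ic50_molar") if c in frame.columns]
        return cls(
            ids=[str(i) for i in frame[id_column]],
            descriptors=frame.drop(columns=drop),
            y=y,
        )


@dataclass
class FitResult:
    """An OLS fit packaged as a QSAR model plus its ANOVA decomposition."""

    model: LinearQSARModel
    residuals: np.ndarray
    SSR: float  # regression (explained) sum of squares
    SSE: float  # error (residual) sum of squares
    df_model: int  # k predictors
    df_resid: int  # n − k − 1
    F: float
    p: float

    @property
    def r(self) -> float:
        return self.model.r

    @property
    def r_squared(self) -> float:
        sst = self.SSR + self.SSE
        return self.SSR / sst if sst > 0 else 0.0


def anova_p(F: float, k: int, n: int) -> float:
    """Upper-tail ANOVA p-value of an overall F statistic with
    (k, n−k−1) degrees of freedom."""
    if k < 1 or n <= k + 1:
        raise ValueError(f"invalid degrees of freedom: k={k}, n={n}")
    if F < 0:
        raise ValueError("F must be >= 0")
    return float(stats.f.sf(F, k, n - k - 1))


def fit_ols(table: TrainingTable, descriptor_subset: Sequence[str]) -> FitResult:
    """Least-squares fit of y on an intercept plus the named descriptors.

    Returns coefficients with their standard errors, the multiple
    correlation r, and the overall ANOVA F and p.  Rank-deficient designs
    raise :class:`CollinearityError` naming the dependent columns.
    """
    names = list(descriptor_subset)
    if not names:
        raise ValueError("descriptor subset must be non-empty")
    missing = [c for c in names if c not in table.descriptors.columns]
    if missing:
        raise KeyError(f"descriptors not in table: {missing}")
    X = table.descriptors[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in names if table.descriptors[c].isna().any()]
        raise ValueError(f"descriptor columns with missing values: {bad}")
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"n={n} too small for k={k} predictors")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        # identify columns whose removal restores full rank
        offenders = []
        for drop in range(k):
            cols = [0] + [j + 1 for j in range(k) if j != drop]
            if np.linalg.matrix_rank(design[:, cols]) == rank:
                offenders.append(names[drop])
        raise CollinearityError(
            f"design matrix rank deficient; collinear columns: {offenders or names}"
        )

    beta, _, _, _ = np.linalg.lstsq(design, table.y, rcond=None)
    fitted = design @ beta
    resid = table.y - fitted
    SSE = float(resid @ resid)
    SST = float(np.sum((table.y - table.y.mean()) ** 2))
    SSR = SST - SSE
    df_model, df_resid = k, n - k - 1
    F = (SSR / df_model) / (SSE / df_resid) if SSE > 0 else np.inf
    p = anova_p(F, k, n) if np.isfinite(F) else 0.0

    sigma2 = SSE / df_resid
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    r = float(np.sqrt(max(SSR, 0.0) / SST)) if SST > 0 else 0.0

    model = LinearQSARModel(
        name="+".join(names),
        intercept=Coefficient(float(beta[0]), float(se[0])),
        coefficients={
            name: Coefficient(float(b), float(s))
            for name, b, s in zip(names, beta[1:], se[1:])
        },
        r=r,
        F=float(F),
        p=p,
        n=n,
    )
    return FitResult(
        model=model,
        residuals=resid,
        SSR=SSR,
        SSE=SSE,
        df_model=df_model,
        df_resid=df_resid,
        F=float(F),
        p=p,
    )


@dataclass
class StepwiseResult:
    """Accepted models (one per size) plus a diagnostic when even the best
    single-descriptor model misses the threshold."""

    models: list[FitResult] = field(default_factory=list)
    best_rejected: Optional[FitResult] = None
    trace: list[str] = field(default_factory=list)


def stepwise_select(
    table: TrainingTable,
    candidate_descriptors: Optional[Sequence[str]] = None,
    F_threshold: float = 15.0,
    max_terms: int = 3,
) -> StepwiseResult:
    """Forward stepwise descriptor selection under an overall-F threshold.

    At each step the descriptor whose addition maximises the overall model
    F is added (ties broken by descriptor-name order, so the procedure is
    deterministic given the table).  A model is retained only if its F
    clears ``F_threshold``; selection stops when no addition does, or at
    ``max_terms``.  Returns the accepted model at each size, smallest
    first.
    """
    candidates = (
        list(candidate_descriptors)
        if candidate_descriptors is not None
        else table.candidate_columns()
    )
    unknown = [c for c in candidates if c not in table.descriptors.columns]
    if unknown:
        raise KeyError(f"candidates not in table: {unknown}")

    result = StepwiseResult()
    selected: list[str] = []
    remaining = sorted(candidates)  # fixed name order for tie-breaking
    while remaining and len(selected) < max_terms:
        trials = []
        for name in remaining:
            try:
                fit = fit_ols(table, selected + [name])
            except (CollinearityError, ValueError):
                continue
            trials.append((name, fit))
        if not trials:
            break
        best_name, best_fit = max(
            trials, key=lambda t: (t[1].F, )  # names already in sorted order
        )
        if best_fit.F >= F_threshold:
            selected.append(best_name)
            remaining.remove(best_name)
            result.models.append(best_fit)
            result.trace.append(
                f"step {len(selected)}: added {best_name} (F={best_fit.F:.2f})"
            )
        else:
            if not result.models:
                result.best_rejected = best_fit
            result.trace.append(
                f"stop: best addition {best_name} has F={best_fit.F:.2f} "
                f"< threshold {F_threshold}"
            )
            break
    return result
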