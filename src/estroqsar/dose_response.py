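"""Percent-inhibition transformation and sigmoidal IC50 estimation.

Raw assay readings (signal ``A`` with antioxidant present, control signal
``A0``) become percent inhibition, 100·(1 − A/A0).  Although the original
readout is fluorescence, A/A0 is treated as a generic signal ratio.  The
concentration–inhibition relation is modelled as a logistic curve in
log-concentration with floor 0 and ceiling 100 fixed and a free Hill
slope:

    y(C) = 100 / (1 + 10^{h·(log10 IC50 − log10 C)})

so the curve passes through 50% at C = IC50 regardless of h.  Fitting is
by nonlinear least squares over all replicate points (no pre-averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit


class InvalidControlError(ValueError):
    """Control signal must be positive."""


@dataclass(frozen=True)
class InhibitionObservation:
    concentration: float  # molar
    signal: float  # A, arbitrary units
    control_signal: float  # A0, arbitrary units
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.control_signal <= 0:
            raise InvalidControlError("control signal A0 must be positive")


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float  # molar
    hill_slope: float
    rss: float
    converged: bool
    n_points: int


def percent_inhibition(A: float, A0: float) -> float:
    """Percent inhibition = (1 − A/A0)·100.  Signal equal to control means
    no inhibition; zero signal means complete inhibition."""
    if A0 <= 0:
        raise InvalidControlError(f"control signal must be > 0, got {A0}")
    if A < 0:
        raise ValueError(f"signal must be >= 0, got {A}")
    return (1.0 - A / A0) * 100.0


def logistic_inhibition(conc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    """The fixed-asymptote dose–response model in molar concentration."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + 10.0 ** (hill * (log_ic50 - np.log10(conc))))


def fit_ic50(
    observations: Iterable[InhibitionObservation],
    range_factor: float = 100.0,
) -> DoseResponseFit:
    """Estimate IC50 and Hill slope from concentration–inhibition data.

    Requires at least four distinct concentrations.  The fit is flagged
    non-converged when the optimiser fails or when the estimated IC50
    falls outside the tested concentration range extended by
    ``range_factor`` on each side (default 100×), i.e. when the data do
    not bracket the inflection.
    """
    obs = list(observations)
    conc = np.array([o.concentration for o in obs])
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    y = np.array([percent_inhibition(o.signal, o.control_signal) for o in obs])

    # start logIC50 at the tested concentration closest to 50% inhibition
    start_log_ic50 = math.log10(conc[np.argmin(np.abs(y - 50.0))])
    converged = True
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # unidentifiable designs are flagged via `converged`, not warned
            warnings.simplefilter("ignore", OptimizeWarning)
            params, _ = curve_fit(
                logistic_inhibition,
                conc,
                y,
                p0=[start_log_ic50, 1.0],
                maxfev=10_000,
            )
        log_ic50, hill = float(params[0]), float(params[1])
    except RuntimeError:
        converged = False
        log_ic50, hill = start_log_ic50, 1.0

    ic50 = 10.0**log_ic50
    resid = y - logistic_inhibition(conc, log_ic50, hill)
    rss = float(resid @ resid)
    lo, hi = conc.min() / range_factor, conc.max() * range_factor
    if not (lo <= ic50 <= hi) or not math.isfinite(ic50):
        converged = False
    return DoseResponseFit(
        ic50=ic50, hill_slope=hill, rss=rss, converged=converged, n_points=len(obs)
    )
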