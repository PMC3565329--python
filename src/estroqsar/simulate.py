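"""Synthetic study data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* a training table of ~70 compounds with the five descriptors sampled
  uniformly over ranges plausible for steroidal phenols and a −log(IC50)
  response generated from a chosen linear model plus Gaussian noise;
* an external set of ~28 compounds with binary more/less-potent-than-
  reference labels (noiselessly derived from a labelling model, optionally
  flipped with a small probability);
* triplicate 5–6 point dose–response curves whose percent inhibition
  follows the logistic model plus Gaussian noise.

Every generator is a pure function of its seed and configuration.  The
descriptor sampling ranges and the default response noise (sd 0.4 on the
−log scale, which puts single-descriptor sample correlations in the
0.45–0.6 band at n = 70) are artifact defaults, not measured values; real
steroid descriptors are also mutually correlated, which the independent
sampling here deliberately ignores (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .dose_response import InhibitionObservation, logistic_inhibition
from .models import LinearQSARModel, classify_vs_reference, predict
from .regression import TrainingTable
from .validation import ExternalCompound

#: Default uniform sampling ranges per descriptor (artifact choices
#: plausible for estradiol-like polycyclic phenols).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "logP": (1.0, 6.0),
    "BDE": (72.0, 92.0),  # kcal/mol
    "HOMO": (-9.5, -8.0),  # eV
    "SI_k1": (8.0, 20.0),
    "SA": (300.0, 600.0),  # Å²
}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Settings shared by the table and external-set generators."""

    model: LinearQSARModel
    n_compounds: int = 70
    noise_sd: float = 0.4  # sd of Gaussian noise on −log(IC50)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    seed: int = 0
    external_size: int = 28
    reference: Optional[DescriptorVector] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError(f"bad range for {name}: ({lo}, {hi})")
        for name in self.model.coefficients:
            if name not in self.ranges:
                raise ConfigError(
                    f"model {self.model.name} uses descriptor {name!r} "
                    "with no sampling range"
                )

    def midpoint_reference(self) -> DescriptorVector:
        """Reference vector at the middle of each sampled range, so labels
        split non-degenerately."""
        mid = {k: (lo + hi) / 2 for k, (lo, hi) in self.ranges.items()}
        return DescriptorVector(**{k: mid.get(k) for k in DESCRIPTOR_NAMES})


def _sample_descriptors(
    rng: np.random.Generator, ranges: dict[str, tuple[float, float]], n: int
) -> pd.DataFrame:
    # column order fixed by DESCRIPTOR_NAMES for seed-stable output
    cols = {}
    for name in DESCRIPTOR_NAMES:
        if name in ranges:
            lo, hi = ranges[name]
            cols[name] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols)


def generate_training_table(cfg: GeneratorConfig) -> TrainingTable:
    """A seeded compound table: descriptors uniform within their ranges,
    response = model prediction + N(0, noise_sd)."""
    rng = np.random.default_rng(cfg.seed)
    desc = _sample_descriptors(rng, cfg.ranges, cfg.n_compounds)
    y = np.array(
        [predict(cfg.model, row).neglog_ic50 for row in desc.to_dict("records")]
    )
    y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.n_compounds)
    ids = [f"cmpd{i + 1:03d}" for i in range(cfg.n_compounds)]
    return TrainingTable(ids=ids, descriptors=desc, y=y)


def generate_external_set(
    cfg: GeneratorConfig,
    labeling_model: Optional[LinearQSARModel] = None,
    label_noise: float = 0.0,
) -> tuple[list[ExternalCompound], DescriptorVector]:
    """A seeded external set with more/less-potent labels.

    Labels are the noiseless classification of each sampled compound
    against the reference under ``labeling_model`` (default: the config's
    generating model), then flipped independently with probability
    ``label_noise``.  Returns the compounds and the reference vector used.
    """
    if not 0 <= label_noise < 0.5:
        raise ConfigError("label_noise must be in [0, 0.5)")
    model = labeling_model if labeling_model is not None else cfg.model
    reference = cfg.reference if cfg.reference is not None else cfg.midpoint_reference()
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from training
    desc = _sample_descriptors(rng, cfg.ranges, cfg.external_size)
    flips = rng.uniform(size=cfg.external_size) < label_noise
    compounds = []
    for i, row in enumerate(desc.to_dict("records")):
        vector = DescriptorVector(**{k: row.get(k) for k in DESCRIPTOR_NAMES})
        cls = classify_vs_reference(model, vector, reference, tie_tol=0.0)
        label = "more_potent" if cls.margin > 0 else "less_potent"
        if flips[i]:
            label = "less_potent" if label == "more_potent" else "more_potent"
        compounds.append(
            ExternalCompound(id=f"ext{i + 1:03d}", descriptors=vector, observed_label=label)
        )
    return compounds, reference


def generate_dose_response(
    ic50: float,
    hill: float,
    levels: Sequence[float],
    replicates: int = 3,
    noise_sd_pct: float = 3.0,
    seed: int = 0,
) -> list[InhibitionObservation]:
    """Seeded raw readings for one compound's dose–response experiment.

    The control signal is fixed at A0 = 1 and signals are generated so
    that percent inhibition equals the logistic curve value plus
    N(0, noise_sd_pct) percentage points.
    """
    levels = list(levels)
    if any(c <= 0 for c in levels) or sorted(levels) != levels:
        raise ConfigError("levels must be positive and sorted ascending")
    rng = np.random.default_rng(seed)
    truth = logistic_inhibition(np.array(levels), np.log10(ic50), hill)
    obs = []
    for rep in range(replicates):
        noisy = truth + rng.normal(0.0, noise_sd_pct, size=len(levels))
        # invert percent inhibition at A0 = 1; clip so signals stay >= 0
        signals = np.clip(1.0 - noisy / 100.0, 0.0, None)
        for conc, a in zip(levels, signals):
            obs.append(
                InhibitionObservation(
                    concentration=conc, signal=float(a), control_signal=1.0, replicate=rep
                )
            )
    return obs
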