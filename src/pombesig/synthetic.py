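"""Synthetic ground truth and noisy multi-genotype time-course panels.

The generator emulates the structure of the quantified Western-blot and
CRIB-GFP panels: per (genotype, observable, hour) records carrying a mean
over biological replicates and the replicate SD. The default panel mirrors
the training design — the five training genotypes measured for ppSpk1 and
tSpk1, plus wild-type and ras1.G17V measured for aCdc42 — over hours 0-24.

The shipped ground-truth parameter set (``data/model_b_truth.json``) is a
Model B point in the fitting box, found once by fitting hand-drawn target
shapes and then frozen. Under it the wild-type ppSpk1 pulse peaks in hours
5-7 and attenuates by more than 30% by hour 24, byr1.DD is sustained,
ras1.G17V peaks earlier, and the scd1 deletion peaks below 60% of wild type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import TimeCourseDataset
from .model import ModelVariant, TRAINING_GENOTYPES
from .parameters import DEFAULT_BOX, ParameterSet
from .simulate import DEFAULT_HOURS, SolverConfig, simulate

__all__ = ["NoiseModel", "GroundTruth", "default_truth", "generate_dataset",
           "DEFAULT_PANEL"]

#: (genotype, observable) pairs of the default training panel.
DEFAULT_PANEL: tuple[tuple[str, str], ...] = tuple(
    [(g, obs) for g in TRAINING_GENOTYPES for obs in ("ppSpk1", "tSpk1")]
    + [("WT", "aCdc42"), ("ras1.G17V", "aCdc42")]
)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise, homoscedastic per observable.

    The per-point SD is ``max(rel_sd, sd_floor) * panel_max`` where
    ``panel_max`` is the largest noiseless value of that observable across
    the panel. Draws below zero are truncated to zero (blot and CRIB
    signals are non-negative).
    """

    rel_sd: float = 0.15
    sd_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.rel_sd < 0 or self.sd_floor < 0:
            raise ValueError("noise fractions must be >= 0")

    def sigma(self, panel_max: float) -> float:
        return max(self.rel_sd, self.sd_floor) * panel_max


@dataclass(frozen=True)
class GroundTruth:
    """A known parameter set with its noiseless observable panel."""

    params: ParameterSet
    variant: ModelVariant
    panel: tuple[tuple[str, str], ...]
    hours: tuple[float, ...]
    noiseless: dict  # (genotype, observable) -> np.ndarray

    def series(self, genotype: str, observable: str) -> np.ndarray:
        return self.noiseless[(genotype, observable)]


def _truth_params() -> tuple[ParameterSet, str]:
    with resources.files("pombesig.data").joinpath("model_b_truth.json").open() as fh:
        raw = json.load(fh)
    return ParameterSet.from_dict(raw["parameters"]), raw["variant"]


def default_truth(
    seed: int = 0,
    hours: Sequence[float] = DEFAULT_HOURS,
    panel: Sequence[tuple[str, str]] = DEFAULT_PANEL,
    solver: SolverConfig = SolverConfig(),
) -> GroundTruth:
    """The packaged Model B ground truth with its noiseless panel.

    The parameter set is a frozen fixture, so the result is identical for
    every ``seed`` (the argument is accepted for interface symmetry with
    :func:`generate_dataset` and recorded nowhere).
    """
    params, variant = _truth_params()
    variant = ModelVariant.coerce(variant)
    hours = tuple(float(h) for h in hours)
    genotypes = list(dict.fromkeys(g for g, _ in panel))
    trajs = {g: simulate(params, variant, g, hours, solver) for g in genotypes}
    noiseless = {(g, obs): trajs[g].state(obs).copy() for g, obs in panel}
    return GroundTruth(params, variant, tuple(panel), hours, noiseless)


def generate_dataset(
    truth: GroundTruth,
    hours: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
) -> TimeCourseDataset:
    """Draw a noisy dataset from a ground truth.

    For each record, ``replicates`` independent draws of
    ``M(i) + Normal(0, sigma(i)^2)`` are truncated at zero; the record
    carries their mean and sample SD (ddof=1; 0 for a single replicate).
    Deterministic for a fixed ``noise.seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    hours = tuple(float(h) for h in (hours if hours is not None else truth.hours))
    hour_ix = [truth.hours.index(h) for h in hours]
    rng = np.random.default_rng(noise.seed)

    panel_max = {}
    for (g, obs), vals in truth.noiseless.items():
        panel_max[obs] = max(panel_max.get(obs, 0.0), float(np.max(vals)))

    rows = []
    for g, obs in truth.panel:
        M = truth.noiseless[(g, obs)][hour_ix]
        sigma = noise.sigma(panel_max[obs])
        for h, m in zip(hours, M):
            draws = m + rng.normal(0.0, sigma, size=replicates) if sigma > 0 else np.full(replicates, m)
            draws = np.clip(draws, 0.0, None)
            sd = float(np.std(draws, ddof=1)) if replicates > 1 else 0.0
            rows.append((g, obs, h, float(np.mean(draws)), sd, replicates))
    df = pd.DataFrame(rows, columns=["genotype", "observable", "hour", "mean", "sd", "n"])
    return TimeCourseDataset(df)


def injected_sigma(truth: GroundTruth, noise: NoiseModel) -> dict[str, float]:
    """Per-observable noise SD the generator injected (for recovery checks)."""
    panel_max = {}
    for (g, obs), vals in truth.noiseless.items():
        panel_max[obs] = max(panel_max.get(obs, 0.0), float(np.max(vals)))
    return {obs: noise.sigma(m) for obs, m in panel_max.items()}
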