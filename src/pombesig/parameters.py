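"""Rate-constant container for the pheromone-signalling ODE models.

The models are parameterised by 29 non-negative constants ``k1``..``k29``.
Most are effective rate constants (per model-hour); a few are normalisation
or structural constants:

* ``k12`` — phospho-Spk1 blot signal corresponding to one unit of
  phosphorylated fraction (ppSpk1/k12 is the normalised active fraction).
* ``k19`` — CRIB-GFP signal at full Cdc42 activation.
* ``k22`` / ``k23`` — clamped active-Ras1 / active-Byr1 levels used by the
  ``ras1.G17V`` and ``byr1.DD`` mutants.
* ``k24`` / ``k25`` — timing offset and steepness of the nitrogen-depletion
  step.
* ``k26`` — nitrogen-dependent Byr1 inhibition constant used by the
  feedback models (B/C).
* ``k27``–``k29`` — Model C extensions (Cdc42→Spk1 boost and the two
  ras1.G17V-specific negative regulations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

N_PARAMS = 29
PARAM_NAMES: tuple[str, ...] = tuple(f"k{i}" for i in range(1, N_PARAMS + 1))

#: Default per-parameter fitting box, as used for both the least-squares
#: initialisation and log-uniform parameter sampling.
DEFAULT_BOX: tuple[float, float] = (0.1, 10.0)


@dataclass(frozen=True)
class ParameterSet:
    """Fixed-order vector of the 29 model constants.

    Models that do not use some ``k_i`` (e.g. ``k27``–``k29`` outside
    Model C) carry them inert.
    """

    values: np.ndarray
    box: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("all parameters must be finite and >= 0")
        for denom in ("k12", "k19", "k25"):
            if v[PARAM_NAMES.index(denom)] <= 0:
                raise ValueError(f"normalisation constant {denom} must be > 0")
        object.__setattr__(self, "values", v)
        box = {name: tuple(self.box.get(name, DEFAULT_BOX)) for name in PARAM_NAMES}
        object.__setattr__(self, "box", box)

    # -- access ------------------------------------------------------------
    def __getattr__(self, name: str):
        if name.startswith("k") and name[1:].isdigit():
            i = int(name[1:])
            if 1 <= i <= N_PARAMS:
                return float(self.values[i - 1])
        raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    def to_vector(self) -> np.ndarray:
        """Copy of the parameters as a length-29 array (k1 first)."""
        return self.values.copy()

    def kvec(self) -> np.ndarray:
        """1-indexed copy (length 30, slot 0 unused) for the ODE kernels."""
        kv = np.empty(N_PARAMS + 1)
        kv[0] = np.nan
        kv[1:] = self.values
        return kv

    def replace(self, **updates: float) -> "ParameterSet":
        v = self.values.copy()
        for name, val in updates.items():
            v[PARAM_NAMES.index(name)] = val
        return ParameterSet(v, box=self.box)

    def box_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.box[n][0] for n in PARAM_NAMES])
        hi = np.array([self.box[n][1] for n in PARAM_NAMES])
        return lo, hi

    # -- construction / io ---------------------------------------------------
    @classmethod
    def from_vector(cls, vec: Iterable[float], box=None) -> "ParameterSet":
        return cls(np.asarray(list(vec), dtype=float), box=box or {})

    @classmethod
    def from_dict(cls, d: Mapping[str, float], box=None) -> "ParameterSet":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise KeyError(f"parameter file missing keys: {missing}")
        return cls(np.array([float(d[n]) for n in PARAM_NAMES]), box=box or {})

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=False)
            fh.write("\n")

    @classmethod
    def ones(cls) -> "ParameterSet":
        return cls(np.ones(N_PARAMS))

    @classmethod
    def sample_loguniform(cls, rng: np.random.Generator, box=DEFAULT_BOX) -> "ParameterSet":
        """Draw all 29 constants log-uniformly from the fitting box."""
        lo, hi = box
        v = np.exp(rng.uniform(np.log(lo), np.log(hi), size=N_PARAMS))
        return cls(v)
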