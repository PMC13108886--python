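"""Model variants, genotype constraints and ODE right-hand sides.

The network couples nutrient status to a MAPK cascade through seven dynamic
quantities: the master transcription factor Ste11, the lumped pheromone
sensing unit Ste4/6, the active fractions of the GTPases Ras1 and Cdc42
(the latter in CRIB-GFP signal units), active MAPKK Byr1, and the total and
dually phosphorylated MAPK Spk1 (both in Western-blot signal units).

Three structural variants are supported:

* **Model A** — the base network: nutrient-driven Ste11 induction, a
  ppSpk1→Ste11 positive feedback, Ste11-driven expression of Ste4/6 and
  Spk1, and the Ste4/6→Ras1→{Cdc42, Byr1}→Spk1 cascade with saturating
  activation terms and nitrogen-dependent inhibition of Cdc42 and Byr1.
* **Model B** — adds a delayed negative feedback in which ppSpk1 enhances
  the turnover of the sensing unit (rate constant ``k6``), summarising
  Sxa2/Rgs1-type attenuation. In Models B/C the nitrogen inhibition of the
  Byr1 node uses its own constant ``k26`` so that ``k6`` drives only the
  feedback.
* **Model C** — extends B with a Cdc42-dependent boost of Spk1
  phosphorylation (``k27``) and, in ``ras1.G17V`` backgrounds only, two
  ppSpk1-dependent attenuations of Ras1-downstream activation
  (``k28``, ``k29``).

Genotypes are declarative constraint lists: *clamps* fix a state variable
to a constant (the variable is removed from the integrated system), and
*rate scalings* multiply the Ras1-activation (``k7``) or Byr1-activation
(``k13``) rate constants.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace as dc_replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "ModelVariant",
    "GenotypeSpec",
    "CompiledSystem",
    "nutrient_level",
    "derivatives",
    "compile_genotype",
    "compile_system",
    "registry_names",
    "PREDICTION_PANEL",
    "TRAINING_GENOTYPES",
]

#: Integration order of the dynamic quantities.
STATE_NAMES: tuple[str, ...] = (
    "Ste11", "Ste4_6", "aRas1", "aCdc42", "ppByr1", "tSpk1", "ppSpk1",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


class ModelVariant(str, Enum):
    """Structural variant tag. C implies B's sensing-unit feedback."""

    A = "A"
    B = "B"
    C = "C"

    @classmethod
    def coerce(cls, v) -> "ModelVariant":
        if isinstance(v, cls):
            return v
        try:
            return cls(str(v).upper())
        except ValueError:
            raise ValueError(f"unknown model variant {v!r}; expected one of A, B, C") from None


class ModelConfigError(ValueError):
    """Raised for unknown variants or malformed genotype constraints."""


# ---------------------------------------------------------------------------
# Nutrient driver (smooth nitrogen-depletion step)
# ---------------------------------------------------------------------------

def nutrient_level(t: float, params: ParameterSet) -> float:
    """Nitrogen-depletion status at model time ``t``, in (0, 1).

    ``N(t) = (1/pi) * [arctan((t - (100 + k24)) / k25) + pi/2]``.

    ``N`` is ~0 in nutrient-rich medium and rises towards 1 after the
    transition centred at ``100 + k24``; ``k25`` sets the steepness.
    Monotone non-decreasing in ``t``.
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    k25 = params.k25
    if k25 <= 0:
        raise ValueError("k25 (transition steepness) must be > 0")
    return (math.atan((t - (100.0 + params.k24)) / k25) + math.pi / 2.0) / math.pi


# ---------------------------------------------------------------------------
# Genotype constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """Declarative description of a strain as model constraints.

    ``clamps`` maps a state-variable name to either a number or the symbolic
    constants ``"k22"``/``"k23"`` (resolved against the parameter set at
    compile time). ``rate_scalings`` multiplies ``k7`` and/or ``k13``.
    Clamps take precedence over rate scalings touching the same axis because
    clamped variables are excluded from the integrated system entirely.
    """

    name: str
    clamps: tuple[tuple[str, object], ...] = ()
    rate_scalings: tuple[tuple[str, float], ...] = ()
    model_c_ras17v: bool = False

    def __post_init__(self) -> None:
        for var, _ in self.clamps:
            if var not in _IDX:
                raise ModelConfigError(f"unknown state variable in clamp: {var!r}")
        for k, _ in self.rate_scalings:
            if k not in ("k7", "k13"):
                raise ModelConfigError(f"rate scalings may only touch k7/k13, got {k!r}")

    def resolved_clamps(self, params: ParameterSet) -> dict[int, float]:
        out: dict[int, float] = {}
        for var, val in self.clamps:
            if isinstance(val, str):
                val = params[val]
            out[_IDX[var]] = float(val)
        return out


#: Wild-type homothallic h90 strain: no constraints.
WT = GenotypeSpec("WT")

# Single-allele building blocks (verbal rules of the mutant implementations).
_TOKENS: dict[str, dict] = {
    "wt": {},
    "ras1.g17v": {"clamps": (("aRas1", "k22"),), "c_flag": True},
    "byr1.dd": {"clamps": (("ppByr1", "k23"),)},
    "scd1del": {"clamps": (("aCdc42", 0.0),)},
    "byr1del": {"clamps": (("ppByr1", 0.0),)},
    "ras1del": {"clamps": (("aRas1", 0.0),)},
    "byr2del": {"scalings": (("k13", 0.0),)},
    "ste4del": {"scalings": (("k13", 0.0),)},
    "ste6del": {"scalings": (("k7", 0.0),)},
    "gpa1del": {"scalings": (("k7", 0.0), ("k13", 0.0))},
    # Constitutively active Gpa1: restores the activation rates that the
    # heterothallic background reduced (provisional encoding).
    "gpa1.ql": {"restore": ("k7", "k13")},
}

#: Heterothallic (single mating type) modifier: 100-fold reduced activation
#: rates plus a fixed low sensing-unit level.
_HMINUS = {"scalings": (("k7", 0.01), ("k13", 0.01)), "clamps": (("Ste4_6", 0.2),)}

_ALIASES = {
    "wildtype": "wt", "h90": "wt",
    "mapkk.byr1.dd": "byr1.dd", "byr1dd": "byr1.dd",
    "ras1.g17v": "ras1.g17v", "ras1g17v": "ras1.g17v", "ras1.gv": "ras1.g17v",
    "gpa1ql": "gpa1.ql",
}


def _norm_token(tok: str) -> str:
    t = tok.strip().lower()
    t = re.sub(r"[δΔ∆]", "del", t)  # unicode deltas (lower() maps Δ -> δ)
    t = re.sub(r"[_\- ]?delta$", "del", t)
    t = t.replace("_", ".")
    return _ALIASES.get(t, t)


def compile_genotype(genotype) -> GenotypeSpec:
    """Resolve a strain name (or pass through a spec) to a :class:`GenotypeSpec`.

    Names are whitespace- or ``+``-separated allele tokens, e.g.
    ``"gpa1Δ ras1.G17V byr1.DD"`` or ``"h- gpa1.QL"``. The heterothallic
    modifier is spelled ``h-`` (also ``h‾``/``hminus``). Unicode deltas and
    ``_delta`` suffixes are accepted.
    """
    if isinstance(genotype, GenotypeSpec):
        return genotype
    if not isinstance(genotype, str):
        raise ModelConfigError(f"genotype must be a name or GenotypeSpec, got {type(genotype)}")
    raw = genotype.strip()
    tokens = [t for t in re.split(r"[+\s]+", raw) if t]
    if not tokens:
        raise ModelConfigError("empty genotype name")

    hminus = False
    clamps: dict[str, object] = {}
    scalings: dict[str, float] = {}
    restore: set[str] = set()
    c_flag = False
    for tok in tokens:
        t = _norm_token(tok)
        if t in ("h-", "h−", "hminus", "h"):
            hminus = True
            continue
        if t not in _TOKENS:
            known = sorted(_TOKENS) + ["h-"]
            raise ModelConfigError(f"unknown genotype token {tok!r}; known tokens: {known}")
        eff = _TOKENS[t]
        for var, val in eff.get("clamps", ()):
            clamps[var] = val
        for k, m in eff.get("scalings", ()):
            scalings[k] = scalings.get(k, 1.0) * m
        restore.update(eff.get("restore", ()))
        c_flag = c_flag or eff.get("c_flag", False)

    if hminus:
        for k, m in _HMINUS["scalings"]:
            scalings[k] = scalings.get(k, 1.0) * m
        for var, val in _HMINUS["clamps"]:
            clamps.setdefault(var, val)
    for k in restore:
        scalings[k] = 1.0

    return GenotypeSpec(
        name=raw if raw else "WT",
        clamps=tuple(sorted(clamps.items())),
        rate_scalings=tuple(sorted((k, m) for k, m in scalings.items() if m != 1.0)),
        model_c_ras17v=c_flag,
    )


#: The five genotypes used to train the model fits.
TRAINING_GENOTYPES: tuple[str, ...] = (
    "WT", "ras1.G17V", "byr1.DD", "ras1.G17V byr1.DD", "scd1del",
)

#: The 20-strain prediction panel: every strain of the epistasis experiments
#: that was not part of the 5-genotype training set. (byr1.DD anchors several
#: of those panels but is a training genotype, so it is not re-counted here.)
PREDICTION_PANEL: tuple[str, ...] = (
    "byr1del",
    "ras1del",
    "ras1del byr1.DD",
    "byr2del",
    "byr2del byr1.DD",
    "ste4del",
    "ste4del ras1.G17V",
    "ste4del byr1.DD",
    "ste6del",
    "ste6del ras1.G17V",
    "ste6del byr1.DD",
    "gpa1del",
    "gpa1del ras1.G17V",
    "gpa1del byr1.DD",
    "gpa1del ras1.G17V byr1.DD",
    "h- WT",
    "h- byr1.DD",
    "h- gpa1.QL",
    "h- ras1.G17V",
    "h- gpa1.QL ras1del",
)


def registry_names() -> list[str]:
    """All built-in strain names (training genotypes + prediction panel)."""
    seen: list[str] = []
    for n in TRAINING_GENOTYPES + PREDICTION_PANEL:
        if n not in seen:
            seen.append(n)
    return seen


def registry_table() -> "list[dict]":
    """Documented name → constraints table for the built-in registry."""
    rows = []
    for name in registry_names():
        g = compile_genotype(name)
        rows.append(
            {
                "name": name,
                "clamps": "; ".join(f"{v}={c}" for v, c in g.clamps) or "-",
                "rate_scalings": "; ".join(f"{k}x{m}" for k, m in g.rate_scalings) or "-",
                "model_c_ras17v": g.model_c_ras17v,
            }
        )
    return rows


def genotypes_from_yaml(path) -> dict[str, GenotypeSpec]:
    """Load user genotype overrides from a YAML mapping.

    Each entry maps a name to ``{clamps: {var: value|k22|k23},
    rate_scalings: {k7|k13: multiplier}, model_c_ras17v: bool}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, cfg in raw.items():
        cfg = cfg or {}
        clamps = tuple(sorted((v, c) for v, c in (cfg.get("clamps") or {}).items()))
        scal = tuple(sorted((k, float(m)) for k, m in (cfg.get("rate_scalings") or {}).items()))
        out[name] = GenotypeSpec(
            name=name, clamps=clamps, rate_scalings=scal,
            model_c_ras17v=bool(cfg.get("model_c_ras17v", False)),
        )
    return out


# ---------------------------------------------------------------------------
# Compiled ODE system
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_full(y, t, k, flags):
    """Full 7-state derivative. ``flags = (fb, knitro, k27e, k28e, k29e)``."""
    Ste11, S46, aR, aC, pB, tS, pS = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    fb, knitro, k27e, k28e, k29e = flags[0], flags[1], flags[2], flags[3], flags[4]
    N = (math.atan((t - (100.0 + k[24])) / k[25]) + math.pi / 2.0) / math.pi

    out = np.empty(7)
    out[0] = k[1] * N + k[2] * pS / k[12] - k[3] * Ste11
    out[1] = k[4] * Ste11 - k[5] * (1.0 + fb * pS / k[12]) * S46
    out[2] = k[7] * S46 * (1.0 - aR) - k[8] * aR
    out[3] = k[19] * (
        k[9] * aR * (1.0 - aC / k[19]) / (1.0 + k28e * pS)
        - k[10] * (1.0 + k[11] * (1.0 - N)) * aC / k[19]
    )
    out[4] = (
        k[13] * S46 * (1.0 + k[14] * aR / (1.0 + k29e * pS) + k[15] * aC / k[19]) * (1.0 - pB)
        - k[16] * (1.0 + knitro * (1.0 - N)) * pB
    )
    out[5] = k[17] * Ste11 - k[18] * tS
    out[6] = (k[20] + k27e * aC / k[19]) * pB * (tS - pS / k[12]) - k[21] * pS / k[12]
    return out


@njit(cache=True)
def _rhs_free(yfree, t, k, flags, template, free_idx):
    """Derivative of the free (non-clamped) subsystem."""
    yfull = template.copy()
    for i in range(free_idx.size):
        yfull[free_idx[i]] = yfree[i]
    dfull = _rhs_full(yfull, t, k, flags)
    dfree = np.empty(free_idx.size)
    for i in range(free_idx.size):
        dfree[i] = dfull[free_idx[i]]
    return dfree


@dataclass(frozen=True)
class CompiledSystem:
    """A (params, variant, genotype) triple lowered to an integrable system.

    Clamped variables are substituted as constants and removed from the
    integrated state so the solver only sees free variables.
    """

    params: ParameterSet
    variant: ModelVariant
    genotype: GenotypeSpec
    kvec: np.ndarray          # 1-indexed, rate scalings applied
    flags: np.ndarray         # (fb, knitro, k27e, k28e, k29e)
    free_idx: np.ndarray      # indices into STATE_NAMES
    template: np.ndarray      # full state with clamp values filled in

    @property
    def n_free(self) -> int:
        return int(self.free_idx.size)

    def rhs_free(self, yfree: np.ndarray, t: float) -> np.ndarray:
        return _rhs_free(np.asarray(yfree, float), float(t), self.kvec, self.flags,
                         self.template, self.free_idx)

    def expand(self, yfree: np.ndarray) -> np.ndarray:
        """Embed free-state rows into the full 7-state layout."""
        yfree = np.atleast_2d(yfree)
        full = np.tile(self.template, (yfree.shape[0], 1))
        full[:, self.free_idx] = yfree
        return full

    def initial_free(self, initial_state=None) -> np.ndarray:
        """Free-variable initial condition (all-zero full state by default)."""
        if initial_state is None:
            full = np.zeros(N_STATES)
        else:
            full = np.asarray(initial_state, dtype=float)
            if full.shape != (N_STATES,):
                raise ValueError(f"initial_state must have length {N_STATES}")
        return full[self.free_idx].copy()


def compile_system(params: ParameterSet, variant, genotype) -> CompiledSystem:
    """Lower a parameter set + variant + genotype to a :class:`CompiledSystem`."""
    variant = ModelVariant.coerce(variant)
    genotype = compile_genotype(genotype)

    kv = params.kvec()
    for kname, mult in genotype.rate_scalings:
        kv[int(kname[1:])] *= mult

    if variant is ModelVariant.A:
        fb, knitro = 0.0, params.k6
    else:  # B and C share the sensing-unit feedback and the k26 nitrogen term
        fb, knitro = params.k6, params.k26
    if variant is ModelVariant.C:
        k27e = params.k27
        k28e = params.k28 if genotype.model_c_ras17v else 0.0
        k29e = params.k29 if genotype.model_c_ras17v else 0.0
    else:
        k27e = k28e = k29e = 0.0
    flags = np.array([fb, knitro, k27e, k28e, k29e])

    clamps = genotype.resolved_clamps(params)
    free_idx = np.array([i for i in range(N_STATES) if i not in clamps], dtype=np.int64)
    template = np.zeros(N_STATES)
    for i, v in clamps.items():
        template[i] = v
    return CompiledSystem(params, variant, genotype, kv, flags, free_idx, template)


def derivatives(state, t, params: ParameterSet, variant, genotype="WT") -> np.ndarray:
    """Full 7-state derivative vector at ``(state, t)``.

    Clamped variables get derivative 0 and their state value is overridden
    by the clamp before evaluation (a clamped variable is constant no matter
    what the caller passes).
    """
    sys = compile_system(params, variant, genotype)
    full = np.asarray(state, dtype=float).copy()
    if full.shape != (N_STATES,):
        raise ValueError(f"state must have length {N_STATES}")
    clamped = np.setdiff1d(np.arange(N_STATES), sys.free_idx)
    full[clamped] = sys.template[clamped]
    dfull = _rhs_full(full, float(t), sys.kvec, sys.flags)
    dfull[clamped] = 0.0
    return dfull
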