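"""Dynamics classification, strain-panel prediction, structure scans and
cortical-trace smoothing.

``classify_dynamics`` operationalises the qualitative phenotypes of the
MAPK time courses: a *transient* pulse (interior peak followed by
attenuation), a *sustained* response, or a *minimal* (near-background)
signal. ``model_structure_scan`` asks whether a model variant can produce a
transient wild-type response anywhere in the fitting box — the structural
difference between the base network (Model A, monotone) and the
negative-feedback networks (B/C).

``smooth_align_traces`` reproduces the CRIB-GFP cortical-profile procedure:
rolling average over +/-5 measurement points, alignment of traces by their
(smoothed) peak position, and a mean curve with per-position SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelVariant, PREDICTION_PANEL, compile_genotype
from .parameters import DEFAULT_BOX, ParameterSet
from .simulate import (
    DEFAULT_HOURS,
    ObservableSeries,
    SimulationError,
    SolverConfig,
    simulate,
)

__all__ = [
    "DynamicsClass",
    "ClassifierThresholds",
    "classify_dynamics",
    "predict_panel",
    "model_structure_scan",
    "StructureScanResult",
    "smooth_align_traces",
    "AlignedTraces",
    "rolling_mean",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """``minimal_frac``: peak below this fraction of the reference maximum is
    background; ``decline_frac``: attenuation from the peak by the final
    sample required to call a pulse transient."""

    minimal_frac: float = 0.05
    decline_frac: float = 0.30


@dataclass(frozen=True)
class DynamicsClass:
    """Classification of one time course."""

    label: str                 # transient | sustained | minimal
    peak_hour: float
    peak_value: float
    decline_fraction: float    # (peak - final) / peak, clipped to [0, 1]


def classify_dynamics(
    series: ObservableSeries | Sequence[float],
    reference_max: Optional[float] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    hours: Optional[Sequence[float]] = None,
) -> DynamicsClass:
    """Label a time course as transient, sustained or minimal.

    *minimal*: peak below ``minimal_frac * reference_max`` (the reference
    defaults to the series' own maximum, so pass a panel-level reference to
    detect null strains). *transient*: the maximum is interior and the final
    value has declined by at least ``decline_frac`` from it. *sustained*:
    everything else — including an all-equal series above the minimal
    threshold. Invariant to uniform rescaling when the reference is rescaled
    identically.
    """
    if isinstance(series, ObservableSeries):
        values = np.asarray(series.values, dtype=float)
        hrs = np.asarray(series.hours, dtype=float)
    else:
        values = np.asarray(series, dtype=float)
        hrs = np.asarray(hours if hours is not None else np.arange(len(values)), dtype=float)
    if values.size == 0:
        raise ValueError("empty series")

    ipk = int(np.argmax(values))  # earliest index on ties
    peak = float(values[ipk])
    final = float(values[-1])
    decline = 0.0 if peak <= 0 else float(np.clip((peak - final) / peak, 0.0, 1.0))
    ref = float(reference_max) if reference_max is not None else peak

    if peak < thresholds.minimal_frac * ref:
        label = "minimal"
    elif 0 < ipk < values.size - 1 and final <= (1.0 - thresholds.decline_frac) * peak:
        label = "transient"
    else:
        label = "sustained"
    return DynamicsClass(label, float(hrs[ipk]), peak, decline)


def predict_panel(
    params: ParameterSet,
    variant,
    genotypes: Sequence[str] = PREDICTION_PANEL,
    hours: Sequence[float] = DEFAULT_HOURS,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    solver: SolverConfig = SolverConfig(),
    observable: str = "ppSpk1",
) -> pd.DataFrame:
    """Simulate each strain with shared parameters and classify its response.

    The classifier reference maximum is the largest peak across the panel,
    so null strains are called minimal relative to the responding ones.
    Returns a table (genotype, class, peak_hour, peak_value,
    decline_fraction) plus the simulated series.
    """
    series = {}
    for g in genotypes:
        traj = simulate(params, variant, g, hours, solver)
        series[g] = traj.state(observable)
    ref = max(float(np.max(v)) for v in series.values())
    rows = []
    for g in genotypes:
        cls = classify_dynamics(series[g], reference_max=ref, thresholds=thresholds,
                                hours=hours)
        rows.append((g, cls.label, cls.peak_hour, cls.peak_value,
                     cls.decline_fraction, series[g]))
    return pd.DataFrame(
        rows,
        columns=["genotype", "class", "peak_hour", "peak_value",
                 "decline_fraction", "series"],
    )


@dataclass
class StructureScanResult:
    """Outcome of a random-parameter scan of one model variant."""

    transient_fraction: float
    n_tested: int
    n_failures: int
    records: pd.DataFrame      # per-sample class labels and peak stats


def model_structure_scan(
    variant,
    n: int = 200,
    seed: int = 0,
    genotype: str = "WT",
    hours: Sequence[float] = DEFAULT_HOURS,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    box: tuple[float, float] = DEFAULT_BOX,
    solver: SolverConfig = SolverConfig(),
) -> StructureScanResult:
    """Fraction of log-uniform parameter sets producing a transient response.

    Samples ``n`` parameter sets log-uniformly over the fitting box,
    simulates the wild-type ppSpk1 course and classifies it against its own
    maximum. Integrator failures are counted separately and excluded from
    the denominator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_fail = 0
    for i in range(n):
        params = ParameterSet.sample_loguniform(rng, box)
        try:
            traj = simulate(params, variant, genotype, hours, solver)
        except SimulationError:
            n_fail += 1
            continue
        cls = classify_dynamics(traj.state("ppSpk1"), thresholds=thresholds, hours=hours)
        rows.append((i, cls.label, cls.peak_hour, cls.peak_value, cls.decline_fraction))
    records = pd.DataFrame(
        rows, columns=["sample", "class", "peak_hour", "peak_value", "decline_fraction"]
    )
    n_ok = len(records)
    frac = float((records["class"] == "transient").mean()) if n_ok else float("nan")
    return StructureScanResult(frac, n_ok, n_fail, records)


# ---------------------------------------------------------------------------
# CRIB-GFP cortical-intensity trace procedure
# ---------------------------------------------------------------------------

MIN_TRACE_LEN = 11  # the +/-5 window must fit


def rolling_mean(trace: np.ndarray, half_window: int = 5) -> np.ndarray:
    """Centred rolling average over ``+/- half_window`` points.

    The window is truncated at the boundaries (symmetric-as-possible), so
    the output has the same length as the input.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        out[i] = x[lo:hi].mean()
    return out


@dataclass
class AlignedTraces:
    """Mean cortical-intensity curve around the aligned peak position.

    ``positions`` are sample offsets relative to each trace's smoothed peak
    (0 = peak); the support is the union of the aligned traces, and ``count``
    gives how many traces cover each position.
    """

    positions: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    count: np.ndarray


def smooth_align_traces(
    traces: Sequence[Sequence[float]],
    half_window: int = 5,
) -> AlignedTraces:
    """Smooth, peak-align and average cortical-intensity line profiles.

    Each trace is (1) smoothed with a centred rolling average over
    ``+/- half_window`` points, (2) shifted so its smoothed maximum sits at
    position 0 (ties broken towards the earliest index), and (3) averaged
    across traces over the union of aligned supports, with the SEM
    (sample SD / sqrt(n covering traces)) per position.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    smoothed = []
    for t in traces:
        x = np.asarray(t, dtype=float)
        if x.ndim != 1 or x.size < MIN_TRACE_LEN:
            raise ValueError(f"each trace must be 1-D with length >= {MIN_TRACE_LEN}")
        if np.any(x < 0):
            raise ValueError("intensity traces must be non-negative")
        smoothed.append(rolling_mean(x, half_window))

    peaks = [int(np.argmax(s)) for s in smoothed]
    lo = min(-p for p in peaks)
    hi = max(s.size - 1 - p for s, p in zip(smoothed, peaks))
    positions = np.arange(lo, hi + 1)

    n_pos = positions.size
    stack = np.full((len(smoothed), n_pos), np.nan)
    for row, (s, p) in enumerate(zip(smoothed, peaks)):
        offs = np.arange(s.size) - p - lo  # indices into positions
        stack[row, offs] = s
    count = np.sum(~np.isnan(stack), axis=0)
    mean = np.nanmean(stack, axis=0)
    multi = count > 1
    sem = np.zeros(n_pos)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nanstd warns on single-trace columns
        sd = np.nanstd(stack, axis=0, ddof=1)
    # SEM from the unbiased sample SD where >= 2 traces cover the position
    sem[multi] = sd[multi] / np.sqrt(count[multi])
    return AlignedTraces(positions, mean, sem, count)


def traces_from_csv(path) -> list[np.ndarray]:
    """Read traces from a CSV with one trace per column (index rows).

    Shorter traces may be padded with blanks; trailing NaNs are dropped.
    """
    df = pd.read_csv(path)
    out = []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        out.append(v)
    return out
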