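"""Signal conditioning for raw e-nose cycles.

Fixed pipeline order: replicate averaging -> Savitzky-Golay smoothing
(window 11, order 3) -> per-temperature Z-score normalization ->
three-sigma outlier screening (cycles with > 5% abnormal points excluded).

Normalization parameters (mu, sigma per sensor) are fitted independently
for each temperature condition and the same parameters drive both the
Z-score and the 3-sigma rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .simulate import ResponseCycle

__all__ = [
    "NormalizationParams",
    "average_sessions",
    "savgol_smooth",
    "zscore",
    "fit_normalization",
    "exclude_outlier_cycles",
    "preprocess_dataset",
    "PreprocessResult",
]

SAVGOL_WINDOW = 11
SAVGOL_POLYORDER = 3


@dataclass(frozen=True)
class NormalizationParams:
    """Per-temperature, per-sensor Z-score parameters.

    ``mu`` and ``sigma`` are the mean and standard deviation of each
    sensor's (smoothed) signal pooled over all cycles and time points
    recorded under the same temperature condition.
    """

    temperature: float
    sensor_ids: tuple
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape or self.mu.size != len(self.sensor_ids):
            raise ValueError("mu/sigma must have one entry per sensor")
        if np.any(self.sigma <= 0):
            bad = [s for s, sg in zip(self.sensor_ids, self.sigma) if sg <= 0]
            raise ValueError(f"non-positive sigma for sensor(s) {bad} at {self.temperature} degC")


def average_sessions(cycles: list[ResponseCycle]) -> ResponseCycle:
    """Pointwise mean of repeated sampling sessions of one sample."""
    if not cycles:
        raise ValueError("average_sessions: empty input")
    first = cycles[0]
    for c in cycles[1:]:
        if c.temperature != first.temperature or c.label != first.label:
            raise ValueError("cycles to average must share temperature and label")
        if c.t.size != first.t.size or not np.allclose(c.t, first.t):
            raise ValueError("cycles to average must share the time grid")
    readings = np.mean([c.readings for c in cycles], axis=0)
    meta = dict(first.meta)
    meta["n_averaged"] = len(cycles)
    return ResponseCycle(
        cycle_id=meta.get("sample_id", first.cycle_id),
        temperature=first.temperature,
        label=first.label,
        t=first.t.copy(),
        readings=readings,
        sensor_ids=first.sensor_ids,
        meta=meta,
    )


def savgol_smooth(trace: np.ndarray, window: int = SAVGOL_WINDOW,
                  polyorder: int = SAVGOL_POLYORDER) -> np.ndarray:
    """Savitzky-Golay smoothing; polynomial-fit edge handling.

    ``mode='interp'`` fits the window polynomial to the first/last
    ``window`` points and evaluates it there, preserving exact
    reproduction of polynomials up to ``polyorder`` across the whole
    trace, edges included.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < window:
        raise ValueError(f"trace length {trace.shape[-1]} shorter than window {window}")
    return savgol_filter(trace, window_length=window, polyorder=polyorder, mode="interp")


def zscore(trace: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Elementwise ``(x - mu) / sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return (np.asarray(trace, dtype=float) - mu) / sigma


def fit_normalization(cycles: list[ResponseCycle]) -> dict[float, NormalizationParams]:
    """Fit per-temperature NormalizationParams, never mixing temperatures."""
    if not cycles:
        raise ValueError("fit_normalization: empty input")
    by_temp: dict[float, list[ResponseCycle]] = {}
    for c in cycles:
        by_temp.setdefault(c.temperature, []).append(c)
    params = {}
    for temp, group in sorted(by_temp.items()):
        stacked = np.concatenate([c.readings for c in group], axis=1)  # sensors x (cycles*time)
        params[temp] = NormalizationParams(
            temperature=temp,
            sensor_ids=group[0].sensor_ids,
            mu=stacked.mean(axis=1),
            sigma=stacked.std(axis=1),
        )
    return params


def normalize_cycle(cycle: ResponseCycle, params: NormalizationParams) -> ResponseCycle:
    z = (cycle.readings - params.mu[:, None]) / params.sigma[:, None]
    return replace(cycle, readings=z, meta={**cycle.meta, "normalized": True})


def exclude_outlier_cycles(
    cycles: list[ResponseCycle],
    params: dict[float, NormalizationParams],
    sigma_mult: float = 3.0,
    max_frac: float = 0.05,
) -> tuple[list[ResponseCycle], list[str]]:
    """Three-sigma screening at the cycle level.

    A point is abnormal when ``|x - mu| > sigma_mult * sigma`` under its
    temperature condition's parameters; a cycle is rejected iff the
    abnormal fraction, pooled over all sensors and time points of that
    cycle, strictly exceeds ``max_frac``.  Returns (kept, rejected ids);
    together they partition the input.
    """
    if not cycles:
        raise ValueError("exclude_outlier_cycles: empty input")
    kept, rejected = [], []
    for c in cycles:
        p = params[c.temperature]
        abnormal = np.abs(c.readings - p.mu[:, None]) > sigma_mult * p.sigma[:, None]
        if abnormal.mean() > max_frac:
            rejected.append(c.cycle_id)
        else:
            kept.append(c)
    return kept, rejected


@dataclass
class PreprocessResult:
    """Output of the full conditioning pipeline."""

    cycles: list
    params: dict
    rejected: list
    report: dict = field(default_factory=dict)


def preprocess_dataset(
    cycles: list[ResponseCycle],
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_POLYORDER,
    sigma_mult: float = 3.0,
    max_frac: float = 0.05,
) -> PreprocessResult:
    """Run the fixed-order pipeline: average -> smooth -> normalize -> screen.

    Replicates (cycles sharing ``meta['sample_id']``) are averaged first;
    smoothing is applied per sensor trace; normalization parameters are
    fitted per temperature on the smoothed data; outlier screening uses
    the same parameters (equivalently, |z| > sigma_mult on the normalized
    traces).
    """
    if not cycles:
        raise ValueError("preprocess_dataset: empty input")

    groups: dict[str, list[ResponseCycle]] = {}
    order = []
    for c in cycles:
        key = c.meta.get("sample_id", c.cycle_id)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(c)
    averaged = [average_sessions(groups[k]) for k in order]

    smoothed = [
        replace(c, readings=savgol_smooth(c.readings, window, polyorder))
        for c in averaged
    ]
    params = fit_normalization(smoothed)
    normalized = [normalize_cycle(c, params[c.temperature]) for c in smoothed]

    kept_z, rejected = [], []
    for c in normalized:
        abnormal = np.abs(c.readings) > sigma_mult
        if abnormal.mean() > max_frac:
            rejected.append(c.cycle_id)
        else:
            kept_z.append(c)

    report = {
        "n_input_cycles": len(cycles),
        "n_samples": len(averaged),
        "n_kept": len(kept_z),
        "rejected_cycle_ids": list(rejected),
        "sigma_mult": sigma_mult,
        "max_abnormal_frac": max_frac,
        "savgol": {"window": window, "polyorder": polyorder},
        "normalization": {
            f"{t:g}": {
                "sensor_ids": list(p.sensor_ids),
                "mu": [float(v) for v in p.mu],
                "sigma": [float(v) for v in p.sigma],
            }
            for t, p in params.items()
        },
    }
    return PreprocessResult(cycles=kept_z, params=params, rejected=rejected, report=report)
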