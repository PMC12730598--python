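"""Global response-curve features and the feature-correlation objective.

Five global curve descriptors are extracted per sensor per cycle:

* ``p_max`` / ``p_min`` — maximum / minimum of the (smoothed, normalized)
  response curve;
* ``t_eq`` — reaction-equilibrium (settling) time: the earliest time after
  which the trace stays within 2% of its final value;
* ``area`` — trapezoidal integral of the curve over the window;
* ``t1, t2, t3`` — 10 / 50 / 90% rise times above the initial value.

The feature-correlation function scores a cycle's ten curves against a
parameterized target curve

    F_target(t; a, b, c, d, e) = a * f(c*t - b) + d + e * Noise(t)

with f the rise-to-plateau reference shape, as

    C(a, b, c, d, e) = sum_i  w_i * Similarity(F_i, F_target)

with similarities mapped into [0, 1].  Maximizing C over the global
variables (a, b, c, d, e) yields the optimal target-curve parameters for
a cycle or a single sensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import rise_plateau

__all__ = [
    "FEATURE_NAMES",
    "CurveFeatures",
    "GlobalVariables",
    "extract_features",
    "feature_table",
    "pivot_features",
    "normalize_weights",
    "similarity",
    "make_target_curve",
    "feature_correlation",
]

FEATURE_NAMES = ("p_max", "p_min", "t_eq", "area", "t1", "t2", "t3")

#: Settling band for the equilibrium time, as a fraction of the final value.
SETTLING_FRACTION = 0.02

#: Rise-time levels as fractions of (p_max - initial value).
RISE_LEVELS = (0.1, 0.5, 0.9)


@dataclass(frozen=True)
class CurveFeatures:
    """The five global descriptors of one response curve."""

    p_max: float
    p_min: float
    t_eq: float
    area: float
    t1: float
    t2: float
    t3: float
    degenerate: bool = False

    def __post_init__(self):
        if self.p_min > self.p_max + 1e-12:
            raise ValueError("p_min must be <= p_max")
        if not (0.0 <= self.t1 <= self.t2 <= self.t3 + 1e-12):
            raise ValueError("rise times must satisfy 0 <= t1 <= t2 <= t3")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class GlobalVariables:
    """Target-curve parameter vector (a, b, c, d, e).

    a: amplitude; b: time shift (in the argument of f, dimensionless after
    c*t); c: time scale, 1/s; d: baseline offset; e: noise amplitude.
    """

    a: float
    b: float
    c: float
    d: float
    e: float = 0.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("time scale c must be > 0")
        if self.e < 0:
            raise ValueError("noise amplitude e must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e], dtype=float)

    @classmethod
    def from_array(cls, x) -> "GlobalVariables":
        a, b, c, d, e = (float(v) for v in x)
        return cls(a=a, b=b, c=c, d=d, e=e)


def _check_uniform(t: np.ndarray) -> None:
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, dt[0]):
        raise ValueError("time grid must be uniform")


def extract_features(trace: np.ndarray, t: np.ndarray) -> CurveFeatures:
    """Extract the global curve features from one preprocessed trace.

    An all-constant trace is degenerate: rise times are set to the trace
    duration and flagged.
    """
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    if trace.shape != t.shape:
        raise ValueError("trace and time grid must have equal length")
    _check_uniform(t)
    duration = float(t[-1] - t[0])

    p_max = float(trace.max())
    p_min = float(trace.min())
    area = float(np.trapezoid(trace, t))

    final = trace[-1]
    band = SETTLING_FRACTION * abs(final)
    outside = np.abs(trace - final) > band
    if outside.any():
        last_out = int(np.flatnonzero(outside)[-1])
        t_eq = float(t[min(last_out + 1, t.size - 1)])
    else:
        t_eq = float(t[0])

    x0 = trace[0]
    rise = p_max - x0
    if rise <= 1e-12:
        t1 = t2 = t3 = duration
        degenerate = True
    else:
        times = []
        for q in RISE_LEVELS:
            level = x0 + q * rise
            idx = np.flatnonzero(trace >= level - 1e-15)
            times.append(float(t[idx[0]]) if idx.size else duration)
        t1, t2, t3 = times
        # enforce ordering against numerical tie noise
        t2 = max(t1, t2)
        t3 = max(t2, t3)
        degenerate = False
    return CurveFeatures(p_max=p_max, p_min=p_min, t_eq=t_eq, area=area,
                         t1=t1, t2=t2, t3=t3, degenerate=degenerate)


def feature_table(cycles) -> "pd.DataFrame":
    """Long-format feature table: one row per (cycle, sensor)."""
    import pandas as pd

    rows = []
    for cyc in cycles:
        for i, sid in enumerate(cyc.sensor_ids):
            f = extract_features(cyc.readings[i], cyc.t)
            rows.append({
                "cycle_id": cyc.cycle_id,
                "temperature_C": cyc.temperature,
                "label": cyc.label,
                "sensor": sid,
                **{name: getattr(f, name) for name in FEATURE_NAMES},
            })
    return pd.DataFrame(rows)


def pivot_features(table) -> tuple:
    """Pivot a long feature table to a wide (cycle x sensor.feature) matrix.

    Returns ``(X, y, temps)`` where ``X`` is a DataFrame with columns like
    ``S1.p_max`` ordered sensor-major (S1..S10), ``y`` the class labels
    and ``temps`` the temperature of each row.
    """
    import pandas as pd

    meta = table[["cycle_id", "temperature_C", "label"]].drop_duplicates("cycle_id")
    wide = table.pivot(index="cycle_id", columns="sensor", values=list(FEATURE_NAMES))
    sensors = sorted(table["sensor"].unique(), key=lambda s: int(s[1:]))
    cols = [(feat, s) for s in sensors for feat in FEATURE_NAMES]
    wide = wide[cols]
    wide.columns = [f"{s}.{feat}" for feat, s in cols]
    wide = wide.loc[meta["cycle_id"]]
    y = meta.set_index("cycle_id")["label"].loc[wide.index]
    temps = meta.set_index("cycle_id")["temperature_C"].loc[wide.index]
    return wide, y, temps


def normalize_weights(w, n: int = 10) -> np.ndarray:
    """Validate and normalize per-sensor weights to sum to one."""
    if w is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=float)
    if w.size != n:
        raise ValueError(f"expected {n} weights, got {w.size}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return w / total


def similarity(curve: np.ndarray, target: np.ndarray, metric: str = "pearson") -> float:
    """Similarity between two equal-length curves, mapped into [0, 1].

    ``cosine`` and ``pearson`` scores s in [-1, 1] map to (s + 1) / 2;
    ``euclidean`` uses 1 / (1 + RMSE).  A zero-variance input under
    ``pearson`` is degenerate: a neutral 0.5 is returned with a warning.
    """
    x = np.asarray(curve, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape:
        raise ValueError("curves must have equal length")
    if metric == "euclidean":
        dist = float(np.sqrt(np.mean((x - y) ** 2)))
        return 1.0 / (1.0 + dist)
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            warnings.warn("zero-norm curve under cosine similarity; returning neutral 0.5")
            return 0.5
        s = float(np.dot(x, y) / (nx * ny))
        return (min(max(s, -1.0), 1.0) + 1.0) / 2.0
    if metric == "pearson":
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            warnings.warn("zero-variance curve under pearson similarity; returning neutral 0.5")
            return 0.5
        s = float(np.corrcoef(x, y)[0, 1])
        return (min(max(s, -1.0), 1.0) + 1.0) / 2.0
    raise ValueError(f"unknown metric {metric!r}")


def make_target_curve(gv: GlobalVariables, t: np.ndarray,
                      seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Evaluate the target curve a*f(c*t - b) + d + e*Noise(t) on a grid.

    With ``seed=None`` or ``e == 0`` the curve is noise-free; otherwise
    the noise is i.i.d. standard Gaussian drawn from the seed.
    """
    t = np.asarray(t, dtype=float)
    x = gv.a * rise_plateau(gv.c * t - gv.b) + gv.d
    if gv.e > 0 and seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        x = x + gv.e * rng.standard_normal(t.size)
    return x


def feature_correlation(
    traces: np.ndarray,
    t: np.ndarray,
    gv: GlobalVariables,
    weights=None,
    metric: str = "pearson",
    noisy_target_seed=None,
) -> float:
    """Weighted feature-correlation score C of a cycle against a target curve.

    ``C = sum_i w_i * Similarity(F_i, F_target(gv))`` over the cycle's
    sensor traces.  The target is generated noise-free by default: the
    noise amplitude ``e`` stays part of the search vector but only enters
    C when ``noisy_target_seed`` is supplied (noisy-target mode).
    C always lies in [0, 1].
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    t = np.asarray(t, dtype=float)
    if traces.shape[1] != t.size:
        raise ValueError("trace length does not match time grid")
    w = normalize_weights(weights, n=traces.shape[0])
    target = make_target_curve(gv, t, seed=noisy_target_seed)
    return float(sum(
        wi * similarity(traces[i], target, metric=metric)
        for i, wi in enumerate(w)
    ))
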