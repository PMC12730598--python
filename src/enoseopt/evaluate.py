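"""Evaluation protocol: accuracy aggregation, CV, generalization, statistics.

Implements the comparison machinery for the ablation study: macro-accuracy
(mean over the four temperature conditions), the redundancy-reduction
formula 100*(1 - kept/10), the 5x2 cross-validation protocol,
leave-one-temperature-out generalization, paired significance tests with
Cohen's d, and assembly of the ablation comparison table with programmatic
internal-consistency checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "macro_accuracy",
    "redundancy_reduction",
    "round_half_up",
    "cv_5x2",
    "leave_one_temperature_out",
    "paired_compare",
    "AblationResult",
    "build_ablation_table",
    "ablation_frame",
]


def macro_accuracy(per_temperature_accuracies) -> float:
    """Arithmetic mean of per-temperature accuracies (percent)."""
    vals = list(per_temperature_accuracies)
    if not vals:
        raise ValueError("macro_accuracy: empty input")
    return float(np.mean(vals))


def redundancy_reduction(sensors_kept: int, total: int = 10) -> float:
    """Redundancy reduction in percent: 100 * (1 - kept/total)."""
    if not 1 <= sensors_kept <= total:
        raise ValueError(f"sensors_kept must lie in [1, {total}]")
    return 100.0 * (1.0 - sensors_kept / total)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: one decimal, ties away from zero (half-up)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cv_5x2(X, y, estimator_factory, seed: int = 0,
           n_repeats: int = 5, n_folds: int = 2):
    """5x2 cross-validation: mean, sd and the ten fold accuracies (percent).

    Five repetitions of stratified two-fold CV; folds are a deterministic
    function of the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least as many samples as folds")
    accs = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 7919 * r)
        for tr, te in skf.split(X, y):
            clf = estimator_factory()
            clf.fit(X[tr], y[tr])
            accs.append(100.0 * float(np.mean(clf.predict(X[te]) == y[te])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1)), accs


def leave_one_temperature_out(X, y, temps, estimator_factory, seeds=(0,)):
    """Train on three temperature conditions, test on the held-out one.

    Returns ``{temperature: (mean, sd)}`` over the seed list.  The wrapper
    classifiers here are deterministic given the split, so the seed list
    mainly matters when the estimator itself is stochastic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    temps = np.asarray(temps, dtype=float)
    uniq = np.unique(temps)
    if len(uniq) < 2:
        raise ValueError("leave-one-temperature-out needs >= 2 temperature conditions")
    out = {}
    for T in uniq:
        test = temps == T
        accs = []
        for s in seeds:
            clf = estimator_factory()
            if hasattr(clf, "random_state"):
                clf.random_state = s
            clf.fit(X[~test], y[~test])
            accs.append(100.0 * float(np.mean(clf.predict(X[test]) == y[test])))
        out[float(T)] = (float(np.mean(accs)), float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0)
    return out


def paired_compare(accuracies_a, accuracies_b, method: str = "t"):
    """Paired significance test and effect size between two accuracy series.

    Returns ``(p_value, cohens_d)`` with d = mean(a - b) / sd(a - b)
    (positive d favours a).  Zero-variance differences make the test
    degenerate: d is 0 for identical series, +/-inf otherwise, and the
    p-value is 1.0 or nan respectively (flagged with a warning).
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired series must have equal length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 1.0, 0.0
        warnings.warn("zero-variance nonzero differences: p undefined, d infinite")
        return float("nan"), math.copysign(float("inf"), diff.mean())
    d = float(diff.mean() / sd)
    if method == "t":
        p = float(stats.ttest_rel(a, b).pvalue)
    elif method == "wilcoxon":
        p = float(stats.wilcoxon(a, b, zero_method="zsplit").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, d


@dataclass
class AblationResult:
    """One row of the ablation comparison table."""

    model: str
    accuracy_by_temperature: dict
    sensors_kept: int
    macro_accuracy: float = field(init=False)
    redundancy_reduction: float = field(init=False)
    relative_gain: float | None = None
    p_value: float | None = None
    cohens_d: float | None = None
    baseline: str | None = None

    def __post_init__(self):
        self.macro_accuracy = macro_accuracy(self.accuracy_by_temperature.values())
        self.redundancy_reduction = redundancy_reduction(self.sensors_kept)


def build_ablation_table(
    rows: dict,
    baseline: str = "RFA",
    comparisons: dict | None = None,
    total_sensors: int = 10,
) -> list[AblationResult]:
    """Assemble the ablation comparison table.

    ``rows`` maps a model name to a dict with ``accuracy_by_temperature``
    (mapping temperature -> percent) and ``sensors_kept``; optionally
    ``fold_accuracies`` for paired statistics.  The relative-gain column
    is each model's macro-accuracy minus the named baseline's
    (the single-RFA model by convention).  Internal consistency — macro
    equals the mean of the per-temperature columns and the redundancy
    column equals the formula — is asserted on every emitted table.
    """
    if not rows:
        raise ValueError("build_ablation_table: no models")
    if baseline not in rows:
        raise ValueError(f"baseline {baseline!r} missing from rows")
    base_macro = macro_accuracy(rows[baseline]["accuracy_by_temperature"].values())

    results = []
    for name, payload in rows.items():
        res = AblationResult(
            model=name,
            accuracy_by_temperature=dict(payload["accuracy_by_temperature"]),
            sensors_kept=int(payload["sensors_kept"]),
        )
        res.relative_gain = None if name == baseline else res.macro_accuracy - base_macro
        if comparisons and name in comparisons:
            other, method = comparisons[name]
            a = rows[name].get("fold_accuracies")
            b = rows[other].get("fold_accuracies")
            if a is None or b is None:
                raise ValueError(f"fold_accuracies required for comparison {name} vs {other}")
            res.p_value, res.cohens_d = paired_compare(a, b, method=method)
            res.baseline = other
        results.append(res)

    for res in results:
        assert np.isclose(
            res.macro_accuracy, np.mean(list(res.accuracy_by_temperature.values()))
        ), f"macro-accuracy inconsistency for {res.model}"
        assert np.isclose(
            res.redundancy_reduction, 100.0 * (1 - res.sensors_kept / total_sensors)
        ), f"redundancy-reduction inconsistency for {res.model}"
    return results


def ablation_frame(results: list, display_rounding: bool = True) -> pd.DataFrame:
    """Render an ablation table as a DataFrame (display rounding half-up, 1 dp)."""
    rows = []
    for r in results:
        row = {"model": r.model}
        for T in sorted(r.accuracy_by_temperature):
            row[f"accuracy_{T:g}C"] = r.accuracy_by_temperature[T]
        row["macro_accuracy"] = r.macro_accuracy
        row["sensors_kept"] = r.sensors_kept
        row["redundancy_reduction"] = r.redundancy_reduction
        row["relative_gain"] = r.relative_gain
        if r.p_value is not None:
            row["p_value"] = r.p_value
            row["cohens_d"] = r.cohens_d
        rows.append(row)
    df = pd.DataFrame(rows)
    if display_rounding:
        for col in df.columns:
            if col in ("model", "sensors_kept", "p_value"):
                continue
            df[col] = df[col].map(lambda v: None if v is None or pd.isna(v)
                                  else round_half_up(v, 1))
    return df
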