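"""Sensor-subset selection: RFA ranking, SA, GA-QPSO and their tri-level chain.

The selection problem is wrapper-based: a candidate subset (a binary mask
over the ten sensors) is scored by the cross-validated accuracy of a
classifier trained on the masked curve features, minus a small parsimony
penalty per retained sensor.  Three optimizers attack it:

* **RFA** — a bagged decision-tree ensemble ranks sensors by summed
  impurity-decrease importance (with an out-of-bag generalization
  estimate); the top-k sensors form a subset / an initial state.
* **SA** — simulated annealing over masks: single-bit-flip moves,
  Metropolis acceptance exp(delta/T) and geometric cooling.
* **GA-QPSO** — the hybrid quantum particle swarm with genetic operators,
  run over continuous positions in [0, 1]^10 thresholded at 0.5.

The tri-level chain runs them sequentially: RFA's top-k mask seeds SA,
whose solution (plus its one-bit perturbations) seeds the GA-QPSO
population; the final subset is the best fitness seen anywhere.  All
optimizers share one stopping rule (improvement < tol for `patience`
consecutive iterations, or `max_iter`) and one cached fitness evaluator,
so ablation chains are compared under identical conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, pivot_features
from .qpso import QPSOConfig, gaqpso_maximize

__all__ = [
    "accuracy",
    "SelectorConfig",
    "SubsetEvaluator",
    "SensorSubset",
    "SelectionResult",
    "RfaRanking",
    "rfa_rank",
    "sa_select",
    "gaqpso_select",
    "tri_optimize",
    "ablation_run",
    "ABLATION_CHAINS",
    "SensorSelectionModel",
    "SensorSelectionResults",
]

ABLATION_CHAINS = ("RFA", "SA", "GA-QPSO", "RFA+SA", "RFA+QPSO", "SA+QPSO", "Tri")


def accuracy(n_correct: int, n_total: int) -> float:
    """Classification accuracy in percent: 100 * n_correct / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return 100.0 * n_correct / n_total


@dataclass(frozen=True)
class SelectorConfig:
    """Shared configuration of the selection optimizers.

    ``size_penalty`` is the parsimony pressure: accuracy points subtracted
    per sensor retained (0.5 = half a percentage point per 10% of the
    array), so a sensor is kept only if it buys at least that much
    accuracy.  ``tol``/``patience``/``max_iter`` implement the common
    stopping rule.
    """

    wrapper: str = "knn"          # "knn" or "forest"
    k_neighbors: int = 5
    n_estimators: int = 200
    size_penalty: float = 0.5
    tol: float = 1e-4
    patience: int = 20
    max_iter: int = 200
    # SA schedule
    sa_t0: float = 1.0
    sa_alpha: float = 0.95
    # GA-QPSO
    pop_size: int = 20
    pc_range: tuple = (0.6, 0.9)
    pm_range: tuple = (0.01, 0.1)
    # RFA
    top_k: int = 6
    # CV protocol
    cv_repeats: int = 5
    cv_folds: int = 2

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")

    def qpso(self) -> QPSOConfig:
        return QPSOConfig(
            pop_size=self.pop_size, max_iter=self.max_iter,
            tol=self.tol, patience=self.patience,
            pc_range=self.pc_range, pm_range=self.pm_range,
        )


def _mask_key(mask) -> tuple:
    return tuple(bool(b) for b in mask)


class SubsetEvaluator:
    """Cached wrapper-classifier fitness of sensor subsets.

    Folds for the 5x2 cross-validation protocol are drawn once from the
    seed and shared by every mask evaluation, so fitness is a
    deterministic pure function of the mask and comparisons between masks
    are paired.  Results are memoized: with only 2^10 - 1 masks, repeated
    queries from the optimizers are free.
    """

    def __init__(self, X: pd.DataFrame, y, temps, config: SelectorConfig | None = None,
                 seed: int = 0):
        self.X = X
        self.y = np.asarray(y)
        self.temps = np.asarray(temps, dtype=float)
        self.config = config or SelectorConfig()
        self.seed = int(seed)
        self.sensors = sorted({c.split(".")[0] for c in X.columns},
                              key=lambda s: int(s[1:]))
        self.n_sensors = len(self.sensors)
        self._cols = {s: [c for c in X.columns if c.startswith(s + ".")]
                      for s in self.sensors}
        self._Xv = X.to_numpy(dtype=float)
        self._col_idx = {s: [X.columns.get_loc(c) for c in self._cols[s]]
                         for s in self.sensors}
        self._folds = self._make_folds(self.y)
        self._folds_by_temp = {
            T: self._make_folds(self.y[self.temps == T], offset=int(T))
            for T in np.unique(self.temps)
        }
        self._cache: dict[tuple, float] = {}
        self._acc_cache: dict[tuple, tuple] = {}

    # -- protocol ---------------------------------------------------------
    def _make_folds(self, y, offset: int = 0):
        folds = []
        for r in range(self.config.cv_repeats):
            skf = StratifiedKFold(n_splits=self.config.cv_folds, shuffle=True,
                                  random_state=self.seed + 7919 * r + offset)
            folds.extend(skf.split(np.zeros(len(y)), y))
        return folds

    def _classifier(self):
        cfg = self.config
        if cfg.wrapper == "knn":
            return make_pipeline(
                StandardScaler(),
                KNeighborsClassifier(n_neighbors=cfg.k_neighbors),
            )
        if cfg.wrapper == "forest":
            return RandomForestClassifier(
                n_estimators=cfg.n_estimators, random_state=self.seed, n_jobs=1
            )
        raise ValueError(f"unknown wrapper {cfg.wrapper!r}")

    def _mask_columns(self, mask) -> list[int]:
        idx = []
        for keep, s in zip(mask, self.sensors):
            if keep:
                idx.extend(self._col_idx[s])
        return idx

    # -- scoring ----------------------------------------------------------
    def cv_accuracy(self, mask, rows=None, folds=None) -> tuple[float, float]:
        """5x2 cross-validated wrapper accuracy (percent): mean, sd over folds."""
        key = (_mask_key(mask), None if rows is None else tuple(np.flatnonzero(rows)))
        if folds is None and key in self._acc_cache:
            return self._acc_cache[key]
        cols = self._mask_columns(mask)
        if not cols:
            raise ValueError("mask keeps no sensors")
        Xv, yv = self._Xv[:, cols], self.y
        if rows is not None:
            Xv, yv = Xv[rows], yv[rows]
        use_folds = folds if folds is not None else self._folds
        accs = []
        for tr, te in use_folds:
            clf = self._classifier()
            clf.fit(Xv[tr], yv[tr])
            accs.append(accuracy(int((clf.predict(Xv[te]) == yv[te]).sum()), len(te)))
        mean, sd = float(np.mean(accs)), float(np.std(accs, ddof=1))
        if folds is None:
            self._acc_cache[key] = (mean, sd)
        return mean, sd

    def fitness(self, mask) -> float:
        """CV accuracy minus the parsimony penalty; memoized."""
        key = _mask_key(mask)
        if not any(key):
            raise ValueError("mask keeps no sensors")
        if key not in self._cache:
            acc, _ = self.cv_accuracy(key)
            self._cache[key] = acc - self.config.size_penalty * sum(key)
        return self._cache[key]

    def accuracy_by_temperature(self, mask) -> dict[float, float]:
        """Per-temperature 5x2 CV accuracy of a subset."""
        out = {}
        for T in sorted(self._folds_by_temp):
            rows = self.temps == T
            mean, _ = self.cv_accuracy(mask, rows=rows, folds=self._folds_by_temp[T])
            out[float(T)] = mean
        return out

    def subset(self, mask) -> "SensorSubset":
        """Package a mask with its fitness and per-temperature accuracies."""
        key = _mask_key(mask)
        fit = self.fitness(key)
        acc, sd = self.cv_accuracy(key)
        return SensorSubset(
            mask=key,
            sensors=tuple(s for k, s in zip(key, self.sensors) if k),
            fitness=fit,
            cv_accuracy=acc,
            cv_accuracy_sd=sd,
            accuracy_by_temperature=self.accuracy_by_temperature(key),
        )


@dataclass(frozen=True)
class SensorSubset:
    """A selected subset with its fitness record."""

    mask: tuple
    sensors: tuple
    fitness: float
    cv_accuracy: float
    cv_accuracy_sd: float
    accuracy_by_temperature: dict = field(default_factory=dict)

    def __post_init__(self):
        if not any(self.mask):
            raise ValueError("a returned subset must keep at least one sensor")

    @property
    def n_kept(self) -> int:
        return int(sum(self.mask))

    @property
    def redundancy_reduction(self) -> float:
        return 100.0 * (1.0 - self.n_kept / len(self.mask))


@dataclass
class SelectionResult:
    """Outcome of one selection chain, with stage artifacts and provenance."""

    chain: str
    subset: SensorSubset
    trace: list = field(default_factory=list)   # best-so-far fitness per iteration
    n_iter: int = 0
    converged: bool = False
    stages: dict = field(default_factory=dict)  # stage name -> SensorSubset / RfaRanking
    seed: int = 0
    config: SelectorConfig | None = None

    def to_dict(self) -> dict:
        return {
            "chain": self.chain,
            "mask": [int(b) for b in self.subset.mask],
            "sensors": list(self.subset.sensors),
            "fitness": self.subset.fitness,
            "cv_accuracy": self.subset.cv_accuracy,
            "cv_accuracy_sd": self.subset.cv_accuracy_sd,
            "accuracy_by_temperature": {f"{k:g}": v for k, v in
                                        self.subset.accuracy_by_temperature.items()},
            "n_kept": self.subset.n_kept,
            "redundancy_reduction": self.subset.redundancy_reduction,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "convergence_trace": [float(v) for v in self.trace],
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# RFA
# ---------------------------------------------------------------------------

@dataclass
class RfaRanking:
    """Random-forest sensor ranking with OOB generalization estimate."""

    sensors: tuple
    importances: np.ndarray           # normalized, sums to 1
    per_sensor_accuracy: dict
    oob_accuracy: float

    def top_k_mask(self, k: int) -> tuple:
        """Mask keeping the k most important sensors (ties: lowest index first)."""
        order = np.lexsort((np.arange(len(self.sensors)), -self.importances))
        keep = set(order[:k])
        return tuple(i in keep for i in range(len(self.sensors)))


def rfa_rank(evaluator: SubsetEvaluator, seed: int = 0) -> RfaRanking:
    """Rank sensors by bagged-tree impurity-decrease importance.

    A random forest is fitted on all features; each sensor's importance is
    the sum over its seven curve features, normalized to sum to one.
    Per-sensor accuracies are single-sensor wrapper CV accuracies; the
    out-of-bag estimate reports ensemble generalization.
    """
    if len(np.unique(evaluator.y)) < 2:
        raise ValueError("rfa_rank requires at least two classes")
    cfg = evaluator.config
    forest = RandomForestClassifier(
        n_estimators=cfg.n_estimators, oob_score=True,
        random_state=seed, n_jobs=1, bootstrap=True,
    )
    forest.fit(evaluator._Xv, evaluator.y)
    imp = np.zeros(evaluator.n_sensors)
    for i, s in enumerate(evaluator.sensors):
        imp[i] = forest.feature_importances_[evaluator._col_idx[s]].sum()
    total = imp.sum()
    if total > 0:
        imp = imp / total
    per_sensor = {}
    for i, s in enumerate(evaluator.sensors):
        mask = tuple(j == i for j in range(evaluator.n_sensors))
        per_sensor[s], _ = evaluator.cv_accuracy(mask)
    return RfaRanking(
        sensors=tuple(evaluator.sensors),
        importances=imp,
        per_sensor_accuracy=per_sensor,
        oob_accuracy=100.0 * float(forest.oob_score_),
    )


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def sa_select(
    fitness_fn,
    n_sensors: int,
    initial_mask,
    config: SelectorConfig,
    rng: np.random.Generator,
) -> tuple[tuple, float, list, int, bool]:
    """Simulated annealing over sensor masks.

    One single-bit-flip move per temperature step; a move emptying the
    mask is re-drawn.  Worse moves (delta < 0) are accepted with
    probability exp(delta / T); T follows geometric cooling T <- alpha*T.
    Returns (best mask, best fitness, best-so-far trace, iterations,
    converged flag).
    """
    mask = _mask_key(initial_mask)
    if len(mask) != n_sensors or not any(mask):
        raise ValueError("initial mask must be valid and non-empty")
    cur_fit = fitness_fn(mask)
    best_mask, best_fit = mask, cur_fit
    T = config.sa_t0
    trace = [best_fit]
    stall = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        for _ in range(100):
            bit = int(rng.integers(n_sensors))
            cand = list(mask)
            cand[bit] = not cand[bit]
            if any(cand):
                break
        cand = tuple(cand)
        cand_fit = fitness_fn(cand)
        delta = cand_fit - cur_fit
        if delta > 0 or (T > 0 and rng.random() < math.exp(min(delta / T, 0.0))):
            mask, cur_fit = cand, cand_fit
        gain = 0.0
        if cur_fit > best_fit:
            gain = cur_fit - best_fit
            best_mask, best_fit = mask, cur_fit
        trace.append(best_fit)
        T *= config.sa_alpha
        stall = stall + 1 if gain < config.tol else 0
        if stall >= config.patience:
            return best_mask, best_fit, trace, it, True
    return best_mask, best_fit, trace, it, False


# ---------------------------------------------------------------------------
# GA-QPSO (binary via continuous positions)
# ---------------------------------------------------------------------------

def _decode(position: np.ndarray) -> tuple:
    """Threshold a position at 0.5; an empty mask keeps the largest entry."""
    mask = position >= 0.5
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return tuple(bool(b) for b in mask)


def _masks_to_positions(masks, rng: np.random.Generator) -> np.ndarray:
    """Map masks to interior positions (0.75 for kept, 0.25 for dropped) with jitter."""
    M = np.asarray([[1.0 if b else 0.0 for b in m] for m in masks])
    pos = 0.25 + 0.5 * M + rng.uniform(-0.1, 0.1, size=M.shape)
    return np.clip(pos, 0.0, 1.0)


def gaqpso_select(
    fitness_fn,
    n_sensors: int,
    config: SelectorConfig,
    rng: np.random.Generator,
    init_masks=None,
) -> tuple[tuple, float, list, int, bool]:
    """GA-QPSO subset search; positions in [0,1]^n thresholded to masks."""
    res = gaqpso_maximize(
        lambda x: fitness_fn(_decode(x)),
        np.zeros(n_sensors), np.ones(n_sensors),
        config.qpso(), rng,
        init=None if init_masks is None else _masks_to_positions(init_masks, rng),
    )
    return _decode(res.x), float(res.fun), res.trace, res.n_iter, res.converged


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def _single_bit_perturbations(mask) -> list[tuple]:
    out = [tuple(mask)]
    for i in range(len(mask)):
        cand = list(mask)
        cand[i] = not cand[i]
        if any(cand):
            out.append(tuple(cand))
    return out


def tri_optimize(evaluator: SubsetEvaluator, config: SelectorConfig | None = None,
                 seed: int = 0) -> SelectionResult:
    """Sequential RFA -> SA -> GA-QPSO selection.

    Stage 1 ranks sensors and keeps the top-k as the initial state;
    stage 2 anneals from it; stage 3 runs GA-QPSO with a population
    seeded around the SA solution (the SA mask plus its single-bit
    perturbations).  The returned subset is the best fitness seen in any
    stage; all stage artifacts are retained.
    """
    config = config or evaluator.config
    ss = np.random.SeedSequence(seed)
    rng_sa, rng_qpso = (np.random.default_rng(s) for s in ss.spawn(2))

    ranking = rfa_rank(evaluator, seed=seed)
    mask_rfa = ranking.top_k_mask(config.top_k)

    mask_sa, fit_sa, trace_sa, it_sa, conv_sa = sa_select(
        evaluator.fitness, evaluator.n_sensors, mask_rfa, config, rng_sa)

    mask_q, fit_q, trace_q, it_q, conv_q = gaqpso_select(
        evaluator.fitness, evaluator.n_sensors, config, rng_qpso,
        init_masks=_single_bit_perturbations(mask_sa))

    candidates = [(evaluator.fitness(mask_rfa), mask_rfa),
                  (fit_sa, mask_sa), (fit_q, mask_q)]
    best_fit, best_mask = max(candidates, key=lambda p: p[0])
    trace = trace_sa + trace_q
    trace = list(np.maximum.accumulate(trace))
    return SelectionResult(
        chain="Tri",
        subset=evaluator.subset(best_mask),
        trace=trace,
        n_iter=it_sa + it_q,
        converged=conv_sa and conv_q,
        stages={
            "rfa": ranking,
            "rfa_subset": evaluator.subset(mask_rfa),
            "sa_subset": evaluator.subset(mask_sa),
            "gaqpso_subset": evaluator.subset(mask_q),
        },
        seed=seed,
        config=config,
    )


def _run_chain(chain: str, evaluator: SubsetEvaluator, config: SelectorConfig,
               seed: int) -> SelectionResult:
    n = evaluator.n_sensors
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2)]
    stages: dict = {}
    full_mask = tuple(True for _ in range(n))

    if chain == "Tri":
        return tri_optimize(evaluator, config, seed)

    if chain == "RFA":
        ranking = rfa_rank(evaluator, seed=seed)
        mask = ranking.top_k_mask(config.top_k)
        fit = evaluator.fitness(mask)
        return SelectionResult(chain=chain, subset=evaluator.subset(mask),
                               trace=[fit], n_iter=1, converged=True,
                               stages={"rfa": ranking}, seed=seed, config=config)

    if chain in ("SA", "RFA+SA", "SA+QPSO"):
        if chain == "RFA+SA":
            ranking = rfa_rank(evaluator, seed=seed)
            stages["rfa"] = ranking
            init = ranking.top_k_mask(config.top_k)
        else:
            init = full_mask
        mask, fit, trace, n_iter, conv = sa_select(
            evaluator.fitness, n, init, config, rngs[0])
        stages["sa_subset"] = evaluator.subset(mask)
        if chain == "SA+QPSO":
            mask_q, fit_q, trace_q, it_q, conv_q = gaqpso_select(
                evaluator.fitness, n, config, rngs[1],
                init_masks=_single_bit_perturbations(mask))
            stages["gaqpso_subset"] = evaluator.subset(mask_q)
            if fit_q > fit:
                mask, fit = mask_q, fit_q
            trace = list(np.maximum.accumulate(trace + trace_q))
            n_iter += it_q
            conv = conv and conv_q
        return SelectionResult(chain=chain, subset=evaluator.subset(mask),
                               trace=trace, n_iter=n_iter, converged=conv,
                               stages=stages, seed=seed, config=config)

    if chain in ("GA-QPSO", "RFA+QPSO"):
        init_masks = None
        if chain == "RFA+QPSO":
            ranking = rfa_rank(evaluator, seed=seed)
            stages["rfa"] = ranking
            init_masks = _single_bit_perturbations(ranking.top_k_mask(config.top_k))
        mask, fit, trace, n_iter, conv = gaqpso_select(
            evaluator.fitness, n, config, rngs[1], init_masks=init_masks)
        stages["gaqpso_subset"] = evaluator.subset(mask)
        return SelectionResult(chain=chain, subset=evaluator.subset(mask),
                               trace=trace, n_iter=n_iter, converged=conv,
                               stages=stages, seed=seed, config=config)

    raise ValueError(f"unknown chain {chain!r}")


def ablation_run(evaluator: SubsetEvaluator, config: SelectorConfig | None = None,
                 seed: int = 0, chains=ABLATION_CHAINS) -> dict[str, SelectionResult]:
    """Run all selection chains under identical features, folds and stopping rule.

    The seven chains share one evaluator (hence one fold set and one
    fitness cache) and per-chain RNG streams derived deterministically
    from the seed; a rerun with the same seed is bitwise identical.
    """
    config = config or evaluator.config
    results = {}
    for i, chain in enumerate(chains):
        results[chain] = _run_chain(chain, evaluator, config, seed + 101 * i)
    return results


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class SensorSelectionModel:
    """Sensor-array selection model over a curve-feature table.

    Built from the wide feature matrix (one row per cycle, columns
    ``S1.p_max`` ... ``S10.t3``), class labels and per-row temperatures.
    ``fit`` runs one of the seven selection chains and returns a results
    object carrying the selected subset, its accuracies and convergence
    diagnostics.
    """

    def __init__(self, X: pd.DataFrame, y, temperatures,
                 config: SelectorConfig | None = None, seed: int = 0):
        self.config = config or SelectorConfig()
        self.evaluator = SubsetEvaluator(X, y, temperatures, self.config, seed=seed)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           config: SelectorConfig | None = None, seed: int = 0):
        """Build from the long-format feature table (cycle, sensor rows)."""
        X, y, temps = pivot_features(table)
        return cls(X, y, temps, config=config, seed=seed)

    def fit(self, chain: str = "Tri", seed: int = 0) -> "SensorSelectionResults":
        if chain not in ABLATION_CHAINS:
            raise ValueError(f"chain must be one of {ABLATION_CHAINS}")
        result = _run_chain(chain, self.evaluator, self.config, seed)
        return SensorSelectionResults(model=self, selection=result)

    def fit_ablation(self, seed: int = 0) -> dict[str, "SensorSelectionResults"]:
        """Fit all seven chains under identical conditions."""
        return {
            name: SensorSelectionResults(model=self, selection=res)
            for name, res in ablation_run(self.evaluator, self.config, seed).items()
        }


@dataclass
class SensorSelectionResults:
    """Fitted selection chain: subset, accuracies, diagnostics."""

    model: SensorSelectionModel
    selection: SelectionResult

    @property
    def subset(self) -> SensorSubset:
        return self.selection.subset

    @property
    def sensors(self) -> tuple:
        return self.subset.sensors

    def summary(self) -> str:
        s = self.subset
        lines = [
            f"Sensor-array selection — chain: {self.selection.chain}",
            "=" * 52,
            f"selected sensors       : {', '.join(s.sensors)}",
            f"sensors retained       : {s.n_kept} / {len(s.mask)}",
            f"redundancy reduction   : {s.redundancy_reduction:.1f} %",
            f"fitness                : {s.fitness:.3f}",
            f"5x2 CV accuracy        : {s.cv_accuracy:.2f} ± {s.cv_accuracy_sd:.2f} %",
            "per-temperature accuracy (%):",
        ]
        for T, acc in sorted(s.accuracy_by_temperature.items()):
            lines.append(f"  {T:>5g} degC : {acc:6.2f}")
        lines.append(
            f"iterations             : {self.selection.n_iter}"
            f" ({'converged' if self.selection.converged else 'iteration cap'})"
        )
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.selection.trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        ax.set_title(f"{self.selection.chain} convergence")
        return ax
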