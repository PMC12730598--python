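"""Declarative pipeline configuration.

A single YAML file describes every stage of the pipeline; it is
schema-validated on load, round-trips load -> save -> load identically,
and supports environment-variable overrides of scalar values via
``ENOSEOPT__section__key=value``.
"""

from __future__ import annotations

import copy
import os
from dataclasses import asdict, dataclass, field

import yaml

from .select import SelectorConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]

_DEFAULTS = {
    "seed": 0,
    "outdir": "enoseopt_results",
    "simulator": {
        "temperatures": [4.0, 12.0, 20.0, 28.0],
        "n_classes": 3,
        "n_cycles_per_class": 12,
        "n_replicates": 1,
        "redundancy": 0.95,
        "class_signal_scale": 1.0,
        "env_jitter_scale": 1.0,
    },
    "preprocess": {
        "savgol_window": 11,
        "savgol_polyorder": 3,
        "sigma_mult": 3.0,
        "max_abnormal_frac": 0.05,
    },
    "features": {
        "metric": "pearson",
        "weights": None,
        "bounds": {
            "a": [0.1, 5.0], "b": [0.0, 5.0], "c": [0.001, 0.2],
            "d": [-3.0, 3.0], "e": [0.0, 0.5],
        },
    },
    "selector": {
        "wrapper": "knn",
        "k_neighbors": 5,
        "n_estimators": 200,
        "size_penalty": 0.5,
        "tol": 1.0e-4,
        "patience": 20,
        "max_iter": 200,
        "sa_t0": 1.0,
        "sa_alpha": 0.95,
        "pop_size": 20,
        "top_k": 6,
        "chains": ["RFA", "SA", "GA-QPSO", "RFA+SA", "RFA+QPSO", "SA+QPSO", "Tri"],
    },
    "validation": {
        "k": 5,
        "k_nn": 3,
        "cohesion_threshold": 0.3,
        "metric": "euclidean",
    },
    "evaluation": {
        "n_seeds": 5,
        "baseline": "RFA",
        "comparison_method": "t",
    },
}

_VALID_METRICS = {"pearson", "cosine", "euclidean"}
_VALID_WRAPPERS = {"knn", "forest"}


@dataclass
class PipelineConfig:
    """Validated configuration tree for the full pipeline."""

    seed: int = 0
    outdir: str = "enoseopt_results"
    simulator: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["simulator"]))
    preprocess: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["preprocess"]))
    features: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["features"]))
    selector: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["selector"]))
    validation: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["validation"]))
    evaluation: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS["evaluation"]))

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        sim = self.simulator
        if sim["n_classes"] < 2:
            raise ValueError("simulator.n_classes must be >= 2")
        if sim["n_cycles_per_class"] < 1:
            raise ValueError("simulator.n_cycles_per_class must be >= 1")
        if not 0 <= sim["redundancy"] < 1:
            raise ValueError("simulator.redundancy must be in [0, 1)")
        pp = self.preprocess
        if pp["savgol_window"] % 2 != 1 or pp["savgol_window"] <= pp["savgol_polyorder"]:
            raise ValueError("savgol_window must be odd and exceed the polynomial order")
        if self.features["metric"] not in _VALID_METRICS:
            raise ValueError(f"features.metric must be one of {sorted(_VALID_METRICS)}")
        if self.selector["wrapper"] not in _VALID_WRAPPERS:
            raise ValueError(f"selector.wrapper must be one of {sorted(_VALID_WRAPPERS)}")
        if self.selector["tol"] <= 0 or self.selector["patience"] < 1:
            raise ValueError("selector.tol must be > 0 and patience >= 1")
        if self.validation["k"] < 1:
            raise ValueError("validation.k must be >= 1")

    def selector_config(self) -> SelectorConfig:
        s = self.selector
        return SelectorConfig(
            wrapper=s["wrapper"], k_neighbors=s["k_neighbors"],
            n_estimators=s["n_estimators"], size_penalty=s["size_penalty"],
            tol=s["tol"], patience=s["patience"], max_iter=s["max_iter"],
            sa_t0=s["sa_t0"], sa_alpha=s["sa_alpha"], pop_size=s["pop_size"],
            top_k=s["top_k"],
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _apply_env_overrides(data: dict, environ=None) -> dict:
    environ = os.environ if environ is None else environ
    for key, raw in environ.items():
        if not key.startswith("ENOSEOPT__"):
            continue
        path = key.split("__")[1:]
        node = data
        for part in path[:-1]:
            if part not in node:
                raise KeyError(f"override {key}: unknown section {part!r}")
            node = node[part]
        leaf = path[-1]
        if leaf not in node:
            raise KeyError(f"override {key}: unknown key {leaf!r}")
        node[leaf] = yaml.safe_load(raw)
    return data


def load_config(path=None, environ=None) -> PipelineConfig:
    """Load, merge with defaults, apply env overrides, and validate."""
    data = copy.deepcopy(_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config section(s) {sorted(unknown)}")
        for section, value in user.items():
            if isinstance(value, dict):
                bad = set(value) - set(_DEFAULTS[section])
                if bad:
                    raise ValueError(f"unknown key(s) {sorted(bad)} in section {section!r}")
                data[section].update(value)
            else:
                data[section] = value
    data = _apply_env_overrides(data, environ)
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
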