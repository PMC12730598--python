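"""End-to-end pipeline: simulate -> preprocess -> features -> select / cluster
-> evaluate -> report.

Every stage writes its artifacts under the configured output directory and
records a manifest (config hash, seed, library versions).  With
``resume=True`` a stage whose artifacts already exist under the same
config hash is skipped and downstream stages are regenerated from them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, save_config
from .curvefit import fit_sensor_global_variables
from .evaluate import ablation_frame, build_ablation_table
from .features import feature_table
from .io import read_cycles, write_cycles
from .preprocess import preprocess_dataset
from .select import SensorSelectionModel
from .simulate import default_scenarios, generate_dataset
from .validate import embed_2d, equivalence_groups, kmeans_cluster, knn_consistency

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "optimize", "validate", "report")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_done(outdir: Path, artifacts: list[str]) -> bool:
    return all((outdir / a).exists() for a in artifacts)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the artifact directory.

    Raises RuntimeError naming the failing stage on any stage error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)

    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            logger.warning("config changed since last run; resume disabled")
            resume = False

    stage = "setup"
    try:
        stage = "simulate"
        dataset_csv = "dataset.csv"
        if not (resume and _stage_done(outdir, [dataset_csv])):
            sim = config.simulator
            scenarios = default_scenarios(
                temperatures=sim["temperatures"], n_classes=sim["n_classes"],
                class_signal_scale=sim["class_signal_scale"],
                env_jitter_scale=sim["env_jitter_scale"],
            )
            cycles = generate_dataset(
                scenarios, sim["n_cycles_per_class"], seed=config.seed,
                redundancy=sim["redundancy"], n_replicates=sim["n_replicates"],
            )
            write_cycles(cycles, outdir / dataset_csv)
            logger.info("simulate: %d cycles -> %s", len(cycles), dataset_csv)
        cycles = read_cycles(outdir / dataset_csv)

        stage = "preprocess"
        pp = config.preprocess
        result = preprocess_dataset(
            cycles, window=pp["savgol_window"], polyorder=pp["savgol_polyorder"],
            sigma_mult=pp["sigma_mult"], max_frac=pp["max_abnormal_frac"],
        )
        (outdir / "preprocess_report.json").write_text(json.dumps(result.report, indent=2))
        logger.info("preprocess: kept %d cycles, rejected %s",
                    len(result.cycles), result.rejected)

        stage = "features"
        features_csv = outdir / "features.csv"
        table = feature_table(result.cycles)
        table.to_csv(features_csv, index=False)

        stage = "optimize"
        model = SensorSelectionModel.from_feature_table(
            table, config=config.selector_config(), seed=config.seed)
        chains = config.selector["chains"]
        selections = {}
        for i, chain in enumerate(chains):
            res = model.fit(chain=chain, seed=config.seed + 101 * i)
            selections[chain] = res
            fname = "selection_" + chain.lower().replace("+", "_").replace("-", "") + ".json"
            (outdir / fname).write_text(json.dumps(res.selection.to_dict(), indent=2))
            logger.info("optimize[%s]: %s fitness=%.2f", chain,
                        ",".join(res.sensors), res.subset.fitness)

        stage = "validate"
        v = config.validation
        gv_table = fit_sensor_global_variables(
            result.cycles, metric=v["metric"], seed=config.seed)
        gv_table.to_csv(outdir / "global_variables.csv", index=False)
        embeddings = embed_2d(gv_table)
        emb_rows, groups_out = [], []
        for temp, emb in sorted(embeddings.items()):
            labels = kmeans_cluster(emb, k=v["k"], seed=config.seed)
            consistency = knn_consistency(emb.coords, labels, k_nn=v["k_nn"])
            groups = equivalence_groups(emb, labels, cohesion_threshold=v["cohesion_threshold"])
            df = emb.to_frame()
            df["cluster"] = labels
            emb_rows.append(df)
            payload = groups.to_dict()
            payload["knn_consistency"] = consistency
            payload["explained_variance_ratio"] = list(emb.explained_variance_ratio)
            groups_out.append(payload)
        pd.concat(emb_rows, ignore_index=True).to_csv(outdir / "embedding.csv", index=False)
        (outdir / "groups.json").write_text(json.dumps(groups_out, indent=2))

        stage = "report"
        rows = {
            name: {
                "accuracy_by_temperature": res.subset.accuracy_by_temperature,
                "sensors_kept": res.subset.n_kept,
            }
            for name, res in selections.items()
        }
        baseline = config.evaluation["baseline"]
        if baseline not in rows:
            baseline = next(iter(rows))
        results = build_ablation_table(rows, baseline=baseline)
        frame = ablation_frame(results)
        frame.to_csv(outdir / "ablation.csv", index=False)
        summary_lines = ["Ablation comparison", "=" * 60, frame.to_string(index=False), ""]
        for name, res in selections.items():
            summary_lines += [res.summary(), ""]
        (outdir / "summary.txt").write_text("\n".join(summary_lines))
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": list(STAGES),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    save_config(config, outdir / "config_used.yaml")
    return outdir
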