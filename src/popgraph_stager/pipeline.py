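"""End-to-end pipeline: cohort -> features -> graphs -> GCN -> reports.

Driven by a single YAML/JSON-style mapping; every stage writes its outputs
under the run directory and is skipped when they already exist, so deleting
an intermediate file reruns that stage and everything downstream.  All
randomness flows from the seeds recorded in the manifest, and result CSVs
are written with fixed formatting so identical configurations produce
byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, generate_cohort, generate_features, \
    generate_volumes
from .containers import FeatureMatrix
from .densenet import DenseNetConfig, extract_features, train_extractor
from .experiments import ExperimentSpec, TASKS, sweep
from .gcn import GCNConfig
from .graph import EdgeFeature, EdgeSpec

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},           # CohortConfig overrides
    "feature_source": "synthetic",  # or "cnn"
    "cnn": {},              # DenseNetConfig overrides (cnn source only)
    "volume": {"shape": [16, 16, 16], "atrophy_amplitude": 0.6},
    "task": "mci_cn",
    "graphs": [{"mode": "baseline"}],
    "gcn": {},              # GCNConfig overrides
    "seeds": [0, 1],
}


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    config = {**DEFAULT_CONFIG, **dict(source)}
    if config["task"] not in TASKS:
        raise ValueError(f"unknown task {config['task']!r}")
    return config


def _edge_specs(config: dict) -> list[EdgeSpec]:
    specs = []
    for g in config["graphs"]:
        feats = [EdgeFeature(f["name"], f["kind"], f.get("beta"))
                 for f in g.get("features", [])]
        specs.append(EdgeSpec(g["mode"], feats))
    return specs


def run_full_pipeline(config, out_dir) -> Path:
    """Run (or resume) every stage; returns the run directory."""
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config, default=list)),
                      "stages": {}}
    stale = False

    def stage(name, outputs, fn):
        nonlocal stale
        outputs = [out / o for o in outputs]
        if stale or not all(p.exists() for p in outputs):
            logger.info("pipeline stage %s: computing", name)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
            stale = True
            manifest["stages"][name] = "computed"
        else:
            logger.info("pipeline stage %s: cached", name)
            manifest["stages"][name] = "cached"

    cohort_cfg = CohortConfig(**{"seed": config["seed"], **config["cohort"]})

    def make_cohort():
        generate_cohort(cohort_cfg).to_csv(out / "cohort.csv")

    stage("cohort", ["cohort.csv"], make_cohort)
    cohort = Cohort.from_csv(out / "cohort.csv")

    def make_features():
        if config["feature_source"] == "synthetic":
            feats = generate_features(cohort, cohort_cfg)
        elif config["feature_source"] == "cnn":
            shape = tuple(config["volume"]["shape"])
            volumes = generate_volumes(
                cohort, shape=shape,
                atrophy_amplitude=config["volume"]["atrophy_amplitude"],
                seed=config["seed"])
            cnn_cfg = DenseNetConfig(**{"input_shape": shape,
                                        "seed": config["seed"],
                                        **config["cnn"]})
            classes = TASKS[config["task"]]
            sub_ids = [i for i, d in zip(cohort.ids, cohort.diagnoses)
                       if d in classes]
            sub = cohort.subset(classes)
            vol_idx = [volumes.ids.index(i) for i in sub_ids]
            sub_vols = type(volumes)(ids=sub_ids, data=volumes.data[vol_idx])
            model, history = train_extractor(
                sub_vols, sub.labels(classes), cohort.split, cnn_cfg)
            history.to_csv(out / "cnn_history.csv", index=False,
                           float_format="%.6f")
            feats_sub = extract_features(model, volumes)
            feats = feats_sub
        else:
            raise ValueError(f"unknown feature source "
                             f"{config['feature_source']!r}")
        feats.to_csv(out / "features.csv")

    stage("features", ["features.csv"], make_features)
    features = FeatureMatrix.from_csv(out / "features.csv")

    def make_results():
        task = config["task"]
        gcn_cfg = GCNConfig(**{"n_classes": len(TASKS[task]),
                               **config["gcn"]})
        table = sweep(cohort, features, _edge_specs(config), task, gcn_cfg,
                      [int(s) for s in config["seeds"]])
        results_dir = out / "results"
        results_dir.mkdir(exist_ok=True)
        table.to_csv(results_dir / "results.csv", index=False,
                     float_format="%.4f")

    stage("results", ["results/results.csv"], make_results)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
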