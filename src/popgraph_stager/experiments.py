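"""Experiment orchestration: edge-function sweeps, threshold search,
results tables, and the planted-signal recovery study.

Three sweep designs mirror the benchmark ablations:

1. AD versus CN with demographic edges — the baseline imaging graph plus the
   seven combined graphs over {age, gender, ApoE4}.
2. MCI classification (AD/MCI or MCI/CN) with neuropsychological edges —
   per score, a validation grid search selects the threshold beta, then one
   non-imaging and one combined graph are evaluated (19 rows with baseline).
3. Three-class staging with the best score from sweep 2 — baseline,
   non-imaging and combined graphs, each with its confusion matrix.

Sweeps are repeated over seeds (fresh split + fresh GCN initialisation per
seed) and reported as mean +/- SD; threshold selection only ever sees the
validation split.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .cohort import (Cohort, CohortConfig, SCORE_NAMES, assign_split,
                     generate_cohort, generate_features, planted_signal_params)
from .containers import FeatureMatrix
from .gcn import GCNConfig, predict, train_transductive
from .graph import (EdgeFeature, EdgeSpec, build_graph, default_threshold_grid,
                    grid_search_threshold)
from .metrics import ConfusionMatrix, binary_metrics, confusion, multiclass_metrics

logger = logging.getLogger(__name__)

#: task -> ordered class labels; the diseased / more-impaired class is last
#: and is the positive class for binary metrics.
TASKS = {
    "ad_cn": ("CN", "AD"),
    "ad_mci": ("MCI", "AD"),
    "mci_cn": ("CN", "MCI"),
    "three_class": ("CN", "MCI", "AD"),
}

METRIC_COLS = ("ACC", "PRE", "REC", "F1", "MCC")


@dataclass
class ExperimentSpec:
    task: str
    edge_specs: list[EdgeSpec] = field(default_factory=list)
    threshold_candidates: dict[str, list[float]] = field(default_factory=dict)
    gcn_config: GCNConfig | None = None
    seeds: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.gcn_config is None:
            n_classes = len(TASKS[self.task])
            lr = 1e-3 if self.task == "ad_cn" else 1e-4
            self.gcn_config = GCNConfig(n_classes=n_classes, learning_rate=lr)


def subset_features(features: FeatureMatrix, ids: list[str]) -> FeatureMatrix:
    index = {sid: i for i, sid in enumerate(features.ids)}
    missing = [sid for sid in ids if sid not in index]
    if missing:
        raise ValueError(f"ids without features: {missing[:10]}")
    rows = [index[sid] for sid in ids]
    return FeatureMatrix(ids=list(ids), values=features.values[rows])


def resplit(cohort: Cohort, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> Cohort:
    """Same subjects, fresh stratified split."""
    split = assign_split(cohort.ids, cohort.diagnoses, fractions, seed=seed)
    return Cohort(subjects=cohort.subjects, split=split)


def evaluate_spec(
    cohort: Cohort,
    features: FeatureMatrix,
    edge_spec: EdgeSpec,
    task: str,
    gcn_config: GCNConfig,
) -> tuple[dict[str, float], ConfusionMatrix]:
    """Train a GCN on one graph and report test-mask metrics."""
    classes = TASKS[task]
    sub = cohort.subset(classes)
    feats = subset_features(features, sub.ids)
    labels = sub.labels(classes)
    graph = build_graph(feats, sub, edge_spec)
    model, _ = train_transductive(graph, labels, gcn_config)
    pred, _ = predict(model, graph)
    test = graph.masks["test"]
    cm = confusion(labels[test], pred[test], list(range(len(classes))))
    cm.class_order = list(classes)
    cm_idx = ConfusionMatrix(cm.counts, list(range(len(classes))))
    if len(classes) == 2:
        cm_idx.positive_class = 1
        row = binary_metrics(cm_idx).as_row()
    else:
        overall, per_class = multiclass_metrics(cm_idx)
        row = {"ACC": overall, "PRE": float("nan"), "REC": float("nan"),
               "F1": float("nan"), "MCC": float("nan")}
    return row, cm


def validation_accuracy(
    cohort: Cohort,
    features: FeatureMatrix,
    edge_spec: EdgeSpec,
    task: str,
    gcn_config: GCNConfig,
) -> float:
    """Validation-mask accuracy for threshold search (test never touched)."""
    classes = TASKS[task]
    sub = cohort.subset(classes)
    feats = subset_features(features, sub.ids)
    labels = sub.labels(classes)
    graph = build_graph(feats, sub, edge_spec)
    model, _ = train_transductive(graph, labels, gcn_config)
    pred, _ = predict(model, graph)
    val = graph.masks["val"]
    return float(np.mean(pred[val] == labels[val]))


def sweep(
    cohort: Cohort,
    features: FeatureMatrix,
    edge_specs: list[EdgeSpec],
    task: str,
    gcn_config: GCNConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Evaluate each edge spec over the seeds; mean +/- SD results table."""
    if not seeds:
        raise ValueError("at least one seed is required")
    rows = []
    for spec in edge_specs:
        per_seed = []
        for seed in seeds:
            c = resplit(cohort, seed=seed)
            cfg = GCNConfig(**{**gcn_config.__dict__, "seed": int(seed)})
            row, _ = evaluate_spec(c, features, spec, task, cfg)
            per_seed.append(row)
        frame = pd.DataFrame(per_seed)
        out = {"edge_function": spec.label}
        for col in METRIC_COLS:
            out[col] = float(frame[col].mean())
            out[col + "_sd"] = float(frame[col].std(ddof=0))
        rows.append(out)
        logger.info("sweep %s: %s ACC %.1f", task, spec.label, out["ACC"])
    return pd.DataFrame(rows)


def demographic_edge_specs(age_beta: float = reference.AGE_BETA) -> list[EdgeSpec]:
    """Baseline plus the 7 demographic combinations as combined graphs."""
    pool = {
        "age": EdgeFeature("age", "quantitative", age_beta),
        "gender": EdgeFeature("gender", "categorical"),
        "apoe4": EdgeFeature("apoe4", "categorical"),
    }
    specs = [EdgeSpec("baseline")]
    for r in (1, 2, 3):
        for combo in itertools.combinations(("age", "gender", "apoe4"), r):
            specs.append(EdgeSpec("combined", [pool[k] for k in combo]))
    return specs


def run_experiment_1(
    cohort: Cohort,
    features: FeatureMatrix,
    spec: ExperimentSpec,
) -> pd.DataFrame:
    """AD-versus-CN sweep over demographic edge functions (8 rows)."""
    if spec.task != "ad_cn":
        raise ValueError("experiment 1 is an AD-versus-CN design")
    age_beta = reference.AGE_BETA
    if "age" in spec.threshold_candidates:
        c0 = resplit(cohort, seed=spec.seeds[0])
        cfg = GCNConfig(**{**spec.gcn_config.__dict__, "seed": spec.seeds[0]})
        age_beta, trace = grid_search_threshold(
            spec.threshold_candidates["age"],
            lambda b: validation_accuracy(
                c0, features,
                EdgeSpec("combined", [EdgeFeature("age", "quantitative", b)]),
                spec.task, cfg))
        logger.info("age threshold search: beta=%g (trace %s)", age_beta, trace)
    specs = spec.edge_specs or demographic_edge_specs(age_beta)
    return sweep(cohort, features, specs, spec.task, spec.gcn_config, spec.seeds)


def run_experiment_2(
    cohort: Cohort,
    features: FeatureMatrix,
    spec: ExperimentSpec,
    scores: tuple[str, ...] = SCORE_NAMES,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, list]]:
    """MCI-classification sweep over neuropsychological edges.

    Per score, the quantitative threshold beta is grid-searched against
    validation accuracy of that score's non-imaging graph (first seed's
    split), then the non-imaging and combined graphs are evaluated over all
    seeds.  Returns the 1 + 2*len(scores) row table, the selected betas and
    the per-score search traces.
    """
    if spec.task not in ("ad_mci", "mci_cn"):
        raise ValueError("experiment 2 is an AD/MCI or MCI/CN design")
    c0 = resplit(cohort, seed=spec.seeds[0])
    cfg0 = GCNConfig(**{**spec.gcn_config.__dict__, "seed": spec.seeds[0]})
    betas: dict[str, float] = {}
    traces: dict[str, list] = {}
    for name in scores:
        candidates = spec.threshold_candidates.get(
            name, default_threshold_grid(cohort.covariate(name)))
        beta, trace = grid_search_threshold(
            candidates,
            lambda b, name=name: validation_accuracy(
                c0, features,
                EdgeSpec("nonimaging", [EdgeFeature(name, "quantitative", b)]),
                spec.task, cfg0))
        betas[name] = beta
        traces[name] = trace
        logger.info("threshold search %s: beta=%g", name, beta)
    edge_specs = [EdgeSpec("baseline")]
    for name in scores:
        f = EdgeFeature(name, "quantitative", betas[name])
        edge_specs.append(EdgeSpec("nonimaging", [f]))
        edge_specs.append(EdgeSpec("combined", [f]))
    table = sweep(cohort, features, edge_specs, spec.task, spec.gcn_config,
                  spec.seeds)
    return table, betas, traces


def best_score_from_table(table: pd.DataFrame) -> str:
    """Score whose non-imaging graph tops the accuracy column."""
    snimg = table[table["edge_function"].str.startswith("Snimg(")]
    label = snimg.loc[snimg["ACC"].idxmax(), "edge_function"]
    return label[len("Snimg("):-1]


def run_experiment_3(
    cohort: Cohort,
    features: FeatureMatrix,
    spec: ExperimentSpec,
    best_feature: str,
    beta: float,
) -> tuple[pd.DataFrame, dict[str, ConfusionMatrix]]:
    """Three-class staging with the winning edge function from sweep 2."""
    if spec.task != "three_class":
        raise ValueError("experiment 3 is a three-class design")
    f = EdgeFeature(best_feature, "quantitative", beta)
    edge_specs = [EdgeSpec("baseline"),
                  EdgeSpec("nonimaging", [f]),
                  EdgeSpec("combined", [f])]
    table = sweep(cohort, features, edge_specs, spec.task, spec.gcn_config,
                  spec.seeds)
    matrices: dict[str, ConfusionMatrix] = {}
    for es in edge_specs:
        c = resplit(cohort, seed=spec.seeds[0])
        cfg = GCNConfig(**{**spec.gcn_config.__dict__, "seed": spec.seeds[0]})
        _, cm = evaluate_spec(c, features, es, spec.task, cfg)
        matrices[es.label] = cm
    return table, matrices


def planted_signal_experiment(
    planted: str = "CDR_SB",
    candidates: tuple[str, ...] = ("CDR_SB", "ADAS11", "ADNI_EF",
                                   "ADNI_LAN", "ADNI_VS"),
    task: str = "mci_cn",
    n_per_class: int = 150,
    n_seeds: int = 10,
    seed: int = 0,
    feature_dim: int = 512,
    class_separation: float = 1.0,
    gcn_config: GCNConfig | None = None,
    grid_points: int = 5,
) -> dict:
    """Planted-signal recovery: can the sweep find the informative covariate?

    A synthetic cohort is drawn in which exactly one score (``planted``)
    separates the classes while the remaining candidates are pure noise, and
    the imaging features carry only moderate signal.  For each candidate the
    threshold is grid-searched on validation (first seed) and the
    non-imaging and combined graphs are evaluated over ``n_seeds`` fresh
    splits, against the baseline imaging graph.  Returns mean test
    accuracies per graph and the candidate ranking by non-imaging accuracy.
    """
    if planted not in candidates:
        raise ValueError("planted covariate must be among the candidates")
    classes = TASKS[task]
    counts = {d: (n_per_class if d in classes else 0) for d in ("CN", "MCI", "AD")}
    config = CohortConfig(
        class_counts=counts,
        covariate_params=planted_signal_params(planted),
        feature_dim=feature_dim,
        class_separation=class_separation,
        seed=seed,
    )
    cohort = generate_cohort(config)
    features = generate_features(cohort, config)
    if gcn_config is None:
        gcn_config = GCNConfig(n_classes=len(classes), learning_rate=3e-3)
    seeds = [int(seed) + k for k in range(n_seeds)]

    spec = ExperimentSpec(task=task, gcn_config=gcn_config, seeds=seeds)
    c0 = resplit(cohort, seed=seeds[0])
    cfg0 = GCNConfig(**{**gcn_config.__dict__, "seed": seeds[0]})
    betas = {}
    for name in candidates:
        grid = default_threshold_grid(cohort.covariate(name), grid_points)
        beta, _ = grid_search_threshold(
            grid,
            lambda b, name=name: validation_accuracy(
                c0, features,
                EdgeSpec("nonimaging", [EdgeFeature(name, "quantitative", b)]),
                task, cfg0))
        betas[name] = beta
    edge_specs = [EdgeSpec("baseline")]
    for name in candidates:
        f = EdgeFeature(name, "quantitative", betas[name])
        edge_specs.append(EdgeSpec("nonimaging", [f]))
        edge_specs.append(EdgeSpec("combined", [f]))
    table = sweep(cohort, features, edge_specs, task, gcn_config, seeds)

    acc = dict(zip(table["edge_function"], table["ACC"]))
    snimg_rank = sorted(candidates,
                        key=lambda n: acc[f"Snimg({n})"], reverse=True)
    return {
        "table": table,
        "betas": betas,
        "baseline_acc": acc["Simg"],
        "planted_snimg_acc": acc[f"Snimg({planted})"],
        "planted_scom_acc": acc[f"Scom({planted})"],
        "ranking": snimg_rank,
        "planted_rank": snimg_rank.index(planted) + 1,
    }
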