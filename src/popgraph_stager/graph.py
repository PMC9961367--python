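"""Population-graph construction from imaging and non-imaging similarity.

Nodes are subjects carrying their imaging feature vector; edges encode
pairwise similarity through one of three edge-assigning functions:

* ``baseline``   — cosine similarity of imaging features (Simg), negatives
  clamped to zero;
* ``nonimaging`` — sum over the selected phenotypic features of indicator
  similarities (Snimg): Kronecker delta for categoricals, a unit step
  ``|ni - nj| < beta`` for quantitative scores;
* ``combined``   — the product Scom = Simg * sum_p Snimg_p, which is large
  only when subjects agree on both imaging and phenotype.

Quantitative thresholds beta are selected by exhaustive grid search against
validation accuracy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .cohort import Cohort
from .containers import FeatureMatrix, PopulationGraph

logger = logging.getLogger(__name__)

MODES = ("baseline", "nonimaging", "combined")


@dataclass
class EdgeFeature:
    name: str
    kind: str  # "categorical" | "quantitative"
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "quantitative"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "quantitative":
            if self.beta is None or not self.beta > 0:
                raise ValueError(
                    f"quantitative feature {self.name!r} needs beta > 0")


@dataclass
class EdgeSpec:
    mode: str
    features: list[EdgeFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "baseline" and self.features:
            raise ValueError("baseline mode takes no non-imaging features")
        if self.mode in ("nonimaging", "combined") and not self.features:
            raise ValueError(f"{self.mode} mode needs at least one feature")

    @property
    def label(self) -> str:
        if self.mode == "baseline":
            return "Simg"
        names = ",".join(f.name for f in self.features)
        return ("Snimg" if self.mode == "nonimaging" else "Scom") + f"({names})"


def imaging_similarity(xi: np.ndarray, xj: np.ndarray) -> float:
    """Cosine similarity of two feature vectors; zero-norm inputs give 0."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    ni, nj = np.linalg.norm(xi), np.linalg.norm(xj)
    if ni == 0.0 or nj == 0.0:
        logger.warning("zero-norm feature vector: similarity defined as 0")
        return 0.0
    return float(xi @ xj / (ni * nj))


def categorical_similarity(ni, nj) -> int:
    """Kronecker delta: 1 iff the categories are equal (missing -> 0)."""
    if ni is None or nj is None or (isinstance(ni, float) and np.isnan(ni)) \
            or (isinstance(nj, float) and np.isnan(nj)):
        logger.warning("missing categorical value treated as unequal")
        return 0
    return int(ni == nj)


def quantitative_similarity(ni: float, nj: float, beta: float) -> int:
    """Unit step on the absolute difference: 1 iff |ni - nj| < beta."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    if not (np.isfinite(ni) and np.isfinite(nj)):
        logger.warning("non-finite quantitative value: similarity 0")
        return 0
    return int(abs(ni - nj) < beta)


def combined_similarity(simg: float, snimg_values: Sequence[int]) -> float:
    """Scom = Simg * sum_p Snimg_p (may exceed 1 for several matches)."""
    if len(snimg_values) == 0:
        raise ValueError("combined similarity needs at least one non-imaging "
                         "value; use baseline mode instead")
    return float(simg) * float(np.sum(snimg_values))


def cosine_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarity; zero-norm rows yield zero similarity."""
    X = np.asarray(X, float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if np.any(zero):
        logger.warning("%d zero-norm feature rows: similarities set to 0",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    C = U @ U.T
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    return np.clip(C, -1.0, 1.0)


def _indicator_matrix(cohort: Cohort, feat: EdgeFeature) -> np.ndarray:
    vals = cohort.covariate(feat.name)
    if feat.kind == "categorical":
        return (vals[:, None] == vals[None, :]).astype(float)
    v = vals.astype(float)
    finite = np.isfinite(v)
    ind = (np.abs(v[:, None] - v[None, :]) < feat.beta).astype(float)
    if not np.all(finite):
        logger.warning("non-finite values in %s treated as dissimilar", feat.name)
        ind[~finite, :] = 0.0
        ind[:, ~finite] = 0.0
    return ind


def build_graph(features: FeatureMatrix, cohort: Cohort,
                spec: EdgeSpec) -> PopulationGraph:
    """Assemble the weighted population graph for one edge-assigning spec."""
    if features.ids != cohort.ids:
        extra = sorted(set(features.ids).symmetric_difference(cohort.ids))
        raise ValueError(f"feature/phenotype id mismatch: {extra[:10]}")
    n = features.n_subjects
    if spec.mode == "baseline":
        A = np.maximum(cosine_matrix(features.values), 0.0)
    else:
        S_nimg = np.zeros((n, n))
        for feat in spec.features:
            S_nimg += _indicator_matrix(cohort, feat)
        if spec.mode == "nonimaging":
            A = S_nimg
        else:
            A = np.maximum(cosine_matrix(features.values), 0.0) * S_nimg
    A = (A + A.T) / 2.0  # symmetrize away float round-off
    np.fill_diagonal(A, 0.0)
    return PopulationGraph(ids=list(features.ids), A=A, X=features.values,
                           masks=cohort.masks())


def grid_search_threshold(
    candidates: Iterable[float],
    evaluate: Callable[[float], float],
) -> tuple[float, list[tuple[float, float]]]:
    """Exhaustive search of beta against a validation-accuracy callback.

    Returns the best beta and the full (beta, accuracy) trace.  Ties break
    toward the smaller beta, i.e. the sparser graph.
    """
    candidates = sorted(float(b) for b in candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    trace = [(b, float(evaluate(b))) for b in candidates]
    for beta, acc in trace:
        logger.info("threshold search: beta=%g -> val acc %.3f", beta, acc)
    best_beta, best_acc = trace[0]
    for beta, acc in trace[1:]:
        if acc > best_acc:
            best_beta, best_acc = beta, acc
    return best_beta, trace


def default_threshold_grid(values: np.ndarray, n_points: int = 10) -> list[float]:
    """Candidate betas spanning the observed score range, evenly spaced."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    span = float(values.max() - values.min()) if values.size else 1.0
    if span <= 0:
        span = 1.0
    return list(np.linspace(span / n_points, span, n_points))
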