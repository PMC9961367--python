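"""Synthetic cohorts with the statistical structure of the ADNI-1 sample.

The real study population (access-controlled) comprises three diagnostic
groups — cognitively normal (CN), mild cognitive impairment (MCI) and
Alzheimer's disease (AD) — each characterised by demographics (age, gender,
ApoE4 allele count) and nine neuropsychological scores.  This module draws
cohorts whose per-class covariate means/SDs and categorical proportions match
the published ADNI-1 summary table, plus class-structured feature vectors
standing in for CNN embeddings and toy 3-D "gray-matter" phantoms, so that
every downstream stage (graph construction, GCN, experiments) is fully
testable without any data download.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureMatrix, VolumeSet

DIAGNOSES = ("CN", "MCI", "AD")
#: disease severity used by the phantom generator (atrophy scales with it)
SEVERITY = {"CN": 0, "MCI": 1, "AD": 2}
SCORE_NAMES = (
    "MMSE", "CDR_SB", "ADAS11", "ADAS13", "FAQ",
    "ADNI_MEM", "ADNI_EF", "ADNI_LAN", "ADNI_VS",
)
#: physiological clipping ranges for scores that have hard bounds
SCORE_BOUNDS = {
    "MMSE": (0.0, 30.0),
    "CDR_SB": (0.0, 18.0),
    "ADAS11": (0.0, 70.0),
    "ADAS13": (0.0, 85.0),
    "FAQ": (0.0, 30.0),
}

COHORT_CSV_COLUMNS = ["id", "diagnosis", "age", "gender", "apoe4",
                      *SCORE_NAMES, "split"]

#: ADNI-1 baseline class sizes
ADNI1_CLASS_COUNTS = {"CN": 229, "MCI": 382, "AD": 187}

#: Per-class covariate calibration from the ADNI-1 summary statistics:
#: quantitative covariates as (mean, sd); gender as P(male); ApoE4 as
#: probabilities of 0/1/2 e4 alleles (normalized counts).
ADNI1_COVARIATES: dict[str, dict] = {
    "CN": {
        "age": (75.9, 5.0),
        "gender_p_male": 119 / 229,
        "apoe4_probs": (168 / 229, 56 / 229, 5 / 229),
        "scores": {
            "MMSE": (29.1, 1.0), "CDR_SB": (0.0, 0.1), "ADAS11": (6.2, 2.9),
            "ADAS13": (9.5, 4.2), "FAQ": (0.1, 0.6), "ADNI_MEM": (1.0, 0.5),
            "ADNI_EF": (0.6, 0.7), "ADNI_LAN": (0.8, 0.7), "ADNI_VS": (0.2, 0.6),
        },
    },
    "MCI": {
        "age": (74.7, 7.5),
        "gender_p_male": 245 / 382,
        "apoe4_probs": (171 / 375, 161 / 375, 43 / 375),
        "scores": {
            "MMSE": (27.3, 1.8), "CDR_SB": (1.6, 0.9), "ADAS11": (11.5, 4.4),
            "ADAS13": (18.7, 6.2), "FAQ": (3.8, 4.4), "ADNI_MEM": (-0.1, 0.6),
            "ADNI_EF": (-0.1, 0.9), "ADNI_LAN": (-0.1, 0.8), "ADNI_VS": (-0.1, 0.8),
        },
    },
    "AD": {
        "age": (75.3, 7.5),
        "gender_p_male": 98 / 187,
        "apoe4_probs": (64 / 187, 87 / 187, 36 / 187),
        "scores": {
            "MMSE": (23.3, 2.0), "CDR_SB": (4.4, 1.6), "ADAS11": (19.7, 4.9),
            "ADAS13": (30.3, 6.1), "FAQ": (13.2, 6.8), "ADNI_MEM": (-0.9, 0.6),
            "ADNI_EF": (-1.0, 0.9), "ADNI_LAN": (-0.8, 0.9), "ADNI_VS": (-0.6, 0.9),
        },
    },
}


@dataclass
class Subject:
    id: str
    diagnosis: str
    age: float
    gender: str
    apoe4: int
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.apoe4 not in (0, 1, 2):
            raise ValueError("apoe4 must be 0, 1 or 2")
        if not self.age > 0:
            raise ValueError("age must be positive")
        missing = set(SCORE_NAMES) - set(self.scores)
        if missing:
            raise ValueError(f"missing scores: {sorted(missing)}")


@dataclass
class Cohort:
    subjects: list[Subject]
    split: dict[str, str]  # id -> train|val|test

    def __post_init__(self) -> None:
        ids = {s.id for s in self.subjects}
        if set(self.split) != ids:
            raise ValueError("split must cover exactly the subject ids")
        bad = {v for v in self.split.values()} - {"train", "val", "test"}
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def diagnoses(self) -> list[str]:
        return [s.diagnosis for s in self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)

    def covariate(self, name: str) -> np.ndarray:
        """Column of a non-imaging covariate, ordered like ``subjects``."""
        if name == "age":
            return np.array([s.age for s in self.subjects], float)
        if name == "gender":
            return np.array([s.gender for s in self.subjects], object)
        if name == "apoe4":
            return np.array([s.apoe4 for s in self.subjects], object)
        if name in SCORE_NAMES:
            return np.array([s.scores[name] for s in self.subjects], float)
        raise KeyError(f"unknown covariate {name!r}")

    def masks(self) -> dict[str, np.ndarray]:
        return {name: np.array([self.split[s.id] == name for s in self.subjects])
                for name in ("train", "val", "test")}

    def labels(self, classes: tuple[str, ...] = DIAGNOSES) -> np.ndarray:
        index = {c: k for k, c in enumerate(classes)}
        return np.array([index[s.diagnosis] for s in self.subjects], int)

    def subset(self, diagnoses: tuple[str, ...]) -> "Cohort":
        keep = [s for s in self.subjects if s.diagnosis in diagnoses]
        return Cohort(subjects=keep, split={s.id: self.split[s.id] for s in keep})

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"id": s.id, "diagnosis": s.diagnosis, "age": s.age,
                   "gender": s.gender, "apoe4": s.apoe4}
            row.update({k: s.scores[k] for k in SCORE_NAMES})
            row["split"] = self.split[s.id]
            rows.append(row)
        return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        subjects = []
        split = {}
        for _, r in df.iterrows():
            sid = str(r["id"])
            subjects.append(Subject(
                id=sid, diagnosis=str(r["diagnosis"]), age=float(r["age"]),
                gender=str(r["gender"]), apoe4=int(r["apoe4"]),
                scores={k: float(r[k]) for k in SCORE_NAMES}))
            split[sid] = str(r["split"])
        return cls(subjects=subjects, split=split)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class CohortConfig:
    """Generator settings; defaults reproduce the ADNI-1 summary structure."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(ADNI1_CLASS_COUNTS))
    covariate_params: dict[str, dict] = field(
        default_factory=lambda: _deepcopy_params(ADNI1_COVARIATES))
    feature_dim: int = 512
    class_separation: float = 2.0
    noise_sd: float = 1.0
    latent_rank: int = 16
    residual_sd: float = 0.3
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for diag, n in self.class_counts.items():
            if diag not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {diag!r}")
            if n < 0:
                raise ValueError("class counts must be nonnegative")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["split_fractions"] = list(self.split_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("cohort config file must state an explicit seed")
        if "split_fractions" in doc:
            doc["split_fractions"] = tuple(doc["split_fractions"])
        if "covariate_params" in doc:
            for params in doc["covariate_params"].values():
                params["age"] = tuple(params["age"])
                params["apoe4_probs"] = tuple(params["apoe4_probs"])
                params["scores"] = {k: tuple(v)
                                    for k, v in params["scores"].items()}
        return cls(**doc)


def _deepcopy_params(params: dict) -> dict:
    return {
        diag: {
            "age": tuple(p["age"]),
            "gender_p_male": float(p["gender_p_male"]),
            "apoe4_probs": tuple(p["apoe4_probs"]),
            "scores": {k: tuple(v) for k, v in p["scores"].items()},
        }
        for diag, p in params.items()
    }


def planted_signal_params(
    planted: str = "CDR_SB",
    planted_shift_sd: float = 4.0,
    base_mean: float = 0.0,
    base_sd: float = 1.0,
) -> dict[str, dict]:
    """Covariate parameters with exactly one class-informative score.

    Every quantitative score is N(base_mean, base_sd) in all classes except
    ``planted``, whose class means are staggered by ``planted_shift_sd``
    standard deviations per severity step (CN < MCI < AD).  Demographics are
    class-independent.  Used for planted-signal recovery experiments, where
    the edge built from the planted covariate should out-rank edges built
    from the uninformative decoys.
    """
    if planted not in SCORE_NAMES:
        raise ValueError(f"unknown score {planted!r}")
    params = {}
    for diag in DIAGNOSES:
        scores = {name: (base_mean, base_sd) for name in SCORE_NAMES}
        scores[planted] = (base_mean + SEVERITY[diag] * planted_shift_sd * base_sd,
                           base_sd)
        # keep bounded scores inside their physiological range
        for name, (mean, sd) in scores.items():
            if name in SCORE_BOUNDS:
                lo, hi = SCORE_BOUNDS[name]
                scores[name] = (float(np.clip(mean, lo + 2 * sd, hi - 2 * sd)), sd)
        params[diag] = {
            "age": (75.0, 6.5),
            "gender_p_male": 0.55,
            "apoe4_probs": (0.5, 0.38, 0.12),
            "scores": scores,
        }
    return params


def assign_split(
    ids: list[str],
    diagnoses: list[str],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Random split into train/val/test, stratified by diagnosis.

    Within each class the three counts are the largest-remainder rounding of
    the configured fractions, so every class is within one subject of its
    exact proportional allocation.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    split: dict[str, str] = {}
    ids_arr = np.asarray(ids, dtype=object)
    diag_arr = np.asarray(diagnoses, dtype=object)
    for diag in sorted(set(diagnoses)):
        class_ids = ids_arr[diag_arr == diag]
        n = len(class_ids)
        order = rng.permutation(n)
        cuts = np.round(np.cumsum(fractions) * n).astype(int)
        names = np.empty(n, dtype=object)
        names[order[: cuts[0]]] = "train"
        names[order[cuts[0]: cuts[1]]] = "val"
        names[order[cuts[1]:]] = "test"
        split.update(dict(zip(class_ids, names)))
    return split


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort from the configured per-class covariate distributions.

    Quantitative covariates are per-class normals clipped to physiological
    ranges; gender and ApoE4 are per-class categoricals.  Deterministic for a
    given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    subjects: list[Subject] = []
    counter = 0
    for diag in DIAGNOSES:  # fixed order => reproducible ids
        n = config.class_counts.get(diag, 0)
        if n == 0:
            continue
        p = config.covariate_params[diag]
        age = np.clip(rng.normal(p["age"][0], p["age"][1], size=n), 40.0, 100.0)
        gender = np.where(rng.random(n) < p["gender_p_male"], "M", "F")
        apoe = rng.choice(3, size=n, p=np.asarray(p["apoe4_probs"], float)
                          / np.sum(p["apoe4_probs"]))
        score_cols = {}
        for name in SCORE_NAMES:
            mean, sd = p["scores"][name]
            vals = rng.normal(mean, sd, size=n)
            if name in SCORE_BOUNDS:
                vals = np.clip(vals, *SCORE_BOUNDS[name])
            score_cols[name] = vals
        for i in range(n):
            subjects.append(Subject(
                id=f"S{counter:04d}",
                diagnosis=diag,
                age=float(age[i]),
                gender=str(gender[i]),
                apoe4=int(apoe[i]),
                scores={name: float(score_cols[name][i]) for name in SCORE_NAMES},
            ))
            counter += 1
    split = assign_split([s.id for s in subjects], [s.diagnosis for s in subjects],
                         config.split_fractions, seed=config.seed)
    return Cohort(subjects=subjects, split=split)


def generate_features(cohort: Cohort, config: CohortConfig) -> FeatureMatrix:
    """Class-structured nonnegative feature vectors emulating CNN embeddings.

    Row i = ReLU(c_{diag(i)} + B z_i + e_i): a nonnegative class centroid
    (entries 0.5 * class_separation * noise_sd * |N(0,1)|), a shared
    low-rank loading matrix B (rank ``latent_rank``, per-coordinate SD
    ``noise_sd``) mixing a subject-specific latent z_i, and a small i.i.d.
    residual e_i (SD ``residual_sd * noise_sd``).  The low-rank term models
    the strong inter-feature correlation of learned CNN embeddings; without
    it, cosine similarities between high-dimensional subjects concentrate on
    a single value and the baseline imaging graph carries no usable
    contrast.  Rectification mimics post-ReLU activations and guarantees
    nonnegative cosine similarities for the graph normalization.
    Deterministic given ``config.seed``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    d = config.feature_dim
    r = config.latent_rank
    ss = np.random.SeedSequence([int(config.seed), 2])
    rng_centroid, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    scale = 0.5 * config.class_separation * config.noise_sd
    centroids = {diag: scale * np.abs(rng_centroid.normal(size=d))
                 for diag in DIAGNOSES}
    loadings = rng_centroid.normal(scale=config.noise_sd / np.sqrt(r),
                                   size=(d, r))
    n = len(cohort)
    latent = rng_noise.normal(size=(n, r))
    residual = rng_noise.normal(scale=config.residual_sd * config.noise_sd,
                                size=(n, d))
    rows = np.stack([centroids[s.diagnosis] for s in cohort.subjects])
    rows = rows + latent @ loadings.T + residual
    return FeatureMatrix(ids=cohort.ids, values=np.maximum(rows, 0.0))


def atrophy_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Fixed pair of ellipsoidal 'medial temporal' regions, boolean mask."""
    D, H, W = shape
    z, y, x = np.meshgrid(np.linspace(0, 1, D), np.linspace(0, 1, H),
                          np.linspace(0, 1, W), indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.35, 0.65):
        e = (((z - 0.45) / 0.14) ** 2 + ((y - 0.55) / 0.10) ** 2
             + ((x - cx) / 0.12) ** 2)
        mask |= e <= 1.0
    return mask


def generate_volumes(
    cohort: Cohort,
    shape: tuple[int, int, int] = (64, 64, 64),
    atrophy_amplitude: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> VolumeSet:
    """Toy gray-matter phantoms with class-proportional regional atrophy.

    Each volume is a smooth radial 'brain' intensity profile in which the
    fixed ellipsoidal regions of :func:`atrophy_mask` are attenuated by a
    factor ``atrophy_amplitude * severity / 2`` (CN=0, MCI=1, AD=2) plus
    i.i.d. voxel noise.  These are statistical phantoms only — no scanner
    physics or registration error is modelled.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("volume shape must be positive")
    D, H, W = shape
    z, y, x = np.meshgrid(np.linspace(-1, 1, D), np.linspace(-1, 1, H),
                          np.linspace(-1, 1, W), indexing="ij")
    r2 = z ** 2 + y ** 2 + x ** 2
    base = 0.25 + 0.75 * np.exp(-r2 / (2 * 0.45 ** 2))
    mask = atrophy_mask(shape)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    data = np.empty((len(cohort), D, H, W), dtype=np.float32)
    for i, subj in enumerate(cohort.subjects):
        atten = np.clip(atrophy_amplitude * SEVERITY[subj.diagnosis] / 2.0, 0, 1)
        vol = base * (1.0 - atten * mask)
        vol = vol + noise_sd * rng.normal(size=shape)
        data[i] = np.maximum(vol, 0.0)
    return VolumeSet(ids=cohort.ids, data=data)
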