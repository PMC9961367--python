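"""Shared in-memory containers passed between pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class FeatureMatrix:
    """Per-subject anatomical embedding: one row per subject, column dim d.

    Row order follows ``ids``; downstream graph construction relies on this
    alignment, so the two fields are validated together.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x dims)")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.values.shape[0]} feature rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"))
        df.columns = [f"f{j}" for j in range(self.dim)]
        df.to_csv(path, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col="id")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(float))


@dataclass
class VolumeSet:
    """A stack of 3-D volumes, one per subject (n, D, H, W)."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("volume data must be 4-D (subjects, D, H, W)")
        if len(self.ids) != self.data.shape[0]:
            raise ValueError("ids and volume stack length differ")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    def write_nifti(self, directory: str | Path, voxel_size: float = 3.0) -> None:
        """One NIfTI-1 file per subject, RAS orientation, isotropic voxels."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        for sid, vol in zip(self.ids, self.data):
            nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine),
                     directory / f"{sid}.nii")

    @classmethod
    def read_nifti(cls, directory: str | Path, ids: list[str]) -> "VolumeSet":
        import nibabel as nib

        directory = Path(directory)
        vols = [np.asarray(nib.load(directory / f"{sid}.nii").dataobj, np.float32)
                for sid in ids]
        return cls(ids=list(ids), data=np.stack(vols))


@dataclass
class PopulationGraph:
    """Undirected weighted population graph.

    A is the symmetric nonnegative adjacency with zero diagonal, X the node
    feature matrix (rows aligned with ``ids``), and ``masks`` boolean
    train/val/test vectors partitioning the nodes.
    """

    ids: list[str]
    A: np.ndarray
    X: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape does not match id count")
        if self.X.shape[0] != n:
            raise ValueError("feature rows do not match id count")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(self.A < 0):
            raise ValueError("adjacency contains negative weights")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        for name, m in self.masks.items():
            self.masks[name] = np.asarray(m, dtype=bool)
            if self.masks[name].shape != (n,):
                raise ValueError(f"mask {name!r} has wrong shape")
        if self.masks:
            total = np.zeros(n, dtype=int)
            for m in self.masks.values():
                total += m.astype(int)
            if np.any(total != 1):
                raise ValueError("masks must partition the node set")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def save(self, directory: str | Path) -> None:
        """Adjacency in Matrix Market coordinate form + sidecar node CSV."""
        import pandas as pd
        from scipy import io as sio
        from scipy import sparse

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(str(directory / "adjacency.mtx"), sparse.coo_matrix(self.A))
        nodes = pd.DataFrame({"id": self.ids})
        for name in ("train", "val", "test"):
            if name in self.masks:
                nodes[name] = self.masks[name].astype(int)
        nodes.to_csv(directory / "nodes.csv", index=False)
        FeatureMatrix(self.ids, self.X).to_csv(directory / "features.csv")

    @classmethod
    def load(cls, directory: str | Path) -> "PopulationGraph":
        import pandas as pd
        from scipy import io as sio

        directory = Path(directory)
        A = np.asarray(sio.mmread(str(directory / "adjacency.mtx")).todense())
        nodes = pd.read_csv(directory / "nodes.csv")
        feats = FeatureMatrix.from_csv(directory / "features.csv")
        masks = {name: nodes[name].to_numpy(bool)
                 for name in ("train", "val", "test") if name in nodes}
        return cls(ids=[str(i) for i in nodes["id"]], A=A, X=feats.values,
                   masks=masks)
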