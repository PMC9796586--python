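"""In-memory containers for volumes, tissue masks and T1 maps.

All volumes are 3D numpy arrays indexed (x, y, z); axial slices are taken
along the third axis. Affines follow the NIfTI convention and are carried
through unchanged (no resampling is performed anywhere in the package).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

TISSUES = ("gm", "wm", "csf")


def _check_3d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D volume, got shape {arr.shape}")
    return arr


@dataclass
class VolumeImage:
    """A 3D scalar intensity volume with voxel geometry metadata."""

    data: np.ndarray
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "VolumeImage.data").astype(float)
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "VolumeImage", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class TissueMasks:
    """Per-tissue binary or probabilistic volumes for GM/WM/CSF.

    Probability maps are reduced to hard masks by per-voxel argmax with a
    0.5 floor on the winning probability (:meth:`hard_masks`).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    extras: Dict[str, np.ndarray] = field(default_factory=dict)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gm = _check_3d(self.gm, "gm mask")
        self.wm = _check_3d(self.wm, "wm mask")
        self.csf = _check_3d(self.csf, "csf mask")
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError(
                "tissue masks must share one grid; got "
                f"gm {self.gm.shape}, wm {self.wm.shape}, csf {self.csf.shape}"
            )
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.gm.shape

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}

    def union(self) -> np.ndarray:
        return (self.gm > 0) | (self.wm > 0) | (self.csf > 0)

    def is_binary(self) -> bool:
        return all(
            np.isin(np.unique(m), (0, 1)).all() for m in self.as_dict().values()
        )

    def hard_masks(self, floor: float = 0.5) -> "TissueMasks":
        """Collapse probability maps to mutually exclusive boolean masks."""
        if self.is_binary():
            return TissueMasks(
                gm=self.gm > 0, wm=self.wm > 0, csf=self.csf > 0, affine=self.affine
            )
        stack = np.stack(
            [np.asarray(self.gm, float), np.asarray(self.wm, float),
             np.asarray(self.csf, float)]
        )
        winner = stack.argmax(axis=0)
        ok = stack.max(axis=0) >= floor
        return TissueMasks(
            gm=ok & (winner == 0),
            wm=ok & (winner == 1),
            csf=ok & (winner == 2),
            affine=self.affine,
        )


@dataclass
class T1Map:
    """Voxelwise T1 in ms with a validity mask and fit provenance."""

    values: np.ndarray
    valid_mask: np.ndarray
    method: str
    meta: Dict = field(default_factory=dict)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = _check_3d(self.values, "T1Map.values").astype(float)
        self.valid_mask = _check_3d(self.valid_mask, "T1Map.valid_mask").astype(bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]
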