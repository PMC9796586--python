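"""NIfTI-1 reading/writing and run configuration."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import yaml

from .containers import T1Map, TissueMasks, VolumeImage

PathLike = Union[str, Path]


def read_volume(path: PathLike) -> VolumeImage:
    """Read a 3D NIfTI-1 volume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D {data.shape}"
        )
    return VolumeImage(data.astype(float), np.asarray(img.affine))


def write_volume(volume: Union[VolumeImage, T1Map], path: PathLike) -> None:
    """Write a volume or T1 map as NIfTI-1 (float64, lossless round trip)."""
    if isinstance(volume, T1Map):
        data, affine = volume.values, volume.affine
    else:
        data, affine = volume.data, volume.affine
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine), str(path))


def read_masks(paths: Union[Sequence[PathLike], Dict[str, PathLike]]) -> TissueMasks:
    """Read GM/WM/CSF masks (in that order, or by name) and check grids."""
    if isinstance(paths, dict):
        ordered = [paths["gm"], paths["wm"], paths["csf"]]
    else:
        ordered = list(paths)
        if len(ordered) != 3:
            raise ValueError("expected exactly three mask paths (GM, WM, CSF)")
    vols = [read_volume(p) for p in ordered]
    for p, v in zip(ordered[1:], vols[1:]):
        if not vols[0].same_grid(v):
            raise ValueError(
                f"mask grid mismatch: {ordered[0]} {vols[0].shape} vs "
                f"{p} {v.shape}"
            )
    return TissueMasks(
        gm=vols[0].data, wm=vols[1].data, csf=vols[2].data, affine=vols[0].affine
    )


def check_congruent(image: VolumeImage, masks: TissueMasks) -> None:
    if image.shape != masks.shape or not np.allclose(
        image.affine, masks.affine, atol=1e-4
    ):
        raise ValueError(
            f"image grid {image.shape} does not match mask grid {masks.shape}"
        )


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run, serialized into reports."""

    sequence: str
    params: Dict = dataclasses.field(default_factory=dict)
    reference_overrides: Dict = dataclasses.field(default_factory=dict)
    sigma: float = 2.0
    min_voxels: int = 50
    clamp_max: float = 5000.0
    lut_range: tuple = (1.0, 5000.0)
    lut_step: float = 1.0
    seed: int = 0
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence not in {"se", "mprage", "ll", "simulate", "compare"}:
            raise ValueError(f"unknown sequence type '{self.sequence}'")
        if self.sigma < 0 or self.min_voxels < 1 or self.clamp_max <= 0:
            raise ValueError("invalid thresholds in run config")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["lut_range"] = list(self.lut_range)
        return d

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**data)


def write_report(report: Dict, path: PathLike) -> None:
    """Write a machine-readable JSON report (config, seeds, diagnostics)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
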