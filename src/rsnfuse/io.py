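"""Readers, writers and run configuration.

NIfTI volumes are flattened to time x voxel matrices in C order of the
in-mask voxel indices, so matrices written back to the same grid/mask
round-trip bit-exactly.  Behavioral tables are CSV with a header row and
one row per subject; non-numeric columns must either use a documented
coding (gender M/F -> +1/-1; handedness right/ambidextrous/left ->
+1/0/-1) or be covered by an explicit ``codings`` mapping — missing
values are rejected outright, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .parallel import ParaIcaConfig

__all__ = [
    "PipelineConfig",
    "read_volume_series",
    "write_volume_series",
    "read_behavior_table",
    "write_maps",
    "DEFAULT_CODINGS",
]

DEFAULT_CODINGS: dict[str, dict[str, float]] = {
    "gender": {"M": 1.0, "F": -1.0, "m": 1.0, "f": -1.0},
    "handedness": {
        "right": 1.0,
        "ambidextrous": 0.0,
        "left": -1.0,
        "R": 1.0,
        "A": 0.0,
        "L": -1.0,
    },
}


@dataclass
class PipelineConfig:
    """Run configuration for the full fusion workflow."""

    volume_paths: list[str] = field(default_factory=list)
    template_path: str | None = None
    behavior_path: str | None = None
    output_dir: str = "."
    mask_path: str | None = None
    k_group: int = 40
    k_subject: int = 60
    drop_initial_volumes: int = 3
    template_r_min: float = 0.4
    template_z_thr: float = 3.0
    template_thr: float | None = None
    network_mask_z: float = 1.96
    para: ParaIcaConfig = field(default_factory=ParaIcaConfig)
    alpha: float = 0.05
    min_cluster_voxels: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name in ("k_group", "k_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.drop_initial_volumes < 0:
            raise ValueError("drop_initial_volumes must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        para = ParaIcaConfig(**raw.pop("para", {}))
        cfg = cls(para=para, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "para"}
        data["para"] = dict(self.para.__dict__)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_volume_series(
    path: str | Path,
    mask: np.ndarray | None = None,
    drop_initial: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D NIfTI as a time x voxel matrix.

    The first ``drop_initial`` volumes are discarded (scanner
    equilibration frames).  With a boolean ``mask`` only in-mask voxels
    are kept, flattened in C index order; otherwise all voxels.

    Returns ``(matrix, affine)``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume series, got {data.ndim}-D")
    if drop_initial >= data.shape[3]:
        raise ValueError(f"cannot drop {drop_initial} of {data.shape[3]} volumes")
    data = data[..., drop_initial:]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume grid {data.shape[:3]}"
            )
        X = data[mask].T          # time x in-mask voxels
    else:
        X = data.reshape(-1, data.shape[3]).T
    return np.ascontiguousarray(X), img.affine


def write_volume_series(
    path: str | Path,
    matrix: np.ndarray,
    grid: tuple[int, int, int],
    affine: np.ndarray,
    mask: np.ndarray | None = None,
) -> None:
    """Write a time x voxel matrix back to a 4-D NIfTI on ``grid``."""
    T = matrix.shape[0]
    vol = np.zeros(grid + (T,))
    if mask is not None:
        vol[np.asarray(mask, dtype=bool)] = matrix.T
    else:
        vol = matrix.T.reshape(grid + (T,))
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_maps(
    path: str | Path,
    maps: np.ndarray,
    grid: tuple[int, int, int],
    affine: np.ndarray,
    mask: np.ndarray | None = None,
) -> None:
    """Write k x voxel component maps as a 4-D NIfTI (k along the 4th axis)."""
    k = maps.shape[0]
    vol = np.zeros(grid + (k,))
    if mask is not None:
        vol[np.asarray(mask, dtype=bool)] = maps.T
    else:
        vol = maps.T.reshape(grid + (k,))
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_behavior_table(
    path: str | Path,
    codings: dict[str, dict[str, float]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Load a subjects x measures behavioral CSV.

    Returns ``(matrix, labels)``.  Missing values raise with the exact
    cell named; categorical columns are mapped through ``codings``
    (falling back to the documented default gender/handedness codes when
    the column name contains those words).
    """
    df = pd.read_csv(path)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: empty table")
    labels = [str(c) for c in df.columns]

    for col in df.columns:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(
                f"{path}: missing value at row {row}, column {col!r} (no imputation)"
            )
        if df[col].dtype == object:
            mapping = None
            if codings and col in codings:
                mapping = codings[col]
            else:
                for key, default in DEFAULT_CODINGS.items():
                    if key in str(col).lower():
                        mapping = default
                        break
            if mapping is None:
                raise ValueError(
                    f"{path}: column {col!r} is non-numeric and has no coding"
                )
            try:
                df[col] = df[col].map(lambda v: mapping[str(v).strip()])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: unknown category {exc} in column {col!r}"
                ) from exc
            if df[col].isna().any():
                bad = df.index[df[col].isna()][0]
                raise ValueError(f"{path}: unmapped category at row {bad}, column {col!r}")
    return df.to_numpy(dtype=float), labels
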