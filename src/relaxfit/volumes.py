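"""NIfTI volume I/O for real multi-TSL acquisitions.

A 4D T1rho-weighted acquisition (X x Y x Z x T) is flattened to an
``(n, T)`` voxel table in row-major (C) order over the spatial axes; the
map is invertible, and masked-out voxels are restored as NaN in all output
parameter maps.  Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .models import TSLSchedule, param_names
from .nls import MapFitResult

__all__ = ["VolumeStack", "read_volume_stack", "write_parameter_maps"]


@dataclass
class VolumeStack:
    """4D intensity data with its schedule, affine and optional mask."""

    data: np.ndarray            # (X, Y, Z, T)
    schedule: TSLSchedule
    affine: np.ndarray
    mask: np.ndarray | None = None  # (X, Y, Z) boolean

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("expected a 4D volume (X, Y, Z, T)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"volume has {self.data.shape[3]} time frames but the schedule "
                f"lists {len(self.schedule)} spin-lock times"
            )
        if self.mask is not None and self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dimensions")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(signals (n, T), voxel_mask (n,))`` in C order."""
        n = int(np.prod(self.spatial_shape))
        signals = self.data.reshape(n, self.data.shape[3])
        voxel_mask = (
            self.mask.reshape(n).astype(bool)
            if self.mask is not None
            else np.ones(n, dtype=bool)
        )
        return signals, voxel_mask

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flatten` for one value per voxel."""
        return np.asarray(values).reshape(self.spatial_shape)


def read_volume_stack(
    path: str | Path,
    tsl_list,
    mask_path: str | Path | None = None,
) -> VolumeStack:
    """Load a 4D NIfTI volume and attach its spin-lock schedule."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    schedule = tsl_list if isinstance(tsl_list, TSLSchedule) else TSLSchedule(tuple(tsl_list))
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return VolumeStack(data=data, schedule=schedule, affine=img.affine, mask=mask)


def write_parameter_maps(
    result: MapFitResult,
    template: VolumeStack,
    out_dir: str | Path,
    prefix: str = "",
) -> dict[str, Path]:
    """Write one 3D NIfTI per parameter plus a residual-norm map.

    Masked-out voxels are NaN in every map.  Returns name -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = int(np.prod(template.spatial_shape))
    if len(result) != n:
        raise ValueError("result count does not match template voxel count")
    names = list(param_names(result.model)) + ["residual_norm"]
    values = np.column_stack([result.params, result.residual_norm])
    paths: dict[str, Path] = {}
    for j, name in enumerate(names):
        vol = template.unflatten(values[:, j])
        img = nib.Nifti1Image(vol.astype(np.float64), template.affine)
        p = out_dir / f"{prefix}{result.model}_{name}.nii.gz"
        nib.save(img, str(p))
        paths[name] = p
    return paths
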