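"""Voxel-map containers: ROI geometry and per-subject connectivity maps.

All spatial quantities live in RAS+ millimetre space: x grows left→right,
y posterior→anterior, z inferior→superior.  Voxel indices are 0-based and
mapped to mm through a NIfTI-style 4x4 affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ROIGeometry:
    """A region of interest on a regular voxel grid.

    Parameters
    ----------
    name
        ROI label, e.g. ``"LPrCGsup"``.
    mask
        Boolean 3-D array; True marks voxels belonging to the ROI.
    affine
        4x4 voxel→mm transform (RAS+).
    template_center_mm
        Centre of the synthetic spatial template (mm).
    template_width_mm
        Full width at half maximum of the Gaussian template (mm).
    template_amplitude
        Peak value of the Gaussian template (connectivity units).
    """

    name: str
    mask: np.ndarray
    affine: np.ndarray
    template_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    template_width_mm: float = 8.0
    template_amplitude: float = 1.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        if mask.ndim != 3:
            raise ValueError("ROI mask must be a 3-D boolean array")
        if not mask.any():
            raise ValueError(f"ROI {self.name!r} has an empty mask")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(k, 3) integer indices of in-mask voxels, C-order (the tie order)."""
        return np.argwhere(self.mask)

    @property
    def coords_mm(self) -> np.ndarray:
        """(k, 3) mm coordinates of in-mask voxel centres."""
        ijk = self.voxel_indices
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def default_grid(
        cls,
        name: str = "ROI",
        shape: tuple[int, int, int] = (12, 12, 12),
        voxel_mm: float = 2.0,
        center_mm: tuple[float, float, float] | None = None,
        width_mm: float = 8.0,
        amplitude: float = 1.0,
    ) -> "ROIGeometry":
        """Desk-scale ROI: full cuboid mask, isotropic voxels, origin at 0."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        if center_mm is None:
            center_mm = tuple(voxel_mm * (s - 1) / 2.0 for s in shape)
        return cls(
            name=name,
            mask=np.ones(shape, dtype=bool),
            affine=affine,
            template_center_mm=center_mm,
            template_width_mm=width_mm,
            template_amplitude=amplitude,
        )


@dataclass
class ConnectivityMap:
    """One subject's voxel-wise connectivity (or activation) values on an ROI.

    ``values[i]`` belongs to the voxel ``roi.voxel_indices[i]``; the ordering
    is the ROI's C-order voxel order and is shared by every map on the same
    geometry, so maps are directly comparable voxel-by-voxel.
    """

    roi: ROIGeometry
    values: np.ndarray
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.roi.n_voxels,):
            raise ValueError(
                f"values shape {self.values.shape} does not match ROI "
                f"{self.roi.name!r} with {self.roi.n_voxels} voxels"
            )

    @property
    def coords_mm(self) -> np.ndarray:
        return self.roi.coords_mm

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter masked values back into a full 3-D volume."""
        vol = np.full(self.roi.mask.shape, fill, dtype=float)
        vol[self.roi.mask] = self.values
        return vol
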