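"""Volumetric image model and the voxel-space half of the pipeline.

Covers the weighted partial-volume-estimation (wPVE) map built from GM/WM/CSF
tissue fractions, Gaussian smoothing to the PET point-spread resolution,
cerebellar-reference (DVR) intensity normalization, world-coordinate
trilinear sampling, and masked statistics.

Conventions: voxel indices are 0-based; the 4x4 affine maps voxel index to
world mm (NIfTI semantics); all surface sampling happens in world space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeImage",
    "TissueFractions",
    "BinaryMask",
    "weighted_pve",
    "gaussian_smooth",
    "dvr_normalize",
    "trilinear_sample",
    "masked_stats",
    "fwhm_to_sigma",
    "GM_WEIGHT",
    "WM_WEIGHT",
    "CSF_WEIGHT",
]

#: Tissue uptake weights: CSF takes up no tracer and WM uptake is about one
#: fourth that of GM, so wPVE = 1.0*GM + 0.25*WM + 0.0*CSF.
GM_WEIGHT = 1.0
WM_WEIGHT = 0.25
CSF_WEIGHT = 0.0

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given FWHM: sigma = FWHM / (2 sqrt(2 ln 2))."""
    return float(fwhm) * _SIGMA_PER_FWHM


@dataclass
class VolumeImage:
    """3-D scalar grid with a voxel-index -> world-mm affine."""

    grid: np.ndarray
    affine: np.ndarray
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3-D; got shape {self.grid.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.isfinite(self.grid).all():
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel indices (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def same_geometry(self, other: "VolumeImage | BinaryMask") -> bool:
        return self.shape == other.grid.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class BinaryMask:
    """A {0,1} voxel mask sharing geometry with a reference image."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        uniq = np.unique(self.grid)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.grid = self.grid.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class TissueFractions:
    """Per-voxel GM / WM / CSF partial-volume fractions, each in [0, 1].

    Fraction sums slightly above 1 (upstream estimators routinely overshoot)
    are renormalized with a warning; sums exceeding 1 by more than the
    tolerance at many voxels still only warn, since the wPVE construction is
    a plain weighted sum.
    """

    gm: VolumeImage
    wm: VolumeImage
    csf: VolumeImage

    _SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        for name, vol in (("wm", self.wm), ("csf", self.csf)):
            if not self.gm.same_geometry(vol):
                raise ValueError(
                    f"tissue map {name!r} does not share the GM map's "
                    f"shape/affine"
                )
        for name, vol in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if vol.grid.min() < -self._SUM_TOL or vol.grid.max() > 1 + self._SUM_TOL:
                raise ValueError(f"tissue fractions of {name!r} outside [0, 1]")
        total = self.gm.grid + self.wm.grid + self.csf.grid
        over = total > 1 + self._SUM_TOL
        if over.any():
            warnings.warn(
                f"tissue fractions sum above 1 at {int(over.sum())} voxels; "
                "clipping by renormalization",
                stacklevel=2,
            )
            scale = np.where(over, total, 1.0)
            for vol in (self.gm, self.wm, self.csf):
                vol.grid = vol.grid / scale


def weighted_pve(tissues: TissueFractions) -> VolumeImage:
    """Weighted partial-volume-estimation map: wPVE = GM + WM/4.

    Encodes the expected fraction of GM-equivalent uptake per voxel under
    the assumptions that CSF takes up no tracer and WM uptake is one fourth
    of GM uptake.
    """
    grid = (
        GM_WEIGHT * tissues.gm.grid
        + WM_WEIGHT * tissues.wm.grid
        + CSF_WEIGHT * tissues.csf.grid
    )
    return VolumeImage(grid, tissues.gm.affine.copy(), units="ratio")


def gaussian_smooth(vol: VolumeImage, fwhm: float) -> VolumeImage:
    """Isotropic Gaussian smoothing with the given FWHM in mm.

    Anisotropic voxel sizes are handled by per-axis sigmas in voxel units.
    Boundaries use zero padding; signals well inside the grid are unaffected
    by the choice.
    """
    if fwhm < 0:
        raise ValueError(f"fwhm must be non-negative; got {fwhm}")
    if fwhm == 0:
        return VolumeImage(vol.grid.copy(), vol.affine.copy(), vol.units)
    sigma_vox = fwhm_to_sigma(fwhm) / vol.voxel_sizes()
    out = ndimage.gaussian_filter(vol.grid, sigma=sigma_vox, mode="constant",
                                  cval=0.0, truncate=4.0)
    return VolumeImage(out, vol.affine.copy(), vol.units)


def dvr_normalize(pet: VolumeImage, cerebellum: BinaryMask) -> VolumeImage:
    """Reference-region intensity normalization of a PET uptake volume.

    Divides every voxel by the mean uptake inside the cerebellar mask, the
    reference region where glucose utilization is relatively preserved,
    yielding a distribution-volume-ratio-style image whose cerebellar mean
    is exactly 1.
    """
    if pet.shape != cerebellum.grid.shape:
        raise ValueError("cerebellum mask does not match the PET grid shape")
    if cerebellum.n_voxels == 0:
        raise ValueError("cerebellar reference mask is empty")
    ref = float(pet.grid[cerebellum.grid].mean())
    if ref <= 0:
        raise ValueError(
            f"cerebellar reference mean must be positive; got {ref}"
        )
    return VolumeImage(pet.grid / ref, pet.affine.copy(), units="DVR")


def trilinear_sample(vol: VolumeImage, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a volume at world-mm points.

    ``points`` may be a single 3-vector or an (n, 3) array.  Points outside
    the convex hull of voxel centers raise; there is no silent extrapolation.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    idx = vol.world_to_voxel(pts)
    upper = np.array(vol.shape, dtype=float) - 1.0
    bad = (idx < -1e-9).any(axis=1) | (idx > upper + 1e-9).any(axis=1)
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"sample point {first} at world {np.atleast_2d(pts)[first]} maps "
            f"outside the voxel-center hull (index {idx[first]})"
        )
    idx = np.clip(idx, 0.0, upper)
    vals = ndimage.map_coordinates(vol.grid, idx.T, order=1, mode="nearest")
    return float(vals[0]) if single else vals


def masked_stats(
    vol: VolumeImage, mask: BinaryMask, voxel_volume: float | None = None
) -> tuple[float, float]:
    """Mean value over a mask and the total mask volume in mm^3."""
    if vol.shape != mask.grid.shape:
        raise ValueError("mask does not match the volume grid shape")
    n = mask.n_voxels
    if n == 0:
        raise ValueError("mask is empty")
    if voxel_volume is None:
        voxel_volume = vol.voxel_volume()
    mean = float(vol.grid[mask.grid].mean())
    return mean, float(n * voxel_volume)
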