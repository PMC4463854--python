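"""Projection of volumetric uptake onto the cortical surface and PVC.

The measured PET signal in cortex is diluted by the partial volume effect:
with a scanner point-spread of several mm and a cortical ribbon only 2-4 mm
thick, GM uptake mixes with low-uptake WM and zero-uptake CSF.  The surface
route corrects this by comparing two maps sampled identically along the
cortical ribbon:

* ``sFDG`` — the normalized PET (DVR) volume averaged along each linked
  inner-to-outer vertex segment (6 samples at fractions 0, .2, ..., 1);
* ``swPVE`` — the weighted tissue map (GM + WM/4), smoothed to the PET
  resolution, averaged along the same segments.

Their ratio after 20 mm FWHM diffusion smoothing on the surface is the
partial-volume-corrected uptake ``csFDG``: where the tissue model says only
40% of a GM-like signal could have been observed, dividing by 0.4 restores
the true uptake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    SurfaceLabelMap,
    SurfacePair,
    VertexScalarMap,
    diffusion_smooth,
    link_thickness,
    regional_mean,
)
from .volume import (
    TissueFractions,
    VolumeImage,
    dvr_normalize,
    gaussian_smooth,
    trilinear_sample,
    weighted_pve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileSamples",
    "sample_profiles",
    "surface_map",
    "partial_volume_correct",
    "build_surface_features",
    "PROFILE_FRACTIONS",
    "DEFAULT_PVE_FLOOR",
]

#: Sampling fractions along each inner->outer segment: the segment is divided
#: into five equal proportions, giving 6 sample points including both
#: boundary vertices.
PROFILE_FRACTIONS = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

#: Smoothed swPVE below this floor (5% effective tissue) marks a vertex as
#: invalid for division rather than producing an exploding ratio.
DEFAULT_PVE_FLOOR = 0.05


@dataclass
class ProfileSamples:
    """Ordered intensity samples along each linked-vertex segment.

    ``values`` has shape (n_vertices, 6); column ``j`` holds the sample at
    fraction ``PROFILE_FRACTIONS[j]`` of the inner->outer segment, so column
    0 sits on the WM/GM vertex and column 5 on the GM/CSF vertex.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(PROFILE_FRACTIONS):
            raise ValueError(
                f"profiles must be (n, {len(PROFILE_FRACTIONS)}); "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("profile samples must be finite")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


def sample_profiles(pair: SurfacePair, vol: VolumeImage) -> ProfileSamples:
    """Sample a volume along each inner->outer linked-vertex segment.

    For vertex ``i`` the sample points are ``inner_i + t (outer_i - inner_i)``
    with ``t`` in {0, .2, .4, .6, .8, 1}; each value is trilinear-interpolated
    from the volume in world space.  A sample point falling outside the
    volume raises, naming the first offending vertex.
    """
    inner, outer = pair.inner.vertices, pair.outer.vertices
    # (n, 6, 3) sample points
    pts = inner[:, None, :] + PROFILE_FRACTIONS[None, :, None] * (
        outer - inner
    )[:, None, :]
    flat = pts.reshape(-1, 3)
    try:
        vals = trilinear_sample(vol, flat)
    except ValueError as err:
        # re-raise with the vertex index instead of the flattened point index
        msg = str(err)
        if "sample point" in msg:
            k = int(msg.split("sample point ")[1].split(" ")[0])
            raise ValueError(
                f"profile sample out of volume bounds at vertex "
                f"{k // len(PROFILE_FRACTIONS)} "
                f"(sample {k % len(PROFILE_FRACTIONS)})"
            ) from err
        raise
    return ProfileSamples(vals.reshape(len(inner), len(PROFILE_FRACTIONS)))


def surface_map(profiles: ProfileSamples, units: str = "dimensionless"
                ) -> VertexScalarMap:
    """Collapse profiles to a surface map: the mean of the 6 samples.

    Applied to the DVR volume this yields sFDG; applied to the smoothed wPVE
    volume it yields swPVE.  The mean (not the maximum of earlier work) is
    used so that uptake and tissue maps are collapsed by the same linear
    functional and their ratio cancels the partial-volume response.
    """
    return VertexScalarMap(profiles.values.mean(axis=1), units=units)


def partial_volume_correct(
    sfdg: VertexScalarMap,
    swpve: VertexScalarMap,
    mesh,
    fwhm: float = 20.0,
    pve_floor: float = DEFAULT_PVE_FLOOR,
    smooth_target: str = "both",
) -> VertexScalarMap:
    """Partial-volume-corrected surface uptake: csFDG = sFDG / swPVE.

    Both maps are diffusion-smoothed on the mesh with the given FWHM before
    the division (``smooth_target="both"``, the default): dividing a smoothed
    numerator by an unsmoothed denominator would reintroduce the
    high-frequency partial-volume pattern the correction is meant to remove.
    ``smooth_target="numerator"`` preserves the alternative reading.

    Vertices whose smoothed swPVE falls below ``pve_floor`` are flagged NaN
    (excluded from downstream regional means) rather than divided.  If more
    than 10% of vertices fall below the floor the tissue model is considered
    broken and an error is raised.
    """
    if len(sfdg) != len(swpve):
        raise ValueError("sFDG and swPVE must live on the same mesh")
    if smooth_target not in ("both", "numerator"):
        raise ValueError(f"unknown smooth_target {smooth_target!r}")
    num = diffusion_smooth(mesh, sfdg, fwhm).values
    if smooth_target == "both":
        den = diffusion_smooth(mesh, swpve, fwhm).values
    else:
        den = swpve.values
    low = den < pve_floor
    frac_low = low.mean()
    if frac_low > 0.10:
        raise ValueError(
            f"{frac_low:.0%} of vertices have smoothed swPVE below "
            f"{pve_floor}; tissue model looks broken"
        )
    if low.any():
        logger.warning("%d vertices below the swPVE floor flagged invalid",
                       int(low.sum()))
    out = np.full_like(num, np.nan)
    out[~low] = num[~low] / den[~low]
    return VertexScalarMap(out, units="ratio", allow_missing=True)


def build_surface_features(
    pair: SurfacePair,
    labels: SurfaceLabelMap,
    dvr: VolumeImage,
    tissues: TissueFractions,
    pet_fwhm: float = 6.0,
    surface_fwhm: float = 20.0,
    pve_floor: float = DEFAULT_PVE_FLOOR,
    smooth_target: str = "both",
    cerebellum=None,
    return_maps: bool = False,
):
    """Per-region cortical thickness and csFDG from co-registered inputs.

    Orchestrates the full surface stage: wPVE from tissue fractions, 6 mm
    Gaussian smoothing to PET resolution, 6-point profile sampling of both
    the (optionally cerebellum-normalized) PET volume and the smoothed wPVE,
    profile means (sFDG, swPVE), 20 mm surface diffusion smoothing and
    division (csFDG), and regional means over the label map; cortical
    thickness regional means come from the t-link distances.

    Returns ``(thickness_means, csfdg_means)`` — two region-name -> value
    dicts over the same key set — or additionally the per-vertex maps when
    ``return_maps`` is set.
    """
    if cerebellum is not None:
        dvr = dvr_normalize(dvr, cerebellum)
    wpve = weighted_pve(tissues)
    wpve_s = gaussian_smooth(wpve, pet_fwhm)  # match PET resolution
    sfdg = surface_map(sample_profiles(pair, dvr), units="DVR")
    swpve = surface_map(sample_profiles(pair, wpve_s), units="ratio")
    mid = pair.mid_mesh
    csfdg = partial_volume_correct(
        sfdg, swpve, mid, fwhm=surface_fwhm, pve_floor=pve_floor,
        smooth_target=smooth_target,
    )
    thickness = link_thickness(pair)
    th_means = regional_mean(thickness, labels)
    up_means = regional_mean(csfdg, labels)
    if set(th_means) != set(up_means):
        missing = set(th_means) ^ set(up_means)
        raise ValueError(
            f"thickness and uptake regional key sets differ: {sorted(missing)}"
        )
    if return_maps:
        maps = {
            "thickness": thickness,
            "sFDG": sfdg,
            "swPVE": swpve,
            "csFDG": csfdg,
        }
        return th_means, up_means, maps
    return th_means, up_means
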