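"""Synthetic imaging subjects and feature cohorts with known ground truth.

The imaging phantom is a spherical-shell cortex: the inner (WM/GM) surface
is a sphere of fixed radius and the outer (GM/CSF) surface sits one cortical
thickness further out, with 39 cortical regions defined as the spherical
Voronoi cells of evenly spread seed directions.  Tissue fractions are
computed by supersampled occupancy, PET activity is the GM + WM/4 weighted
uptake convolved with the scanner point-spread Gaussian plus noise, and a
separate cerebellar sphere (uptake 1) and hippocampal ellipsoid provide the
reference region and the subcortical structure.  A spherical shell exercises
profiles, partial-volume effects and smoothing exactly like a folded cortex
would, while giving closed-form shell volumes as oracles.

The cohort generator draws per-subject regional feature vectors from group
multivariate Gaussians with configurable mean shifts (in SD units) and an
exchangeable inter-feature correlation, emulating the subjects x features
table the classifier consumes.  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .features import CORTICAL_REGIONS, PREDEFINED_REGIONS, feature_name
from .geometry import SurfaceLabelMap, SurfacePair, TriangleMesh
from .volume import BinaryMask, TissueFractions, VolumeImage

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomTruth",
    "PhantomSubject",
    "generate_phantom",
    "generate_cohort",
    "region_seed_directions",
]

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


def region_seed_directions(n: int) -> np.ndarray:
    """``n`` roughly evenly spread unit vectors (Fibonacci sphere)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = _GOLDEN * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class PhantomSpec:
    """Geometry, uptake and acquisition parameters of a synthetic subject.

    Thickness and uptake may be a single value (uniform cortex) or a
    per-region mapping; regions not named fall back to the uniform value.
    Uptake is in DVR units (cerebellum = 1); the default GM uptake of 1.2
    and thickness of 3 mm are typical cortical values.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    inner_radius: float = 20.0
    thickness: float | dict[str, float] = 3.0
    uptake: float | dict[str, float] = 1.2
    wm_uptake_fraction: float = 0.25
    psf_fwhm: float = 6.0
    noise_sd: float = 0.01
    subdivisions: int = 4
    supersample: int = 3
    regions: tuple[str, ...] = CORTICAL_REGIONS
    hippocampus_uptake: float = 1.2
    seed: int = 0

    # fixed internal geometry (mm, world coordinates)
    cortex_center: tuple[float, float, float] = (0.0, 0.0, 14.0)
    cerebellum_center: tuple[float, float, float] = (0.0, 0.0, -34.0)
    cerebellum_radius: float = 13.0
    cerebellum_mask_erosion: float = 7.0
    hippocampus_axes: tuple[float, float, float] = (8.0, 5.0, 5.0)
    icv_radius: float = 50.0

    def thickness_of(self) -> np.ndarray:
        return _per_region(self.thickness, self.regions, "thickness")

    def uptake_of(self) -> np.ndarray:
        return _per_region(self.uptake, self.regions, "uptake")

    def validate(self) -> None:
        th = self.thickness_of()
        if (th <= 0).any():
            raise ValueError("cortical thickness must be positive")
        extent = np.array(self.grid_shape) * self.voxel_size / 2.0
        outer = self.inner_radius + th.max()
        margin = 2.0 * self.psf_fwhm
        top = abs(self.cortex_center[2]) + outer
        bottom = abs(self.cerebellum_center[2]) + self.cerebellum_radius
        if top + margin > extent.min() or bottom + margin > extent.min():
            raise ValueError(
                "phantom geometry overflows the grid: structures need a "
                f"{margin:.0f} mm margin inside a +/-{extent.min():.0f} mm grid"
            )


def _per_region(value, regions, what) -> np.ndarray:
    if isinstance(value, dict):
        unknown = set(value) - set(regions) - {"default"}
        if unknown:
            raise ValueError(f"unknown regions in {what}: {sorted(unknown)}")
        default = value.get("default")
        out = []
        for r in regions:
            if r in value:
                out.append(value[r])
            elif default is not None:
                out.append(default)
            else:
                raise ValueError(f"{what} missing for region {r!r} "
                                 "(provide a 'default' entry)")
        return np.asarray(out, dtype=float)
    return np.full(len(regions), float(value))


@dataclass
class PhantomTruth:
    """Ground truth of a synthetic subject or cohort — the acceptance oracle."""

    region_uptake: dict[str, float] = field(default_factory=dict)
    region_thickness: dict[str, float] = field(default_factory=dict)
    hippocampus_uptake: float | None = None
    hippocampus_volume_mm3: float | None = None
    icv_volume_mm3: float | None = None
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class PhantomSubject:
    """All co-registered pieces of one synthetic imaging subject."""

    pair: SurfacePair
    labels: SurfaceLabelMap
    tissues: TissueFractions
    pet: VolumeImage
    cerebellum: BinaryMask
    hippocampus: BinaryMask
    icv: BinaryMask
    truth: PhantomTruth
    #: native-space region labels: cortical-band voxels carry the region id
    #: of their radial direction (1..n_regions), hippocampal voxels carry
    #: n_regions + 1; used by the volume-based feature route.
    native_labels: VolumeImage = None
    native_lexicon: dict[int, str] = field(default_factory=dict)


def _affine(spec: PhantomSpec) -> np.ndarray:
    """Voxel->world affine centering the grid on the world origin."""
    aff = np.eye(4)
    aff[:3, :3] *= spec.voxel_size
    aff[:3, 3] = -(np.asarray(spec.grid_shape) - 1) * spec.voxel_size / 2.0
    return aff


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Build one synthetic subject: surfaces, labels, tissues, PET, masks.

    Occupancy fractions come from a ``supersample^3`` subgrid per voxel;
    noise-free activity is ``u_region * GM + wm_fraction * u_region * WM``
    (CSF takes up nothing), convolved with the PSF Gaussian, plus additive
    Gaussian noise.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_regions = len(spec.regions)
    seeds = region_seed_directions(n_regions)
    th = spec.thickness_of()
    up = spec.uptake_of()
    aff = _affine(spec)
    nx, ny, nz = spec.grid_shape
    s = spec.supersample

    cortex_c = np.asarray(spec.cortex_center)
    cereb_c = np.asarray(spec.cerebellum_center)
    hip_ax = np.asarray(spec.hippocampus_axes)

    # world coordinates of supersample points along each axis
    offs = (np.arange(s) + 0.5) / s - 0.5  # voxel-relative offsets
    ax_world = [
        (np.arange(n)[:, None] + offs[None, :]) * spec.voxel_size
        + aff[d, 3]
        for d, n in enumerate((nx, ny, nz))
    ]
    xs = ax_world[0].ravel()  # (nx*s,)
    ys = ax_world[1].ravel()
    zs = ax_world[2].ravel()

    gm = np.zeros(spec.grid_shape)
    wm = np.zeros(spec.grid_shape)
    activity = np.zeros(spec.grid_shape)

    # process in z-slabs to bound memory
    slab = max(1, 2 ** 19 // (len(xs) * len(ys) * s))
    for z0 in range(0, nz, slab):
        z1 = min(z0 + slab, nz)
        Z = zs[z0 * s: z1 * s]
        X, Y, Zw = np.meshgrid(xs, ys, Z, indexing="ij")
        pts = np.stack([X, Y, Zw], axis=-1).reshape(-1, 3)

        d_cortex = pts - cortex_c
        r = np.linalg.norm(d_cortex, axis=1)
        safe_r = np.maximum(r, 1e-12)
        dirs = d_cortex / safe_r[:, None]
        rid = np.argmax(dirs @ seeds.T, axis=1)

        outer_r = spec.inner_radius + th[rid]
        in_wm = r < spec.inner_radius
        in_gm = (~in_wm) & (r < outer_r)
        in_cereb = np.linalg.norm(pts - cereb_c, axis=1) < spec.cerebellum_radius
        in_hip = (((pts - cortex_c) / hip_ax) ** 2).sum(axis=1) < 1.0

        sub_gm = np.zeros(len(pts))
        sub_wm = np.zeros(len(pts))
        sub_act = np.zeros(len(pts))
        # hippocampus overrides WM: a GM structure with its own uptake
        hip = in_hip
        wm_only = in_wm & ~hip
        sub_gm[hip] = 1.0
        sub_act[hip] = spec.hippocampus_uptake
        sub_wm[wm_only] = 1.0
        sub_act[wm_only] = spec.wm_uptake_fraction * up[rid[wm_only]]
        sub_gm[in_gm] = 1.0
        sub_act[in_gm] = up[rid[in_gm]]
        cereb = in_cereb & ~(in_wm | in_gm | hip)
        sub_gm[cereb] = 1.0
        sub_act[cereb] = 1.0  # reference-region uptake defines DVR = 1

        shape6 = (nx, s, ny, s, z1 - z0, s)
        gm[:, :, z0:z1] += sub_gm.reshape(shape6).mean(axis=(1, 3, 5))
        wm[:, :, z0:z1] += sub_wm.reshape(shape6).mean(axis=(1, 3, 5))
        activity[:, :, z0:z1] += sub_act.reshape(shape6).mean(axis=(1, 3, 5))

    csf = np.clip(1.0 - gm - wm, 0.0, 1.0)
    sigma_vox = spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.voxel_size
    if spec.psf_fwhm > 0:
        pet_grid = ndimage.gaussian_filter(activity, sigma_vox, mode="constant")
    else:
        pet_grid = activity.copy()
    if spec.noise_sd > 0:
        pet_grid = pet_grid + rng.normal(0.0, spec.noise_sd, size=pet_grid.shape)

    tissues = TissueFractions(
        gm=VolumeImage(gm, aff, "fraction"),
        wm=VolumeImage(wm, aff, "fraction"),
        csf=VolumeImage(csf, aff, "fraction"),
    )
    pet = VolumeImage(pet_grid, aff, "DVR")

    # masks at voxel centers
    ci = np.indices(spec.grid_shape).reshape(3, -1).T
    centers = ci * spec.voxel_size + aff[:3, 3]
    r_cereb = np.linalg.norm(centers - cereb_c, axis=1)
    cereb_mask = (
        r_cereb < spec.cerebellum_radius - spec.cerebellum_mask_erosion
    ).reshape(spec.grid_shape)
    hip_mask = ((((centers - cortex_c) / hip_ax) ** 2).sum(axis=1) < 1.0
                ).reshape(spec.grid_shape)
    icv_c = 0.5 * (cortex_c + cereb_c)
    icv_mask = (np.linalg.norm(centers - icv_c, axis=1) < spec.icv_radius
                ).reshape(spec.grid_shape)

    # native-space labels: a generous radial band around the cortical shell
    # (one voxel beyond each boundary, so partial GM voxels are captured)
    dc = centers - cortex_c
    rc = np.linalg.norm(dc, axis=1)
    dirs_c = dc / np.maximum(rc, 1e-12)[:, None]
    rid_c = np.argmax(dirs_c @ seeds.T, axis=1)
    band = (rc > spec.inner_radius - spec.voxel_size) & (
        rc < spec.inner_radius + th[rid_c] + spec.voxel_size)
    native = np.where(band, rid_c + 1, 0)
    native[hip_mask.ravel()] = n_regions + 1
    native_labels = VolumeImage(native.reshape(spec.grid_shape).astype(float),
                                aff, "label")
    native_lexicon = {i + 1: name for i, name in enumerate(spec.regions)}
    native_lexicon[n_regions + 1] = "hippocampus"

    # linked surfaces: concentric subdivided icosahedra with per-region
    # radial offsets equal to the specified thickness
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    vdirs = np.asarray(ico.vertices, dtype=float)
    vdirs /= np.linalg.norm(vdirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)
    vertex_rid = np.argmax(vdirs @ seeds.T, axis=1)
    inner_v = cortex_c + spec.inner_radius * vdirs
    outer_v = cortex_c + (spec.inner_radius + th[vertex_rid])[:, None] * vdirs
    pair = SurfacePair(TriangleMesh(inner_v, faces), TriangleMesh(outer_v, faces))
    lexicon = {i + 1: name for i, name in enumerate(spec.regions)}
    labels = SurfaceLabelMap(vertex_rid + 1, lexicon)

    vox_vol = spec.voxel_size ** 3
    truth = PhantomTruth(
        region_uptake={name: float(up[i]) for i, name in enumerate(spec.regions)},
        region_thickness={name: float(th[i]) for i, name in enumerate(spec.regions)},
        hippocampus_uptake=spec.hippocampus_uptake,
        hippocampus_volume_mm3=float(hip_mask.sum() * vox_vol),
        icv_volume_mm3=float(icv_mask.sum() * vox_vol),
    )
    return PhantomSubject(
        pair=pair,
        labels=labels,
        tissues=tissues,
        pet=pet,
        cerebellum=BinaryMask(cereb_mask.astype(int), aff),
        hippocampus=BinaryMask(hip_mask.astype(int), aff),
        icv=BinaryMask(icv_mask.astype(int), aff),
        truth=truth,
        native_labels=native_labels,
        native_lexicon=native_lexicon,
    )


def _default_smf_features() -> tuple[str, ...]:
    return tuple(
        feature_name(r, m) for m in ("MRI", "FDG") for r in PREDEFINED_REGIONS
    )


@dataclass
class CohortSpec:
    """Synthetic feature-cohort specification.

    Group sizes default to the study cohort (85 NC / 163 MCI / 71 AD).
    ``shifts`` gives each group's per-feature mean shift in SD units
    (baseline NC at 0); by default AD is shifted -1.5 SD on the 12 MRI
    features and MCI by half of that, emulating atrophy/hypometabolism
    effects that are negative in patients.  Features share an exchangeable
    correlation ``rho``; per-feature baselines and SDs give the values
    realistic units (mm for thickness-like, DVR for uptake-like columns)
    without affecting the classifier, which is affine-invariant per feature.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 85, "MCI": 163, "AD": 71}
    )
    features: tuple[str, ...] = field(default_factory=_default_smf_features)
    shifts: dict[str, dict[str, float]] | None = None
    rho: float = 0.2
    baselines: dict[str, float] | None = None
    sds: dict[str, float] | None = None
    seed: int = 0

    def shift_matrix(self) -> dict[str, np.ndarray]:
        d = len(self.features)
        if self.shifts is not None:
            out = {}
            for g in self.group_sizes:
                per = self.shifts.get(g, {})
                out[g] = np.array([per.get(f, 0.0) for f in self.features])
            return out
        shifted = [f for f in self.features if "[MRI]" in f][: d // 2]
        base = np.array([-1.5 if f in shifted else 0.0 for f in self.features])
        return {
            g: base * {"NC": 0.0, "MCI": 0.5, "AD": 1.0}.get(g, 1.0)
            for g in self.group_sizes
        }

    def covariance(self) -> np.ndarray:
        d = len(self.features)
        cov = np.full((d, d), self.rho)
        np.fill_diagonal(cov, 1.0)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(f"correlation rho={self.rho} is not positive definite")
        return cov


def generate_cohort(spec: CohortSpec):
    """Draw a labelled feature table with controlled group effects.

    Returns ``(FeatureTable, PhantomTruth)`` where the truth records each
    group's per-feature effect size in SD units.  Deterministic per seed.
    """
    from .features import MODALITIES, FeatureTable  # local to avoid cycle
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    shifts = spec.shift_matrix()
    cov = spec.covariance()
    L = np.linalg.cholesky(cov)
    d = len(spec.features)

    base = np.array([
        (spec.baselines or {}).get(
            f, 2.5 if "[MRI]" in f else 1.2
        ) for f in spec.features
    ])
    sd = np.array([
        (spec.sds or {}).get(f, 0.25 if "[MRI]" in f else 0.12)
        for f in spec.features
    ])

    rows, labs, ids = [], [], []
    for g, n in spec.group_sizes.items():
        if n < 0:
            raise ValueError("group sizes must be non-negative")
        z = rng.standard_normal((n, d)) @ L.T + shifts[g]
        rows.append(base + sd * z)
        labs += [g] * n
        ids += [f"{g}{i:03d}" for i in range(n)]
    data = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, d)),
                        index=pd.Index(ids, name="subject"),
                        columns=list(spec.features))
    labels = pd.Series(labs, index=data.index, name="diagnosis")
    modality = {}
    for f in spec.features:
        tag = f.rsplit("[", 1)[-1].rstrip("]") if "[" in f else "MRI"
        modality[f] = tag if tag in MODALITIES else "MRI"
    table = FeatureTable(data, labels, modality)
    truth = PhantomTruth(group_effects={
        g: dict(zip(spec.features, shifts[g])) for g in spec.group_sizes
    })
    return table, truth
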