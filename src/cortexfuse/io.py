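"""File formats: NIfTI-1 volumes, GIFTI/OBJ surfaces, vertex maps, labels.

Volumes round-trip through nibabel with the affine honored and data scaled
per the header slope/intercept (``get_fdata``).  Surfaces are read/written
as GIFTI surface files (``.surf.gii``) or Wavefront OBJ; vertex scalar maps
as GIFTI functional files (``.func.gii``) or one-value-per-line text; label
maps as GIFTI label files or two-column text plus a JSON lexicon.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import SurfaceLabelMap, SurfacePair, TriangleMesh, VertexScalarMap
from .volume import BinaryMask, VolumeImage

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_mesh",
    "save_mesh",
    "load_surface_pair",
    "load_vertex_map",
    "save_vertex_map",
    "load_label_map",
    "save_label_map",
]


def load_volume(path, units: str = "dimensionless") -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.get_fdata(), dtype=float),
                       img.affine, units)


def save_volume(vol: VolumeImage, path) -> None:
    nib.save(nib.Nifti1Image(vol.grid.astype(np.float32), vol.affine), str(path))


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata()) > 0.5
    return BinaryMask(grid.astype(int), img.affine)


def save_mask(mask: BinaryMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine), str(path))


def _is_gifti(path) -> bool:
    return "".join(Path(path).suffixes).endswith(".gii")


def load_mesh(path) -> TriangleMesh:
    """Read a surface from GIFTI (.surf.gii) or Wavefront OBJ."""
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(str(path))
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return TriangleMesh(np.asarray(verts, float), np.asarray(faces, int))
    if path.suffix.lower() == ".obj":
        verts, faces = [], []
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
        return TriangleMesh(np.array(verts), np.array(faces, dtype=int))
    raise ValueError(f"unsupported surface format: {path.name}")


def save_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    if _is_gifti(path):
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    elif path.suffix.lower() == ".obj":
        lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported surface format: {path.name}")


def load_surface_pair(inner_path, outer_path) -> SurfacePair:
    return SurfacePair(load_mesh(inner_path), load_mesh(outer_path))


def load_vertex_map(path, units: str = "dimensionless") -> VertexScalarMap:
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(str(path))
        values = np.concatenate([d.data.ravel() for d in img.darrays])
    else:
        values = np.loadtxt(path, ndmin=1)
    return VertexScalarMap(values, units=units,
                           allow_missing=bool(np.isnan(values).any()))


def save_vertex_map(vmap: VertexScalarMap, path) -> None:
    path = Path(path)
    if _is_gifti(path):
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(vmap.values.astype(np.float32),
                                     intent="NIFTI_INTENT_NONE"),
        ])
        nib.save(img, str(path))
    else:
        np.savetxt(path, vmap.values, fmt="%.10g")


def load_label_map(path, lexicon_path=None) -> SurfaceLabelMap:
    """Read labels from GIFTI label files or two-column text + JSON lexicon."""
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(str(path))
        ids = np.concatenate([d.data.ravel() for d in img.darrays]).astype(int)
        lex = {}
        if img.labeltable is not None:
            lex = {lab.key: lab.label for lab in img.labeltable.labels
                   if lab.key != 0}
        return SurfaceLabelMap(ids, lex)
    arr = np.loadtxt(path, dtype=int, ndmin=2)
    ids = np.zeros(arr[:, 0].max() + 1, dtype=int)
    ids[arr[:, 0]] = arr[:, 1]
    if lexicon_path is None:
        raise ValueError("text label maps need a JSON lexicon file")
    lex = {int(k): v for k, v in json.loads(Path(lexicon_path).read_text()).items()}
    return SurfaceLabelMap(ids, lex)


def save_label_map(labels: SurfaceLabelMap, path, lexicon_path=None) -> None:
    path = Path(path)
    if _is_gifti(path):
        table = nib.gifti.GiftiLabelTable()
        for key, name in sorted(labels.lexicon.items()):
            lab = nib.gifti.GiftiLabel(key=key)
            lab.label = name
            table.labels.append(lab)
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(labels.region_id.astype(np.int32),
                                     intent="NIFTI_INTENT_LABEL"),
        ])
        img.labeltable = table
        nib.save(img, str(path))
    else:
        rows = np.column_stack([np.arange(len(labels)), labels.region_id])
        np.savetxt(path, rows, fmt="%d")
        if lexicon_path is not None:
            Path(lexicon_path).write_text(
                json.dumps({str(k): v for k, v in labels.lexicon.items()},
                           indent=1)
            )
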