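"""Regional feature assembly and the two feature-selection schemes.

Each subject contributes, per region, an MRI feature (mean cortical
thickness, or ICV-normalized GM volume in the volume-based variant) and an
FDG feature (partial-volume-corrected uptake).  The region lexicon holds 39
cortical surface regions plus the hippocampus (40 total); 12 of the 40 are
the predefined AD-associated regions used for the selected multimodal
feature (SMF) set:

* SMF — 12 predefined regions x 2 modalities = 24 features;
* SSF — the same 12 regions, one modality = 12 features;
* all — 40 regions x 2 modalities = 80 whole-brain features;
* volume-based — 24 features from volumetric GM volumes and masked uptake.

The data-driven alternative ranks all 40 regions by two-sample |t| between
the groups and keeps the top 12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import (
    BinaryMask,
    TissueFractions,
    VolumeImage,
    gaussian_smooth,
    masked_stats,
    weighted_pve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CORTICAL_REGIONS",
    "PREDEFINED_REGIONS",
    "RegionLexicon",
    "FeatureTable",
    "hippocampal_features",
    "volumetric_features",
    "assemble",
    "select_data_driven",
    "feature_name",
]

#: The predefined AD-associated regions (11 cortical + hippocampus).
PREDEFINED_REGIONS = (
    "angular gyrus",
    "inferior frontal gyrus",
    "inferior occipital gyrus",
    "medial occipital gyrus",
    "middle temporal gyrus",
    "parahippocampal gyrus",
    "posterior cingulate gyrus",
    "precuneus",
    "rectus gyrus",
    "superior occipital gyrus",
    "supramarginal gyrus",
    "hippocampus",
)

#: 39 cortical surface regions (the 11 predefined cortical regions first).
CORTICAL_REGIONS = tuple(r for r in PREDEFINED_REGIONS if r != "hippocampus") + (
    "superior frontal gyrus",
    "middle frontal gyrus",
    "medial frontal gyrus",
    "orbitofrontal cortex",
    "frontal pole",
    "precentral gyrus",
    "postcentral gyrus",
    "paracentral lobule",
    "supplementary motor area",
    "rolandic operculum",
    "superior parietal lobule",
    "inferior parietal lobule",
    "superior temporal gyrus",
    "inferior temporal gyrus",
    "temporal pole",
    "fusiform gyrus",
    "heschl gyrus",
    "entorhinal cortex",
    "insula",
    "anterior cingulate gyrus",
    "middle cingulate gyrus",
    "cuneus",
    "lingual gyrus",
    "calcarine cortex",
    "olfactory cortex",
    "subcallosal area",
    "planum temporale",
    "occipitotemporal gyrus",
)

MODALITIES = ("MRI", "FDG")
DIAGNOSES = ("NC", "MCI", "AD")
#: Clinical severity order used to pick the positive class of a pair.
SEVERITY = {"NC": 0, "MCI": 1, "AD": 2}


def feature_name(region: str, modality: str) -> str:
    """Canonical feature-column name, e.g. ``'precuneus [FDG]'``."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return f"{region} [{modality}]"


@dataclass(frozen=True)
class RegionLexicon:
    """The 40-region lexicon (39 cortical + hippocampus) and its predefined
    12-region subset."""

    regions: tuple[str, ...] = CORTICAL_REGIONS + ("hippocampus",)
    predefined: tuple[str, ...] = PREDEFINED_REGIONS

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")
        if not set(self.predefined) <= set(self.regions):
            raise ValueError("predefined subset must be contained in the lexicon")

    def __len__(self) -> int:
        return len(self.regions)


DEFAULT_LEXICON = RegionLexicon()


@dataclass
class FeatureTable:
    """Subjects x named regional features with diagnosis labels.

    ``data`` is a DataFrame indexed by subject id; ``labels`` a Series of
    diagnoses aligned to it; ``modality`` maps each feature column to
    "MRI" or "FDG"; ``source`` tags the extraction route ("surface" or
    "volume").
    """

    data: pd.DataFrame
    labels: pd.Series
    modality: dict[str, str] = field(default_factory=dict)
    source: str = "surface"

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels must be indexed like the feature table")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"feature table has missing values in {bad}")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        unknown = set(self.labels) - set(DIAGNOSES)
        if unknown:
            raise ValueError(f"unknown diagnoses: {sorted(unknown)}")
        missing_tags = [c for c in self.data.columns if c not in self.modality]
        if missing_tags:
            raise ValueError(f"features without a modality tag: {missing_tags}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def pair_subset(self, group_a: str, group_b: str) -> "FeatureTable":
        """Rows belonging to either diagnosis of a pairwise comparison."""
        sel = self.labels.isin([group_a, group_b])
        return FeatureTable(
            self.data[sel].copy(), self.labels[sel].copy(),
            dict(self.modality), self.source,
        )

    def matrix_and_coding(self, positive_class: str
                          ) -> tuple[np.ndarray, np.ndarray]:
        """X matrix and 0/1 y with ``positive_class`` coded 1."""
        y = (self.labels == positive_class).astype(int).to_numpy()
        return self.data.to_numpy(dtype=float), y

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "diagnosis", self.labels)
        out.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path, modality: dict[str, str] | None = None,
                 source: str = "surface") -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject")
        labels = df.pop("diagnosis")
        if modality is None:
            # infer from canonical "region [MOD]" names
            modality = {}
            for c in df.columns:
                tag = c.rsplit("[", 1)[-1].rstrip("]") if "[" in c else ""
                if tag not in MODALITIES:
                    raise ValueError(
                        f"cannot infer modality of column {c!r}; pass a mapping"
                    )
                modality[c] = tag
        return cls(df, labels, modality, source)


def hippocampal_features(
    dvr: VolumeImage,
    tissues: TissueFractions,
    hip_mask: BinaryMask,
    icv_mask: BinaryMask,
    pet_fwhm: float = 6.0,
    pve_floor: float = 0.05,
) -> tuple[float, float]:
    """ICV-normalized hippocampal volume and partial-volume-corrected uptake.

    Volume = hippocampal voxel volume / intracranial voxel volume
    (dimensionless).  Uptake = mean over the hippocampal mask of
    DVR / smoothed wPVE, with voxels whose smoothed wPVE falls below the
    floor excluded from the mean.
    """
    if hip_mask.n_voxels == 0 or icv_mask.n_voxels == 0:
        raise ValueError("hippocampus and ICV masks must be nonempty")
    vol_feature = hip_mask.n_voxels / icv_mask.n_voxels
    wpve_s = gaussian_smooth(weighted_pve(tissues), pet_fwhm)
    sel = hip_mask.grid & (wpve_s.grid >= pve_floor)
    if not sel.any():
        raise ValueError("all hippocampal voxels fall below the wPVE floor")
    corrected = dvr.grid[sel] / wpve_s.grid[sel]
    return float(vol_feature), float(corrected.mean())


def volumetric_features(
    dvr: VolumeImage,
    tissues: TissueFractions,
    native_labels: VolumeImage,
    icv_mask: BinaryMask,
    lexicon: dict[int, str],
    pet_fwhm: float = 6.0,
    pve_floor: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Per-region (ICV-normalized GM volume, mean corrected uptake).

    GM volume of a region is the sum of GM fraction x voxel volume over the
    region's voxels, divided by the ICV volume; uptake is the masked mean of
    the PVC-corrected DVR (DVR / smoothed wPVE).  Empty regions are omitted
    and logged.
    """
    if dvr.shape != native_labels.shape:
        raise ValueError("label volume does not match the DVR grid")
    vox_vol = dvr.voxel_volume()
    _, icv_volume = masked_stats(dvr, icv_mask)
    wpve_s = gaussian_smooth(weighted_pve(tissues), pet_fwhm)
    lab = native_labels.grid.astype(int)
    out: dict[str, tuple[float, float]] = {}
    for rid, name in lexicon.items():
        if rid == 0:
            continue
        sel = lab == rid
        if not sel.any():
            logger.warning("label volume has no voxels for region %r", name)
            continue
        gm_volume = float(tissues.gm.grid[sel].sum() * vox_vol) / icv_volume
        ok = sel & (wpve_s.grid >= pve_floor)
        if not ok.any():
            logger.warning("region %r entirely below the wPVE floor", name)
            continue
        uptake = float((dvr.grid[ok] / wpve_s.grid[ok]).mean())
        out[name] = (gm_volume, uptake)
    return out


def assemble(
    subject_values: dict[str, dict[str, dict[str, float]]],
    labels: dict[str, str],
    scheme: str = "SMF",
    lexicon: RegionLexicon = DEFAULT_LEXICON,
    regions: tuple[str, ...] | None = None,
    source: str = "surface",
) -> FeatureTable:
    """Assemble per-subject regional maps into a feature table.

    Parameters
    ----------
    subject_values : mapping
        ``subject -> modality ("MRI"/"FDG") -> region -> value``.
    labels : mapping
        ``subject -> diagnosis``.
    scheme : str
        "SMF" (12 predefined regions x 2 modalities = 24 columns),
        "SSF-MRI" / "SSF-FDG" (12 columns of one modality),
        "all" (40 regions x 2 = 80 columns), or "volume-based"
        (24 columns; values must come from the volumetric route).
    regions : tuple of str, optional
        Overrides the scheme's region set (used for data-driven selections).
    """
    if scheme in ("SMF", "volume-based"):
        use_regions = lexicon.predefined
        use_modalities = MODALITIES
    elif scheme == "SSF-MRI":
        use_regions = lexicon.predefined
        use_modalities = ("MRI",)
    elif scheme == "SSF-FDG":
        use_regions = lexicon.predefined
        use_modalities = ("FDG",)
    elif scheme == "all":
        use_regions = lexicon.regions
        use_modalities = MODALITIES
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if regions is not None:
        use_regions = tuple(regions)

    subjects = list(subject_values)
    columns = [feature_name(r, m) for m in use_modalities for r in use_regions]
    rows = np.empty((len(subjects), len(columns)))
    for i, s in enumerate(subjects):
        j = 0
        for m in use_modalities:
            per_region = subject_values[s].get(m, {})
            for r in use_regions:
                if r not in per_region:
                    raise ValueError(
                        f"subject {s!r} is missing region {r!r} "
                        f"({m}); cannot assemble"
                    )
                rows[i, j] = per_region[r]
                j += 1
    df = pd.DataFrame(rows, index=pd.Index(subjects, name="subject"),
                      columns=columns)
    lab = pd.Series([labels[s] for s in subjects], index=df.index,
                    name="diagnosis")
    modality = {
        feature_name(r, m): m for m in use_modalities for r in use_regions
    }
    return FeatureTable(
        df, lab, modality,
        source="volume" if scheme == "volume-based" else source,
    )


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Classic two-sample t statistic with pooled variance."""
    na, nb = len(a), len(b)
    sp2 = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if sp2 <= 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) / denom)


def select_data_driven(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    k: int = 12,
    welch: bool = False,
) -> tuple[str, ...]:
    """Data-driven region selection: top-k regions by two-sample |t|.

    A per-region score is the maximum |t| across that region's modalities
    (two-sample t between the two groups, pooled variance by default,
    Welch optionally).  Ties break deterministically by region name.
    Returns the selected region names, sorted by descending score.
    """
    sub = table.pair_subset(group_a, group_b)
    ya = sub.labels == group_a
    yb = sub.labels == group_b
    if ya.sum() < 2 or yb.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    stat = _welch_t if welch else _pooled_t

    region_scores: dict[str, float] = {}
    for col in sub.feature_names:
        region = col.rsplit(" [", 1)[0]
        a = sub.data.loc[ya, col].to_numpy(dtype=float)
        b = sub.data.loc[yb, col].to_numpy(dtype=float)
        t = abs(stat(a, b))
        region_scores[region] = max(region_scores.get(region, 0.0), t)
    if k > len(region_scores):
        raise ValueError(
            f"k={k} exceeds the {len(region_scores)} available regions"
        )
    ranked = sorted(region_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(name for name, _ in ranked[:k])
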