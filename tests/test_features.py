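"""Feature assembly, hippocampal/volumetric features, and region selection."""

import numpy as np
import pandas as pd
import pytest

import cortexfuse as cf
from cortexfuse.features import (
    CORTICAL_REGIONS,
    DEFAULT_LEXICON,
    PREDEFINED_REGIONS,
    FeatureTable,
    assemble,
    feature_name,
    hippocampal_features,
    select_data_driven,
    volumetric_features,
)
from cortexfuse.volume import BinaryMask, TissueFractions, VolumeImage, dvr_normalize

AFF = np.eye(4)


def make_table(X, labels, features=None):
    features = features or [feature_name(r, "MRI") for r in
                            PREDEFINED_REGIONS[: X.shape[1]]]
    df = pd.DataFrame(X, columns=features,
                      index=pd.Index([f"s{i}" for i in range(len(X))],
                                     name="subject"))
    lab = pd.Series(labels, index=df.index, name="diagnosis")
    modality = {f: ("FDG" if "[FDG]" in f else "MRI") for f in features}
    return FeatureTable(df, lab, modality)


class TestLexicon:
    def test_sizes(self):
        assert len(CORTICAL_REGIONS) == 39
        assert len(DEFAULT_LEXICON) == 40
        assert len(PREDEFINED_REGIONS) == 12
        assert set(PREDEFINED_REGIONS) <= set(DEFAULT_LEXICON.regions)

    def test_names_unique(self):
        assert len(set(DEFAULT_LEXICON.regions)) == 40


class TestHippocampalFeatures:
    def uniform_subject(self, u=1.4):
        shape = (24, 24, 24)
        gm = VolumeImage(np.full(shape, 0.6), AFF)
        wm = VolumeImage(np.full(shape, 0.2), AFF)
        csf = VolumeImage(np.full(shape, 0.2), AFF)
        tissues = TissueFractions(gm, wm, csf)
        wpve = 0.6 + 0.25 * 0.2  # constant, so smoothing is inert
        dvr = VolumeImage(np.full(shape, u * wpve), AFF, "DVR")
        hip = np.zeros(shape, dtype=int)
        hip[11:13, 11:13, 11:13] = 1
        icv = np.ones(shape, dtype=int)
        return dvr, tissues, BinaryMask(hip, AFF), BinaryMask(icv, AFF)

    def test_volume_is_voxel_count_ratio(self):
        dvr, tissues, hip, icv = self.uniform_subject()
        v, _ = hippocampal_features(dvr, tissues, hip, icv)
        assert v == pytest.approx(8 / 24 ** 3)

    def test_exact_correction_when_dvr_is_u_times_wpve(self):
        dvr, tissues, hip, icv = self.uniform_subject(u=1.4)
        _, u = hippocampal_features(dvr, tissues, hip, icv, pet_fwhm=0.0)
        assert u == pytest.approx(1.4, rel=1e-9)
        # with PSF smoothing the interior constant is still recovered closely
        _, u_s = hippocampal_features(dvr, tissues, hip, icv)
        assert u_s == pytest.approx(1.4, rel=0.05)

    def test_empty_mask_rejected(self):
        dvr, tissues, hip, icv = self.uniform_subject()
        empty = BinaryMask(np.zeros(dvr.shape, dtype=int), AFF)
        with pytest.raises(ValueError, match="nonempty"):
            hippocampal_features(dvr, tissues, empty, icv)

    def test_phantom_hippocampus_recovered_within_5pct(self, phantom_subject):
        subj = phantom_subject
        dvr = dvr_normalize(subj.pet, subj.cerebellum)
        v, u = hippocampal_features(dvr, subj.tissues, subj.hippocampus,
                                    subj.icv)
        assert u == pytest.approx(subj.truth.hippocampus_uptake, rel=0.05)
        assert v == pytest.approx(
            subj.truth.hippocampus_volume_mm3 / subj.truth.icv_volume_mm3)


class TestVolumetricFeatures:
    def test_region_gm_volume_accumulation(self):
        shape = (10, 10, 10)
        gm = np.zeros(shape)
        lab = np.zeros(shape)
        gm[:1], lab[:1] = 0.5, 1.0  # 100 voxels of GM fraction 0.5
        tissues = TissueFractions(VolumeImage(gm, AFF),
                                  VolumeImage(np.zeros(shape), AFF),
                                  VolumeImage(np.zeros(shape), AFF))
        dvr = VolumeImage(np.full(shape, 0.5), AFF)
        icv = BinaryMask(np.ones(shape, dtype=int), AFF)
        out = volumetric_features(dvr, tissues, VolumeImage(lab, AFF), icv,
                                  {1: "roi"})
        gm_vol_norm, _ = out["roi"]
        assert gm_vol_norm * 1000.0 == pytest.approx(50.0)  # ICV = 1000 mm^3

    def test_phantom_shell_volumes_within_10pct(self, phantom_subject):
        subj = phantom_subject
        dvr = dvr_normalize(subj.pet, subj.cerebellum)
        out = volumetric_features(dvr, subj.tissues, subj.native_labels,
                                  subj.icv, subj.native_lexicon)
        r_in = 20.0
        r_out = r_in + 3.0
        shell_per_region = 4 / 3 * np.pi * (r_out ** 3 - r_in ** 3) / 39
        icv_mm3 = subj.truth.icv_volume_mm3
        for name, (gv, uptake) in out.items():
            if name == "hippocampus":
                continue
            assert gv * icv_mm3 == pytest.approx(shell_per_region, rel=0.10)
            assert uptake == pytest.approx(1.2, rel=0.05)


class TestAssemble:
    def subject_values(self, subjects, regions=None, base=1.0):
        regions = regions or DEFAULT_LEXICON.regions
        return {
            s: {m: {r: base + i for i, r in enumerate(regions)}
                for m in ("MRI", "FDG")}
            for s in subjects
        }

    @pytest.mark.parametrize("scheme, width", [
        ("SMF", 24), ("SSF-MRI", 12), ("SSF-FDG", 12),
        ("all", 80), ("volume-based", 24),
    ])
    def test_scheme_widths(self, scheme, width):
        vals = self.subject_values(["a", "b", "c"])
        table = assemble(vals, {"a": "AD", "b": "NC", "c": "NC"}, scheme)
        assert len(table.feature_names) == width

    def test_ssf_modality_tags(self):
        vals = self.subject_values(["a", "b"])
        table = assemble(vals, {"a": "AD", "b": "NC"}, "SSF-MRI")
        assert all(m == "MRI" for m in table.modality.values())

    def test_smf_is_union_of_the_two_ssf_sets(self):
        vals = self.subject_values(["a", "b"])
        labs = {"a": "AD", "b": "NC"}
        smf = set(assemble(vals, labs, "SMF").feature_names)
        ssf = set(assemble(vals, labs, "SSF-MRI").feature_names) | set(
            assemble(vals, labs, "SSF-FDG").feature_names)
        assert smf == ssf

    def test_permutation_equivariant_in_subjects(self):
        rng = np.random.default_rng(0)
        subjects = [f"s{i}" for i in range(6)]
        vals = {
            s: {m: {r: float(rng.normal()) for r in DEFAULT_LEXICON.regions}
                for m in ("MRI", "FDG")}
            for s in subjects
        }
        labs = {s: ("AD" if i % 2 else "NC") for i, s in enumerate(subjects)}
        t1 = assemble(vals, labs, "SMF")
        shuffled = {s: vals[s] for s in reversed(subjects)}
        t2 = assemble(shuffled, labs, "SMF")
        assert t2.data.loc["s3"].equals(t1.data.loc["s3"])
        assert list(t2.data.index) == list(reversed(list(t1.data.index)))

    def test_missing_region_names_subject_and_region(self):
        vals = self.subject_values(["a", "b"])
        del vals["a"]["FDG"]["precuneus"]
        with pytest.raises(ValueError, match="'a'.*precuneus"):
            assemble(vals, {"a": "AD", "b": "NC"}, "SMF")


class TestSelectDataDriven:
    def full_table(self, rng, n=30, shift_region=None, shift=0.0):
        regions = DEFAULT_LEXICON.regions
        cols = [feature_name(r, m) for m in ("MRI", "FDG") for r in regions]
        X = rng.normal(size=(2 * n, len(cols)))
        labels = ["AD"] * n + ["NC"] * n
        if shift_region is not None:
            j = cols.index(feature_name(shift_region, "MRI"))
            X[:n, j] += shift
        return make_table(X, labels, features=cols)

    def test_true_effect_region_ranked_first(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = self.full_table(rng, n=30, shift_region="precuneus",
                                    shift=2.0)
            sel = select_data_driven(table, "AD", "NC", k=12)
            hits += sel[0] == "precuneus"
        assert hits >= 48  # standardized effect 2.0 at n=30/30 dominates

    def test_null_selection_is_exchangeable_across_regions(self):
        """With identical group distributions every region should land in
        the top 12 equally often (chi-square over 1000 seeds)."""
        from scipy.stats import chisquare

        counts = {r: 0 for r in DEFAULT_LEXICON.regions}
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            table = self.full_table(rng, n=8)
            for r in select_data_driven(table, "AD", "NC", k=12):
                counts[r] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_k_equals_all_regions_returns_all(self):
        rng = np.random.default_rng(1)
        table = self.full_table(rng, n=5)
        assert set(select_data_driven(table, "AD", "NC", k=40)) == set(
            DEFAULT_LEXICON.regions)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(2)
        table = self.full_table(rng, n=5)
        with pytest.raises(ValueError, match="exceeds"):
            select_data_driven(table, "AD", "NC", k=41)

    def test_invariant_to_affine_rescaling_of_a_feature(self):
        rng = np.random.default_rng(3)
        table = self.full_table(rng, n=10, shift_region="precuneus", shift=1.0)
        sel1 = select_data_driven(table, "AD", "NC", k=12)
        col = feature_name("angular gyrus", "FDG")
        table.data[col] = table.data[col] * 250.0 - 17.0
        sel2 = select_data_driven(table, "AD", "NC", k=12)
        assert sel1 == sel2


class TestFeatureTable:
    def test_missing_values_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_table(X, ["AD", "NC", "AD", "NC"])

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        cols = [feature_name(r, m) for m in ("MRI", "FDG")
                for r in PREDEFINED_REGIONS]
        table = make_table(rng.normal(size=(5, 24)),
                           ["AD", "NC", "AD", "NC", "MCI"], features=cols)
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data)
        assert back.modality == table.modality
        assert list(back.labels) == list(table.labels)

    def test_pair_subset_filters_rows(self):
        table = make_table(np.ones((5, 3)), ["AD", "NC", "MCI", "AD", "NC"])
        sub = table.pair_subset("AD", "NC")
        assert sub.n_subjects == 4
        assert set(sub.labels) == {"AD", "NC"}
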