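"""Synthetic dataset generator: determinism, severity structure, MOS mapping,
reference selection, and manifest round-trips."""

import os

import numpy as np
import pytest

import g2npan as g
from g2npan.dataset import (DatasetConfig, FusedImage, ImageGroup, assign_mos,
                            build_dataset, clean_fusion, generate_source_pair,
                            load_dataset, make_image_groups, select_reference,
                            synthesize_fusion_variants)


class TestSourcePair:
    def test_deterministic_and_bounded(self):
        s1, f1 = generate_source_pair(7, 128)
        s2, f2 = generate_source_pair(7, 128)
        assert np.array_equal(s1, s2) and np.array_equal(f1, f2)
        for arr in (s1, f1):
            assert arr.shape == (128, 128)
            assert arr.min() >= 0 and arr.max() <= 1

    def test_seed_sensitivity(self):
        s1, _ = generate_source_pair(7, 128)
        s2, _ = generate_source_pair(8, 128)
        assert np.abs(s1 - s2).max() > 0

    @pytest.mark.parametrize("bad", [31, 16, 48, 0])
    def test_size_precondition(self, bad):
        with pytest.raises(ValueError, match="power of two"):
            generate_source_pair(1, bad)


@pytest.fixture(scope="module")
def pair():
    return generate_source_pair(5, 32)


class TestFusionVariants:

    def test_zero_severity_is_clean_fusion(self, pair):
        (v,) = synthesize_fusion_variants(pair, 1, [0.0], variant_seed=1)
        clean = clean_fusion(*pair, color=True)
        assert np.array_equal(v.pixels, clean)
        assert not v.severity_map.any()

    def test_mse_to_clean_increases_with_severity(self, pair):
        variants = synthesize_fusion_variants(pair, 3, [0.0, 0.5, 1.0],
                                              variant_seed=2)
        clean = clean_fusion(*pair, color=True)
        mses = [float(((v.pixels - clean) ** 2).mean()) for v in variants]
        assert mses[0] < mses[1] < mses[2]

    def test_ten_variants_pairwise_distinct(self, pair):
        grid = np.linspace(0, 0.9, 10)
        variants = synthesize_fusion_variants(pair, 10, grid, variant_seed=3)
        assert len(variants) == 10
        for i in range(10):
            for j in range(i + 1, 10):
                assert np.abs(variants[i].pixels - variants[j].pixels).max() > 0

    def test_severity_grid_validation(self, pair):
        with pytest.raises(ValueError, match="non-empty"):
            synthesize_fusion_variants(pair, 0, [], variant_seed=1)
        with pytest.raises(ValueError, match="distinct"):
            synthesize_fusion_variants(pair, 2, [0.3, 0.3], variant_seed=1)
        with pytest.raises(ValueError):
            synthesize_fusion_variants(pair, 1, [1.5], variant_seed=1)


class TestMos:
    @pytest.mark.parametrize("severity,expected",
                             [(0.0, 5.0), (1.0, 1.0), (0.5, 3.0), (0.25, 4.0)])
    def test_linear_map(self, severity, expected):
        assert assign_mos(severity) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError, match=r"\[0, 1\]"):
                assign_mos(bad)

    def test_strictly_decreasing_without_noise(self):
        sevs = np.linspace(0, 1, 11)
        mos = [assign_mos(s) for s in sevs]
        assert all(a > b for a, b in zip(mos, mos[1:]))

    def test_noise_is_bounded_and_clipped(self, rng):
        vals = [assign_mos(0.5, noise_sd=0.3, rng=rng) for _ in range(50)]
        assert all(3.0 - 0.6 - 1e-9 <= v <= 3.0 + 0.6 + 1e-9 for v in vals)
        assert len(set(vals)) > 1


def _group_with_mos(mos_list):
    px = np.zeros((4, 4, 3), np.float32)
    variants = [FusedImage(pixels=px, group_id=0, variant_id=i, mos=m)
                for i, m in enumerate(mos_list)]
    return ImageGroup(group_id=0, variants=variants)


class TestReferenceSelection:
    def test_unique_maximum(self):
        assert select_reference(_group_with_mos([2, 5, 3])) == 1

    def test_tie_break_is_seeded_and_uniform(self):
        group = _group_with_mos([5, 5, 3])
        first = select_reference(group, tie_seed=42)
        assert first in (0, 1)
        assert select_reference(group, tie_seed=42) == first
        picks = {select_reference(group, tie_seed=s) for s in range(30)}
        assert picks == {0, 1}  # both maximizers reachable

    def test_single_variant(self):
        assert select_reference(_group_with_mos([2.5])) == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_reference(ImageGroup(group_id=0, variants=[]))


class TestGroupStructure:
    def test_invariants(self, tiny_groups):
        for grp in tiny_groups:
            grp.validate()
            ref_flags = [v.variant_id == grp.reference_variant_id
                         for v in grp.variants]
            assert sum(ref_flags) == 1
            best = max(v.mos for v in grp.variants)
            assert grp.reference.mos == best

    def test_mos_ranking_matches_inverse_severity(self, tiny_groups):
        for grp in tiny_groups:
            # base severity = map value outside the boosted patch = map min
            sev = [float(v.severity_map.min()) if v.severity_map.any() else 0.0
                   for v in grp.variants]
            mos = [v.mos for v in grp.variants]
            assert np.array_equal(np.argsort(sev), np.argsort(mos)[::-1])

    def test_default_shape_is_129_groups_of_10(self):
        cfg = DatasetConfig(size=32, seed=5)
        groups = make_image_groups(cfg)
        assert len(groups) == 129
        assert all(len(grp.variants) == 10 for grp in groups)
        assert sum(len(grp.variants) for grp in groups) == 1290

    def test_zero_groups_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_image_groups(DatasetConfig(n_groups=0, size=32))


@pytest.fixture(scope="module")
def built(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    cfg = DatasetConfig(n_groups=3, n_variants=4, size=32, n_grayscale=1,
                        seed=9)
    manifest = build_dataset(cfg, str(out))
    return cfg, str(out), manifest


class TestManifestRoundTrip:

    def test_round_trip_preserves_groups(self, built):
        cfg, out, manifest = built
        groups = load_dataset(manifest.path)
        orig = make_image_groups(cfg)
        assert len(groups) == len(orig)
        for got, want in zip(groups, orig):
            assert got.group_id == want.group_id
            assert got.reference_variant_id == want.reference_variant_id
            for gv, wv in zip(got.variants, want.variants):
                assert gv.mos == pytest.approx(wv.mos, abs=1e-6)
                # 8-bit PNG quantization bound
                assert np.abs(gv.pixels - wv.pixels).max() <= 1 / 255 + 1e-7

    def test_rebuild_is_byte_identical(self, built, tmp_path):
        cfg, out, _ = built
        build_dataset(cfg, str(tmp_path))
        with open(os.path.join(out, "manifest.csv"), "rb") as fh:
            a = fh.read()
        with open(tmp_path / "manifest.csv", "rb") as fh:
            b = fh.read()
        assert a == b

    def test_manifest_row_count(self, built):
        _, _, manifest = built
        assert len(manifest.rows) == 12
        assert manifest.rows.is_reference.sum() == 3

    def test_duplicate_reference_rejected(self, built, tmp_path):
        _, out, manifest = built
        df = manifest.rows.copy()
        df.loc[df.group_id == 0, "is_reference"] = 1
        bad = tmp_path / "manifest.csv"
        df.to_csv(bad, index=False)
        for sub in ("images", "severity"):
            (tmp_path / sub).symlink_to(os.path.join(out, sub))
        with pytest.raises(ValueError, match="is_reference"):
            load_dataset(str(bad))

    def test_duplicate_variant_rejected(self, built, tmp_path):
        _, out, manifest = built
        import pandas as pd
        df = manifest.rows.copy()
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        bad = tmp_path / "manifest.csv"
        df.to_csv(bad, index=False)
        for sub in ("images", "severity"):
            (tmp_path / sub).symlink_to(os.path.join(out, sub))
        with pytest.raises(ValueError, match="duplicate"):
            load_dataset(str(bad))

    def test_missing_image_named_in_error(self, built, tmp_path):
        _, out, manifest = built
        df = manifest.rows.copy()
        df.loc[0, "file_path"] = "images/nonexistent.png"
        bad = tmp_path / "manifest.csv"
        df.to_csv(bad, index=False)
        for sub in ("images", "severity"):
            (tmp_path / sub).symlink_to(os.path.join(out, sub))
        with pytest.raises(FileNotFoundError, match="nonexistent.png"):
            load_dataset(str(bad))

    def test_missing_manifest_rejected(self):
        with pytest.raises(FileNotFoundError):
            load_dataset("/no/such/manifest.csv")


class TestFusedImageInvariants:
    def test_out_of_range_pixels_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            FusedImage(pixels=np.full((4, 4, 3), 1.5), group_id=0, variant_id=0)

    def test_bad_mos_rejected(self):
        with pytest.raises(ValueError, match="mos"):
            FusedImage(pixels=np.zeros((4, 4, 3)), group_id=0, variant_id=0,
                       mos=0.5)

    def test_severity_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="severity_map"):
            FusedImage(pixels=np.zeros((4, 4, 3)), group_id=0, variant_id=0,
                       severity_map=np.zeros((8, 8)))
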