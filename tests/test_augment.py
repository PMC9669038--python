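"""Transforms, tumor-preserving crops and pool bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sarcopipe.augment import (
    AugmentConfig,
    augment_pool,
    crop_to_roi,
    load_slice_image,
    materialize,
    random_transform,
)
from sarcopipe.cohort import SliceRecord


def _identity_config(**kw):
    base = dict(
        target_per_class=10,
        flip=False,
        rotation_deg_range=(0.0, 0.0),
        zoom_range=(1.0, 1.0),
        brightness_range=(1.0, 1.0),
        crop_size=(32, 32),
        seed=0,
    )
    base.update(kw)
    return AugmentConfig(**base)


class _ScriptedRng:
    """Deterministic stand-in for a Generator: scripted uniform/random draws."""

    def __init__(self, randoms=(), uniforms=None):
        self._randoms = list(randoms)
        self._uniform_override = uniforms

    def random(self):
        return self._randoms.pop(0)

    def uniform(self, lo, hi):
        if self._uniform_override is not None:
            return self._uniform_override.pop(0)
        return lo

    def integers(self, lo, hi):
        return lo


class TestRandomTransform:
    def test_identity_configuration_is_noop(self, rng):
        image = np.arange(64 * 64, dtype=float).reshape(64, 64) % 251
        bbox = (10, 12, 30, 40)
        out, out_bbox = random_transform(image, bbox, _identity_config(), rng)
        np.testing.assert_array_equal(out, image)
        assert out_bbox == bbox

    def test_horizontal_flip_reflects_bbox(self):
        image = np.zeros((48, 64))
        bbox = (10, 5, 20, 15)
        cfg = _identity_config(flip=True)
        fake = _ScriptedRng(randoms=[0.1, 0.9])  # hflip yes, vflip no
        out, out_bbox = random_transform(image, bbox, cfg, fake)
        assert out_bbox == (64 - 20, 5, 64 - 10, 15)

    def test_vertical_flip_reflects_bbox(self):
        image = np.zeros((48, 64))
        bbox = (10, 5, 20, 15)
        cfg = _identity_config(flip=True)
        fake = _ScriptedRng(randoms=[0.9, 0.1])  # hflip no, vflip yes
        out, out_bbox = random_transform(image, bbox, cfg, fake)
        assert out_bbox == (10, 48 - 15, 20, 48 - 5)

    def test_rotation_90_matches_per_pixel_remap(self, rng):
        """At an exact 90-degree angle the affine resampling must equal a
        brute-force gather of every pixel through the inverse map."""
        n = 32
        image = np.random.default_rng(3).random((n, n)) * 255
        bbox = (8, 10, 20, 22)
        cfg = _identity_config(rotation_deg_range=(90.0, 90.0))
        out, out_bbox = random_transform(image, bbox, cfg, rng)

        theta = np.deg2rad(90.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        c = (n - 1) / 2.0
        oracle = np.empty_like(image)
        for yp in range(n):
            for xp in range(n):
                x, y = np.linalg.inv(rot) @ (np.array([xp, yp]) - c) + c
                oracle[yp, xp] = image[int(round(y)), int(round(x))]
        np.testing.assert_allclose(out, oracle, atol=1e-8)

        corners = np.array([[8, 10], [19, 10], [8, 21], [19, 21]], float)
        mapped = (rot @ (corners - c).T).T + c
        assert out_bbox == (
            int(np.floor(mapped[:, 0].min())),
            int(np.floor(mapped[:, 1].min())),
            int(np.ceil(mapped[:, 0].max())) + 1,
            int(np.ceil(mapped[:, 1].max())) + 1,
        )

    def test_brightness_scales_and_clips(self, rng):
        image = np.full((32, 32), 200.0)
        cfg = _identity_config(brightness_range=(1.5, 1.5))
        out, _ = random_transform(image, (4, 4, 8, 8), cfg, rng)
        assert out.max() == 255.0

    def test_offcanvas_transform_raises(self):
        # a zoom far out pushes the tiny corner tumor off the canvas
        image = np.zeros((64, 64))
        cfg = _identity_config(zoom_range=(30.0, 30.0))
        fake = _ScriptedRng(uniforms=[0.0, 30.0, 1.0] * 10)
        with pytest.raises(ValueError, match="off-canvas"):
            random_transform(image, (0, 0, 2, 2), cfg, fake)


class TestCropToRoi:
    def test_equal_size_is_identity(self, rng):
        image = np.random.default_rng(0).random((32, 32))
        out = crop_to_roi(image, (5, 5, 10, 10), (32, 32), rng)
        np.testing.assert_array_equal(out, image)

    def test_deterministic_crop_is_tumor_centred(self):
        image = np.random.default_rng(0).random((100, 100))
        bbox = (40, 50, 56, 66)  # centre (48, 58)
        out = crop_to_roi(image, bbox, (32, 32), deterministic=True)
        np.testing.assert_array_equal(out, image[42:74, 32:64])

    def test_deterministic_crop_clamps_at_border(self):
        image = np.random.default_rng(0).random((100, 100))
        bbox = (0, 0, 10, 10)
        out = crop_to_roi(image, bbox, (32, 32), deterministic=True)
        np.testing.assert_array_equal(out, image[0:32, 0:32])

    def test_small_image_resized_and_padded(self, rng):
        image = np.random.default_rng(0).random((20, 30))
        out = crop_to_roi(image, (2, 2, 10, 10), (64, 64), rng)
        assert out.shape == (64, 64)

    def test_wide_bbox_window_maximizes_overlap(self, rng):
        """Against a brute-force search over every feasible window."""
        image = np.random.default_rng(1).random((60, 200))
        bbox = (20, 10, 180, 40)  # wider than the crop
        crop = (32, 32)
        for deterministic in (False, True):
            out = crop_to_roi(image, bbox, crop, rng, deterministic=deterministic)
            # locate the window that was returned
            found = None
            for y0 in range(60 - 32 + 1):
                for x0 in range(200 - 32 + 1):
                    if np.array_equal(image[y0 : y0 + 32, x0 : x0 + 32], out):
                        found = (x0, y0)
                        break
                if found:
                    break
            assert found is not None
            x0, y0 = found
            bx0, by0, bx1, by1 = bbox

            def overlap(w0, extent, b0, b1):
                return max(0, min(w0 + extent, b1) - max(w0, b0))

            best_x = max(
                overlap(x, 32, bx0, bx1) for x in range(200 - 32 + 1)
            )
            assert overlap(x0, 32, bx0, bx1) == best_x
            assert x0 <= (bx0 + bx1) // 2 <= x0 + 31
            assert y0 <= (by0 + by1) // 2 <= y0 + 31

    def test_empty_image_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            crop_to_roi(np.empty((0, 0)), (0, 0, 1, 1), (8, 8), rng)


class TestAugmentPool:
    def test_exact_balanced_pool(self, small_records):
        cfg = _identity_config(target_per_class=10)
        pool = augment_pool(small_records, cfg)
        assert len(pool) == 20
        assert (pool["class"] == "sarcoma_group").sum() == 10
        assert (pool["class"] == "leiomyoma").sum() == 10

    def test_reproducible_under_seed(self, small_records):
        cfg = _identity_config(target_per_class=25)
        assert augment_pool(small_records, cfg).equals(
            augment_pool(small_records, cfg)
        )

    def test_empty_class_rejected(self, small_records):
        only_neg = [r for r in small_records if not r.is_positive]
        with pytest.raises(ValueError, match="no source slices"):
            augment_pool(only_neg, _identity_config())

    def test_draws_uniform_over_slices_not_patients(self):
        """Chi-square: a 9-slice patient draws ~9x more than a 1-slice one."""
        records = []
        for pid, n in (("SARA", 9), ("SARB", 1)):
            for k in range(n):
                records.append(
                    SliceRecord(
                        patient_id=pid,
                        study_id=f"{pid}-E1",
                        series_id=f"{pid}-E1-T2axi",
                        sequence_type="T2axi",
                        slice_index=k,
                        label="sarcoma_group",
                        image_path="x.png",
                        tumor_bbox=(1, 1, 5, 5),
                    )
                )
        records.append(
            SliceRecord(
                patient_id="LMA1",
                study_id="LMA1-E1",
                series_id="LMA1-E1-T2axi",
                sequence_type="T2axi",
                slice_index=0,
                label="leiomyoma",
                image_path="y.png",
                tumor_bbox=(1, 1, 5, 5),
            )
        )
        pool = augment_pool(
            records, _identity_config(target_per_class=10_000, seed=3)
        )
        pos = pool[pool["class"] == "sarcoma_group"]
        counts = pos["source_slice_id"].value_counts()
        assert len(counts) == 10
        assert chisquare(counts.to_numpy()).pvalue > 1e-3
        per_patient = pos["source_slice_id"].str.split("-").str[0].value_counts()
        assert 8.0 < per_patient["SARA"] / per_patient["SARB"] < 10.0

    def test_identity_pool_is_resampler(self, small_records):
        """With identity transforms every materialized image equals its
        source image (crop size = canvas)."""
        cfg = _identity_config(target_per_class=5, crop_size=(64, 64))
        pool = augment_pool(small_records, cfg)
        by_id = {r.slice_id: r for r in small_records}
        for row in pool.itertuples(index=False):
            rec = by_id[row.source_slice_id]
            out = materialize(rec, row.transform_seed, cfg)
            np.testing.assert_array_equal(out, load_slice_image(rec))
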