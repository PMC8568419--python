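"""Slice IO, HU window filtering and patient-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paraseg.dataset import (
    HUImage,
    apply_hu_filter,
    load_manifest,
    normalize_hu,
    read_mask,
    read_slice,
    split_by_patient,
    write_dicom_slice,
    write_mask_png,
    write_png16_slice,
    write_split_tsv,
    read_split_tsv,
)
from paraseg.phantoms import PhantomSpec, generate_cohort, write_cohort


class TestReadSlice:
    def test_dicom_rescale_applied(self, tmp_path):
        """Stored value x slope + intercept: 1024 x 1 - 1024 -> 0 HU."""
        import pydicom

        px = np.full((16, 16), 1024, dtype=np.int16)
        path = tmp_path / "a.dcm"
        write_dicom_slice(px, path)
        ds = pydicom.dcmread(str(path))
        ds.RescaleIntercept = -1024.0
        ds.save_as(str(path), enforce_file_format=True)
        img = read_slice(path)
        assert (img.pixels == 0).all()

    def test_dicom_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        px = rng.integers(-1000, 1500, (32, 32)).astype(np.int16)
        write_dicom_slice(px, tmp_path / "b.dcm")
        img = read_slice(tmp_path / "b.dcm")
        assert np.array_equal(img.pixels, px)

    def test_dicom_missing_rescale_tags_errors(self, tmp_path):
        import pydicom

        path = tmp_path / "c.dcm"
        write_dicom_slice(np.zeros((8, 8), np.int16), path)
        ds = pydicom.dcmread(str(path))
        del ds.RescaleSlope
        del ds.RescaleIntercept
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(ValueError, match="Rescale"):
            read_slice(path)

    def test_png_without_calibration_errors(self, tmp_path):
        px = np.full((8, 8), 50, dtype=np.int16)
        write_png16_slice(px, tmp_path / "d.png")
        with pytest.raises(ValueError, match="calibration"):
            read_slice(tmp_path / "d.png")

    def test_png_roundtrip_with_calibration(self, tmp_path):
        px = np.arange(-32, 32, dtype=np.int16).reshape(8, 8)
        slope, intercept = write_png16_slice(px, tmp_path / "e.png")
        img = read_slice(tmp_path / "e.png", slope=slope, intercept=intercept)
        assert np.array_equal(img.pixels, px)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            HUImage(np.zeros((8, 16), np.int16))

    def test_manifest_roundtrip(self, tmp_path):
        cohort = generate_cohort(2, 2, PhantomSpec(image_size=32), seed=1)
        manifest = write_cohort(cohort, tmp_path, "dicom")
        back = load_manifest(manifest)
        assert len(back) == 2
        orig = {r.patient_id: r for r in cohort}
        for rec in back:
            for k, (img, mask) in enumerate(rec.slices):
                oi, om = orig[rec.patient_id].slices[k]
                assert np.array_equal(img, oi)
                assert np.array_equal(mask, om)

    def test_mask_png_roundtrip(self, tmp_path):
        m = (np.arange(64).reshape(8, 8) % 2).astype(np.uint8)
        write_mask_png(m, tmp_path / "m.png")
        assert np.array_equal(read_mask(tmp_path / "m.png"), m)


class TestHUFilter:
    def test_inclusive_window_bounds(self):
        """Enumerated 3x3 grid: -29 and +150 retained, -30 and +151 removed."""
        img = np.array([[-30, -29, 0],
                        [150, 151, 60],
                        [-1000, 700, 149]], dtype=np.int16)
        roi = np.ones((3, 3), np.uint8)
        expected = np.zeros((3, 3), np.uint8)
        for r in range(3):
            for c in range(3):
                expected[r, c] = 1 if -29 <= img[r, c] <= 150 else 0
        gt = apply_hu_filter(img, roi)
        assert np.array_equal(gt.pixels, expected)
        assert gt.hu_window == (-29, 150)

    def test_empty_roi_gives_empty_gt(self):
        img = np.full((4, 4), 60, np.int16)
        gt = apply_hu_filter(img, np.zeros((4, 4), np.uint8))
        assert gt.pixels.sum() == 0

    def test_noiseless_phantom_gt_equals_roi(self, noiseless_phantom):
        img, roi = noiseless_phantom
        gt = apply_hu_filter(img, roi)
        assert np.array_equal(gt.pixels, roi)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="hu_lo"):
            apply_hu_filter(np.zeros((2, 2), np.int16),
                            np.zeros((2, 2), np.uint8), 10, -10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_hu_filter(np.zeros((2, 2), np.int16),
                            np.zeros((3, 3), np.uint8))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_subset_law_and_idempotence(self, seed):
        """Filter output never exceeds the ROI; re-filtering is a no-op."""
        rng = np.random.default_rng(seed)
        img = rng.integers(-1024, 2000, (12, 12)).astype(np.int16)
        roi = rng.integers(0, 2, (12, 12)).astype(np.uint8)
        gt = apply_hu_filter(img, roi)
        assert (gt.pixels <= roi).all()
        again = apply_hu_filter(img, gt.pixels)
        assert np.array_equal(again.pixels, gt.pixels)


class TestNormalize:
    def test_fixed_linear_map(self):
        img = np.array([[-1024, 0], [1024, -1024]], dtype=np.int16)
        out = normalize_hu(img)
        assert out.dtype == np.float32
        assert np.allclose(out, [[0.0, 0.5], [1.0, 0.0]])

    def test_clipping_outside_range(self):
        img = np.array([[3000, -1024]], dtype=np.int16)
        # non-square arrays are fine for plain arrays
        out = normalize_hu(np.vstack([img, img]))
        assert out.max() == 1.0 and out.min() == 0.0


class TestSplit:
    def test_study_counts_256_patients(self):
        """256 patients -> 154/51/51, i.e. 616/204/204 images at 4 slices."""
        ids = [f"P{i}" for i in range(256)]
        s = split_by_patient(ids, seed=0)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (154, 51, 51)
        assert (len(s.train_ids) * 4, len(s.val_ids) * 4, len(s.test_ids) * 4) \
            == (616, 204, 204)

    def test_exact_ratio_ten(self):
        s = split_by_patient(range(10), seed=1)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (6, 2, 2)

    def test_determinism_and_seed_sensitivity(self):
        ids = [f"P{i}" for i in range(40)]
        a = split_by_patient(ids, seed=5)
        b = split_by_patient(ids, seed=5)
        assert a == b
        c = split_by_patient(ids, seed=6)
        assert a.train_ids != c.train_ids

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            split_by_patient(range(10), ratios=(0.5, 0.3, 0.3))

    @given(n=st.integers(3, 1000), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_exhaustive_and_disjoint(self, n, seed):
        ids = {f"P{i}" for i in range(n)}
        s = split_by_patient(ids, seed=seed)
        assert s.train_ids | s.val_ids | s.test_ids == ids
        assert not (s.train_ids & s.val_ids)
        assert not (s.train_ids & s.test_ids)
        assert not (s.val_ids & s.test_ids)
        assert len(s.test_ids) >= 1

    def test_no_image_level_leakage(self, tiny_cohort):
        """No patient's slices land in two partitions."""
        s = split_by_patient({r.patient_id for r in tiny_cohort}, seed=2)
        seen = {}
        for rec in tiny_cohort:
            part = s.partition_of(rec.patient_id)
            for _ in rec.slices:
                assert seen.setdefault(rec.patient_id, part) == part

    def test_split_tsv_roundtrip(self, tmp_path):
        s = split_by_patient([f"P{i}" for i in range(12)], seed=3)
        write_split_tsv(s, tmp_path / "s.tsv")
        back = read_split_tsv(tmp_path / "s.tsv")
        assert back.train_ids == s.train_ids
        assert back.val_ids == s.val_ids
        assert back.test_ids == s.test_ids
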