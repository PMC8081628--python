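import numpy as np
import pytest

from kneemetry import point_line_distance
from kneemetry.errors import ValidationError
from kneemetry.phantom import (
    PhantomSpec,
    PhantomTruth,
    _min_joint_gap,
    degrade,
    make_phantom,
    make_suite,
)


class TestMakePhantom:
    def test_determinism_bit_identical(self):
        spec = PhantomSpec(gaussian_noise_sd=4.0, salt_pepper_frac=0.01)
        img1, t1 = make_phantom(spec, seed=7)
        img2, t2 = make_phantom(spec, seed=7)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1.to_dict() == t2.to_dict()

    def test_noise_changes_pixels_not_truth(self):
        spec = PhantomSpec(gaussian_noise_sd=5.0)
        img1, t1 = make_phantom(spec, seed=1)
        img2, t2 = make_phantom(spec, seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)
        assert t1.to_dict() == t2.to_dict()

    def test_noiseless_rendering_is_clean(self):
        """Without noise or blur the image is the piecewise silhouette:
        almost all pixels sit exactly at the three spec intensity levels and
        the rest are anti-aliased blends at the borders."""
        spec = PhantomSpec(gaussian_noise_sd=0.0, salt_pepper_frac=0.0,
                           blur_sigma=0.0)
        img, _ = make_phantom(spec, seed=1)
        levels = {spec.intensity_background, spec.intensity_soft,
                  spec.intensity_bone}
        frac_exact = np.isin(img.pixels, list(levels)).mean()
        assert frac_exact >= 0.95
        assert img.pixels.min() >= spec.intensity_background
        assert img.pixels.max() <= spec.intensity_bone

    def test_worked_example_truth_ratio(self):
        spec = PhantomSpec(ljsd_true=53.0, hlts_true=40.0)
        _, truth = make_phantom(spec, seed=1)
        assert truth.ratio == pytest.approx(1.325, abs=1e-12)

    def test_truth_self_consistency(self, default_phantom):
        """Recomputing point-line distances from the truth landmarks must
        reproduce the stated LJSD and HLTS."""
        _, _, truth = default_phantom
        lat_condyle = (truth.up_left if truth.laterality == "lateral_left"
                       else truth.up_right)
        assert point_line_distance(lat_condyle, truth.baseline) == pytest.approx(
            truth.ljsd, abs=1e-6)
        assert point_line_distance(truth.spine_lateral, truth.baseline) == (
            pytest.approx(truth.hlts, abs=1e-6))

    def test_all_landmarks_inside_joint_bbox(self, default_phantom):
        _, img, truth = default_phantom
        bb = truth.joint_bbox
        H = img.height
        for p in (truth.up_left, truth.up_right, truth.spine_lateral,
                  truth.spine_medial, truth.plateau_left, truth.plateau_right):
            x, y = p.to_raster(H)
            assert bb.x0 <= x < bb.x1 and bb.y0 <= y < bb.y1

    def test_truth_roundtrip_dict(self, default_phantom):
        _, _, truth = default_phantom
        again = PhantomTruth.from_dict(truth.to_dict())
        assert again.to_dict() == truth.to_dict()

    def test_mirrored_laterality(self):
        left = PhantomSpec(laterality="lateral_left")
        right = PhantomSpec(laterality="lateral_right")
        img_l, t_l = make_phantom(left, seed=3)
        img_r, t_r = make_phantom(right, seed=3)
        assert np.array_equal(img_r.pixels, img_l.pixels[:, ::-1])
        W = left.width
        assert t_r.spine_lateral.x == pytest.approx(
            (W - 1) - t_l.spine_lateral.x)
        assert t_r.ratio == t_l.ratio

    def test_joint_gap_guard(self, default_phantom):
        spec, _, _ = default_phantom
        assert _min_joint_gap(spec) >= 3.0


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            ({"ljsd_true": -1.0}, "must be > 0"),
            ({"ljsd_true": 5.0}, "outside [0.2, 2.5]"),
            ({"baseline_tilt": 7.0}, "tilt"),
            ({"spine_offset_lat": -200.0}, "plateau span"),
            ({"intensity_soft": 10}, "intensity"),
            ({"salt_pepper_frac": 0.2}, "salt_pepper"),
            ({"contrast_compression": 0.0}, "contrast"),
            ({"hlts_true": 300.0}, ""),
        ],
    )
    def test_invalid_specs_name_the_invariant(self, kwargs, fragment):
        spec = PhantomSpec(**kwargs)
        with pytest.raises(ValidationError) as exc:
            spec.validate()
        assert fragment.lower() in str(exc.value).lower()


class TestDegrade:
    def test_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (80, 80)).astype(np.uint8)
        out = degrade(img, salt_pepper_frac=0.0, contrast_compression=1.0,
                      stripes=False, seed=1)
        assert np.array_equal(out, img)

    def test_salt_pepper_fraction(self):
        img = np.full((200, 200), 128, dtype=np.uint8)
        out = degrade(img, salt_pepper_frac=0.01, seed=5)
        corrupted = np.isin(out, (0, 255)).mean()
        assert corrupted == pytest.approx(0.01, abs=0.004)
        assert set(np.unique(out)) <= {0, 128, 255}

    def test_contrast_compression_scales_sd(self):
        rng = np.random.default_rng(1)
        img = rng.normal(128, 40, (150, 150)).clip(0, 255).astype(np.uint8)
        out = degrade(img, contrast_compression=0.2, seed=0)
        assert out.std() == pytest.approx(0.2 * img.std(), rel=0.1)


class TestMakeSuite:
    def test_generating_mean_recovered(self):
        manifest = make_suite("control", 200, seed=42,
                              generating_mean=0.7, generating_sd=0.2)
        ratios = np.array([e["truth"]["ratio"] for e in manifest["entries"]])
        assert abs(ratios.mean() - 0.7) <= 3 * 0.2 / np.sqrt(200)

    def test_degenerate_sd_yields_exact_ratio(self):
        manifest = make_suite("control", 1, seed=1,
                              generating_mean=0.9, generating_sd=0.0)
        assert manifest["entries"][0]["truth"]["ratio"] == pytest.approx(0.9)

    def test_manifest_determinism(self, tmp_path):
        m1 = make_suite("discoid", 5, seed=11, out_dir=tmp_path / "a")
        m2 = make_suite("discoid", 5, seed=11, out_dir=tmp_path / "b")
        assert m1["entries"] == m2["entries"]
        for e in m1["entries"]:
            assert (tmp_path / "a" / e["file"]).read_bytes() == (
                tmp_path / "b" / e["file"]).read_bytes()

    def test_truncation_bounds(self):
        manifest = make_suite("discoid", 50, seed=2)
        for e in manifest["entries"]:
            assert 0.3 <= e["truth"]["ratio"] <= 1.8

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            make_suite("control", 0, seed=1)
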