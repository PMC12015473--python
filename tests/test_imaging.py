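"""Segmentation and morphometrics against closed-form shape geometry."""

import imageio.v3 as iio
import numpy as np
import pytest

from budmetrics.imaging import (
    BudMask,
    InputError,
    ScanImage,
    SegmentationConfig,
    ValidationError,
    extract_features,
    measure_bud,
    read_scan,
    segment_buds,
    validate_against_reference,
)
from budmetrics.synthetic import ShapeSpec, render_scene


def _single_shape_scan(shape_kind, length, width, angle, dpi=600.0, seed=3):
    """Render one shape centered on a canvas just big enough for it."""
    px_per_cm = dpi / 2.54
    half = int(length / 2 * px_per_cm) + 40
    shape = ShapeSpec(shape_kind, length, width, (half, half), angle)
    return render_scene([shape], dpi=dpi, canvas_px=(2 * half, 2 * half), seed=seed)


class TestReadScan:
    def test_png_roundtrip_and_scale(self, tmp_path):
        arr = np.zeros((20, 30, 3), dtype=np.uint8)
        path = tmp_path / "scan.png"
        iio.imwrite(path, arr)
        img = read_scan(path, dpi=600, accession_id="ACC0001")
        assert img.shape == (20, 30)
        assert img.scale_cm == pytest.approx(2.54 / 600)
        assert img.accession_id == "ACC0001"

    def test_grayscale_promoted_to_rgb(self, tmp_path):
        gray = np.arange(100, dtype=np.uint8).reshape(10, 10)
        path = tmp_path / "gray.png"
        iio.imwrite(path, gray)
        img = read_scan(path, dpi=600)
        assert img.pixels.shape == (10, 10, 3)
        assert (img.pixels[..., 0] == img.pixels[..., 1]).all()
        assert (img.pixels[..., 1] == img.pixels[..., 2]).all()

    def test_single_pixel_image_is_valid(self, tmp_path):
        path = tmp_path / "dot.png"
        iio.imwrite(path, np.zeros((1, 1, 3), dtype=np.uint8))
        img = read_scan(path, dpi=600)
        assert segment_buds(img) == []

    def test_bad_dpi_rejected(self, tmp_path):
        path = tmp_path / "x.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            read_scan(path, dpi=0)

    def test_unreadable_file_is_input_error(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(InputError):
            read_scan(bad, dpi=600)
        with pytest.raises(InputError):
            read_scan(tmp_path / "absent.png", dpi=600)


class TestSegmentation:
    def test_three_shapes_found(self, three_bud_scene, seg_cfg):
        scan, truth = three_bud_scene
        masks = segment_buds(scan, seg_cfg)
        assert len(masks) == len(truth)
        assert not any(m.touches_border for m in masks)

    def test_uniform_black_yields_nothing(self, seg_cfg):
        img = ScanImage(np.zeros((100, 100, 3), dtype=np.uint8), dpi=600)
        assert segment_buds(img, seg_cfg) == []

    def test_border_shape_excluded_then_kept(self):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[0:60, 50:110] = 180  # touches the top border
        scan = ScanImage(img, dpi=600)
        assert segment_buds(scan, SegmentationConfig(exclude_border=True)) == []
        masks = segment_buds(scan, SegmentationConfig(exclude_border=False))
        assert len(masks) == 1 and masks[0].touches_border

    def test_small_specks_filtered(self, seg_cfg):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[100:104, 100:104] = 200  # 4x4 px << min_area_cm2
        assert segment_buds(ScanImage(img, dpi=600), seg_cfg) == []

    def test_reading_order(self):
        img = np.zeros((300, 300, 3), dtype=np.uint8)
        img[200:240, 20:60] = 180  # lower-left
        img[30:70, 200:240] = 180  # upper-right
        masks = segment_buds(ScanImage(img, dpi=600), SegmentationConfig(min_area_cm2=0.005))
        assert [m.bbox[0] for m in masks] == sorted(m.bbox[0] for m in masks)


class TestMeasureBud:
    @pytest.mark.parametrize(
        "kind,length,width,angle",
        [
            ("stadium", 2.65, 0.35, 0.0),
            ("stadium", 2.65, 0.35, 37.0),
            ("ellipse", 2.65, 0.35, 12.0),
            ("ellipse", 3.8, 0.55, 145.0),
            ("circle", 1.0, 1.0, 0.0),
        ],
    )
    def test_closed_forms_within_two_percent(self, kind, length, width, angle, seg_cfg):
        scan, truth = _single_shape_scan(kind, length, width, angle)
        masks = segment_buds(scan, seg_cfg)
        assert len(masks) == 1
        f = measure_bud(masks[0], scan.scale_cm)
        t = truth.iloc[0]
        assert f.length_cm == pytest.approx(t.length_cm, rel=0.02)
        assert f.width_cm == pytest.approx(t.width_cm, rel=0.02)
        assert f.perimeter_cm == pytest.approx(t.perimeter_cm, rel=0.02)
        assert f.area_cm2 == pytest.approx(t.area_cm2, rel=0.02)

    def test_circle_is_isotropic(self, seg_cfg):
        scan, _ = _single_shape_scan("circle", 1.0, 1.0, 0.0)
        f = measure_bud(segment_buds(scan, seg_cfg)[0], scan.scale_cm)
        assert f.length_cm == pytest.approx(f.width_cm, rel=0.01)
        assert f.area_cm2 == pytest.approx(np.pi / 4, rel=0.02)

    def test_scale_equivariance(self, seg_cfg):
        feats = {}
        for dpi in (300.0, 600.0):
            scan, _ = _single_shape_scan("stadium", 2.0, 0.4, 25.0, dpi=dpi)
            feats[dpi] = measure_bud(segment_buds(scan, seg_cfg)[0], scan.scale_cm)
        s = 2.54 / 300.0  # coarser grid bounds the digitization error
        assert abs(feats[300.0].length_cm - feats[600.0].length_cm) <= 2 * s
        assert abs(feats[300.0].width_cm - feats[600.0].width_cm) <= 2 * s
        assert abs(feats[300.0].perimeter_cm - feats[600.0].perimeter_cm) <= 4 * s

    def test_geometric_invariants_hold(self, three_bud_scene, seg_cfg):
        scan, _ = three_bud_scene
        for m in segment_buds(scan, seg_cfg):
            f = measure_bud(m, scan.scale_cm)
            assert f.length_cm >= f.width_cm
            assert f.perimeter_cm >= 2 * np.sqrt(np.pi * f.area_cm2)
            assert f.area_cm2 <= f.length_cm * f.width_cm

    def test_single_pixel_convention(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        s = 2.54 / 600
        f = measure_bud(BudMask(1, mask, (2, 2, 3, 3), False), s)
        assert (f.length_cm, f.width_cm, f.perimeter_cm) == (s, s, 4 * s)


class TestExtractFeatures:
    def test_count_conservation(self, three_bud_scene, seg_cfg):
        scan, truth = three_bud_scene
        scan2 = ScanImage(scan.pixels, scan.dpi, accession_id="B")
        table = extract_features([scan, scan2], seg_cfg)
        assert len(table) == 2 * len(truth)
        assert list(table["bud_index"].unique()) == [1, 2, 3]

    def test_empty_batch_gives_header_only(self, seg_cfg):
        table = extract_features([], seg_cfg)
        assert table.empty
        assert list(table.columns) == [
            "accession_id", "bud_index", "length_cm", "width_cm", "perimeter_cm", "area_cm2",
        ]

    def test_composition_matches_per_mask_measurement(self, three_bud_scene, seg_cfg):
        scan, _ = three_bud_scene
        table = extract_features([scan], seg_cfg)
        direct = [measure_bud(m, scan.scale_cm) for m in segment_buds(scan, seg_cfg)]
        assert np.allclose(table["area_cm2"], [f.area_cm2 for f in direct])
        assert np.allclose(table["length_cm"], [f.length_cm for f in direct])


class TestValidation:
    def test_identity_is_perfect(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        out = validate_against_reference(t, t)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["rmse"] == pytest.approx(0.0)

    def test_pure_bias(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        out = validate_against_reference(t + 0.05, t)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["rmse"] == pytest.approx(0.05)
        assert out["intercept"] == pytest.approx(0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            validate_against_reference([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            validate_against_reference([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
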