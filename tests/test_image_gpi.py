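"""Green-pixel-intensity extraction: ratio arithmetic, sampling, corrections."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chloropix.errors import AnnotationError, GeometryError, InvalidPixelError, ValidationError
from chloropix.image_gpi import (
    GpiReading,
    PhotoAnnotation,
    PixelRGB,
    analyze_photoset,
    gpi_final,
    gpi_of_photo,
    green_pixel_intensity,
    load_image,
    sample_region_pixels,
)

channels = st.integers(min_value=0, max_value=255)


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((100, 100, 100), 1 / 3),  # achromatic
        ((0, 255, 0), 1.0),  # pure green
        ((255, 255, 255), 1 / 3),
        ((10, 10, 10), 1 / 3),  # same ratio as white: scale invariance
        ((30, 40, 30), 0.40),
    ],
)
def test_gpi_of_single_pixels(rgb, expected):
    assert green_pixel_intensity(PixelRGB(*rgb)) == pytest.approx(expected, abs=1e-12)


def test_black_pixel_rejected_with_coordinate():
    with pytest.raises(InvalidPixelError, match=r"row=4.*col=7"):
        green_pixel_intensity(PixelRGB(0, 0, 0, row=4, col=7))


def test_channel_out_of_range_rejected():
    with pytest.raises(ValidationError):
        PixelRGB(256, 0, 0)


@settings(derandomize=True, max_examples=100)
@given(r=channels, g=channels, b=channels, k=st.integers(min_value=1, max_value=5))
def test_gpi_invariant_under_channel_scaling(r, g, b, k):
    """G/(R+G+B) is unchanged by uniform scaling, exactly for integer scales."""
    if r + g + b == 0 or max(r, g, b) * k > 255:
        return
    base = green_pixel_intensity(PixelRGB(r, g, b))
    scaled = green_pixel_intensity(PixelRGB(r * k, g * k, b * k))
    assert 0 <= base <= 1
    if g > 0:
        assert base > 0
    assert scaled == pytest.approx(base, abs=1e-12)


def _uniform_image(culture=(40, 120, 40), background=(250, 250, 250)):
    img = np.empty((60, 80, 3), dtype=np.uint8)
    img[:] = background
    img[20:50, 30:50] = culture
    return img


def _annotation():
    return PhotoAnnotation(
        image_path=None,
        culture_shadow_region=[20, 30, 28, 50],
        culture_lit_region=[28, 30, 50, 50],
        background_left_region=[20, 5, 50, 15],
        background_right_region=[20, 65, 50, 75],
    )


def test_sampling_constant_image_returns_fill_colors():
    img = _uniform_image()
    culture, background = sample_region_pixels(img, _annotation(), seed=0)
    assert len(culture) == 3 and len(background) == 6
    assert all((p.r, p.g, p.b) == (40, 120, 40) for p in culture)
    assert all((p.r, p.g, p.b) == (250, 250, 250) for p in background)


def test_sampling_is_stratified_and_seed_dependent():
    rng_img = np.random.default_rng(0)
    img = np.clip(
        rng_img.normal(128, 30, (60, 80, 3)), 0, 255
    ).astype(np.uint8)
    ann = _annotation()
    coords_by_seed = {}
    for seed in (1, 2):
        culture, background = sample_region_pixels(img, ann, seed=seed)
        shadow = [p for p in culture if 20 <= p.row < 28]
        lit = [p for p in culture if 28 <= p.row < 50]
        assert len(shadow) >= 1 and len(lit) >= 1 and len(shadow) + len(lit) == 3
        left = [p for p in background if p.col < 40]
        assert len(left) == 3
        coords_by_seed[seed] = [(p.row, p.col) for p in culture + background]
    assert coords_by_seed[1] != coords_by_seed[2]
    # determinism: same seed, same pixels
    again, _ = sample_region_pixels(img, ann, seed=1)
    assert [(p.row, p.col) for p in again] == coords_by_seed[1][:3]


def test_empty_and_out_of_bounds_regions_rejected():
    img = _uniform_image()
    bad = _annotation()
    bad.culture_lit_region = [28, 30, 28, 50]  # zero rows
    with pytest.raises(AnnotationError):
        sample_region_pixels(img, bad, seed=0)
    oob = _annotation()
    oob.background_right_region = [20, 65, 50, 999]
    with pytest.raises(GeometryError):
        sample_region_pixels(img, oob, seed=0)


def test_overlapping_regions_rejected():
    ann = _annotation()
    ann.background_left_region = [20, 30, 28, 50]  # same as culture shadow
    with pytest.raises(AnnotationError, match="overlap"):
        ann.validate((60, 80))


def test_gpi_of_photo_green_culture_gray_background():
    culture = [PixelRGB(0, 255, 0)] * 3
    background = [PixelRGB(85, 85, 85)] * 6
    reading = gpi_of_photo(culture, background)
    assert reading.gpi_sample == pytest.approx(1 - 1 / 3, abs=1e-12)


def test_gpi_of_photo_blank_flask_is_zero():
    px = [PixelRGB(200, 210, 205)]
    assert gpi_of_photo(px * 3, px * 6).gpi_sample == pytest.approx(0, abs=1e-12)


def test_gpi_of_photo_matches_brute_force_mean():
    # culture GPIs 0.40, 0.42, 0.44 against an achromatic background
    culture = [PixelRGB(30, 40, 30), PixelRGB(29, 42, 29), PixelRGB(28, 44, 28)]
    background = [PixelRGB(85, 85, 85)] * 6
    reading = gpi_of_photo(culture, background)
    brute = sum(green_pixel_intensity(p) for p in culture) / 3 - sum(
        green_pixel_intensity(p) for p in background
    ) / 6
    assert reading.gpi_sample == pytest.approx(brute, abs=1e-12)
    assert reading.gpi_sample == pytest.approx(0.42 - 1 / 3, abs=1e-12)


def test_gpi_of_photo_pixel_count_contract():
    px = PixelRGB(10, 20, 30)
    with pytest.raises(ValidationError):
        gpi_of_photo([px] * 2, [px] * 6)
    with pytest.raises(ValidationError):
        gpi_of_photo([px] * 3, [px] * 5)


def _reading(gpi_sample, idx=1):
    return GpiReading(gpi_culture=0.0, gpi_background=0.0, gpi_sample=gpi_sample, photo_index=idx)


def test_gpi_final_hand_arithmetic_and_identity():
    same = [_reading(0.04, i) for i in range(1, 4)]
    assert gpi_final(same, same).gpi_final == pytest.approx(0.0, abs=1e-12)
    sample = [_reading(v, i) for i, v in enumerate((0.05, 0.06, 0.07), 1)]
    baseline = [_reading(v, i) for i, v in enumerate((0.00, 0.01, -0.01), 1)]
    assert gpi_final(sample, baseline).gpi_final == pytest.approx(0.06, abs=1e-12)
    with pytest.raises(ValidationError):
        gpi_final(sample[:2], baseline)


@settings(derandomize=True, max_examples=50)
@given(
    gpis=st.lists(st.floats(-0.1, 0.9), min_size=6, max_size=6),
    shift=st.floats(-0.2, 0.2),
)
def test_gpi_final_invariant_under_common_shift(gpis, shift):
    """Adding a constant to every photo's GPI leaves gpi_final unchanged."""
    sample = [_reading(v, i) for i, v in enumerate(gpis[:3], 1)]
    baseline = [_reading(v, i) for i, v in enumerate(gpis[3:], 1)]
    shifted = gpi_final(
        [_reading(r.gpi_sample + shift, r.photo_index) for r in sample],
        [_reading(r.gpi_sample + shift, r.photo_index) for r in baseline],
    )
    assert shifted.gpi_final == pytest.approx(
        gpi_final(sample, baseline).gpi_final, abs=1e-9
    )


def test_sampled_background_matches_renderer_ground_truth(rendered_photo):
    truth = rendered_photo.truth
    gpis = []
    for seed in range(20):
        _, background = sample_region_pixels(
            rendered_photo.image, rendered_photo.annotation, seed=seed
        )
        gpis.extend(green_pixel_intensity(p) for p in background)
    assert np.mean(gpis) == pytest.approx(truth["background_gpi"], abs=0.005)


def test_annotation_json_roundtrip(tmp_path):
    ann = _annotation()
    ann.image_path = "photo.png"
    ann.sample_id = "S01"
    path = tmp_path / "ann.json"
    ann.to_json(path)
    back = PhotoAnnotation.from_json(path)
    assert back.sample_id == "S01"
    assert back.role == "sample"
    assert list(back.culture_lit_region) == [28, 30, 50, 50]
    (tmp_path / "bad.json").write_text("{}")
    with pytest.raises(AnnotationError):
        PhotoAnnotation.from_json(tmp_path / "bad.json")


def test_load_image_composites_alpha_over_white(tmp_path):
    from PIL import Image

    rgba = np.zeros((4, 4, 4), dtype=np.uint8)  # fully transparent black
    Image.fromarray(rgba, mode="RGBA").save(tmp_path / "t.png")
    arr = load_image(tmp_path / "t.png")
    assert arr.shape == (4, 4, 3)
    assert (arr == 255).all()


def test_analyze_photoset_role_and_count_contracts(rendered_photo):
    ann_s = rendered_photo.annotation
    with pytest.raises(ValidationError):
        analyze_photoset([ann_s] * 2, [ann_s] * 3, seed=0)
    with pytest.raises(AnnotationError):
        # baseline annotations must carry the baseline role
        analyze_photoset(
            [ann_s] * 3,
            [ann_s] * 3,
            seed=0,
            sample_images=[rendered_photo.image] * 3,
            baseline_images=[rendered_photo.image] * 3,
        )
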