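import numpy as np
import pytest

from choroquant.regions import (
    MaskSet,
    RegionSpec,
    circle_mask,
    combine_exclusions,
    cvi_eligibility,
    region_masks,
    regional_mean,
)
from choroquant.volume import EnFaceMap


def _spec(nx=500, ny=500, spacing=24.0):
    return RegionSpec(
        fovea_center=((nx - 1) / 2.0, (ny - 1) / 2.0), lateral_spacing_um=spacing
    )


def test_circle_pixel_count_matches_area():
    spec = _spec()
    mask = circle_mask(spec, 5.0, (500, 500))
    radius_px = 2500.0 / 24.0
    expected = np.pi * radius_px**2
    assert abs(mask.sum() - expected) / expected <= 0.01


def test_degenerate_circle_at_most_one_pixel():
    spec = _spec(nx=21, ny=21, spacing=100.0)
    mask = circle_mask(spec, 1e-6, (21, 21))
    assert mask.sum() <= 1


def test_rim_set_identities():
    spec = _spec(nx=64, ny=64, spacing=187.5)
    masks = region_masks(spec, (64, 64))
    np.testing.assert_array_equal(
        masks["rim"], masks["circle11"] & ~masks["circle5"]
    )
    np.testing.assert_array_equal(
        masks["rim"] | masks["circle5"], masks["circle11"]
    )
    assert not (masks["rim"] & masks["circle5"]).any()


def test_circle_exceeding_grid_reports_overflow():
    spec = RegionSpec(fovea_center=(10.0, 10.0), lateral_spacing_um=24.0)
    with pytest.raises(ValueError, match="exceeds the grid"):
        circle_mask(spec, 11.0, (500, 500))


def test_combine_exclusions_none_is_region():
    ms = MaskSet(shape=(8, 8))
    region = np.zeros((8, 8), dtype=bool)
    region[2:6, 2:6] = True
    np.testing.assert_array_equal(combine_exclusions(ms, region), region)


def test_single_visit_exclusion_applies_to_all_visits():
    # an area masked at any one visit is removed from the shared frame
    ms = MaskSet(shape=(8, 8))
    excl = np.zeros((8, 8), dtype=bool)
    excl[3, 3] = True
    ms.visit_exclusions["exudation"] = excl
    region = np.ones((8, 8), dtype=bool)
    combined = combine_exclusions(ms, region)
    assert not combined[3, 3]
    assert combined.sum() == 63


def test_fully_excluded_region_yields_missing_mean():
    ms = MaskSet(shape=(8, 8))
    ms.visit_exclusions["v"] = np.ones((8, 8), dtype=bool)
    region = np.ones((8, 8), dtype=bool)
    analysis = combine_exclusions(ms, region)
    assert analysis.sum() == 0
    m = EnFaceMap(values=np.ones((8, 8)), units="um", missing=np.zeros((8, 8), bool))
    res = regional_mean(m, analysis)
    assert res.missing and np.isnan(res.value)


@pytest.mark.parametrize(
    "n_excluded,expected", [(100, True), (101, False), (0, True)]
)
def test_eligibility_exact_threshold(n_excluded, expected):
    circle5 = np.zeros((40, 40), dtype=bool)
    circle5.ravel()[:1000] = True
    excl = np.zeros((40, 40), dtype=bool)
    excl.ravel()[:n_excluded] = True
    eligible, fraction = cvi_eligibility(excl, circle5)
    assert eligible is expected
    assert fraction == pytest.approx(n_excluded / 1000.0)


def test_eligibility_monotone_in_exclusion(rng):
    circle5 = rng.uniform(size=(30, 30)) < 0.5
    excl = rng.uniform(size=(30, 30)) < 0.2
    smaller = excl & (rng.uniform(size=(30, 30)) < 0.5)
    e_big, f_big = cvi_eligibility(excl, circle5)
    e_small, f_small = cvi_eligibility(smaller, circle5)
    assert f_small <= f_big
    if e_big:
        assert e_small  # shrinking the exclusion never flips to ineligible


def test_empty_circle_rejected():
    with pytest.raises(ValueError, match="empty"):
        cvi_eligibility(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


def test_regional_mean_constant_and_mixture():
    m = EnFaceMap(values=np.full((6, 6), 42.0), units="um", missing=np.zeros((6, 6), bool))
    mask = np.zeros((6, 6), dtype=bool)
    mask[1:4, 1:4] = True
    assert regional_mean(m, mask).value == pytest.approx(42.0)

    values = np.concatenate([np.full(18, 100.0), np.full(18, 200.0)]).reshape(6, 6)
    m2 = EnFaceMap(values=values, units="um", missing=np.zeros((6, 6), bool))
    assert regional_mean(m2, np.ones((6, 6), bool)).value == pytest.approx(150.0)


def test_area_weighted_mean_identity(rng):
    # mean(circle11) equals the count-weighted mean of circle5 and rim
    spec = _spec(nx=64, ny=64, spacing=187.5)
    masks = region_masks(spec, (64, 64))
    values = rng.uniform(50, 400, size=(64, 64))
    missing = rng.uniform(size=(64, 64)) < 0.1
    m = EnFaceMap(values=values, units="um", missing=missing)
    r5 = regional_mean(m, masks["circle5"])
    rr = regional_mean(m, masks["rim"])
    r11 = regional_mean(m, masks["circle11"])
    combined = (r5.value * r5.n_pixels + rr.value * rr.n_pixels) / (
        r5.n_pixels + rr.n_pixels
    )
    assert r11.n_pixels == r5.n_pixels + rr.n_pixels
    assert r11.value == pytest.approx(combined, abs=1e-10)


def test_phantom_regional_thickness_tracks_truth(segmented_phantom):
    from choroquant.maps import thickness_map

    vol, truth, comp, surf = segmented_phantom
    spec = RegionSpec(
        fovea_center=vol.fovea_center, lateral_spacing_um=vol.lateral_spacing_um
    )
    masks = region_masks(spec, surf.shape)
    m = thickness_map(surf, vol.axial_spacing_um)
    got = regional_mean(m, masks["circle5"]).value
    expected = truth.true_thickness_map[masks["circle5"]].mean()
    assert abs(got - expected) <= 2.0
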