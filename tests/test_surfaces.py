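import itertools

import numpy as np
import pandas as pd
import pytest

from choroquant.maps import round_half_up, thickness_map
from choroquant.surfaces import (
    ChoroidSegmentationParams,
    SurfaceSet,
    _min_cost_path,
    apply_corrections,
    segment_choroid,
    segment_surface,
)
from choroquant.synthetic import PhantomParams, SmoothField2D, generate_phantom
from choroquant.volume import OCTVolume


def _step_volume(k, shape=(4, 6, 16), high=200.0, low=20.0):
    data = np.full(shape, high)
    data[:, :, k:] = low
    return OCTVolume(intensity=data)


def test_perfect_step_edge_recovered_everywhere():
    k = 9
    vol = _step_volume(k)
    surf = segment_surface(vol, "bright_to_dark", smooth_sigma_z=0, smooth_sigma_lateral=0)
    # edge-centre convention: the step into voxel k is reported at k - 0.5,
    # which rounds to slab start k
    np.testing.assert_allclose(surf, k - 0.5)
    np.testing.assert_array_equal(round_half_up(surf), k)


def test_max_step_zero_keeps_flat_surface():
    k = 7
    vol = _step_volume(k)
    surf = segment_surface(
        vol, "bright_to_dark", max_step=0, smooth_sigma_z=0, smooth_sigma_lateral=0
    )
    np.testing.assert_allclose(surf, k - 0.5)


def test_dark_to_bright_polarity():
    vol = _step_volume(5, high=10.0, low=250.0)  # rising edge
    surf = segment_surface(vol, "dark_to_bright", smooth_sigma_z=0, smooth_sigma_lateral=0)
    np.testing.assert_allclose(surf, 4.5)


@pytest.mark.parametrize("max_step", [1, 2])
def test_dp_path_matches_exhaustive_minimum(rng, max_step):
    # brute-force oracle over all feasible paths on a small grid
    nx, nz = 7, 5
    for _ in range(10):
        cost = rng.standard_normal((nx, nz))
        path = _min_cost_path(cost, np.arange(-max_step, max_step + 1))
        got = cost[np.arange(nx), path].sum()
        best = np.inf
        for cand in itertools.product(range(nz), repeat=nx):
            if any(abs(cand[i + 1] - cand[i]) > max_step for i in range(nx - 1)):
                continue
            best = min(best, cost[np.arange(nx), list(cand)].sum())
        assert got == pytest.approx(best)
        assert np.all(np.abs(np.diff(path)) <= max_step)


def test_empty_band_rejected():
    vol = _step_volume(5)
    with pytest.raises(ValueError, match="empty search band"):
        segment_surface(vol, "bright_to_dark", band=(4, 4))


def test_noiseless_phantom_bm_within_one_voxel(noiseless_phantom):
    vol, truth = noiseless_phantom
    surf = segment_choroid(vol)
    err = np.abs(surf.bm - truth.true_bm)
    assert (err <= 1.0).mean() >= 0.99


def test_noiseless_phantom_csi_within_one_voxel(noiseless_phantom):
    vol, truth = noiseless_phantom
    surf = segment_choroid(vol)
    err = np.abs(surf.csi - truth.true_csi)
    assert (err <= 1.0).mean() >= 0.95


def test_constant_thickness_phantom_recovered():
    params = PhantomParams(
        seed=6, thickness_field_um=SmoothField2D(mean=150.0, amplitude=0.0)
    )
    vol, truth = generate_phantom(params)
    surf = segment_choroid(vol)
    median_um = np.median(surf.csi - surf.bm) * vol.axial_spacing_um
    assert 145.0 <= median_um <= 155.0


def test_shadow_compensation_improves_csi_under_shadow():
    from choroquant.synthetic import ShadowArtifact
    from choroquant.attenuation import AttenuationParams

    params = PhantomParams(
        seed=8,
        shadow_artifacts=[ShadowArtifact(center_xy=(20.0, 20.0), radius_um=1200.0, factor=0.35)],
    )
    vol, truth = generate_phantom(params)
    # shadowed columns
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    inside = np.hypot(yy - 20, xx - 20) * params.lateral_spacing_um <= 1000.0

    with_comp = segment_choroid(vol)
    # degrade the compensation toward identity by using n ~ 0 (flat powers)
    weak = ChoroidSegmentationParams(attenuation=AttenuationParams(exponent_n=0.05))
    without = segment_choroid(vol, weak)
    err_with = np.abs(with_comp.csi - truth.true_csi)[inside].mean()
    err_without = np.abs(without.csi - truth.true_csi)[inside].mean()
    assert err_with <= err_without


def test_surfaceset_invariants():
    bm = np.full((3, 3), 10.0)
    with pytest.raises(ValueError, match="exceeds csi"):
        SurfaceSet(bm=bm, csi=bm - 1)
    s = SurfaceSet(bm=bm, csi=bm)  # zero thickness is legal
    assert thickness_map(s, 2.0).values.sum() == 0.0


def test_corrections_identity_and_single_point():
    bm = np.full((4, 4), 10.0)
    csi = np.full((4, 4), 30.0)
    surf = SurfaceSet(bm=bm, csi=csi)
    same = apply_corrections(surf, [])
    np.testing.assert_array_equal(same.bm, surf.bm)
    assert (same.provenance == "auto").all()

    fixed = apply_corrections(surf, [("bm", 3, 1, 15.0)])
    assert fixed.bm[3, 1] == 15.0
    assert fixed.provenance[3, 1] == "corrected"
    untouched = np.ones((4, 4), dtype=bool)
    untouched[3, 1] = False
    np.testing.assert_array_equal(fixed.bm[untouched], surf.bm[untouched])


def test_correction_violating_order_lists_offender():
    surf = SurfaceSet(bm=np.full((4, 4), 10.0), csi=np.full((4, 4), 30.0))
    with pytest.raises(ValueError, match=r"\(y=2, x=2\)"):
        apply_corrections(surf, [("csi", 2, 2, 5.0)])


def test_corrections_dataframe_input():
    surf = SurfaceSet(bm=np.full((4, 4), 10.0), csi=np.full((4, 4), 30.0))
    df = pd.DataFrame([{"surface": "csi", "y": 0, "x": 0, "z": 25.0}])
    out = apply_corrections(surf, df)
    assert out.csi[0, 0] == 25.0
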