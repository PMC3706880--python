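"""Spatial-frequency ratio curves, overlap features and TFN."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import direct_dft3, flood_fill_labels
from sock.features import (
    RATIO_CAP,
    compute_overlap_feature,
    compute_ratio_curves,
    compute_tfn,
    label_clusters,
    spectral_partition,
    spectral_radius_grid,
)
from sock.ica_io import ICADecomposition, SockInputError


def _decomposition(volumes, voxel_size=(3.0, 3.0, 3.0), tr=2.0):
    maps = np.stack(volumes, axis=-1)
    return ICADecomposition(
        unthresholded_maps=maps,
        thresholded_maps=maps,
        tr_seconds=tr,
        voxel_size_mm=voxel_size,
    )


def test_constant_volume_is_maximally_smooth():
    dec = _decomposition([np.ones((8, 8, 8))])
    curves = compute_ratio_curves(dec, n_radii=10)
    # all magnitude sits at zero frequency, inside every sphere
    assert (curves.curves[0] == RATIO_CAP).all()


def test_checkerboard_along_one_axis_has_zero_ratio():
    vol = np.ones((8, 8, 8))
    vol[1::2, :, :] = -1.0  # single mode at the spatial Nyquist frequency
    dec = _decomposition([vol])
    curves = compute_ratio_curves(dec, n_radii=10)
    assert (curves.curves[0] == 0).all()


def test_all_zero_map_warns_and_yields_zero_curve():
    dec = _decomposition([np.zeros((6, 6, 6)), np.ones((6, 6, 6))])
    with pytest.warns(UserWarning, match="identically zero"):
        curves = compute_ratio_curves(dec, n_radii=5)
    assert (curves.curves[0] == 0).all()


def test_non_finite_voxels_are_fatal():
    vol = np.ones((4, 4, 4))
    vol[0, 0, 0] = np.nan
    with pytest.raises(SockInputError, match="non-finite"):
        compute_ratio_curves(_decomposition([vol]), n_radii=5)


def test_fft_magnitudes_match_direct_dft_oracle():
    rng = np.random.default_rng(3)
    vol = rng.standard_normal((8, 8, 8))
    np.testing.assert_allclose(
        np.abs(np.fft.fftn(vol)), np.abs(direct_dft3(vol)), rtol=1e-8, atol=1e-10
    )


def test_smoothing_raises_ratio_curve_everywhere():
    """Checked against an independent direct-DFT partition of the spectrum."""
    rng = np.random.default_rng(11)
    vox = (3.0, 3.0, 3.0)
    raw = rng.standard_normal((8, 8, 8))
    smoothed = ndimage.gaussian_filter(raw, 1.5)
    radii = spectral_radius_grid(raw.shape, vox, 10)

    def oracle_curve(vol):
        freqs = np.meshgrid(
            *[np.fft.fftfreq(n, d=d) for n, d in zip(vol.shape, vox)], indexing="ij"
        )
        dist = np.sqrt(sum(f**2 for f in freqs))
        mag = np.abs(direct_dft3(vol))
        return np.array(
            [mag[dist < r].sum() / max(mag[dist >= r].sum(), 1e-30) for r in radii]
        )

    dec = _decomposition([raw, smoothed], voxel_size=vox)
    curves = compute_ratio_curves(dec, n_radii=10)
    np.testing.assert_allclose(curves.curves[0], oracle_curve(raw), rtol=1e-8)
    np.testing.assert_allclose(curves.curves[1], oracle_curve(smoothed), rtol=1e-8)
    assert (curves.curves[1] >= curves.curves[0]).all()


def test_ratio_curves_monotone_and_partition_conserved():
    rng = np.random.default_rng(5)
    vox = (3.0, 3.0, 4.5)  # anisotropic voxels
    for _ in range(10):
        vol = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), rng.uniform(0, 2))
        radii = spectral_radius_grid(vol.shape, vox, 15)
        low, high = spectral_partition(vol, vox, radii)
        total = np.abs(np.fft.fftn(vol)).sum()
        np.testing.assert_allclose(low + high, total, rtol=1e-12)
        assert (np.diff(low) >= 0).all()
        assert (np.diff(high) <= 0).all()
        dec = _decomposition([vol], voxel_size=vox)
        curve = compute_ratio_curves(dec, n_radii=15).curves[0]
        assert (np.diff(curve) >= -1e-12 * np.abs(curve[:-1])).all()


def test_ratio_curve_scale_equivariance():
    rng = np.random.default_rng(9)
    vol = rng.standard_normal((8, 8, 8))
    c1 = compute_ratio_curves(_decomposition([vol]), n_radii=8).curves
    c2 = compute_ratio_curves(_decomposition([5.0 * vol]), n_radii=8).curves
    np.testing.assert_allclose(c1, c2, rtol=1e-12)


# --- overlap features ---


def test_empty_thresholded_map_gives_zero_feature():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    feat = compute_overlap_feature(np.zeros((5, 5, 5)), mask)
    assert (feat.activity, feat.overlap_fraction, feat.n_clusters_overlapping) == (0, 0, 0)


def test_suprathreshold_equal_to_mask_is_full_overlap():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    zmap = np.where(mask, 3.1, 0.0)
    feat = compute_overlap_feature(zmap, mask)
    assert feat.activity == pytest.approx(1.0)
    assert feat.overlap_fraction == pytest.approx(1.0)
    assert feat.n_clusters_overlapping == 1


def test_partial_cluster_overlap_counts_full_cluster_volume():
    """8-voxel cluster, 2 voxels inside a 10-voxel mask: activity counts the
    whole cluster (8/10), the fraction only the overlapping voxels (2/8)."""
    zmap = np.zeros((5, 5, 5))
    zmap[1:3, 1:3, 1:3] = 4.0  # one 2x2x2 cluster
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[1, 1:3, 1] = True  # 2 voxels inside the cluster
    mask[4, 0:4, 0:2] = True  # 8 voxels elsewhere, not suprathreshold
    assert mask.sum() == 10
    assert int((zmap != 0).sum()) == 8
    feat = compute_overlap_feature(zmap, mask, connectivity=26)
    assert feat.activity == pytest.approx(0.8)
    assert feat.overlap_fraction == pytest.approx(0.25)
    assert feat.n_clusters_overlapping == 1


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_cluster_labels_match_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(13)
    volumes = [np.ones((6, 6, 6), dtype=bool)]
    single = np.zeros((6, 6, 6), dtype=bool)
    single[2, 3, 4] = True
    volumes.append(single)
    volumes += [rng.random((6, 6, 6)) < p for p in (0.1, 0.3, 0.5)]
    for active in volumes:
        got, n_got = label_clusters(active, connectivity)
        want = flood_fill_labels(active, connectivity)
        assert n_got == want.max()
        # same partition up to label renumbering
        for k in range(1, n_got + 1):
            members = want[got == k]
            assert len(np.unique(members)) <= 1
        assert ((got > 0) == (want > 0)).all()


def test_overlap_grid_mismatch_and_empty_mask_fatal():
    with pytest.raises(SockInputError, match="grid"):
        compute_overlap_feature(np.zeros((4, 4, 4)), np.ones((5, 5, 5), dtype=bool))
    with pytest.raises(SockInputError, match="empty"):
        compute_overlap_feature(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))


# --- temporal frequency noise ---


def test_tfn_bin_counting_tr2_100_bins():
    """TR = 2 s, 100 unit-power bins: spacing 0.0025 Hz, Nyquist 0.25 Hz;
    bins at or above 0.08 Hz are k = 32..100, so TFN = 69."""
    feat = compute_tfn(np.ones(100), tr_seconds=2.0, cutoff_hz=0.08)
    assert feat.nyquist_hz == pytest.approx(0.25)
    assert feat.tfn == pytest.approx(69.0)
    assert feat.total_power == pytest.approx(100.0)


def test_tfn_zero_when_power_below_cutoff():
    ps = np.zeros(100)
    ps[:10] = 5.0  # bins 1..10 -> 0.0025..0.025 Hz, all below 0.08
    assert compute_tfn(ps, tr_seconds=2.0).tfn == 0.0


def test_tfn_cutoff_to_zero_recovers_total_power():
    rng = np.random.default_rng(2)
    ps = rng.random(64)
    feat = compute_tfn(ps, tr_seconds=2.5, cutoff_hz=1e-9)
    assert feat.tfn == pytest.approx(feat.total_power) == pytest.approx(ps.sum())


def test_tfn_cutoff_at_nyquist_warns_and_is_zero():
    with pytest.warns(UserWarning, match="Nyquist"):
        feat = compute_tfn(np.ones(10), tr_seconds=2.0, cutoff_hz=0.25)
    assert feat.tfn == 0.0


def test_tfn_negative_power_is_fatal():
    with pytest.raises(SockInputError, match="negative"):
        compute_tfn(np.array([1.0, -0.1]), tr_seconds=2.0)
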