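"""Channel computation against brute-force convolution / eigensolver oracles."""

import numpy as np
import pytest
from scipy import ndimage

from emseg import channels as ch
from emseg.stack_io import VoxelStack


def _gaussian_derivative_kernel_1d(sigma, order, radius):
    """Sampled analytic Gaussian-derivative kernel, normalized so the
    order-0 kernel sums to one (independent re-derivation for the oracle)."""
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    norm = g.sum()
    if order == 0:
        return g / norm
    if order == 1:
        return (-x / sigma ** 2) * g / norm
    if order == 2:
        return (x ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * g / norm
    raise ValueError(order)


def _dense_derivative(volume, sigma, orders):
    """Dense separable correlation with explicitly sampled kernels.

    ``orders`` is (oz, oy, ox); correlation (not convolution) matches the
    filter convention of the implementation.
    """
    radius = int(4 * sigma + 0.5)
    out = volume.astype(np.float64)
    for axis, order in enumerate(orders):
        k = _gaussian_derivative_kernel_1d(sigma, order, radius)
        out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
    return out


def test_constant_volume_has_trivial_channels():
    stack = VoxelStack(np.full((12, 14, 14), 0.4))
    cs = ch.grims_channels(stack, ch.GrimsConfig([1.5]))
    s000, gradmag, lam1, lam2, lam3 = cs.channels
    interior = (slice(4, -4),) * 3
    assert np.allclose(s000[interior], 0.4, atol=1e-9)
    assert np.allclose(gradmag[interior], 0.0, atol=1e-9)
    # truncated discrete second-derivative kernels leave a ~1e-4 residual
    for lam in (lam1, lam2, lam3):
        assert np.allclose(lam[interior], 0.0, atol=1e-3)


def test_four_scales_give_twenty_channels():
    """Four scales times five rotation-invariant components."""
    stack = VoxelStack(np.zeros((6, 8, 8)))
    cs = ch.grims_channels(stack, ch.GrimsConfig([1.0, 2.0, 3.0, 4.0]))
    assert cs.n_channels == 20
    assert len(cs.names) == 20


def test_impulse_channels_match_dense_convolution():
    """Each GRIMS ingredient equals dense correlation with sampled kernels."""
    vol = np.zeros((21, 21, 21))
    vol[10, 10, 10] = 1.0
    sigma = 2.0
    stack = VoxelStack(vol)
    cs = ch.grims_channels(stack, ch.GrimsConfig([sigma]))
    s000, gradmag = cs.channels[0], cs.channels[1]

    d000 = _dense_derivative(vol, sigma, (0, 0, 0))
    assert np.abs(s000 - d000).max() < 1e-6

    # gradient magnitude from the three dense first derivatives
    gx = sigma * _dense_derivative(vol, sigma, (0, 0, 1))
    gy = sigma * _dense_derivative(vol, sigma, (0, 1, 0))
    gz = sigma * _dense_derivative(vol, sigma, (1, 0, 0))
    dense_grad = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    assert np.abs(gradmag - dense_grad).max() < 1e-6

    # eigenvalue channels from the dense Hessian
    s2 = sigma ** 2
    hxx = s2 * _dense_derivative(vol, sigma, (0, 0, 2))
    hyy = s2 * _dense_derivative(vol, sigma, (0, 2, 0))
    hzz = s2 * _dense_derivative(vol, sigma, (2, 0, 0))
    hxy = s2 * _dense_derivative(vol, sigma, (0, 1, 1))
    hxz = s2 * _dense_derivative(vol, sigma, (1, 0, 1))
    hyz = s2 * _dense_derivative(vol, sigma, (1, 1, 0))
    lam1, lam2, lam3 = ch.hessian_eigenvalues(hxx, hxy, hxz, hyy, hyz, hzz)
    for got, want in zip(cs.channels[2:5], (lam1, lam2, lam3)):
        assert np.abs(got - want).max() < 1e-6


def test_hessian_diagonal_case():
    a = np.full((3, 3, 3), 5.0)
    b = np.full((3, 3, 3), 2.0)
    c = np.full((3, 3, 3), -1.0)
    zero = np.zeros((3, 3, 3))
    lam1, lam2, lam3 = ch.hessian_eigenvalues(a, zero, zero, b, zero, c)
    assert np.allclose(lam1, 5.0) and np.allclose(lam2, 2.0) \
        and np.allclose(lam3, -1.0)


def test_hessian_trace_identity_and_dense_eigensolver(rng):
    shape = (4, 5, 6)
    hxx, hyy, hzz = (rng.normal(size=shape) for _ in range(3))
    hxy, hxz, hyz = (rng.normal(size=shape) for _ in range(3))
    lam1, lam2, lam3 = ch.hessian_eigenvalues(hxx, hxy, hxz, hyy, hyz, hzz)
    assert np.all(lam1 >= lam2 - 1e-12) and np.all(lam2 >= lam3 - 1e-12)
    np.testing.assert_allclose(lam1 + lam2 + lam3, hxx + hyy + hzz, atol=1e-9)
    # per-voxel generic eigensolver oracle
    for _ in range(50):
        i, j, k = (rng.integers(0, s) for s in shape)
        H = np.array([[hxx[i, j, k], hxy[i, j, k], hxz[i, j, k]],
                      [hxy[i, j, k], hyy[i, j, k], hyz[i, j, k]],
                      [hxz[i, j, k], hyz[i, j, k], hzz[i, j, k]]])
        w = np.sort(np.linalg.eigvals(H).real)[::-1]
        np.testing.assert_allclose(
            [lam1[i, j, k], lam2[i, j, k], lam3[i, j, k]], w, atol=1e-8)


def test_rotation_invariance_of_grims_vector(rng):
    """The 5 channel values agree between a volume and its 90-degree
    rotation at corresponding interior voxels."""
    vol = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2.0)
    cs = ch.grims_channels(VoxelStack(vol), ch.GrimsConfig([2.0]))
    rot = np.rot90(vol, k=1, axes=(1, 2))      # 90 degrees in the yx plane
    cs_rot = ch.grims_channels(VoxelStack(rot), ch.GrimsConfig([2.0]))
    interior = (slice(8, -8),) * 3
    for c in range(5):
        back = np.rot90(cs_rot.channels[c], k=-1, axes=(1, 2))
        assert np.abs(cs.channels[c] - back)[interior].max() < 1e-6


def test_scale_normalized_response_peaks_near_blob_width():
    """For a Gaussian blob of width s the normalized Laplacian response at
    the centre peaks within one grid step of the matching scale."""
    s = 4.0
    zz, yy, xx = np.mgrid[:33, :33, :33].astype(float) - 16.0
    blob = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / (2 * s ** 2))
    grid = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    responses = []
    for sigma in grid:
        cs = ch.grims_channels(VoxelStack(blob), ch.GrimsConfig([sigma]))
        lap = cs.channels[2] + cs.channels[3] + cs.channels[4]
        responses.append(abs(lap[16, 16, 16]))
    peak = grid[int(np.argmax(responses))]
    # the 3-D normalized Laplacian optimum sits at sigma = s * sqrt(2/3)
    assert abs(peak - s) <= 1.0 + 1e-9


def test_elliptical_kernel_normalization_and_shape():
    cfg = ch.EllipticalKernelConfig(5.0, 5.0, 2.0)
    kernel = ch.elliptical_kernel(cfg)
    assert abs(kernel.sum() - 1.0) < 1e-12
    # circular annulus: symmetric under 90-degree rotation
    np.testing.assert_allclose(kernel, np.rot90(kernel))
    # annulus: centre empty, ring populated
    cy, cx = (np.array(kernel.shape) - 1) // 2
    assert kernel[cy, cx] == 0.0
    assert kernel[cy, cx + 5] > 0.0


def test_elliptical_constant_slice_identity():
    stack = VoxelStack(np.full((3, 24, 24), 0.7))
    resp = ch.elliptical_channel(stack, ch.EllipticalKernelConfig(4, 4, 2))
    assert np.allclose(resp, 0.7, atol=1e-12)


def test_elliptical_ring_matches_dense_convolution(rng):
    """Response at a synthetic ring centre equals direct dense 2-D sums."""
    cfg = ch.EllipticalKernelConfig(4.0, 4.0, 2.0)
    vol = rng.random((3, 40, 40))
    yy, xx = np.mgrid[:40, :40].astype(float)
    r = np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2)
    vol[1][np.abs(r - 4.0) <= 1.0] = 1.0
    resp = ch.elliptical_channel(VoxelStack(vol), cfg)
    kernel = ch.elliptical_kernel(cfg)
    hy, hx = (np.array(kernel.shape) - 1) // 2
    patch = vol[1, 20 - hy:20 + hy + 1, 20 - hx:20 + hx + 1]
    assert abs(resp[1, 20, 20] - (patch * kernel).sum()) < 1e-6


def test_elliptical_kernel_larger_than_slice_rejected():
    stack = VoxelStack(np.zeros((2, 8, 8)))
    with pytest.raises(ValueError):
        ch.elliptical_channel(stack, ch.EllipticalKernelConfig(10, 10, 2))


def test_integral_volume_box_sums(rng):
    vol = rng.random((12, 13, 14))
    ivol = ch.integral_volume(vol)
    # all-ones box identity
    ones = ch.integral_volume(np.ones((10, 10, 10)))
    assert ch.box_sum(ones, 2, 7, 1, 6, 3, 8) == 125
    zeros = ch.integral_volume(np.zeros((6, 6, 6)))
    assert ch.box_sum(zeros, 0, 6, 0, 6, 0, 6) == 0
    # 200 random boxes vs brute force
    for _ in range(200):
        z0, y0, x0 = (rng.integers(0, s) for s in vol.shape)
        z1 = rng.integers(z0 + 1, vol.shape[0] + 1)
        y1 = rng.integers(y0 + 1, vol.shape[1] + 1)
        x1 = rng.integers(x0 + 1, vol.shape[2] + 1)
        direct = vol[z0:z1, y0:y1, x0:x1].sum()
        got = ch.box_sum(ivol, z0, z1, y0, y1, x0, x1)
        assert abs(got - direct) <= 1e-6 * max(1.0, abs(direct))


def test_feature_bank_default_size_and_determinism():
    bank = ch.sample_feature_bank(21, seed=5)
    assert len(bank) == 1200
    again = ch.sample_feature_bank(21, seed=5)
    np.testing.assert_array_equal(bank.channel, again.channel)
    np.testing.assert_array_equal(bank.offset, again.offset)
    rebuilt = ch.FeatureBank.from_dict(bank.to_dict())
    np.testing.assert_array_equal(bank.offset, rebuilt.offset)


def test_feature_bank_offsets_uniform():
    """Chi-square check that cube offsets cover the allowed range uniformly."""
    from scipy import stats

    bank = ch.sample_feature_bank(4, n_features=10_000, max_offset=5, seed=11)
    values, counts = np.unique(bank.offset.ravel(), return_counts=True)
    assert values.min() == -5 and values.max() == 5
    _, p = stats.chisquare(counts)
    assert p > 1e-3


def test_extract_features_constant_channel_and_brute_force(rng):
    vol = rng.random((10, 12, 12))
    channels = np.stack([np.ones_like(vol), vol])
    ivols = ch.integral_volumes(channels)
    bank = ch.sample_feature_bank(2, n_features=60, cube_edge=5, max_offset=3,
                                  seed=2)
    voxels = np.stack([rng.integers(0, s, 40) for s in vol.shape], axis=1)
    feats = ch.extract_features(bank, ivols, voxels)
    for i, (vz, vy, vx) in enumerate(voxels):
        for k in range(len(bank)):
            e = int(bank.edge[k])
            oz, oy, ox = bank.offset[k]
            z0, z1 = max(0, vz + oz - e // 2), min(vol.shape[0], vz + oz - e // 2 + e)
            y0, y1 = max(0, vy + oy - e // 2), min(vol.shape[1], vy + oy - e // 2 + e)
            x0, x1 = max(0, vx + ox - e // 2), min(vol.shape[2], vx + ox - e // 2 + e)
            direct = 0.0
            if z0 < z1 and y0 < y1 and x0 < x1:
                direct = channels[bank.channel[k], z0:z1, y0:y1, x0:x1].sum()
            assert abs(feats[i, k] - direct) <= 1e-5 * max(1.0, abs(direct))


def test_extract_features_interior_constant_cube():
    channels = np.ones((1, 11, 11, 11))
    ivols = ch.integral_volumes(channels)
    bank = ch.sample_feature_bank(1, n_features=10, cube_edge=5, max_offset=0,
                                  seed=0)
    feats = ch.extract_features(bank, ivols, np.array([[5, 5, 5]]))
    np.testing.assert_allclose(feats, 125.0)


def test_channels_export_h5(tmp_path, rng):
    import h5py

    from emseg.stack_io import VoxelStack

    stack = VoxelStack(rng.random((6, 10, 10)))
    cs = ch.grims_channels(stack, ch.GrimsConfig([1.0, 2.0]))
    ellip = ch.elliptical_channel(stack, ch.EllipticalKernelConfig(2, 2, 1))
    ch.write_channels_h5(tmp_path / "c.h5", cs, ellip)
    with h5py.File(tmp_path / "c.h5") as fh:
        assert set(fh.keys()) == set(cs.names) | {"ellip"}
        np.testing.assert_allclose(fh["s000_1"][()],
                                   cs.channels[0].astype(np.float32))


def test_extract_features_corner_clipping():
    """Boxes straddling the stack limits are clipped, not padded."""
    channels = np.ones((1, 11, 11, 11))
    ivols = ch.integral_volumes(channels)
    bank = ch.sample_feature_bank(1, n_features=5, cube_edge=5, max_offset=0,
                                  seed=0)
    corner = ch.extract_features(bank, ivols, np.array([[0, 0, 0]]))
    np.testing.assert_allclose(corner, 27.0)   # 3x3x3 survives the clip
    empty = ch.extract_features(bank, ivols, np.empty((0, 3), dtype=int))
    assert empty.shape == (0, 5)
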