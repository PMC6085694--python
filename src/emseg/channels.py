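"""Image channels: GRIMS rotation-invariant descriptors, the elliptical
vesicle kernel, summed-volume tables and pooled cubic box features.

The GRIMS (Gaussian Rotation Invariant MultiScale) descriptor computes, at
each scale sigma, scale-normalized Gaussian derivatives

    s_ijk = sigma^(i+j+k) * G_sigma * d^(i+j+k) / (dx^i dy^j dz^k)

and condenses them into a 5-vector per voxel: the smoothed intensity s_000,
the gradient magnitude sqrt(s_100^2 + s_010^2 + s_001^2), and the three
eigenvalues of the Hessian matrix sorted in descending order.  Rotating the
volume permutes derivative directions but leaves all five values unchanged,
which is what makes the descriptor rotation invariant.

Contextual pooling follows the integral-channel-features idea: a per-voxel
feature is the sum of one channel over a cube placed at a random offset from
the voxel, computed in O(1) from a summed-volume table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from emseg.stack_io import VoxelStack

#: channel names per GRIMS scale, in storage order
GRIMS_COMPONENTS = ("s000", "gradmag", "lam1", "lam2", "lam3")


@dataclass
class GrimsConfig:
    """Scales and anisotropy handling for the GRIMS descriptor.

    ``spacing_aware`` divides sigma by the per-axis voxel spacing so that the
    kernel has the same physical extent along anisotropic axes.
    """

    scales: Sequence[float]
    spacing_aware: bool = False

    def __post_init__(self) -> None:
        scales = [float(s) for s in self.scales]
        if not scales:
            raise ValueError("at least one scale required")
        if any(s <= 0 for s in scales):
            raise ValueError(f"scales must be positive, got {scales}")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"scales must be strictly increasing, got {scales}")
        self.scales = scales


@dataclass
class GrimsChannelSet:
    """Stacked GRIMS channels: shape ``(5 * n_scales, z, y, x)``.

    Channel ``5*j + c`` is component ``GRIMS_COMPONENTS[c]`` at scale
    ``scales[j]``.
    """

    scales: list[float]
    channels: np.ndarray

    @property
    def names(self) -> list[str]:
        return [f"{comp}_{s:g}" for s in self.scales for comp in GRIMS_COMPONENTS]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


@dataclass
class EllipticalKernelConfig:
    """Elliptic annulus ("torus-like") kernel matched to vesicle geometry.

    ``r1``/``r2`` are the semi-axes along x and y in voxels and ``w`` the
    annulus thickness; set from the average radii and rim width of a
    representative set of vesicles.
    """

    r1: float
    r2: float
    w: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("radii must be positive")
        if not (0 < self.w <= 2 * min(self.r1, self.r2)):
            raise ValueError(f"thickness w={self.w} out of range for radii "
                             f"({self.r1}, {self.r2})")


@dataclass
class FeatureBank:
    """Random (channel, cube-offset) pooled-feature specification.

    Each of the ``n_features`` entries names one channel, a per-axis integer
    offset of the cube centre relative to the described voxel, and the cube
    edge length.  The bank is exactly regenerable from its parameters and
    seed, which is what gets serialized inside model files.
    """

    channel: np.ndarray          # (K,) int
    offset: np.ndarray           # (K, 3) int, (z, y, x)
    edge: np.ndarray             # (K,) int
    n_channels: int
    cube_edge: int
    max_offset: int
    rng_seed: int

    def __len__(self) -> int:
        return len(self.channel)

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_features": len(self),
            "cube_edge": self.cube_edge,
            "max_offset": self.max_offset,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureBank":
        return sample_feature_bank(
            n_channels=d["n_channels"],
            n_features=d["n_features"],
            cube_edge=d["cube_edge"],
            max_offset=d["max_offset"],
            seed=d["rng_seed"],
        )


def grims_channels(stack: VoxelStack, cfg: GrimsConfig) -> GrimsChannelSet:
    """Compute the five GRIMS channels at every configured scale.

    Derivative subscripts follow the (x, y, z) convention while arrays are
    stored (z, y, x); reflective boundaries are used throughout.
    """
    data = stack.data
    if not np.all(np.isfinite(data)):
        raise ValueError("input volume contains non-finite values")
    if min(cfg.scales) < 0.5:
        raise ValueError("scales below 0.5 voxels render the discrete Gaussian "
                         "degenerate")
    out = np.empty((5 * len(cfg.scales), *data.shape), dtype=np.float64)
    for j, sigma in enumerate(cfg.scales):
        sig_axes, norm = _axis_sigmas(sigma, stack.spacing, cfg.spacing_aware)

        def deriv(ox: int, oy: int, oz: int) -> np.ndarray:
            # ndimage order argument is per array axis (z, y, x)
            res = ndimage.gaussian_filter(data, sig_axes, order=(oz, oy, ox),
                                          mode="reflect")
            return res * (norm[2] ** ox) * (norm[1] ** oy) * (norm[0] ** oz)

        s000 = deriv(0, 0, 0)
        gx, gy, gz = deriv(1, 0, 0), deriv(0, 1, 0), deriv(0, 0, 1)
        gradmag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        hxx, hyy, hzz = deriv(2, 0, 0), deriv(0, 2, 0), deriv(0, 0, 2)
        hxy, hxz, hyz = deriv(1, 1, 0), deriv(1, 0, 1), deriv(0, 1, 1)
        lam1, lam2, lam3 = hessian_eigenvalues(hxx, hxy, hxz, hyy, hyz, hzz)
        out[5 * j + 0] = s000
        out[5 * j + 1] = gradmag
        out[5 * j + 2] = lam1
        out[5 * j + 3] = lam2
        out[5 * j + 4] = lam3
    return GrimsChannelSet(list(cfg.scales), out)


def _axis_sigmas(sigma: float, spacing: Sequence[float], spacing_aware: bool):
    """Per-axis filter sigmas (z, y, x) and derivative normalization factors.

    The normalization multiplies a derivative of order d along an axis by
    (effective sigma along that axis)^d, which reduces to sigma^d for
    isotropic unit spacing.
    """
    if spacing_aware:
        sig = tuple(sigma / s for s in spacing)
    else:
        sig = (sigma, sigma, sigma)
    return sig, sig


def hessian_eigenvalues(hxx, hxy, hxz, hyy, hyz, hzz):
    """Per-voxel eigenvalues of the symmetric 3x3 Hessian, sorted descending.

    Accepts six same-shaped arrays (the unique Hessian entries) and returns
    three arrays ``lam1 >= lam2 >= lam3``.
    """
    shape = np.asarray(hxx).shape
    for h in (hxy, hxz, hyy, hyz, hzz):
        if np.asarray(h).shape != shape:
            raise ValueError("Hessian component shapes differ")
    H = np.empty((*shape, 3, 3), dtype=np.float64)
    H[..., 0, 0] = hxx
    H[..., 0, 1] = H[..., 1, 0] = hxy
    H[..., 0, 2] = H[..., 2, 0] = hxz
    H[..., 1, 1] = hyy
    H[..., 1, 2] = H[..., 2, 1] = hyz
    H[..., 2, 2] = hzz
    lam = np.linalg.eigvalsh(H)          # ascending
    return lam[..., 2], lam[..., 1], lam[..., 0]


def elliptical_kernel(cfg: EllipticalKernelConfig) -> np.ndarray:
    """Binary elliptic annulus, normalized to unit sum.

    A 2-D point p = (px, py) relative to the kernel centre lies on the
    annulus when its elliptical radius r(p) = sqrt((px/r1)^2 + (py/r2)^2)
    satisfies |r(p) - 1| * min(r1, r2) <= w / 2.
    """
    hx = int(np.ceil(cfg.r1 + cfg.w))
    hy = int(np.ceil(cfg.r2 + cfg.w))
    py, px = np.mgrid[-hy:hy + 1, -hx:hx + 1].astype(np.float64)
    r = np.sqrt((px / cfg.r1) ** 2 + (py / cfg.r2) ** 2)
    mask = np.abs(r - 1.0) * min(cfg.r1, cfg.r2) <= cfg.w / 2.0
    kernel = mask.astype(np.float64)
    total = kernel.sum()
    if total == 0:
        raise ValueError("annulus kernel is empty; check radii/thickness")
    return kernel / total


def elliptical_channel(stack: VoxelStack, cfg: EllipticalKernelConfig) -> np.ndarray:
    """Slice-wise 2-D filtering with the elliptic annulus kernel.

    Vesicles are slice-local ring structures, so the kernel is applied
    independently within each z-slice ('same' size, reflective borders).
    Dark vesicle rims therefore produce low responses along the annulus.
    """
    kernel = elliptical_kernel(cfg)
    ky, kx = kernel.shape
    _, ny, nx = stack.data.shape
    if ky > ny or kx > nx:
        raise ValueError(f"kernel {kernel.shape} larger than slice ({ny}, {nx})")
    out = np.empty_like(stack.data)
    for z in range(stack.data.shape[0]):
        ndimage.correlate(stack.data[z], kernel, output=out[z], mode="reflect")
    return out


def integral_volume(channel: np.ndarray) -> np.ndarray:
    """Summed-volume table with a zero-padded leading plane per axis.

    ``ivol[z, y, x]`` is the sum of the channel over ``[:z, :y, :x]``, so any
    half-open box sum is an 8-corner inclusion-exclusion lookup.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    ivol = np.zeros(tuple(s + 1 for s in channel.shape), dtype=np.float64)
    ivol[1:, 1:, 1:] = channel.cumsum(0).cumsum(1).cumsum(2)
    return ivol


def box_sum(ivol: np.ndarray, z0, z1, y0, y1, x0, x1):
    """O(1) box sums over half-open boxes; accepts scalars or index arrays."""
    return (
        ivol[z1, y1, x1] - ivol[z0, y1, x1] - ivol[z1, y0, x1] - ivol[z1, y1, x0]
        + ivol[z0, y0, x1] + ivol[z0, y1, x0] + ivol[z1, y0, x0] - ivol[z0, y0, x0]
    )


def sample_feature_bank(
    n_channels: int,
    n_features: int = 1200,
    cube_edge: int = 5,
    max_offset: int = 15,
    seed: int = 0,
) -> FeatureBank:
    """Draw the random pooled-feature bank.

    Each feature picks a channel uniformly and a cube-centre offset uniform
    over ``[-max_offset, max_offset]`` per axis; the default bank holds 1200
    features over 5x5x5-voxel cubes.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    channel = rng.integers(0, n_channels, size=n_features)
    offset = rng.integers(-max_offset, max_offset + 1, size=(n_features, 3))
    edge = np.full(n_features, cube_edge, dtype=np.int64)
    return FeatureBank(channel, offset, edge, n_channels, cube_edge, max_offset,
                       int(seed))


def integral_volumes(channels: np.ndarray) -> np.ndarray:
    """Summed-volume tables for a ``(C, z, y, x)`` channel array."""
    channels = np.asarray(channels)
    out = np.zeros((channels.shape[0], *(s + 1 for s in channels.shape[1:])),
                   dtype=np.float64)
    for c in range(channels.shape[0]):
        out[c] = integral_volume(channels[c])
    return out


def extract_features(
    bank: FeatureBank,
    ivols: np.ndarray,
    voxels: np.ndarray,
    out_dtype=np.float32,
) -> np.ndarray:
    """Pooled-cube feature matrix (len(voxels) x len(bank)).

    Parameters
    ----------
    bank:
        Feature specification.
    ivols:
        Summed-volume tables ``(C, z+1, y+1, x+1)`` from
        :func:`integral_volumes`.
    voxels:
        Integer voxel coordinates ``(N, 3)`` in (z, y, x).

    Boxes that straddle the volume limits are clipped to the volume (a box
    entirely outside sums to zero); this mirrors the context degradation
    near stack borders instead of inventing padded content.
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        return np.empty((0, len(bank)), dtype=out_dtype)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise ValueError(f"voxels must be (N, 3), got {voxels.shape}")
    shape = np.array(ivols.shape[1:]) - 1
    if (voxels < 0).any() or (voxels >= shape).any():
        raise ValueError("voxel coordinates out of bounds")
    n = voxels.shape[0]
    out = np.empty((n, len(bank)), dtype=out_dtype)
    vz, vy, vx = voxels[:, 0], voxels[:, 1], voxels[:, 2]
    for k in range(len(bank)):
        e = int(bank.edge[k])
        half = e // 2
        oz, oy, ox = bank.offset[k]
        z0 = np.clip(vz + oz - half, 0, shape[0])
        z1 = np.clip(vz + oz - half + e, 0, shape[0])
        y0 = np.clip(vy + oy - half, 0, shape[1])
        y1 = np.clip(vy + oy - half + e, 0, shape[1])
        x0 = np.clip(vx + ox - half, 0, shape[2])
        x1 = np.clip(vx + ox - half + e, 0, shape[2])
        out[:, k] = box_sum(ivols[bank.channel[k]], z0, z1, y0, y1, x0, x1)
    return out


def extract_features_grid(
    bank: FeatureBank,
    ivols: np.ndarray,
    z_range: tuple[int, int],
    fields: dict[tuple[int, int], np.ndarray] | None = None,
    fields_z0: int | None = None,
    out_dtype=np.float32,
) -> np.ndarray:
    """Pooled features for every voxel of a contiguous z-block.

    Equivalent to :func:`extract_features` over the full (z, y, x) grid of
    ``z_range`` in raster order, but exploits the grid structure: a feature
    is the clipped box sum *centred at voxel + offset*, so for each
    (channel, edge) pair the centred box-sum field is evaluated once on a
    grid padded by the maximum offset, and every feature reduces to a plain
    array slice of that field.  This is the fast path used when scoring
    whole stacks.
    """
    nz, ny, nx = (s - 1 for s in ivols.shape[1:])
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"z range {z_range} out of bounds for {nz} slices")
    pad = int(np.abs(bank.offset).max(initial=0))
    n = (z1 - z0) * ny * nx
    # F-order keeps per-feature column writes contiguous
    out = np.empty((n, len(bank)), dtype=out_dtype, order="F")
    if fields is None:
        fields = grid_box_fields(bank, ivols, z_range)
        fields_z0 = z0
    zoff = z0 - (fields_z0 if fields_z0 is not None else z0)
    for k in range(len(bank)):
        key = (int(bank.channel[k]), int(bank.edge[k]))
        oz, oy, ox = (int(v) for v in bank.offset[k])
        field = fields[key]
        view = field[zoff + pad + oz: zoff + pad + oz + (z1 - z0),
                     pad + oy: pad + oy + ny,
                     pad + ox: pad + ox + nx]
        out[:, k] = view.reshape(n)
    return out


def write_channels_h5(path, grims: GrimsChannelSet,
                      elliptical: np.ndarray | None = None) -> None:
    """Export channels to HDF5, one dataset per channel
    (``s000_<sigma>``, ``gradmag_<sigma>``, ``lam{1,2,3}_<sigma>``, ``ellip``)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, channel in zip(grims.names, grims.channels):
            fh.create_dataset(name, data=channel.astype(np.float32))
        if elliptical is not None:
            fh.create_dataset("ellip", data=np.asarray(elliptical,
                                                       dtype=np.float32))


def grid_box_fields(
    bank: FeatureBank,
    ivols: np.ndarray,
    z_range: tuple[int, int],
) -> dict[tuple[int, int], np.ndarray]:
    """Centred clipped box-sum fields per (channel, edge), padded by the
    bank's maximum offset, for reuse across the chunks of one z-block."""
    nz, ny, nx = (s - 1 for s in ivols.shape[1:])
    z0, z1 = z_range
    pad = int(np.abs(bank.offset).max(initial=0))
    fields: dict[tuple[int, int], np.ndarray] = {}
    for key in {(int(c), int(e)) for c, e in zip(bank.channel, bank.edge)}:
        channel, e = key
        half = e // 2
        cz = np.arange(z0 - pad, z1 + pad)
        cy = np.arange(-pad, ny + pad)
        cx = np.arange(-pad, nx + pad)
        za, zb = np.clip(cz - half, 0, nz), np.clip(cz - half + e, 0, nz)
        ya, yb = np.clip(cy - half, 0, ny), np.clip(cy - half + e, 0, ny)
        xa, xb = np.clip(cx - half, 0, nx), np.clip(cx - half + e, 0, nx)
        iv = ivols[channel]
        field = (iv[np.ix_(zb, yb, xb)] - iv[np.ix_(za, yb, xb)]
                 - iv[np.ix_(zb, ya, xb)] - iv[np.ix_(zb, yb, xa)]
                 + iv[np.ix_(za, ya, xb)] + iv[np.ix_(za, yb, xa)]
                 + iv[np.ix_(zb, ya, xa)] - iv[np.ix_(za, ya, xa)])
        fields[key] = field.astype(np.float32)
    return fields
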