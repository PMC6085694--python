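"""Seeded synthetic EM-like phantom stacks.

The generator emulates, at the morphology level, the structures a serial
block-face EM stack of neural tissue presents to a voxel classifier:

* **mitochondria** — dark, roughly ellipsoidal bodies of widely varying size
  and random orientation;
* **synapses** — thin, elongated, gently curved dark slabs (synaptic
  densities), each flanked on one side by a cluster of **vesicles**, small
  spheres whose dark rims appear as rings in individual slices.  Vesicles
  are rendered but deliberately *not* labeled: they are context indicating a
  nearby synapse, not a segmentation target;
* optional **membranes** — thin perturbed sheets crossing the volume;
* a bright, smoothly textured background plus additive Gaussian noise.

Everything derives from a single seed, so volumes are bitwise reproducible.
The phantom reproduces geometry and contrast, not EM texture statistics:
real stacks add staining variability, imaging artifacts and far richer
ultrastructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from emseg.stack_io import LabelVolume, VoxelStack

BACKGROUND, MITOCHONDRION, SYNAPSE, MEMBRANE = 0, 1, 2, 3


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of the synthetic stack.

    Default contrasts keep every labeled class at least two noise standard
    deviations away from the background mean; default counts put roughly 4%
    of voxels in mitochondria and 1% in synapses, the kind of heavy class
    imbalance voxel classifiers face in real tissue.
    """

    shape: tuple[int, int, int] = (96, 128, 128)
    seed: int = 0

    n_mitochondria: int = 25
    mito_semiaxes: tuple[float, float] = (5.0, 12.0)

    n_synapses: int = 12
    synapse_radius: tuple[float, float] = (8.0, 16.0)
    synapse_thickness: tuple[float, float] = (2.5, 4.0)
    synapse_curvature: tuple[float, float] = (0.005, 0.03)

    vesicles_per_synapse: tuple[int, int] = (6, 12)
    vesicle_radius: float = 4.0
    vesicle_rim_width: float = 1.5
    vesicle_cluster_spread: float = 7.0

    n_membranes: int = 0
    membrane_thickness: float = 2.0

    background_mean: float = 0.72
    mito_mean: float = 0.30
    synapse_mean: float = 0.22
    vesicle_rim_mean: float = 0.35
    vesicle_lumen_mean: float = 0.60
    membrane_mean: float = 0.35
    texture_std: float = 0.03
    noise_std: float = 0.04

    #: nominal labeled-voxel fractions implied by the default geometry
    target_fractions: dict = field(
        default_factory=lambda: {MITOCHONDRION: 0.041, SYNAPSE: 0.012})

    max_placement_attempts: int = 200

    def class_names(self) -> list[str]:
        names = ["background", "mitochondrion", "synapse"]
        if self.n_membranes > 0:
            names.append("membrane")
        return names


def generate(config: PhantomConfig) -> tuple[VoxelStack, LabelVolume]:
    """Render the phantom; returns a (stack, labels) pair.

    Structures are placed with rejection sampling so labeled masks never
    overlap; a structure that cannot be placed within the configured number
    of attempts raises a RuntimeError.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    labels = np.zeros(shape, dtype=np.int64)

    # smooth background texture
    tex = rng.normal(0.0, 1.0, shape)
    tex = ndimage.gaussian_filter(tex, 6.0)
    tex *= config.texture_std / max(tex.std(), 1e-12)
    intensity = np.full(shape, config.background_mean) + tex

    for _ in range(config.n_mitochondria):
        _place_mitochondrion(rng, config, labels, intensity)
    for _ in range(config.n_synapses):
        _place_synapse(rng, config, labels, intensity)
    for _ in range(config.n_membranes):
        _place_membrane(rng, config, labels, intensity)

    intensity += rng.normal(0.0, config.noise_std, shape)
    np.clip(intensity, 0.0, 1.0, out=intensity)
    return VoxelStack(intensity), LabelVolume(labels, config.class_names())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation from the QR decomposition of a Gaussian."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _local_grid(center, half_extent, shape):
    """Integer bounding box around center and the relative coordinate grids."""
    lo = [max(0, int(np.floor(c - h))) for c, h in zip(center, half_extent)]
    hi = [min(s, int(np.ceil(c + h)) + 1) for c, h, s in zip(center, half_extent, shape)]
    if any(a >= b for a, b in zip(lo, hi)):
        return None
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    coords = np.meshgrid(*[np.arange(a, b, dtype=np.float64) - c
                           for a, b, c in zip(lo, hi, center)], indexing="ij")
    return sl, coords


def _place_mitochondrion(rng, config, labels, intensity) -> None:
    shape = labels.shape
    a_lo, a_hi = config.mito_semiaxes
    for _ in range(config.max_placement_attempts):
        semi = rng.uniform(a_lo, a_hi, size=3)
        rot = _random_rotation(rng)
        margin = semi.max()
        center = np.array([_random_center(rng, s, margin) for s in shape])
        got = _local_grid(center, [margin + 2] * 3, shape)
        if got is None:
            continue
        sl, (dz, dy, dx) = got
        rel = np.stack([dz, dy, dx], axis=-1) @ rot
        quad = ((rel / semi) ** 2).sum(axis=-1)
        mask = quad <= 1.0
        # a 1.5-voxel clearance keeps every body a separate connected component
        inflated = ((rel / (semi + 1.5)) ** 2).sum(axis=-1) <= 1.0
        if not mask.any() or labels[sl][inflated].any():
            continue
        labels[sl][mask] = MITOCHONDRION
        # slight internal texture keeps the body from being perfectly flat
        intensity[sl][mask] = config.mito_mean + 0.02 * np.cos(quad[mask] * 6.0)
        return
    raise RuntimeError("could not place mitochondrion; volume too crowded")


def _place_synapse(rng, config, labels, intensity) -> None:
    shape = labels.shape
    for _ in range(config.max_placement_attempts):
        radius = rng.uniform(*config.synapse_radius)
        thick = rng.uniform(*config.synapse_thickness)
        kappa = rng.uniform(*config.synapse_curvature)
        normal = _random_rotation(rng)[:, 0]
        t1, t2 = _tangent_basis(normal)
        margin = radius + thick + kappa * radius ** 2 + 1
        ves_reach = (config.vesicle_cluster_spread + config.vesicle_radius
                     + thick + 4)
        center = np.array([_random_center(rng, s, margin + ves_reach)
                           for s in shape])
        got = _local_grid(center, [margin] * 3, shape)
        if got is None:
            continue
        sl, (dz, dy, dx) = got
        rel = np.stack([dz, dy, dx], axis=-1)
        d = rel @ normal
        u = rel @ t1
        v = rel @ t2
        rho2 = u ** 2 + v ** 2
        mask = (np.abs(d - kappa * rho2) <= thick / 2.0) & (rho2 <= radius ** 2)
        if not mask.any():
            continue
        # synapses may abut other structures: carve away small overlaps,
        # retry only when most of the slab would be lost
        overlap = labels[sl][mask] != BACKGROUND
        if overlap.mean() > 0.5:
            continue
        mask = mask & (labels[sl] == BACKGROUND)
        if not mask.any():
            continue
        labels[sl][mask] = SYNAPSE
        intensity[sl][mask] = config.synapse_mean
        _place_vesicle_cluster(rng, config, labels, intensity, center, normal,
                               thick)
        return
    raise RuntimeError("could not place synapse; volume too crowded")


def _place_vesicle_cluster(rng, config, labels, intensity, syn_center, normal,
                           thick) -> None:
    """Unlabeled vesicle rings on one side of a synapse."""
    side = rng.choice([-1.0, 1.0])
    offset = thick / 2 + config.vesicle_radius + 2.0
    cluster = syn_center + side * offset * normal
    n_ves = int(rng.integers(config.vesicles_per_synapse[0],
                             config.vesicles_per_synapse[1] + 1))
    shape = labels.shape
    rv, wv = config.vesicle_radius, config.vesicle_rim_width
    for _ in range(n_ves):
        c = cluster + rng.normal(0.0, config.vesicle_cluster_spread, 3)
        got = _local_grid(c, [rv + wv] * 3, shape)
        if got is None:
            continue
        sl, (dz, dy, dx) = got
        r = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2)
        rim = (np.abs(r - rv) <= wv / 2.0) & (labels[sl] == BACKGROUND)
        lumen = (r < rv - wv / 2.0) & (labels[sl] == BACKGROUND)
        intensity[sl][rim] = config.vesicle_rim_mean
        intensity[sl][lumen] = config.vesicle_lumen_mean


def _place_membrane(rng, config, labels, intensity) -> None:
    shape = labels.shape
    for _ in range(config.max_placement_attempts):
        normal = _random_rotation(rng)[:, 0]
        t1, t2 = _tangent_basis(normal)
        center = np.array([rng.uniform(0.3 * s, 0.7 * s) for s in shape])
        zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                 indexing="ij")
        rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
        d = rel @ normal
        u = rel @ t1
        v = rel @ t2
        wobble = 2.0 * np.sin(2 * np.pi * u / 48.0) + 1.5 * np.cos(2 * np.pi * v / 64.0)
        mask = (np.abs(d - wobble) <= config.membrane_thickness / 2.0) \
            & (labels == BACKGROUND)
        if not mask.any():
            continue
        labels[mask] = MEMBRANE
        intensity[mask] = config.membrane_mean
        return
    raise RuntimeError("could not place membrane")


def _random_center(rng: np.random.Generator, extent: int, margin: float) -> float:
    """Uniform placement keeping ``margin`` clearance where the volume allows
    it; in small volumes the margin shrinks and structures may clip."""
    m = min(margin, 0.4 * extent)
    return rng.uniform(m, extent - m)


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def anisotropize(stack: VoxelStack, labels: LabelVolume, factor: int
                 ) -> tuple[VoxelStack, LabelVolume]:
    """Decimate the z-axis by an integer factor, emulating coarse sectioning.

    Intensities are block-averaged; labels take the majority vote within
    each block (ties resolve to the lowest class index); z-spacing scales by
    the factor.  Trailing slices that do not fill a block are dropped.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nz = stack.shape[0]
    if factor > nz:
        raise ValueError(f"factor {factor} exceeds z extent {nz}")
    if factor == 1:
        return stack, labels
    nz_out = nz // factor
    data = stack.data[: nz_out * factor].reshape(nz_out, factor,
                                                 *stack.shape[1:])
    lab = labels.labels[: nz_out * factor].reshape(nz_out, factor,
                                                   *labels.shape[1:])
    avg = data.mean(axis=1)
    counts = np.stack([(lab == c).sum(axis=1)
                       for c in range(labels.n_classes)], axis=0)
    voted = counts.argmax(axis=0)
    spacing = (stack.spacing[0] * factor, stack.spacing[1], stack.spacing[2])
    return (VoxelStack(avg, spacing),
            LabelVolume(voted.astype(np.int64), labels.class_names))
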