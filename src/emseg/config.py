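"""Declarative run configuration (YAML) for the full pipeline.

The schema is strict: unknown keys are rejected so typos fail loudly.
Defaults follow the experimental protocol of the method: 50 boosting
iterations of depth-10 trees with 10% weighted sub-sampling, 1200 pooled
features over 5x5x5 cubes, 4 selected scales, half of the background voxels
discarded, and a vesicle kernel matched to the average vesicle radii.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    shape: tuple[int, int, int] = (96, 128, 128)
    n_mitochondria: int = 25
    n_synapses: int = 12
    n_membranes: int = 0
    mito_semiaxes: tuple[float, float] = (5.0, 12.0)
    synapse_radius: tuple[float, float] = (8.0, 16.0)
    noise_std: float = 0.04


class GridSection(_Strict):
    """Candidate GRIMS scales: ``count`` equally distributed values over
    ``[start, stop]`` inclusive.

    The default grid spans half a voxel (the smallest usable discrete
    Gaussian) up to the radius of the largest phantom structures in 0.5
    steps; stacks with larger structures should extend ``stop``.
    """

    start: float = 0.5
    stop: float = 8.0
    count: int = 16


class EllipticalSection(_Strict):
    """Vesicle kernel parameters: the average radii and rim width of the
    stack's vesicles (here, the phantom's defaults)."""

    r1: float = 4.0
    r2: float = 4.0
    w: float = 1.5


class FeatureSection(_Strict):
    n_features: int = 1200
    cube_edge: int = 5
    max_offset: int = 15


class BoostSection(_Strict):
    n_iterations: int = 50
    tree_depth: int = 10
    subsample_fraction: float = 0.10
    max_features: int | None = 128


class RegularizeSection(_Strict):
    lambda_s: float = 1.0
    border_width: int = 2


class SamplingSection(_Strict):
    """Caps on the voxel samples used for training; the full test block is
    always scored."""

    max_train_voxels: int = 60000
    max_select_voxels: int = 8000
    max_border_voxels: int = 30000


class RunConfig(_Strict):
    seed: int = 0
    stack_path: str | None = None
    labels_path: str | None = None
    class_names: list[str] | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    train_fraction: float = Field(0.5, gt=0.0, lt=1.0)

    phantom: PhantomSection = PhantomSection()
    scale_grid: GridSection = GridSection()
    k_scales: int = 4
    spacing_aware: bool = False
    elliptical: EllipticalSection = EllipticalSection()
    features: FeatureSection = FeatureSection()
    boost: BoostSection = BoostSection()
    regularize: RegularizeSection = RegularizeSection()
    sampling: SamplingSection = SamplingSection()
    n_curve_points: int = 200
    chunk_slices: int = 4


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
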