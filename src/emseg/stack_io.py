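"""Volume, label and curve I/O plus the geometry conventions of the package.

Conventions
-----------
* Axis order is ``(z, y, x)``; ``z`` indexes the serial-section (slice) axis.
* Coordinates are 0-based; slice ranges are half-open ``[start, stop)``.
* Intensities are held as floating point internally regardless of the file
  bit-depth; 8/16-bit integer sources are normalized to ``[0, 1]`` at load so
  kernel responses are comparable across acquisitions.
* Label volumes are small non-negative integers; class index 0 is background.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised when a file decodes but violates the expected layout."""


@dataclass
class VoxelStack:
    """A 3-D grayscale intensity volume with per-axis physical spacing.

    Parameters
    ----------
    data:
        3-D float array in ``(z, y, x)`` order.
    spacing:
        Physical voxel size per axis ``(z, y, x)`` in arbitrary but
        consistent units.  The anisotropy factor of a stack is
        ``spacing[0] / spacing[1]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer class labels aligned voxel-for-voxel with a :class:`VoxelStack`.

    ``class_names[0]`` is always the background class.
    """

    labels: np.ndarray
    class_names: Sequence[str] = ("background",)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3-D label volume, got ndim={self.labels.ndim}")
        self.class_names = list(self.class_names)
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError(
                f"label {int(self.labels.max())} out of range for "
                f"{len(self.class_names)} classes"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class SplitSpec:
    """Contiguous half-open z-ranges for a train/test split.

    Mirrors the usual EM protocol of taking the first block of consecutive
    slices for training and the remainder for testing.
    """

    train_slices: tuple[int, int]
    test_slices: tuple[int, int]

    def __post_init__(self) -> None:
        t0, t1 = self.train_slices
        s0, s1 = self.test_slices
        if t0 < 0 or s0 < 0 or t1 < t0 or s1 < s0:
            raise ValueError("slice ranges must be non-negative and ordered")
        if max(t0, s0) < min(t1, s1):
            raise ValueError(
                f"train {self.train_slices} and test {self.test_slices} ranges overlap"
            )


def _normalize_intensity(arr: np.ndarray) -> np.ndarray:
    """Cast to float, mapping integer bit-depths onto [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return arr.astype(np.float64)


def read_stack(
    path: str | Path,
    fmt: str | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    dataset: str = "volume",
    normalize: bool = True,
) -> VoxelStack:
    """Read a 3-D grayscale volume from multipage TIFF or HDF5.

    Parameters
    ----------
    path:
        File to read.  ``fmt`` defaults from the extension
        (``.tif/.tiff`` vs ``.h5/.hdf5``).
    spacing:
        Per-axis voxel size; supplied by the caller (e.g. from a run
        configuration) rather than parsed from TIFF tags, whose dialects
        vary across microscope vendors.
    dataset:
        HDF5 dataset name.
    normalize:
        Map integer intensities onto ``[0, 1]``.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tiff":
        try:
            arr = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    elif fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise FormatError(f"{path} has no dataset {dataset!r}")
            arr = fh[dataset][()]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tiff' or 'hdf5'")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path} decodes to ndim={arr.ndim}, expected a 3-D stack")
    if normalize:
        arr = _normalize_intensity(arr)
    return VoxelStack(arr.astype(np.float64), spacing)


def write_stack(stack: VoxelStack, path: str | Path, fmt: str | None = None,
                dataset: str = "volume") -> None:
    """Write a volume as float32 multipage TIFF or HDF5."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    data = stack.data.astype(np.float32)
    if fmt == "tiff":
        tifffile.imwrite(path, data)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=data)
            fh.attrs["spacing"] = stack.spacing
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(
    path: str | Path,
    class_names: Sequence[str],
    fmt: str | None = None,
    dataset: str = "labels",
) -> LabelVolume:
    """Read an integer label volume (uint8 on disk)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tiff":
        arr = tifffile.imread(path)
    elif fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise FormatError(f"{path} has no dataset {dataset!r}")
            arr = fh[dataset][()]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path} labels are {arr.dtype}, expected integer")
    return LabelVolume(arr.astype(np.int64), class_names)


def write_labels(labels: LabelVolume, path: str | Path, fmt: str | None = None,
                 dataset: str = "labels") -> None:
    """Write labels as uint8 (at most 255 classes)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if labels.n_classes > 256:
        raise ValueError("uint8 label files support at most 256 classes")
    data = labels.labels.astype(np.uint8)
    if fmt == "tiff":
        tifffile.imwrite(path, data)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=data)
            fh.attrs["class_names"] = list(labels.class_names)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def split_stack(
    stack: VoxelStack,
    labels: LabelVolume,
    spec: SplitSpec,
) -> tuple[tuple[VoxelStack, LabelVolume], tuple[VoxelStack, LabelVolume]]:
    """Split a stack and its labels into train/test z-blocks.

    Returns ``((train_stack, train_labels), (test_stack, test_labels))``.
    A zero-extent range yields an empty block; downstream training rejects it.
    """
    if stack.shape != labels.shape:
        raise ValueError(f"stack {stack.shape} and labels {labels.shape} differ")
    nz = stack.shape[0]
    for name, (a, b) in (("train", spec.train_slices), ("test", spec.test_slices)):
        if b > nz:
            raise ValueError(f"{name} range {(a, b)} exceeds z extent {nz}")

    def _block(rng: tuple[int, int]) -> tuple[VoxelStack, LabelVolume]:
        a, b = rng
        data = stack.data[a:b]
        if data.shape[0] == 0:
            # degenerate empty block: keep geometry information
            data = data.reshape(0, *stack.shape[1:])
        vs = VoxelStack.__new__(VoxelStack)
        vs.data = data
        vs.spacing = stack.spacing
        return vs, LabelVolume(labels.labels[a:b], labels.class_names)

    return _block(spec.train_slices), _block(spec.test_slices)


def write_curve_csv(points: np.ndarray, path: str | Path) -> None:
    """Write a Jaccard-curve point list as CSV (background_fraction, jaccard)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["background_fraction", "jaccard"])
        for x, y in np.asarray(points):
            writer.writerow([f"{x:.8g}", f"{y:.8g}"])


def read_curve_csv(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["background_fraction", "jaccard"]:
            raise FormatError(f"{path}: unexpected curve header {header}")
        return np.array([[float(a), float(b)] for a, b in reader])


def save_model_json(model: dict, path: str | Path) -> None:
    """Serialize a model document (trees inlined as plain lists) to JSON."""
    with open(path, "w") as fh:
        json.dump(model, fh, default=_json_default)


def load_model_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer format from extension {suffix!r}")
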