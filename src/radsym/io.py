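"""Image and detection-table I/O and the package-wide coordinate convention.

Coordinate convention
---------------------
Every pixel is a point measurement, not a square: pixel centers sit at
integer coordinates and the first pixel of the first row/slice is at
``(0.0, 0.0[, 0.0])``.  All positions in this package are reported in
``(x, y[, z])`` order in pixel units.  No module applies a half-pixel
shift; the convention lives in :data:`PIXEL_CENTER_ORIGIN` alone.

Internally image data is indexed in ``(x, y[, z])`` axis order, so
``volume.region(lo, hi)[ix, iy, iz]`` is the pixel at coordinate
``(lo[0]+ix, lo[1]+iy, lo[2]+iz)``.  Multi-page TIFFs (page axis = z,
rows = y, columns = x) and chunked zarr stores (written in the same
``(z, y, x)`` disk order) are transposed on access.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import zarr

#: Coordinate of the center of the first pixel of the first row/slice.
PIXEL_CENTER_ORIGIN = 0.0

#: Column order of the detection-table CSV.
DETECTION_COLUMNS = ("x", "y", "z", "t", "c", "intensity")

#: Decimal places used when formatting coordinates.
CSV_DECIMALS = 6


class UnsupportedDimensionalityError(ValueError):
    """Raised for images that are not 2- or 3-dimensional."""


@dataclass
class ImageVolume:
    """An n-dimensional (n = 2 or 3) scalar intensity grid.

    Parameters
    ----------
    data
        Either an in-memory ndarray already in internal ``(x, y[, z])``
        index order, or a lazily-read zarr array in ``(z, y[, x]) ``
        disk order with ``transposed=True``.
    spacing
        Optional physical pixel size per axis in µm, ``(x, y[, z])``.
    transposed
        True when ``data`` is stored in reversed (disk) axis order and
        must be transposed on access.  Used for lazy zarr stores.
    """

    data: object
    spacing: Optional[tuple] = None
    transposed: bool = False

    def __post_init__(self):
        nd = self.data.ndim
        if nd < 2 or nd > 3:
            raise UnsupportedDimensionalityError(
                f"only 2D and 3D images are supported, got {nd}D"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all image extents must be >= 1")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        """Extents in internal (x, y[, z]) order."""
        s = self.data.shape
        return tuple(reversed(s)) if self.transposed else tuple(s)

    def region(self, lo: Sequence[int], hi: Sequence[int]) -> np.ndarray:
        """Read the half-open box ``[lo, hi)`` as a float64 ndarray.

        Coordinates are internal (x, y[, z]); the box must lie inside
        the image.  For lazy stores only the requested chunks are read.
        """
        lo = tuple(int(v) for v in lo)
        hi = tuple(int(v) for v in hi)
        shape = self.shape
        if any(l < 0 or h > s or l >= h for l, h, s in zip(lo, hi, shape)):
            raise ValueError(f"region [{lo}, {hi}) outside image of shape {shape}")
        if self.transposed:
            sl = tuple(slice(l, h) for l, h in zip(reversed(lo), reversed(hi)))
            block = np.asarray(self.data[sl]).T
        else:
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            block = np.asarray(self.data[sl])
        block = np.asarray(block, dtype=np.float64)
        if not np.all(np.isfinite(block)):
            raise ValueError("image contains non-finite values")
        return block

    def ndarray(self) -> np.ndarray:
        """The full image as a float64 ndarray in internal axis order."""
        return self.region((0,) * self.ndim, self.shape)


def from_array(arr: np.ndarray, spacing: Optional[tuple] = None) -> ImageVolume:
    """Wrap an ndarray already in internal (x, y[, z]) order."""
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return ImageVolume(arr, spacing=spacing)


def read_image(path: str, dataset: Optional[str] = None) -> ImageVolume:
    """Read a TIFF file or a chunked zarr store into an :class:`ImageVolume`.

    TIFFs are loaded eagerly; zarr stores stay lazy (pixels are read on
    demand through :meth:`ImageVolume.region`).  ``dataset`` names the
    array inside a zarr group and is ignored for TIFFs.
    """
    if not os.path.exists(path):
        raise IOError(f"no such image: {path}")
    if os.path.isdir(path):  # chunked store
        root = zarr.open_group(path, mode="r")
        name = dataset if dataset is not None else "image"
        try:
            arr = root[name]
        except KeyError:
            raise IOError(f"dataset {name!r} not found in store {path}")
        if arr.ndim < 2 or arr.ndim > 3:
            raise UnsupportedDimensionalityError(
                f"dataset {name!r} is {arr.ndim}D; only 2D/3D supported"
            )
        return ImageVolume(arr, transposed=True)
    data = tifffile.imread(path)
    data = np.squeeze(data)
    if data.ndim < 2 or data.ndim > 3:
        raise UnsupportedDimensionalityError(
            f"{path} has {data.ndim} dimensions; only 2D/3D supported"
        )
    # TIFF axes are (z, y, x) / (y, x) -> internal (x, y[, z])
    arr = np.asarray(data, dtype=np.float64).T
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path} contains non-finite values")
    return ImageVolume(np.ascontiguousarray(arr))


def write_image(volume_or_array, path: str, dataset: str = "image",
                chunks: Optional[tuple] = None) -> None:
    """Write an image as TIFF (``.tif``/``.tiff``) or as a zarr store.

    Arrays are given in internal (x, y[, z]) order and written in
    (z, y, x) disk order.
    """
    arr = volume_or_array.ndarray() if isinstance(volume_or_array, ImageVolume) \
        else np.asarray(volume_or_array, dtype=np.float64)
    disk = np.ascontiguousarray(arr.T)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, disk.astype(np.float32),
                         photometric="minisblack")
        return
    root = zarr.open_group(path, mode="a")
    if chunks is None:
        chunks = tuple(min(s, 64) for s in disk.shape)
    if dataset in root:
        del root[dataset]
    z = root.create_array(dataset, shape=disk.shape, chunks=chunks,
                          dtype=disk.dtype)
    z[...] = disk


def write_detections(spots, path: str) -> int:
    """Write spots to CSV with header ``x,y,z,t,c,intensity``.

    2D positions get a constant-zero z column.  Returns the row count.
    """
    rows = []
    for s in spots:
        pos = np.asarray(s.position, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite spot position {pos}")
        x, y = pos[0], pos[1]
        z = pos[2] if pos.size == 3 else 0.0
        rows.append((x, y, z, 1, 1, float(s.intensity)))
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(",".join(DETECTION_COLUMNS) + "\n")
        for x, y, z, t, c, inten in rows:
            fh.write(
                f"{x:.{CSV_DECIMALS}f},{y:.{CSV_DECIMALS}f},{z:.{CSV_DECIMALS}f},"
                f"{int(t)},{int(c)},{inten:.{CSV_DECIMALS}f}\n"
            )
    return len(rows)


def read_detections(path: str) -> pd.DataFrame:
    """Read a detection-table CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection table {path} lacks columns {missing}")
    return df


def read_mask(path: str) -> ImageVolume:
    """Read a binary mask TIFF (nonzero = inside)."""
    return read_image(path)
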