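"""Data model and HDF5/CSV readers and writers for hyperspectral maps.

A hyperspectral map is one sample's absorbance cube: ``rows x cols`` detector
pixels, each holding a full mid-infrared spectrum on a shared wavenumber axis
stored in descending order (3900 -> 900 cm^-1, the acquisition convention).
All windowed computations in the package go through :func:`slice_band`, which
is the single source of truth for interval inclusivity (closed intervals in
cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

NATIVE_FPA_SHAPE = (128, 128)
#: nominal imaged area edge with the 20x ATR objective, micrometers
NOMINAL_IMAGE_EDGE_UM = 64.0


def nominal_pixel_size_um(map_shape: tuple = NATIVE_FPA_SHAPE) -> float:
    """Nominal detector pixel size in micrometers (64 um / 128 px = 0.5 um)."""
    return NOMINAL_IMAGE_EDGE_UM / max(map_shape)

__all__ = [
    "HyperspectralMap",
    "PixelMask",
    "PixelPool",
    "FormatError",
    "read_map",
    "write_map",
    "slice_band",
    "read_metadata",
    "write_metadata",
    "read_pool",
    "write_pool",
    "concat_pools",
]


class FormatError(ValueError):
    """An on-disk map violates the expected layout or an invariant."""


#: metadata attributes carried by every map, in canonical column order
META_FIELDS = ("sample_id", "mouse_id", "strain", "dose_gy", "day", "split")


@dataclass
class HyperspectralMap:
    """One sample's absorbance cube plus its wavenumber axis and metadata.

    Parameters
    ----------
    absorbance : ndarray, shape (rows, cols, n_points)
        Absorbance at each detector pixel and spectral point.
    axis : ndarray, shape (n_points,)
        Wavenumbers in cm^-1, strictly decreasing.
    meta : dict
        Sample metadata; keys from ``META_FIELDS``.
    """

    absorbance: np.ndarray
    axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.absorbance.ndim != 3:
            raise FormatError(
                f"absorbance must be 3-D (rows, cols, n_points); got shape "
                f"{self.absorbance.shape}"
            )
        if self.axis.ndim != 1 or self.axis.size != self.absorbance.shape[2]:
            raise FormatError(
                f"axis length {self.axis.size} does not match spectral "
                f"dimension {self.absorbance.shape[2]}"
            )
        if not np.all(np.diff(self.axis) < 0):
            raise FormatError(
                "wavenumber axis must be strictly decreasing (3900 -> 900)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.absorbance.shape

    @property
    def is_native_fpa(self) -> bool:
        """True when the spatial grid matches the native 128x128 detector."""
        return self.absorbance.shape[:2] == NATIVE_FPA_SHAPE

    @property
    def n_pixels(self) -> int:
        return self.absorbance.shape[0] * self.absorbance.shape[1]

    def pixel(self, row: int, col: int) -> np.ndarray:
        return self.absorbance[row, col]

    def with_data(self, absorbance: np.ndarray, axis: np.ndarray | None = None
                  ) -> "HyperspectralMap":
        """Copy of this map with a new cube (and optionally a new axis)."""
        return HyperspectralMap(
            absorbance=absorbance,
            axis=self.axis if axis is None else axis,
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperspectralMap):
            return NotImplemented
        return (
            np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.axis, other.axis)
            and {k: self.meta.get(k) for k in META_FIELDS}
            == {k: other.meta.get(k) for k in META_FIELDS}
        )


@dataclass
class PixelMask:
    """Boolean accepted/rejected grid over a map's detector pixels.

    ``provenance`` records which stage produced the mask ("qc", "center",
    "pacmap", or an intersection label such as "qc&center").
    """

    accepted: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.accepted.ndim != 2:
            raise FormatError("mask must be a 2-D boolean grid")

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def intersect(self, other: "PixelMask") -> "PixelMask":
        if self.accepted.shape != other.accepted.shape:
            raise FormatError("mask shapes differ")
        return PixelMask(
            accepted=self.accepted & other.accepted,
            provenance=f"{self.provenance}&{other.provenance}",
        )

    def indices(self) -> np.ndarray:
        """Accepted (row, col) pairs in row-major order, shape (n, 2)."""
        return np.argwhere(self.accepted)


@dataclass
class PixelPool:
    """Flattened pixel records surviving QC and region selection.

    ``records`` has one row per pixel (columns sample_id, row, col plus the
    sample metadata) aligned with the rows of ``spectra``.
    """

    records: pd.DataFrame
    spectra: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.axis = np.asarray(self.axis, dtype=float)
        if len(self.records) != self.spectra.shape[0]:
            raise FormatError(
                f"{len(self.records)} records but {self.spectra.shape[0]} spectra"
            )
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.axis.size:
            raise FormatError("spectra must be (n_pixels, n_points) matching axis")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.records["sample_id"].to_numpy()

    def exposed_labels(self) -> np.ndarray:
        """Binary labels: 1 where dose > 0 Gy."""
        return (self.records["dose_gy"].to_numpy() > 0).astype(int)

    def subset(self, row_mask: np.ndarray) -> "PixelPool":
        return PixelPool(
            records=self.records.loc[np.asarray(row_mask)].reset_index(drop=True),
            spectra=self.spectra[np.asarray(row_mask)],
            axis=self.axis,
        )


def concat_pools(pools: Iterable[PixelPool]) -> PixelPool:
    pools = list(pools)
    if not pools:
        raise ValueError("no pools to concatenate")
    axis = pools[0].axis
    for p in pools[1:]:
        if not np.array_equal(p.axis, axis):
            raise FormatError("pixel pools have mismatched axes")
    return PixelPool(
        records=pd.concat([p.records for p in pools], ignore_index=True),
        spectra=np.vstack([p.spectra for p in pools]),
        axis=axis,
    )


# ---------------------------------------------------------------------------
# HDF5 layout: dataset "absorbance" [rows, cols, N], dataset "wavenumbers" [N],
# metadata as root attributes.
# ---------------------------------------------------------------------------

def write_map(m: HyperspectralMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("absorbance", data=m.absorbance)
        f.create_dataset("wavenumbers", data=m.axis)
        for k in META_FIELDS:
            if k in m.meta and m.meta[k] is not None:
                v = m.meta[k]
                # plain python scalars: h5py rejects numpy unicode scalars
                f.attrs[k] = str(v) if isinstance(v, str) else (
                    v.item() if hasattr(v, "item") else v)


def read_map(path) -> HyperspectralMap:
    with h5py.File(path, "r") as f:
        for ds in ("absorbance", "wavenumbers"):
            if ds not in f:
                raise FormatError(f"file {path} lacks required dataset '{ds}'")
        cube = f["absorbance"][()]
        axis = f["wavenumbers"][()]
        meta = {}
        for k in META_FIELDS:
            if k in f.attrs:
                v = f.attrs[k]
                meta[k] = v.item() if hasattr(v, "item") else v
    # __post_init__ enforces the descending-axis and shape invariants
    return HyperspectralMap(absorbance=cube, axis=axis, meta=meta)


def write_metadata(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pool(pool: PixelPool, path) -> None:
    """Pixel pool to HDF5: spectra matrix, axis, and record columns."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=pool.spectra)
        f.create_dataset("wavenumbers", data=pool.axis)
        g = f.create_group("records")
        for col in pool.records.columns:
            data = pool.records[col].to_numpy()
            if data.dtype == object or data.dtype.kind in "US":
                data = data.astype("S")
            g.create_dataset(col, data=data)


def read_pool(path) -> PixelPool:
    with h5py.File(path, "r") as f:
        for ds in ("spectra", "wavenumbers", "records"):
            if ds not in f:
                raise FormatError(f"file {path} lacks required item '{ds}'")
        spectra = f["spectra"][()]
        axis = f["wavenumbers"][()]
        cols = {}
        for col in f["records"]:
            data = f["records"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
    return PixelPool(records=pd.DataFrame(cols), spectra=spectra, axis=axis)


def slice_band(values: np.ndarray, axis: np.ndarray, lo: float, hi: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Select the closed wavenumber interval [lo, hi] along the last axis.

    Returns ``(sub_values, sub_axis)`` preserving the axis order of the
    input. Raises ``ValueError`` on an empty overlap or lo > hi.
    """
    axis = np.asarray(axis, dtype=float)
    values = np.asarray(values)
    if lo > hi:
        raise ValueError(f"band interval reversed: lo={lo} > hi={hi}")
    sel = (axis >= lo) & (axis <= hi)
    if not sel.any():
        raise ValueError(
            f"band [{lo}, {hi}] cm^-1 has no overlap with axis "
            f"[{axis.min():.1f}, {axis.max():.1f}]"
        )
    return values[..., sel], axis[sel]
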