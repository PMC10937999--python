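"""Manifold-embedding outlier removal and region pooling.

Pixels are embedded in 2-D on the 1500-1700 cm^-1 band (amide I + II, the
dominant spectral region) with a neighbor-graph manifold-approximation
embedding; pixels whose mean distance to their k nearest embedding neighbors
exceeds a high percentile of that score's distribution are rejected, and
accepted/rejected masks are regrouped per sample image. On well-formed data
well over 99% of pixels sit on the manifold and survive.

The embedding optimizer is a pluggable backend: "umap" (default) or "pca"
(deterministic linear surrogate, useful for fast tests). The comparison arm
to embedding-based pooling is plain center-region pooling (the central 21x21
detector window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import PixelMask, PixelPool, slice_band

__all__ = [
    "EmbeddingResult",
    "embed_pixels",
    "outlier_mask",
    "center_region_mask",
    "morans_i",
]


@dataclass
class EmbeddingResult:
    """2-D embedding of a pixel pool plus per-pixel outlier scores."""

    coords: np.ndarray
    pixel_index: pd.DataFrame  # sample_id, row, col per embedding row
    knn_distance: np.ndarray | None = None
    accepted: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def embed_pixels(pool: PixelPool, band: tuple = (1500.0, 1700.0),
                 seed: int = 0, method: str = "umap",
                 n_neighbors: int = 15) -> EmbeddingResult:
    """Embed the pool's spectra restricted to ``band`` into 2-D, seeded.

    ``method="umap"`` uses the neighbor-graph manifold embedding;
    ``method="pca"`` substitutes the first two principal components (exactly
    deterministic and fast, with the same downstream contract).
    """
    if pool.n_pixels < 10:
        raise ValueError(
            f"embedding undefined at trivial scale ({pool.n_pixels} pixels < 10)"
        )
    X, _ = slice_band(pool.spectra, pool.axis, *band)
    X = np.asarray(X, dtype=np.float32)
    if method == "umap":
        import umap  # deferred: first import triggers jit warm-up

        nn = int(min(n_neighbors, pool.n_pixels - 1))
        reducer = umap.UMAP(
            n_components=2, n_neighbors=nn, random_state=int(seed),
            min_dist=0.1,
        )
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    elif method == "pca":
        coords = PCA(n_components=2, random_state=int(seed)).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    index = pool.records[["sample_id", "row", "col"]].copy()
    return EmbeddingResult(
        coords=coords, pixel_index=index,
        params={"band": band, "seed": seed, "method": method,
                "n_neighbors": n_neighbors},
    )


def outlier_mask(emb: EmbeddingResult, k: int = 20,
                 percentile: float = 99.5,
                 map_shape: tuple = (128, 128)) -> dict[str, PixelMask]:
    """Reject embedding-space outliers; return per-sample detector masks.

    A pixel is rejected when its mean distance to its ``k`` nearest embedding
    neighbors exceeds the ``percentile`` of that score over all pixels.
    ``emb.accepted`` and ``emb.knn_distance`` are filled in place.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    n = emb.coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} pixels, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.coords)
    dist, _ = nn.kneighbors(emb.coords)
    score = dist[:, 1:].mean(axis=1)  # drop self-distance
    cutoff = np.percentile(score, percentile)
    accepted = score <= cutoff
    emb.knn_distance = score
    emb.accepted = accepted

    masks: dict[str, PixelMask] = {}
    for sid, grp in emb.pixel_index.groupby("sample_id", sort=False):
        grid = np.zeros(map_shape, dtype=bool)
        rows = grp["row"].to_numpy()
        cols = grp["col"].to_numpy()
        grid[rows, cols] = accepted[grp.index.to_numpy()]
        masks[sid] = PixelMask(accepted=grid, provenance="pacmap")
    return masks


def center_region_mask(map_shape: tuple = (128, 128), size: int = 21
                       ) -> PixelMask:
    """Central ``size x size`` detector window (rows/cols 53-73 on 128x128).

    Offset is ``floor((edge - size) / 2)`` per axis, 0-based inclusive.
    """
    rows, cols = map_shape
    if size > rows or size > cols:
        raise ValueError(f"center window {size} exceeds map shape {map_shape}")
    r0 = (rows - size) // 2
    c0 = (cols - size) // 2
    grid = np.zeros(map_shape, dtype=bool)
    grid[r0:r0 + size, c0:c0 + size] = True
    return PixelMask(accepted=grid, provenance="center")


def morans_i(grid: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of a binary grid, rook adjacency.

    Used to verify that rejected pixels show no spatial pattern on the
    detector (I near 0 for spatially random rejection).
    """
    z = np.asarray(grid, dtype=float)
    z = z - z.mean()
    denom = (z * z).sum()
    if denom == 0:
        return 0.0
    num = 0.0
    w_sum = 0.0
    for axis in (0, 1):
        a = np.moveaxis(z, axis, 0)
        num += 2.0 * (a[:-1] * a[1:]).sum()
        w_sum += 2.0 * a[:-1].size
    n = z.size
    return float((n / w_sum) * (num / denom))
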