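"""Five-step spectral pretreatment pipeline.

Order: (1) range clipping to [900, 3600] cm^-1, (2) dead-pixel filling by
5x5 mean of live neighbors, (3) 5x5 spatial median denoising per wavenumber
channel, (4) rubber-band baseline correction (piecewise-linear baseline
through anchor-snapped support points augmented by the lower convex hull
between consecutive anchors), (5) normalization to the maximum absorbance in
the amide II region [1480, 1590] cm^-1.

Spatial filters truncate their window at the image boundary (no padding).
Steps 1-3 are map-level; steps 4-5 apply per pixel and are also exposed as
sklearn-style transformers over (n_spectra, n_points) matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import HyperspectralMap, PixelMask, slice_band

try:  # jitted hull loop; pure-python fallback keeps small inputs working
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


__all__ = [
    "PreprocessParams",
    "clip_range",
    "fill_dead_pixels",
    "median_denoise",
    "rubberband_baseline",
    "normalize_amide2",
    "preprocess_map",
    "RubberbandBaseline",
    "BandMaxNormalizer",
]


@dataclass(frozen=True)
class PreprocessParams:
    clip_window: tuple = (900.0, 3600.0)
    fill_kernel: int = 5
    median_kernel: int = 5
    dead_threshold: float = 0.1
    baseline_anchors: tuple = (3600.0, 2750.0, 1800.0, 900.0)
    anchor_halfwidth: float = 25.0
    amide2_window: tuple = (1480.0, 1590.0)
    baseline_first: bool = False  # apply baseline before median denoising

    def __post_init__(self) -> None:
        for k in (self.fill_kernel, self.median_kernel):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"spatial kernels must be odd and >= 3, got {k}")
        lo, hi = self.clip_window
        for a in self.baseline_anchors:
            if not (lo <= a <= hi):
                raise ValueError(f"baseline anchor {a} outside clip window {self.clip_window}")


# ---------------------------------------------------------------------------
# (1) range clipping
# ---------------------------------------------------------------------------

def clip_range(m: HyperspectralMap, params: PreprocessParams = PreprocessParams()
               ) -> HyperspectralMap:
    """Restrict the map to the closed clip window; idempotent."""
    cube, axis = slice_band(m.absorbance, m.axis, *params.clip_window)
    return m.with_data(cube, axis)


# ---------------------------------------------------------------------------
# (2) dead-pixel filling
# ---------------------------------------------------------------------------

def _dead_mask(cube: np.ndarray, threshold: float) -> np.ndarray:
    totals = cube.sum(axis=-1)
    return totals < threshold * np.median(totals)


def fill_dead_pixels(m: HyperspectralMap,
                     params: PreprocessParams = PreprocessParams()
                     ) -> tuple[HyperspectralMap, PixelMask]:
    """Replace dead pixels by the mean spectrum of live 5x5 neighbors.

    A pixel is dead when its total absorbance falls below ``dead_threshold``
    times the image median total. The window truncates at the boundary; a
    dead pixel whose window holds no live pixel falls back to the image-wide
    live mean. Returns the repaired map and the dead mask.
    """
    cube = m.absorbance
    rows, cols, _ = cube.shape
    if np.median(cube.sum(axis=-1)) <= 0:
        raise ValueError("all pixels are dead; map is unusable")
    dead = _dead_mask(cube, params.dead_threshold)
    if dead.all():
        raise ValueError("all pixels are dead; map is unusable")
    if not dead.any():
        return m.with_data(cube.copy()), PixelMask(dead, provenance="dead")
    out = cube.copy()
    h = params.fill_kernel // 2
    global_mean = cube[~dead].mean(axis=0)
    for r, c in np.argwhere(dead):
        r0, r1 = max(0, r - h), min(rows, r + h + 1)
        c0, c1 = max(0, c - h), min(cols, c + h + 1)
        live = ~dead[r0:r1, c0:c1]
        if live.any():
            out[r, c] = cube[r0:r1, c0:c1][live].mean(axis=0)
        else:
            out[r, c] = global_mean
    return m.with_data(out), PixelMask(dead, provenance="dead")


# ---------------------------------------------------------------------------
# (3) spatial median denoising
# ---------------------------------------------------------------------------

def median_denoise(m: HyperspectralMap,
                   params: PreprocessParams = PreprocessParams()
                   ) -> HyperspectralMap:
    """Per-channel 5x5 spatial median filter, window truncated at edges."""
    cube = m.absorbance
    rows, cols, n = cube.shape
    k = params.median_kernel
    h = k // 2
    out = np.empty_like(cube)
    # NaN-pad the spatial border; after sorting, NaNs land at the window
    # tail, and the in-bounds count per position is pure geometry, so the
    # median indexes the middle of the valid sorted prefix directly (much
    # faster than nanmedian). Spectral axis chunked to bound workspace.
    rc = (np.minimum(np.arange(rows) + h + 1, rows)
          - np.maximum(np.arange(rows) - h, 0))
    cc = (np.minimum(np.arange(cols) + h + 1, cols)
          - np.maximum(np.arange(cols) - h, 0))
    counts = rc[:, None] * cc[None, :]
    i_lo = ((counts - 1) // 2)[:, :, None, None]
    i_hi = (counts // 2)[:, :, None, None]
    chunk = max(1, int(1e6 // (rows * cols)))
    pad_shape = (rows + 2 * h, cols + 2 * h)
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        padded = np.full(pad_shape + (e - s,), np.nan, dtype=cube.dtype)
        padded[h:h + rows, h:h + cols] = cube[:, :, s:e]
        win = np.lib.stride_tricks.sliding_window_view(
            padded, (k, k), axis=(0, 1)
        ).reshape(rows, cols, e - s, k * k)
        srt = np.sort(win, axis=-1)
        lo = np.take_along_axis(srt, np.broadcast_to(i_lo, srt.shape[:3] + (1,)),
                                axis=-1)[..., 0]
        hi = np.take_along_axis(srt, np.broadcast_to(i_hi, srt.shape[:3] + (1,)),
                                axis=-1)[..., 0]
        out[:, :, s:e] = 0.5 * (lo + hi)
    return m.with_data(out)


# ---------------------------------------------------------------------------
# (4) rubber-band baseline correction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lower_hull_baselines(x: np.ndarray, Y: np.ndarray, seg_idx: np.ndarray
                          ) -> np.ndarray:  # pragma: no cover - jitted
    """Piecewise-linear lower-convex-hull baseline per row of Y.

    ``x`` ascending; ``seg_idx`` are the support-point indices (ascending,
    first == segment starts, last == end). The hull is computed within each
    consecutive support-point pair so the baseline always passes through the
    support points. Outside the outer support points the baseline continues
    along the outermost hull segments (linear extrapolation), so a straight
    line is its own baseline over the whole axis.
    """
    n_spec, n = Y.shape
    out = np.empty_like(Y)
    stack = np.empty(n, np.int64)
    for p in range(n_spec):
        y = Y[p]
        base = out[p]
        base[:] = 0.0
        for s in range(len(seg_idx) - 1):
            a, b = seg_idx[s], seg_idx[s + 1]
            top = 0
            stack[0] = a
            for i in range(a + 1, b + 1):
                while top >= 1:
                    i1 = stack[top - 1]
                    i2 = stack[top]
                    cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (
                        y[i2] - y[i1]
                    ) * (x[i] - x[i1])
                    if cross <= 0.0:
                        top -= 1
                    else:
                        break
                top += 1
                stack[top] = i
            for v in range(top):
                i1, i2 = stack[v], stack[v + 1]
                slope = (y[i2] - y[i1]) / (x[i2] - x[i1])
                for i in range(i1, i2 + 1):
                    base[i] = y[i1] + slope * (x[i] - x[i1])
        lo, hi = seg_idx[0], seg_idx[-1]
        if hi > lo:
            sl = (base[lo + 1] - base[lo]) / (x[lo + 1] - x[lo])
            for i in range(lo):
                base[i] = base[lo] + sl * (x[i] - x[lo])
            sr = (base[hi] - base[hi - 1]) / (x[hi] - x[hi - 1])
            for i in range(hi + 1, n):
                base[i] = base[hi] + sr * (x[i] - x[hi])
        else:
            base[:lo] = base[lo]
            base[hi:] = base[hi]
    return out


def _rubberband_many(Y: np.ndarray, axis: np.ndarray,
                     params: PreprocessParams) -> np.ndarray:
    """Baselines for a stack of spectra (n_spectra, n_points), original order.

    Support points snap to each spectrum's own window minima; spectra sharing
    the same support-index tuple are batched into one jitted hull call.
    """
    flip = axis[0] > axis[-1]
    x = axis[::-1].copy() if flip else axis.copy()
    Ya = np.ascontiguousarray(Y[:, ::-1] if flip else Y, dtype=np.float64)
    # anchor windows are pure geometry: locate them once, then snap each
    # spectrum to its own window minima
    wins = []
    for a in sorted(params.baseline_anchors):
        sel = np.nonzero(np.abs(x - a) <= params.anchor_halfwidth)[0]
        if sel.size == 0:
            raise ValueError(f"baseline anchor {a} cm^-1 outside the axis")
        wins.append(sel)
    snapped = np.column_stack([w[np.argmin(Ya[:, w], axis=1)] for w in wins])
    groups: dict[tuple, list[int]] = {}
    for i in range(Ya.shape[0]):
        si = tuple(np.unique(snapped[i]))
        groups.setdefault(si, []).append(i)
    base = np.empty_like(Ya)
    for si, rows in groups.items():
        rows = np.asarray(rows)
        base[rows] = _lower_hull_baselines(
            x, Ya[rows], np.asarray(si, dtype=np.int64)
        )
    return base[:, ::-1] if flip else base


def rubberband_baseline(spectrum: np.ndarray, axis: np.ndarray,
                        params: PreprocessParams = PreprocessParams()
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Rubber-band baseline of one spectrum: ``(baseline, corrected)``.

    The baseline interpolates linearly through support points (the spectrum
    minimum within +-``anchor_halfwidth`` of each anchor) augmented by the
    lower convex hull of the spectrum between consecutive support points, so
    the corrected spectrum is non-negative over the anchor span and exactly
    zero for spectra that are straight lines.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    base = _rubberband_many(spectrum[None, :], np.asarray(axis, float), params)[0]
    return base, spectrum - base


# ---------------------------------------------------------------------------
# (5) amide II peak normalization
# ---------------------------------------------------------------------------

def normalize_amide2(spectrum: np.ndarray, axis: np.ndarray,
                     params: PreprocessParams = PreprocessParams()
                     ) -> np.ndarray:
    """Divide by the maximum absorbance in the amide II window.

    Raises ``ValueError`` for degenerate pixels whose window maximum is not
    positive (such pixels are dropped by map-level callers).
    """
    sub, _ = slice_band(np.asarray(spectrum, float), axis, *params.amide2_window)
    peak = float(np.max(sub))
    if peak <= 0:
        raise ValueError(
            f"degenerate pixel: amide II window maximum {peak:.3g} is not positive"
        )
    return np.asarray(spectrum, float) / peak


def _normalize_many(Y: np.ndarray, axis: np.ndarray, params: PreprocessParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    sub, _ = slice_band(Y, axis, *params.amide2_window)
    peaks = sub.max(axis=-1)
    good = peaks > 0
    out = np.zeros_like(Y, dtype=float)
    out[good] = Y[good] / peaks[good][..., None]
    return out, good


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_map(m: HyperspectralMap,
                   params: PreprocessParams = PreprocessParams(),
                   return_info: bool = False):
    """Run the five pretreatment steps on one map in the fixed order.

    Returns the processed map; with ``return_info=True`` also a dict holding
    the dead-pixel mask and the boolean grid of pixels that survived
    normalization (degenerate pixels are zeroed and flagged).
    """
    m1 = clip_range(m, params)
    m2, dead = fill_dead_pixels(m1, params)
    if params.baseline_first:
        flat = m2.absorbance.reshape(-1, m2.axis.size)
        base = _rubberband_many(flat, m2.axis, params)
        m3 = median_denoise(m2.with_data(
            (flat - base).reshape(m2.absorbance.shape)), params)
        corrected = m3.absorbance.reshape(-1, m3.axis.size)
    else:
        m3 = median_denoise(m2, params)
        flat = m3.absorbance.reshape(-1, m3.axis.size)
        base = _rubberband_many(flat, m3.axis, params)
        corrected = flat - base
    normed, good = _normalize_many(corrected, m3.axis, params)
    out = m3.with_data(normed.reshape(m3.absorbance.shape).astype(float))
    if return_info:
        info = {
            "dead": dead,
            "normalized_ok": good.reshape(m3.absorbance.shape[:2]),
            "params": params,
        }
        return out, info
    return out


# ---------------------------------------------------------------------------
# sklearn-style transformers over (n_spectra, n_points) matrices
# ---------------------------------------------------------------------------

class RubberbandBaseline(TransformerMixin, BaseEstimator):
    """Rubber-band baseline correction as a stateless sklearn transformer.

    Parameters
    ----------
    axis : array-like
        Wavenumber axis matching the feature columns.
    anchors : tuple of float
        Baseline anchor wavenumbers (cm^-1).
    anchor_halfwidth : float
        Snapping half-window around each anchor (cm^-1).
    """

    def __init__(self, axis=None, anchors=(3600.0, 2750.0, 1800.0, 900.0),
                 anchor_halfwidth=25.0):
        self.axis = axis
        self.anchors = anchors
        self.anchor_halfwidth = anchor_halfwidth

    def _params(self) -> PreprocessParams:
        lo = min(min(self.anchors), float(np.min(self.axis)))
        hi = max(max(self.anchors), float(np.max(self.axis)))
        return PreprocessParams(
            clip_window=(lo, hi), baseline_anchors=tuple(self.anchors),
            anchor_halfwidth=self.anchor_halfwidth,
        )

    def fit(self, X, y=None):
        if self.axis is None:
            raise ValueError("axis must be provided")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(np.asarray(self.axis)):
            raise ValueError("X must be (n_spectra, n_points) matching axis")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        base = _rubberband_many(X, np.asarray(self.axis, float), self._params())
        return X - base


class BandMaxNormalizer(TransformerMixin, BaseEstimator):
    """Divide each spectrum by its maximum within a wavenumber window.

    Default window is the amide II region [1480, 1590] cm^-1.
    """

    def __init__(self, axis=None, window=(1480.0, 1590.0)):
        self.axis = axis
        self.window = window

    def fit(self, X, y=None):
        if self.axis is None:
            raise ValueError("axis must be provided")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        sub, _ = slice_band(X, np.asarray(self.axis, float), *self.window)
        peaks = sub.max(axis=-1)
        if np.any(peaks <= 0):
            raise ValueError(
                f"{int((peaks <= 0).sum())} degenerate spectra with non-positive "
                "window maximum"
            )
        return X / peaks[:, None]
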