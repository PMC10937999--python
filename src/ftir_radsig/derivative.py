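"""Savitzky-Golay second-derivative spectroscopy and biomarker peak analysis.

Second derivatives are taken with respect to wavenumber using the actual
axis spacing, so intensities are comparable across clip settings. The sign
convention is the standard one: an absorbance maximum appears as a
second-derivative minimum at the same position, which is why biomarker
"peaks" are located as local minima. Samples where the SG window would be
truncated (the first and last half-window points) are marked invalid (NaN)
rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .io import PixelPool
from .synth import PeakRecord

__all__ = [
    "DerivParams",
    "second_derivative",
    "SecondDerivative",
    "group_mean_spectra",
    "difference_spectrum",
    "peak_minima",
    "peak_shift",
    "peak_table",
]

#: relative tolerance on axis-spacing uniformity
_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class DerivParams:
    """SG filter settings; window 5 / polyorder 3 is the standard choice for
    a second derivative at this spectral sampling."""

    window_length: int = 5
    polyorder: int = 3
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if not (self.window_length > self.polyorder >= self.deriv_order):
            raise ValueError(
                f"need window_length > polyorder >= deriv_order, got "
                f"{self.window_length}/{self.polyorder}/{self.deriv_order}"
            )
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")


def _uniform_spacing(axis: np.ndarray) -> float:
    d = np.diff(np.asarray(axis, float))
    if d.size == 0:
        raise ValueError("axis too short")
    if np.max(np.abs(d - d[0])) > _SPACING_RTOL * abs(d[0]):
        raise ValueError("axis spacing is not uniform within tolerance")
    return float(d[0])


def second_derivative(spectrum: np.ndarray, axis: np.ndarray,
                      params: DerivParams = DerivParams()) -> np.ndarray:
    """SG second derivative w.r.t. wavenumber; edge samples set to NaN.

    Works on a single spectrum or a stack (derivative along the last axis).
    """
    delta = _uniform_spacing(axis)
    out = savgol_filter(
        np.asarray(spectrum, float),
        window_length=params.window_length,
        polyorder=params.polyorder,
        deriv=params.deriv_order,
        delta=abs(delta),
        axis=-1,
        mode="interp",
    )
    h = params.window_length // 2
    out[..., :h] = np.nan
    out[..., -h:] = np.nan
    return out


class SecondDerivative(TransformerMixin, BaseEstimator):
    """SG second derivative as an sklearn transformer over spectra rows."""

    def __init__(self, axis=None, window_length=5, polyorder=3):
        self.axis = axis
        self.window_length = window_length
        self.polyorder = polyorder

    def fit(self, X, y=None):
        if self.axis is None:
            raise ValueError("axis must be provided")
        _uniform_spacing(self.axis)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return second_derivative(
            np.asarray(X, float), np.asarray(self.axis, float),
            DerivParams(self.window_length, self.polyorder),
        )


def group_mean_spectra(pool: PixelPool, group_key: str = "dose_gy",
                       binary: bool = False) -> dict:
    """Arithmetic mean spectrum per group of pixels.

    ``binary=True`` collapses dose groups into control (0 Gy) vs exposed
    (> 0 Gy), keyed "control"/"exposed".
    """
    if binary:
        labels = np.where(pool.records["dose_gy"].to_numpy() > 0,
                          "exposed", "control")
    else:
        labels = pool.records[group_key].to_numpy()
    out = {}
    for g in pd.unique(labels):
        sel = labels == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        out[g] = pool.spectra[sel].mean(axis=0)
    if not out:
        raise ValueError("no groups present")
    return out


def difference_spectrum(mean_treated: np.ndarray, mean_control: np.ndarray,
                        negate: bool = False) -> np.ndarray:
    """treated - control; multiplied by -1 when ``negate`` (display only)."""
    mean_treated = np.asarray(mean_treated, float)
    mean_control = np.asarray(mean_control, float)
    if mean_treated.shape != mean_control.shape:
        raise ValueError("mean spectra shapes differ")
    d = mean_treated - mean_control
    return -d if negate else d


def _local_minima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima of a 1-D array with NaNs."""
    good = np.isfinite(y)
    idx = []
    for i in range(1, y.size - 1):
        if not (good[i - 1] and good[i] and good[i + 1]):
            continue
        if y[i] <= y[i - 1] and y[i] <= y[i + 1] and (
            y[i] < y[i - 1] or y[i] < y[i + 1]
        ):
            idx.append(i)
    return np.asarray(idx, dtype=int)


def peak_minima(second_deriv: np.ndarray, axis: np.ndarray,
                records, search_halfwidth: float = 10.0) -> pd.DataFrame:
    """Locate each biomarker band as a second-derivative local minimum.

    For every record the deepest local minimum within
    +-``search_halfwidth`` cm^-1 of the nominal position is reported with its
    intensity (value at the minimum) and peak-to-peak amplitude (mean of the
    two flanking local maxima minus the minimum). Records with no local
    minimum in the window are flagged ``found=False`` rather than failing.
    """
    y = np.asarray(second_deriv, float)
    axis = np.asarray(axis, float)
    minima = _local_minima(y)
    maxima = _local_minima(-y)
    rows = []
    for rec in records:
        pos = rec.position if isinstance(rec, PeakRecord) else float(rec)
        cand = minima[np.abs(axis[minima] - pos) <= search_halfwidth]
        row = {
            "peak_number": getattr(rec, "peak_number", None),
            "nominal_cm1": pos,
            "assignment": getattr(rec, "assignment", ""),
            "found": cand.size > 0,
            "found_cm1": np.nan,
            "intensity": np.nan,
            "peak_to_peak": np.nan,
        }
        if cand.size:
            i = cand[np.argmin(y[cand])]
            row["found_cm1"] = axis[i]
            row["intensity"] = y[i]
            left = maxima[maxima < i]
            right = maxima[maxima > i]
            flank = [y[left[-1]]] if left.size else []
            flank += [y[right[0]]] if right.size else []
            if flank:
                row["peak_to_peak"] = float(np.mean(flank) - y[i])
        rows.append(row)
    return pd.DataFrame(rows)


def peak_shift(control_spectrum: np.ndarray, treated_spectrum: np.ndarray,
               axis: np.ndarray, record, search_halfwidth: float = 10.0
               ) -> float:
    """Signed band-position shift (treated minimum minus control minimum).

    Both inputs are second-derivative spectra. Raises if either side has no
    local minimum within the search window of the record's nominal position.
    """
    found = []
    for spec, side in ((control_spectrum, "control"),
                       (treated_spectrum, "treated")):
        df = peak_minima(spec, axis, [record], search_halfwidth)
        if not df["found"].iloc[0]:
            raise ValueError(
                f"no local minimum near {record.position} cm^-1 in the "
                f"{side} spectrum"
            )
        found.append(df["found_cm1"].iloc[0])
    return float(found[1] - found[0])


def peak_table(pool: PixelPool, records, params: DerivParams = DerivParams(),
               search_halfwidth: float = 10.0) -> pd.DataFrame:
    """Biomarker table from a preprocessed pixel pool.

    Mean control and exposed spectra are second-derivative transformed; for
    each record the exposed-side minimum position/intensity, the
    control-relative intensity change, and the position shift are reported.
    """
    means = group_mean_spectra(pool, binary=True)
    if "control" not in means or "exposed" not in means:
        raise ValueError("pool must contain both control and exposed pixels")
    d_ctrl = second_derivative(means["control"], pool.axis, params)
    d_trt = second_derivative(means["exposed"], pool.axis, params)
    ctrl = peak_minima(d_ctrl, pool.axis, records, search_halfwidth)
    trt = peak_minima(d_trt, pool.axis, records, search_halfwidth)
    out = trt.rename(columns={
        "found_cm1": "exposed_cm1", "intensity": "exposed_intensity",
        "peak_to_peak": "exposed_peak_to_peak",
    })
    out["control_cm1"] = ctrl["found_cm1"]
    out["control_intensity"] = ctrl["intensity"]
    out["control_peak_to_peak"] = ctrl["peak_to_peak"]
    out["delta_intensity"] = out["exposed_intensity"] - out["control_intensity"]
    out["shift_cm1"] = out["exposed_cm1"] - out["control_cm1"]
    out["found"] = ctrl["found"] & trt["found"]
    return out
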