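"""Pixel quality control for hyperspectral maps.

Three-stage filter applied independently per detector pixel on raw spectra:

1. amide signal-to-noise ratio must reach ``snr_threshold`` (default 200),
2. amide / CO2 signal ratio must reach ``co2_ratio_threshold`` (default 15),
3. if more than ``pixel_cap`` pixels survive, keep the ``pixel_cap`` pixels
   with the lowest noise level (default cap 100).

"Amide signal" is the maximum absorbance in the amide I window [1600, 1700]
cm^-1 (the dominant band, so the SNR is best-case); the noise level is the
standard deviation in the spectrally quiet [1800, 2300] cm^-1 region; the CO2
signal is the maximum in [2300, 2400] cm^-1. All windows are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HyperspectralMap, PixelMask, slice_band

__all__ = ["QCParams", "amide_signal", "noise_level", "co2_signal",
           "qc_mask", "rank_and_cap", "qc_map"]

#: denominators at or below this are treated as absent (ratio passes)
_EPS = 1e-12


@dataclass(frozen=True)
class QCParams:
    snr_threshold: float = 200.0
    co2_ratio_threshold: float = 15.0
    pixel_cap: int = 100
    amide_window: tuple = (1600.0, 1700.0)
    co2_window: tuple = (2300.0, 2400.0)
    noise_window: tuple = (1800.0, 2300.0)

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0 or self.co2_ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.pixel_cap < 1:
            raise ValueError("pixel_cap must be >= 1")


def amide_signal(spectrum: np.ndarray, axis: np.ndarray,
                 params: QCParams = QCParams()) -> float:
    """Maximum absorbance within the amide window."""
    sub, _ = slice_band(spectrum, axis, *params.amide_window)
    return float(np.max(sub))


def noise_level(spectrum: np.ndarray, axis: np.ndarray,
                params: QCParams = QCParams()) -> float:
    """Standard deviation of absorbance within the noise-signature window."""
    sub, _ = slice_band(spectrum, axis, *params.noise_window)
    if sub.shape[-1] < 3:
        raise ValueError(
            f"noise window {params.noise_window} holds fewer than 3 axis points"
        )
    return float(np.std(sub))


def co2_signal(spectrum: np.ndarray, axis: np.ndarray,
               params: QCParams = QCParams()) -> float:
    """Maximum absorbance within the CO2 window."""
    sub, _ = slice_band(spectrum, axis, *params.co2_window)
    return float(np.max(sub))


def _pixel_stats(m: HyperspectralMap, params: QCParams):
    """(amide, noise, co2) images, vectorized over pixels."""
    cube, axis = m.absorbance, m.axis
    amide, _ = slice_band(cube, axis, *params.amide_window)
    noise, _ = slice_band(cube, axis, *params.noise_window)
    if noise.shape[-1] < 3:
        raise ValueError(
            f"noise window {params.noise_window} holds fewer than 3 axis points"
        )
    co2, _ = slice_band(cube, axis, *params.co2_window)
    return amide.max(axis=-1), noise.std(axis=-1), co2.max(axis=-1)


def qc_mask(m: HyperspectralMap, params: QCParams = QCParams()) -> PixelMask:
    """Accept pixels passing both the SNR and the amide/CO2 ratio filter.

    A vanishing noise level with positive amide signal passes the SNR test
    (absence of noise is not a defect); likewise a vanishing CO2 signal
    passes the contamination test. A pixel with no amide signal fails.
    """
    amide, noise, co2 = _pixel_stats(m, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_ok = np.where(
            noise > _EPS, amide / np.maximum(noise, _EPS) >= params.snr_threshold,
            amide > _EPS,
        )
        co2_ok = np.where(
            co2 > _EPS, amide / np.maximum(co2, _EPS) >= params.co2_ratio_threshold,
            amide > _EPS,
        )
    return PixelMask(accepted=snr_ok & co2_ok, provenance="qc")


def rank_and_cap(m: HyperspectralMap, mask: PixelMask,
                 params: QCParams = QCParams()) -> PixelMask:
    """Keep at most ``pixel_cap`` accepted pixels, lowest noise level first.

    Ties at the cap boundary break by (row, col) lexicographic order, so the
    result is deterministic. With at most ``pixel_cap`` accepted pixels the
    mask is returned unchanged apart from provenance.
    """
    if mask.n_accepted <= params.pixel_cap:
        return PixelMask(accepted=mask.accepted.copy(), provenance="qc+cap")
    _, noise, _ = _pixel_stats(m, params)
    idx = np.argwhere(mask.accepted)  # row-major => (row, col) lexicographic
    order = np.argsort(noise[idx[:, 0], idx[:, 1]], kind="stable")
    keep = idx[order[: params.pixel_cap]]
    out = np.zeros_like(mask.accepted)
    out[keep[:, 0], keep[:, 1]] = True
    return PixelMask(accepted=out, provenance="qc+cap")


def qc_map(m: HyperspectralMap, params: QCParams = QCParams()
           ) -> tuple[PixelMask, dict]:
    """Full per-image QC: filter then rank-and-cap; returns mask + counts."""
    raw = qc_mask(m, params)
    capped = rank_and_cap(m, raw, params)
    summary = {
        "sample_id": m.meta.get("sample_id"),
        "n_accepted_raw": raw.n_accepted,
        "n_retained": capped.n_accepted,
    }
    return capped, summary
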