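"""Seeded synthetic ATR-FPA hyperspectral cohort generator.

Emulates the statistical structure of in-vivo mouse-ear ATR-FTIR imaging
cohorts: Gaussian absorption bands at the canonical biomolecular positions
(amide I/II dominant), smooth scattering baselines, an atmospheric CO2 band
at 2300-2400 cm^-1, dead detector pixels, heteroscedastic per-point noise,
per-animal random amplitude effects, and radiation-exposure effects — signed
band-intensity perturbations, the O-P-O band shift 1236 -> 1240 cm^-1 and the
ester carbonyl shift 1735 -> 1743 cm^-1, a flat (threshold-like) dose
response over 0.1-2 Gy, and a time-since-exposure modulation peaking at
day 14.

Effect sizes are calibrated on the second-derivative scale: a band-amplitude
change of ``delta * 1e-4 * sigma**2`` changes the analytic second derivative
of the Gaussian at its center by ``delta * 1e-4`` (in the normalized
absorbance units the downstream difference spectra are computed in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .io import HyperspectralMap

__all__ = [
    "PeakRecord",
    "SyntheticConfig",
    "TABLE_BANDS",
    "default_band_table",
    "band_sum",
    "generate_spectrum",
    "generate_map",
    "generate_cohort",
    "iter_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakRecord:
    """One biomarker band: nominal position, exposure effect, and band shape.

    ``delta_intensity`` is the exposure-induced change of the
    second-derivative peak intensity in units of 1e-4 (dimensionless, on
    amide-II-normalized spectra); ``direction`` is the sign of the intensity
    change; ``shift`` is the exposure-induced position shift in cm^-1
    (0 for no shift). ``amplitude`` and ``fwhm`` parameterize the synthetic
    Gaussian band and are generator config, not measured quantities.
    """

    peak_number: int
    position: float
    direction: str  # "up" | "down"
    shift: float
    delta_intensity: float
    assignment: str
    amplitude: float = 0.3
    fwhm: float = 20.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    @property
    def signed_delta(self) -> float:
        """Signed second-derivative intensity change (x 1e-4 units)."""
        s = 1.0 if self.direction == "up" else -1.0
        return s * self.delta_intensity


# The sixteen biomarker bands (position cm^-1, direction, shift cm^-1,
# delta-intensity x 1e-4, assignment). Amplitudes/FWHMs are synthetic-shape
# choices producing an amide-I-dominant, skin-like fingerprint once the
# spectrum is normalized to the amide II maximum.
TABLE_BANDS: tuple[PeakRecord, ...] = (
    PeakRecord(1, 2922, "up", 0, 0.3, "nu_as(C-H) of >CH2 in lipids, proteins", 0.55, 24),
    PeakRecord(2, 2851, "up", 0, 0.4, "nu_s(C-H) of >CH2 in lipids, proteins", 0.35, 20),
    PeakRecord(3, 1743, "up", 8, 0.5, "nu(C=O) of acyl groups in saturated esters", 0.25, 18),
    PeakRecord(4, 1691, "up", 0, 0.2, "Amide I; beta-turns", 0.45, 18),
    PeakRecord(5, 1648, "down", 0, 1.1, "Amide I; random coils", 1.35, 18),
    PeakRecord(6, 1626, "up", 0, 1.5, "Amide I; beta-sheets", 0.90, 18),
    PeakRecord(7, 1553, "down", 0, 0.9, "Amide II", 1.00, 30),
    PeakRecord(8, 1518, "down", 0, 0.3, "Tyrosine ring stretching", 0.50, 18),
    PeakRecord(9, 1458, "up", 0, 0.8, "delta(C-H) of CH3, CH2 in proteins, lipids", 0.45, 20),
    PeakRecord(10, 1402, "up", 0, 0.6, "nu(COO-) in proteins, lipids", 0.35, 20),
    PeakRecord(11, 1336, "down", 0, 0.3, "delta(C-H) of CH2 side chains", 0.20, 18),
    PeakRecord(12, 1236, "up", 4, 0.2, "nu_as(O-P-O) of nucleic acids", 0.45, 16),
    PeakRecord(13, 1172, "down", 0, 0.1, "nu(-CH2OH) of Ser, Thr, Tyr", 0.25, 16),
    PeakRecord(14, 1083, "down", 0, 0.5, "nu_s(O-P-O) of nucleic acids", 0.40, 18),
    PeakRecord(15, 1024, "down", 0, 0.1, "nu(C-O) of carbohydrate side chains", 0.30, 16),
    PeakRecord(16, 972, "up", 0, 0.1, "trans C=C bonds", 0.15, 14),
)

#: broad amide A / O-H, N-H stretch background band (not a biomarker row)
_AMIDE_A = (3290.0, 0.50, 220.0)  # center, amplitude, fwhm


def default_band_table() -> list[PeakRecord]:
    return list(TABLE_BANDS)


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of a synthetic cohort.

    Defaults mirror the study conditions: doses {0, 0.1, 0.5, 1, 2} Gy, days
    {5, 14, 21, 49, 90}, a 3900-900 cm^-1 axis with 4096 points, a flat
    (threshold-like) dose response and a day-effect profile peaking at 14
    days post exposure.
    """

    n_mice_per_group: int = 2
    doses: tuple = (0.0, 0.1, 0.5, 1.0, 2.0)
    days: tuple = (5, 14, 21, 49, 90)
    axis_start: float = 3900.0
    axis_end: float = 900.0
    n_points: int = 4096
    map_shape: tuple = (128, 128)
    band_table: list = field(default_factory=default_band_table)
    shift_pairs: tuple = ((1236.0, 1240.0), (1735.0, 1743.0))
    dose_response: str = "flat"  # "flat" | "linear"
    day_effect_profile: dict = field(
        default_factory=lambda: {5: 0.5, 14: 1.0, 21: 0.9, 49: 0.7, 90: 0.4}
    )
    noise_sd: float = 0.005
    het_noise_coef: float = 0.01
    baseline_params: dict = field(
        default_factory=lambda: {"offset": 0.05, "slope": 0.02, "curvature": 0.01}
    )
    dead_pixel_rate: float = 0.01
    co2_amplitude: float = 0.02
    animal_effect_sd: float = 0.05
    pixel_scale_sd: float = 0.05
    baseline_pixel_sd: float = 0.2
    train_fraction: float = 0.6
    strains: tuple = ("C57BL/6J", "BALB/cJ")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dead_pixel_rate < 1.0):
            raise ValueError("dead_pixel_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.axis_start <= self.axis_end:
            raise ValueError("axis must be descending: axis_start > axis_end")
        if self.dose_response not in ("flat", "linear"):
            raise ValueError(f"unknown dose_response {self.dose_response!r}")
        if not self.doses or not self.days:
            raise ValueError("doses and days must be non-empty")
        lo, hi = self.axis_end, self.axis_start
        for rec in self.band_table:
            for pos in self._band_positions(rec):
                if not (lo <= pos <= hi):
                    raise ValueError(
                        f"band {rec.peak_number} position {pos} cm^-1 outside "
                        f"axis [{lo}, {hi}]"
                    )

    @property
    def axis(self) -> np.ndarray:
        """Wavenumber axis, descending 3900 -> 900 cm^-1."""
        return np.linspace(self.axis_start, self.axis_end, self.n_points)

    def _band_positions(self, rec: PeakRecord) -> tuple[float, float]:
        """(control, exposed) center positions of a band.

        A band participating in a shift pair sits at the pair's first element
        in controls and at its second in exposed animals; table rows may print
        either side, so both are matched.
        """
        for ctrl, treat in self.shift_pairs:
            if rec.position in (ctrl, treat):
                return float(ctrl), float(treat)
        return float(rec.position), float(rec.position)

    def dose_multiplier(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        if self.dose_response == "flat":
            return 1.0
        return float(dose) / max(self.doses)

    def day_multiplier(self, day: int) -> float:
        return float(self.day_effect_profile.get(day, 1.0))


def _gaussians(axis: np.ndarray, centers: np.ndarray, sigmas: np.ndarray
               ) -> np.ndarray:
    """Unit-amplitude Gaussian profiles, shape (n_bands, n_points)."""
    z = (axis[None, :] - centers[:, None]) / sigmas[:, None]
    return np.exp(-0.5 * z * z)


def band_sum(config: SyntheticConfig, dose: float, day: int,
             amp_scale: float = 1.0) -> np.ndarray:
    """Analytic noise-free band mixture for one condition (closed form).

    The oracle for the generator: sum over bands of
    ``amp_scale * (A_i + dA_i) * exp(-(nu - c_i)^2 / (2 sigma_i^2))`` plus the
    broad amide A background, where ``dA_i = s_i * Delta_i*1e-4 * sigma_i^2 *
    day_mult * dose_mult`` and ``c_i`` is the control or exposed center.
    """
    axis = config.axis
    effect = config.dose_multiplier(dose) * config.day_multiplier(day)
    exposed = config.dose_multiplier(dose) > 0
    centers, sigmas, amps = [], [], []
    for rec in config.band_table:
        ctrl_pos, treat_pos = config._band_positions(rec)
        centers.append(treat_pos if exposed else ctrl_pos)
        sigmas.append(rec.sigma)
        amps.append(
            rec.amplitude + rec.signed_delta * 1e-4 * rec.sigma**2 * effect
        )
    c, a, f = _AMIDE_A
    centers.append(c)
    sigmas.append(f * _FWHM_TO_SIGMA)
    amps.append(a)
    profiles = _gaussians(axis, np.asarray(centers, float), np.asarray(sigmas, float))
    return amp_scale * (np.asarray(amps, float) @ profiles)


def _baseline(config: SyntheticConfig, scale: float = 1.0) -> np.ndarray:
    """Smooth scattering baseline: quadratic in (nu - 900)/3000."""
    p = config.baseline_params
    t = (config.axis - config.axis_end) / (config.axis_start - config.axis_end)
    return scale * (
        p.get("offset", 0.0) + p.get("slope", 0.0) * t + p.get("curvature", 0.0) * t**2
    )


_CO2_CENTER, _CO2_FWHM = 2350.0, 45.0


def _co2_profile(axis: np.ndarray) -> np.ndarray:
    z = (axis - _CO2_CENTER) / (_CO2_FWHM * _FWHM_TO_SIGMA)
    return np.exp(-0.5 * z * z)


def generate_spectrum(config: SyntheticConfig, dose: float, day: int,
                      animal_offset: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """One pixel spectrum: band mixture + baseline + noise.

    ``animal_offset`` is the per-mouse random amplitude effect (relative,
    e.g. +0.05 scales all bands by 1.05). With ``noise_sd=0``,
    ``het_noise_coef=0`` and zero baseline params the output equals
    :func:`band_sum` exactly.
    """
    if dose not in config.doses:
        raise ValueError(f"dose {dose} not among config doses {config.doses}")
    if day not in config.days:
        raise ValueError(f"day {day} not among config days {config.days}")
    clean = band_sum(config, dose, day, amp_scale=1.0 + animal_offset)
    out = clean + _baseline(config)
    if config.noise_sd > 0 or config.het_noise_coef > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sd = np.sqrt(
            config.noise_sd**2 + (config.het_noise_coef * np.abs(clean)) ** 2
        )
        out = out + rng.standard_normal(out.size) * sd
    return out


_DEAD_FACTOR_MAX = 0.05


def generate_map(config: SyntheticConfig, dose: float, day: int,
                 mouse_id: str = "m0", seed: int | None = None,
                 animal_offset: float = 0.0, split: str = "train",
                 sample_id: str | None = None,
                 strain: str | None = None) -> HyperspectralMap:
    """One synthetic detector image for a (mouse, dose, day) condition.

    Pixels share the mouse's band mixture, individually scaled by a
    multiplicative contact-quality jitter; each pixel gets its own baseline
    scale, CO2 amplitude and noise. Dead pixels (spectrum multiplied by a
    factor < 0.05) are planted uniformly at random at ``dead_pixel_rate``.
    """
    if dose not in config.doses:
        raise ValueError(f"dose {dose} not among config doses {config.doses}")
    if day not in config.days:
        raise ValueError(f"day {day} not among config days {config.days}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.map_shape
    n_px = rows * cols
    axis = config.axis

    clean = band_sum(config, dose, day, amp_scale=1.0 + animal_offset).astype(np.float32)
    base = _baseline(config).astype(np.float32)
    co2 = _co2_profile(axis).astype(np.float32)

    px_scale = (1.0 + config.pixel_scale_sd * rng.standard_normal(n_px)).astype(np.float32)
    bl_scale = (1.0 + config.baseline_pixel_sd * rng.standard_normal(n_px)).astype(np.float32)
    co2_amp = (config.co2_amplitude * rng.uniform(0.5, 1.5, n_px)).astype(np.float32)

    cube = (
        px_scale[:, None] * clean[None, :]
        + bl_scale[:, None] * base[None, :]
        + co2_amp[:, None] * co2[None, :]
    )
    if config.noise_sd > 0 or config.het_noise_coef > 0:
        sd = np.sqrt(
            config.noise_sd**2
            + (config.het_noise_coef * np.abs(px_scale[:, None] * clean[None, :])) ** 2
        ).astype(np.float32)
        cube += rng.standard_normal(cube.shape, dtype=np.float32) * sd

    if config.dead_pixel_rate > 0:
        dead = rng.random(n_px) < config.dead_pixel_rate
        if dead.any():
            cube[dead] *= rng.uniform(0.0, _DEAD_FACTOR_MAX, int(dead.sum())
                                      ).astype(np.float32)[:, None]

    meta = {
        "sample_id": sample_id or f"{mouse_id}_d{day}",
        "mouse_id": mouse_id,
        "strain": strain or config.strains[0],
        "dose_gy": float(dose),
        "day": int(day),
        "split": split,
    }
    return HyperspectralMap(cube.reshape(rows, cols, config.n_points), axis, meta)


def cohort_metadata(config: SyntheticConfig) -> pd.DataFrame:
    """Cohort design table: one row per (mouse, day) sample.

    Each mouse carries exactly one dose for all its measurement days; the
    train/test split is assigned at the mouse level (so no mouse contributes
    samples to both splits), stratified within dose groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    rows = []
    mouse_counter = 0
    for dose in config.doses:
        n = config.n_mice_per_group
        n_train = int(round(config.train_fraction * n))
        split_order = np.array(["train"] * n_train + ["test"] * (n - n_train))
        rng.shuffle(split_order)
        for i in range(n):
            mouse_id = f"m{mouse_counter:03d}"
            strain = config.strains[mouse_counter % len(config.strains)]
            for day in config.days:
                rows.append(
                    {
                        "sample_id": f"{mouse_id}_d{day}",
                        "mouse_id": mouse_id,
                        "strain": strain,
                        "dose_gy": float(dose),
                        "day": int(day),
                        "split": split_order[i],
                    }
                )
            mouse_counter += 1
    return pd.DataFrame(rows)


def _animal_offsets(config: SyntheticConfig, mouse_ids) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    return {
        m: config.animal_effect_sd * rng.standard_normal()
        for m in sorted(set(mouse_ids))
    }


def iter_cohort(config: SyntheticConfig
                ) -> Iterator[tuple[HyperspectralMap, dict]]:
    """Stream (map, metadata-row) pairs without holding the cohort in memory."""
    meta = cohort_metadata(config)
    offsets = _animal_offsets(config, meta["mouse_id"])
    for idx, row in meta.iterrows():
        map_seed = np.random.SeedSequence(
            [config.seed, 0x5A3, int(idx)]
        ).generate_state(1)[0]
        m = generate_map(
            config,
            dose=row["dose_gy"],
            day=row["day"],
            mouse_id=row["mouse_id"],
            seed=int(map_seed),
            animal_offset=offsets[row["mouse_id"]],
            split=row["split"],
            sample_id=row["sample_id"],
            strain=row["strain"],
        )
        yield m, row.to_dict()


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[list[HyperspectralMap], pd.DataFrame]:
    """Full cohort as a list of maps plus the metadata table."""
    if config.n_mice_per_group < 1:
        raise ValueError("n_mice_per_group must be >= 1")
    maps = [m for m, _ in iter_cohort(config)]
    return maps, cohort_metadata(config)
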