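"""Seeded synthetic two-layer tissue datasets: spectra, ultrasound images, truth.

The generator emulates the two study designs the analysis pipeline targets:

* a **phantom** whose bottom layer carries a patent-blue-like absorber
  (peak 635-640 nm) under a non-absorbing-at-that-band top layer whose
  thickness ramps from 0 to 15 mm across measurement locations;
* **animal tissue** with fat/muscle layer pairs whose reflectance shows the
  fat and water bands near 935, 985 and 1200 nm, with dip depths shifting
  monotonically with top-layer thickness, plus a speckled two-layer
  ultrasound image per measurement.

The optical forward model is a two-layer modified Beer-Lambert mixture: for
source-detector distance SDD the detected photons sample the top layer with
path fraction ``f = min(1, thickness / SDD)`` (sampling depth is
approximately the fiber distance), so

    R(lambda) = S(lambda) * exp(-[f*mu_top + (1-f)*mu_bot](lambda) * SDD)

with Gaussian absorption bands mu(lambda) and a smooth power-law scattering
baseline S. The bottom layer's bands vanish once the top layer is thicker
than the fiber distance. Raw detector counts add a dark offset, a
per-acquisition multiplicative gain jitter (which the 800 nm normalization
must cancel) and additive Gaussian noise; white references encode the
nominal gain exactly, so calibrating a noise-free acquisition recovers the
model reflectance.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so every generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import RawSpectrumPair
from .ultrasound import USImage

__all__ = [
    "ChromophoreBand",
    "LayerOpticalSpec",
    "SyntheticSample",
    "default_tissue_library",
    "model_reflectance",
    "simulate_spectrum",
    "simulate_us_image",
    "simulate_phantom_dataset",
    "simulate_animal_dataset",
    "DEFAULT_NOISE_SD",
    "SDD_MM",
]

#: The probe's two source-detector distances (mm).
SDD_MM = (2.0, 6.0)

#: Default relative additive detector noise (fraction of nominal gain).
DEFAULT_NOISE_SD = 0.01

#: Detector wavelength grids (1 nm sampling).
_VIS_GRID = np.arange(400.0, 1101.0, 1.0)
_NIR_GRID = np.arange(900.0, 1701.0, 1.0)
_DETECTOR_GRIDS = {"VIS": _VIS_GRID, "NIR": _NIR_GRID}
_DETECTOR_GAINS = {"VIS": 4000.0, "NIR": 3000.0}
_DARK_LEVEL = 100.0
_GAIN_JITTER_SD = 0.05

#: Animal-study top layer thickness distributions (mm): mean, SD per stratum.
ANIMAL_THICKNESS_STATS = {
    ("fat", "muscle"): (2.81, 1.90),
    ("muscle", "fat"): (3.25, 1.57),
}


@dataclass(frozen=True)
class ChromophoreBand:
    """A Gaussian absorption band: center (nm), scale (nm), strength (mm^-1)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 400.0 <= self.center_nm <= 1600.0:
            raise ValueError("center_nm must lie in [400, 1600] nm")


_LAYER_LABELS = ("fat", "muscle", "phantom_top", "phantom_bottom")


@dataclass(frozen=True)
class LayerOpticalSpec:
    """Phenomenological optics of one homogeneous layer."""

    label: str
    bands: tuple[ChromophoreBand, ...]
    scatter_amplitude: float
    scatter_slope: float

    def __post_init__(self) -> None:
        if self.label not in _LAYER_LABELS:
            raise ValueError(f"label must be one of {_LAYER_LABELS}")
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter_amplitude must be positive")

    def absorption(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Total absorption mu(lambda) in mm^-1 as a sum of Gaussian bands."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        mu = np.zeros_like(wl)
        for b in self.bands:
            mu += b.amplitude * np.exp(-0.5 * ((wl - b.center_nm) / b.width_nm) ** 2)
        return mu

    def scattering(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Smooth power-law scattering baseline, 1 at 800 nm before amplitude."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        return self.scatter_amplitude * (wl / 800.0) ** (-self.scatter_slope)


@dataclass(frozen=True)
class SyntheticSample:
    """One synthetic measurement: spectra at both fiber distances, optional US."""

    sample_id: str
    location_id: str
    thickness_mm: float
    top_label: str
    bottom_label: str
    raw: dict[tuple[str, float], RawSpectrumPair]
    us_image: USImage | None = None
    truth_boundary_row: int | None = None
    pixel_mm: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError("thickness_mm must be non-negative")
        sdds = sorted({sdd for _det, sdd in self.raw})
        if tuple(sdds) != SDD_MM:
            raise ValueError(f"expected raw spectra at SDDs {SDD_MM}, got {sdds}")
        if self.us_image is not None and self.truth_boundary_row is None:
            raise ValueError("us_image requires truth_boundary_row")


def default_tissue_library() -> dict[str, LayerOpticalSpec]:
    """Optical specs for the four layer classes.

    Band placement encodes the qualitative spectral contrasts the pipeline
    exploits: the phantom bottom absorbs at 637 nm (patent blue analogue),
    fat absorbs more strongly near 935 and 1200 nm than near 985 nm, muscle
    (water-dominated) the other way round; both share the strong ~1450 nm
    water overtone. Amplitudes are chosen so class spectra overlap but stay
    separable.
    """
    water_band = ChromophoreBand(1450.0, 40.0, 0.35)
    return {
        "fat": LayerOpticalSpec(
            "fat",
            (
                ChromophoreBand(935.0, 15.0, 0.25),
                ChromophoreBand(985.0, 12.0, 0.05),
                ChromophoreBand(1200.0, 25.0, 0.22),
                water_band,
            ),
            scatter_amplitude=1.0,
            scatter_slope=0.8,
        ),
        "muscle": LayerOpticalSpec(
            "muscle",
            (
                ChromophoreBand(935.0, 15.0, 0.06),
                ChromophoreBand(985.0, 12.0, 0.30),
                ChromophoreBand(1200.0, 25.0, 0.06),
                ChromophoreBand(1450.0, 40.0, 0.55),
            ),
            scatter_amplitude=0.9,
            scatter_slope=1.1,
        ),
        "phantom_top": LayerOpticalSpec(
            "phantom_top",
            (water_band,),
            scatter_amplitude=1.1,
            scatter_slope=1.4,
        ),
        "phantom_bottom": LayerOpticalSpec(
            "phantom_bottom",
            (ChromophoreBand(637.0, 25.0, 0.50), water_band),
            scatter_amplitude=1.0,
            scatter_slope=1.0,
        ),
    }


def model_reflectance(
    wavelengths_nm: np.ndarray,
    thickness_mm: float,
    top: LayerOpticalSpec,
    bottom: LayerOpticalSpec,
    sdd_mm: float,
) -> np.ndarray:
    """Noise- and gain-free two-layer reflectance on an arbitrary grid."""
    f = min(1.0, thickness_mm / sdd_mm)
    mu = f * top.absorption(wavelengths_nm) + (1.0 - f) * bottom.absorption(
        wavelengths_nm
    )
    scatter = f * top.scattering(wavelengths_nm) + (1.0 - f) * bottom.scattering(
        wavelengths_nm
    )
    return scatter * np.exp(-mu * sdd_mm)


def _resolve_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def simulate_spectrum(
    thickness_mm: float,
    top: LayerOpticalSpec,
    bottom: LayerOpticalSpec,
    sdd_mm: float,
    gain: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed=0,
    gain_jitter_sd: float = _GAIN_JITTER_SD,
) -> dict[str, RawSpectrumPair]:
    """Simulate one acquisition: raw VIS and NIR counts plus references.

    ``gain`` scales both detectors' nominal throughput; ``noise_sd`` is the
    additive count noise as a fraction of the nominal per-detector gain. A
    per-acquisition multiplicative gain jitter (SD ``gain_jitter_sd``) hits
    the measurement but not the white reference, emulating lamp drift
    between the reference session and the measurement.
    """
    if thickness_mm < 0:
        raise ValueError("thickness_mm must be non-negative")
    if sdd_mm not in SDD_MM:
        raise ValueError(f"sdd_mm must be one of {SDD_MM}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _resolve_rng(rng_seed)
    jitter = 1.0 + rng.normal(0.0, gain_jitter_sd) if gain_jitter_sd > 0 else 1.0
    out: dict[str, RawSpectrumPair] = {}
    for detector, grid in _DETECTOR_GRIDS.items():
        det_gain = gain * _DETECTOR_GAINS[detector]
        model = model_reflectance(grid, thickness_mm, top, bottom, sdd_mm)
        noise = rng.normal(0.0, noise_sd * det_gain, size=grid.shape) if noise_sd else 0.0
        counts = _DARK_LEVEL + det_gain * jitter * model + noise
        white = np.full_like(grid, _DARK_LEVEL + det_gain)
        dark = np.full_like(grid, _DARK_LEVEL)
        out[detector] = RawSpectrumPair(detector, float(sdd_mm), grid.copy(), counts, white, dark)
    return out


def simulate_us_image(
    thickness_mm: float,
    pixel_mm: float = 0.05,
    height_px: int = 160,
    width_px: int = 96,
    contact_row: int = 10,
    speckle_scale: float = 0.15,
    rng_seed=0,
    top_level: float = 0.35,
    bottom_level: float = 0.65,
    fibrous_rows: int = 0,
) -> tuple[USImage, int]:
    """Two-layer B-mode-like image with a contact stripe and a boundary step.

    The bright transducer contact stripe sits at ``contact_row``; the
    layer-intensity step is at ``contact_row + round(thickness_mm /
    pixel_mm)``. Multiplicative unit-mean gamma speckle with coefficient of
    variation ``speckle_scale`` is applied; ``fibrous_rows`` optionally adds
    bright horizontal streaks inside the top layer (emulating fibrous
    texture that can distract the boundary finder). Intensities are clipped
    to [0, 1]. Returns the image and the true boundary row.
    """
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    if contact_row >= height_px:
        raise ValueError("contact_row must lie inside the image")
    boundary_row = contact_row + int(round(thickness_mm / pixel_mm))
    if boundary_row >= height_px:
        raise ValueError(
            f"boundary row {boundary_row} falls outside the {height_px}-row image"
        )
    rng = _resolve_rng(rng_seed)
    img = np.empty((height_px, width_px), dtype=float)
    rows = np.arange(height_px)[:, None]
    img[:] = np.where(rows < boundary_row, top_level, bottom_level)
    img[:contact_row] = 0.05  # standoff above the transducer face
    img[contact_row : contact_row + 2] = 0.95  # bright contact stripe
    if fibrous_rows > 0 and boundary_row - contact_row > 8:
        streak_rows = rng.integers(contact_row + 4, boundary_row - 2, size=fibrous_rows)
        img[streak_rows] = np.minimum(1.0, img[streak_rows] + 0.45)
    if speckle_scale > 0:
        shape = 1.0 / speckle_scale**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return USImage(img, pixel_mm), boundary_row


def _spawn_seeds(rng_seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(rng_seed, np.random.SeedSequence):
        return rng_seed.spawn(n)
    return np.random.SeedSequence(rng_seed).spawn(n)


def simulate_phantom_dataset(
    n_locations: int = 15,
    n_orientations: int = 4,
    n_repeats: int = 3,
    thickness_range: tuple[float, float] = (0.0, 15.0),
    rng_seed=0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[SyntheticSample]:
    """Phantom study: a thickness ramp across locations, repeated acquisitions.

    ``n_locations`` measurement locations whose top-layer thickness increases
    linearly over ``thickness_range``; per location, ``n_orientations`` probe
    orientations times ``n_repeats`` repeats that differ only in their noise
    realization (defaults: 15 x 4 x 3 = 180 measurements). Phantom samples
    carry spectra only.
    """
    if min(n_locations, n_orientations, n_repeats) < 1:
        raise ValueError("all counts must be >= 1")
    library = default_tissue_library()
    top, bottom = library["phantom_top"], library["phantom_bottom"]
    thicknesses = np.linspace(thickness_range[0], thickness_range[1], n_locations)
    n_total = n_locations * n_orientations * n_repeats
    seeds = _spawn_seeds(rng_seed, n_total * len(SDD_MM))
    samples: list[SyntheticSample] = []
    i = 0
    for loc in range(n_locations):
        for orient in range(n_orientations):
            for rep in range(n_repeats):
                raw: dict[tuple[str, float], RawSpectrumPair] = {}
                for sdd in SDD_MM:
                    pair = simulate_spectrum(
                        float(thicknesses[loc]),
                        top,
                        bottom,
                        sdd,
                        noise_sd=noise_sd,
                        rng_seed=np.random.default_rng(seeds[i]),
                    )
                    raw[("VIS", sdd)] = pair["VIS"]
                    raw[("NIR", sdd)] = pair["NIR"]
                    i += 1
                samples.append(
                    SyntheticSample(
                        sample_id=f"ph_loc{loc:02d}_or{orient}_rep{rep}",
                        location_id=f"ph_loc{loc:02d}",
                        thickness_mm=float(thicknesses[loc]),
                        top_label="phantom_top",
                        bottom_label="phantom_bottom",
                        raw=raw,
                    )
                )
    return samples


def simulate_animal_dataset(
    n_per_class: int = 100,
    thickness_max: float = 6.0,
    include_zero_thickness: bool = True,
    rng_seed=0,
    noise_sd: float = DEFAULT_NOISE_SD,
    thickness_jitter_sd: float = 0.0,
    speckle_scale: float = 0.15,
    pixel_mm: float = 0.05,
) -> list[SyntheticSample]:
    """Animal study: fat-on-muscle and muscle-on-fat strata with spectra + US.

    Top-layer thicknesses are drawn per stratum from a truncated normal with
    the study means/SDs (2.81 +/- 1.90 mm for fat on muscle, 3.25 +/- 1.57 mm
    for muscle on fat), clipped to [0, ``thickness_max``); with
    ``include_zero_thickness`` the first sample of each stratum is a
    single-layer (thickness 0) measurement. Every sample is its own
    cross-validation location. ``thickness_jitter_sd`` optionally adds
    zero-mean noise to the *recorded* ground-truth thickness, emulating
    manual ultrasound thickness-reading error; the spectra and image always
    follow the true thickness.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    library = default_tissue_library()
    strata = list(ANIMAL_THICKNESS_STATS.items())
    seeds = _spawn_seeds(rng_seed, len(strata) * n_per_class)
    samples: list[SyntheticSample] = []
    for s, ((top_label, bottom_label), (mean, sd)) in enumerate(strata):
        a, b = (0.0 - mean) / sd, (thickness_max - mean) / sd
        for j in range(n_per_class):
            rng = np.random.default_rng(seeds[s * n_per_class + j])
            if include_zero_thickness and j == 0:
                thickness = 0.0
            else:
                thickness = float(
                    stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
                )
            raw: dict[tuple[str, float], RawSpectrumPair] = {}
            for sdd in SDD_MM:
                pair = simulate_spectrum(
                    thickness,
                    library[top_label],
                    library[bottom_label],
                    sdd,
                    noise_sd=noise_sd,
                    rng_seed=rng,
                )
                raw[("VIS", sdd)] = pair["VIS"]
                raw[("NIR", sdd)] = pair["NIR"]
            us, boundary_row = simulate_us_image(
                thickness,
                pixel_mm=pixel_mm,
                speckle_scale=speckle_scale,
                rng_seed=rng,
                # fat is the more echogenic, brighter layer
                top_level=0.65 if top_label == "fat" else 0.35,
                bottom_level=0.35 if top_label == "fat" else 0.65,
            )
            recorded = thickness
            if thickness_jitter_sd > 0:
                recorded = max(0.0, thickness + rng.normal(0.0, thickness_jitter_sd))
            sid = f"an_{top_label}{j:03d}"
            samples.append(
                SyntheticSample(
                    sample_id=sid,
                    location_id=sid,
                    thickness_mm=recorded,
                    top_label=top_label,
                    bottom_label=bottom_label,
                    raw=raw,
                    us_image=us,
                    truth_boundary_row=boundary_row,
                    pixel_mm=pixel_mm,
                )
            )
    return samples
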