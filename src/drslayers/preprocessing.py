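"""Calibration, stitching and normalization of dual-detector reflectance spectra.

A measurement consists of two raw spectra: a visible-range detector
(400-1100 nm) and a near-infrared detector (900-1700 nm), each with white
(Spectralon) and dark (source off) reference acquisitions. The chain

    calibrate -> stitch -> normalize_800

turns the pair into a single calibrated reflectance spectrum on the
canonical 1 nm grid 400..1599 nm (1200 points), with the 1600-1700 nm
tail discarded for its low signal-to-noise ratio and the whole spectrum
normalized to the reflectance at 800 nm, a region without significant
tissue absorption, so that global intensity (lamp/gain) differences cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CANONICAL_WAVELENGTHS_NM",
    "VIS_RANGE_NM",
    "NIR_RANGE_NM",
    "RawSpectrumPair",
    "CalibratedSpectrum",
    "CalibrationError",
    "calibrate",
    "stitch",
    "normalize_800",
    "preprocess_measurement",
]

#: Canonical wavelength grid: 400, 401, ..., 1599 nm (1200 samples).
CANONICAL_WAVELENGTHS_NM = np.arange(400.0, 1600.0, 1.0)

VIS_RANGE_NM = (400.0, 1100.0)
NIR_RANGE_NM = (900.0, 1700.0)


class CalibrationError(ValueError):
    """White and dark references coincide, or coverage/normalization fails."""


@dataclass(frozen=True)
class RawSpectrumPair:
    """Uncalibrated counts plus references for one detector at one fiber distance.

    Parameters
    ----------
    detector : {"VIS", "NIR"}
    sdd_mm : float
        Source-detector distance in mm (2 or 6 in the reference setup).
    wavelengths_nm, counts, white, dark : ndarray
        Strictly ascending wavelength grid and three conformable count arrays.
    """

    detector: str
    sdd_mm: float
    wavelengths_nm: np.ndarray
    counts: np.ndarray
    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        if self.detector not in ("VIS", "NIR"):
            raise ValueError(f"unknown detector {self.detector!r}")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending 1-D")
        for name in ("counts", "white", "dark"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} not conformable with wavelengths")


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Stitched reflectance on the canonical 1200-point grid."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sdd_mm: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.shape != CANONICAL_WAVELENGTHS_NM.shape or not np.array_equal(
            wl, CANONICAL_WAVELENGTHS_NM
        ):
            raise ValueError("spectrum must live on the canonical 400..1599 nm grid")
        if np.asarray(self.reflectance).shape != wl.shape:
            raise ValueError("reflectance not conformable with wavelengths")

    def value_at(self, wavelength_nm: float) -> float:
        idx = int(np.searchsorted(self.wavelengths_nm, wavelength_nm))
        if idx >= len(self.wavelengths_nm) or self.wavelengths_nm[idx] != wavelength_nm:
            raise KeyError(f"{wavelength_nm} nm not on the canonical grid")
        return float(self.reflectance[idx])


def calibrate(
    r_meas: np.ndarray,
    r_white: np.ndarray,
    r_dark: np.ndarray,
    wavelengths_nm: np.ndarray | None = None,
) -> np.ndarray:
    """Reference-calibrate raw counts: ``(R_meas - R_dark) / (R_white - R_dark)``.

    Raises :class:`CalibrationError` if the white and dark references coincide
    at any sample (naming the wavelength when a grid is supplied).
    """
    r_meas = np.asarray(r_meas, dtype=float)
    r_white = np.asarray(r_white, dtype=float)
    r_dark = np.asarray(r_dark, dtype=float)
    denom = r_white - r_dark
    bad = np.atleast_1d(denom == 0.0)
    if bad.any():
        where = np.flatnonzero(bad)
        if wavelengths_nm is not None:
            label = f"{np.asarray(wavelengths_nm).ravel()[where[0]]:g} nm"
        else:
            label = f"sample index {where[0]}"
        raise CalibrationError(f"white and dark references coincide at {label}")
    return (r_meas - r_dark) / denom


def stitch(
    vis_wavelengths_nm: np.ndarray,
    vis_values: np.ndarray,
    nir_wavelengths_nm: np.ndarray,
    nir_values: np.ndarray,
    sdd_mm: float,
    crossover_nm: float = 1000.0,
    rescale_nir: bool = True,
) -> CalibratedSpectrum:
    """Merge calibrated VIS and NIR spectra into one canonical-grid spectrum.

    Values below ``crossover_nm`` come from the VIS detector, values at or
    above it from the NIR detector. The NIR segment is multiplied by a single
    scalar so the two detectors agree at the crossover wavelength (the two
    spectrometers have independent throughputs), then both segments are
    linearly resampled onto the canonical grid; wavelengths >= 1600 nm are
    discarded.
    """
    vis_wl = np.asarray(vis_wavelengths_nm, dtype=float)
    nir_wl = np.asarray(nir_wavelengths_nm, dtype=float)
    vis_v = np.asarray(vis_values, dtype=float)
    nir_v = np.asarray(nir_values, dtype=float)

    lo, hi = CANONICAL_WAVELENGTHS_NM[0], CANONICAL_WAVELENGTHS_NM[-1]
    if vis_wl[0] > lo or vis_wl[-1] < crossover_nm:
        raise CalibrationError(
            f"VIS detector does not cover [{lo:g}, {crossover_nm:g}] nm"
        )
    if nir_wl[0] > crossover_nm or nir_wl[-1] < hi:
        raise CalibrationError(
            f"NIR detector does not cover [{crossover_nm:g}, {hi:g}] nm"
        )

    if rescale_nir:
        vis_at = float(np.interp(crossover_nm, vis_wl, vis_v))
        nir_at = float(np.interp(crossover_nm, nir_wl, nir_v))
        if nir_at == 0.0:
            raise CalibrationError("NIR reflectance is zero at the crossover")
        nir_v = nir_v * (vis_at / nir_at)

    grid = CANONICAL_WAVELENGTHS_NM
    out = np.empty_like(grid)
    below = grid < crossover_nm
    out[below] = np.interp(grid[below], vis_wl, vis_v)
    out[~below] = np.interp(grid[~below], nir_wl, nir_v)
    return CalibratedSpectrum(grid.copy(), out, float(sdd_mm))


def normalize_800(spec: CalibratedSpectrum) -> CalibratedSpectrum:
    """Divide the spectrum by its value at the 800 nm grid point."""
    ref = spec.value_at(800.0)
    if ref == 0.0:
        raise CalibrationError("reflectance at 800 nm is zero; cannot normalize")
    return CalibratedSpectrum(
        spec.wavelengths_nm.copy(), spec.reflectance / ref, spec.sdd_mm
    )


def preprocess_measurement(
    vis: RawSpectrumPair,
    nir: RawSpectrumPair,
    crossover_nm: float = 1000.0,
    rescale_nir: bool = True,
) -> CalibratedSpectrum:
    """Full chain: calibrate both detectors, stitch, and 800 nm-normalize."""
    if vis.detector != "VIS" or nir.detector != "NIR":
        raise ValueError("expected one VIS and one NIR raw spectrum, in that order")
    if vis.sdd_mm != nir.sdd_mm:
        raise ValueError("detector pair must share the source-detector distance")
    vis_cal = calibrate(vis.counts, vis.white, vis.dark, vis.wavelengths_nm)
    nir_cal = calibrate(nir.counts, nir.white, nir.dark, nir.wavelengths_nm)
    stitched = stitch(
        vis.wavelengths_nm,
        vis_cal,
        nir.wavelengths_nm,
        nir_cal,
        sdd_mm=vis.sdd_mm,
        crossover_nm=crossover_nm,
        rescale_nir=rescale_nir,
    )
    return normalize_800(stitched)
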