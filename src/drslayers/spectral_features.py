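"""Spectral feature extraction: dip-to-peak heights and dyadic wavelet coefficients.

Two complementary reductions of the 1200-point reflectance spectrum:

* **Peak features** — max-minus-min reflectance in three fixed windows that
  bracket the fat/water absorption bands at 935, 985 and 1200 nm
  (920-960, 960-1150 and 1150-1325 nm). Three values per fiber distance.
* **Wavelet features** — the level-6 approximation of a dyadic wavelet
  decomposition (8-tap Symlet low-pass filter, symmetric boundary,
  decimation by 2 per level), a 25-coefficient coarse sketch of the whole
  spectrum.

Concatenating both fiber distances (2 mm first, then 6 mm) yields the
6-feature peak set or the 50-feature wavelet set used by the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocessing import CalibratedSpectrum

__all__ = [
    "PEAK_WINDOWS_NM",
    "WAVELET_NAME",
    "WAVELET_LEVELS",
    "FeatureVector",
    "peak_features",
    "wavelet_features",
    "combine_features",
    "wavelet_approx_length",
]

#: (window name, low nm, high nm), endpoints inclusive; ordered by band center.
PEAK_WINDOWS_NM = (
    ("peak935", 920.0, 960.0),
    ("peak985", 960.0, 1150.0),
    ("peak1200", 1150.0, 1325.0),
)

WAVELET_NAME = "sym4"  # its scaling (low-pass) filter has 8 taps
WAVELET_LEVELS = 6


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values from one extraction method (or a concatenation).

    ``method`` is one of ``peaks | wavelet | ultrasound | combined``.
    """

    method: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(self.names) != vals.shape[0]:
            raise ValueError("names and values must have equal length")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def peak_features(spec: CalibratedSpectrum) -> FeatureVector:
    """Dip-to-peak heights in the three fat/water band windows.

    For each window the feature is ``max - min`` of the reflectance over all
    canonical grid points with window_lo <= wavelength <= window_hi. Order:
    935-region, 985-region, 1200-region.
    """
    wl = spec.wavelengths_nm
    r = spec.reflectance
    names, vals = [], []
    sdd_tag = f"sdd{spec.sdd_mm:g}"
    for name, lo, hi in PEAK_WINDOWS_NM:
        sel = (wl >= lo) & (wl <= hi)
        window = r[sel]
        names.append(f"{name}_{sdd_tag}")
        vals.append(float(window.max() - window.min()))
    return FeatureVector("peaks", tuple(names), np.array(vals))


def wavelet_approx_length(n: int, filter_len: int = 8, levels: int = WAVELET_LEVELS) -> int:
    """Output length of the level-``levels`` approximation for an ``n``-sample input.

    Per level, symmetric-extension convolution with an ``filter_len``-tap
    filter followed by decimation by 2 maps a length-n signal to
    ``floor((n + filter_len - 1) / 2)`` coefficients.
    """
    for _ in range(levels):
        n = (n + filter_len - 1) // 2
    return n


def wavelet_features(spec: CalibratedSpectrum) -> FeatureVector:
    """Level-6 dyadic wavelet approximation (25 coefficients on the 1200 grid).

    Each level convolves the previous approximation with the 8-tap Symlet
    scaling filter under half-sample symmetric extension and decimates by 2;
    the chain for a 1200-sample spectrum is 1200 -> 603 -> 305 -> 156 -> 81
    -> 44 -> 25.
    """
    approx = np.asarray(spec.reflectance, dtype=float)
    if wavelet_approx_length(len(approx)) < 1:
        raise ValueError(f"input of length {len(approx)} too short for 6 levels")
    for _ in range(WAVELET_LEVELS):
        approx, _detail = pywt.dwt(approx, WAVELET_NAME, mode="symmetric")
    sdd_tag = f"sdd{spec.sdd_mm:g}"
    names = tuple(f"wav{i:02d}_{sdd_tag}" for i in range(len(approx)))
    return FeatureVector("wavelet", names, approx)


def combine_features(f_2mm: FeatureVector, f_6mm: FeatureVector) -> FeatureVector:
    """Concatenate same-method feature vectors from the 2 mm and 6 mm distances."""
    if f_2mm.method != f_6mm.method:
        raise ValueError(
            f"cannot combine methods {f_2mm.method!r} and {f_6mm.method!r}"
        )
    return FeatureVector(
        f_2mm.method,
        f_2mm.names + f_6mm.names,
        np.concatenate([f_2mm.values, f_6mm.values]),
    )
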