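"""Named experiment arms: featurize a dataset and run the evaluation protocols.

An *arm* names one end-to-end analysis: which samples (phantom ramp, one
animal stratum, or all animal samples), which feature set (peak heights,
wavelet coefficients, ultrasound descriptor, their concatenations, or the
full 1200-wavelength spectrum) and which model/protocol (linear SVR or
exponential-kernel GPR thickness regression; quadratic-SVM layer
classification). Regression arms on animal tissue run per stratum — the
fat-on-muscle and muscle-on-fat pairings are modeled separately — mirroring
how a surgeon-facing system would know which tissue pair it is probing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modeling import (
    ClassificationReport,
    CVConfig,
    RegressionReport,
    StudyTable,
    run_classification,
    run_regression,
)
from .preprocessing import CalibratedSpectrum, preprocess_measurement
from .spectral_features import FeatureVector, combine_features, peak_features, wavelet_features
from .synthetic import SDD_MM, SyntheticSample
from .ultrasound import us_features

__all__ = [
    "preprocess_sample",
    "build_study_table",
    "list_arms",
    "run_arm",
    "FEATURE_METHODS",
]

FEATURE_METHODS = (
    "peaks",
    "wavelet",
    "peaks+us",
    "wavelet+us",
    "us",
    "full_spectrum_sdd2",
    "full_spectrum_sdd6",
)


def preprocess_sample(
    sample: SyntheticSample, crossover_nm: float = 1000.0, rescale_nir: bool = True
) -> dict[float, CalibratedSpectrum]:
    """Calibrate/stitch/normalize both fiber distances of one measurement."""
    return {
        sdd: preprocess_measurement(
            sample.raw[("VIS", sdd)],
            sample.raw[("NIR", sdd)],
            crossover_nm=crossover_nm,
            rescale_nir=rescale_nir,
        )
        for sdd in SDD_MM
    }


def _spectral_vector(
    spectra: dict[float, CalibratedSpectrum], extractor
) -> FeatureVector:
    f2, f6 = (extractor(spectra[sdd]) for sdd in SDD_MM)
    return combine_features(f2, f6)


def _full_spectrum_vector(spec: CalibratedSpectrum) -> FeatureVector:
    names = tuple(f"wl{int(w):04d}_sdd{spec.sdd_mm:g}" for w in spec.wavelengths_nm)
    return FeatureVector("combined", names, spec.reflectance)


def features_for_sample(sample: SyntheticSample, method: str) -> FeatureVector:
    """One sample's feature vector for a named feature method."""
    if method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {method!r}; choose from {FEATURE_METHODS}")
    if method.startswith("full_spectrum"):
        sdd = float(method.removeprefix("full_spectrum_sdd"))
        return _full_spectrum_vector(preprocess_sample(sample)[sdd])
    if method == "us":
        if sample.us_image is None:
            raise ValueError(f"sample {sample.sample_id} has no ultrasound image")
        return us_features(sample.us_image)
    base = method.removesuffix("+us")
    spectra = preprocess_sample(sample)
    extractor = peak_features if base == "peaks" else wavelet_features
    vec = _spectral_vector(spectra, extractor)
    if method.endswith("+us"):
        usv = us_features(sample.us_image)
        vec = FeatureVector(
            "combined", vec.names + usv.names, np.concatenate([vec.values, usv.values])
        )
    return vec


def build_study_table(samples: list[SyntheticSample], method: str) -> StudyTable:
    """Featurize a sample list into the table the evaluation protocols consume."""
    rows = []
    names: tuple[str, ...] | None = None
    for s in samples:
        vec = features_for_sample(s, method)
        if names is None:
            names = vec.names
        elif vec.names != names:
            raise ValueError("inconsistent feature names across samples")
        row = {
            "sample_id": s.sample_id,
            "location_id": s.location_id,
            "thickness_mm": s.thickness_mm,
            "top_label": s.top_label,
            "bottom_label": s.bottom_label,
        }
        row.update(vec.as_dict())
        rows.append(row)
    assert names is not None
    return StudyTable(pd.DataFrame(rows), names)


def _stratum(samples: list[SyntheticSample], top_label: str) -> list[SyntheticSample]:
    return [s for s in samples if s.top_label == top_label]


def _regression_row(name: str, stratum: str, rep: RegressionReport) -> dict:
    return {
        "arm": name,
        "stratum": stratum,
        "model": rep.model,
        "mean_abs_error_mm": rep.mean_abs_error,
        "sd_abs_error_mm": rep.sd_abs_error,
        "bland_altman_bias_mm": rep.bias,
        "bland_altman_lower_mm": rep.lower_loa,
        "bland_altman_upper_mm": rep.upper_loa,
        "n_samples": rep.n_samples,
        "n_iterations": rep.n_iterations,
    }


def _classification_row(name: str, rep: ClassificationReport) -> dict:
    return {
        "arm": name,
        "layer": rep.layer,
        "positive_label": rep.positive_label,
        "accuracy": rep.accuracy,
        "mcc": rep.mcc,
        "auc": rep.auc,
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "n_samples": rep.n_samples,
        "n_iterations": rep.n_iterations,
    }


_REGRESSION_FEATURES = {
    "peaks": "peaks",
    "wavelet": "wavelet",
    "peaks_us": "peaks+us",
    "wavelet_us": "wavelet+us",
    "us": "us",
}
_REGRESSION_MODELS = {"linsvm": "linear_svm", "gpr": "exponential_gpr"}


def list_arms() -> list[str]:
    """All runnable experiment arm names."""
    arms = ["phantom_gpr_full_spectrum"]
    arms += [
        f"animal_{feat}_{model}"
        for feat in _REGRESSION_FEATURES
        for model in _REGRESSION_MODELS
    ]
    arms += [
        f"classify_layer{layer}_{feat}" for layer in (1, 2) for feat in ("peaks", "wavelet")
    ]
    return arms


def run_arm(
    name: str, samples: list[SyntheticSample], cv: CVConfig = CVConfig()
) -> pd.DataFrame:
    """Execute one named arm end-to-end; returns one report row per sub-experiment."""
    if name == "phantom_gpr_full_spectrum":
        rows = []
        for sdd in SDD_MM:
            table = build_study_table(samples, f"full_spectrum_sdd{sdd:g}")
            rep = run_regression(table, "exponential_gpr", cv)
            rows.append(_regression_row(name, f"sdd{sdd:g}", rep))
        return pd.DataFrame(rows)

    if name.startswith("animal_"):
        stem = name.removeprefix("animal_")
        feat_key, _, model_key = stem.rpartition("_")
        if feat_key not in _REGRESSION_FEATURES or model_key not in _REGRESSION_MODELS:
            raise ValueError(f"unknown arm {name!r}; valid arms: {list_arms()}")
        method = _REGRESSION_FEATURES[feat_key]
        model = _REGRESSION_MODELS[model_key]
        rows = []
        for top in ("fat", "muscle"):
            table = build_study_table(_stratum(samples, top), method)
            rep = run_regression(table, model, cv)
            rows.append(_regression_row(name, f"{top}_on_top", rep))
        return pd.DataFrame(rows)

    if name.startswith("classify_layer"):
        stem = name.removeprefix("classify_layer")
        layer_num, _, feat = stem.partition("_")
        if layer_num not in ("1", "2") or feat not in ("peaks", "wavelet"):
            raise ValueError(f"unknown arm {name!r}; valid arms: {list_arms()}")
        table = build_study_table(samples, feat)
        rep = run_classification(
            table, layer="first" if layer_num == "1" else "second", cv=cv
        )
        return pd.DataFrame([_classification_row(name, rep)])

    raise ValueError(f"unknown arm {name!r}; valid arms: {list_arms()}")
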