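"""On-disk dataset layout: spectra CSVs, reference CSV, ultrasound PNGs, manifest.

A generated dataset directory contains

* ``spectra_{VIS|NIR}_sdd{2|6}.csv`` — wide tables (wavelength_nm plus one
  column of raw counts per sample),
* ``references.csv`` — per-session white/dark reference counts, long format
  (detector, sdd_mm, wavelength_nm, white, dark),
* ``us/<sample_id>.png`` — 16-bit grayscale ultrasound images,
* ``manifest.csv`` — sample_id, location_id, thickness_mm, labels, pixel
  spacing and true boundary row, with the generator configuration echoed in
  ``#``-prefixed header lines for provenance.

References are stored once per detector/distance: they model the white and
dark acquisitions taken at the start of a measurement session, shared by
all measurements of that session.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocessing import RawSpectrumPair
from .synthetic import SDD_MM, SyntheticSample
from .ultrasound import USImage

__all__ = ["write_dataset", "load_dataset"]

_DETECTORS = ("VIS", "NIR")


def _csv_with_header(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_dataset(
    samples: list[SyntheticSample],
    outdir: str | os.PathLike,
    config: dict | None = None,
    force: bool = False,
) -> Path:
    """Write a generated dataset to ``outdir``; returns the directory path."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"{k} = {v}" for k, v in (config or {}).items()]

    for det in _DETECTORS:
        for sdd in SDD_MM:
            cols = {"wavelength_nm": samples[0].raw[(det, sdd)].wavelengths_nm}
            for s in samples:
                cols[s.sample_id] = s.raw[(det, sdd)].counts
            _csv_with_header(
                pd.DataFrame(cols), outdir / f"spectra_{det}_sdd{sdd:g}.csv", header
            )

    ref_frames = []
    for det in _DETECTORS:
        for sdd in SDD_MM:
            raw = samples[0].raw[(det, sdd)]
            ref_frames.append(
                pd.DataFrame(
                    {
                        "detector": det,
                        "sdd_mm": sdd,
                        "wavelength_nm": raw.wavelengths_nm,
                        "white": raw.white,
                        "dark": raw.dark,
                    }
                )
            )
    _csv_with_header(pd.concat(ref_frames), outdir / "references.csv", header)

    rows = []
    for s in samples:
        us_path = ""
        if s.us_image is not None:
            (outdir / "us").mkdir(exist_ok=True)
            us_path = f"us/{s.sample_id}.png"
            img16 = np.round(s.us_image.intensities * 65535).astype(np.uint16)
            iio.imwrite(outdir / us_path, img16)
        rows.append(
            {
                "sample_id": s.sample_id,
                "location_id": s.location_id,
                "thickness_mm": s.thickness_mm,
                "top_label": s.top_label,
                "bottom_label": s.bottom_label,
                "pixel_mm": s.pixel_mm if s.pixel_mm is not None else "",
                "truth_boundary_row": (
                    s.truth_boundary_row if s.truth_boundary_row is not None else ""
                ),
                "us_path": us_path,
            }
        )
    _csv_with_header(pd.DataFrame(rows), outdir / "manifest.csv", header)
    return outdir


def load_dataset(outdir: str | os.PathLike) -> list[SyntheticSample]:
    """Read a dataset directory written by :func:`write_dataset`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv", comment="#")
    refs = pd.read_csv(outdir / "references.csv", comment="#")
    spectra = {
        (det, sdd): pd.read_csv(outdir / f"spectra_{det}_sdd{sdd:g}.csv", comment="#")
        for det in _DETECTORS
        for sdd in SDD_MM
    }
    ref_arrays = {}
    for (det, sdd), _tab in spectra.items():
        sel = refs[(refs["detector"] == det) & (refs["sdd_mm"] == sdd)]
        ref_arrays[(det, sdd)] = (
            sel["wavelength_nm"].to_numpy(),
            sel["white"].to_numpy(),
            sel["dark"].to_numpy(),
        )

    samples = []
    for row in manifest.itertuples(index=False):
        raw = {}
        for det in _DETECTORS:
            for sdd in SDD_MM:
                wl, white, dark = ref_arrays[(det, sdd)]
                counts = spectra[(det, sdd)][row.sample_id].to_numpy(dtype=float)
                raw[(det, sdd)] = RawSpectrumPair(det, sdd, wl, counts, white, dark)
        us_image = None
        boundary = None
        pixel_mm = None
        if isinstance(row.us_path, str) and row.us_path:
            img = iio.imread(outdir / row.us_path).astype(float) / 65535.0
            pixel_mm = float(row.pixel_mm)
            us_image = USImage(img, pixel_mm)
            boundary = int(row.truth_boundary_row)
        samples.append(
            SyntheticSample(
                sample_id=row.sample_id,
                location_id=row.location_id,
                thickness_mm=float(row.thickness_mm),
                top_label=row.top_label,
                bottom_label=row.bottom_label,
                raw=raw,
                us_image=us_image,
                truth_boundary_row=boundary,
                pixel_mm=pixel_mm,
            )
        )
    return samples
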