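"""File-format glue: series manifests, mzML, and result tables.

The plain-text series dialect is a manifest CSV with columns
``step,delta_cv,path`` pointing at per-step CSVs with columns
``mz,intensity``.  mzML files (centroided or profile) are read through
:mod:`pyteomics.mzml`, pairing spectra in file order with a supplied
voltage schedule.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .spectra import EductCourse, Spectrum, SpectrumSeries

__all__ = [
    "write_series",
    "read_series",
    "read_series_mzml",
    "write_course_csv",
    "read_course_csv",
]


def write_series(series: SpectrumSeries, directory, stem: str = "step") -> str:
    """Write a series as manifest + per-step CSVs; returns the manifest path."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, (dcv, spec) in enumerate(series.steps, start=1):
        name = f"{stem}_{i:02d}.csv"
        pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity}).to_csv(
            os.path.join(directory, name), index=False)
        rows.append({"step": i, "delta_cv": dcv, "path": name})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_series(manifest_path, label: str = "") -> SpectrumSeries:
    """Read a series back from a manifest CSV (paths relative to it)."""
    mdir = os.path.dirname(os.path.abspath(manifest_path))
    mf = pd.read_csv(manifest_path).sort_values("step")
    steps = []
    for _, row in mf.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(mdir, p)
        df = pd.read_csv(p)
        steps.append((float(row["delta_cv"]),
                      Spectrum(df["mz"].to_numpy(), df["intensity"].to_numpy())))
    return SpectrumSeries(steps=tuple(steps), label=label)


def _iter_mzml_spectra(path):
    """Minimal mzML spectrum iterator (m/z + intensity arrays).

    Handles 32/64-bit float binary arrays, uncompressed or zlib-compressed —
    the encodings centroided/profile exports actually use.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    for _, elem in ET.iterparse(str(path)):
        if elem.tag != ns + "spectrum":
            continue
        arrays = {}
        for bda in elem.iter(ns + "binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(ns + "cvParam")}
            binary = bda.find(ns + "binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in accs:            # zlib compression
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in accs else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        if "mz" in arrays and "intensity" in arrays:
            yield arrays["mz"], arrays["intensity"]
        elem.clear()


def read_series_mzml(path, cv_steps, label: str = "") -> SpectrumSeries:
    """Read one spectrum per voltage step from an mzML file, in file order.

    ``cv_steps`` supplies the voltage schedule; the file must contain at
    least as many spectra as steps (extra spectra are ignored).
    """
    steps = []
    schedule = list(cv_steps)
    for mz, inten in _iter_mzml_spectra(path):
        if len(steps) >= len(schedule):
            break
        order = np.argsort(mz)
        steps.append((float(schedule[len(steps)]),
                      Spectrum(mz[order], inten[order])))
    if len(steps) < len(schedule):
        raise ValueError(
            f"mzML holds {len(steps)} spectra but the schedule has "
            f"{len(schedule)} steps"
        )
    return SpectrumSeries(steps=tuple(steps), label=label)


def write_course_csv(course: EductCourse, path) -> None:
    pd.DataFrame({
        "delta_cv": course.dcv,
        "educt_pct_mean": course.mean,
        "educt_pct_sd": course.sd,
        "n": course.n.astype(int),
    }).to_csv(path, index=False)


def read_course_csv(path) -> EductCourse:
    df = pd.read_csv(path)
    return EductCourse(df["delta_cv"].to_numpy(), df["educt_pct_mean"].to_numpy(),
                       df["educt_pct_sd"].to_numpy(), df["n"].to_numpy())
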