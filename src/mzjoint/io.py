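"""Reading and writing of the standard formats the toolkit touches.

Formats: mzML runs (read), MSP spectral libraries (read), the tool's own
CSV feature-table dialect (read/write) and targeted-list CSVs (read).
"""
from __future__ import annotations

import logging
import math

import pandas as pd

from . import _mzml
from .errors import FormatError, SchemaError
from .model import Feature, LibraryEntry, Run, TargetEntry

logger = logging.getLogger(__name__)

FEATURE_TABLE_COLUMNS = [
    "feature_id",
    "mz",
    "rt",
    "rtmin",
    "rtmax",
    "intensity",
    "area",
    "source",
    "ms2_scan",
]


def read_mzml(path: str, sample_id: str | None = None, mass_tol: float = 0.01) -> Run:
    """Read a centroided mzML run.

    RTs are normalised to seconds. MS2 precursor intensities missing from
    the file are filled from the nearest preceding MS1 scan within
    ``mass_tol`` of the precursor m/z.
    """
    run = _mzml.read_mzml(path, sample_id=sample_id)
    for spec in run.spectra:
        if spec.ms_level != 2 or spec.precursor_intensity is not None:
            continue
        parent = None
        if spec.precursor_scan_index is not None:
            parent = run.spectra[spec.precursor_scan_index]
        else:
            for idx in reversed(run.ms1_index):
                if run.spectra[idx].rt <= spec.rt:
                    parent = run.spectra[idx]
                    break
        if parent is not None and spec.precursor_mz is not None:
            spec.precursor_intensity = parent.max_intensity_in_window(
                spec.precursor_mz - mass_tol, spec.precursor_mz + mass_tol
            )
    return run


def read_msp(path: str) -> list[LibraryEntry]:
    """Parse an MSP spectral library.

    Records lacking a precursor m/z or fragment peaks are skipped (count
    logged). Raises FormatError when no parseable record exists.
    """
    entries: list[LibraryEntry] = []
    skipped = 0
    record: dict = {}
    fragments: list[tuple[float, float]] = []
    expecting_peaks = False

    def flush() -> None:
        nonlocal skipped, record, fragments, expecting_peaks
        if record or fragments:
            name = record.get("name")
            pmz = record.get("precursormz")
            if name is not None and pmz is not None and fragments:
                entries.append(
                    LibraryEntry(
                        compound_name=name,
                        precursor_mz=pmz,
                        fragments=fragments,
                        adduct=record.get("adduct"),
                        ids=record.get("ids"),
                    )
                )
            else:
                skipped += 1
        record, fragments, expecting_peaks = {}, [], False

    with open(path, encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not expecting_peaks:
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "").replace("_", "")
                value = value.strip()
                if key == "name":
                    if "name" in record or fragments:
                        flush()
                    record["name"] = value
                elif key in ("precursormz", "precursorm/z", "exactmass"):
                    try:
                        record.setdefault("precursormz", float(value))
                    except ValueError:
                        pass
                elif key in ("precursortype", "adduct", "iontype"):
                    record["adduct"] = value
                elif key in ("comment", "comments", "inchikey", "hmdb", "kegg"):
                    prev = record.get("ids")
                    record["ids"] = f"{prev};{value}" if prev else value
                elif key == "numpeaks":
                    expecting_peaks = True
                continue
            parts = line.replace(",", " ").split()
            if len(parts) >= 2:
                try:
                    fragments.append((float(parts[0]), float(parts[1])))
                    continue
                except ValueError:
                    pass
            if expecting_peaks and len(parts) < 2:
                expecting_peaks = False
    flush()
    if skipped:
        logger.info("read_msp: skipped %d incomplete MSP records", skipped)
    if not entries:
        raise FormatError(f"{path}: no parseable MSP record")
    return entries


def read_feature_table(path: str) -> list[Feature]:
    """Read a CSV feature table (external tables become the PP tier)."""
    df = pd.read_csv(path)
    missing = {"mz", "rt", "intensity"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
    features = []
    for i, row in df.iterrows():
        rt = float(row["rt"])
        rtmin = float(row["rtmin"]) if "rtmin" in df.columns and not _isna(row["rtmin"]) else rt
        rtmax = float(row["rtmax"]) if "rtmax" in df.columns and not _isna(row["rtmax"]) else rt
        ms2 = None
        if "ms2_scan" in df.columns and not _isna(row["ms2_scan"]):
            ms2 = int(row["ms2_scan"])
        features.append(
            Feature(
                feature_id=str(row["feature_id"]) if "feature_id" in df.columns else f"F{i:04d}",
                mz=float(row["mz"]),
                rt=rt,
                rtmin=rtmin,
                rtmax=rtmax,
                intensity=float(row["intensity"]),
                area=float(row["area"]) if "area" in df.columns and not _isna(row["area"]) else 0.0,
                source=str(row["source"]) if "source" in df.columns else "PP",
                ms2_scan=ms2,
            )
        )
    return features


def write_feature_table(features: list[Feature], path: str) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt": f.rt,
            "rtmin": f.rtmin,
            "rtmax": f.rtmax,
            "intensity": f.intensity,
            "area": f.area,
            "source": f.source,
            "ms2_scan": f.ms2_scan,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS).to_csv(path, index=False)


def read_target_list(path: str) -> list[TargetEntry]:
    """Read a targeted-list CSV with columns name, mz, rt (RT seconds)."""
    df = pd.read_csv(path)
    missing = {"name", "mz", "rt"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
    return [
        TargetEntry(name=str(r["name"]), mz=float(r["mz"]), rt=float(r["rt"]))
        for _, r in df.iterrows()
    ]


def _isna(value) -> bool:
    try:
        return value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value)
    except (TypeError, ValueError):
        return False
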