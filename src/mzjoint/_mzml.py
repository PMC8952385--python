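"""Minimal mzML 1.1 reader/writer built on the standard library.

Supports the subset of mzML needed here: centroided MS1/MS2 spectra with
64-/32-bit float binary arrays, optional zlib compression on read, scan
start times in seconds or minutes, and DDA precursor metadata. The writer
always emits uncompressed 64-bit floats with no timestamps so that output
is a pure, byte-deterministic function of the in-memory run.
"""
from __future__ import annotations

import base64
import re
import struct
import xml.etree.ElementTree as ET
import zlib
from xml.sax.saxutils import escape

import numpy as np

from .errors import EmptyRunError, FormatError
from .model import Run, Spectrum

# CV accessions (PSI-MS controlled vocabulary)
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_PEAK_INTENSITY = "MS:1000042"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(b64_text: str, dtype: str, compressed: bool, n: int) -> np.ndarray:
    raw = base64.b64decode(b64_text)
    if compressed:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype)
    if n and arr.size != n:
        raise FormatError(f"binary array length {arr.size} != declared {n}")
    return arr.astype(np.float64)


def _parse_binary_arrays(spec_elem) -> tuple[np.ndarray, np.ndarray]:
    mz = intens = None
    n_declared = int(spec_elem.get("defaultArrayLength", "0"))
    for bda in spec_elem.iter():
        if _localname(bda.tag) != "binaryDataArray":
            continue
        dtype, compressed, kind, text = "<f8", False, None, ""
        for child in bda:
            name = _localname(child.tag)
            if name == "cvParam":
                acc = child.get("accession", "")
                if acc == _ACC_FLOAT64:
                    dtype = "<f8"
                elif acc == _ACC_FLOAT32:
                    dtype = "<f4"
                elif acc == _ACC_ZLIB:
                    compressed = True
                elif acc == _ACC_MZ_ARRAY:
                    kind = "mz"
                elif acc == _ACC_INT_ARRAY:
                    kind = "intensity"
            elif name == "binary":
                text = child.text or ""
        if kind == "mz":
            mz = _decode_binary(text, dtype, compressed, n_declared)
        elif kind == "intensity":
            intens = _decode_binary(text, dtype, compressed, n_declared)
    if mz is None or intens is None:
        raise FormatError("spectrum missing m/z or intensity binary array")
    return mz, intens


def _parse_spectrum(elem, index: int, id_to_index: dict[str, int]) -> Spectrum:
    ms_level = 1
    rt = None
    is_profile = False
    precursor_mz = precursor_intensity = None
    precursor_scan_index = None
    for node in elem.iter():
        name = _localname(node.tag)
        if name == "cvParam":
            acc = node.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(node.get("value", "1"))
            elif acc == _ACC_PROFILE:
                is_profile = True
            elif acc == _ACC_SCAN_START:
                val = float(node.get("value", "0"))
                unit = (node.get("unitName") or "").lower()
                rt = val * 60.0 if unit.startswith("minute") else val
            elif acc == _ACC_SELECTED_MZ:
                precursor_mz = float(node.get("value", "0"))
            elif acc == _ACC_PEAK_INTENSITY:
                precursor_intensity = float(node.get("value", "0"))
        elif name == "precursor":
            ref = node.get("spectrumRef")
            if ref is not None and ref in id_to_index:
                precursor_scan_index = id_to_index[ref]
    if is_profile:
        raise FormatError(
            f"spectrum {index} is profile mode; only centroided data is supported"
        )
    if rt is None:
        raise FormatError(f"spectrum {index} has no scan start time")
    mz, intens = _parse_binary_arrays(elem)
    order = np.argsort(mz, kind="stable")
    return Spectrum(
        scan_index=index,
        ms_level=ms_level,
        rt=rt,
        mz_values=mz[order],
        intensities=intens[order],
        precursor_mz=precursor_mz,
        precursor_intensity=precursor_intensity,
        precursor_scan_index=precursor_scan_index,
    )


def read_mzml(path: str, sample_id: str | None = None) -> Run:
    """Parse an mzML file into a Run. Raises FormatError / EmptyRunError."""
    try:
        tree = ET.parse(path)
    except (ET.ParseError, OSError) as exc:
        raise FormatError(f"cannot parse mzML file {path}: {exc}") from exc
    root = tree.getroot()
    if _localname(root.tag) not in ("mzML", "indexedmzML"):
        raise FormatError(f"{path}: root element is not mzML")

    spec_elems = [e for e in root.iter() if _localname(e.tag) == "spectrum"]
    id_to_index = {e.get("id", ""): i for i, e in enumerate(spec_elems)}
    spectra = [_parse_spectrum(e, i, id_to_index) for i, e in enumerate(spec_elems)]
    if not any(s.ms_level == 1 for s in spectra):
        raise EmptyRunError(f"{path}: no MS1 scans")
    if sample_id is None:
        run_elem = next(
            (e for e in root.iter() if _localname(e.tag) == "run"), None
        )
        if run_elem is not None and run_elem.get("id"):
            sample_id = run_elem.get("id")
        else:
            sample_id = re.sub(
                r"\.mzml$", "", str(path).rsplit("/", 1)[-1], flags=re.I
            )
    return Run(sample_id=sample_id, spectra=spectra, ms1_index=[])


def _b64_f64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(raw).decode("ascii")


def _spectrum_xml(s: Spectrum, run: Run) -> str:
    n = s.n_peaks
    lines = [
        f'      <spectrum index="{s.scan_index}" id="scan={s.scan_index}" '
        f'defaultArrayLength="{n}">',
        f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" '
        f'value="{s.ms_level}"/>',
        f'        <cvParam cvRef="MS" accession="{_ACC_CENTROID}" '
        f'name="centroid spectrum" value=""/>',
        '        <scanList count="1">',
        "          <scan>",
        f'            <cvParam cvRef="MS" accession="{_ACC_SCAN_START}" '
        f'name="scan start time" value="{s.rt!r}" unitName="second"/>',
        "          </scan>",
        "        </scanList>",
    ]
    if s.ms_level == 2 and s.precursor_mz is not None:
        ref = ""
        if s.precursor_scan_index is not None:
            ref = f' spectrumRef="scan={s.precursor_scan_index}"'
        lines += [
            '        <precursorList count="1">',
            f"          <precursor{ref}>",
            '            <selectedIonList count="1">',
            "              <selectedIon>",
            f'                <cvParam cvRef="MS" accession="{_ACC_SELECTED_MZ}" '
            f'name="selected ion m/z" value="{s.precursor_mz!r}"/>',
        ]
        if s.precursor_intensity is not None:
            lines.append(
                f'                <cvParam cvRef="MS" accession="{_ACC_PEAK_INTENSITY}" '
                f'name="peak intensity" value="{s.precursor_intensity!r}"/>'
            )
        lines += [
            "              </selectedIon>",
            "            </selectedIonList>",
            "          </precursor>",
            "        </precursorList>",
        ]
    for kind_acc, kind_name, values in (
        (_ACC_MZ_ARRAY, "m/z array", s.mz_values),
        (_ACC_INT_ARRAY, "intensity array", s.intensities),
    ):
        b64 = _b64_f64(values)
        lines += [
            '        <binaryDataArrayList count="2">' if kind_acc == _ACC_MZ_ARRAY else "",
            f'          <binaryDataArray encodedLength="{len(b64)}">',
            f'            <cvParam cvRef="MS" accession="{_ACC_FLOAT64}" '
            f'name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" '
            'name="no compression" value=""/>',
            f'            <cvParam cvRef="MS" accession="{kind_acc}" '
            f'name="{kind_name}" value=""/>',
            f"            <binary>{b64}</binary>",
            "          </binaryDataArray>",
        ]
    lines += ["        </binaryDataArrayList>", "      </spectrum>"]
    return "\n".join(line for line in lines if line)


def write_mzml(run: Run, path: str) -> None:
    """Serialize a Run as uncompressed 64-bit mzML (deterministic bytes)."""
    header = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        '  <run id="%s">\n'
        '    <spectrumList count="%d">\n'
    ) % (escape(run.sample_id, {'"': "&quot;"}), len(run.spectra))
    footer = "    </spectrumList>\n  </run>\n</mzML>\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        for s in run.spectra:
            fh.write(_spectrum_xml(s, run))
            fh.write("\n")
        fh.write(footer)
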