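"""Shared fixtures: hand-built runs, synthetic runs and an MSP library."""
from __future__ import annotations

import numpy as np
import pytest

from mzjoint.model import LibraryEntry, Run, Spectrum
from mzjoint.peaks import PeakPickingConfig
from mzjoint.simulate import SynthConfig, generate_run


def make_ms1_run(traces: dict[float, dict[int, float]], n_scans: int,
                 cycle: float = 1.0, sample_id: str = "test") -> Run:
    """Build an MS1-only run from {mz: {scan_position: intensity}} traces."""
    spectra = []
    for k in range(n_scans):
        mzs, intens = [], []
        for mz, points in sorted(traces.items()):
            if k in points and points[k] > 0:
                mzs.append(mz)
                intens.append(points[k])
        spectra.append(
            Spectrum(
                scan_index=k, ms_level=1, rt=k * cycle,
                mz_values=np.array(mzs), intensities=np.array(intens),
            )
        )
    return Run(sample_id=sample_id, spectra=spectra, ms1_index=[])


def add_ms2(run: Run, precursor_mz: float, rt: float,
            fragments: list[tuple[float, float]] | None = None,
            precursor_intensity: float | None = None) -> Run:
    """Append an MS2 scan to a run (re-sorting by RT)."""
    fragments = fragments or [(50.0, 100.0), (80.0, 200.0)]
    mzs = np.array([m for m, _ in fragments])
    ints = np.array([i for _, i in fragments])
    spec = Spectrum(
        scan_index=len(run.spectra), ms_level=2, rt=rt,
        mz_values=mzs, intensities=ints,
        precursor_mz=precursor_mz, precursor_intensity=precursor_intensity,
    )
    return Run(sample_id=run.sample_id, spectra=run.spectra + [spec], ms1_index=[])


def gaussian_trace(apex_scan: int, sigma_scans: float, height: float,
                   n_scans: int, baseline: float = 0.0,
                   floor: float = 1.0) -> dict[int, float]:
    """Dense Gaussian + constant baseline trace as {scan: intensity}."""
    out = {}
    for k in range(n_scans):
        v = height * np.exp(-((k - apex_scan) ** 2) / (2 * sigma_scans**2))
        v = max(v, baseline)
        if v >= floor:
            out[k] = v
    return out


@pytest.fixture(scope="session")
def default_pp_config() -> PeakPickingConfig:
    return PeakPickingConfig()


@pytest.fixture(scope="session")
def synth_run():
    """Standard synthetic DDA run (seed 1) with ground truth."""
    cfg = SynthConfig(seed=1)
    run, truth = generate_run(cfg)
    return cfg, run, truth


@pytest.fixture(scope="session")
def library_entries() -> list[LibraryEntry]:
    return [
        LibraryEntry(
            compound_name=f"compound_{i}",
            precursor_mz=150.0 + 37.0 * i,
            fragments=[(60.0 + 10 * j + i, 100.0 * (j + 1)) for j in range(5)],
            ids=f"HMDB{i:07d}",
        )
        for i in range(8)
    ]


MSP_TEXT = """\
Name: alanine
PRECURSORMZ: 90.0549
PRECURSORTYPE: [M+H]+
Comment: HMDB0000161
Num Peaks: 3
44.0495 999
45.0532 120
90.0549 450

Name: caffeine
PRECURSORMZ: 195.0877
Num Peaks: 2
138.0662 999
110.0713 350

Name: empty-record
PRECURSORMZ: 123.4567
Num Peaks: 0

Name: glycine
PRECURSORMZ: 76.0393
Num Peaks: 1
30.0344 999
"""


@pytest.fixture()
def msp_file(tmp_path):
    path = tmp_path / "library.msp"
    path.write_text(MSP_TEXT)
    return path
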