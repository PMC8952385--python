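"""Core domain types shared across mzjoint modules.

All retention times are seconds, all m/z values are Thomson, scan indices
are 0-based ordinal positions within a run, and m/z windows are closed
intervals ``[x - tol, x + tol]``.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Spectrum:
    """One centroided MS1 or MS2 scan.

    ``mz_values`` are strictly increasing; ``intensities`` is the matching
    array of non-negative abundances. MS2 scans carry precursor metadata.
    """

    scan_index: int
    ms_level: int
    rt: float
    mz_values: np.ndarray
    intensities: np.ndarray
    precursor_mz: float | None = None
    precursor_intensity: float | None = None
    precursor_scan_index: int | None = None

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError("mz_values and intensities must have equal length")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires precursor_mz")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")

    @property
    def n_peaks(self) -> int:
        return int(self.mz_values.size)

    def max_intensity_in_window(self, mz_lo: float, mz_hi: float) -> float:
        """Maximum centroid intensity with m/z in the closed window, 0 if none."""
        lo = bisect.bisect_left(self.mz_values, mz_lo)
        hi = bisect.bisect_right(self.mz_values, mz_hi)
        if hi <= lo:
            return 0.0
        return float(self.intensities[lo:hi].max())


@dataclass
class Run:
    """An RT-ordered collection of spectra from one file."""

    sample_id: str
    spectra: list[Spectrum]
    ms1_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra.sort(key=lambda s: (s.rt, s.scan_index))
        for i, s in enumerate(self.spectra):
            s.scan_index = i
        if not self.ms1_index:
            self.ms1_index = [s.scan_index for s in self.spectra if s.ms_level == 1]

    @property
    def ms1_spectra(self) -> list[Spectrum]:
        return [self.spectra[i] for i in self.ms1_index]

    @property
    def ms2_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def ms1_rts(self) -> np.ndarray:
        return np.array([self.spectra[i].rt for i in self.ms1_index])

    def ms1_position(self, scan_index: int) -> int:
        """Ordinal position among MS1 scans of the MS1 scan at/just before scan_index."""
        pos = bisect.bisect_right(self.ms1_index, scan_index) - 1
        return max(pos, 0)

    def ms1_cycle(self) -> float:
        """Median spacing between consecutive MS1 scans (seconds)."""
        rts = self.ms1_rts()
        if rts.size < 2:
            return 1.0
        return float(np.median(np.diff(rts)))


@dataclass
class Feature:
    """One extracted metabolic feature in one sample.

    ``source`` tags the extraction tier: "PP" (peak picking), "MR" (MS2
    rescue) or "TL" (targeted list).
    """

    feature_id: str
    mz: float
    rt: float
    rtmin: float
    rtmax: float
    intensity: float
    area: float
    source: str
    ms2_scan: int | None = None
    sn: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("PP", "MR", "TL"):
            raise ValueError(f"invalid source tag {self.source!r}")
        if not (self.rtmin <= self.rt <= self.rtmax):
            raise ValueError("rt must lie within [rtmin, rtmax]")


@dataclass
class LibraryEntry:
    """One MSP spectral-library record."""

    compound_name: str
    precursor_mz: float
    fragments: list[tuple[float, float]]
    adduct: str | None = None
    ids: str | None = None


@dataclass
class TargetEntry:
    """One row of a user-supplied targeted compound list."""

    name: str
    mz: float
    rt: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("target m/z must be positive")
        if self.rt < 0:
            raise ValueError("target rt must be non-negative")


@dataclass
class PrecursorCandidate:
    """A deduplicated MS2 precursor considered for feature rescue."""

    mz: float
    rt: float
    intensity: float
    ms2_scan: int
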