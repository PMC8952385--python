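"""MS2 spectral-library annotation by weighted dot-product similarity."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedScoreError
from .model import Feature, LibraryEntry, Run

logger = logging.getLogger(__name__)


@dataclass
class AnnotationConfig:
    precursor_tol: float = 0.01    # Th
    fragment_tol: float = 0.02     # Th
    score_threshold: float = 0.7
    intensity_power: float = 0.5   # weight exponent on intensity
    mz_power: float = 0.0          # weight exponent on m/z

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 <= self.score_threshold <= 1):
            raise ValueError("score_threshold must be in [0, 1]")


def match_fragments(spec_a: list[tuple[float, float]],
                    spec_b: list[tuple[float, float]],
                    fragment_tol: float) -> list[tuple[int, int]]:
    """Greedy one-to-one fragment matching by nearest m/z within tolerance.

    Candidate pairs are taken in order of ascending m/z difference, ties
    broken toward the higher summed intensity.
    """
    pairs = []
    for i, (mza, ia) in enumerate(spec_a):
        for j, (mzb, ib) in enumerate(spec_b):
            d = abs(mza - mzb)
            if d <= fragment_tol:
                pairs.append((d, -(ia + ib), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def dot_product(spec_a: list[tuple[float, float]],
                spec_b: list[tuple[float, float]],
                cfg: AnnotationConfig | None = None) -> float:
    """Weighted dot-product similarity in [0, 1].

    Fragments are matched greedily by nearest m/z within ``fragment_tol``;
    with weights w = intensity**intensity_power * mz**mz_power, the score
    is (sum of matched w_a * w_b)**2 divided by (sum of all w_a**2) *
    (sum of all w_b**2). Symmetric; 1.0 for identical spectra.
    """
    cfg = cfg or AnnotationConfig()
    if not spec_a or not spec_b:
        raise UndefinedScoreError("dot product undefined for empty spectrum")

    def weight(mz: float, inten: float) -> float:
        return (inten ** cfg.intensity_power) * (mz ** cfg.mz_power)

    wa = [weight(mz, i) for mz, i in spec_a]
    wb = [weight(mz, i) for mz, i in spec_b]
    matches = match_fragments(spec_a, spec_b, cfg.fragment_tol)
    num = sum(wa[i] * wb[j] for i, j in matches) ** 2
    den = sum(w * w for w in wa) * sum(w * w for w in wb)
    if den == 0:
        return 0.0
    return min(num / den, 1.0)


ANNOTATION_COLUMNS = [
    "feature_id", "compound_name", "score", "precursor_delta_mz",
    "library_ids", "rank",
]


def annotate(features: list[Feature], run: Run, library: list[LibraryEntry],
             cfg: AnnotationConfig | None = None) -> pd.DataFrame:
    """Score each feature's attached MS2 spectrum against library entries
    whose precursor m/z lies within ``precursor_tol`` of the feature m/z.

    Hits at or above ``score_threshold`` are reported, best first
    (rank 1 = top hit per feature).
    """
    cfg = cfg or AnnotationConfig()
    if not library:
        raise ValueError("library must be non-empty")
    rows = []
    for f in features:
        if f.ms2_scan is None:
            continue
        spec = run.spectra[f.ms2_scan]
        fragments = list(zip(spec.mz_values.tolist(), spec.intensities.tolist()))
        if not fragments:
            logger.info("annotate: feature %s has empty MS2; skipped", f.feature_id)
            continue
        hits = []
        for entry in library:
            delta = entry.precursor_mz - f.mz
            if abs(delta) > cfg.precursor_tol:
                continue
            score = dot_product(fragments, entry.fragments, cfg)
            if score >= cfg.score_threshold:
                hits.append((score, entry, delta))
        hits.sort(key=lambda h: -h[0])
        for rank, (score, entry, delta) in enumerate(hits, start=1):
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "compound_name": entry.compound_name,
                    "score": score,
                    "precursor_delta_mz": delta,
                    "library_ids": entry.ids or "",
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
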