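"""MS2-precursor-based feature rescue (the MR tier).

Pipeline: deduplicate DDA MS2 precursors, drop those already extracted by
peak picking, relocate each survivor to its chromatographic peak apex, and
validate against local noise and a consecutive-scan requirement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ApexNotFoundError
from .model import Feature, PrecursorCandidate, Run

logger = logging.getLogger(__name__)


@dataclass
class MRConfig:
    dedup_mz_tol: float = 0.01        # Th
    dedup_rt_tol: float = 30.0        # s
    find_ppm_tol: float = 10.0        # ppm, precursor-to-raw matching
    confirm_mass_tol: float = 0.01    # Th
    confirm_rt_tol: float = 60.0      # s
    noise_fold: float = 3.0
    min_consecutive_scans: int = 4
    noise_floor: float = 100.0        # fallback when too few noise points

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Rejection:
    """A precursor candidate that failed validation, with a reason code."""

    candidate: PrecursorCandidate
    reason: str  # noise_fail | consecutive_fail | no_apex | not_novel


def precursor_candidates(run: Run) -> list[PrecursorCandidate]:
    """All MS2 precursors of a run, one candidate per MS2 scan.

    Intensity is taken from the parent MS1 scan when resolvable, falling
    back to the precursor intensity recorded in the MS2 header.
    """
    out = []
    for s in run.ms2_spectra:
        if s.precursor_mz is None:
            continue
        intensity = s.precursor_intensity
        if s.precursor_scan_index is not None:
            parent = run.spectra[s.precursor_scan_index]
            from_parent = parent.max_intensity_in_window(
                s.precursor_mz - 0.01, s.precursor_mz + 0.01
            )
            if from_parent > 0:
                intensity = from_parent
        out.append(
            PrecursorCandidate(
                mz=s.precursor_mz,
                rt=s.rt,
                intensity=intensity or 0.0,
                ms2_scan=s.scan_index,
            )
        )
    return out


def dedupe_precursors(run: Run, cfg: MRConfig) -> list[PrecursorCandidate]:
    """Keep only the highest-intensity precursor within each
    (dedup_mz_tol, dedup_rt_tol) window.

    Clustering is greedy in descending intensity: a precursor within both
    tolerances of an already-kept one is absorbed. Result sorted by (mz, rt).
    """
    cands = precursor_candidates(run)
    cands.sort(key=lambda c: (-c.intensity, c.mz, c.rt))
    kept: list[PrecursorCandidate] = []
    for c in cands:
        absorbed = any(
            abs(c.mz - k.mz) <= cfg.dedup_mz_tol
            and abs(c.rt - k.rt) <= cfg.dedup_rt_tol
            for k in kept
        )
        if not absorbed:
            kept.append(c)
    kept.sort(key=lambda c: (c.mz, c.rt))
    return kept


def filter_novel(candidates: list[PrecursorCandidate], picked: list[Feature],
                 cfg: MRConfig) -> list[PrecursorCandidate]:
    """Drop candidates already covered by a picked feature within
    (confirm_mass_tol, confirm_rt_tol); order preserved."""
    return [
        c for c in candidates
        if not any(
            abs(c.mz - f.mz) <= cfg.confirm_mass_tol
            and abs(c.rt - f.rt) <= cfg.confirm_rt_tol
            for f in picked
        )
    ]


def extract_eic(run: Run, mz: float, mass_tol: float, rt_center: float,
                rt_tol: float) -> list[tuple[int, float, float]]:
    """Extracted ion chromatogram: one (scan_index, rt, intensity) point per
    MS1 scan with RT in [rt_center - rt_tol, rt_center + rt_tol].

    Per-scan intensity is the maximum centroid intensity within
    [mz - mass_tol, mz + mass_tol], 0 when no centroid matches.
    """
    lo, hi = rt_center - rt_tol, rt_center + rt_tol
    points = []
    for idx in run.ms1_index:
        spec = run.spectra[idx]
        if spec.rt < lo:
            continue
        if spec.rt > hi:
            break
        points.append(
            (idx, spec.rt, spec.max_intensity_in_window(mz - mass_tol, mz + mass_tol))
        )
    return points


def relocate_to_apex(run: Run, cand: PrecursorCandidate,
                     cfg: MRConfig) -> PrecursorCandidate:
    """Move a candidate to the apex of its EIC within the confirm window.

    Ties in intensity are broken toward the point nearest the original
    trigger RT. Raises ApexNotFoundError on an all-zero EIC.
    """
    eic = extract_eic(run, cand.mz, cfg.confirm_mass_tol, cand.rt, cfg.confirm_rt_tol)
    nonzero = [(i, rt, inten) for i, rt, inten in eic if inten > 0]
    if not nonzero:
        raise ApexNotFoundError(
            f"no signal for precursor m/z {cand.mz:.4f} near rt {cand.rt:.1f}"
        )
    best = max(nonzero, key=lambda p: (p[2], -abs(p[1] - cand.rt)))
    return PrecursorCandidate(
        mz=cand.mz, rt=best[1], intensity=best[2], ms2_scan=cand.ms2_scan
    )


def estimate_local_noise(eic: list[tuple[int, float, float]],
                         exclude_rt: tuple[float, float],
                         floor: float) -> float:
    """Local noise = median of nonzero EIC intensities with RT outside
    [lo, hi]; the configured floor when fewer than 4 such points exist.
    Never below 1."""
    lo, hi = exclude_rt
    outside = [i for _, rt, i in eic if (rt < lo or rt > hi) and i > 0]
    if len(outside) < 4:
        return max(float(floor), 1.0)
    return max(float(np.median(outside)), 1.0)


def _consecutive_stretch(eic, apex_pos: int) -> tuple[int, int]:
    """Bounds (inclusive positions in eic) of the maximal consecutive
    nonzero stretch containing the apex."""
    lo = apex_pos
    while lo > 0 and eic[lo - 1][2] > 0:
        lo -= 1
    hi = apex_pos
    while hi < len(eic) - 1 and eic[hi + 1][2] > 0:
        hi += 1
    return lo, hi


def validate_feature(run: Run, cand: PrecursorCandidate,
                     cfg: MRConfig) -> Feature | Rejection:
    """Validate an apex-relocated candidate: apex must exceed
    noise_fold x local noise and lie in a stretch of at least
    min_consecutive_scans consecutive nonzero MS1 scans."""
    eic = extract_eic(run, cand.mz, cfg.confirm_mass_tol, cand.rt, cfg.confirm_rt_tol)
    apex_pos = min(
        range(len(eic)), key=lambda i: (abs(eic[i][1] - cand.rt), -eic[i][2])
    )
    lo, hi = _consecutive_stretch(eic, apex_pos)
    if hi - lo + 1 < cfg.min_consecutive_scans:
        return Rejection(cand, "consecutive_fail")
    noise = estimate_local_noise(
        eic, (eic[lo][1], eic[hi][1]), cfg.noise_floor
    )
    if cand.intensity <= cfg.noise_fold * noise:
        return Rejection(cand, "noise_fail")
    seg = eic[lo:hi + 1]
    rts = np.array([p[1] for p in seg])
    intens = np.array([p[2] for p in seg])
    return Feature(
        feature_id="",
        mz=cand.mz,
        rt=cand.rt,
        rtmin=float(rts[0]),
        rtmax=float(rts[-1]),
        intensity=cand.intensity,
        area=float(np.trapezoid(intens, rts)),
        source="MR",
        ms2_scan=cand.ms2_scan,
        sn=float(cand.intensity / noise),
    )


def run_mr(run: Run, picked: list[Feature], cfg: MRConfig | None = None,
           rejections: list[Rejection] | None = None) -> list[Feature]:
    """Full MR pipeline: dedupe -> novelty filter -> apex relocation ->
    validation. Returns valid MR features sorted by (mz, rt)."""
    cfg = cfg or MRConfig()
    deduped = dedupe_precursors(run, cfg)
    novel = filter_novel(deduped, picked, cfg)
    features: list[Feature] = []
    for cand in novel:
        try:
            relocated = relocate_to_apex(run, cand, cfg)
        except ApexNotFoundError:
            if rejections is not None:
                rejections.append(Rejection(cand, "no_apex"))
            continue
        result = validate_feature(run, relocated, cfg)
        if isinstance(result, Feature):
            features.append(result)
        elif rejections is not None:
            rejections.append(result)
    # two precursors relocated to the same apex describe one feature
    features.sort(key=lambda f: (-f.intensity, f.mz, f.rt))
    unique: list[Feature] = []
    for f in features:
        if not any(
            abs(f.mz - u.mz) <= cfg.dedup_mz_tol
            and abs(f.rt - u.rt) <= cfg.dedup_rt_tol
            for u in unique
        ):
            unique.append(f)
    features = unique
    features.sort(key=lambda f: (f.mz, f.rt))
    for i, f in enumerate(features):
        f.feature_id = f"MR{i + 1:04d}"
    logger.info(
        "MR: %d precursors -> %d unique -> %d novel -> %d valid",
        len(run.ms2_spectra), len(deduped), len(novel), len(features),
    )
    return features
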