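"""centWave-style chromatographic peak picking from MS1 scans (the PP tier).

Two stages: region-of-interest (ROI) detection by walking MS1 scans in RT
order and extending m/z-consistent traces, then peak localisation inside
each ROI with a Mexican-hat continuous wavelet transform over scales
spanning the configured peak-width bounds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Feature, Run

# consecutive MS1 scans a trace may miss before it is closed
MAX_SCAN_GAP = 2
# peak boundaries stop where intensity falls to baseline plus this fraction
# of apex-above-baseline (or baseline + noise_sd, whichever is higher)
BOUNDARY_FRACTION = 0.05


@dataclass
class PeakPickingConfig:
    """Parameters of the PP tier (names mirror the usual centWave knobs)."""

    ppm_tol: float = 10.0
    peakwidth_min: float = 5.0
    peakwidth_max: float = 20.0
    sn_threshold: float = 3.0
    mzdiff: float = 0.01
    prefilter_k: int = 3
    prefilter_intensity: float = 100.0
    noise_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.peakwidth_min >= self.peakwidth_max:
            raise ValueError("peakwidth_min must be < peakwidth_max")
        for name in ("ppm_tol", "peakwidth_min", "sn_threshold", "mzdiff",
                     "prefilter_k", "prefilter_intensity", "noise_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROI:
    """A contiguous m/z-consistent trace across MS1 scans."""

    mz_center: float
    scan_span: tuple[int, int]
    trace: list[tuple[int, float, float]]  # (ms1 position, mz, intensity)


@dataclass
class _Trace:
    weighted_mz: float = 0.0
    weight: float = 0.0
    points: list = field(default_factory=list)
    gap: int = 0

    @property
    def mean_mz(self) -> float:
        return self.weighted_mz / self.weight

    def add(self, pos: int, mz: float, intensity: float) -> None:
        w = max(intensity, 1.0)
        self.weighted_mz += mz * w
        self.weight += w
        self.points.append((pos, mz, intensity))
        self.gap = 0


def detect_rois(run: Run, cfg: PeakPickingConfig,
                max_scan_gap: int = MAX_SCAN_GAP) -> list[ROI]:
    """Build ROIs by extending traces whose running intensity-weighted mean
    m/z matches incoming centroids within ``ppm_tol``.

    A trace survives up to ``max_scan_gap`` consecutive MS1 scans without a
    matching centroid. Finished traces are kept iff at least ``prefilter_k``
    points reach ``prefilter_intensity`` and the trace maximum exceeds
    ``noise_floor``.
    """
    active: list[_Trace] = []
    finished: list[ROI] = []

    def finalize(trace: _Trace) -> None:
        pts = trace.points
        strong = sum(1 for _, _, i in pts if i >= cfg.prefilter_intensity)
        if strong < cfg.prefilter_k:
            return
        if max(i for _, _, i in pts) <= cfg.noise_floor:
            return
        finished.append(
            ROI(
                mz_center=trace.mean_mz,
                scan_span=(pts[0][0], pts[-1][0]),
                trace=pts,
            )
        )

    for pos, spec in enumerate(run.ms1_spectra):
        mzs = spec.mz_values
        intens = spec.intensities
        if active:
            means = np.array([t.mean_mz for t in active])
            order = np.argsort(means)
            sorted_means = means[order]
        else:
            order = sorted_means = np.array([])
        matched: dict[int, tuple[float, float, float]] = {}  # trace -> (dmz, mz, I)
        used_centroids: set[int] = set()
        for ci in range(mzs.size):
            mz = mzs[ci]
            if sorted_means.size == 0:
                continue
            j = np.searchsorted(sorted_means, mz)
            best = None
            for k in (j - 1, j):
                if 0 <= k < sorted_means.size:
                    mean = sorted_means[k]
                    dmz = abs(mz - mean)
                    if dmz / mean * 1e6 <= cfg.ppm_tol:
                        if best is None or dmz < best[0]:
                            best = (dmz, int(order[k]))
            if best is None:
                continue
            dmz, ti = best
            prev = matched.get(ti)
            if prev is None or intens[ci] > prev[2]:
                matched[ti] = (dmz, mz, intens[ci])
                used_centroids.add(ci)

        next_active: list[_Trace] = []
        for ti, trace in enumerate(active):
            hit = matched.get(ti)
            if hit is not None:
                trace.add(pos, hit[1], hit[2])
                next_active.append(trace)
            else:
                trace.gap += 1
                if trace.gap > max_scan_gap:
                    finalize(trace)
                else:
                    next_active.append(trace)
        for ci in range(mzs.size):
            if ci in used_centroids:
                continue
            t = _Trace()
            t.add(pos, float(mzs[ci]), float(intens[ci]))
            next_active.append(t)
        active = next_active

    for trace in active:
        finalize(trace)
    finished.sort(key=lambda r: (r.mz_center, r.scan_span[0]))
    return finished


def _ricker(n_points: int, scale: float) -> np.ndarray:
    """Mexican-hat wavelet sampled on ``n_points`` points."""
    x = np.arange(n_points) - (n_points - 1) / 2.0
    a2 = scale * scale
    amp = 2.0 / (np.sqrt(3.0 * scale) * np.pi**0.25)
    return amp * (1.0 - x * x / a2) * np.exp(-x * x / (2.0 * a2))


def _cwt_max(signal: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Maximum CWT coefficient per point across the scale set."""
    best = np.full(signal.size, -np.inf)
    for scale in scales:
        width = min(int(10 * scale + 1), signal.size)
        kernel = _ricker(width, scale)
        coeff = np.convolve(signal, kernel, mode="same")
        best = np.maximum(best, coeff)
    return best


def _dense_roi(roi: ROI, run: Run) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand an ROI trace to dense (rt, intensity, mz) arrays over its scan span."""
    first, last = roi.scan_span
    n = last - first + 1
    rts = np.array([run.ms1_spectra[first + i].rt for i in range(n)])
    intensity = np.zeros(n)
    mz = np.full(n, np.nan)
    for pos, m, i in roi.trace:
        intensity[pos - first] = i
        mz[pos - first] = m
    return rts, intensity, mz


def _find_boundaries(intensity: np.ndarray, apex: int, baseline: float,
                     noise_sd: float) -> tuple[int, int]:
    """Descend from the apex until the trace meets the local baseline."""
    stop = baseline + max(noise_sd, BOUNDARY_FRACTION * (intensity[apex] - baseline))
    left = apex
    while left > 0 and intensity[left - 1] > stop:
        if intensity[left - 1] > intensity[left] and \
                intensity[left] < baseline + 0.10 * (intensity[apex] - baseline):
            break  # local minimum well below the peak: split point
        left -= 1
    right = apex
    n = intensity.size
    while right < n - 1 and intensity[right + 1] > stop:
        if intensity[right + 1] > intensity[right] and \
                intensity[right] < baseline + 0.10 * (intensity[apex] - baseline):
            break
        right += 1
    return left, right


def _local_stats(intensity: np.ndarray, left: int, right: int,
                 cfg: PeakPickingConfig) -> tuple[float, float]:
    """Baseline and noise SD from ROI trace points outside [left, right]."""
    outside = np.concatenate([intensity[:left], intensity[right + 1:]])
    outside = outside[outside > 0]
    if outside.size >= 4:
        baseline = float(np.median(outside))
        noise_sd = float(1.4826 * np.median(np.abs(outside - baseline)))
        return baseline, max(noise_sd, 1.0)
    return float(np.median(intensity[intensity > 0])) if np.any(intensity > 0) else 0.0, \
        float(cfg.noise_floor)


def pick_peaks(run: Run, cfg: PeakPickingConfig,
               ms2_mass_tol: float = 0.01) -> list[Feature]:
    """Detect PP features in all ROIs of a run.

    Candidates are CWT maxima; they are kept when the boundary-to-boundary
    width lies within the peak-width bounds and S/N >= ``sn_threshold``.
    Features closer than ``mzdiff`` in m/z with overlapping RT ranges are
    merged keeping the higher apex. Each feature is assigned the MS2 scan
    whose precursor matches within ``ms2_mass_tol`` and whose trigger RT
    falls inside the feature's RT range.
    """
    cycle = run.ms1_cycle()
    features: list[Feature] = []
    for roi in detect_rois(run, cfg):
        rts, intensity, mzs = _dense_roi(roi, run)
        n = intensity.size
        if n < cfg.prefilter_k:
            continue
        scale_lo = max(cfg.peakwidth_min / (2.0 * cycle), 1.0)
        scale_hi = max(cfg.peakwidth_max / (2.0 * cycle), scale_lo + 1e-9)
        scales = np.geomspace(scale_lo, scale_hi, 10)
        coeff = _cwt_max(intensity, scales)
        # candidate apexes: local maxima of the CWT response with signal
        candidates = [
            i for i in range(1, n - 1)
            if coeff[i] > 0 and coeff[i] >= coeff[i - 1] and coeff[i] >= coeff[i + 1]
        ]
        if n >= 2 and coeff[0] > 0 and coeff[0] >= coeff[1]:
            candidates.insert(0, 0)
        if n >= 2 and coeff[-1] > 0 and coeff[-1] >= coeff[-2]:
            candidates.append(n - 1)
        claimed: list[tuple[int, int]] = []
        for cand in sorted(candidates, key=lambda i: -intensity[i]):
            # refine to the raw-intensity local maximum nearby
            radius = max(int(round(scale_lo)), 1)
            lo = max(cand - radius, 0)
            hi = min(cand + radius + 1, n)
            apex = lo + int(np.argmax(intensity[lo:hi]))
            if intensity[apex] <= 0:
                continue
            if any(a <= apex <= b for a, b in claimed):
                continue
            # reject candidates sitting on a monotone slope (e.g. the tail
            # of a wide distorted peak): the apex must be a raw local max
            left_ok = apex == 0 or intensity[apex] >= intensity[apex - 1]
            right_ok = apex == n - 1 or intensity[apex] >= intensity[apex + 1]
            if not (left_ok and right_ok):
                continue
            if 0 < apex < n - 1 and \
                    intensity[apex] <= min(intensity[apex - 1], intensity[apex + 1]):
                continue
            baseline, noise_sd = _local_stats(intensity, apex, apex, cfg)
            left, right = _find_boundaries(intensity, apex, baseline, noise_sd)
            baseline, noise_sd = _local_stats(intensity, left, right, cfg)
            left, right = _find_boundaries(intensity, apex, baseline, noise_sd)
            width = rts[right] - rts[left]
            if not (cfg.peakwidth_min <= width <= cfg.peakwidth_max):
                continue
            sn = (intensity[apex] - baseline) / max(noise_sd, 1.0)
            if sn < cfg.sn_threshold:
                continue
            claimed.append((left, right))
            seg = slice(left, right + 1)
            seg_i = intensity[seg]
            seg_mz = mzs[seg]
            good = ~np.isnan(seg_mz) & (seg_i > 0)
            mz = float(np.average(seg_mz[good], weights=seg_i[good])) if good.any() \
                else roi.mz_center
            features.append(
                Feature(
                    feature_id="",
                    mz=mz,
                    rt=float(rts[apex]),
                    rtmin=float(rts[left]),
                    rtmax=float(rts[right]),
                    intensity=float(intensity[apex]),
                    area=float(np.trapezoid(seg_i, rts[seg])),
                    source="PP",
                    sn=float(sn),
                )
            )

    features = _merge_close(features, cfg.mzdiff, cfg.peakwidth_min)
    features.sort(key=lambda f: (f.mz, f.rt))
    for i, f in enumerate(features):
        f.feature_id = f"PP{i + 1:04d}"
    _attach_ms2(features, run, ms2_mass_tol)
    return features


def _merge_close(features: list[Feature], mzdiff: float,
                 min_rt_sep: float) -> list[Feature]:
    """Merge features closer than mzdiff in m/z whose RT ranges overlap or
    whose apexes are closer than ``min_rt_sep``; the higher apex wins."""
    features = sorted(features, key=lambda f: -f.intensity)
    kept: list[Feature] = []
    for f in features:
        dup = any(
            abs(f.mz - k.mz) < mzdiff
            and ((f.rtmin <= k.rtmax and k.rtmin <= f.rtmax)
                 or abs(f.rt - k.rt) < min_rt_sep)
            for k in kept
        )
        if not dup:
            kept.append(f)
    return kept


def _attach_ms2(features: list[Feature], run: Run, mass_tol: float) -> None:
    ms2 = run.ms2_spectra
    for f in features:
        best = None
        for s in ms2:
            if s.precursor_mz is None:
                continue
            if abs(s.precursor_mz - f.mz) <= mass_tol and f.rtmin <= s.rt <= f.rtmax:
                key = (s.precursor_intensity or 0.0, -abs(s.rt - f.rt))
                if best is None or key > best[0]:
                    best = (key, s.scan_index)
        if best is not None:
            f.ms2_scan = best[1]
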