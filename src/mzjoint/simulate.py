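"""Seeded synthetic DDA LC-MS runs with ground truth.

Emulates a data-dependent acquisition: MS1 scans on a fixed cycle carrying
a matrix baseline plus injected chromatographic peaks, followed by top-N
MS2 triggering with a dynamic-exclusion window. Peak shapes are normalised
to unit apex on the scan grid, so the realised apex intensity of every
injected peak is exactly ``height * dilution`` — which makes the ground
truth an exact oracle for apex-based assertions. Baseline intensities also
scale with the dilution factor, emulating matrix dilution.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _mzml
from .errors import ConfigError
from .model import Feature, LibraryEntry, Run, Spectrum

SHAPE_CLASSES = ("gaussian", "fronting", "tailing", "shoulder", "spike")


@dataclass
class SynthConfig:
    seed: int = 0
    rt_span: float = 300.0
    ms1_cycle: float = 1.0
    dda_top_n: int = 3
    dda_trigger_threshold: float = 300.0
    dda_exclusion_cycles: int = 2
    baseline_mean: float = 100.0
    baseline_sd: float = 30.0
    n_background_per_scan: int = 40
    channel_baseline_prob: float = 0.4
    n_gaussian: int = 20
    n_distorted: int = 10
    n_subthreshold: int = 5
    mz_range: tuple[float, float] = (100.0, 900.0)
    height_range: tuple[float, float] = (2e4, 2e5)
    sigma_range: tuple[float, float] = (1.5, 3.5)
    dilution_factors: tuple[float, ...] = (1.0,)
    distorted_classes: tuple[str, ...] = ("fronting", "tailing")
    subthreshold_height_range: tuple[float, float] = (800.0, 2000.0)
    mz_jitter_ppm: float = 2.0
    min_centroid_intensity: float = 5.0
    # peaks whose scaled apex falls below this lose their Gaussian shape
    # and render as broad tailing peaks (chromatographic degradation at
    # low abundance); 0 disables
    shape_degrade_threshold: float = 0.0
    library: list[LibraryEntry] | None = None

    def __post_init__(self) -> None:
        if self.rt_span < 10 * self.ms1_cycle:
            raise ConfigError("rt_span must cover at least 10 MS1 cycles")
        if self.n_gaussian < 0 or self.n_distorted < 0 or self.n_subthreshold < 0:
            raise ConfigError("peak counts must be non-negative")
        bad = set(self.distorted_classes) - set(SHAPE_CLASSES)
        if bad:
            raise ConfigError(f"unknown shape classes {sorted(bad)}")


@dataclass
class _PeakSpec:
    peak_id: int
    mz: float
    rt_center: float
    height: float
    sigma: float
    shape_class: str
    tau: float = 0.0
    compound: str | None = None
    fragments: list[tuple[float, float]] = field(default_factory=list)


TRUTH_COLUMNS = [
    "peak_id", "mz", "rt", "height", "shape_class", "subthreshold",
    "dilution", "ms2_triggered", "compound",
]


def _unit_shape(peak: _PeakSpec, grid: np.ndarray) -> np.ndarray:
    """Peak profile over the scan grid, normalised to unit maximum."""
    t, rt0, s = grid, peak.rt_center, peak.sigma
    if peak.shape_class == "gaussian":
        y = np.exp(-((t - rt0) ** 2) / (2 * s**2))
    elif peak.shape_class in ("fronting", "tailing"):
        k = max(peak.tau / s, 0.05)
        x = t if peak.shape_class == "tailing" else (2 * rt0 - t)
        y = stats.exponnorm.pdf(x, k, loc=rt0, scale=s)
    elif peak.shape_class == "shoulder":
        y = np.exp(-((t - rt0) ** 2) / (2 * s**2)) + 0.45 * np.exp(
            -((t - rt0 - 2.2 * s) ** 2) / (2 * (0.8 * s) ** 2)
        )
    elif peak.shape_class == "spike":
        y = np.zeros_like(t)
        idx = int(np.argmin(np.abs(t - rt0)))
        y[idx] = 1.0
        if idx + 1 < y.size:
            y[idx + 1] = 0.5
    else:  # pragma: no cover
        raise ConfigError(f"unknown shape class {peak.shape_class}")
    peak_max = y.max()
    if peak_max <= 0:
        return np.zeros_like(y)
    return y / peak_max


def _random_fragments(rng: np.random.Generator, precursor_mz: float,
                      n: int = 5) -> list[tuple[float, float]]:
    mzs = np.sort(rng.uniform(50.0, max(precursor_mz - 1.0, 60.0), n))
    intens = rng.uniform(0.05, 1.0, n)
    return list(zip(mzs.tolist(), intens.tolist()))


def _draw_peaks(cfg: SynthConfig, rng: np.random.Generator) -> list[_PeakSpec]:
    n_total = cfg.n_gaussian + cfg.n_distorted + cfg.n_subthreshold
    mzs: list[float] = []
    while len(mzs) < n_total:
        mz = float(rng.uniform(*cfg.mz_range))
        if all(abs(mz - m) > 0.05 for m in mzs):
            mzs.append(mz)
    rt_lo, rt_hi = 0.1 * cfg.rt_span, 0.9 * cfg.rt_span
    peaks = []
    library = cfg.library or []
    for i in range(n_total):
        if i < cfg.n_gaussian:
            shape = "gaussian"
            height = float(rng.uniform(*cfg.height_range))
            sigma = float(rng.uniform(*cfg.sigma_range))
            tau = 0.0
        elif i < cfg.n_gaussian + cfg.n_distorted:
            shape = cfg.distorted_classes[(i - cfg.n_gaussian) % len(cfg.distorted_classes)]
            height = float(rng.uniform(*cfg.height_range))
            sigma = float(rng.uniform(3.0, 5.0))
            tau = float(rng.uniform(6.0, 12.0))
        else:
            # narrow low peaks the PP width filter legitimately rejects
            shape = "gaussian"
            height = float(rng.uniform(*cfg.subthreshold_height_range))
            sigma = float(rng.uniform(0.6, 0.9))
            tau = 0.0
        compound = None
        fragments: list[tuple[float, float]]
        if library and i < len(library):
            compound = library[i].compound_name
            fragments = list(library[i].fragments)
        else:
            fragments = _random_fragments(rng, mzs[i])
        peaks.append(
            _PeakSpec(
                peak_id=i,
                mz=mzs[i],
                rt_center=float(rng.uniform(rt_lo, rt_hi)),
                height=height,
                sigma=sigma,
                shape_class=shape,
                tau=tau,
                compound=compound,
                fragments=fragments,
            )
        )
    return peaks


def _is_subthreshold(cfg: SynthConfig, peak: _PeakSpec) -> bool:
    return peak.peak_id >= cfg.n_gaussian + cfg.n_distorted


def generate_run(cfg: SynthConfig, dilution: float = 1.0,
                 path: str | None = None,
                 sample_id: str | None = None) -> tuple[Run, pd.DataFrame]:
    """Generate one DDA run and its ground-truth table.

    The peak roster is a function of the seed alone, so runs generated at
    different dilution factors share identical peaks scaled in intensity.
    When ``path`` is given the run is also written as mzML (byte
    deterministic for a fixed config and dilution).
    """
    rng = np.random.default_rng(cfg.seed)
    peaks = _draw_peaks(cfg, rng)
    # per-dilution stream, decoupled from the roster draw
    dil_key = int(round(dilution * 1e6))
    scan_rng = np.random.default_rng([cfg.seed, dil_key])

    # chromatographic degradation: low-abundance Gaussians render distorted
    effective: list[_PeakSpec] = []
    for p in peaks:
        if (cfg.shape_degrade_threshold > 0
                and p.shape_class == "gaussian"
                and p.height * dilution < cfg.shape_degrade_threshold):
            effective.append(replace(p, shape_class="tailing",
                                     sigma=max(p.sigma, 3.0), tau=8.0))
        else:
            effective.append(p)
    peaks = effective

    n_scans = int(np.floor(cfg.rt_span / cfg.ms1_cycle)) + 1
    grid = np.arange(n_scans) * cfg.ms1_cycle
    profiles = np.stack([_unit_shape(p, grid) for p in peaks]) if peaks else \
        np.zeros((0, n_scans))
    apex_idx = profiles.argmax(axis=1) if peaks else np.array([], dtype=int)

    ms2_triggered = np.zeros(len(peaks), dtype=bool)
    exclusion: list[tuple[float, float]] = []  # (mz, rt of trigger)
    spectra: list[Spectrum] = []
    scan_counter = 0
    mz_lo, mz_hi = cfg.mz_range
    jitter_sd = cfg.mz_jitter_ppm * 1e-6

    for k in range(n_scans):
        rt = float(grid[k])
        mz_list: list[float] = []
        int_list: list[float] = []
        owners: list[int] = []  # peak_id or -1 for matrix
        # matrix background
        n_bg = cfg.n_background_per_scan
        bg_mz = scan_rng.uniform(mz_lo, mz_hi, n_bg)
        bg_int = scan_rng.lognormal(
            np.log(max(cfg.baseline_mean, 1e-6)),
            cfg.baseline_sd / max(cfg.baseline_mean, 1e-6),
            n_bg,
        ) * dilution
        for mz, inten in zip(bg_mz, bg_int):
            if inten >= cfg.min_centroid_intensity:
                mz_list.append(float(mz))
                int_list.append(float(inten))
                owners.append(-1)
        # per-channel baseline and peak signal
        channel_hits = scan_rng.uniform(size=len(peaks)) < cfg.channel_baseline_prob
        channel_int = scan_rng.lognormal(
            np.log(max(cfg.baseline_mean, 1e-6)),
            cfg.baseline_sd / max(cfg.baseline_mean, 1e-6),
            len(peaks),
        ) * dilution
        jitters = scan_rng.normal(0.0, jitter_sd, len(peaks) or 1)
        for pi, peak in enumerate(peaks):
            # one centroid per m/z channel per scan: the chromatographic
            # signal or, when absent/weaker, the matrix baseline draw
            signal = profiles[pi, k] * peak.height * dilution
            chem = float(channel_int[pi]) if channel_hits[pi] else 0.0
            value = max(signal, chem)
            if value >= cfg.min_centroid_intensity:
                mz_list.append(peak.mz * (1.0 + jitters[pi]))
                int_list.append(float(value))
                owners.append(peak.peak_id if signal >= chem else -1)
        order = np.argsort(mz_list, kind="stable")
        mz_arr = np.asarray(mz_list)[order]
        int_arr = np.asarray(int_list)[order]
        owner_arr = np.asarray(owners)[order] if owners else np.array([], dtype=int)
        ms1_scan_index = scan_counter
        spectra.append(
            Spectrum(
                scan_index=scan_counter,
                ms_level=1,
                rt=rt,
                mz_values=mz_arr,
                intensities=int_arr,
            )
        )
        scan_counter += 1
        # DDA top-N triggering with dynamic exclusion
        exclusion = [(m, t) for m, t in exclusion
                     if rt - t <= cfg.dda_exclusion_cycles * cfg.ms1_cycle]
        eligible = [
            i for i in range(mz_arr.size)
            if int_arr[i] >= cfg.dda_trigger_threshold
            and not any(abs(mz_arr[i] - m) <= 0.01 for m, _ in exclusion)
        ]
        eligible.sort(key=lambda i: -int_arr[i])
        for slot, ci in enumerate(eligible[: cfg.dda_top_n]):
            pmz = float(mz_arr[ci])
            exclusion.append((pmz, rt))
            owner = int(owner_arr[ci])
            if owner >= 0:
                ms2_triggered[owner] = True
                base = peaks[owner].fragments
            else:
                base = _random_fragments(scan_rng, pmz)
            frag_scale = float(int_arr[ci]) / max(max(i for _, i in base), 1e-12)
            noise = scan_rng.lognormal(0.0, 0.05, len(base))
            frag_mz = np.array([m for m, _ in base])
            frag_int = np.array([i for _, i in base]) * frag_scale * noise
            forder = np.argsort(frag_mz, kind="stable")
            spectra.append(
                Spectrum(
                    scan_index=scan_counter,
                    ms_level=2,
                    rt=rt + (slot + 1) * cfg.ms1_cycle / (cfg.dda_top_n + 1),
                    mz_values=frag_mz[forder],
                    intensities=frag_int[forder],
                    precursor_mz=pmz,
                    precursor_intensity=float(int_arr[ci]),
                    precursor_scan_index=ms1_scan_index,
                )
            )
            scan_counter += 1

    if sample_id is None:
        sample_id = f"synth_seed{cfg.seed}_dil{dilution:g}"
    run = Run(sample_id=sample_id, spectra=spectra, ms1_index=[])
    truth = pd.DataFrame(
        [
            {
                "peak_id": p.peak_id,
                "mz": p.mz,
                "rt": float(grid[apex_idx[i]]),
                "height": p.height * dilution,
                "shape_class": p.shape_class,
                "subthreshold": _is_subthreshold(cfg, p),
                "dilution": dilution,
                "ms2_triggered": bool(ms2_triggered[i]),
                "compound": p.compound,
            }
            for i, p in enumerate(peaks)
        ],
        columns=TRUTH_COLUMNS,
    )
    if path is not None:
        _mzml.write_mzml(run, path)
    return run, truth


def generate_dilution_series(cfg: SynthConfig) -> list[tuple[float, Run, pd.DataFrame]]:
    """One run per configured dilution factor, sharing the same peak roster."""
    return [(d, *generate_run(cfg, dilution=d)) for d in cfg.dilution_factors]


@dataclass
class ExtractionScore:
    recall: float
    precision: float
    recall_by_class: dict[str, float]
    tier_counts: dict[str, int]
    matches: list[tuple[int, int]]  # (found index, truth row position)
    precision_defined: bool = True


def score_extraction(found: list[Feature], truth: pd.DataFrame,
                     mass_tol: float = 0.01,
                     rt_tol: float = 10.0) -> ExtractionScore:
    """Match found features to ground-truth peaks (greedy by distance,
    one-to-one) and report recall per shape class plus overall precision."""
    pairs = []
    t_mz = truth["mz"].to_numpy()
    t_rt = truth["rt"].to_numpy()
    for fi, f in enumerate(found):
        dmz = np.abs(t_mz - f.mz)
        drt = np.abs(t_rt - f.rt)
        for ti in np.flatnonzero((dmz <= mass_tol) & (drt <= rt_tol)):
            pairs.append((dmz[ti] / mass_tol + drt[ti] / rt_tol, fi, int(ti)))
    pairs.sort()
    used_f: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, fi, ti in pairs:
        if fi in used_f or ti in used_t:
            continue
        used_f.add(fi)
        used_t.add(ti)
        matches.append((fi, ti))
    n_truth = len(truth)
    recall = len(matches) / n_truth if n_truth else 0.0
    classes = truth["shape_class"].to_numpy()
    matched_t = {ti for _, ti in matches}
    by_class: dict[str, float] = {}
    for cls in pd.unique(classes):
        pos = np.flatnonzero(classes == cls)
        by_class[str(cls)] = sum(1 for p in pos if p in matched_t) / pos.size
    tier_counts: dict[str, int] = {"PP": 0, "MR": 0, "TL": 0}
    for fi, _ in matches:
        tier_counts[found[fi].source] += 1
    if found:
        precision = len(matches) / len(found)
        defined = True
    else:
        precision = 0.0
        defined = False
    return ExtractionScore(
        recall=recall,
        precision=precision,
        recall_by_class=by_class,
        tier_counts=tier_counts,
        matches=matches,
        precision_defined=defined,
    )
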