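"""Serial-dilution calibration curves and LOD estimation.

LOD is the concentration at which the fitted line reaches 3x the local
noise intensity: LOD = (3 * noise - intercept) / slope, floored at 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InsufficientPointsError, InvalidFitError

#: sentinel for "no LOD reachable" (compound never detected by a tier-set)
LOD_NOT_REACHED = math.inf


@dataclass
class CalibrationSeries:
    """One compound's dilution series.

    ``points`` holds (concentration, intensity, detected_by) triples;
    ``intensity``/``detected_by`` are None at undetected levels.
    ``noise_intensity`` is the local noise at the compound's (m/z, RT),
    taken from the lowest-concentration run where it was detected.
    """

    compound: str
    points: list[tuple[float, float | None, str | None]] = field(default_factory=list)
    noise_intensity: float = 0.0

    def detected(self) -> list[tuple[float, float]]:
        return [(c, i) for c, i, _ in self.points if i is not None]


def fit_calibration(series: CalibrationSeries) -> tuple[float, float, float]:
    """OLS of intensity on concentration over detected points.

    Returns (slope, intercept, r_squared).
    """
    pts = series.detected()
    if len(pts) < 2:
        raise InsufficientPointsError(
            f"{series.compound}: {len(pts)} detected point(s), need >= 2"
        )
    conc = np.array([c for c, _ in pts])
    intens = np.array([i for _, i in pts])
    if np.ptp(conc) == 0:
        raise DegenerateFitError(f"{series.compound}: zero concentration variance")
    result = stats.linregress(conc, intens)
    return float(result.slope), float(result.intercept), float(result.rvalue**2)


def estimate_lod(series: CalibrationSeries,
                 fit: tuple[float, float] | tuple[float, float, float]) -> float:
    """Concentration at which the calibration line reaches 3x noise."""
    slope, intercept = fit[0], fit[1]
    if slope <= 0:
        raise InvalidFitError(f"{series.compound}: non-positive slope {slope}")
    return max((3.0 * series.noise_intensity - intercept) / slope, 0.0)


def _lod_or_sentinel(series: CalibrationSeries) -> tuple[float, float, float, float, int]:
    """(lod, slope, intercept, r2, n_points); sentinel LOD when unfittable."""
    try:
        slope, intercept, r2 = fit_calibration(series)
        lod = estimate_lod(series, (slope, intercept))
        return lod, slope, intercept, r2, len(series.detected())
    except (InsufficientPointsError, DegenerateFitError, InvalidFitError):
        return LOD_NOT_REACHED, math.nan, math.nan, math.nan, len(series.detected())


def compare_lods(series_pp: dict[str, CalibrationSeries],
                 series_joint: dict[str, CalibrationSeries]) -> pd.DataFrame:
    """Per-compound LODs from the PP-only tier-set vs the joint tier-set.

    fold_change = lod_pp / lod_joint (NaN when either is the not-reached
    sentinel and the other is too; inf when only PP failed).
    """
    rows = []
    for compound in sorted(set(series_pp) | set(series_joint)):
        sp = series_pp.get(compound, CalibrationSeries(compound))
        sj = series_joint.get(compound, CalibrationSeries(compound))
        lod_pp, slope, intercept, r2, n = _lod_or_sentinel(sp)
        lod_joint, slope_j, intercept_j, r2_j, n_j = _lod_or_sentinel(sj)
        if math.isinf(lod_pp) and math.isinf(lod_joint):
            fold = math.nan
        elif math.isinf(lod_pp):
            fold = math.inf
        elif lod_joint == 0:
            fold = math.inf if lod_pp > 0 else 1.0
        else:
            fold = lod_pp / lod_joint
        rows.append(
            {
                "compound": compound,
                "lod_pp": lod_pp,
                "lod_joint": lod_joint,
                "fold_change": fold,
                "slope": slope_j,
                "intercept": intercept_j,
                "r2": r2_j,
                "n_points": n_j,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound", "lod_pp", "lod_joint", "fold_change", "slope",
                 "intercept", "r2", "n_points"],
    )


def series_for_compound(name: str, mz: float, rt: float,
                        features_by_conc: dict[float, list],
                        runs_by_conc: dict[float, "object"],
                        mass_tol: float = 0.01, rt_tol: float = 10.0,
                        noise_floor: float = 100.0) -> CalibrationSeries:
    """Assemble a CalibrationSeries for one compound from per-concentration
    feature lists and raw runs.

    At each concentration the nearest feature within (mass_tol, rt_tol) of
    the compound's (m/z, RT) counts as the detection. The noise intensity
    is estimated from the EIC of the lowest-concentration run in which the
    compound was detected, excluding the peak region.
    """
    from .rescue import _consecutive_stretch, estimate_local_noise, extract_eic

    points: list[tuple[float, float | None, str | None]] = []
    detected_concs: list[float] = []
    for conc in sorted(features_by_conc):
        best = None
        for f in features_by_conc[conc]:
            if abs(f.mz - mz) <= mass_tol and abs(f.rt - rt) <= rt_tol:
                if best is None or f.intensity > best.intensity:
                    best = f
        if best is None:
            points.append((conc, None, None))
        else:
            points.append((conc, best.intensity, best.source))
            detected_concs.append(conc)
    noise = 0.0
    if detected_concs:
        lowest = min(detected_concs)
        eic = extract_eic(runs_by_conc[lowest], mz, mass_tol, rt, 60.0)
        nonzero = [i for i, p in enumerate(eic) if p[2] > 0]
        if nonzero:
            # exclude the contiguous signal stretch around the apex so the
            # peak (and its tail) does not inflate the noise estimate
            apex_pos = max(nonzero, key=lambda i: eic[i][2])
            lo, hi = _consecutive_stretch(eic, apex_pos)
            noise = estimate_local_noise(eic, (eic[lo][1], eic[hi][1]), noise_floor)
        else:
            noise = noise_floor
    return CalibrationSeries(compound=name, points=points, noise_intensity=noise)


def rsd_percent(values) -> float:
    """Relative standard deviation of replicate intensities, in percent."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or arr.mean() == 0:
        return math.nan
    return float(arr.std(ddof=1) / arr.mean() * 100.0) if arr.size > 1 else 0.0


def mean_rsd_by_tier(intensities: pd.DataFrame, sources: pd.Series) -> pd.Series:
    """Mean per-feature RSD%% grouped by extraction tier.

    ``intensities``: rows = features, columns = replicate samples;
    ``sources``: per-row tier tag aligned with ``intensities``.
    """
    rsds = intensities.apply(lambda row: rsd_percent(row.dropna()), axis=1)
    return rsds.groupby(sources).mean()
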