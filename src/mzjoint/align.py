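"""Cross-sample feature grouping and gap filling.

Density-style grouping: features are binned into overlapping m/z slices;
within a slice, maxima of a Gaussian kernel density over RT define groups.
Gap filling back-extracts the raw EIC maximum for samples in which a group
has no member.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingRunError
from .model import Feature, Run
from .rescue import extract_eic


@dataclass
class AlignmentConfig:
    bw: float = 5.0        # RT kernel bandwidth, s
    mzwid: float = 0.015   # m/z slice width, Th
    minfrac: float = 0.5
    minsamp: int = 1
    max_groups_per_slice: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.minfrac <= 1):
            raise ValueError("minfrac must be in (0, 1]")


@dataclass
class FeatureGroup:
    group_id: str
    mz_med: float
    rt_med: float
    members: dict[str, Feature] = field(default_factory=dict)
    intensities: dict[str, float] = field(default_factory=dict)
    filled: dict[str, bool] = field(default_factory=dict)

    @property
    def source_summary(self) -> dict[str, int]:
        counts = {"PP": 0, "MR": 0, "TL": 0}
        for f in self.members.values():
            counts[f.source] += 1
        return counts


def group_features(tables: dict[str, list[Feature]],
                   cfg: AlignmentConfig | None = None) -> list[FeatureGroup]:
    """Group per-sample features across samples.

    A group is kept iff it has members from at least
    max(minsamp, ceil(minfrac * n_samples)) samples; each sample
    contributes its nearest-RT feature. Output sorted by (mz_med, rt_med).
    """
    cfg = cfg or AlignmentConfig()
    samples = sorted(tables)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("at least one sample required")
    min_members = max(cfg.minsamp, math.ceil(cfg.minfrac * n_samples))

    flat = [(sid, f) for sid in samples for f in tables[sid]]
    if not flat:
        return []
    mzs = np.array([f.mz for _, f in flat])
    order = np.argsort(mzs)
    groups: list[FeatureGroup] = []
    mz_lo = mzs.min() - cfg.mzwid / 2
    mz_hi = mzs.max()
    step = cfg.mzwid / 2
    slice_lo = mz_lo
    while slice_lo <= mz_hi:
        lo_i = np.searchsorted(mzs[order], slice_lo)
        hi_i = np.searchsorted(mzs[order], slice_lo + cfg.mzwid, side="right")
        members = [flat[order[i]] for i in range(lo_i, hi_i)]
        if len(members) >= min_members:
            groups.extend(_group_slice(members, cfg, min_members))
        slice_lo += step

    groups = _dedupe_groups(groups, cfg)
    groups.sort(key=lambda g: (g.mz_med, g.rt_med))
    for i, g in enumerate(groups):
        g.group_id = f"G{i + 1:05d}"
    return groups


def _group_slice(members: list[tuple[str, Feature]], cfg: AlignmentConfig,
                 min_members: int) -> list[FeatureGroup]:
    rts = np.array([f.rt for _, f in members])
    grid_lo, grid_hi = rts.min() - 3 * cfg.bw, rts.max() + 3 * cfg.bw
    grid = np.arange(grid_lo, grid_hi + cfg.bw / 4, cfg.bw / 4)
    density = np.exp(
        -((grid[:, None] - rts[None, :]) ** 2) / (2 * cfg.bw**2)
    ).sum(axis=1)
    is_max = np.zeros(grid.size, dtype=bool)
    is_max[1:-1] = (density[1:-1] >= density[:-2]) & (density[1:-1] >= density[2:]) \
        & (density[1:-1] > 0)
    peak_rts = grid[is_max]
    peak_heights = density[is_max]
    if peak_rts.size == 0:
        return []
    keep = np.argsort(-peak_heights)[: cfg.max_groups_per_slice]
    peak_rts = np.sort(peak_rts[keep])

    # each feature joins the nearest density maximum
    assignment = np.argmin(np.abs(rts[:, None] - peak_rts[None, :]), axis=1)
    out = []
    for gi in range(peak_rts.size):
        idx = np.flatnonzero(assignment == gi)
        if idx.size == 0:
            continue
        rt_center = float(np.median(rts[idx]))
        best: dict[str, Feature] = {}
        for i in idx:
            sid, f = members[i]
            if sid not in best or abs(f.rt - rt_center) < abs(best[sid].rt - rt_center):
                best[sid] = f
        if len(best) < min_members:
            continue
        group = FeatureGroup(
            group_id="",
            mz_med=float(np.median([f.mz for f in best.values()])),
            rt_med=float(np.median([f.rt for f in best.values()])),
            members=best,
            intensities={sid: f.intensity for sid, f in best.items()},
            filled={sid: False for sid in best},
        )
        out.append(group)
    return out


def _dedupe_groups(groups: list[FeatureGroup],
                   cfg: AlignmentConfig) -> list[FeatureGroup]:
    """Overlapping slices produce duplicates; keep the larger group within
    (mzwid/2, bw/2) of another."""
    groups = sorted(groups, key=lambda g: (-len(g.members), g.mz_med, g.rt_med))
    kept: list[FeatureGroup] = []
    for g in groups:
        dup = any(
            abs(g.mz_med - k.mz_med) < cfg.mzwid / 2
            and abs(g.rt_med - k.rt_med) < cfg.bw / 2
            for k in kept
        )
        if not dup:
            kept.append(g)
    return kept


def gap_fill(groups: list[FeatureGroup], runs: dict[str, Run],
             cfg: AlignmentConfig | None = None,
             mass_tol: float = 0.01) -> list[FeatureGroup]:
    """Fill missing (group, sample) cells with the raw EIC maximum in the
    box [mz_med +/- mass_tol] x [rt_med +/- bw]; 0 when no signal."""
    cfg = cfg or AlignmentConfig()
    sample_ids = sorted(set(runs) | {s for g in groups for s in g.members})
    for g in groups:
        for sid in sample_ids:
            if sid in g.intensities:
                continue
            if sid not in runs or runs[sid] is None:
                raise MissingRunError(f"no raw run for sample {sid}")
            eic = extract_eic(runs[sid], g.mz_med, mass_tol, g.rt_med, cfg.bw)
            g.intensities[sid] = max((p[2] for p in eic), default=0.0)
            g.filled[sid] = True
    return groups


def aligned_table(groups: list[FeatureGroup], sample_ids: list[str]) -> pd.DataFrame:
    """Aligned table with one row per group and one column per sample."""
    rows = []
    for g in groups:
        s = g.source_summary
        row = {
            "group_id": g.group_id,
            "mz_med": g.mz_med,
            "rt_med": g.rt_med,
            "source_summary": f"PP:{s['PP']};MR:{s['MR']};TL:{s['TL']}",
        }
        for sid in sample_ids:
            row[sid] = g.intensities.get(sid, np.nan)
        row["filled_flags"] = ";".join(
            sid for sid in sample_ids if g.filled.get(sid, False)
        )
        rows.append(row)
    cols = ["group_id", "mz_med", "rt_med", "source_summary", *sample_ids, "filled_flags"]
    return pd.DataFrame(rows, columns=cols)
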