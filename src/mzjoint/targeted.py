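"""Targeted-list extraction (the TL tier).

Targets not already covered by PP or MR features are searched directly in
the raw MS1 data; candidates must beat the local noise by the configured
fold and must not duplicate a freshly rescued MR feature.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Feature, Run, TargetEntry
from .rescue import _consecutive_stretch, estimate_local_noise, extract_eic

logger = logging.getLogger(__name__)


@dataclass
class TLConfig:
    mass_tol: float = 0.01       # Th
    rt_tol: float = 30.0         # s
    noise_fold: float = 3.0
    min_consecutive_scans: int = 4
    noise_floor: float = 100.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TargetOutcome:
    """Per-target extraction report."""

    target: TargetEntry
    status: str  # extracted | already_extracted | noise_fail | mr_collision | no_signal
    feature: Feature | None = None


def run_tl(run: Run, targets: list[TargetEntry], existing: list[Feature],
           cfg: TLConfig | None = None,
           outcomes: list[TargetOutcome] | None = None) -> list[Feature]:
    """Extract TL features for every target missed by PP and MR.

    ``existing`` is the union of PP and MR features. Each target yields at
    most one feature (the best apex inside its window). Output order is
    (mz, rt), independent of target-list order.
    """
    cfg = cfg or TLConfig()
    mr_apex_positions = [
        _nearest_ms1_position(run, f.rt) for f in existing if f.source == "MR"
    ]
    mr_mzs = [f.mz for f in existing if f.source == "MR"]
    features: list[Feature] = []
    seen: set[tuple[float, float]] = set()
    for target in targets:
        outcome = _extract_one(run, target, existing, cfg, mr_apex_positions, mr_mzs)
        if outcomes is not None:
            outcomes.append(outcome)
        if outcome.feature is not None:
            key = (round(outcome.feature.mz, 6), round(outcome.feature.rt, 4))
            if key not in seen:
                seen.add(key)
                features.append(outcome.feature)
    features.sort(key=lambda f: (f.mz, f.rt))
    for i, f in enumerate(features):
        f.feature_id = f"TL{i + 1:04d}"
    logger.info("TL: %d targets -> %d features", len(targets), len(features))
    return features


def _nearest_ms1_position(run: Run, rt: float) -> int:
    rts = run.ms1_rts()
    return int(np.argmin(np.abs(rts - rt)))


def _extract_one(run: Run, target: TargetEntry, existing: list[Feature],
                 cfg: TLConfig, mr_apex_positions: list[int],
                 mr_mzs: list[float]) -> TargetOutcome:
    for f in existing:
        if abs(target.mz - f.mz) <= cfg.mass_tol and abs(target.rt - f.rt) <= cfg.rt_tol:
            return TargetOutcome(target, "already_extracted")
    eic = extract_eic(run, target.mz, cfg.mass_tol, target.rt, cfg.rt_tol)
    nonzero = [(i, p) for i, p in enumerate(eic) if p[2] > 0]
    if not nonzero:
        return TargetOutcome(target, "no_signal")
    apex_pos, apex = max(nonzero, key=lambda ip: (ip[1][2], -abs(ip[1][1] - target.rt)))
    lo, hi = _consecutive_stretch(eic, apex_pos)
    if hi - lo + 1 < cfg.min_consecutive_scans:
        return TargetOutcome(target, "no_signal")
    noise = estimate_local_noise(eic, (eic[lo][1], eic[hi][1]), cfg.noise_floor)
    if apex[2] <= cfg.noise_fold * noise:
        return TargetOutcome(target, "noise_fail")
    apex_ms1_pos = run.ms1_position(apex[0])
    for mr_pos, mr_mz in zip(mr_apex_positions, mr_mzs):
        if abs(apex_ms1_pos - mr_pos) < cfg.min_consecutive_scans \
                and abs(target.mz - mr_mz) <= cfg.mass_tol:
            return TargetOutcome(target, "mr_collision")
    seg = eic[lo:hi + 1]
    rts = np.array([p[1] for p in seg])
    intens = np.array([p[2] for p in seg])
    feature = Feature(
        feature_id="",
        mz=target.mz,
        rt=float(apex[1]),
        rtmin=float(rts[0]),
        rtmax=float(rts[-1]),
        intensity=float(apex[2]),
        area=float(np.trapezoid(intens, rts)),
        source="TL",
        sn=float(apex[2] / noise),
    )
    return TargetOutcome(target, "extracted", feature)
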