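import numpy as np
import pytest

from mzjoint.errors import ApexNotFoundError
from mzjoint.model import Feature, PrecursorCandidate
from mzjoint.peaks import PeakPickingConfig, pick_peaks
from mzjoint.rescue import (
    MRConfig,
    Rejection,
    dedupe_precursors,
    estimate_local_noise,
    extract_eic,
    filter_novel,
    relocate_to_apex,
    run_mr,
    validate_feature,
)
from mzjoint.simulate import SynthConfig, generate_run, score_extraction

from conftest import add_ms2, gaussian_trace, make_ms1_run


def _run_with_precursors(precursors, n_scans=80):
    """MS1 baseline run plus one MS2 scan per (mz, rt, intensity)."""
    run = make_ms1_run({500.0: {k: 200.0 for k in range(n_scans)}}, n_scans)
    for mz, rt, inten in precursors:
        run = add_ms2(run, mz, rt, precursor_intensity=inten)
    return run


class TestDedupePrecursors:
    def test_keeps_highest_intensity_within_window(self):
        run = _run_with_precursors(
            [(200.0000, 100.0, 500.0), (200.0050, 110.0, 900.0)]
        )
        kept = dedupe_precursors(run, MRConfig())
        assert len(kept) == 1
        assert kept[0].intensity == 900.0
        assert kept[0].mz == pytest.approx(200.0050)

    def test_outside_mz_window_kept_separately(self):
        run = _run_with_precursors(
            [(200.00, 100.0, 500.0), (200.02, 100.0, 900.0)]
        )
        assert len(dedupe_precursors(run, MRConfig())) == 2

    def test_single_precursor_identity(self):
        run = _run_with_precursors([(321.1234, 60.0, 777.0)])
        kept = dedupe_precursors(run, MRConfig())
        assert len(kept) == 1
        assert kept[0].mz == pytest.approx(321.1234)
        assert kept[0].intensity == 777.0

    def test_no_ms2_returns_empty(self):
        run = make_ms1_run({500.0: {k: 200.0 for k in range(20)}}, 20)
        assert dedupe_precursors(run, MRConfig()) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 51))
        precursors = [
            (float(rng.uniform(100, 110)), float(rng.uniform(0, 200)),
             float(rng.uniform(100, 10000)))
            for _ in range(n)
        ]
        run = _run_with_precursors(precursors, n_scans=210)
        cfg = MRConfig()
        kept = dedupe_precursors(run, cfg)
        oracle = _dedupe_oracle(precursors, cfg)
        assert sorted((round(c.mz, 6), round(c.intensity, 3)) for c in kept) == \
            sorted((round(m, 6), round(i, 3)) for m, _, i in oracle)


def _dedupe_oracle(precursors, cfg):
    """Independent O(n^2) clustering: repeatedly take the global intensity
    maximum and delete everything inside its window."""
    remaining = sorted(precursors, key=lambda p: (-p[2], p[0], p[1]))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            p for p in remaining
            if abs(p[0] - best[0]) > cfg.dedup_mz_tol
            or abs(p[1] - best[1]) > cfg.dedup_rt_tol
        ]
    return kept


class TestFilterNovel:
    def _feature(self, mz, rt):
        return Feature("PP0001", mz, rt, rt - 5, rt + 5, 1e4, 1e4, "PP")

    def test_candidate_near_picked_dropped(self):
        cand = PrecursorCandidate(200.000, 100.0, 500.0, 1)
        picked = [self._feature(200.004, 130.0)]
        assert filter_novel([cand], picked, MRConfig()) == []

    def test_candidate_outside_mass_tol_kept(self):
        cand = PrecursorCandidate(200.000, 100.0, 500.0, 1)
        picked = [self._feature(200.02, 100.0)]
        assert filter_novel([cand], picked, MRConfig()) == [cand]

    def test_empty_picked_identity(self):
        cands = [PrecursorCandidate(200.0, 100.0, 500.0, 1),
                 PrecursorCandidate(300.0, 50.0, 900.0, 3)]
        assert filter_novel(cands, [], MRConfig()) == cands


class TestExtractEic:
    def test_matches_injected_trace(self):
        trace = gaussian_trace(20, 3.0, 5e4, 40)
        run = make_ms1_run({250.0: trace}, n_scans=40)
        eic = extract_eic(run, 250.0, 0.01, 20.0, 10.0)
        assert len(eic) == 21
        for scan_idx, rt, inten in eic:
            assert inten == pytest.approx(trace.get(int(rt), 0.0))

    def test_no_signal_all_zero(self):
        run = make_ms1_run({250.0: {k: 1000.0 for k in range(20)}}, 20)
        eic = extract_eic(run, 600.0, 0.01, 10.0, 5.0)
        assert len(eic) == 11
        assert all(i == 0.0 for _, _, i in eic)

    def test_window_beyond_run_end(self):
        run = make_ms1_run({250.0: {k: 1000.0 for k in range(20)}}, 20)
        assert extract_eic(run, 250.0, 0.01, 500.0, 10.0) == []


class TestRelocateToApex:
    def _run(self):
        return make_ms1_run(
            {250.0: gaussian_trace(30, 4.0, 1e5, 60)}, n_scans=60
        )

    def test_rising_edge_relocated(self):
        run = self._run()
        # trigger at ~40% of apex height on the rising flank
        trigger_rt = 30 - 4.0 * np.sqrt(2 * np.log(1 / 0.4))
        cand = PrecursorCandidate(250.0, float(trigger_rt), 4e4, 0)
        moved = relocate_to_apex(run, cand, MRConfig())
        assert moved.intensity == pytest.approx(1e5)
        assert moved.rt == pytest.approx(30.0)
        assert moved.ms2_scan == 0

    def test_already_at_apex_unchanged(self):
        run = self._run()
        cand = PrecursorCandidate(250.0, 30.0, 1e5, 0)
        moved = relocate_to_apex(run, cand, MRConfig())
        assert moved.rt == 30.0
        assert moved.intensity == pytest.approx(1e5)

    def test_no_signal_raises(self):
        run = self._run()
        cand = PrecursorCandidate(999.0, 30.0, 100.0, 0)
        with pytest.raises(ApexNotFoundError):
            relocate_to_apex(run, cand, MRConfig())


class TestEstimateLocalNoise:
    def test_constant_baseline(self):
        eic = [(k, float(k), 100.0) for k in range(20)]
        assert estimate_local_noise(eic, (8.0, 12.0), 50.0) == 100.0

    def test_median_by_enumeration(self):
        values = [80.0, 90.0, 100.0, 110.0, 120.0]
        eic = [(k, float(k), v) for k, v in enumerate(values)]
        # exclusion window [10, 20] excludes nothing
        assert estimate_local_noise(eic, (10.0, 20.0), 50.0) == 100.0

    def test_fallback_to_floor(self):
        eic = [(0, 0.0, 50.0), (1, 1.0, 60.0), (2, 2.0, 0.0)]
        assert estimate_local_noise(eic, (10.0, 20.0), 100.0) == 100.0


class TestValidateFeature:
    def _run(self, apex, n_nonzero, baseline=100.0):
        # peak stretch of n_nonzero scans centered at 30, baseline elsewhere
        points = {}
        for k in range(60):
            if abs(k - 30) <= (n_nonzero - 1) // 2:
                points[k] = apex - 10.0 * abs(k - 30)
        trace = {250.0: points, 260.0: {k: baseline for k in range(60)}}
        return make_ms1_run(trace, n_scans=60)

    def test_valid_feature(self):
        run = self._run(apex=400.0, n_nonzero=7)
        cand = PrecursorCandidate(250.0, 30.0, 400.0, 0)
        cfg = MRConfig(noise_floor=100.0)
        result = validate_feature(run, cand, cfg)
        assert isinstance(result, Feature)
        assert result.source == "MR"
        assert result.intensity == 400.0
        assert result.rtmin <= result.rt <= result.rtmax

    def test_noise_fail(self):
        run = self._run(apex=250.0, n_nonzero=7)
        cand = PrecursorCandidate(250.0, 30.0, 250.0, 0)
        result = validate_feature(run, cand, MRConfig(noise_floor=100.0))
        assert isinstance(result, Rejection)
        assert result.reason == "noise_fail"

    def test_consecutive_fail(self):
        run = self._run(apex=400.0, n_nonzero=3)
        cand = PrecursorCandidate(250.0, 30.0, 400.0, 0)
        result = validate_feature(run, cand, MRConfig(noise_floor=100.0))
        assert isinstance(result, Rejection)
        assert result.reason == "consecutive_fail"


class TestRunMr:
    def test_distorted_peaks_rescued(self):
        cfg = SynthConfig(seed=5, n_gaussian=20, n_distorted=10, n_subthreshold=0)
        run, truth = generate_run(cfg)
        pp = pick_peaks(run, PeakPickingConfig())
        mr = run_mr(run, pp, MRConfig())
        distorted = truth[truth.shape_class.isin(["fronting", "tailing"])]
        assert distorted.ms2_triggered.all()
        score = score_extraction(pp + mr, truth)
        matched_t = {ti for _, ti in score.matches}
        rescued = sum(1 for i in distorted.index if i in matched_t)
        assert rescued == len(distorted) == 10

    def test_ms2_only_on_picked_peaks_gives_zero(self):
        cfg = SynthConfig(seed=5, n_distorted=0, n_subthreshold=0)
        run, _ = generate_run(cfg)
        pp = pick_peaks(run, PeakPickingConfig())
        assert run_mr(run, pp, MRConfig()) == []

    def test_no_ms2_gives_zero(self):
        cfg = SynthConfig(seed=5, dda_top_n=0)
        run, _ = generate_run(cfg)
        pp = pick_peaks(run, PeakPickingConfig())
        assert run_mr(run, pp, MRConfig()) == []


@pytest.fixture(scope="module")
def extracted():
    cfg = SynthConfig(seed=13)
    run, truth = generate_run(cfg)
    pp = pick_peaks(run, PeakPickingConfig())
    mr = run_mr(run, pp, MRConfig())
    return run, pp, mr


class TestMrInvariants:
    def test_disjoint_from_pp(self, extracted):
        _, pp, mr = extracted
        cfg = MRConfig()
        for m in mr:
            for p in pp:
                assert not (
                    abs(m.mz - p.mz) <= cfg.confirm_mass_tol
                    and abs(m.rt - p.rt) <= cfg.confirm_rt_tol
                )

    def test_noise_and_consecutive_conditions_hold(self, extracted):
        run, _, mr = extracted
        cfg = MRConfig()
        for m in mr:
            eic = extract_eic(run, m.mz, cfg.confirm_mass_tol, m.rt,
                              cfg.confirm_rt_tol)
            noise = estimate_local_noise(eic, (m.rtmin, m.rtmax), cfg.noise_floor)
            assert m.intensity > cfg.noise_fold * noise
            in_stretch = [p for p in eic if m.rtmin <= p[1] <= m.rtmax]
            assert len(in_stretch) >= cfg.min_consecutive_scans
            assert all(p[2] > 0 for p in in_stretch)

    def test_apex_dominates_trigger_intensity(self, extracted):
        run, pp, mr = extracted
        cands = {c.ms2_scan: c for c in dedupe_precursors(run, MRConfig())}
        for m in mr:
            if m.ms2_scan in cands:
                assert m.intensity >= cands[m.ms2_scan].intensity - 1e-9

    def test_noise_fold_monotonicity(self, extracted):
        run, pp, _ = extracted
        n_strict = len(run_mr(run, pp, MRConfig(noise_fold=5.0)))
        n_loose = len(run_mr(run, pp, MRConfig(noise_fold=2.0)))
        assert n_loose >= n_strict
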