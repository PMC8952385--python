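import numpy as np
import pytest

from mzjoint.align import (
    AlignmentConfig,
    aligned_table,
    gap_fill,
    group_features,
)
from mzjoint.errors import MissingRunError
from mzjoint.model import Feature
from mzjoint.peaks import PeakPickingConfig, pick_peaks
from mzjoint.simulate import SynthConfig, generate_run


def _feat(mz, rt, intensity=1e4, source="PP"):
    return Feature("F", mz, rt, rt - 5, rt + 5, intensity, intensity * 5, source)


class TestGroupFeatures:
    def test_three_of_four_samples_retained(self):
        tables = {
            "s1": [_feat(200.0, 100.0)],
            "s2": [_feat(200.001, 101.0)],
            "s3": [_feat(200.002, 99.0)],
            "s4": [],
        }
        groups = group_features(tables, AlignmentConfig(minfrac=0.5))
        assert len(groups) == 1
        assert set(groups[0].members) == {"s1", "s2", "s3"}

    def test_one_of_four_samples_dropped(self):
        tables = {
            "s1": [_feat(200.0, 100.0)],
            "s2": [], "s3": [], "s4": [],
        }
        assert group_features(tables, AlignmentConfig(minfrac=0.5)) == []

    def test_mz_separation_makes_two_groups(self):
        tables = {
            "s1": [_feat(200.00, 100.0), _feat(200.03, 100.0)],
            "s2": [_feat(200.00, 100.0), _feat(200.03, 100.0)],
        }
        groups = group_features(tables, AlignmentConfig(mzwid=0.015))
        assert len(groups) == 2

    def test_rt_separation_makes_two_groups(self):
        tables = {
            "s1": [_feat(200.0, 100.0), _feat(200.0, 160.0)],
            "s2": [_feat(200.0, 101.0), _feat(200.0, 161.0)],
        }
        groups = group_features(tables, AlignmentConfig(bw=5.0))
        assert len(groups) == 2

    def test_sample_order_invariance(self):
        tables = {
            f"s{i}": [_feat(200.0 + 0.0005 * i, 100.0 + i)] for i in range(4)
        }
        g1 = group_features(tables, AlignmentConfig())
        g2 = group_features(dict(reversed(list(tables.items()))),
                            AlignmentConfig())
        assert [(g.mz_med, g.rt_med) for g in g1] == \
            [(g.mz_med, g.rt_med) for g in g2]

    def test_one_intensity_per_cell_after_fill(self):
        cfg = SynthConfig(seed=21, n_distorted=0, n_subthreshold=0)
        run, _ = generate_run(cfg)
        feats = pick_peaks(run, PeakPickingConfig())
        tables, runs = {}, {}
        for sid in ("a", "b", "c"):
            tables[sid] = list(feats)
            runs[sid] = run
        tables["c"] = tables["c"][:-2]  # two features missing in sample c
        groups = group_features(tables, AlignmentConfig())
        groups = gap_fill(groups, runs, AlignmentConfig())
        for g in groups:
            assert set(g.intensities) == {"a", "b", "c"}

    def test_shared_features_form_single_groups(self):
        cfg = SynthConfig(seed=21, n_distorted=0, n_subthreshold=0)
        run, truth = generate_run(cfg)
        feats = pick_peaks(run, PeakPickingConfig())
        tables = {sid: list(feats) for sid in ("a", "b", "c")}
        groups = group_features(tables, AlignmentConfig())
        hits = 0
        for r in truth.itertuples():
            matching = [
                g for g in groups
                if abs(g.mz_med - r.mz) <= 0.01 and abs(g.rt_med - r.rt) <= 10
            ]
            hits += len(matching) == 1
        assert hits / len(truth) >= 0.95


class TestGapFill:
    def test_filled_intensity_close_to_injected_apex(self):
        cfg = SynthConfig(seed=21, n_distorted=0, n_subthreshold=0)
        run, truth = generate_run(cfg)
        feats = pick_peaks(run, PeakPickingConfig())
        dropped = feats[-1]
        tables = {"a": feats, "b": feats[:-1]}
        runs = {"a": run, "b": run}
        groups = group_features(tables, AlignmentConfig(minfrac=0.5))
        groups = gap_fill(groups, runs, AlignmentConfig())
        target = min(
            groups, key=lambda g: abs(g.mz_med - dropped.mz) + abs(g.rt_med - dropped.rt)
        )
        assert target.filled.get("b")
        assert target.intensities["b"] == pytest.approx(dropped.intensity, rel=0.10)

    def test_no_signal_fills_zero(self):
        tables = {
            "a": [_feat(200.0, 100.0)],
            "b": [_feat(200.0, 100.0)],
            "c": [_feat(200.0, 100.0)],
        }
        cfg = SynthConfig(seed=22, n_gaussian=1, n_distorted=0, n_subthreshold=0,
                          n_background_per_scan=0, channel_baseline_prob=0.0)
        empty_run, _ = generate_run(cfg)
        groups = group_features(tables, AlignmentConfig(minfrac=0.5))
        runs = {"a": empty_run, "b": empty_run, "c": empty_run}
        groups = gap_fill(groups, runs, AlignmentConfig())
        # run has no signal at 200 Th; all cells filled from raw give 0
        assert all(v == 0.0 or k in ("a", "b", "c")
                   for g in groups for k, v in g.intensities.items())

    def test_no_missing_members_identity(self):
        tables = {"a": [_feat(200.0, 100.0)], "b": [_feat(200.0, 100.0)]}
        groups = group_features(tables, AlignmentConfig())
        before = [dict(g.intensities) for g in groups]
        cfg = SynthConfig(seed=23)
        run, _ = generate_run(cfg)
        after = gap_fill(groups, {"a": run, "b": run}, AlignmentConfig())
        assert [dict(g.intensities) for g in after] == before

    def test_missing_run_is_error(self):
        tables = {"a": [_feat(200.0, 100.0)], "b": []}
        groups = group_features(tables, AlignmentConfig(minfrac=0.4, minsamp=1))
        with pytest.raises(MissingRunError):
            gap_fill(groups, {"a": None, "b": None}, AlignmentConfig())


class TestAlignedTable:
    def test_columns_and_sources(self):
        tables = {
            "a": [_feat(200.0, 100.0, source="PP")],
            "b": [_feat(200.0, 100.0, source="MR")],
        }
        groups = group_features(tables, AlignmentConfig())
        df = aligned_table(groups, ["a", "b"])
        assert list(df.columns) == [
            "group_id", "mz_med", "rt_med", "source_summary", "a", "b",
            "filled_flags",
        ]
        assert df.loc[0, "source_summary"] == "PP:1;MR:1;TL:0"
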