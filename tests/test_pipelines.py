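"""The three analysis aims: scan-rescan assignment and selection, the
paired-bias grids, mover classification, and cohort reporting."""

import numpy as np
import pandas as pd
import pytest

from dwimotion.errors import ValidationError
from dwimotion.motion_descriptors import MotionSummary
from dwimotion.pipelines import (
    ScanRecord,
    assign_scan_rescan,
    classify_movers,
    cohort_report,
    group_motion_comparison,
    mover_group_diff,
    paired_bias_test,
    select_top_movers_diff,
)
from dwimotion.simulate import (
    FEATURE_POPULATIONS,
    CohortSimConfig,
    FeatureSimConfig,
    TraceSimConfig,
    simulate_cohort,
    simulate_paired_features,
)


def make_record(subject="s1", session="ses1", scan_index=1, mean=0.1, **kw):
    summary = MotionSummary(
        mean_rel_mm_per_vol=mean,
        median_rel_mm_per_vol=mean * 0.9,
        mean_rel_mm_per_min=mean * 20.0,
        trans_rate_per_vol=np.zeros(3),
        trans_rate_per_min=np.zeros(3),
        rot_rate_per_vol=np.zeros(3),
        rot_rate_per_min=np.zeros(3),
        cumulative_mm=np.linspace(0.0, 9.0 * mean, 10),
        tr_seconds=3.0,
    )
    defaults = dict(cohort="SYN", age=50.0, sex="F", dx="CN")
    defaults.update(kw)
    return ScanRecord(subject=subject, session=session, scan_index=scan_index,
                      summary=summary, **defaults)


class TestAssignScanRescan:
    def test_ordering_by_motion(self):
        r1 = make_record(scan_index=1, mean=0.2)
        r2 = make_record(scan_index=2, mean=0.1)
        less, more = assign_scan_rescan([r1, r2])
        assert less is r2 and more is r1

    def test_tie_goes_to_first_scan(self):
        r1 = make_record(scan_index=1, mean=0.1)
        r2 = make_record(scan_index=2, mean=0.1)
        less, more = assign_scan_rescan([r1, r2])
        assert less is r1 and more is r2

    def test_invariant_to_input_order(self):
        r1 = make_record(scan_index=1, mean=0.3)
        r2 = make_record(scan_index=2, mean=0.15)
        assert assign_scan_rescan([r1, r2]) == assign_scan_rescan([r2, r1])

    def test_wrong_scan_count_rejected(self):
        with pytest.raises(ValidationError):
            assign_scan_rescan([make_record()])


class TestSelectTopMovers:
    def _sessions(self, diffs):
        out = {}
        for i, d in enumerate(diffs):
            subj = f"sub-{i:03d}"
            less = make_record(subject=subj, scan_index=1, mean=0.1)
            more = make_record(subject=subj, scan_index=2, mean=0.1 + d)
            out[subj] = (less, more)
        return out

    def test_selects_largest_differences(self, rng):
        diffs = rng.uniform(0, 0.5, size=300)
        sessions = self._sessions(diffs)
        selected = select_top_movers_diff(sessions, k=120)
        expected = set(np.array(sorted(sessions))[np.argsort(-diffs, kind="stable")[:120]])
        assert set(selected) == expected
        assert len(selected) == 120

    def test_k_equals_n_returns_all(self):
        sessions = self._sessions([0.1, 0.2, 0.3])
        assert set(select_top_movers_diff(sessions, k=3)) == set(sessions)

    def test_boundary_tie_broken_by_subject_id(self):
        sessions = self._sessions([0.3, 0.1, 0.1])
        selected = select_top_movers_diff(sessions, k=2)
        assert selected == ["sub-000", "sub-001"]  # lexicographic at the tie

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_top_movers_diff(self._sessions([0.1]), k=2)


class TestPairedBiasTest:
    def test_identical_tables_all_p_one(self):
        less, _ = simulate_paired_features(
            FeatureSimConfig(n_subjects=10, seed=5, domains=("micro",))
        )
        grid = paired_bias_test(less, less.assign(scan="scan-more"), "micro")
        assert np.all(grid.table["p"] == 1.0)
        assert grid.n_significant == 0
        assert np.all(grid.table["pct_change"] == 0.0)

    def test_grid_dimensions(self):
        cfg = FeatureSimConfig(n_subjects=12, seed=6, domains=("micro", "macro"))
        less, more = simulate_paired_features(cfg)
        micro = paired_bias_test(less, more, "micro")
        macro = paired_bias_test(less, more, "macro")
        assert micro.n_tests == 200 and micro.grid_shape == (4, 50)
        assert macro.n_tests == 350 and macro.grid_shape == (7, 50)

    def test_injected_shift_detected_and_quantified(self):
        cfg = FeatureSimConfig(
            n_subjects=120,
            seed=7,
            domains=("micro",),
            injected_bias={("FA", "AF_left"): 0.95},
            populations={**FEATURE_POPULATIONS, "FA": (0.45, 0.03, 0.45 * 0.001)},
        )
        less, more = simulate_paired_features(cfg)
        grid = paired_bias_test(less, more, "micro")
        row = grid.table.set_index(["measure", "bundle"]).loc[("FA", "AF_left")]
        assert bool(row["reject"])
        assert row["pct_change"] == pytest.approx(-5.0, abs=0.1)
        others = grid.table.set_index(["measure", "bundle"]).drop(index=("FA", "AF_left"))
        assert others["reject"].sum() <= 2  # null features stay quiet

    def test_unpaired_subject_rejected(self):
        less, more = simulate_paired_features(
            FeatureSimConfig(n_subjects=8, seed=8, domains=("micro",))
        )
        with pytest.raises(ValidationError, match="unpaired"):
            paired_bias_test(less, more[more["subject"] != "sub-0003"], "micro")

    def test_conn_domain_has_five_tests(self):
        less, more = simulate_paired_features(
            FeatureSimConfig(n_subjects=8, seed=9, domains=("conn",), conn_nodes=30)
        )
        grid = paired_bias_test(less, more, "conn")
        assert grid.n_tests == 5


class TestClassifyMovers:
    def _pool(self):
        # 100 sessions with values 0.01 .. 1.00: quartiles are unambiguous
        records = []
        for i in range(100):
            records.append(
                make_record(subject=f"sub-{i:03d}", session="ses-1", mean=(i + 1) / 100.0)
            )
        return records

    def test_hand_computed_percentile_partition(self):
        records = self._pool()
        labels = classify_movers(records, pct=25.0)
        values = np.array([(i + 1) / 100.0 for i in range(100)])
        low = np.percentile(values, 25.0)
        high = np.percentile(values, 75.0)
        for i in range(100):
            v = values[i]
            expected = "non_mover" if v < low else "mover" if v > high else "neither"
            assert labels[f"sub-{i:03d}"] == expected

    def test_extreme_subject_labels(self):
        records = self._pool()
        labels = classify_movers(records)
        assert labels["sub-000"] == "non_mover"
        assert labels["sub-099"] == "mover"

    def test_mixed_sessions_are_neither(self):
        records = self._pool()
        records.append(make_record(subject="sub-mix", session="ses-1", mean=0.01))
        records.append(make_record(subject="sub-mix", session="ses-2", mean=0.99))
        assert classify_movers(records)["sub-mix"] == "neither"

    def test_stable_under_dataset_duplication(self):
        records = self._pool()
        doubled = records + [
            make_record(subject=r.subject, session="ses-2", mean=r.summary.mean_rel_mm_per_vol)
            for r in records
        ]
        assert classify_movers(records) == classify_movers(doubled)


class TestMoverGroupDiff:
    def _features(self, labels, shift=0.0, n_bundles=4, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subj, label in labels.items():
            for b in range(n_bundles):
                for measure in ("FA", "MD", "AD", "RD"):
                    val = rng.normal(0.0, sd) + (shift if label == "mover" else 0.0)
                    rows.append((subj, "ses-1", "scan-1", f"B{b}", measure, val))
        return pd.DataFrame(
            rows, columns=["subject", "session", "scan", "bundle", "measure", "value"]
        )

    def _demo(self, labels, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject": list(labels),
                "age": rng.uniform(20, 80, len(labels)),
                "sex": rng.choice(["F", "M"], len(labels)),
            }
        )

    def test_null_features_mostly_quiet(self):
        labels = {f"s{i}": ("mover" if i % 2 else "non_mover") for i in range(40)}
        feats = self._features(labels, shift=0.0, n_bundles=50)
        grid = mover_group_diff(feats, labels, self._demo(labels), "micro")
        assert grid.n_tests == 200
        assert grid.n_significant <= 5  # BH on null features

    def test_injected_group_shift_detected(self):
        labels = {f"s{i}": ("mover" if i < 40 else "non_mover") for i in range(80)}
        feats = self._features(labels, shift=0.0, n_bundles=4, seed=3)
        target = (feats["bundle"] == "B0") & (feats["measure"] == "FA")
        movers = feats["subject"].isin([s for s, l in labels.items() if l == "mover"])
        feats.loc[target & movers, "value"] += 3.0  # 3 noise-sd shift
        grid = mover_group_diff(feats, labels, self._demo(labels), "micro")
        row = grid.table.set_index(["measure", "bundle"]).loc[("FA", "B0")]
        assert bool(row["reject"])
        assert row["coef"] == pytest.approx(3.0, abs=1.0)

    def test_single_group_rejected(self):
        labels = {f"s{i}": "mover" for i in range(10)}
        feats = self._features(labels)
        with pytest.raises(ValidationError):
            mover_group_diff(feats, labels, self._demo(labels), "micro")


class TestCohortReport:
    def test_single_scan_echoes_summary(self):
        rec = make_record(mean=0.123)
        rep = cohort_report([rec])
        assert rep["SYN"]["n_scans"] == 1
        assert rep["SYN"]["mm_per_vol"]["mean"] == pytest.approx(0.123)

    def test_child_cohort_reports_more_motion_than_adult(self):
        child = simulate_cohort(
            CohortSimConfig(n_subjects=25, age_range=(1.0, 8.0), cohort_id="CHILD", seed=11),
            TraceSimConfig(n_volumes=30),
        )
        adult = simulate_cohort(
            CohortSimConfig(n_subjects=25, age_range=(25.0, 55.0), cohort_id="ADULT", seed=12),
            TraceSimConfig(n_volumes=30),
        )
        rep = cohort_report(child + adult)
        assert rep["CHILD"]["mm_per_min"]["mean"] > rep["ADULT"]["mm_per_min"]["mean"]

    def test_ap_translation_dominates_with_default_anisotropy(self):
        recs = simulate_cohort(
            CohortSimConfig(n_subjects=30, age_range=(25.0, 55.0), seed=13),
            TraceSimConfig(n_volumes=40),
        )
        trans = cohort_report(recs)["SYN"]["trans_mm_per_min"]
        assert trans["PA"] > trans["LR"] and trans["PA"] > trans["IS"]


class TestGroupMotionComparison:
    def test_offset_group_detected(self):
        rng = np.random.default_rng(21)
        records = [
            make_record(subject=f"cn{i}", dx="CN", mean=float(abs(rng.normal(0.10, 0.02))))
            for i in range(100)
        ] + [
            make_record(subject=f"ad{i}", dx="AD", mean=float(abs(rng.normal(0.15, 0.02))))
            for i in range(100)
        ]
        table = group_motion_comparison(records)
        row = table[(table["group_a"] == "AD") & (table["group_b"] == "CN")].iloc[0]
        assert bool(row["reject"])

    def test_null_rejection_rate_within_binomial_interval(self):
        rng = np.random.default_rng(22)
        n_rep, alpha = 200, 0.05
        rejections = 0
        tests = 0
        for _ in range(n_rep):
            records = [
                make_record(subject=f"a{i}", dx="CN", mean=float(abs(rng.normal(0.1, 0.02))))
                for i in range(20)
            ] + [
                make_record(subject=f"b{i}", dx="CI", mean=float(abs(rng.normal(0.1, 0.02))))
                for i in range(20)
            ]
            table = group_motion_comparison(records)
            rejections += int(table["reject"].sum())
            tests += len(table)
        rate = rejections / tests
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / tests)
        assert rate <= alpha + half  # one test per replicate: BH = plain alpha test

    def test_single_group_rejected(self):
        records = [make_record(subject=f"s{i}", dx="CN") for i in range(5)]
        with pytest.raises(ValidationError):
            group_motion_comparison(records)

    def test_groups_of_one_rejected(self):
        records = [make_record(subject="a", dx="CN"), make_record(subject="b", dx="AD")]
        with pytest.raises(ValidationError):
            group_motion_comparison(records)
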