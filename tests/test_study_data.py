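import zlib

import numpy as np
import pytest

from gistmem.geometry import Layout, Point, Screen, dist
from gistmem.study_data import (
    Cohort,
    SchemaError,
    apply_exclusions,
    apply_swap_correction,
    cohort_to_frame,
    correct_cohort_swaps,
    detect_swaps,
    read_cohort,
    write_cohort,
)
from gistmem.synthetic import GenerativeParams, generate_cohort

from conftest import make_record


@pytest.fixture
def swap_layout():
    """Four well-separated items on a wide screen, for misbinding scenarios."""
    return Layout(
        screen=Screen(1366, 768),
        labels=("A", "B", "C", "D"),
        points=(Point(100, 100), Point(300, 100), Point(900, 600), Point(1200, 200)),
    )


class TestCohortIO:
    def _small_cohort(self, toy_layout):
        recs = [
            make_record(toy_layout, [(310, 305), (690, 310), (505, 590)], (495, 400),
                        session="S1"),
            make_record(toy_layout, [(320, 290), (710, 295), (520, 615)], (510, 395),
                        session="S2"),
        ]
        return Cohort(toy_layout, recs)

    def test_round_trip(self, toy_layout, tmp_path):
        cohort = self._small_cohort(toy_layout)
        path = tmp_path / "trials.csv"
        write_cohort(cohort, path)
        back = read_cohort(path, toy_layout)
        assert len(back.records) == 2
        for a, b in zip(cohort.records, back.records):
            assert a.participant_id == b.participant_id and a.session == b.session
            for lab in toy_layout.labels:
                assert a.retrieved[lab] == b.retrieved[lab]
            assert a.reported_center == b.reported_center

    def test_round_trip_frame_equality(self, toy_layout, tmp_path):
        cohort = self._small_cohort(toy_layout)
        import pandas as pd

        f1 = cohort_to_frame(cohort)
        f2 = cohort_to_frame(read_cohort(f1, toy_layout))
        key = ["participant_id", "session", "record_type", "item_label"]
        pd.testing.assert_frame_equal(
            f1.sort_values(key).reset_index(drop=True),
            f2.sort_values(key).reset_index(drop=True),
            check_dtype=False,
        )

    def test_missing_center_row_is_schema_error(self, toy_layout):
        df = cohort_to_frame(self._small_cohort(toy_layout))
        broken = df[~((df.session == "S2") & (df.record_type == "center"))]
        with pytest.raises(SchemaError, match="S2"):
            read_cohort(broken, toy_layout)

    def test_duplicate_item_row_is_schema_error(self, toy_layout):
        df = cohort_to_frame(self._small_cohort(toy_layout))
        import pandas as pd
        dup = pd.concat([df, df[(df.session == "S1") & (df.item_label == "a")]])
        with pytest.raises(SchemaError, match="duplicate"):
            read_cohort(dup, toy_layout)

    def test_unknown_label_is_schema_error(self, toy_layout):
        df = cohort_to_frame(self._small_cohort(toy_layout))
        df.loc[(df.session == "S1") & (df.item_label == "a"), "item_label"] = "zzz"
        with pytest.raises(SchemaError, match="zzz"):
            read_cohort(df, toy_layout)


class TestSwapDetection:
    def test_hand_constructed_swap_found(self, swap_layout):
        # A and B exchanged labels; retrievals land near the partner's spot
        rec = make_record(
            swap_layout,
            {"A": (290, 100), "B": (110, 100), "C": (905, 605), "D": (1195, 205)},
            (600, 300),
        )
        assert detect_swaps(rec, swap_layout) == [("A", "B")]
        fixed = apply_swap_correction(rec, [("A", "B")])
        assert dist(fixed.retrieved["A"], swap_layout.point_of("A")) == pytest.approx(10)
        assert dist(fixed.retrieved["B"], swap_layout.point_of("B")) == pytest.approx(10)

    def test_own_nearest_retrievals_give_no_pairs(self, swap_layout):
        rec = make_record(
            swap_layout,
            {"A": (105, 95), "B": (298, 110), "C": (890, 610), "D": (1210, 190)},
            (600, 300),
        )
        assert detect_swaps(rec, swap_layout) == []

    def test_third_retrieval_in_range_blocks_pair(self, swap_layout):
        # C's retrieval intrudes into the A-B neighbourhood (condition 4)
        rec = make_record(
            swap_layout,
            {"A": (290, 100), "B": (110, 100), "C": (250, 120), "D": (1195, 205)},
            (600, 300),
        )
        assert ("A", "B") not in detect_swaps(rec, swap_layout)

    def test_far_mutual_nearest_blocks_pair(self, swap_layout):
        # mutual nearest but outside the half-separation range (condition 3)
        rec = make_record(
            swap_layout,
            {"A": (430, 100), "B": (-30, 100), "C": (905, 605), "D": (1195, 205)},
            (600, 300),
        )
        assert detect_swaps(rec, swap_layout) == []

    def test_correction_is_idempotent_under_redetection(self, swap_layout):
        rec = make_record(
            swap_layout,
            {"A": (290, 100), "B": (110, 100), "C": (905, 605), "D": (1195, 205)},
            (600, 300),
        )
        once = apply_swap_correction(rec, detect_swaps(rec, swap_layout))
        assert detect_swaps(once, swap_layout) == []
        twice = apply_swap_correction(once, detect_swaps(once, swap_layout))
        assert twice.retrieved == once.retrieved

    def test_overlapping_pairs_rejected(self, swap_layout):
        rec = make_record(
            swap_layout,
            {"A": (290, 100), "B": (110, 100), "C": (905, 605), "D": (1195, 205)},
            (600, 300),
        )
        with pytest.raises(ValueError):
            apply_swap_correction(rec, [("A", "B"), ("B", "C")])

    def test_swap_back_never_increases_pair_error(self, swap_layout):
        """On random records, any detected pair improves after swapping back."""
        rng = np.random.default_rng(17)
        enc = swap_layout.coords()
        for _ in range(200):
            ret = enc + rng.normal(0, 150, size=enc.shape)
            ret = np.clip(ret, 0, [swap_layout.screen.width, swap_layout.screen.height])
            rec = make_record(swap_layout, [tuple(p) for p in ret], (600, 300))
            for a, b in detect_swaps(rec, swap_layout):
                before = dist(rec.retrieved[a], swap_layout.point_of(a)) + dist(
                    rec.retrieved[b], swap_layout.point_of(b)
                )
                after = dist(rec.retrieved[b], swap_layout.point_of(a)) + dist(
                    rec.retrieved[a], swap_layout.point_of(b)
                )
                assert after < before

    def test_correction_is_noop_on_swap_free_cohort(self, exp1_layout):
        params = GenerativeParams(
            n_participants=6, sessions=("S1",), delay_groups={"24h": 6},
            item_error_scale=60.0, gist_error_scale=30.0, swap_rate=0.0, seed=5,
        )
        cohort = generate_cohort(exp1_layout, params)
        corrected = correct_cohort_swaps(cohort)
        for a, b in zip(cohort.records, corrected.records):
            assert a.retrieved == b.retrieved


class TestExclusions:
    def _nominal_record(self, layout, pid, session="S1", jitter=20.0, rng=None):
        rng = rng or np.random.default_rng(zlib.crc32(pid.encode()))
        enc = layout.coords()
        ret = enc + rng.normal(0, jitter, size=enc.shape)
        tc = layout.true_center
        return make_record(
            layout, [tuple(p) for p in ret], (tc.x + 5, tc.y - 5), pid=pid,
            group="24h" if layout.outlier_label is None else "within_subject",
        )

    def test_corner_gist_report_excluded_exp1(self, exp1_layout):
        recs = [self._nominal_record(exp1_layout, f"p{i:02d}") for i in range(6)]
        bad = self._nominal_record(exp1_layout, "bad")
        bad = make_record(
            exp1_layout,
            [(p.x, p.y) for p in bad.retrieved.values()],
            (3.0, 3.0),  # screen corner: farther from the true center than chance
            pid="bad",
        )
        cohort = Cohort(exp1_layout, recs + [bad])
        kept, report = apply_exclusions(cohort, "exp1")
        assert report.excluded.get("bad") == "gist_out_of_scope"
        assert "bad" not in kept.participant_ids

    def test_zero_variance_cohort_has_no_sd_exclusions(self, exp1_layout):
        # identical records -> SD is 0 and nobody is strictly above mean + 3 SD
        enc = [(p.x + 15, p.y) for p in exp1_layout.points]
        tc = exp1_layout.true_center
        recs = [
            make_record(exp1_layout, enc, (tc.x + 10, tc.y), pid=f"p{i:02d}")
            for i in range(5)
        ]
        kept, report = apply_exclusions(Cohort(exp1_layout, recs), "exp1")
        assert report.excluded == {}
        assert report.retained_n == 5

    def test_extreme_performer_hits_three_sd_rule(self, exp1_layout):
        rng = np.random.default_rng(23)
        recs = [
            self._nominal_record(exp1_layout, f"p{i:02d}", rng=rng) for i in range(20)
        ]
        sc = exp1_layout.screen
        wild = make_record(
            exp1_layout,
            [(sc.width - 5.0, 5.0)] * exp1_layout.n_items,  # every item at a far corner
            (exp1_layout.true_center.x, exp1_layout.true_center.y),
            pid="wild",
        )
        kept, report = apply_exclusions(Cohort(exp1_layout, recs + [wild]), "exp1")
        assert report.excluded.get("wild") == "three_sd"

    def test_misplaced_outlier_excluded_exp2(self, exp2_layout):
        rng = np.random.default_rng(29)
        recs = [self._nominal_record(exp2_layout, f"p{i:02d}", rng=rng) for i in range(8)]
        # this participant drags the outlier into the main cluster
        lc = exp2_layout.local_center
        bad_ret = {lab: recs[0].retrieved[lab] for lab in exp2_layout.labels}
        bad_ret[exp2_layout.outlier_label] = lc
        bad = make_record(
            exp2_layout,
            {lab: (p.x, p.y) for lab, p in bad_ret.items()},
            (lc.x, lc.y),
            pid="bad",
            group="within_subject",
        )
        kept, report = apply_exclusions(Cohort(exp2_layout, recs + [bad]), "exp2")
        assert report.excluded.get("bad") == "outlier_misplaced"

    def test_exp2_does_not_apply_gist_scope_rule(self, exp2_layout):
        # a far-off gist report alone is not an exclusion in the outlier design
        rng = np.random.default_rng(31)
        recs = [self._nominal_record(exp2_layout, f"p{i:02d}", rng=rng) for i in range(8)]
        far = make_record(
            exp2_layout,
            {lab: (p.x, p.y) for lab, p in recs[0].retrieved.items()},
            (exp2_layout.point_of(exp2_layout.outlier_label).x,
             exp2_layout.point_of(exp2_layout.outlier_label).y),
            pid="farg",
            group="within_subject",
        )
        kept, report = apply_exclusions(Cohort(exp2_layout, recs + [far]), "exp2")
        assert report.excluded.get("farg") != "gist_out_of_scope"

    def test_participant_local_rules_are_monotone(self, exp1_layout):
        """Adding a well-behaved participant cannot trigger rule (a) for others."""
        rng = np.random.default_rng(37)
        recs = [self._nominal_record(exp1_layout, f"p{i:02d}", rng=rng) for i in range(10)]
        _, before = apply_exclusions(Cohort(exp1_layout, recs), "exp1")
        extra = self._nominal_record(exp1_layout, "extra", rng=rng)
        _, after = apply_exclusions(Cohort(exp1_layout, recs + [extra]), "exp1")
        gist_before = {p for p, r in before.excluded.items() if r == "gist_out_of_scope"}
        gist_after = {p for p, r in after.excluded.items() if r == "gist_out_of_scope"}
        assert gist_before == gist_after

    def test_tiny_cohort_skips_sd_rule_with_warning(self, exp1_layout):
        rec = self._nominal_record(exp1_layout, "only")
        with pytest.warns(UserWarning, match="3 SD"):
            kept, report = apply_exclusions(Cohort(exp1_layout, [rec]), "exp1")
        assert report.retained_n == 1
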