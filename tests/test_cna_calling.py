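import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cghcohort import cna_calling as cc
from cghcohort.io_formats import CloneMap, Config


def moving_median_oracle(values, window):
    """Direct per-index moving median with shrinking end windows."""
    half = window // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        w = [v for v in values[lo:hi] if not np.isnan(v)]
        out.append(float(np.median(w)) if w else np.nan)
    return np.array(out)


class TestSmoothProfile:
    def test_window_one_is_identity(self):
        v = np.array([0.1, -0.5, 0.3, np.nan])
        out = cc.smooth_profile(v, 1)
        assert np.array_equal(out, v, equal_nan=True)

    def test_constant_sequence_preserved(self):
        v = np.full(7, 0.42)
        assert np.allclose(cc.smooth_profile(v, 5), 0.42)

    def test_plateau_example_window3(self):
        v = np.array([0, 0, -0.32, -0.32, -0.32, 0, 0])
        out = cc.smooth_profile(v, 3)
        expected = np.array([0, 0, -0.32, -0.32, -0.32, 0, 0])
        assert np.allclose(out, expected)

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=-2, max_value=2, allow_nan=False),
                st.just(np.nan),
            ),
            min_size=1,
            max_size=30,
        ),
        st.sampled_from([1, 3, 5, 7]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_oracle(self, values, window):
        import warnings

        v = np.array(values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cc.smooth_profile(v, window)
        assert np.allclose(out, moving_median_oracle(v, window), equal_nan=True)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            cc.smooth_profile(np.zeros(5), 4)

    def test_all_missing_warns(self):
        with pytest.warns(UserWarning, match="all-missing"):
            out = cc.smooth_profile(np.full(5, np.nan), 3)
        assert np.all(np.isnan(out))

    def test_2d_matches_per_column(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(20, 4))
        block[3, 1] = np.nan
        out = cc.smooth_profile(block, 5)
        for j in range(4):
            assert np.allclose(
                out[:, j], cc.smooth_profile(block[:, j], 5), equal_nan=True
            )


class TestCallStates:
    def test_examples(self, cfg):
        states = cc.call_states(np.array([0.0, 0.25, -0.30, np.nan]), cfg)
        assert list(states) == [0, 1, -1, 0]

    def test_boundaries_inclusive(self, cfg):
        states = cc.call_states(np.array([cfg.gain_cut, cfg.loss_cut]), cfg)
        assert list(states) == [1, -1]

    @given(ratio=st.floats(min_value=0.01, max_value=10, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_threshold_scale_equivalence(self, ratio):
        """Calling on the ratio scale equals calling log2(ratio) at log2 cuts."""
        cfg = Config()
        log2_state = cc.call_states(np.array([np.log2(ratio)]), cfg)[0]
        if ratio >= cfg.gain_ratio:
            assert log2_state == 1
        elif ratio <= cfg.loss_ratio:
            assert log2_state == -1
        else:
            assert log2_state == 0

    @given(
        st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=40),
        st.floats(min_value=1.01, max_value=1.5),
        st.floats(min_value=1.01, max_value=1.5),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotonicity_in_thresholds(self, values, g1, g2):
        lo_gain, hi_gain = sorted([g1, g2])
        v = np.array(values)
        n_lo = np.sum(cc.call_states(v, Config(gain_ratio=lo_gain)) == 1)
        n_hi = np.sum(cc.call_states(v, Config(gain_ratio=hi_gain)) == 1)
        assert n_hi <= n_lo


def extract_oracle(states, raw, positions, cfg):
    """Brute-force enumeration of maximal qualifying runs."""
    out = []
    i = 0
    while i < len(states):
        j = i
        while j + 1 < len(states) and states[j + 1] == states[i]:
            j += 1
        if states[i] != 0 and (j - i + 1) >= cfg.min_segment_clones:
            mean = float(np.nanmean(raw[i : j + 1]))
            out.append(
                (
                    float(positions[i]),
                    float(positions[j]) + 1.0,
                    "gain" if states[i] > 0 else "loss",
                    j - i + 1,
                )
            )
        i = j + 1
    return out


class TestExtractSegments:
    def test_three_clone_loss_run(self, cfg):
        segs = cc.extract_segments(
            [-1, -1, -1], [-0.5, -0.5, -0.5], [47.0, 48.0, 49.0], "CFA16", "c1", cfg
        )
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_mb, seg.end_mb, seg.size_mb) == (47.0, 50.0, 3.0)
        assert seg.state == "loss" and seg.n_clones == 3

    def test_short_runs_suppressed(self, cfg):
        segs = cc.extract_segments(
            [-1, 0, -1], [-0.5, 0.0, -0.5], [1.0, 2.0, 3.0], "CFA1", "c1", cfg
        )
        assert segs == []

    def test_homozygous_flag_from_raw_mean(self, cfg):
        segs = cc.extract_segments(
            [-1, -1, -1], [-1.2, -1.2, -1.2], [43.0, 44.0, 45.0], "CFA11", "c1", cfg
        )
        assert segs[0].homozygous_flag
        shallow = cc.extract_segments(
            [-1, -1, -1], [-0.5, -0.5, -0.5], [43.0, 44.0, 45.0], "CFA11", "c1", cfg
        )
        assert not shallow[0].homozygous_flag

    def test_homozygous_requires_loss_state(self):
        with pytest.raises(ValueError):
            cc.Segment("c", "CFA1", 0, 1, "gain", 0.5, 2, homozygous_flag=True)

    @given(
        st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20),
        st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_run_enumeration_oracle(self, states, min_clones):
        cfg = Config(min_segment_clones=min_clones)
        raw = np.asarray(states, dtype=float) * 0.5
        pos = np.arange(len(states), dtype=float)
        got = [
            (s.start_mb, s.end_mb, s.state, s.n_clones)
            for s in cc.extract_segments(states, raw, pos, "CFA1", "c", cfg)
        ]
        assert got == extract_oracle(np.array(states), raw, pos, cfg)


class TestCallCase:
    def test_pure_noise_profiles_stay_flat(self, cfg, toy_map):
        big_map = CloneMap.from_records(
            [(f"P{i:03d}", "CFA1", float(i)) for i in range(120)],
            chrom_lengths={"CFA1": 125.0},
        )
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = cc.call_case("c", rng.normal(0, 0.05, 120), big_map, cfg)
            assert not res.aberrant

    def test_zero_noise_plant_recovered_exactly(self, cfg, toy_map):
        values = np.zeros(10)
        values[4:7] = -0.5
        res = cc.call_case("c", values, toy_map, cfg)
        assert len(res.segments) == 1
        seg = res.segments[0]
        assert (seg.start_mb, seg.end_mb, seg.state) == (4.0, 7.0, "loss")

    def test_aberrant_iff_segments(self, cfg, toy_map):
        flat = cc.call_case("c", np.zeros(10), toy_map, cfg)
        assert not flat.aberrant and flat.segments == []


class TestCohortCalls:
    def test_f1_case_carrying_cfa16_plant(self, f1_cohort, f1_results):
        carriers = {
            t.case_id
            for t in f1_cohort.truth
            if t.chrom == "CFA16" and t.start_mb == 47.0
        }
        by_case = {r.case_id: r for r in f1_results}
        cid = sorted(carriers)[0]
        hits = [
            s
            for s in by_case[cid].segments
            if s.chrom == "CFA16" and s.overlaps("CFA16", 47.0, 53.0) and s.state == "loss"
        ]
        assert len(hits) == 1

    def test_f1_aberrant_count(self, f1_results):
        assert sum(r.aberrant for r in f1_results) == 86


class TestSummarize:
    @pytest.mark.filterwarnings("ignore:no aberrant FCR")
    def test_two_case_arithmetic(self, result_factory):
        r1 = result_factory(
            "BMD001",
            [("CFA1", 0, 3, "loss"), ("CFA1", 10, 13, "loss"), ("CFA2", 0, 3, "gain")],
        )
        r2 = result_factory("BMD002", [("CFA1", 0, 3, "loss"), ("CFA2", 0, 3, "gain")])
        from cghcohort.io_formats import CaseMeta

        meta = [
            CaseMeta("BMD001", "BMD", "USA"),
            CaseMeta("BMD002", "BMD", "USA"),
        ]
        summary = cc.summarize_cohort([r1, r2], meta)
        combined = summary["combined"]
        assert combined.mean_n_cnas == pytest.approx(2.5)
        assert combined.mean_n_losses == pytest.approx(1.5)
        assert combined.mean_n_gains == pytest.approx(1.0)
        assert combined.loss_gain_ratio == pytest.approx(1.5)

    @pytest.mark.filterwarnings("ignore:no aberrant FCR")
    def test_single_loss_size_stats(self, result_factory):
        from cghcohort.io_formats import CaseMeta

        r = result_factory("BMD001", [("CFA1", 0, 3, "loss")])
        summary = cc.summarize_cohort([r], [CaseMeta("BMD001", "BMD", "USA")])
        assert summary["combined"].mean_size_loss_mb == pytest.approx(3.0)
        assert summary["combined"].sd_size_loss_mb == 0.0

    def test_empty_stratum_warns(self, result_factory):
        from cghcohort.io_formats import CaseMeta

        r = result_factory("BMD001", [("CFA1", 0, 3, "loss")])
        with pytest.warns(UserWarning, match="FCR"):
            summary = cc.summarize_cohort([r], [CaseMeta("BMD001", "BMD", "USA")])
        assert "FCR" not in summary

    def test_f1_mean_cna_count_near_expected(self, f1_results):
        counts = [len(r.segments) for r in f1_results if r.aberrant]
        assert abs(np.mean(counts) - 30.7) <= 2 * 17.6 / np.sqrt(86)


class TestSizeHistogram:
    def test_single_loss(self, result_factory):
        segs = result_factory("c", [("CFA1", 0, 3, "loss")]).segments
        hist = cc.size_histogram(segs, [0, 15, 30, 45])
        assert list(hist["loss"]) == [1, 0, 0]
        assert list(hist["gain"]) == [0, 0, 0]

    def test_empty(self):
        hist = cc.size_histogram([], [0, 10, 20])
        assert list(hist["loss"]) == [0, 0]

    def test_left_closed_right_open(self, result_factory):
        segs = result_factory("c", [("CFA1", 0, 15, "loss")]).segments
        hist = cc.size_histogram(segs, [0, 15, 30])
        assert list(hist["loss"]) == [0, 1]
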