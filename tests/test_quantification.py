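import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from promforge.quantification import (
    ExpressionPatternRecord,
    GatingConfig,
    MissingStrainError,
    StrainSummary,
    VisualScore,
    baseline_subtract,
    classify_and_count,
    gate_adults,
    relative_to_control,
    score_summary,
    summaries_frame,
    summarize_strain,
    summarize_strains,
)
from promforge.synthetic_data import synth_copas


def events_frame(rows):
    return pd.DataFrame(rows, columns=["strain", "tof", "extinction", "green"])


class TestGating:
    def test_tof_bounds_inclusive(self):
        df = events_frame(
            [
                ("s", 1499, 100, 1.0),
                ("s", 1500, 100, 1.0),
                ("s", 1800, 100, 1.0),
                ("s", 1801, 100, 1.0),
            ]
        )
        gated = gate_adults(df)
        assert list(gated["tof"]) == [1500, 1800]

    def test_extinction_bound_strict(self):
        df = events_frame(
            [("s", 1600, 34999.9, 1.0), ("s", 1600, 35000.0, 1.0)]
        )
        gated = gate_adults(df)
        assert list(gated["extinction"]) == [34999.9]

    def test_empty_in_empty_out(self):
        assert len(gate_adults(events_frame([]))) == 0

    def test_order_preserved(self):
        df = events_frame(
            [("a", 1600, 1, 3.0), ("b", 1700, 1, 1.0), ("a", 1550, 1, 2.0)]
        )
        assert list(gate_adults(df)["green"]) == [3.0, 1.0, 2.0]

    def test_planted_adult_fraction_recovered(self):
        events, truth = synth_copas(
            {"s": 1.0}, n_events=10_000, adult_fraction=0.3, seed=8
        )
        gated = gate_adults(events)
        frac = len(gated) / len(events)
        # adults fall in the TOF window w.p. Phi(3) - Phi(-3)
        expected = 0.3 * (stats.norm.cdf(3) - stats.norm.cdf(-3))
        assert abs(frac - expected) < 0.03

    def test_gating_config_validation(self):
        with pytest.raises(ValueError):
            GatingConfig(tof_min=1800, tof_max=1500)
        with pytest.raises(ValueError):
            GatingConfig(extinction_max=0)

    def test_negative_tof_rejected(self):
        with pytest.raises(ValueError):
            gate_adults(events_frame([("s", -1, 0, 0.0)]))

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 3000, allow_nan=False),
                st.floats(0, 60000, allow_nan=False),
            ),
            max_size=40,
        ),
        st.floats(0, 200),
        st.floats(0, 200),
        st.floats(1, 20000),
    )
    @settings(max_examples=50, deadline=None)
    def test_gating_monotone(self, pts, widen_lo, widen_hi, raise_ext):
        df = events_frame([("s", t, e, 0.0) for t, e in pts])
        narrow = gate_adults(df, GatingConfig(1500, 1800, 35000))
        wide = gate_adults(
            df, GatingConfig(1500 - widen_lo, 1800 + widen_hi, 35000 + raise_ext)
        )
        assert set(narrow.index) <= set(wide.index)


class TestSummaries:
    def test_hand_arithmetic(self):
        df = events_frame(
            [("s", 1600, 1, 1.0), ("s", 1600, 1, 2.0), ("s", 1600, 1, 3.0)]
        )
        s = summarize_strain(df, "s")
        assert s.mean_green == 2.0
        assert s.sem_green == pytest.approx(1 / math.sqrt(3))
        assert s.n_gated == 3

    def test_single_event_sem_undefined(self):
        df = events_frame([("s", 1600, 1, 5.0)])
        s = summarize_strain(df, "s")
        assert s.mean_green == 5.0
        assert s.sem_green is None

    def test_missing_strain_error(self):
        df = events_frame([("s", 1600, 1, 5.0)])
        with pytest.raises(MissingStrainError):
            summarize_strain(df, "t")

    def test_lognormal_mean_within_3_sem(self, rng):
        mu, sigma = 2.0, 0.5
        draws = rng.lognormal(mu, sigma, size=10_000)
        df = events_frame([("s", 1600, 1, g) for g in draws])
        s = summarize_strain(df, "s")
        analytic = math.exp(mu + sigma**2 / 2)
        assert abs(s.mean_green - analytic) < 3 * s.sem_green

    def test_permutation_invariance(self, rng):
        greens = rng.normal(10, 2, size=50)
        df = events_frame([("s", 1600, 1, g) for g in greens])
        shuffled = df.sample(frac=1.0, random_state=4)
        a = summarize_strain(df, "s")
        b = summarize_strain(shuffled, "s")
        assert a.mean_green == pytest.approx(b.mean_green)
        assert a.sem_green == pytest.approx(b.sem_green)


class TestNormalization:
    @pytest.fixture
    def summaries(self):
        return [
            StrainSummary("N2", 10, 100.0, 1.0),
            StrainSummary("hi", 10, 350.0, 2.0),
            StrainSummary("lo", 10, 150.0, 2.0),
        ]

    def test_baseline_subtraction(self, summaries):
        out = baseline_subtract(summaries, "N2")
        by = {s.strain: s.baseline_subtracted_mean for s in out}
        assert by == {"N2": 0.0, "hi": 250.0, "lo": 50.0}

    def test_differences_preserved(self, summaries):
        out = baseline_subtract(summaries, "N2")
        by = {s.strain: s for s in out}
        assert (
            by["hi"].baseline_subtracted_mean - by["lo"].baseline_subtracted_mean
            == by["hi"].mean_green - by["lo"].mean_green
        )

    def test_ratio_mode(self, summaries):
        out = relative_to_control(summaries, "N2", "ratio")
        by = {s.strain: s.relative_to_control for s in out}
        assert by["hi"] == 3.5
        assert by["N2"] == 1.0
        assert all(s.relative_mode == "ratio" for s in out)

    def test_difference_mode(self, summaries):
        out = relative_to_control(summaries, "N2", "difference")
        assert {s.strain: s.relative_to_control for s in out}["hi"] == 250.0

    def test_missing_control(self, summaries):
        with pytest.raises(MissingStrainError):
            baseline_subtract(summaries, "CB4856")

    def test_zero_control_ratio_rejected(self):
        summaries = [StrainSummary("N2", 5, 0.0, 1.0), StrainSummary("x", 5, 5.0, 1.0)]
        with pytest.raises(ZeroDivisionError):
            relative_to_control(summaries, "N2", "ratio")

    def test_planted_ratios_recovered(self):
        folds = {"N2": 1.0, "x2": 2.0, "x5": 5.0, "x10": 10.0}
        events, _ = synth_copas(folds, n_events=5000, adult_fraction=0.6, seed=12)
        gated = gate_adults(events)
        out = relative_to_control(summarize_strains(gated), "N2", "ratio")
        for s in out:
            assert s.relative_to_control == pytest.approx(folds[s.strain], rel=0.05)


class TestVisualScores:
    def test_hand_arithmetic(self):
        scores = [VisualScore("s", i, v) for i, v in enumerate([4, 4, 3])]
        out = score_summary(scores)
        assert out.loc["s", "mean_score"] == pytest.approx(11 / 3)
        assert out.loc["s", "sem_score"] == pytest.approx(
            np.std([4, 4, 3], ddof=1) / math.sqrt(3)
        )

    def test_all_zero(self):
        out = score_summary([VisualScore("s", i, 0) for i in range(3)])
        assert out.loc["s", "mean_score"] == 0.0

    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            VisualScore("s", 0, 5)

    def test_blinding_applied(self):
        scores = [VisualScore("code7", 0, 4), VisualScore("code7", 1, 2)]
        out = score_summary(scores, blinding={"code7": "klp-19"})
        assert list(out.index) == ["klp-19"]

    def test_unknown_blind_code(self):
        with pytest.raises(KeyError):
            score_summary([VisualScore("codeX", 0, 1)], blinding={"code7": "x"})

    def test_rank_concordance_with_cytometry(self):
        # planted monotone truth: visual scores and folds increase together
        folds = {"N2": 1.0, "a": 2.0, "b": 5.0, "c": 10.0, "d": 20.0}
        events, _ = synth_copas(folds, n_events=4000, adult_fraction=0.5, seed=5)
        gated = gate_adults(events)
        ratios = {
            s.strain: s.relative_to_control
            for s in relative_to_control(summarize_strains(gated), "N2", "ratio")
        }
        visual = {"N2": 0, "a": 1, "b": 2, "c": 3, "d": 4}
        names = sorted(folds)
        rho = stats.spearmanr(
            [ratios[n] for n in names], [visual[n] for n in names]
        ).statistic
        assert rho >= 0.9


class TestClassification:
    def test_reference_pattern_counts(self):
        from promforge.fixtures import load_expression_patterns

        counts = classify_and_count(load_expression_patterns())
        assert counts == {
            "somatic_and_germline": 6,
            "none": 3,
            "germline_specific": 9,
        }

    def test_empty_input(self):
        assert classify_and_count([]) == {
            "somatic_and_germline": 0,
            "none": 0,
            "germline_specific": 0,
        }

    def test_single_record(self):
        counts = classify_and_count(
            [ExpressionPatternRecord("p", "germline_specific")]
        )
        assert counts["germline_specific"] == 1
        assert sum(counts.values()) == 1

    def test_duplicate_promoter_rejected(self):
        recs = [
            ExpressionPatternRecord("p", "none"),
            ExpressionPatternRecord("p", "germline_specific"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            classify_and_count(recs)

    def test_pattern_set_closed(self):
        with pytest.raises(ValueError):
            ExpressionPatternRecord("p", "ubiquitous")


def test_summaries_frame_columns():
    frame = summaries_frame([StrainSummary("s", 3, 1.0, 0.5, 0.0, 1.0, "ratio")])
    assert list(frame.columns) == [
        "strain", "n", "mean", "sem", "baseline_subtracted",
        "relative_mode", "relative_value",
    ]
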