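"""Scoring-chain unit tests: IRT arithmetic, transition labels, cosine
similarity, ratio identities, speed classes, switch-relative positions, and
participant summaries."""

import numpy as np
import pandas as pd
import pytest

import semforage as sf
from semforage.errors import DataError, NumericError
from conftest import make_spoken_log, make_typed_log


class TestComputeIrt:
    def test_spoken_definition(self):
        log = make_spoken_log(["A", "A"], [None, 2.5], first_onset=10.0)
        # offset_1 = 10.4; place onset_2 at 12.9 -> irt 2.5
        df = sf.compute_irt(log, mode="spoken")
        assert np.isnan(df["irt"].iloc[0])
        assert df["irt"].iloc[1] == pytest.approx(2.5)

    def test_first_response_per_cue_undefined(self):
        log = pd.concat([make_spoken_log(["A", "B"], [None, 1.0], cue="c0"),
                         make_spoken_log(["A"], [None], cue="c1")],
                        ignore_index=True)
        df = sf.compute_irt(log)
        first = df.groupby(["participant", "cue"]).nth(0)
        assert first["irt"].isna().all()

    def test_typed_thinking_time_correction(self):
        # fastest speed 4 chars/s from response 1 (12 chars in 3 s);
        # response 2: raw 6 s, measured typing 5 s, theoretical 3 s
        # -> thinking 2 s -> IRT 8 s
        log = pd.DataFrame([
            dict(participant="p0", cue="c0", response_index=1, word="abcdefghijkl",
                 first_keypress=2.0, validation=5.0, n_chars=12, meaning="A"),
            dict(participant="p0", cue="c0", response_index=2, word="mnopqrstuvwx",
                 first_keypress=11.0, validation=16.0, n_chars=12, meaning="A"),
        ])
        df = sf.compute_irt(log, mode="typed")
        assert df["irt"].iloc[0] == pytest.approx(2.0)   # trial start, no thinking
        assert df["irt"].iloc[1] == pytest.approx(8.0)

    def test_negative_irt_raises_with_row(self):
        log = make_spoken_log(["A", "A"], [None, 1.0])
        log.loc[1, "onset"] = log.loc[0, "offset"] - 0.5
        with pytest.raises(DataError, match="response_index=2"):
            sf.compute_irt(log)

    def test_typed_missing_columns(self):
        log = make_spoken_log(["A", "A"], [None, 1.0])
        with pytest.raises(sf.scoring.FormatError):
            sf.compute_irt(log, mode="typed")


class TestTransitions:
    @pytest.mark.parametrize("meanings,expected", [
        (["A", "A", "B"], ["initial", "clustering", "switching"]),
        (["A", "B", "A"], ["initial", "switching", "switching"]),
        (["A", "A", "A"], ["initial", "clustering", "clustering"]),
    ])
    def test_labels(self, meanings, expected):
        log = make_spoken_log(meanings, [None, 1, 1])
        df = sf.label_transitions(log)
        assert list(df["transition"]) == expected

    def test_missing_meaning_raises(self):
        log = make_spoken_log(["A", "A"], [None, 1.0])
        log.loc[1, "meaning"] = np.nan
        with pytest.raises(DataError):
            sf.label_transitions(log)


class TestIrs:
    def _log_with_table(self, vectors):
        words = list(vectors)
        log = make_spoken_log(["A"] * len(words), [None] + [1.0] * (len(words) - 1),
                              words=words)
        return log, {w: np.asarray(v, float) for w, v in vectors.items()}

    def test_identical_orthogonal_and_closed_form(self):
        log, table = self._log_with_table(
            {"a": [1, 0], "b": [1, 0], "c": [0, 1], "d": [1, 1]})
        df = sf.compute_irs(log, table)
        assert df["irs"].iloc[1] == pytest.approx(1.0)        # identical
        assert df["irs"].iloc[2] == pytest.approx(0.0, abs=1e-12)  # orthogonal
        assert df["irs"].iloc[3] == pytest.approx(1 / np.sqrt(2), abs=5e-6)

    def test_missing_vector_counted(self):
        log, table = self._log_with_table({"a": [1, 0], "b": [1, 0]})
        log.loc[1, "word"] = "unknown"
        with pytest.warns(UserWarning, match="without"):
            df = sf.compute_irs(log, table)
        assert np.isnan(df["irs"].iloc[1])
        assert df.attrs["irs_missing"] == 1

    def test_zero_norm_vector_raises(self):
        log, table = self._log_with_table({"a": [1, 0], "b": [0, 0]})
        with pytest.raises(NumericError, match="b"):
            sf.compute_irs(log, table)


class TestMarginalsAndRatios:
    def test_per_cue_marginal_mean(self):
        log = make_typed_log(["A", "A", "B"], [2.0, 4.0, 6.0])
        df = sf.compute_irt(log, mode="typed")
        marg = sf.marginal_values(df)
        assert marg["marginal_irt"].iloc[0] == pytest.approx(4.0)

    def test_grand_long_term_across_cues(self):
        a = make_typed_log(["A", "A"], [2.0, 4.0], cue="c0")   # mean 3
        b = make_typed_log(["A", "A"], [4.0, 6.0], cue="c1")   # mean 5
        df = sf.compute_irt(pd.concat([a, b], ignore_index=True), mode="typed")
        marg = sf.marginal_values(df)
        assert marg["long_term_irt"].iloc[0] == pytest.approx(4.0)

    def test_single_defined_irt(self):
        log = make_spoken_log(["A", "A"], [None, 3.3])
        marg = sf.marginal_values(sf.compute_irt(log))
        assert marg["marginal_irt"].iloc[0] == pytest.approx(3.3)

    def test_ratio_examples_and_mean_identity(self):
        log = make_typed_log(["A", "A", "B"], [2.0, 4.0, 6.0])
        df = sf.compute_ratios(sf.compute_irt(log, mode="typed"))
        assert list(df["irtr"]) == pytest.approx([0.5, 1.0, 1.5])
        assert df["irtr"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_marginal_rejected(self):
        log = make_typed_log(["A", "A"], [0.0, 0.0])
        with pytest.raises(DataError):
            sf.compute_ratios(sf.compute_irt(log, mode="typed"))

    def test_irsr_epsilon_guard(self):
        log = make_spoken_log(["A", "A", "A"], [None, 1, 1],
                              words=["a", "b", "c"])
        irt_df = sf.compute_irt(log)
        # IRS values 0 and -1 -> marginal -0.5 -> IRSr defined
        table = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0]),
                 "c": np.array([0.0, -1.0])}
        df = sf.compute_ratios(sf.compute_irs(irt_df, table))
        assert df["irsr"].notna().sum() == 2
        # IRS values 0 and 0 -> marginal below epsilon -> IRSr undefined
        table2 = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0]),
                  "c": np.array([-1.0, 0.0])}
        df2 = sf.compute_ratios(sf.compute_irs(irt_df, table2))
        assert df2["irsr"].isna().all()


class TestSpeedAndPositions:
    def test_boundary_classified_slow(self):
        log = make_typed_log(["A", "A", "A"], [2.0, 2.0, 2.0])
        df = sf.classify_speed(sf.compute_ratios(sf.compute_irt(log, "typed")))
        assert (df["speed"] == "slow").all()  # IRTr exactly 1 everywhere

    def test_fast_slow_split(self):
        log = make_typed_log(["A", "A", "B"], [2.0, 4.0, 6.0])
        df = sf.label_transitions(log)
        df = sf.classify_speed(sf.compute_ratios(sf.compute_irt(df, "typed")))
        assert list(df["speed"]) == ["fast", "slow", "slow"]

    def test_position_sequence(self):
        log = make_spoken_log(["A", "A", "A", "B", "B", "B"],
                              [None, 1, 1, 1, 1, 1])
        df = sf.label_transitions(sf.compute_irt(log))
        assert list(df["transition"]) == ["initial", "clustering", "clustering",
                                          "switching", "clustering", "clustering"]
        df, anchors = sf.align_positions(df)
        assert list(df["position"]) == ["none", "-2", "-1", "S", "+1", "+2"]

    def test_adjacent_switches(self):
        log = make_spoken_log(["A", "A", "B", "C"], [None, 1, 1, 1])
        df, anchors = sf.align_positions(sf.label_transitions(sf.compute_irt(log)))
        first = anchors[anchors["switch_row"] == 2]
        assert set(first["position"]) == {"S", "-1"}   # no +1: next is a switch

    def test_bare_switch(self):
        log = make_spoken_log(["A", "B"], [None, 1])
        df, anchors = sf.align_positions(sf.label_transitions(sf.compute_irt(log)))
        assert set(anchors["position"]) == {"S"}

    def test_dual_role_between_two_switches(self):
        log = make_spoken_log(["A", "B", "B", "C"], [None, 1, 1, 1])
        df, anchors = sf.align_positions(sf.label_transitions(sf.compute_irt(log)))
        roles = set(anchors.loc[anchors["row"] == 2, "position"])
        assert roles == {"+1", "-1"}


class TestSummaries:
    def test_unique_word_fluency(self):
        log = make_spoken_log(["A", "A", "A"], [None, 1, 1],
                              words=["a", "B", "a"])
        bundle = sf.score(log)
        # case-folded dedup: {a, b}
        assert bundle.summaries["polyft_fluency"].iloc[0] == pytest.approx(2.0)

    def test_hand_traced_three_response_toy(self):
        log = make_typed_log(["A", "A", "B"], [2.0, 4.0, 6.0])
        bundle = sf.score(log, mode="typed")
        s = bundle.summaries.iloc[0]
        assert s["switching_irt"] == pytest.approx(6.0)
        assert s["clustering_irt"] == pytest.approx(4.0)
        assert s["pre_switch_irt"] == pytest.approx(4.0)
        assert s["pre_switch_gap"] == pytest.approx(0.0)
        assert s["long_term_irt"] == pytest.approx(4.0)

    def test_all_fast_clustering(self):
        # equal IRTs make every labeled response IRTr == 1 -> slow clustering
        log = make_typed_log(["A", "A", "A"], [2.0, 2.0, 2.0])
        bundle = sf.score(log, mode="typed")
        s = bundle.summaries.iloc[0]
        assert s["n_slow_clustering"] == s["n_labeled"] == 2
        assert s["n_fast_switching"] == s["n_fast_clustering"] == 0
        assert bool(s["flagged_no_switch"])

    def test_counts_partition_labeled(self, small_scored):
        s = small_scored.summaries
        total = (s["n_fast_clustering"] + s["n_fast_switching"]
                 + s["n_slow_clustering"] + s["n_slow_switching"])
        assert (total == s["n_labeled"]).all()

    def test_per_cue_mean_irtr_is_one(self, small_scored):
        means = small_scored.scored.groupby(["participant", "cue"])["irtr"].mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_row_order_invariance(self, small_cohort):
        shuffled = small_cohort.logs.sample(frac=1.0, random_state=1)
        a = sf.score(small_cohort.logs).summaries
        b = sf.score(shuffled).summaries
        pd.testing.assert_frame_equal(a, b)
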