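import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emochimera import (
    a_prime,
    a_prime_relative_difference,
    benefit,
    condition_pivot,
    d_prime,
    discrimination_curve,
    normalized_ratio,
    participant_totals,
    percent_from_mean_total,
    score_responses,
    sdt_table,
)
from emochimera.psychometrics import SchemaError

rates = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def table(rows):
    defaults = dict(participant_id="p1", group="good", sex="male",
                    stimulus_id="s1", condition="org", cue="tfs",
                    true_label="happy", response="happy")
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestScoring:
    def test_match_is_correct_mismatch_is_not(self):
        rt = table([
            {"true_label": "happy", "response": "happy", "cue": "tfs"},
            {"true_label": "sad", "response": "happy", "cue": "env", "stimulus_id": "s2"},
        ])
        out = score_responses(rt)
        assert out["correct"].tolist() == [True, False]

    def test_same_trial_opposite_cue_labels_score_oppositely(self):
        # one chimera response appears twice: correct for its TFS label,
        # incorrect for the complementary ENV label
        rt = table([
            {"cue": "tfs", "true_label": "happy", "response": "happy"},
            {"cue": "env", "true_label": "sad", "response": "happy"},
        ])
        out = score_responses(rt)
        assert out.loc[out.cue == "tfs", "correct"].item()
        assert not out.loc[out.cue == "env", "correct"].item()

    def test_duplicate_trial_rejected(self):
        rt = table([{}, {}])
        with pytest.raises(SchemaError, match="duplicate"):
            score_responses(rt)

    def test_unknown_label_rejected(self):
        rt = table([{"response": "angry"}])
        with pytest.raises(SchemaError):
            score_responses(rt)


class TestDiscriminationCurve:
    def test_three_of_four_is_75_percent(self):
        rt = table([
            {"stimulus_id": f"s{i}", "response": "happy" if i < 3 else "sad"}
            for i in range(4)
        ])
        curve = discrimination_curve(rt)
        assert curve["percent_correct"].item() == pytest.approx(75.0)
        assert curve["n_trials"].item() == 4

    def test_all_correct_table_is_100_everywhere(self, tiny_manifest):
        rows = [dict(participant_id="p1", group="good", sex="male",
                     stimulus_id=r.stimulus_id, condition=r.condition, cue="tfs",
                     true_label=r.true_label, response=r.true_label)
                for r in tiny_manifest.itertuples()]
        curve = discrimination_curve(pd.DataFrame(rows))
        assert np.allclose(curve["percent_correct"], 100.0)

    def test_uniform_random_responder_near_chance(self):
        rng = np.random.default_rng(42)
        n = 2000
        rt = table([
            {"stimulus_id": f"s{i}",
             "true_label": "happy" if i % 2 else "sad",
             "response": "happy" if rng.random() < 0.5 else "sad"}
            for i in range(n)
        ])
        pc = discrimination_curve(rt)["percent_correct"].item()
        assert abs(pc - 50.0) < 4 * 100 * 0.5 / np.sqrt(n)  # 4 binomial SDs

    def test_empty_stratum_never_reported_as_zero(self):
        rt = table([{"condition": "org"}])
        curve = discrimination_curve(rt)
        assert "nb64" not in set(curve.loc[curve.n_trials > 0, "condition"])
        assert not ((curve["percent_correct"] == 0) & (curve["n_trials"] == 0)).any()

    def test_participant_first_aggregation(self):
        # participant means weigh equally regardless of trial counts
        rt = table(
            [{"participant_id": "p1", "stimulus_id": f"s{i}", "response": "happy"}
             for i in range(8)]  # p1: 100% of 8 trials
            + [{"participant_id": "p2", "stimulus_id": "s0", "response": "sad"}]
        )  # p2: 0% of 1 trial
        pc = discrimination_curve(rt)["percent_correct"].item()
        assert pc == pytest.approx(50.0)

    def test_totals_consistent_with_percent(self, tiny_scored):
        totals = participant_totals(tiny_scored[tiny_scored.cue == "tfs"], "org")
        assert np.allclose(
            totals["percent_correct"],
            100.0 * totals["total_correct"] / totals["n_stimuli"],
        )

    def test_mean_total_to_percent_table_structure(self):
        assert percent_from_mean_total(31.25, 32) == pytest.approx(97.65625)
        assert percent_from_mean_total(30.50, 32) == pytest.approx(95.3125)


class TestNormalizedRatio:
    def test_equal_curves_give_unity(self):
        assert np.allclose(normalized_ratio([80, 60], [80, 60]), 1.0)

    def test_arithmetic(self):
        assert normalized_ratio([80.0], [40.0]).item() == pytest.approx(2.0)

    def test_reciprocal_identity(self):
        h, s = np.array([90.0, 70, 55]), np.array([85.0, 60, 50])
        assert np.allclose(normalized_ratio(h, s) * normalized_ratio(s, h), 1.0)

    def test_zero_denominator_marked_nan(self):
        out = normalized_ratio([50.0], [0.0])
        assert np.isnan(out).all()


class TestAPrime:
    def test_chance_perfect_and_hand_computed(self):
        assert a_prime(0.3, 0.3) == pytest.approx(0.5)
        assert a_prime(1.0, 0.0) == pytest.approx(1.0)
        assert a_prime(0.75, 0.25) == pytest.approx(5.0 / 6.0)

    @settings(deadline=None, max_examples=200)
    @given(h=rates, f=rates)
    def test_complement_symmetry_and_bounds(self, h, f):
        a = a_prime(h, f)
        assert 0.0 <= a <= 1.0
        assert a + a_prime(f, h) == pytest.approx(1.0, abs=1e-12)

    def test_corner_cases_resolve_to_half(self):
        assert a_prime(0.0, 0.0) == pytest.approx(0.5)
        assert a_prime(1.0, 1.0) == pytest.approx(0.5)

    def test_rejects_rates_outside_unit_interval(self):
        with pytest.raises(ValueError):
            a_prime(1.2, 0.5)


class TestDPrime:
    def test_chance_is_near_zero(self):
        assert abs(d_prime(0.5, 0.5, 100, 100)) < 0.01

    def test_correction_keeps_extremes_finite(self):
        assert np.isfinite(d_prime(1.0, 0.0, 16, 16))

    def test_monotone_in_hits_and_rank_agreement_with_a_prime(self):
        hs = np.linspace(0.55, 0.95, 9)
        d = d_prime(hs, 0.2, 50, 50)
        a = a_prime(hs, 0.2)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(a) > 0)
        fs = np.linspace(0.05, 0.45, 9)
        assert np.all(np.diff(d_prime(0.8, fs, 50, 50)) < 0)
        assert np.all(np.diff(a_prime(0.8, fs)) < 0)


class TestBenefit:
    def test_equal_curves_give_zero(self):
        assert np.allclose(benefit([0.7, 0.6], [0.7, 0.6], "tfs"), 0.0)

    def test_perfect_cue_gives_unity(self):
        assert benefit([1.0], [0.6], "tfs").item() == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        assert benefit([0.8], [0.6], "tfs").item() == pytest.approx(0.5)

    def test_sign_opposition(self):
        rng = np.random.default_rng(1)
        tfs = rng.uniform(0.05, 0.95, 50)
        env = rng.uniform(0.05, 0.95, 50)
        t = benefit(tfs, env, "tfs")
        e = benefit(env, tfs, "env")
        assert np.all(np.sign(t) == -np.sign(e))

    def test_unit_denominator_marked_nan(self):
        assert np.isnan(benefit([0.8], [1.0], "tfs")).all()

    def test_rejects_percent_scale_inputs(self):
        with pytest.raises(ValueError):
            benefit([80.0], [60.0], "tfs")


class TestAPrimeRelativeDifference:
    def test_first_year_musician_pair(self):
        assert a_prime_relative_difference(0.7725, 0.5794) == pytest.approx(25.00)

    def test_last_year_musician_pair(self):
        assert a_prime_relative_difference(0.7805, 0.5632) == pytest.approx(27.84)

    def test_equal_inputs_and_zero_reference(self):
        assert a_prime_relative_difference(0.7, 0.7) == 0.0
        assert np.isnan(a_prime_relative_difference(0.0, 0.5))


class TestSdtAndPivot:
    def test_sdt_table_recovers_designed_rates(self):
        rows = []
        # 20 happy stimuli: 15 hits; 20 sad stimuli: 5 false alarms
        for i in range(20):
            rows.append({"stimulus_id": f"h{i}", "true_label": "happy",
                         "response": "happy" if i < 15 else "sad"})
            rows.append({"stimulus_id": f"s{i}", "true_label": "sad",
                         "response": "happy" if i < 5 else "sad"})
        out = sdt_table(table(rows), by=("group",))
        assert out["hit_rate"].item() == pytest.approx(0.75)
        assert out["fa_rate"].item() == pytest.approx(0.25)
        assert out["a_prime"].item() == pytest.approx(a_prime(0.75, 0.25))

    def test_condition_pivot_shape_and_alignment(self, tiny_scored):
        mat, groups = condition_pivot(tiny_scored, cue="tfs")
        assert list(mat.columns) == ["org", "nb2", "nb4", "nb8", "nb16", "nb32", "nb64"]
        assert len(mat) == len(groups) == 64
        assert mat.to_numpy().min() >= 0 and mat.to_numpy().max() <= 1
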