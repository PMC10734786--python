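"""Pairing schemes, Bland-Altman statistics, CV and test-retest precision."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pwvalid as pv
from pwvalid.agreement import Reading, age_band_label
from pwvalid.errors import (ConfigurationError, DomainError,
                            InsufficientDataError, ValidationDataError)


def make_session(test_vals, ref_vals, mode="simultaneous", **kw):
    if mode == "simultaneous":
        test_ts = ref_ts = (0.0, 60.0, 120.0)
    else:
        ref_ts = (0.0, 120.0, 240.0, 360.0)
        test_ts = (60.0, 180.0, 300.0)
    return pv.MeasurementSession(
        participant_id=kw.pop("pid", "P1"), mode=mode,
        test_readings=tuple(Reading(t, v) for t, v in zip(test_ts, test_vals)),
        reference_readings=tuple(Reading(t, v)
                                 for t, v in zip(ref_ts, ref_vals)), **kw)


class TestSessionValidation:
    def test_count_mismatch_names_participant(self):
        with pytest.raises(ValidationDataError, match="P7"):
            pv.MeasurementSession(
                participant_id="P7", mode="simultaneous",
                test_readings=(Reading(0, 8.0), Reading(1, 8.1)),
                reference_readings=(Reading(0, 8.0), Reading(1, 8.0),
                                    Reading(2, 8.0)))

    def test_sequential_needs_four_references(self):
        with pytest.raises(ValidationDataError, match="4 reference"):
            make_session((8, 8, 8), (8, 8, 8), mode="sequential")

    def test_timestamps_must_increase(self):
        with pytest.raises(ValidationDataError, match="strictly increasing"):
            pv.MeasurementSession(
                participant_id="P1", mode="simultaneous",
                test_readings=(Reading(0, 8.0), Reading(0, 8.1),
                               Reading(1, 8.2)),
                reference_readings=(Reading(0, 8.0), Reading(1, 8.0),
                                    Reading(2, 8.0)))

    def test_nonpositive_pwv_rejected(self):
        with pytest.raises(ValidationDataError, match="> 0"):
            make_session((8.0, -1.0, 8.2), (8.0, 8.1, 8.2))


class TestPairSimultaneous:
    @pytest.mark.parametrize("tvals,rvals,expected_mean", [
        ((8.0, 8.2, 8.1), (8.0, 8.2, 8.1), 0.0),
        ((9.0, 9.2, 9.1), (8.0, 8.2, 8.1), 1.0),
        ((8.4, 8.0, 8.6), (8.1, 8.2, 8.3), 0.13333333333),
    ])
    def test_mean_difference(self, tvals, rvals, expected_mean):
        p = pv.pair_simultaneous(make_session(tvals, rvals))
        assert p.participant_mean_difference == pytest.approx(expected_mean)

    def test_hand_computed_pairs(self):
        p = pv.pair_simultaneous(make_session((8.4, 8.0, 8.6),
                                              (8.1, 8.2, 8.3)))
        diffs = [d for _, _, d in p.per_pair]
        assert diffs == pytest.approx([0.3, -0.2, 0.3])

    def test_wrong_mode_rejected(self):
        s = make_session((8, 8, 8), (8, 8, 8, 8), mode="sequential")
        with pytest.raises(ValidationDataError):
            pv.pair_simultaneous(s)


class TestPairSequential:
    def test_constant_references(self):
        p = pv.pair_sequential(make_session((8.3, 8.5, 8.7),
                                            (8.0, 8.0, 8.0, 8.0),
                                            mode="sequential"))
        assert [c for _, c, _ in p.per_pair] == pytest.approx([8.0] * 3)

    def test_canonical_interleaving_uses_flanking_pairs(self):
        """T at midpoints: comparators mean(R1,R2), mean(R2,R3), mean(R3,R4)."""
        p = pv.pair_sequential(make_session((8.3, 8.5, 8.7),
                                            (8.0, 8.2, 8.4, 8.6),
                                            mode="sequential"))
        assert [c for _, c, _ in p.per_pair] == pytest.approx([8.1, 8.3, 8.5])
        assert [d for _, _, d in p.per_pair] == pytest.approx([0.2, 0.2, 0.2])
        assert p.participant_mean_difference == pytest.approx(0.2)

    def test_each_comparator_uses_two_references(self):
        p = pv.pair_sequential(make_session((8.3, 8.5, 8.7),
                                            (8.0, 8.2, 8.4, 8.6),
                                            mode="sequential"))
        assert len(p.per_pair) == 3

    def test_off_midpoint_picks_nearest_two(self):
        """A test reading close to R2 uses R1 and R2 or R2 and R3 by time."""
        s = pv.MeasurementSession(
            participant_id="P1", mode="sequential",
            test_readings=(Reading(115.0, 8.3), Reading(180.0, 8.5),
                           Reading(300.0, 8.7)),
            reference_readings=(Reading(0.0, 8.0), Reading(120.0, 8.2),
                                Reading(240.0, 8.4), Reading(360.0, 8.6)))
        # T1 at 115 s: nearest refs are R2 (5 s) and R3 (125 s)? no: R1 is
        # 115 s away, R3 is 125 s -> R2 and R1
        p = pv.pair_sequential(s)
        assert p.per_pair[0][1] == pytest.approx(0.5 * (8.0 + 8.2))


class TestSummarize:
    def test_constant_differences(self):
        sessions = [make_session((8.5, 8.5, 8.5), (8.0, 8.0, 8.0), pid=f"P{i}")
                    for i in range(5)]
        paired = [pv.pair_simultaneous(s) for s in sessions]
        s = pv.summarize_agreement(paired)
        assert s.mean_diff == pytest.approx(0.5)
        assert s.sd_diff == pytest.approx(0.0)
        assert s.grading.grade == "good"

    def test_hand_listed_differences(self):
        """Mean/SD over ten fixed differences match a spreadsheet-style
        oracle computed by direct formula."""
        diffs = [0.1, -0.2, 0.4, 0.0, 0.3, -0.1, 0.5, 0.2, -0.3, 0.6]
        sessions = [make_session((8.0 + d, 8.0 + d, 8.0 + d), (8.0, 8.0, 8.0),
                                 pid=f"P{i}") for i, d in enumerate(diffs)]
        s = pv.summarize_agreement([pv.pair_simultaneous(x) for x in sessions])
        mean = sum(diffs) / 10
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / 9)
        assert s.mean_diff == pytest.approx(mean)
        assert s.sd_diff == pytest.approx(sd)
        assert s.loa_high - s.loa_low == pytest.approx(4 * sd)

    def test_insufficient_data(self):
        p = pv.pair_simultaneous(make_session((8, 8, 8), (8, 8, 8)))
        with pytest.raises(InsufficientDataError):
            pv.summarize_agreement([p])

    def test_mean_shift_property(self):
        rng = np.random.default_rng(3)
        base = rng.normal(8.0, 1.0, 12)
        paired0 = [pv.pair_simultaneous(make_session(
            (b + 0.1, b + 0.2, b), (b, b, b), pid=f"P{i}"))
            for i, b in enumerate(base)]
        shifted = [pv.pair_simultaneous(make_session(
            (b + 0.6, b + 0.7, b + 0.5), (b, b, b), pid=f"P{i}"))
            for i, b in enumerate(base)]
        s0, s1 = pv.summarize_agreement(paired0), pv.summarize_agreement(shifted)
        assert s1.mean_diff == pytest.approx(s0.mean_diff + 0.5)
        assert s1.sd_diff == pytest.approx(s0.sd_diff, abs=1e-9)

    def test_figure_scenario_end_to_end(self):
        """85 participants with bias 0.36 / SD 0.44 reproduce the worked
        grading example through the full pairing path."""
        cfg = pv.SimulationConfig(seed=2024)
        records, sessions = pv.simulate_study(cfg)
        paired = [pv.pair_session(s) for s in sessions]
        s = pv.summarize_agreement(paired)
        assert s.mean_diff == pytest.approx(0.36, abs=0.15)
        assert s.grading.grade in ("good", "acceptable")

    def test_proportional_bias_recovered_by_regression(self):
        cfg = pv.SimulationConfig(n_participants=400, bias_constant=0.0,
                                  bias_proportional=0.05, bias_between_sd=0.05,
                                  test_noise_sd=0.05, reference_noise_sd=0.05,
                                  seed=11)
        _, sessions = pv.simulate_study(cfg)
        s = pv.summarize_agreement([pv.pair_session(x) for x in sessions])
        assert s.ba_regression.slope == pytest.approx(0.05, abs=0.02)


class TestStratified:
    def test_small_stratum_marked_not_estimable(self):
        paired = [pv.pair_simultaneous(make_session(
            (8.2, 8.2, 8.2), (8.0, 8.0, 8.0), pid=f"P{i}")) for i in range(5)]
        out = pv.stratified_agreement(paired, ["f", "f", "f", "f", "m"])
        assert out["m"] is None
        assert out["f"].n == 4

    def test_sex_specific_bias_recovery(self):
        rng = np.random.default_rng(5)
        paired, labels = [], []
        for i in range(200):
            sex = "male" if i % 2 else "female"
            bias = 0.2 if sex == "male" else 0.6
            b = float(rng.normal(8.0, 1.0))
            d = bias + float(rng.normal(0, 0.1))
            paired.append(pv.pair_simultaneous(make_session(
                (b + d,) * 3, (b,) * 3, pid=f"P{i}")))
            labels.append(sex)
        out = pv.stratified_agreement(paired, labels)
        assert out["male"].mean_diff == pytest.approx(0.2, abs=0.05)
        assert out["female"].mean_diff == pytest.approx(0.6, abs=0.05)

    def test_weighted_strata_reproduce_overall_mean(self):
        rng = np.random.default_rng(8)
        paired = [pv.pair_simultaneous(make_session(
            tuple(8.0 + rng.normal(0.3, 0.2, 3)), (8.0,) * 3, pid=f"P{i}"))
            for i in range(30)]
        labels = [str(i % 3) for i in range(30)]
        out = pv.stratified_agreement(paired, labels)
        total = pv.summarize_agreement(paired)
        weighted = sum(s.n * s.mean_diff for s in out.values()) / 30
        assert weighted == pytest.approx(total.mean_diff, abs=1e-12)
        assert sum(s.n for s in out.values()) == 30

    def test_label_count_mismatch(self):
        paired = [pv.pair_simultaneous(make_session(
            (8.1, 8.1, 8.1), (8.0, 8.0, 8.0)))]
        with pytest.raises(ConfigurationError):
            pv.stratified_agreement(paired, ["a", "b"])


class TestAgeBands:
    @pytest.mark.parametrize("age,label", [
        (18, "18-29"), (29.9, "18-29"), (30, "30-49"), (49, "30-49"),
        (50, "50-69"), (69.5, "50-69"), (70, ">=70"), (95, ">=70")])
    def test_partition(self, age, label):
        assert age_band_label(age) == label

    def test_minor_rejected(self):
        with pytest.raises(DomainError):
            age_band_label(17)


class TestCV:
    def test_identical_measurements(self):
        assert pv.coefficient_of_variation(10.0, 10.0) == 0.0

    def test_closed_form(self):
        assert pv.coefficient_of_variation(8.0, 10.0) == pytest.approx(
            100 * math.sqrt(2) / 9)

    @given(m1=st.floats(0.5, 20), m2=st.floats(0.5, 20),
           c=st.floats(0.1, 100))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, m1, m2, c):
        assert pv.coefficient_of_variation(m1, m2) == pytest.approx(
            pv.coefficient_of_variation(c * m1, c * m2), rel=1e-9)

    def test_domain(self):
        with pytest.raises(DomainError):
            pv.coefficient_of_variation(0.0, 5.0)


class TestTestRetest:
    def test_identical_repeats(self):
        rep = pv.test_retest_report({f"P{i}": (8.0, 8.0) for i in range(4)})
        assert rep.mean_diff == 0.0
        assert rep.mean_cv == 0.0
        assert rep.exceeding_limit == ()

    def test_half_normal_mean_difference(self):
        """Within-device noise SD 0.3: E|d| = 0.6/sqrt(pi) ~ 0.3385."""
        rng = np.random.default_rng(21)
        repeats = {f"P{i}": tuple(8.0 + rng.normal(0, 0.3, 2))
                   for i in range(4000)}
        rep = pv.test_retest_report(repeats)
        observed = np.mean([abs(v[1] - v[0]) for v in repeats.values()])
        assert observed == pytest.approx(0.6 / math.sqrt(math.pi), abs=0.02)
        assert rep.sd_diff == pytest.approx(0.3 * math.sqrt(2), abs=0.02)

    def test_limit_flagging_and_exclusion(self):
        rep = pv.test_retest_report(
            {"A": (8.0, 8.1), "B": (8.0, 9.5), "C": (8.0,)},
            agreement_limit=1.0)
        assert rep.exceeding_limit == ("B",)
        assert rep.excluded == (("C", "only 1 repeat(s), need 2"),)
        assert rep.n == 2
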