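"""Tests for the heliox statistical pipeline."""

import numpy as np
import pandas as pd
import pytest

from vocalcpg.stats import (
    auc_effect_ratio,
    call_rate_test,
    cohens_f2,
    condition_proportions,
    fit_duration_model,
    fit_occurrence_glm,
    group_syllables,
    harmonic_metrics,
    respiration_rate,
    welch_spectrum,
)
from vocalcpg.synth import gen_tonal_waveform


def _syllables(rows):
    base = {"subject": "s1", "day": 10, "session": "a", "condition": "air"}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestGroupSyllables:
    def test_small_gap_merges_same_type(self):
        df = _syllables([
            {"call_type": "trill", "onset_s": 0.0, "offset_s": 0.2},
            {"call_type": "trill", "onset_s": 0.5, "offset_s": 0.7},  # gap 0.3
        ])
        calls = group_syllables(df)
        assert len(calls) == 1
        assert calls.loc[0, "n_syllables"] == 2
        assert calls.loc[0, "offset_s"] == pytest.approx(0.7)
        assert calls.loc[0, "syllable_total_s"] == pytest.approx(0.4)

    def test_gap_above_half_second_splits(self):
        df = _syllables([
            {"call_type": "trill", "onset_s": 0.0, "offset_s": 0.2},
            {"call_type": "trill", "onset_s": 0.8, "offset_s": 1.0},  # gap 0.6
        ])
        assert len(group_syllables(df)) == 2

    def test_boundary_gap_exactly_half_second_merges(self):
        df = _syllables([
            {"call_type": "twitter", "onset_s": 0.0, "offset_s": 0.2},
            {"call_type": "twitter", "onset_s": 0.7, "offset_s": 0.9},  # gap 0.5
        ])
        assert len(group_syllables(df)) == 1

    def test_type_change_always_splits(self):
        df = _syllables([
            {"call_type": "trill", "onset_s": 0.0, "offset_s": 0.2},
            {"call_type": "twitter", "onset_s": 0.3, "offset_s": 0.5},  # gap 0.1
        ])
        calls = group_syllables(df)
        assert len(calls) == 2
        assert set(calls["call_type"]) == {"trill", "twitter"}

    def test_overlap_rejected(self):
        df = _syllables([
            {"call_type": "trill", "onset_s": 0.0, "offset_s": 0.5},
            {"call_type": "trill", "onset_s": 0.3, "offset_s": 0.8},
        ])
        with pytest.raises(ValueError):
            group_syllables(df)


class TestConditionProportions:
    def _calls(self):
        rows = []
        # subject s1, sessions on days 25 and 27 (one pair), both conditions
        for sess, day in (("s1_a", 25), ("s1_b", 27)):
            for cond in ("air", "heliox"):
                types = (["trill"] * 2 + ["contact"] * 3) if cond == "heliox" \
                    else (["trill"] * 1 + ["contact"] * 4)
                for i, ct in enumerate(types):
                    rows.append({
                        "subject": "s1", "day": day, "session": sess,
                        "condition": cond, "call_type": ct,
                        "onset_s": float(i), "offset_s": float(i) + 0.4,
                    })
        return group_syllables(pd.DataFrame(rows))

    def test_proportion_arithmetic_and_pair_day(self):
        props = condition_proportions(self._calls())
        hx_trill = props.query("condition == 'heliox' and call_type == 'trill'")
        assert hx_trill["proportion"].iloc[0] == pytest.approx(4 / 10)
        assert (props["day"] == 26.0).all()  # mean of days 25 and 27

    def test_types_sum_to_one_within_cell(self):
        props = condition_proportions(self._calls())
        sums = props.groupby(["subject", "pair", "condition"])["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_all_contact_cell(self):
        rows = [{
            "subject": "s1", "day": 3, "session": "a", "condition": "air",
            "call_type": "contact", "onset_s": float(i), "offset_s": i + 0.5,
        } for i in range(5)]
        props = condition_proportions(group_syllables(pd.DataFrame(rows)))
        by_type = props.set_index("call_type")["proportion"]
        assert by_type["contact"] == 1.0
        assert by_type["trill"] == 0.0 and by_type["twitter"] == 0.0


def _glm_dataset(rng, n_calls=2000, beta3=0.0, base_logit=-1.0,
                 subject_effects=(0.0, 0.3, -0.3)):
    subjects = rng.choice(3, size=n_calls)
    heliox = rng.integers(0, 2, size=n_calls)
    logit = base_logit + np.array(subject_effects)[subjects] + beta3 * heliox
    p = 1 / (1 + np.exp(-logit))
    is_trill = rng.random(n_calls) < p
    return pd.DataFrame({
        "subject": [f"m{s + 1}" for s in subjects],
        "day": 10,
        "session": "x",
        "condition": np.where(heliox == 1, "heliox", "air"),
        "call_type": np.where(is_trill, "trill", "contact"),
        "onset_s": np.arange(n_calls, dtype=float),
        "offset_s": np.arange(n_calls, dtype=float) + 0.3,
    })


class TestOccurrenceGLM:
    def test_type_i_error_calibration(self, rng):
        # null simulations: |beta3| < 2 SE in >= 93% of seeds
        inside = 0
        n_rep = 100
        for _ in range(n_rep):
            g = fit_occurrence_glm(_glm_dataset(rng, beta3=0.0), "trill")
            inside += abs(g.beta3) < 2 * g.beta3_se
        assert inside >= 93

    def test_effect_recovery(self, rng):
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            g = fit_occurrence_glm(_glm_dataset(rng, beta3=0.8), "trill")
            hits += abs(g.beta3 - 0.8) < 2 * g.beta3_se
        assert hits / n_rep >= 0.90

    def test_subject_dummies_absorb_subject_effects(self, rng):
        g = fit_occurrence_glm(_glm_dataset(rng, n_calls=20000, beta3=0.5,
                                            subject_effects=(0.0, 1.0, -1.0)), "trill")
        assert g.params["S2"] == pytest.approx(1.0, abs=0.15)
        assert g.params["S3"] == pytest.approx(-1.0, abs=0.15)

    def test_requires_both_conditions(self, rng):
        df = _glm_dataset(rng)
        with pytest.raises(ValueError):
            fit_occurrence_glm(df[df["condition"] == "air"], "trill")


class TestAUCEffectRatio:
    def test_equal_aucs_give_zero(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        p = y * 0.2 + rng.random(200) * 0.8  # weakly informative (AUC > 0.5)
        assert auc_effect_ratio(p, p, y) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        # construct outcomes/scores with known AUCs: use the identity
        # r = (auc_c - auc_0) / (auc_0 - 0.5) on directly computed AUCs
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500).astype(float)
        p0 = y * 0.4 + rng.random(500) * 0.6  # weakly informative
        pc = y * 0.6 + rng.random(500) * 0.4  # more informative
        a0, ac = roc_auc_score(y, p0), roc_auc_score(y, pc)
        assert auc_effect_ratio(pc, p0, y) == pytest.approx((ac - a0) / (a0 - 0.5))

    def test_uninformative_reduced_model_undefined(self, rng):
        y = np.array([0.0, 1.0] * 50)
        p0 = 1.0 - y  # AUC 0 < 0.5
        with pytest.raises(ValueError):
            auc_effect_ratio(y, p0, y)

    def test_invariance_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        pc = np.clip(y * 0.3 + rng.random(300) * 0.7, 1e-6, 1 - 1e-6)
        p0 = np.clip(y * 0.1 + rng.random(300) * 0.9, 1e-6, 1 - 1e-6)
        r = auc_effect_ratio(pc, p0, y)
        for f in (lambda x: x ** 3, np.log, lambda x: 1 / (1 + np.exp(-5 * x))):
            assert auc_effect_ratio(f(pc), f(p0), y) == pytest.approx(r)


class TestDurationModel:
    def _contact(self, factor, n_per_cell=20):
        rows = []
        for subj in ("m1", "m2"):
            for day in (5, 6):
                base = 0.5 + 0.01 * day
                for cond, f in (("air", 1.0), ("heliox", factor)):
                    for i in range(n_per_cell):
                        rows.append({
                            "subject": subj, "day": day, "session": f"{subj}{day}",
                            "condition": cond, "call_type": "contact",
                            "onset_s": float(i), "offset_s": float(i) + base * f,
                        })
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("delta", [0.05, 0.11, 0.2])
    def test_exact_recovery_of_injected_fraction(self, delta):
        m = fit_duration_model(self._contact(1.0 - delta))
        assert abs(m.beta3 + delta) < 0.01

    def test_identical_conditions_give_zero(self):
        m = fit_duration_model(self._contact(1.0))
        assert m.beta3 == pytest.approx(0.0, abs=1e-12)
        assert m.cohens_f2 == pytest.approx(0.0, abs=1e-12)

    def test_days_without_air_dropped_and_reported(self):
        df = self._contact(0.9)
        df = df[~((df["day"] == 6) & (df["condition"] == "air"))]
        m = fit_duration_model(df)
        assert ("m1", 6) in m.dropped_days and ("m2", 6) in m.dropped_days
        assert m.beta3 == pytest.approx(-0.1, abs=0.01)


class TestCohensF2:
    def test_formula(self):
        assert cohens_f2(0.5, 0.4) == pytest.approx(0.2)

    def test_no_improvement_gives_zero(self):
        assert cohens_f2(0.37, 0.37) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)
        with pytest.raises(ValueError):
            cohens_f2(0.3, 0.5)


class TestCallRateTest:
    def test_identical_pairs_no_evidence(self):
        _, p = call_rate_test([2.0, 3.0, 4.0, 5.0, 6.0], [2.0, 3.0, 4.0, 5.0, 6.0])
        assert p == 1.0

    def test_systematic_shift_detected(self, rng):
        air = rng.uniform(1, 4, 20)
        _, p = call_rate_test(air, air * 1.5)
        assert p < 0.01

    def test_antisymmetric_differences_near_null_centre(self):
        # signed ranks cancel exactly: statistic at the null centre n(n+1)/4
        air = np.array([10.0, 10, 10, 10, 10, 10])
        hel = air + np.array([1.0, -1, 2, -2, 3, -3])
        stat, p = call_rate_test(air, hel)
        assert stat == pytest.approx(6 * 7 / 4)  # 10.5
        assert p > 0.9

    def test_few_pairs_warn(self):
        with pytest.warns(UserWarning):
            call_rate_test([1.0, 2.0], [2.0, 3.0])


class TestSpectral:
    def test_white_noise_flat_psd(self, rng):
        x = rng.normal(size=2 ** 17)
        res = welch_spectrum(x, 44100.0)
        band = res.psd[8:-8]
        assert 10 * np.log10(band.max() / band.min()) < 3.0

    def test_sine_peak_location(self):
        x = gen_tonal_waveform(8000.0, [1.0], 1.0, 44100.0)
        res = welch_spectrum(x, 44100.0)
        peak = res.freqs[np.argmax(res.psd)]
        df = res.freqs[1] - res.freqs[0]
        assert abs(peak - 8000.0) <= df

    def test_parseval_identity(self, rng):
        x = rng.normal(size=2 ** 16)
        res = welch_spectrum(x, 1000.0)
        power = np.trapezoid(res.psd, res.freqs)
        assert abs(power - np.var(x)) / np.var(x) < 0.01

    def test_too_short_syllable_rejected(self):
        with pytest.raises(ValueError):
            welch_spectrum(np.zeros(800), 44100.0)

    def test_nan_audio_rejected(self):
        x = np.zeros(4096)
        x[5] = np.nan
        with pytest.raises(ValueError):
            welch_spectrum(x, 44100.0)


class TestHarmonicMetrics:
    def test_amplitude_ratio_ten_gives_twenty_db(self):
        x = gen_tonal_waveform(5000.0, [1.0, 10.0], 1.0, 44100.0)
        res = harmonic_metrics(welch_spectrum(x, 44100.0))
        assert res.f0 == pytest.approx(5000.0, abs=50)
        assert res.f1 == pytest.approx(10000.0, abs=50)
        assert res.f1_f0_ratio_db == pytest.approx(20.0, abs=0.5)

    def test_equal_amplitudes_zero_db(self):
        x = gen_tonal_waveform(5000.0, [1.0, 1.0], 1.0, 44100.0)
        res = harmonic_metrics(welch_spectrum(x, 44100.0))
        assert res.f1_f0_ratio_db == pytest.approx(0.0, abs=0.5)

    def test_single_harmonic_leaves_f1_absent(self):
        x = gen_tonal_waveform(5000.0, [1.0], 1.0, 44100.0)
        res = harmonic_metrics(welch_spectrum(x, 44100.0))
        assert res.f0 == pytest.approx(5000.0, abs=50)
        assert res.f1 is None and res.f1_f0_ratio_db is None

    def test_heliox_like_second_harmonic_boost_recovered(self):
        # matched stimuli: heliox-like boosts the second harmonic 8x
        air = gen_tonal_waveform(7000.0, [1.0, 0.25], 1.0, 44100.0)
        hel = gen_tonal_waveform(7000.0, [1.0, 2.0], 1.0, 44100.0)
        r_air = harmonic_metrics(welch_spectrum(air, 44100.0)).f1_f0_ratio_db
        r_hel = harmonic_metrics(welch_spectrum(hel, 44100.0)).f1_f0_ratio_db
        assert r_hel - r_air == pytest.approx(20 * np.log10(8.0), abs=1.0)


class TestRespirationRate:
    def test_cycle_counting(self):
        t = np.arange(0, 4, 0.01)
        x = np.sin(2 * np.pi * 2.5 * t - np.pi / 2)
        rate, n = respiration_rate(x, [(0.0, 2.0)], 100.0)
        assert n == 5
        assert rate == pytest.approx(2.5, abs=0.05)

    def test_faster_cycling_ratio(self):
        t = np.arange(0, 10, 0.01)
        slow = np.sin(2 * np.pi * 2.0 * t)
        fast = np.sin(2 * np.pi * 2.0 * 1.249 * t)
        r_slow, _ = respiration_rate(slow, [(0.5, 9.5)], 100.0)
        r_fast, _ = respiration_rate(fast, [(0.5, 9.5)], 100.0)
        assert r_fast / r_slow == pytest.approx(1.25, abs=0.03)

    def test_window_invariance_at_constant_cycle_density(self):
        t = np.arange(0, 20, 0.01)
        x = np.sin(2 * np.pi * 2.0 * t)
        full, _ = respiration_rate(x, [(0.0, 20.0)], 100.0)
        halves, _ = respiration_rate(x, [(0.0, 5.0), (10.0, 15.0)], 100.0)
        assert halves == pytest.approx(full, rel=0.06)

    def test_flat_trace_zero_with_flag(self):
        rate, n = respiration_rate(np.zeros(1000), [(0.0, 5.0)], 100.0)
        assert rate == 0.0 and n == 0
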