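import math

import numpy as np
import pytest

from valencecode.behavior import anticipatory_licks
from valencecode.config import five_odor_task
from valencecode.preprocess import baseline_normalize
from valencecode.responsivity import trial_responses
from valencecode.session import Trial
from valencecode.simulate import (
    KineticParams,
    LickModel,
    SimConfig,
    generate_licks,
    generate_population,
    transient_waveform,
)

from conftest import noise_free_sim


class TestTransientWaveform:
    def test_starts_at_zero_and_is_nonnegative(self):
        w = transient_waveform(KineticParams(), 25, 5.0)
        assert w[0] == 0.0
        assert np.all(w >= 0)

    @pytest.mark.parametrize(
        "rise,decay", [(0.2, 1.0), (0.3, 1.5), (0.1, 0.5)]
    )
    def test_peak_frame_matches_analytic_argmax(self, rise, decay):
        # argmax of exp(-t/d) - exp(-t/r) is (rd/(d-r))·ln(d/r)
        rate = 5.0
        k = KineticParams(rise_tau_s=rise, decay_tau_s=decay)
        w = transient_waveform(k, 50, rate)
        t_peak = (rise * decay / (decay - rise)) * math.log(decay / rise)
        assert int(np.argmax(w)) == round(rate * t_peak)

    def test_amplitude_scales_linearly(self):
        k1 = KineticParams(amplitude=1.0)
        k2 = KineticParams(amplitude=2.0)
        np.testing.assert_allclose(
            transient_waveform(k2, 20, 5.0), 2.0 * transient_waveform(k1, 20, 5.0)
        )

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(rise_tau_s=-0.1)
        with pytest.raises(ValueError):
            KineticParams(rise_tau_s=1.0, decay_tau_s=0.5)


class TestGeneratePopulation:
    def test_seed_determinism(self):
        sim = SimConfig(session=five_odor_task(n_days=1))
        s1, g1 = generate_population(sim, seed=7)
        s2, g2 = generate_population(sim, seed=7)
        np.testing.assert_array_equal(s1.traces, s2.traces)
        assert s1.trials == s2.trials
        assert g1.archetypes == g2.archetypes and g1.kinetics == g2.kinetics

    def test_population_bookkeeping(self):
        sim = SimConfig(
            counts={
                "valence_coder": 10,
                "identity_coder": 10,
                "salience_coder": 0,
                "nonresponsive": 10,
            },
            session=five_odor_task(n_days=1),
        )
        session, truth = generate_population(sim, seed=1)
        assert session.n_neurons == 30
        kinds = truth.kinds()
        assert kinds.count("valence_coder") == 10
        assert kinds.count("identity_coder") == 10
        assert kinds.count("nonresponsive") == 10
        assert session.n_trials == 150  # 5 types x 30 trials, one day

    def test_equal_type_counts_per_half_session(self):
        sim = SimConfig(session=five_odor_task(n_days=1))
        session, _ = generate_population(sim, seed=2)
        half = session.n_trials // 2
        first = [t.stimulus for t in session.trials[:half]]
        second = [t.stimulus for t in session.trials[half:]]
        for stim in session.config.stimulus_set:
            assert first.count(stim) == second.count(stim) == 15

    def test_omission_fraction(self):
        sim = SimConfig(session=five_odor_task(n_days=1))
        session, _ = generate_population(sim, seed=3)
        for stim in session.config.stimulus_set:
            omitted = [
                t for t in session.trials
                if t.stimulus == stim and not t.outcome_delivered
            ]
            assert len(omitted) == 3  # 10% of 30

    def test_zero_neurons_rejected(self):
        sim = SimConfig(counts={k: 0 for k in ("valence_coder", "identity_coder",
                                               "salience_coder", "nonresponsive")})
        with pytest.raises(ValueError, match="zero"):
            generate_population(sim, seed=0)

    def test_noise_free_identity_coder_flat_off_preferred(self):
        sim = noise_free_sim(
            {"valence_coder": 0, "identity_coder": 1, "salience_coder": 0,
             "nonresponsive": 0}
        )
        session, truth = generate_population(sim, seed=4)
        spec = truth.archetypes[0]
        kin = truth.kinetics[0]
        preferred = [s for s, g in spec.tuning.items() if g != 0][0]
        for ti, trial in enumerate(session.trials):
            if trial.stimulus != preferred:
                np.testing.assert_allclose(
                    session.traces[0, ti], kin.baseline_f, rtol=1e-12
                )
            else:
                assert session.traces[0, ti].max() > kin.baseline_f

    def test_noise_free_valence_coder_same_valence_equal(self):
        sim = noise_free_sim(
            {"valence_coder": 1, "identity_coder": 0, "salience_coder": 0,
             "nonresponsive": 0}
        )
        session, _ = generate_population(sim, seed=5)
        norm = baseline_normalize(session)
        resp = trial_responses(norm, session.config)
        cfg = session.config
        means = {
            s: np.nanmean(resp[0, session.trial_indices(stimulus=s)])
            for s in cfg.stimulus_set
        }
        assert means["odor1"] == pytest.approx(means["odor2"], abs=1e-9)
        assert means["odor4"] == pytest.approx(means["odor5"], abs=1e-9)
        assert abs(means["odor5"] - means["odor1"]) > 0.5


class TestGenerateLicks:
    def test_sated_zero_rate_gives_no_licks(self):
        cfg = five_odor_task()
        model = LickModel(sated_lick_prob=0.0)
        rng = np.random.default_rng(0)
        t = Trial(0, "odor5", day=4, block=2, outcome_delivered=False)
        assert generate_licks(t, cfg, sated=True, lick_model=model, rng=rng) == ()

    def test_aversive_stimulus_never_licks_by_default(self):
        cfg = five_odor_task()
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = Trial(0, "odor1", day=4, block=1, outcome_delivered=True)
            assert generate_licks(t, cfg, sated=False, lick_model=LickModel(), rng=rng) == ()

    def test_poisson_anticipatory_mean(self):
        # rate 3/s over the 1.3 s onset->outcome epoch => mean count 3.9
        cfg = five_odor_task()
        model = LickModel(
            anticipatory_rate_hz={"large_water": 3.0}, learning_schedule={}
        )
        rng = np.random.default_rng(6)
        counts = []
        for _ in range(1000):
            t = Trial(0, "odor5", day=4, block=1, outcome_delivered=False)
            licks = generate_licks(t, cfg, sated=False, lick_model=model, rng=rng)
            counts.append(len(licks))
        mean = np.mean(counts)
        se = math.sqrt(3.9 / 1000)
        assert abs(mean - 3.9) < 3 * se

    def test_rewarded_exceed_aversive_in_expectation(self):
        sim = SimConfig(
            counts={"valence_coder": 1, "identity_coder": 0,
                    "salience_coder": 0, "nonresponsive": 0},
            session=five_odor_task(n_days=4),
        )
        session, _ = generate_population(sim, seed=8)
        cfg = session.config
        by_val = {"rewarded": [], "aversive": []}
        for t in session.trials:
            v = cfg.valence_map[t.stimulus]
            if v in by_val:
                by_val[v].append(anticipatory_licks(t, cfg))
        assert np.mean(by_val["rewarded"]) > np.mean(by_val["aversive"])

    def test_licks_sorted_and_inside_window(self, small_session):
        window = small_session.config.window_s
        for t in small_session.trials:
            licks = np.asarray(t.lick_times_s)
            assert np.all(np.diff(licks) >= 0)
            if licks.size:
                assert licks[0] >= 0 and licks[-1] < window
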