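import numpy as np
import pytest

from valencecode.config import five_odor_task
from valencecode.geometry import (
    condition_matrices,
    cosine_similarity_subgroups,
    euclidean_contrast,
    pca_trajectories,
)
from valencecode.preprocess import NormalizedTraces
from valencecode.session import ImagingSession, Trial

CFG = five_odor_task(n_days=1, trials_per_type_per_day=3)
VAL = CFG.valence_map


def make_session_and_norm(values):
    """values: neurons x trials x frames ΔF/F with 3 trials per stimulus."""
    n, t, f = values.shape
    trials = []
    for rep in range(t // len(CFG.stimulus_set)):
        for s in CFG.stimulus_set:
            trials.append(Trial(len(trials), s, 1))
    session = ImagingSession(
        config=CFG, traces=np.ones((n, t, CFG.n_frames)) * 10, trials=trials
    )
    padded = np.zeros((n, t, CFG.n_frames))
    padded[:, :, :f] = values
    norm = NormalizedTraces(
        values=padded,
        baseline_per_trial=np.ones((n, t)),
        valid=np.ones((n, t), dtype=bool),
    )
    return session, norm


class TestConditionMatrices:
    def test_mean_of_single_trial_is_that_trial(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(2, 5, 4))
        cfg = five_odor_task(n_days=1, trials_per_type_per_day=1)
        trials = [Trial(i, s, 1) for i, s in enumerate(cfg.stimulus_set)]
        padded = np.zeros((2, 5, cfg.n_frames))
        padded[:, :, :4] = vals
        session = ImagingSession(
            config=cfg, traces=np.ones((2, 5, cfg.n_frames)), trials=trials
        )
        norm = NormalizedTraces(padded, np.ones((2, 5)), np.ones((2, 5), bool))
        mats = condition_matrices(norm, session, epoch_frames=np.arange(4))
        for i, s in enumerate(cfg.stimulus_set):
            np.testing.assert_allclose(mats[s], vals[:, i, :])

    def test_opposite_trials_cancel(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(1, 1, 3))
        vals = np.zeros((1, 15, 3))
        vals[:, 0] = v[:, 0]
        vals[:, 5] = -v[:, 0]  # trials 0 and 5 are both odor1
        session, norm = make_session_and_norm(vals)
        mats = condition_matrices(
            norm, session, trial_indices=np.arange(6),
            epoch_frames=np.arange(3),
        )
        np.testing.assert_allclose(mats["odor1"], 0.0, atol=1e-12)

    def test_hand_computed_means(self):
        vals = np.zeros((2, 15, 2))
        # odor1 trials are indices 0, 5, 10
        vals[0, [0, 5, 10], 0] = [1.0, 2.0, 3.0]
        vals[1, [0, 5, 10], 1] = [4.0, 5.0, 9.0]
        session, norm = make_session_and_norm(vals)
        mats = condition_matrices(norm, session, epoch_frames=np.arange(2))
        np.testing.assert_allclose(mats["odor1"], [[2.0, 0.0], [0.0, 6.0]])

    def test_empty_condition_raises(self):
        vals = np.zeros((1, 15, 2))
        session, norm = make_session_and_norm(vals)
        with pytest.raises(ValueError, match="odor1"):
            condition_matrices(
                norm, session,
                trial_indices=np.array([1, 2, 3]),  # no odor1 trials
                epoch_frames=np.arange(2),
            )


class TestCosine:
    def mats(self, a, b):
        zero = np.zeros_like(np.atleast_2d(a), dtype=float)
        return {
            "odor1": np.atleast_2d(a).astype(float),
            "odor2": zero,
            "odor3": zero,
            "odor4": zero,
            "odor5": np.atleast_2d(b).astype(float),
        }

    def sample(self, report, a, b):
        rows = report.samples
        sel = rows[(rows.stimulus_a == a) & (rows.stimulus_b == b)]
        return sel["cosine"].iloc[0]

    def test_identical_vectors(self):
        m = self.mats([1.0, 2.0], [1.0, 2.0])
        rep = cosine_similarity_subgroups(m, {"g": np.array([0])}, VAL)
        assert self.sample(rep, "odor1", "odor5") == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        m = self.mats([1.0, 0.0], [0.0, 1.0])
        rep = cosine_similarity_subgroups(m, {"g": np.array([0])}, VAL)
        assert self.sample(rep, "odor1", "odor5") == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_angle(self):
        m = self.mats([1.0, 0.0], [1.0, 1.0])
        rep = cosine_similarity_subgroups(m, {"g": np.array([0])}, VAL)
        assert self.sample(rep, "odor1", "odor5") == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_sample_excluded(self):
        m = self.mats([1.0, 0.0], [1.0, 1.0])  # odor2 is all zeros
        rep = cosine_similarity_subgroups(m, {"g": np.array([0])}, VAL)
        pairs = set(zip(rep.samples.stimulus_a, rep.samples.stimulus_b))
        assert ("odor1", "odor2") not in pairs


class TestEuclideanContrast:
    def test_identical_matrices_undefined(self):
        m = {s: np.ones((2, 3)) for s in CFG.stimulus_set}
        c = euclidean_contrast(m, VAL)
        assert np.isnan(c.percent_contrast)

    def test_constructed_sixty_eight_percent(self):
        # same-valence pair distances 1, opposite-valence distances 1.68
        h = np.sqrt(1.68**2 - 0.5)
        m = {
            "odor1": np.array([[0.5, 0.0, 0.0]]),
            "odor2": np.array([[-0.5, 0.0, 0.0]]),
            "odor3": np.array([[9.0, 9.0, 9.0]]),  # neutral: ignored
            "odor4": np.array([[0.0, 0.5, h]]),
            "odor5": np.array([[0.0, -0.5, h]]),
        }
        c = euclidean_contrast(m, VAL)
        assert c.mean_norm_same == pytest.approx(1.0)
        assert c.mean_norm_opposite == pytest.approx(1.68)
        assert c.percent_contrast == pytest.approx(68.0)

    def test_random_matrices_match_direct_arithmetic(self):
        rng = np.random.default_rng(7)
        m = {s: rng.normal(size=(3, 4)) for s in CFG.stimulus_set}
        c = euclidean_contrast(m, VAL)
        same = [np.sqrt(((m["odor1"] - m["odor2"]) ** 2).sum()),
                np.sqrt(((m["odor4"] - m["odor5"]) ** 2).sum())]
        opp = [np.sqrt(((m[a] - m[b]) ** 2).sum())
               for a in ("odor1", "odor2") for b in ("odor4", "odor5")]
        expected = 100 * (np.mean(opp) - np.mean(same)) / np.mean(same)
        assert c.percent_contrast == pytest.approx(expected)

    def test_neuron_permutation_invariance(self):
        rng = np.random.default_rng(8)
        m = {s: rng.normal(size=(6, 4)) for s in CFG.stimulus_set}
        perm = rng.permutation(6)
        mp = {s: v[perm] for s, v in m.items()}
        a, b = euclidean_contrast(m, VAL), euclidean_contrast(mp, VAL)
        assert a.percent_contrast == pytest.approx(b.percent_contrast)


class TestPcaTrajectories:
    def test_rank_one_data(self):
        pattern = np.array([1.0, -2.0, 0.5])
        mats = {
            s: np.outer(pattern, np.linspace(0, i + 1, 8))
            for i, s in enumerate(CFG.stimulus_set)
        }
        traj = pca_trajectories(mats, n_components=2)
        assert traj.variance_explained[0] > 0.999

    def test_two_neuron_components_match_eigendecomposition(self):
        rng = np.random.default_rng(9)
        x = rng.multivariate_normal([0, 0], [[3.0, 1.2], [1.2, 1.0]], size=40)
        mats = {"odor1": x[:20].T, "odor5": x[20:].T,
                "odor2": x[:20].T, "odor3": x[:20].T, "odor4": x[:20].T}
        stacked = np.concatenate([mats[s].T for s in mats], axis=0)
        cov = np.cov(stacked.T, bias=False)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        traj = pca_trajectories(mats, n_components=2)
        # recover the component from two projected points
        p = traj.trajectories["odor1"]
        recon = np.linalg.lstsq(
            stacked - stacked.mean(0), np.concatenate(
                [traj.trajectories[s][:, 0] for s in mats]), rcond=None
        )[0]
        recon /= np.linalg.norm(recon)
        assert abs(recon @ lead) == pytest.approx(1.0, abs=1e-6)

    def test_neuron_reordering_changes_nothing_up_to_sign(self):
        rng = np.random.default_rng(10)
        mats = {s: rng.normal(size=(5, 6)) for s in CFG.stimulus_set}
        perm = rng.permutation(5)
        matp = {s: v[perm] for s, v in mats.items()}
        a = pca_trajectories(mats).trajectories["odor1"]
        b = pca_trajectories(matp).trajectories["odor1"]
        for k in range(3):
            assert (np.allclose(a[:, k], b[:, k], atol=1e-8)
                    or np.allclose(a[:, k], -b[:, k], atol=1e-8))

    def test_too_many_components_rejected(self):
        mats = {s: np.zeros((2, 4)) for s in CFG.stimulus_set}
        with pytest.raises(ValueError):
            pca_trajectories(mats, n_components=5)
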