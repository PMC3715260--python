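"""FFSM pose recognition: fuzzy update, cycle constraint, durations."""

import numpy as np
import pytest

from wimotion import ffsm_pose as fp, motion_features as mf, synthetic_motion as sm


@pytest.fixture(scope="module")
def model():
    return fp.default_sun_salutation_model()


def pose_features(model, pose, n=1):
    theta = np.tile(model.states[pose].theta_deg, (n, 1))
    dtheta = np.zeros((n, 5))
    return theta, dtheta


def concentrated(model, j):
    a = np.zeros(model.n_states)
    a[j] = 1.0
    return a


class TestStep:
    def test_core_features_absorbing(self, model):
        a = concentrated(model, 2)
        theta, dtheta = pose_features(model, 2)
        for _ in range(50):
            a = fp.step(a, theta[0], dtheta[0], model)
        assert a[2] >= 0.99
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_evidence_leaves_activations_unchanged(self, model):
        # static features far from every template: nothing fires
        a = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
        theta = np.full(5, 100.0)  # matches no pose region everywhere
        mu = model.state_membership(theta)[0]
        assert mu.max() == 0.0
        out = fp.step(a, theta, np.zeros(5), model)
        np.testing.assert_allclose(out, a)

    def test_gap_features_hold_activations(self, model):
        a = concentrated(model, 1)
        theta = np.array([np.nan, 20, 170, 180, 180])
        out = fp.step(a, theta, np.zeros(5), model)
        np.testing.assert_array_equal(out, a)

    def test_invalid_activations_rejected(self, model):
        with pytest.raises(ValueError, match="sum"):
            fp.step(np.array([0.7, 0.7, 0, 0, 0, 0]),
                    np.zeros(5), np.zeros(5), model)

    def test_transition_sweep_moves_mass_monotonically(self, model):
        # ramp from pose-1 core to pose-2 core with motion present
        th1 = np.array(model.states[1].theta_deg)
        th2 = np.array(model.states[2].theta_deg)
        a = concentrated(model, 1)
        masses = []
        for s in np.linspace(0, 1, 80):
            theta = th1 + s * (th2 - th1)
            dtheta = np.full(5, 30.0)  # moving
            a = fp.step(a, theta, dtheta, model)
            masses.append(a[2])
        masses = np.array(masses)
        assert (np.diff(masses) >= -1e-9).all()
        assert masses[-1] > 0.99

    def test_conservation_under_random_inputs(self, model, rng):
        a = concentrated(model, 0)
        for _ in range(300):
            theta = rng.uniform(0, 180, 5)
            dtheta = rng.uniform(-50, 50, 5)
            a = fp.step(a, theta, dtheta, model)
            assert a.sum() == pytest.approx(1.0, abs=1e-9)
            assert ((a >= 0) & (a <= 1)).all()


@pytest.fixture(scope="module")
def exercise():
    script = sm.sun_salutation_script(hold_s=4.0, transition_s=1.0,
                                      noise_sigma_g=0.02, seed=3)
    ex = sm.gen_exercise(script)
    g = ex.streams_g()
    calibs = {i: mf.calibrate(g[i][:320]) for i in g}
    return script, mf.extract_features(g, calibs)


class TestRecognize:

    def test_starts_dominant_on_q0(self, exercise):
        _, feats = exercise
        tl = fp.recognize(feats)
        assert (tl.dominant[:160] == 0).all()
        assert tl.activations[0, 0] > 0.9

    def test_visits_all_poses_in_cycle_order(self, exercise):
        _, feats = exercise
        tl = fp.recognize(feats)
        order = [d for d, prev in zip(tl.dominant, np.r_[-1, tl.dominant[:-1]])
                 if d != prev]
        assert order == [0, 1, 2, 3, 4, 5, 0]

    def test_activations_sum_to_one_everywhere(self, exercise):
        _, feats = exercise
        tl = fp.recognize(feats)
        np.testing.assert_allclose(tl.activations.sum(axis=1), 1.0, atol=1e-9)

    def test_out_of_order_pattern_does_not_skip_states(self, model):
        # q3's pattern presented while the machine is still early in the
        # cycle: the ordered transition structure forbids a jump, so q3
        # must stay inactive throughout
        n = 200
        theta3 = np.tile(model.states[3].theta_deg, (n, 1))
        dtheta3 = np.full((n, 5), 30.0)
        theta = np.vstack([np.tile(model.states[1].theta_deg, (50, 1)),
                           theta3])
        dtheta = np.vstack([np.zeros((50, 5)), dtheta3])
        tl = fp.recognize((theta, dtheta), model)
        assert tl.activations[:, 3].max() < 0.01

    def test_wrong_dimensionality_rejected(self, model):
        with pytest.raises(ValueError, match=r"\(n, 5\)"):
            fp.recognize((np.zeros((10, 4)), np.zeros((10, 4))), model)


class TestDurations:
    def test_hand_arithmetic_mean_and_unbiased_std(self, model):
        rep = fp.DurationReport(
            per_pose={1: [4.0, 5.0, 6.0, 5.0]}, n_repetitions=4)
        m, s = rep.pose_mean_std(1)
        assert m == pytest.approx(5.0)
        assert s == pytest.approx(np.std([4, 5, 6, 5], ddof=1))

    def test_exact_holds_recovered(self):
        script = sm.sun_salutation_script(hold_s=5.0, transition_s=1.0,
                                          noise_sigma_g=0.0, seed=0)
        ex = sm.gen_exercise(script)
        g = ex.streams_g()
        calibs = {i: mf.calibrate(g[i][:320]) for i in g}
        tl = fp.recognize(mf.extract_features(g, calibs))
        rep = fp.durations(tl)
        truth = sm.true_pose_durations(script)
        for p in range(1, 6):
            m, s = rep.pose_mean_std(p)
            assert m == pytest.approx(np.mean(truth[p]), abs=0.1)
            assert s == pytest.approx(0.0, abs=1e-9)

    def test_shortest_pose_identified(self):
        # one pose held much shorter than the rest must show up as the
        # minimum of the report
        script = sm.sun_salutation_script(hold_s=6.0, transition_s=1.0,
                                          noise_sigma_g=0.01, seed=5,
                                          hold_overrides={4: 2.0})
        ex = sm.gen_exercise(script)
        g = ex.streams_g()
        calibs = {i: mf.calibrate(g[i][:320]) for i in g}
        rep = fp.durations(fp.recognize(mf.extract_features(g, calibs)))
        means = {p: rep.pose_mean_std(p)[0] for p in range(1, 6)}
        assert min(means, key=means.get) == 4

    def test_no_repetition_raises(self, model):
        tl = fp.PoseTimeline(
            times=np.arange(10) / 160.0,
            activations=np.tile(concentrated(model, 0), (10, 1)),
            dominant=np.zeros(10, dtype=int),
            sampling_rate_hz=160.0, model=model)
        with pytest.raises(ValueError, match="repetition"):
            fp.durations(tl)

    def test_report_schema(self):
        rep = fp.DurationReport(per_pose={p: [3.0, 4.0] for p in range(1, 6)},
                                n_repetitions=2)
        df = rep.to_dataframe()
        for col in ("q1_mean_s", "q5_std_s", "pose_mean_s",
                    "exercise_mean_s", "exercise_std_s"):
            assert col in df.columns
        assert df["exercise_mean_s"].iloc[0] == pytest.approx(5 * 3.5)


class TestModelIO:
    def test_yaml_round_trip(self, model, tmp_path):
        path = tmp_path / "model.yaml"
        fp.save_model(model, path)
        loaded = fp.load_model(path)
        assert loaded.n_states == model.n_states
        for a, b in zip(loaded.states, model.states):
            assert a.theta_deg == b.theta_deg
            assert a.support_deg == pytest.approx(b.support_deg)

    def test_bundled_model_matches_default(self):
        from importlib import resources
        with resources.as_file(
            resources.files("wimotion") / "data" / "sun_salutation.yaml"
        ) as p:
            loaded = fp.load_model(p)
        default = fp.default_sun_salutation_model()
        for a, b in zip(loaded.states, default.states):
            assert a.theta_deg == b.theta_deg
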