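import numpy as np
import pytest
from scipy import stats as st

from oracles import (
    karcher_residual_ref,
    random_spd,
    spd_distance_ref,
    spd_mean_two_ref,
    exact_binomial_chance_pct,
)

from bcistim.bci import (
    assign_performance_group,
    chance_threshold,
    csp_features,
    estimate_covariance,
    evaluate_offline_accuracy,
    fit_csp,
    fit_flda,
    fit_mdm,
    geometric_mean,
    predict_flda,
    predict_mdm,
    riemannian_distance,
    score_subject,
    PerformanceRecord,
)
from bcistim.io import ROI_9, EpochSet
from bcistim.synthetic import SyntheticConfig, generate_subject


class TestCovariance:
    def test_hand_toy(self):
        epoch = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        c = estimate_covariance(epoch, shrinkage=0.0)
        assert c[0, 0] == pytest.approx(4 / 3)
        assert c[1, 1] == pytest.approx(4 / 3)
        assert c[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_white_channels(self):
        rng = np.random.default_rng(0)
        c = estimate_covariance(rng.standard_normal((2, 10_000)))
        rho = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
        assert abs(rho) < 0.05
        assert c[0, 0] == pytest.approx(1.0, rel=0.1)
        assert c[1, 1] == pytest.approx(1.0, rel=0.1)

    def test_zero_channel_still_spd(self):
        epoch = np.vstack([np.zeros(100), np.random.default_rng(1).standard_normal(100)])
        c = estimate_covariance(epoch)
        assert np.linalg.eigvalsh(c).min() > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            estimate_covariance(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestRiemannianDistance:
    def test_identity_property(self):
        a = random_spd(np.random.default_rng(0), 4)
        assert riemannian_distance(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_example(self):
        a = np.eye(2)
        b = np.diag([np.e**2, 1.0])
        assert riemannian_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_congruence_invariance(self):
        rng = np.random.default_rng(3)
        a, b = random_spd(rng, 3), random_spd(rng, 3)
        w = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        d1 = riemannian_distance(a, b)
        d2 = riemannian_distance(w @ a @ w.T, w @ b @ w.T)
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c = (random_spd(rng, 3) for _ in range(3))
            dab = riemannian_distance(a, b)
            dba = riemannian_distance(b, a)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab <= riemannian_distance(a, c) + riemannian_distance(c, b) + 1e-8

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            riemannian_distance(np.diag([1.0, -1.0]), np.eye(2))


class TestGeometricMean:
    def test_single_matrix(self):
        a = random_spd(np.random.default_rng(5), 3)
        assert np.allclose(geometric_mean([a]), a)

    def test_scalar_matrices(self):
        m = geometric_mean([2.0 * np.eye(3), 8.0 * np.eye(3)])
        assert np.allclose(m, 4.0 * np.eye(3), atol=1e-7)

    def test_commuting_pair(self):
        m = geometric_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        assert np.allclose(m, np.diag([2.0, 2.0]), atol=1e-7)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        mats = [random_spd(rng, 3) for _ in range(5)]
        m1 = geometric_mean(mats)
        m2 = geometric_mean(mats[::-1])
        assert np.allclose(m1, m2, atol=1e-6)

    def test_congruence_equivariant(self):
        rng = np.random.default_rng(7)
        mats = [random_spd(rng, 3) for _ in range(4)]
        w = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        m1 = geometric_mean([w @ a @ w.T for a in mats])
        m2 = w @ geometric_mean(mats) @ w.T
        assert np.allclose(m1, m2, atol=1e-5 * np.abs(m2).max())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean([])


class TestSpdOracleAgreement:
    """Dual-route checks against scipy matrix-function reference implementations."""

    def test_distance_matches_reference_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            d = int(rng.integers(2, 6))
            a, b = random_spd(rng, d), random_spd(rng, d)
            assert riemannian_distance(a, b) == pytest.approx(
                spd_distance_ref(a, b), abs=1e-6
            )

    def test_two_matrix_mean_matches_closed_form(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = random_spd(rng, 3), random_spd(rng, 3)
            m = geometric_mean([a, b])
            assert np.allclose(m, spd_mean_two_ref(a, b), atol=1e-6)

    def test_mean_satisfies_karcher_condition(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            mats = [random_spd(rng, 3) for _ in range(5)]
            x = geometric_mean(mats)
            assert karcher_residual_ref(x, mats) < 1e-6


class TestMdm:
    def _two_class_model(self):
        rng = np.random.default_rng(11)
        epochs, labels = [], []
        for cls, scale in (("left", [4, 1]), ("right", [1, 4])):
            for _ in range(6):
                e = rng.standard_normal((2, 500)) * np.sqrt(scale)[:, None]
                epochs.append(e)
                labels.append(cls)
        return fit_mdm(np.array(epochs), labels)

    def test_trial_equal_to_class_mean(self):
        model = self._two_class_model()
        assert predict_mdm(model, model.class_means["left"]) == "left"
        assert predict_mdm(model, model.class_means["right"]) == "right"

    def test_tie_breaks_to_first_sorted_class(self):
        from bcistim.bci import MdmModel
        model = MdmModel(class_means={"left": np.eye(2), "right": 4 * np.eye(2)},
                         classes=("left", "right"))
        d_l = riemannian_distance(2 * np.eye(2), np.eye(2))
        d_r = riemannian_distance(2 * np.eye(2), 4 * np.eye(2))
        assert d_l == pytest.approx(d_r, abs=1e-12)
        assert predict_mdm(model, 2.0 * np.eye(2)) == "left"

    def test_rescaling_invariance(self):
        model = self._two_class_model()
        rng = np.random.default_rng(12)
        trial = rng.standard_normal((2, 500)) * np.sqrt([4, 1])[:, None]
        cov = estimate_covariance(trial)
        pred1 = predict_mdm(model, cov)
        # common congruence of trial AND means leaves predictions unchanged
        w = np.diag([3.0, 0.5])
        from bcistim.bci import MdmModel
        scaled = MdmModel(
            class_means={k: w @ v @ w.T for k, v in model.class_means.items()},
            classes=model.classes,
        )
        pred2 = predict_mdm(scaled, w @ cov @ w.T)
        assert pred1 == pred2

    def test_missing_class_raises(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            fit_mdm(rng.standard_normal((4, 2, 100)), ["left"] * 4)


class TestCspFlda:
    def test_analytic_csp_eigenvalues(self):
        rng = np.random.default_rng(14)
        epochs, labels = [], []
        for cls, scale in (("a", [4, 1]), ("b", [1, 4])):
            for _ in range(40):
                epochs.append(rng.standard_normal((2, 2000)) * np.sqrt(scale)[:, None])
                labels.append(cls)
        model = fit_csp(np.array(epochs), labels, n_select=2)
        assert np.allclose(sorted(model.eigenvalues), [0.2, 0.8], atol=0.03)
        # filters align with coordinate axes up to sign/scale
        for row in model.filters:
            r = np.abs(row) / np.abs(row).max()
            assert min(r) < 0.15

    def test_whitened_eigenvalues_sum_to_one(self):
        rng = np.random.default_rng(15)
        epochs = rng.standard_normal((30, 4, 600))
        labels = ["a"] * 15 + ["b"] * 15
        model = fit_csp(epochs, labels, n_select=2)
        # lambda_i(Ca) + lambda_i(Cb) = 1 in the whitened space
        assert np.all((model.eigenvalues > 0) & (model.eigenvalues < 1))
        flipped = fit_csp(epochs, ["b"] * 15 + ["a"] * 15, n_select=2)
        assert np.allclose(np.sort(model.eigenvalues) + np.sort(flipped.eigenvalues)[::-1],
                           1.0, atol=1e-9)

    def test_flda_boundary_at_zero_for_symmetric_classes(self):
        rng = np.random.default_rng(16)
        f = np.concatenate([rng.normal(-1, 1, (200, 1)), rng.normal(1, 1, (200, 1))])
        labels = np.array(["a"] * 200 + ["b"] * 200)
        model = fit_flda(f, labels)
        boundary = -model.bias / model.weights[0]
        assert abs(boundary) < 0.2

    def test_null_classes_near_chance(self):
        rng = np.random.default_rng(17)
        epochs = rng.standard_normal((80, 3, 400))
        labels = np.array(["a", "b"] * 40)
        csp = fit_csp(epochs[:40], labels[:40], n_select=2)
        flda = fit_flda(csp_features(csp, epochs[:40]), labels[:40])
        acc = np.mean(predict_flda(flda, csp_features(csp, epochs[40:])) == labels[40:])
        lo, hi = st.binom.interval(0.95, 40, 0.5)
        assert lo / 40 <= acc <= hi / 40

    def test_online_variants_run_on_synthetic_subject(self, pre_only_subject):
        from bcistim.bci import train_online_classifier, predict_online
        from bcistim.io import extract_epochs, filter_signal, BandDefinition, RawRecording
        raw, events, _ = pre_only_subject
        x = filter_signal(raw.samples, raw.fs, "bandpass", BandDefinition("bp", 8, 30))
        filtered = RawRecording(x, raw.fs, raw.channel_labels)
        train = extract_epochs(filtered, events, (1000, 3500), phase="offline")
        test = extract_epochs(filtered, events, (1000, 3500), phase="online")
        for variant in ("19ch_2+2", "9ch_1+1"):
            csp, flda = train_online_classifier(train, variant=variant)
            preds = predict_online(csp, flda, test)
            assert set(preds) <= {"left", "right"}
            assert len(preds) == test.n_trials


class TestChanceThreshold:
    def test_reproduces_printed_threshold(self):
        assert chance_threshold(80, 0.05) == pytest.approx(60.69, abs=0.05)

    def test_monotone_decreasing_to_50(self):
        values = [chance_threshold(n) for n in (40, 80, 400, 10_000, 1_000_000)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(50.0, abs=0.2)

    def test_close_to_exact_binomial_quantile(self):
        exact = exact_binomial_chance_pct(80, alpha=0.05)
        assert exact == pytest.approx(60.0, abs=1e-9)
        assert abs(chance_threshold(80) - exact) < 1.0

    def test_degenerate_alpha_rejected(self):
        with pytest.raises(ValueError):
            chance_threshold(80, alpha=0.0)


class TestPerformanceGroups:
    @pytest.mark.parametrize("acc,expected", [(52.5, "low"), (74.17, "high"),
                                              (60.69, "high")])
    def test_assignment_rule(self, acc, expected):
        rec = PerformanceRecord(subject="s", session="pre", accuracy=acc, n_test_trials=80)
        assert assign_performance_group(rec, 60.69) == expected
        assert rec.group == expected

    def test_accuracy_bounds_enforced(self):
        with pytest.raises(ValueError):
            PerformanceRecord(subject="s", session="pre", accuracy=105.0, n_test_trials=80)


class TestOfflineAccuracy:
    def test_perfect_predictions_scores_100(self):
        rng = np.random.default_rng(18)
        data, labels = [], []
        for cls, scale in (("left", [9, 1]), ("right", [1, 9])):
            for _ in range(10):
                data.append(rng.standard_normal((2, 800)) * np.sqrt(scale)[:, None])
                labels.append(cls)
        ep = EpochSet(data=np.array(data), window_ms=(0, 800 / 300 * 1000),
                      labels=np.array(labels), fs=300.0, channel_labels=("C3", "C4"))
        blocks = np.array(([1] * 5 + [2] * 5) * 2)
        rec = evaluate_offline_accuracy(ep, blocks, train_blocks=(1,), test_blocks=(2,))
        assert rec.accuracy == 100.0

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(20)
        data = rng.standard_normal((80, 3, 400))
        labels = np.array(["left", "right"] * 40)
        rng.shuffle(labels)
        ep = EpochSet(data=data, window_ms=(0, 400 / 300 * 1000), labels=labels,
                      fs=300.0, channel_labels=("C3", "Cz", "C4"))
        blocks = np.repeat([1, 2, 3, 4], 20)
        rec = evaluate_offline_accuracy(ep, blocks)
        lo, hi = st.binom.interval(0.95, rec.n_test_trials, 0.5)
        assert 100 * lo / rec.n_test_trials <= rec.accuracy <= 100 * hi / rec.n_test_trials

    def test_no_test_trials_raises(self):
        rng = np.random.default_rng(20)
        ep = EpochSet(data=rng.standard_normal((4, 2, 300)), window_ms=(0, 1000),
                      labels=np.array(["left", "right"] * 2), fs=300.0,
                      channel_labels=("C3", "C4"))
        with pytest.raises(ValueError, match="test"):
            evaluate_offline_accuracy(ep, np.array([1, 1, 2, 2]))


class TestScoringCalibration:
    """Simulation-calibrated behavior of the full scoring chain (scaled-down
    trial counts keep the suite inside its time budget)."""

    def test_null_generator_is_at_chance(self):
        correct = total = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=600 + seed, erd_depth=0.0,
                                  n_trials_per_block=10, sessions=("pre",))
            raw, events, _ = generate_subject(cfg)
            rec = score_subject(raw, events, "pre")
            correct += round(rec.accuracy / 100 * rec.n_test_trials)
            total += rec.n_test_trials
        lo, hi = st.binom.interval(0.95, total, 0.5)
        assert lo <= correct <= hi

    def test_deep_erd_clears_chance_threshold_in_90pct_of_seeds(self):
        thr = chance_threshold(80)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=700 + seed, erd_depth=0.6,
                                  n_trials_per_block=20, sessions=("pre",))
            raw, events, _ = generate_subject(cfg)
            if score_subject(raw, events, "pre").accuracy > thr:
                wins += 1
        assert wins >= 0.9 * n_seeds

    def test_high_minus_low_performer_gap_exceeds_10_points(self):
        means = {}
        for depth in (0.1, 0.7):
            accs = []
            for seed in range(10):
                cfg = SyntheticConfig(seed=800 + seed, erd_depth=depth,
                                      n_trials_per_block=10, sessions=("pre",))
                raw, events, _ = generate_subject(cfg)
                accs.append(score_subject(raw, events, "pre").accuracy)
            means[depth] = np.mean(accs)
        assert means[0.7] - means[0.1] > 10.0


class TestFullScoringPipeline:
    def test_strong_erd_beats_threshold(self):
        cfg = SyntheticConfig(seed=42, erd_depth=0.6, n_trials_per_block=20,
                              sessions=("pre",))
        raw, events, _ = generate_subject(cfg)
        rec = score_subject(raw, events, "pre")
        assert rec.accuracy > chance_threshold(80)
        assert rec.meta["quality"] == "keep"

    def test_roi_channels_used(self):
        cfg = SyntheticConfig(seed=43, n_trials_per_block=4, sessions=("pre",))
        raw, events, _ = generate_subject(cfg)
        rec = score_subject(raw, events, "pre", roi=ROI_9)
        assert rec.n_test_trials > 0
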