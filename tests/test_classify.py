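"""Metrics, count reconstruction, jackknife tuning, and grouped CV."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

import sersdx
from sersdx.classify import (
    LOPO,
    LOSO,
    ConfusionCounts,
    Dataset,
    ModelConfig,
    build_task,
    compute_metrics,
    counts_from_rates,
    cross_validate,
    jackknife_optimize,
    round_half_away,
    run_two_step,
)
from sersdx.errors import ConfigError, DegenerateInputError, ValidationError

SMALL = ModelConfig(C_grid=(1.0, 16.0), gamma_grid=(2.0**-7, 2.0**-3))


def _blob_dataset(rng, n_per_class=12, sep=4.0, d=6, patients_per_class=4, shuffle_labels=False):
    """Two Gaussian blobs with patient structure; separable when sep is large."""
    X, y, patients = [], [], []
    for label, sign in (("A", -1.0), ("B", 1.0)):
        centre = np.zeros(d)
        centre[0] = sign * sep / 2.0
        for i in range(n_per_class):
            X.append(centre + rng.normal(size=d))
            y.append(label)
            patients.append(f"{label}{i % patients_per_class}")
    y = np.array(y)
    if shuffle_labels:
        y = rng.permutation(y)
    return Dataset(
        X=np.array(X), y=y, patients=np.array(patients),
        positive_label="A", negative_label="B",
    )


class TestMetrics:
    def test_known_confusion_table(self):
        """Hand-checked oracle: tp=149 fn=4 tn=70 fp=25."""
        r = compute_metrics(ConfusionCounts(tp=149, fn=4, tn=70, fp=25))
        assert r.se == pytest.approx(149 / 153)
        assert r.sp == pytest.approx(70 / 95)
        assert r.acc == pytest.approx(219 / 248)
        assert r.mcc == pytest.approx(0.7551, abs=5e-5)

    def test_perfect_and_inverted_classifier(self):
        perfect = compute_metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert (perfect.se, perfect.sp, perfect.acc, perfect.mcc) == (1.0, 1.0, 1.0, 1.0)
        inverted = compute_metrics(ConfusionCounts(tp=0, fn=10, tn=0, fp=10))
        assert inverted.mcc == -1.0

    def test_mcc_zero_convention_on_degenerate_margin(self):
        # classifier that always predicts positive: tn+fn marginal is 0
        r = compute_metrics(ConfusionCounts(tp=10, fn=0, tn=0, fp=10))
        assert r.mcc == 0.0

    def test_mcc_matches_sklearn(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 2, size=40)
            y_pred = rng.integers(0, 2, size=40)
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            if tp + fn == 0 or tn + fp == 0:
                continue
            ours = compute_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)).mcc
            assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_metrics(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))
        with pytest.raises(DegenerateInputError):
            compute_metrics(ConfusionCounts(tp=0, fn=0, tn=0, fp=0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, fn=0, tn=1, fp=0)


class TestCountReconstruction:
    @pytest.mark.parametrize("x,expected", [(2.5, 3), (-2.5, -3), (2.4, 2), (-2.4, -2), (0.0, 0)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected

    def test_rates_roundtrip_first_example(self):
        """se=0.935, sp=0.772, n_pos=153, n_neg=101 -> tp=143, tn=78."""
        c = counts_from_rates(0.935, 0.772, 153, 101)
        assert (c.tp, c.fn, c.tn, c.fp) == (143, 10, 78, 23)
        r = compute_metrics(c)
        assert round(100 * r.acc, 1) == 87.0

    def test_rates_roundtrip_second_example(self):
        """se=0.514, sp=0.791, n_pos=105, n_neg=153 -> tp=54, tn=121."""
        c = counts_from_rates(0.514, 0.791, 105, 153)
        assert (c.tp, c.tn) == (54, 121)
        assert round(100 * compute_metrics(c).acc, 1) == 67.8

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ConfigError):
            counts_from_rates(1.1, 0.5, 10, 10)


class TestDataset:
    def test_build_task_dimensions(self, default_processed):
        ds = build_task(default_processed, "PA", "Normal")
        assert ds.X.shape == (254, 801)
        assert set(np.unique(ds.y)) == {"PA", "Normal"}
        assert len(set(ds.patients.tolist())) == 51

    def test_identical_labels_rejected(self, default_processed):
        with pytest.raises(ConfigError):
            build_task(default_processed, "PA", "PA")

    def test_missing_group_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError):
            build_task(tiny_cohort, "PA", "MEC")

    def test_scale_relative_gamma_resolution(self):
        rng = np.random.default_rng(0)
        ds = _blob_dataset(rng)
        cfg = ModelConfig(gamma_grid=(1.0, 4.0))
        resolved = ds.resolved_gammas(cfg)
        scale = 1.0 / (ds.X.shape[1] * ds.X.var())
        assert resolved == pytest.approx((scale, 4.0 * scale))
        absolute = ModelConfig(gamma_grid=(1.0, 4.0), gamma_mode="absolute")
        assert ds.resolved_gammas(absolute) == (1.0, 4.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(C_grid=())
        with pytest.raises(ConfigError):
            ModelConfig(gamma_grid=(-1.0,))
        with pytest.raises(ConfigError):
            ModelConfig(gamma_mode="auto")


class TestJackknife:
    def test_separable_blobs_reach_perfect_inner_accuracy(self):
        ds = _blob_dataset(np.random.default_rng(7), sep=10.0)
        C, gamma, acc = jackknife_optimize(ds, SMALL)
        assert acc == 1.0
        assert C in SMALL.C_grid
        assert gamma > 0

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(5):
            ds = _blob_dataset(np.random.default_rng(100 + seed), sep=0.0, shuffle_labels=True)
            accs.append(jackknife_optimize(ds, SMALL)[2])
        # LOO accuracy on pure noise; the max over a 4-point grid sits near 0.5
        assert np.mean(accs) < 0.75

    def test_tie_break_prefers_smallest_c_then_gamma(self):
        """Replay the grid by hand: the winner must be the lexicographically
        smallest (C, gamma) pair among the argmax set."""
        from sklearn.metrics.pairwise import rbf_kernel

        from sersdx.classify import _loo_predictions

        ds = _blob_dataset(np.random.default_rng(7), sep=10.0)
        cfg = ModelConfig(C_grid=(1.0, 4.0, 16.0), gamma_grid=(2.0**-7, 2.0**-5))
        C, gamma, acc = jackknife_optimize(ds, cfg)
        scale = ds.gamma_scale()
        grid = {}
        for g_raw in cfg.gamma_grid:
            K = rbf_kernel(ds.X, gamma=g_raw * scale)
            for c in cfg.C_grid:
                preds = _loo_predictions(K, ds.y, c, cfg.class_weight)
                grid[(c, g_raw)] = float(np.mean(preds == ds.y))
        best = max(grid.values())
        winner = min(k for k, v in grid.items() if v == best)
        assert acc == best
        assert (C, gamma) == (winner[0], pytest.approx(winner[1] * scale))

    def test_singleton_class_rejected(self):
        ds = Dataset(
            X=np.random.default_rng(0).normal(size=(3, 4)),
            y=np.array(["A", "B", "B"]),
            patients=np.array(["p0", "p1", "p2"]),
            positive_label="A", negative_label="B",
        )
        with pytest.raises(DegenerateInputError):
            jackknife_optimize(ds, SMALL)

    def test_exact_loo_matches_naive_refit(self):
        """The support-vector shortcut must agree with refitting every fold."""
        from sklearn.metrics.pairwise import rbf_kernel
        from sklearn.svm import SVC

        from sersdx.classify import _loo_predictions

        ds = _blob_dataset(np.random.default_rng(3), sep=2.0)
        K = rbf_kernel(ds.X, gamma=0.05)
        for C in (0.5, 8.0):
            fast = _loo_predictions(K, ds.y, C, "balanced")
            naive = np.empty_like(ds.y)
            idx = np.arange(ds.n)
            for i in idx:
                tr = idx[idx != i]
                svc = SVC(C=C, kernel="precomputed", class_weight="balanced")
                svc.fit(K[np.ix_(tr, tr)], ds.y[tr])
                naive[i] = svc.predict(K[np.ix_([i], tr)])[0]
            assert np.array_equal(fast, naive)


class TestCrossValidation:
    def test_loso_covers_every_spectrum_once(self):
        ds = _blob_dataset(np.random.default_rng(11), sep=10.0)
        counts, details = cross_validate(ds, LOSO, SMALL, return_details=True)
        assert details["n_folds"] == ds.n
        assert counts.tp + counts.fn + counts.tn + counts.fp == ds.n

    def test_lopo_one_fold_per_patient(self):
        ds = _blob_dataset(np.random.default_rng(11), sep=10.0)
        counts, details = cross_validate(ds, LOPO, SMALL, return_details=True)
        assert details["n_folds"] == len(set(ds.patients.tolist()))
        assert counts.tp + counts.fn + counts.tn + counts.fp == ds.n

    def test_separable_blobs_classified_perfectly_both_schemes(self):
        ds = _blob_dataset(np.random.default_rng(11), sep=10.0)
        for scheme in (LOSO, LOPO):
            r = compute_metrics(cross_validate(ds, scheme, SMALL), scheme=scheme)
            assert r.acc == 1.0

    def test_unknown_scheme_rejected(self):
        ds = _blob_dataset(np.random.default_rng(11))
        with pytest.raises(ConfigError):
            cross_validate(ds, "KFOLD", SMALL)

    def test_single_patient_class_fold_skipped_with_warning(self):
        """A patient owning an entire class leaves a one-class training fold."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 4))
        y = np.array(["A"] * 4 + ["B"] * 4)
        patients = np.array(["pa"] * 4 + [f"pb{i}" for i in range(4)])
        ds = Dataset(X=X, y=y, patients=patients, positive_label="A", negative_label="B")
        with pytest.warns(UserWarning, match="skipped"):
            counts, details = cross_validate(
                ds, LOPO, SMALL, return_details=True, hyperparams=(1.0, 0.1)
            )
        assert details["skipped_folds"] == ["pa"]
        assert counts.tp + counts.fn == 0  # all positives lived in the skipped fold

    def test_supplied_hyperparams_skip_tuning(self):
        ds = _blob_dataset(np.random.default_rng(11), sep=10.0)
        counts, details = cross_validate(ds, LOSO, SMALL, return_details=True,
                                         hyperparams=(2.0, 0.05))
        assert (details["C"], details["gamma"]) == (2.0, 0.05)
        assert "inner_accuracy" not in details


@pytest.fixture(scope="module")
def small_report():
    cfg = sersdx.SyntheticConfig(
        patients_per_group={"PA": 4, "WT": 4, "MEC": 4, "Normal": 4},
        spectra_per_patient=(3, 3),
        effect_size=2.0,
        patient_sd=0.1,
        noise_sd=1.0,
        seed=21,
    )
    cohort = sersdx.preprocess_cohort(sersdx.generate_cohort(cfg))
    return run_two_step(cohort, ModelConfig(C_grid=(1.0, 16.0), gamma_grid=(2.0**-5, 2.0**-1)))


class TestTwoStep:
    def test_all_twelve_cells_present(self, small_report):
        assert len(small_report.reports) == 12
        keys = {(r.task, r.scheme, r.step) for r in small_report.reports}
        assert (("Normal", "PA"), LOSO, 1) in keys
        assert (("PA", "Normal"), LOPO, 1) in keys  # tumor positive under LOPO
        assert (("PA", "WT"), LOSO, 2) in keys
        assert (("WT", "MEC"), LOPO, 2) in keys

    def test_counts_cover_both_groups(self, small_report):
        r = small_report.get("Normal", "MEC", LOSO)
        assert r.counts.n_positive == 12  # Normal: 4 patients x 3 spectra
        assert r.counts.n_negative == 12

    def test_strong_effect_beats_chance(self, small_report):
        accs = [r.acc for r in small_report.reports if r.scheme == LOSO]
        assert np.mean(accs) > 0.7

    def test_missing_group_warned_not_fatal(self, tiny_cohort):
        proc = sersdx.preprocess_cohort(tiny_cohort)
        report = run_two_step(proc, ModelConfig(C_grid=(1.0,), gamma_grid=(1.0,)))
        # only PA and Normal exist: 1 task x 2 schemes survive, 5 tasks warned
        assert len(report.reports) == 2
        assert len(report.warnings) == 5
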