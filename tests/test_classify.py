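"""Classification regimes, sweeps, experiments, and the model front."""

import numpy as np
import pytest

from rotasuite.classify import (
    DEFAULT_GRIDS,
    SuiteShiftClassifier,
    EvalReport,
    featurize,
    hyperparameter_sweep,
    noise_experiment,
    run_regime,
    sparsity_experiment,
)
from rotasuite.rosum import build_rosum
from rotasuite.shifts import ShieldingParams, generate_experimental_like, generate_theoretical

SEPARABLE_ROTS = ("1a", "1b", "2a", "2[")  # one per dd family


@pytest.fixture(scope="module")
def clean_records(catalog):
    """Noise-free, well-separated records: separable by construction."""
    params = ShieldingParams(noise_sd=0.0, alpha_amps=(), gamma_amps=())
    return generate_theoretical(
        catalog, ["AA", "CC"], 10, params, seed=0, rotamer_ids=SEPARABLE_ROTS
    )


@pytest.fixture(scope="module")
def noisy_records(catalog):
    return generate_theoretical(
        catalog, ["AA", "CC"], 12, seed=1,
        rotamer_ids=("1a", "1c", "1b", "1z", "2a", "4d", "2[", "4p"),
    )


@pytest.fixture(scope="module")
def rosum_dd(catalog):
    return build_rosum(catalog, "dd")


class TestFeaturize:
    def test_dimension_without_sequence(self, catalog, clean_records):
        X, y, dropped = featurize(clean_records, catalog, use_sequence=False)
        assert X.shape[1] == 5 and dropped == 0

    def test_dimension_with_sequence(self, catalog, clean_records):
        X, y, _ = featurize(clean_records, catalog, use_sequence=True)
        assert X.shape[1] == 21

    def test_scheme_label_mapping(self, catalog, clean_records):
        _, y, _ = featurize(clean_records, catalog, scheme_id="dd")
        assert set(y) <= set("abcd")

    def test_nonfinite_records_dropped(self, catalog, clean_records):
        import copy

        records = copy.deepcopy(clean_records)
        records[0].delta = np.array([np.nan] * 5)
        X, y, dropped = featurize(records, catalog)
        assert dropped == 1 and len(y) == len(records) - 1


class TestRunRegime:
    def test_separable_fixture_perfect_f1(self, catalog, clean_records, rosum_dd):
        rep = run_regime(
            "theo_vs_theo", clean_records, clean_records, "dd", "NN",
            rosum_dd, catalog, seed=0,
        )
        assert rep.f1 == pytest.approx(1.0)
        assert rep.weighted_accuracy == pytest.approx(1.0)

    def test_rand_on_balanced_classes(self, catalog, clean_records, rosum_dd):
        """Plain accuracy of RAND on k balanced classes is ~1/k."""
        rep = run_regime(
            "exp_vs_theo", clean_records, clean_records, "dd", "RAND",
            rosum_dd, catalog, seed=0,
        )
        # recall under weighted averaging equals plain accuracy
        k = 4
        n = rep.n_test
        se = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(rep.recall - 1 / k) < 3 * se + 1e-9

    def test_shuffled_labels_indistinguishable_from_random(self, catalog, noisy_records, rosum_dd):
        import copy

        rng = np.random.default_rng(0)
        f1s = []
        for rep_i in range(20):
            shuffled = copy.deepcopy(noisy_records)
            labels = [r.rotamer_id for r in shuffled]
            rng.shuffle(labels)
            for r, lab in zip(shuffled, labels):
                r.rotamer_id = lab
            rep = run_regime(
                "exp_vs_theo", noisy_records, shuffled, "dd", "NN",
                rosum_dd, catalog, seed=rep_i,
            )
            f1s.append(rep.f1)
        rand = run_regime(
            "exp_vs_theo", noisy_records, noisy_records, "dd", "RAND",
            rosum_dd, catalog, seed=0,
        )
        # shuffled-label NN scores sit in the random-chance band
        assert abs(np.mean(f1s) - rand.f1) < 3 * np.std(f1s) + 0.05

    def test_loo_deterministic(self, catalog, clean_records, rosum_dd):
        reps = [
            run_regime(
                "theo_vs_theo", clean_records, clean_records, "dd", "DT",
                rosum_dd, catalog, seed=7,
            )
            for _ in range(2)
        ]
        assert reps[0].to_dict() == reps[1].to_dict()

    def test_loo_requires_same_set(self, catalog, clean_records, rosum_dd):
        with pytest.raises(ValueError, match="leave-one-out"):
            run_regime(
                "theo_vs_theo", clean_records, list(clean_records), "dd", "NN",
                rosum_dd, catalog,
            )

    def test_report_round_trips(self, catalog, clean_records, rosum_dd):
        rep = run_regime(
            "exp_vs_theo", clean_records, clean_records, "dd", "NN",
            rosum_dd, catalog, seed=0,
        )
        assert EvalReport.from_dict(rep.to_dict()) == rep


class TestSweep:
    def test_single_point_grid(self, catalog, clean_records, rosum_dd):
        reports, best = hyperparameter_sweep(
            "exp_vs_theo", clean_records, clean_records, "dd", rosum_dd,
            catalog, grids={"NN": [{"n_neighbors": 1}]},
        )
        assert len(reports) == 1 and set(best) == {"NN"}

    def test_separable_fixture_all_nn_settings_perfect(self, catalog, clean_records, rosum_dd):
        reports, best = hyperparameter_sweep(
            "exp_vs_theo", clean_records, clean_records, "dd", rosum_dd,
            catalog, grids={"NN": [{"n_neighbors": k} for k in (1, 3, 5)]},
        )
        assert all(r.f1 == pytest.approx(1.0) for r in reports)

    def test_best_dominates_grid(self, catalog, noisy_records, rosum_dd):
        reports, best = hyperparameter_sweep(
            "exp_vs_theo", noisy_records, noisy_records, "dd", rosum_dd,
            catalog, grids={"NN": DEFAULT_GRIDS["NN"], "DT": DEFAULT_GRIDS["DT"]},
        )
        for name, top in best.items():
            assert all(top.f1 >= r.f1 for r in reports if r.classifier == name)


class TestExperiments:
    def test_full_retention_zero_delta(self, catalog, clean_records, rosum_dd):
        profile = dict.fromkeys(SEPARABLE_ROTS, 1.0)
        full, sparse = sparsity_experiment(
            clean_records, profile, "dd", rosum_dd, catalog, seed=0
        )
        assert full.weighted_accuracy == pytest.approx(sparse.weighted_accuracy)

    def test_aggressive_sparsification_lowers_weighted_accuracy(self, catalog, noisy_records):
        ros = build_rosum(catalog, None)
        profile = dict.fromkeys({r.rotamer_id for r in noisy_records}, 2)
        full, sparse = sparsity_experiment(
            noisy_records, profile, None, ros, catalog, seed=0
        )
        assert sparse.weighted_accuracy < full.weighted_accuracy

    def test_experiments_reproducible(self, catalog, noisy_records, rosum_dd):
        profile = dict.fromkeys({r.rotamer_id for r in noisy_records}, 0.5)
        a = sparsity_experiment(noisy_records, profile, "dd", rosum_dd, catalog, seed=3)
        b = sparsity_experiment(noisy_records, profile, "dd", rosum_dd, catalog, seed=3)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_zero_noise_identical_to_control(self, catalog, clean_records, rosum_dd):
        control, noisy = noise_experiment(
            clean_records, noise_sd=0.0, scheme_id="dd", rosum=rosum_dd,
            catalog=catalog, seed=0,
        )
        assert control.to_dict() == noisy.to_dict()

    def test_scores_degrade_monotonically_with_noise(self, catalog, noisy_records):
        ros = build_rosum(catalog, None)
        levels = (0.0, 0.5, 1.47, 3.0)
        mean_scores = []
        for sd in levels:
            scores = [
                noise_experiment(
                    noisy_records, noise_sd=sd, scheme_id=None, rosum=ros,
                    catalog=catalog, seed=s,
                )[1].weighted_accuracy
                for s in range(10)
            ]
            mean_scores.append(np.mean(scores))
        assert all(b <= a + 0.02 for a, b in zip(mean_scores, mean_scores[1:]))

    def test_coarse_families_more_noise_robust(self, catalog, noisy_records, rosum_dd):
        """At 1.47 ppm noise the dd-family F1 degrades less than the
        rotamer-level F1 (coarser classes by construction)."""
        ros46 = build_rosum(catalog, None)
        drops = {}
        for scheme, ros in ((None, ros46), ("dd", rosum_dd)):
            control, noisy = noise_experiment(
                noisy_records, noise_sd=1.47, scheme_id=scheme, rosum=ros,
                catalog=catalog, seed=0,
            )
            drops[scheme] = control.f1 - noisy.f1
        assert drops["dd"] < drops[None]


class TestModelFront:
    def test_fit_returns_results_with_summary(self, catalog, clean_records):
        model = SuiteShiftClassifier(clean_records, catalog, scheme_id="dd", classifier="NN")
        res = model.fit("theo_vs_theo")
        assert res.f1 == pytest.approx(1.0)
        text = res.summary()
        assert "weighted accuracy" in text and "theo_vs_theo" in text

    def test_exp_vs_theo_requires_test_records(self, catalog, clean_records):
        model = SuiteShiftClassifier(clean_records, catalog, scheme_id="dd")
        with pytest.raises(ValueError):
            model.fit("exp_vs_theo")

    def test_from_dataframe(self, catalog, clean_records):
        from rotasuite.shifts import records_to_frame

        model = SuiteShiftClassifier.from_dataframe(
            records_to_frame(clean_records), catalog, scheme_id="dd"
        )
        assert model.fit("theo_vs_theo").f1 == pytest.approx(1.0)


def test_scheme_coarsening_monotonicity(catalog, noisy_records):
    """On the default synthetic fixture F1(dd) >= F1(46 rotamers) for every
    classifier (coarse pucker families separate; rotamer detail does not)."""
    exp = generate_experimental_like(noisy_records, seed=5)
    for clf in ("NN", "DT", "RF", "SVM", "RAND"):
        f1s = {}
        for scheme in (None, "dd"):
            ros = build_rosum(catalog, scheme)
            rep = run_regime(
                "exp_vs_theo", noisy_records, exp, scheme, clf, ros, catalog, seed=0
            )
            f1s[scheme] = rep.f1
        assert f1s["dd"] >= f1s[None], clf
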