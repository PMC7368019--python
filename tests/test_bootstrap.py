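"""Synthetic-rat resampling, z-scoring, SVM cross-validation, bootstrap."""

import numpy as np
import pytest
from sklearn.base import clone

from veptools.bootstrap import (
    BootstrapResult,
    ClassifierConfig,
    SyntheticRat,
    SyntheticRatBootstrapSVM,
    bootstrap_classification,
    classify_once,
    electrode_config,
    make_synthetic_rats,
    shuffled_label_control,
    zscore_rats,
)
from veptools.errors import ConfigurationError, DataError
from veptools.spectral import FeaturePool, build_feature_pools

from conftest import make_sample_table


def pool_of(values, key=("SC_L", "red", 1), n_rats=13):
    values = np.asarray(values, dtype=float)
    rats = np.array(
        [f"r{i % n_rats}" for i in range(len(values))], dtype=object
    )
    return FeaturePool(
        electrode=key[0],
        wavelength=key[1],
        harmonic=key[2],
        amplitudes=values,
        rat_ids=rats,
        bin_indices=np.arange(len(values)),
    )


class TestElectrodeConfig:
    def test_all_electrodes_has_40_features(self):
        specs, names = electrode_config("all_electrodes")
        assert len(names) == 40
        for _, (group, keys) in specs.items():
            assert len(keys) == 40

    def test_sc_left_vs_right_has_10_aligned_features(self):
        specs, names = electrode_config("sc_left_vs_right")
        assert len(names) == 10
        (la, (ga, ka)), (lb, (gb, kb)) = specs.items()
        assert ga == gb == "alpha_syn"
        assert [k[1:] for k in ka] == [k[1:] for k in kb]
        assert {k[0] for k in ka} == {"SC_L"}
        assert {k[0] for k in kb} == {"SC_R"}

    def test_custom_counts(self):
        specs, names = electrode_config(
            "all_electrodes",
            wavelengths=("red", "green"),
            harmonics=(1,),
        )
        assert len(names) == 8

    def test_unknown_selector_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            electrode_config("nope")


class TestMakeSyntheticRats:
    def test_exact_partition_uses_every_sample_once(self):
        cfg = ClassifierConfig(n_synthetic_per_class=13, bins_per_rat=90)
        values = np.arange(1170, dtype=float)
        pools = {("SC_L", "red", 1): pool_of(values)}
        rats = make_synthetic_rats(
            pools, "A", cfg, np.random.default_rng(0)
        )
        # partition: the 13 x 90 assigned bins are exactly the pool
        total = sum(r.features[("SC_L", "red", 1)] * 90 for r in rats)
        assert total == pytest.approx(values.sum())
        assert len(rats) == 13

    def test_single_rat_gets_pool_mean(self):
        cfg = ClassifierConfig(n_synthetic_per_class=1, bins_per_rat=90)
        values = np.random.default_rng(1).normal(10, 2, 90)
        pools = {"f": values}
        (rat,) = make_synthetic_rats(pools, "A", cfg, np.random.default_rng(2))
        assert rat.features["f"] == pytest.approx(values.mean())

    def test_constant_pool_gives_constant_feature(self):
        cfg = ClassifierConfig(n_synthetic_per_class=4, bins_per_rat=10)
        pools = {"f": np.full(40, 7.5)}
        for seed in (0, 1):
            rats = make_synthetic_rats(
                pools, "A", cfg, np.random.default_rng(seed)
            )
            assert all(r.features["f"] == pytest.approx(7.5) for r in rats)

    def test_short_pool_error_names_feature_and_shortfall(self):
        cfg = ClassifierConfig(n_synthetic_per_class=13, bins_per_rat=90)
        pools = {("SC_L", "red", 1): pool_of(np.ones(100))}
        with pytest.raises(DataError, match="SC_L.*100.*1170"):
            make_synthetic_rats(pools, "A", cfg, np.random.default_rng(0))

    def test_with_replacement_accepts_short_pool(self):
        cfg = ClassifierConfig(
            n_synthetic_per_class=13,
            bins_per_rat=90,
            sampling="with_replacement",
        )
        pools = {"f": np.ones(100)}
        rats = make_synthetic_rats(pools, "A", cfg, np.random.default_rng(0))
        assert len(rats) == 13


class TestZScore:
    def test_hand_computed_population_zscores(self):
        rat = SyntheticRat("A", {"a": 2.0, "b": 4.0, "c": 6.0})
        (out,) = zscore_rats([rat])
        np.testing.assert_allclose(
            out.z_features, [-1.22474487, 0.0, 1.22474487]
        )

    def test_translation_and_scale_invariance(self):
        r1 = SyntheticRat("A", {"a": 1.0, "b": 2.0, "c": 5.0})
        r2 = SyntheticRat("A", {"a": 11.0, "b": 12.0, "c": 15.0})  # +10
        r3 = SyntheticRat("A", {"a": 3.0, "b": 6.0, "c": 15.0})  # x3
        out = zscore_rats([r1, r2, r3])
        np.testing.assert_allclose(out[0].z_features, out[1].z_features)
        np.testing.assert_allclose(out[0].z_features, out[2].z_features)

    def test_zero_variance_rejected(self):
        rat = SyntheticRat("A", {"a": 1.0, "b": 1.0})
        with pytest.raises(DataError, match="variance"):
            zscore_rats([rat])

    def test_per_feature_axis(self):
        r1 = SyntheticRat("A", {"a": 1.0, "b": 10.0})
        r2 = SyntheticRat("B", {"a": 3.0, "b": 20.0})
        out = zscore_rats([r1, r2], axis="per_feature")
        np.testing.assert_allclose(out[0].z_features, [-1.0, -1.0])
        np.testing.assert_allclose(out[1].z_features, [1.0, 1.0])


def rats_from_matrix(x, labels):
    rats = []
    for row, lab in zip(x, labels):
        rats.append(
            SyntheticRat(lab, {f"f{j}": v for j, v in enumerate(row)})
        )
    return zscore_rats(rats)


class TestClassifyOnce:
    def test_cleanly_separated_classes_reach_full_accuracy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(13, 10)) + np.linspace(1, 2, 10)
        b = rng.normal(0.0, 0.01, size=(13, 10)) + np.linspace(2, 1, 10)
        rats = rats_from_matrix(np.vstack([a, b]), ["A"] * 13 + ["B"] * 13)
        cfg = ClassifierConfig()
        assert classify_once(rats, cfg, np.random.default_rng(1)) == 1.0

    def test_label_independent_features_near_chance(self):
        """Random features: accuracy centred near (and slightly below)
        chance — the documented small-sample CV pessimism."""
        rng = np.random.default_rng(3)
        cfg = ClassifierConfig()
        accs = []
        for _ in range(60):
            x = rng.normal(size=(26, 10)) + np.linspace(5, 6, 10)
            rats = rats_from_matrix(x, ["A"] * 13 + ["B"] * 13)
            accs.append(classify_once(rats, cfg, rng))
        assert 0.35 < np.mean(accs) < 0.6

    def test_identical_feature_duplicates_carry_no_usable_signal(self):
        """Duplicating every animal into both classes leaves no true class
        signal.  Cross-validation does not return 50% here: the held-out
        copy's twin sits in the training set with the opposite label, so
        the classifier memorises the twin and anti-predicts — accuracy
        lands well *below* chance, never above it."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(13, 10)) + np.linspace(5, 6, 10)
        rats = rats_from_matrix(
            np.vstack([x, x]), ["A"] * 13 + ["B"] * 13
        )
        accs = [
            classify_once(rats, ClassifierConfig(), np.random.default_rng(s))
            for s in range(20)
        ]
        assert np.mean(accs) < 0.5

    def test_single_class_rejected(self):
        rats = rats_from_matrix(np.random.default_rng(0).normal(size=(4, 3)),
                                ["A"] * 4)
        with pytest.raises(DataError, match="two classes"):
            classify_once(rats, ClassifierConfig(k_folds=2),
                          np.random.default_rng(0))


class TestBootstrapResult:
    def _result(self, accs, n=None):
        accs = np.asarray(accs, dtype=float)
        return BootstrapResult(
            per_iteration_accuracy=accs, config=ClassifierConfig()
        )

    def test_p_below_chance_definition(self):
        accs = np.concatenate([np.full(30, 0.4), np.full(970, 0.9)])
        res = self._result(accs)
        assert res.p_below_chance == pytest.approx(0.03)
        assert res.significant

    def test_zero_subchance_reported_below_resolution(self):
        res = self._result(np.full(1000, 0.9))
        assert res.p_label == "p < 0.001"

    def test_mean_is_mean(self):
        res = self._result([0.2, 0.4, 0.9])
        assert res.mean_accuracy == pytest.approx(0.5)


class TestBootstrap:
    def _pools(self, rng, shift=0.0, n=260, n_feats=6):
        pools = {}
        for j in range(n_feats):
            key = ("SC_L", f"w{j}", 1)
            vals = rng.normal(10 + (shift if j < 2 else 0), 1.0, n)
            pools[key] = pool_of(vals, key=key, n_rats=13)
        return pools

    def _config(self, **kw):
        base = dict(
            n_synthetic_per_class=4,
            bins_per_rat=20,
            n_iterations=25,
            k_folds=4,
            sampling="with_replacement",
            seed=42,
        )
        base.update(kw)
        return ClassifierConfig(**base)

    def test_identical_seed_reproduces_distribution(self):
        rng = np.random.default_rng(0)
        pa, pb = self._pools(rng), self._pools(rng, shift=1.0)
        r1 = bootstrap_classification(pa, pb, self._config())
        r2 = bootstrap_classification(pa, pb, self._config())
        np.testing.assert_array_equal(
            r1.per_iteration_accuracy, r2.per_iteration_accuracy
        )

    def test_strong_effect_is_significant(self):
        rng = np.random.default_rng(1)
        pa, pb = self._pools(rng), self._pools(rng, shift=3.0)
        res = bootstrap_classification(pa, pb, self._config())
        assert res.mean_accuracy > 0.8
        assert res.significant

    def test_shuffled_control_near_chance_both_units(self):
        rng = np.random.default_rng(2)
        pa, pb = self._pools(rng), self._pools(rng, shift=3.0)
        animal = shuffled_label_control(
            pa, pb, self._config(n_iterations=60, shuffle_unit="animal")
        )
        synth = shuffled_label_control(
            pa, pb, self._config(n_iterations=60, shuffle_unit="synthetic_rat")
        )
        assert abs(animal.mean_accuracy - 0.5) < 0.12
        assert synth.mean_accuracy < animal.mean_accuracy + 0.05
        assert animal.shuffled and synth.shuffled

    def test_animal_shuffle_requires_provenance(self):
        cfg = self._config(shuffle_unit="animal")
        pools = {"f": np.ones(200), "g": np.ones(200)}
        with pytest.raises(ConfigurationError, match="provenance"):
            bootstrap_classification(pools, pools, cfg, shuffle_labels=True)

    def test_mismatched_feature_counts_rejected(self):
        rng = np.random.default_rng(3)
        pa = self._pools(rng)
        pb = self._pools(rng)
        del pb[("SC_L", "w0", 1)]
        with pytest.raises(ConfigurationError, match="number of features"):
            bootstrap_classification(pa, pb, self._config())


class TestEstimator:
    def test_sklearn_params_roundtrip_and_clone(self):
        est = SyntheticRatBootstrapSVM(n_iterations=7, random_state=3)
        params = est.get_params()
        assert params["n_iterations"] == 7
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(svm_c=2.0)
        assert est.svm_c == 2.0

    def test_fit_sets_fitted_attributes(self):
        df = make_sample_table(n_rats=3, n_bins=30, group="alpha_syn")
        df2 = make_sample_table(
            n_rats=3, n_bins=30, group="control", amplitude=10.5,
            rng=np.random.default_rng(9),
        )
        import pandas as pd

        table = pd.concat([df, df2], ignore_index=True)
        est = SyntheticRatBootstrapSVM(
            n_synthetic_per_class=4,
            bins_per_rat=15,
            n_iterations=5,
            k_folds=4,
            sampling="with_replacement",
            run_shuffled_control=True,
            random_state=0,
        )
        est.fit(table)
        assert 0.0 <= est.mean_accuracy_ <= 1.0
        assert len(est.per_iteration_accuracy_) == 5
        assert len(est.feature_names_) == 40
        assert hasattr(est, "shuffled_mean_accuracy_")
        assert est.score() == est.mean_accuracy_

    def test_sc_left_vs_right_uses_10_features(self):
        df = make_sample_table(n_rats=3, n_bins=30, group="alpha_syn")
        est = SyntheticRatBootstrapSVM(
            electrode_configuration="sc_left_vs_right",
            n_synthetic_per_class=4,
            bins_per_rat=15,
            n_iterations=4,
            k_folds=4,
            sampling="with_replacement",
            random_state=1,
        )
        est.fit(df)
        assert len(est.feature_names_) == 10
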