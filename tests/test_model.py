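import numpy as np
import pandas as pd
import pytest

from mrnadecay import ConfigurationError, ValidationError
from mrnadecay import model as md
from mrnadecay.features import build_schema

FAST = {"max_iter": 60, "learning_rate": 0.18}


def synth_dataset(
    n=3000,
    seed=0,
    noise=0.1,
    k_fn=None,
    level_fn=None,
    n_groups=4,
):
    """Feature-level synthetic dataset with known functional truth.

    Uses a narrow 2-isoform schema to keep the boosted fits fast."""
    rng = np.random.default_rng(seed)
    schema = build_schema(n_isoforms=2, pad_to=None)
    X = pd.DataFrame(
        rng.normal(size=(n, schema.dimension)),
        columns=schema.names,
        index=[f"v{i}" for i in range(n)],
    )
    f1 = X["iso1_log_tir"].to_numpy()
    f2 = X["iso1_ssrna_total_nt"].to_numpy()
    f3 = X["iso1_gc_frac"].to_numpy()
    if k_fn is None:
        k_fn = lambda: 0.3 + 0.1 * np.tanh(f1) + 0.05 * f2 + 0.02 * f3**2
    k = k_fn() + noise * rng.normal(size=n)
    outcomes = {}
    for t in (0, 2, 4, 8, 16):
        if level_fn is None:
            base = 1.5 * f1 - 0.8 * f2
        else:
            base = level_fn()
        outcomes[f"ln_level_t{t}"] = base - k * t + noise * rng.normal(size=n)
    outcomes = pd.DataFrame(outcomes, index=X.index)
    outcomes["k"] = k
    groups = pd.Series(
        [f"g{i % n_groups}" for i in range(n)], index=X.index, name="group"
    )
    return md.Dataset(X=X, outcomes=outcomes, groups=groups, schema=schema)


class TestSplit:
    def test_group_of_10_splits_8_2(self):
        groups = pd.Series(["a"] * 10, index=[f"v{i}" for i in range(10)])
        split = md.split_by_group(groups, 0.8, seed=0)
        assert (split == "train").sum() == 8

    def test_largest_remainder_arithmetic(self):
        # sizes {10, 5} at f=0.8 -> floors 8 + 4 = 12 = round(0.8 * 15)
        groups = pd.Series(["a"] * 10 + ["b"] * 5, index=[f"v{i}" for i in range(15)])
        split = md.split_by_group(groups, 0.8, seed=1)
        assert (split[groups == "a"] == "train").sum() == 8
        assert (split[groups == "b"] == "train").sum() == 4

    def test_same_seed_identical(self):
        groups = pd.Series(
            np.repeat(["a", "b", "c"], 50), index=[f"v{i}" for i in range(150)]
        )
        assert md.split_by_group(groups, seed=3).equals(md.split_by_group(groups, seed=3))

    def test_no_leakage_and_per_group_fraction(self):
        rng = np.random.default_rng(0)
        groups = pd.Series(
            rng.choice(["a", "b", "c", "d"], size=500), index=[f"v{i}" for i in range(500)]
        )
        split = md.split_by_group(groups, 0.8, seed=0)
        train = set(split.index[split == "train"])
        test = set(split.index[split == "test"])
        assert not train & test
        assert len(train | test) == 500
        for g, n in groups.value_counts().items():
            n_train = (split[groups == g] == "train").sum()
            assert abs(n_train - 0.8 * n) <= 1

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            md.split_by_group(pd.Series(["a"]), 1.5)


class TestLevelModels:
    def test_linear_truth_recovered(self):
        # ln-level an exact function of two features -> test R2 > 0.95
        ds = synth_dataset(n=5000, seed=1, noise=0.02)
        ds.split = md.split_by_group(ds.groups, seed=1)
        models = md.train_level_models(ds, FAST, seed=1)
        preds = md.predict_levels(models, ds.X.loc[ds.rows("test")])
        obs = ds.outcomes.loc[ds.rows("test"), "ln_level_t0"]
        r2 = np.corrcoef(preds["pred_ln_level_t0"], obs)[0, 1] ** 2
        assert r2 > 0.95

    def test_pure_noise_outcome_r2_near_zero(self):
        rng = np.random.default_rng(2)
        ds = synth_dataset(n=5000, seed=2)
        for c in ds.outcomes.columns:
            ds.outcomes[c] = rng.normal(size=len(ds.outcomes))
        ds.split = md.split_by_group(ds.groups, seed=2)
        models = md.train_level_models(ds, FAST, seed=2)
        preds = md.predict_levels(models, ds.X.loc[ds.rows("test")])
        obs = ds.outcomes.loc[ds.rows("test"), "ln_level_t0"]
        r2 = np.corrcoef(preds["pred_ln_level_t0"], obs)[0, 1] ** 2
        assert abs(r2) < 0.05

    def test_determinism(self):
        ds = synth_dataset(n=800, seed=3)
        ds.split = md.split_by_group(ds.groups, seed=3)
        p1 = md.predict_levels(md.train_level_models(ds, FAST, seed=3), ds.X)
        p2 = md.predict_levels(md.train_level_models(ds, FAST, seed=3), ds.X)
        assert p1.equals(p2)

    def test_constant_outcome_rejected(self):
        ds = synth_dataset(n=200, seed=4)
        ds.outcomes["ln_level_t0"] = 1.0
        ds.split = md.split_by_group(ds.groups, seed=4)
        with pytest.raises(ValidationError):
            md.train_level_models(ds, FAST, seed=4)


class TestDecayModel:
    def test_smooth_truth_recovered(self):
        ds = synth_dataset(n=5000, seed=5, noise=0.02)
        ds.split = md.split_by_group(ds.groups, seed=5)
        bundle = md.train_bundle(ds, FAST, seed=5)
        assert bundle.metrics["test"]["r2_decay"] > 0.8

    def test_augmentation_helps_when_levels_carry_signal(self):
        # k depends on a latent factor visible only through the measured
        # levels' decay; the level models encode it, so augmentation should
        # not hurt (median over 5 seeds)
        diffs = []
        for seed in range(3):
            ds = synth_dataset(n=1500, seed=seed, noise=0.05)
            ds.split = md.split_by_group(ds.groups, seed=seed)
            bundle = md.train_bundle(ds, FAST, seed=seed)
            level_models = bundle.level_models
            # non-augmented: decay model on raw features only
            train_idx = ds.rows("train")
            raw = md.BoostedRegressor(FAST, seed=seed).fit(
                ds.X.loc[train_idx].to_numpy(float),
                ds.outcomes.loc[train_idx, "k"].to_numpy(float),
            )
            test_idx = ds.rows("test")
            obs = ds.outcomes.loc[test_idx, "k"].to_numpy(float)
            r2_aug = bundle.metrics["test"]["r2_decay"]
            pred_raw = raw.predict(ds.X.loc[test_idx].to_numpy(float))
            r2_raw = np.corrcoef(pred_raw, obs)[0, 1] ** 2
            diffs.append(r2_aug - r2_raw)
        assert np.median(diffs) >= -0.01

    def test_constant_k_rejected(self):
        ds = synth_dataset(n=500, seed=6)
        ds.outcomes["k"] = 0.5
        ds.split = md.split_by_group(ds.groups, seed=6)
        models = md.train_level_models(ds, FAST, seed=6)
        with pytest.raises(ValidationError):
            md.train_decay_model(ds, models, FAST, seed=6)

    def test_schema_coverage_checked(self):
        ds = synth_dataset(n=500, seed=7)
        ds.split = md.split_by_group(ds.groups, seed=7)
        models = md.train_level_models(ds, FAST, seed=7)
        del models[16]
        from mrnadecay import SchemaError

        with pytest.raises(SchemaError):
            md.train_decay_model(ds, models, FAST, seed=7)


class TestEvaluate:
    def test_perfect_predictor_metrics(self):
        ds = synth_dataset(n=300, seed=8, noise=0.0)
        ds.split = md.split_by_group(ds.groups, seed=8)

        class Perfect:
            def __init__(self, values):
                self.values = values

            def predict(self, X):
                return self.values[: len(X)]

        # hand-wire a bundle whose predictions equal the outcomes
        bundle = md.ModelBundle(
            level_models={
                t: Perfect(ds.outcomes[f"ln_level_t{t}"].to_numpy())
                for t in (0, 2, 4, 8, 16)
            },
            decay_model=Perfect(ds.outcomes["k"].to_numpy()),
            hyperparams={},
            schema_hash="x",
            split_seed=8,
        )
        metrics = md.evaluate(bundle, ds)
        assert metrics["test"]["r2_decay"] == pytest.approx(1.0)
        assert metrics["test"]["median_relative_error_k"] == pytest.approx(0.0)

    def test_mean_predictor_r2_zero(self):
        ds = synth_dataset(n=300, seed=9)
        ds.split = md.split_by_group(ds.groups, seed=9)

        class Mean:
            def predict(self, X):
                return np.zeros(len(X))

        bundle = md.ModelBundle(
            level_models={t: Mean() for t in (0, 2, 4, 8, 16)},
            decay_model=Mean(),
            hyperparams={},
            schema_hash="x",
            split_seed=9,
        )
        metrics = md.evaluate(bundle, ds)
        assert metrics["test"]["r2_decay"] == 0.0

    def test_hand_computed_metrics_match(self):
        # spreadsheet-style oracle on a 10-variant table
        obs = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        pred = obs + np.array([0.02, -0.03, 0.01, 0.0, 0.05, -0.02, 0.0, 0.04, -0.01, 0.03])
        r = np.corrcoef(pred, obs)[0, 1]
        rel = np.median(np.abs(pred - obs) / obs)
        assert md._r2(pred, obs) == pytest.approx(r**2)
        assert np.median(np.abs(pred - obs) / np.abs(obs)) == pytest.approx(rel)

    def test_empty_test_split_is_error(self):
        ds = synth_dataset(n=100, seed=10)
        ds.split = pd.Series("train", index=ds.X.index)
        models = md.train_level_models(ds, FAST, seed=10)
        bundle = md.ModelBundle(models, md.train_decay_model(ds, models, FAST, seed=10),
                                {}, "x", 10)
        with pytest.raises(ValidationError):
            md.evaluate(bundle, ds)


class TestPruning:
    def _dataset_with_noise_feature(self, seed):
        rng = np.random.default_rng(seed)
        n = 800
        schema = build_schema(n_isoforms=1, pad_to=None)
        X = pd.DataFrame(
            rng.normal(size=(n, schema.dimension)),
            columns=schema.names,
            index=[f"v{i}" for i in range(n)],
        )
        k = 0.3 + 0.2 * X["iso1_log_tir"].to_numpy() + 0.01 * rng.normal(size=n)
        outcomes = pd.DataFrame(
            {f"ln_level_t{t}": -k * t + 0.5 * X["iso1_log_tir"] for t in (0, 2, 4, 8, 16)},
            index=X.index,
        )
        outcomes["k"] = k
        groups = pd.Series(["g"] * n, index=X.index)
        ds = md.Dataset(X=X, outcomes=outcomes, groups=groups, schema=schema)
        ds.split = md.split_by_group(ds.groups, seed=seed)
        return ds

    def test_noise_feature_pruned_truth_feature_retained(self):
        outcomes = []
        for seed in range(5):
            ds = self._dataset_with_noise_feature(seed)
            bundle = md.train_bundle(ds, FAST, seed=seed, backend="gbr")
            kept, dropped, _ = md.feature_importance_prune(
                bundle, ds, threshold=1e-3, hyperparams=FAST, seed=seed, backend="gbr"
            )
            outcomes.append(
                ("iso1_gc_frac" in dropped, "iso1_log_tir" in kept)
            )
        assert np.median([o[0] for o in outcomes]) == 1  # pure-noise feature pruned
        assert all(o[1] for o in outcomes)  # truth-generating feature retained

    def test_zero_threshold_prunes_nothing_important(self):
        ds = self._dataset_with_noise_feature(0)
        bundle = md.train_bundle(ds, FAST, seed=0, backend="gbr")
        kept, dropped, _ = md.feature_importance_prune(
            bundle, ds, threshold=-1.0, hyperparams=FAST, seed=0, backend="gbr"
        )
        assert dropped == []


class TestIsoformAblation:
    def test_truth_on_isoform2_favors_top5(self):
        # k depends on the second isoform's 4-mer skew: only the top-5
        # feature set sees it
        def build(top5):
            def builder(seed):
                rng = np.random.default_rng(seed)
                n = 900
                schema = build_schema(n_isoforms=2, pad_to=None)
                X = pd.DataFrame(
                    rng.normal(size=(n, schema.dimension)),
                    columns=schema.names,
                    index=[f"v{i}" for i in range(n)],
                )
                hidden = X["iso2_rpph_skew"].to_numpy()
                k = 0.3 + 0.3 * hidden + 0.02 * rng.normal(size=n)
                if not top5:
                    # top-1 tracking: isoform-2 block unavailable (sentinel)
                    for c in X.columns:
                        if c.startswith(("iso2_", "iso3_", "iso4_", "iso5_")):
                            X[c] = -1.0
                outcomes = pd.DataFrame(
                    {f"ln_level_t{t}": -k * t + rng.normal(size=n) * 0.01 for t in (0, 2, 4, 8, 16)},
                    index=X.index,
                )
                outcomes["k"] = k
                groups = pd.Series(["g"] * n, index=X.index)
                return md.Dataset(X=X, outcomes=outcomes, groups=groups, schema=schema)

            return builder

        result = md.isoform_ablation(
            {"top5": build(True), "top1": build(False)}, seeds=range(2), hyperparams=FAST
        )
        assert result["difference"].median() > 0.2

    def test_identical_builders_zero_difference(self):
        def builder(seed):
            ds = synth_dataset(n=600, seed=seed)
            return ds

        result = md.isoform_ablation(
            {"a": builder, "b": builder}, seeds=[0, 1], hyperparams=FAST
        )
        assert (result["difference"] == 0).all()


class TestBundleIO:
    def test_save_load_round_trip(self, tmp_path):
        ds = synth_dataset(n=600, seed=11)
        ds.split = md.split_by_group(ds.groups, seed=11)
        bundle = md.train_bundle(ds, FAST, seed=11)
        bundle.save(tmp_path / "model")
        loaded = md.ModelBundle.load(tmp_path / "model")
        assert np.allclose(loaded.predict_k(ds.X), bundle.predict_k(ds.X))
        assert loaded.schema_hash == bundle.schema_hash
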