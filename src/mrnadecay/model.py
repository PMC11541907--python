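"""Staged boosted-tree models of mRNA levels and decay rate.

Five level models (one per timepoint, ln-level outcome) are trained on the
feature matrix; the decay model is trained on the features augmented with
the five *predicted* ln-levels. Splitting is stratified by design group with
largest-remainder rounding so every group contributes the same train
fraction.

The boosting backend sits behind a thin regressor interface so any
gradient-boosted-tree implementation can be swapped in; the default is
scikit-learn's histogram gradient booster with a fixed random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrnadecay._errors import ConfigurationError, SchemaError, ValidationError
from mrnadecay.features.schema import FeatureSchema

DEFAULT_HYPERPARAMS: dict = {
    "max_iter": 200,
    "learning_rate": 0.1,
    "max_leaf_nodes": 31,
    "min_samples_leaf": 20,
    "l2_regularization": 0.0,
}

LEVEL_OUTCOME_PREFIX = "ln_level_t"
DECAY_OUTCOME = "k"


class BoostedRegressor:
    """Thin deterministic wrapper around a gradient-boosted-tree backend.

    backend 'hist' (default) uses HistGradientBoostingRegressor with
    permutation importances; backend 'gbr' uses GradientBoostingRegressor
    with impurity importances (slower, used for importance-sensitive work at
    small n).
    """

    def __init__(self, hyperparams: Mapping | None = None, seed: int = 0, backend: str = "hist"):
        self.hyperparams = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
        self.seed = seed
        self.backend = backend
        self._model = None
        self._importance_cache: np.ndarray | None = None

    def _make(self):
        if self.backend == "hist":
            from sklearn.ensemble import HistGradientBoostingRegressor

            return HistGradientBoostingRegressor(
                max_iter=int(self.hyperparams["max_iter"]),
                learning_rate=float(self.hyperparams["learning_rate"]),
                max_leaf_nodes=int(self.hyperparams["max_leaf_nodes"]),
                min_samples_leaf=int(self.hyperparams["min_samples_leaf"]),
                l2_regularization=float(self.hyperparams["l2_regularization"]),
                random_state=self.seed,
            )
        if self.backend == "gbr":
            from sklearn.ensemble import GradientBoostingRegressor

            return GradientBoostingRegressor(
                n_estimators=min(int(self.hyperparams["max_iter"]), 200),
                learning_rate=float(self.hyperparams["learning_rate"]),
                max_depth=6,
                min_samples_leaf=int(self.hyperparams["min_samples_leaf"]),
                random_state=self.seed,
            )
        raise ConfigurationError(f"unknown backend {self.backend!r}")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoostedRegressor":
        from threadpoolctl import threadpool_limits

        if float(np.std(y)) == 0.0:
            raise ValidationError("outcome is constant; refusing to fit")
        self._model = self._make()
        # single-threaded fit: results are bit-identical across machines
        with threadpool_limits(limits=1):
            self._model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        self._importance_cache = None
        self._train_Xy = (np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        from threadpoolctl import threadpool_limits

        if self._model is None:
            raise ValidationError("regressor is not fitted")
        with threadpool_limits(limits=1):
            return self._model.predict(np.asarray(X, dtype=float))

    def importances(self, n_repeats: int = 3, max_samples: int = 2000) -> np.ndarray:
        """Per-feature importances (impurity- or permutation-based)."""
        if self._model is None:
            raise ValidationError("regressor is not fitted")
        if self._importance_cache is not None:
            return self._importance_cache
        if hasattr(self._model, "feature_importances_"):
            imp = np.asarray(self._model.feature_importances_)
        else:
            from sklearn.inspection import permutation_importance

            X, y = self._train_Xy
            if len(X) > max_samples:
                rng = np.random.default_rng(self.seed)
                idx = rng.choice(len(X), size=max_samples, replace=False)
                X, y = X[idx], y[idx]
            res = permutation_importance(
                self._model, X, y, n_repeats=n_repeats, random_state=self.seed
            )
            imp = np.maximum(res.importances_mean, 0.0)
        self._importance_cache = imp
        return imp


@dataclass
class Dataset:
    X: pd.DataFrame  # variants x schema columns
    outcomes: pd.DataFrame  # ln_level_t{t} columns + k
    groups: pd.Series  # design group label per variant
    schema: FeatureSchema
    split: pd.Series | None = None  # 'train' / 'test'

    def __post_init__(self):
        if not self.X.index.equals(self.outcomes.index):
            raise ValidationError("features and outcomes must share an index")
        if not self.X.index.equals(self.groups.index):
            raise ValidationError("features and groups must share an index")

    @property
    def timepoints(self) -> list[int]:
        return sorted(
            int(c[len(LEVEL_OUTCOME_PREFIX):])
            for c in self.outcomes.columns
            if c.startswith(LEVEL_OUTCOME_PREFIX)
        )

    def rows(self, part: str) -> pd.Index:
        if self.split is None:
            raise ValidationError("dataset has no split assignment")
        return self.split.index[self.split == part]


def split_by_group(
    groups: pd.Series, train_fraction: float = 0.8, seed: int = 0
) -> pd.Series:
    """Stratified train/test assignment with largest-remainder rounding.

    Within each design group, floor(f*n) variants go to train; leftover
    slots up to round(f*N_total) are given to groups with the largest
    fractional remainders (ties broken by group name). Shuffling within
    groups is seeded.
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sizes = groups.value_counts()
    floors = {g: int(math.floor(train_fraction * n)) for g, n in sizes.items()}
    total_target = int(round(train_fraction * len(groups)))
    leftover = total_target - sum(floors.values())
    remainders = sorted(
        ((train_fraction * n - floors[g], g) for g, n in sizes.items()),
        key=lambda t: (-t[0], t[1]),
    )
    for i in range(max(leftover, 0)):
        g = remainders[i % len(remainders)][1]
        if floors[g] < sizes[g]:
            floors[g] += 1
    assignment = pd.Series("test", index=groups.index, dtype=object)
    for g, n_train in floors.items():
        members = groups.index[groups == g].to_numpy()
        order = rng.permutation(len(members))
        assignment.loc[members[order[:n_train]]] = "train"
    return assignment


def _finite_or_raise(y: pd.Series, name: str) -> np.ndarray:
    arr = y.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError(f"outcome {name} contains non-finite values")
    return arr


def train_level_models(
    dataset: Dataset, hyperparams: Mapping | None = None, seed: int = 0, backend: str = "hist"
) -> dict[int, BoostedRegressor]:
    """One regressor per timepoint on ln-transformed levels (train split only)."""
    models: dict[int, BoostedRegressor] = {}
    train_idx = dataset.rows("train")
    X = dataset.X.loc[train_idx].to_numpy(dtype=float)
    for t in dataset.timepoints:
        col = f"{LEVEL_OUTCOME_PREFIX}{t}"
        y = _finite_or_raise(dataset.outcomes.loc[train_idx, col], col)
        models[t] = BoostedRegressor(hyperparams, seed=seed + t, backend=backend).fit(X, y)
    return models


def predict_levels(models: Mapping[int, BoostedRegressor], X: pd.DataFrame) -> pd.DataFrame:
    arr = X.to_numpy(dtype=float)
    return pd.DataFrame(
        {f"pred_{LEVEL_OUTCOME_PREFIX}{t}": m.predict(arr) for t, m in sorted(models.items())},
        index=X.index,
    )


def augment_features(X: pd.DataFrame, models: Mapping[int, BoostedRegressor]) -> pd.DataFrame:
    """Features + predicted ln-levels (predictions used for both splits)."""
    return pd.concat([X, predict_levels(models, X)], axis=1)


def train_decay_model(
    dataset: Dataset,
    level_models: Mapping[int, BoostedRegressor],
    hyperparams: Mapping | None = None,
    seed: int = 0,
    backend: str = "hist",
) -> BoostedRegressor:
    """Decay-rate regressor on the augmented feature set (train split only)."""
    if len(level_models) != len(dataset.timepoints):
        raise SchemaError("level models do not cover the dataset timepoints")
    aug = augment_features(dataset.X, level_models)
    train_idx = dataset.rows("train")
    y = _finite_or_raise(dataset.outcomes.loc[train_idx, DECAY_OUTCOME], DECAY_OUTCOME)
    return BoostedRegressor(hyperparams, seed=seed, backend=backend).fit(
        aug.loc[train_idx].to_numpy(dtype=float), y
    )


@dataclass
class ModelBundle:
    level_models: dict[int, BoostedRegressor]
    decay_model: BoostedRegressor
    hyperparams: dict
    schema_hash: str
    split_seed: int
    metrics: dict = field(default_factory=dict)

    def predict_ln_levels(self, X: pd.DataFrame) -> pd.DataFrame:
        return predict_levels(self.level_models, X)

    def predict_k(self, X: pd.DataFrame) -> np.ndarray:
        aug = augment_features(X, self.level_models)
        return self.decay_model.predict(aug.to_numpy(dtype=float))

    def save(self, outdir: str | Path) -> None:
        import joblib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t, m in self.level_models.items():
            joblib.dump(m, outdir / f"level_t{t}.joblib")
        joblib.dump(self.decay_model, outdir / "decay.joblib")
        (outdir / "bundle.json").write_text(
            json.dumps(
                {
                    "hyperparams": self.hyperparams,
                    "schema_hash": self.schema_hash,
                    "split_seed": self.split_seed,
                    "metrics": self.metrics,
                    "timepoints": sorted(self.level_models),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, outdir: str | Path) -> "ModelBundle":
        import joblib

        outdir = Path(outdir)
        meta = json.loads((outdir / "bundle.json").read_text())
        level_models = {
            t: joblib.load(outdir / f"level_t{t}.joblib") for t in meta["timepoints"]
        }
        return cls(
            level_models=level_models,
            decay_model=joblib.load(outdir / "decay.joblib"),
            hyperparams=meta["hyperparams"],
            schema_hash=meta["schema_hash"],
            split_seed=meta["split_seed"],
            metrics=meta["metrics"],
        )


def train_bundle(
    dataset: Dataset,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    backend: str = "hist",
) -> ModelBundle:
    """Train the five level models plus the decay model; evaluate both splits."""
    if dataset.split is None:
        dataset.split = split_by_group(dataset.groups, seed=seed)
    level_models = train_level_models(dataset, hyperparams, seed=seed, backend=backend)
    decay_model = train_decay_model(dataset, level_models, hyperparams, seed=seed, backend=backend)
    bundle = ModelBundle(
        level_models=level_models,
        decay_model=decay_model,
        hyperparams=dict(DEFAULT_HYPERPARAMS, **(hyperparams or {})),
        schema_hash=dataset.schema.version_hash,
        split_seed=seed,
    )
    bundle.metrics = evaluate(bundle, dataset)
    return bundle


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(stats.pearsonr(pred, obs).statistic ** 2)


def evaluate(bundle: ModelBundle, dataset: Dataset) -> dict:
    """Squared-Pearson accuracy per target and median relative error of k."""
    if dataset.split is None:
        raise ValidationError("dataset has no split assignment")
    if len(dataset.rows("test")) == 0:
        raise ValidationError("empty test split")
    out: dict = {}
    pred_levels = bundle.predict_ln_levels(dataset.X)
    pred_k = pd.Series(bundle.predict_k(dataset.X), index=dataset.X.index)
    for part in ("train", "test"):
        idx = dataset.rows(part)
        metrics = {}
        for t in dataset.timepoints:
            obs = dataset.outcomes.loc[idx, f"{LEVEL_OUTCOME_PREFIX}{t}"].to_numpy(float)
            metrics[f"r2_level_t{t}"] = _r2(
                pred_levels.loc[idx, f"pred_{LEVEL_OUTCOME_PREFIX}{t}"].to_numpy(), obs
            )
        obs_k = dataset.outcomes.loc[idx, DECAY_OUTCOME].to_numpy(float)
        metrics["r2_decay"] = _r2(pred_k.loc[idx].to_numpy(), obs_k)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(pred_k.loc[idx].to_numpy() - obs_k) / np.abs(obs_k)
        metrics["median_relative_error_k"] = float(np.nanmedian(rel))
        out[part] = metrics
    return out


def feature_importance_prune(
    bundle: ModelBundle,
    dataset: Dataset,
    threshold: float,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    backend: str = "hist",
) -> tuple[list[str], list[str], ModelBundle]:
    """Drop features unimportant in all six models, refit on the remainder.

    Returns (kept names, dropped names, refit bundle). Importances for the
    decay model cover the augmented columns; only the schema columns are
    candidates for dropping.
    """
    n_feat = dataset.X.shape[1]
    imps = [m.importances() for m in bundle.level_models.values()]
    imps.append(bundle.decay_model.importances()[:n_feat])
    stacked = np.vstack(imps)
    droppable = (stacked <= threshold).all(axis=0)
    kept = [c for c, drop in zip(dataset.X.columns, droppable) if not drop]
    dropped = [c for c, drop in zip(dataset.X.columns, droppable) if drop]
    if not kept:
        raise ValidationError("importance threshold would drop every feature")
    reduced = Dataset(
        X=dataset.X[kept],
        outcomes=dataset.outcomes,
        groups=dataset.groups,
        schema=dataset.schema,
        split=dataset.split,
    )
    refit = train_bundle(reduced, hyperparams, seed=seed, backend=backend)
    return kept, dropped, refit


def isoform_ablation(
    dataset_builders: Mapping[str, "callable"],
    seeds: Sequence[int],
    hyperparams: Mapping | None = None,
    backend: str = "hist",
    target: str = "decay",
) -> pd.DataFrame:
    """Paired accuracy comparison between feature-set variants (e.g. top-1
    vs top-5 isoform tracking).

    ``dataset_builders`` maps setting name -> callable(seed) -> Dataset.
    Returns per-seed test R2 per setting plus the paired difference.
    """
    rows = []
    for seed in seeds:
        row = {"seed": seed}
        for name, builder in dataset_builders.items():
            ds = builder(seed)
            if ds.split is None:
                ds.split = split_by_group(ds.groups, seed=seed)
            bundle = train_bundle(ds, hyperparams, seed=seed, backend=backend)
            key = "r2_decay" if target == "decay" else "r2_level_t0"
            row[name] = bundle.metrics["test"][key]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("seed")
    names = list(dataset_builders)
    if len(names) == 2:
        df["difference"] = df[names[0]] - df[names[1]]
    return df
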