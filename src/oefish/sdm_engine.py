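"""Boosted regression tree (BRT) occurrence models.

One presence/absence model is fitted per species by stagewise gradient
boosting on Bernoulli deviance, with the regime used throughout the pipeline:
tree complexity (interaction depth) 5, per-tree row subsampling (bag
fraction) 0.15, 10-fold cross-validation to choose the tree count, and a
learning rate set so that at least 1,000 trees are assembled — starting at
0.01 and halving (bounded retries) until the cross-validation-optimal tree
count reaches the floor.  Model skill is summarised by cross-validated AUC
computed from pooled out-of-fold predictions, and each covariate's relative
influence is its percentage share of the ensemble's total loss reduction.

LightGBM provides the tree backend; the surrounding protocol (fold
construction, deviance curves, tree-count selection, learning-rate halving,
influence normalisation) is implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from . import _schema as S
from .errors import (
    ConvergenceError,
    DegenerateTargetError,
    SchemaError,
    UnfittableSpeciesError,
)

__all__ = [
    "BRTConfig",
    "SpeciesModelBundle",
    "PredictionResult",
    "fit_species_model",
    "predict_probability",
    "cv_auc",
]


@dataclass(frozen=True)
class BRTConfig:
    """Hyperparameter regime for every boosted-tree fit in the pipeline.

    ``tree_complexity`` is the per-tree interaction depth, ``bag_fraction``
    the per-tree row subsampling rate, and ``min_trees`` the floor the
    learning-rate halving protocol must reach.  ``max_trees`` caps the tree
    count explored per cross-validation round (default 2.5x ``min_trees``);
    if the deviance curve is still falling at the cap, the cap is accepted as
    the optimal count (it already satisfies the floor).
    """

    tree_complexity: int = 5
    min_trees: int = 1000
    initial_learning_rate: float = 0.01
    bag_fraction: float = 0.15
    n_folds: int = 10
    seed: int = 0
    max_trees: int | None = None
    max_halvings: int = 6
    min_samples_leaf: int = 10

    def __post_init__(self) -> None:
        if self.tree_complexity < 1 or self.min_trees < 1 or self.n_folds < 2:
            raise ValueError("tree_complexity, min_trees >= 1 and n_folds >= 2 required")
        if not (0 < self.initial_learning_rate <= 1 and 0 < self.bag_fraction <= 1):
            raise ValueError("learning rate and bag fraction must lie in (0, 1]")

    @property
    def tree_cap(self) -> int:
        return self.max_trees if self.max_trees is not None else int(2.5 * self.min_trees)

    def backend_params(self, objective: str, learning_rate: float) -> dict:
        return {
            "objective": objective,
            "learning_rate": learning_rate,
            # Tree complexity k = k splits per tree (k+1 terminal nodes), the
            # convention of the ecological BRT literature; depth is capped at
            # k as well so a tree can be a k-way interaction at most.
            "max_depth": self.tree_complexity,
            "num_leaves": self.tree_complexity + 1,
            "bagging_fraction": self.bag_fraction,
            "bagging_freq": 1,
            "min_child_samples": self.min_samples_leaf,
            "min_split_gain": 0.0,
            "seed": self.seed % (2**31),
            "bagging_seed": (self.seed + 1) % (2**31),
            "feature_fraction_seed": (self.seed + 2) % (2**31),
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
            "verbosity": -1,
        }


@dataclass
class SpeciesModelBundle:
    """A fitted per-species model with its evaluation metadata.

    ``threshold`` and ``kappa_at_threshold`` are filled in by the threshold
    selection stage; ``allowed_classes`` restricts prediction to the river
    classes the training data covered (None = no restriction).
    """

    species: str
    ensemble: lgb.Booster
    feature_names: list[str]
    n_trees: int
    learning_rate: float
    cv_auc: float
    cv_auc_folds: list[float]
    relative_influence: dict[str, float]
    prevalence: float
    native: bool = True
    allowed_classes: frozenset | None = None
    threshold: float | None = None
    kappa_at_threshold: float | None = None
    fit_log: list[dict] = field(default_factory=list)

    def with_threshold(self, threshold: float, kappa: float) -> "SpeciesModelBundle":
        out = replace(self)
        out.threshold = threshold
        out.kappa_at_threshold = kappa
        return out

    # -- serialization: JSON metadata + backend-native model text ----------
    def save(self, directory) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "species": self.species,
            "feature_names": self.feature_names,
            "n_trees": self.n_trees,
            "learning_rate": self.learning_rate,
            "cv_auc": self.cv_auc,
            "cv_auc_folds": self.cv_auc_folds,
            "relative_influence": self.relative_influence,
            "prevalence": self.prevalence,
            "native": self.native,
            "allowed_classes": sorted(self.allowed_classes) if self.allowed_classes else None,
            "threshold": self.threshold,
            "kappa_at_threshold": self.kappa_at_threshold,
            "fit_log": self.fit_log,
        }
        (d / f"{self.species}.json").write_text(json.dumps(meta, indent=1))
        self.ensemble.save_model(str(d / f"{self.species}.lgbm.txt"))
        return d

    @classmethod
    def load(cls, directory, species: str) -> "SpeciesModelBundle":
        d = Path(directory)
        meta = json.loads((d / f"{species}.json").read_text())
        booster = lgb.Booster(model_file=str(d / f"{species}.lgbm.txt"))
        allowed = meta["allowed_classes"]
        return cls(
            species=meta["species"],
            ensemble=booster,
            feature_names=meta["feature_names"],
            n_trees=meta["n_trees"],
            learning_rate=meta["learning_rate"],
            cv_auc=meta["cv_auc"],
            cv_auc_folds=meta["cv_auc_folds"],
            relative_influence=meta["relative_influence"],
            prevalence=meta["prevalence"],
            native=meta["native"],
            allowed_classes=frozenset(allowed) if allowed is not None else None,
            threshold=meta["threshold"],
            kappa_at_threshold=meta["kappa_at_threshold"],
            fit_log=meta["fit_log"],
        )


@dataclass
class PredictionResult:
    """Per-reach probabilities; masked reaches carry NaN plus a reason."""

    probabilities: np.ndarray
    masked: dict  # reach_id -> reason code


def cv_auc(labels, scores) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The probability that a randomly chosen presence outscores a randomly
    chosen absence, counting ties as half — computed from average ranks, so it
    is invariant to strictly increasing transforms of the scores.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _deviance_curves(X, y, cfg: BRTConfig, learning_rate: float, objective: str):
    """Per-fold metric-vs-tree-count curves plus held-out fold indices/preds.

    Returns (summed_curve, folds) where folds is a list of
    (test_index, booster) so out-of-fold predictions can be extracted at any
    tree count without refitting.
    """
    metric = "binary_logloss" if objective == "binary" else "l2"
    params = dict(cfg.backend_params(objective, learning_rate), metric=metric)
    if objective == "binary":
        splitter = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed % (2**32))
        splits = splitter.split(X, y)
    else:
        splitter = KFold(cfg.n_folds, shuffle=True, random_state=cfg.seed % (2**32))
        splits = splitter.split(X)

    curves, folds = [], []
    for train_idx, test_idx in splits:
        d_train = lgb.Dataset(X[train_idx], label=y[train_idx])
        d_test = lgb.Dataset(X[test_idx], label=y[test_idx], reference=d_train)
        history: dict = {}
        booster = lgb.train(
            params,
            d_train,
            num_boost_round=cfg.tree_cap,
            valid_sets=[d_test],
            valid_names=["heldout"],
            callbacks=[lgb.record_evaluation(history)],
        )
        curves.append(np.asarray(history["heldout"][metric]))
        folds.append((test_idx, booster))
    n = min(len(c) for c in curves)
    return np.sum([c[:n] for c in curves], axis=0), folds


def _fit_boosted(X, y, cfg: BRTConfig, objective: str):
    """The shared fitting protocol: CV tree-count selection + rate halving.

    Returns (booster, n_trees, learning_rate, oof_predictions, fold_tests,
    fit_log).  ``oof_predictions`` are pooled held-out predictions at the
    selected tree count; ``fold_tests`` the matching fold index arrays.
    """
    learning_rate = cfg.initial_learning_rate
    fit_log = []
    for _attempt in range(cfg.max_halvings + 1):
        curve, folds = _deviance_curves(X, y, cfg, learning_rate, objective)
        n_opt = int(np.argmin(curve)) + 1
        at_cap = n_opt >= len(curve)
        fit_log.append(
            {"learning_rate": learning_rate, "cv_optimal_trees": n_opt, "at_cap": bool(at_cap)}
        )
        if n_opt >= cfg.min_trees:
            break
        learning_rate /= 2.0
    else:
        raise ConvergenceError(
            f"cross-validation-optimal tree count stayed below {cfg.min_trees} "
            f"after {cfg.max_halvings} halvings (final learning rate {learning_rate:g})"
        )

    oof = np.empty(len(y), dtype=float)
    for test_idx, booster in folds:
        oof[test_idx] = booster.predict(X[test_idx], num_iteration=n_opt)

    params = cfg.backend_params(objective, learning_rate)
    final = lgb.train(params, lgb.Dataset(X, label=y), num_boost_round=n_opt)
    return final, n_opt, learning_rate, oof, [t for t, _ in folds], fit_log


def _relative_influence(booster: lgb.Booster, feature_names: list[str]) -> dict[str, float]:
    """Each covariate's share of total loss reduction across splits, as %."""
    gain = booster.feature_importance(importance_type="gain")
    total = gain.sum()
    if total <= 0:
        # No splits at all: spread uniformly so the 100% contract holds.
        gain = np.ones_like(gain, dtype=float)
        total = gain.sum()
    return {name: float(100.0 * g / total) for name, g in zip(feature_names, gain)}


def fit_species_model(
    occurrence,
    covariates: pd.DataFrame,
    cfg: BRTConfig,
    species: str = "species",
    native: bool = True,
    allowed_classes=None,
) -> SpeciesModelBundle:
    """Fit one species' presence/absence BRT.

    ``occurrence`` is the per-site 0/1 outcome aligned with ``covariates``
    (one row per training site; non-numeric columns such as identifiers or
    the river-class label are ignored).  Missing covariate values are
    permitted — the tree backend routes them natively.
    """
    y = np.asarray(occurrence).astype(int)
    if len(y) != len(covariates):
        raise ValueError("occurrence and covariates are misaligned")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise UnfittableSpeciesError(
            f"{species}: need >= 2 presences and >= 2 absences (got {n_pos}/{n_neg})"
        )
    X_df = covariates.select_dtypes(include=[np.number])
    feature_names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)

    booster, n_trees, lr, oof, fold_tests, fit_log = _fit_boosted(X, y, cfg, "binary")
    pooled_auc = cv_auc(y, oof)
    fold_aucs = []
    for test_idx in fold_tests:
        if 0 < y[test_idx].sum() < len(test_idx):
            fold_aucs.append(cv_auc(y[test_idx], oof[test_idx]))
    return SpeciesModelBundle(
        species=species,
        ensemble=booster,
        feature_names=feature_names,
        n_trees=n_trees,
        learning_rate=lr,
        cv_auc=pooled_auc,
        cv_auc_folds=fold_aucs,
        relative_influence=_relative_influence(booster, feature_names),
        prevalence=n_pos / len(y),
        native=native,
        allowed_classes=frozenset(allowed_classes) if allowed_classes is not None else None,
        fit_log=fit_log,
    )


def predict_probability(bundle: SpeciesModelBundle, reaches: pd.DataFrame) -> PredictionResult:
    """Capture probability for every reach in the table.

    Reaches whose river class is outside the bundle's retained classes are
    masked (NaN probability plus a reason code) rather than extrapolated.
    """
    missing = [c for c in bundle.feature_names if c not in reaches.columns]
    if missing:
        raise SchemaError(f"reach table lacks model covariates: {missing}")
    X = reaches[bundle.feature_names].to_numpy(dtype=float)
    probs = bundle.ensemble.predict(X, num_iteration=bundle.n_trees)
    probs = np.clip(np.asarray(probs, dtype=float), 0.0, 1.0)

    masked: dict = {}
    if bundle.allowed_classes is not None and S.RIVER_CLASS in reaches.columns:
        outside = ~reaches[S.RIVER_CLASS].isin(bundle.allowed_classes).to_numpy()
        probs[outside] = np.nan
        for reach in reaches.index[outside]:
            masked[reach] = "out-of-class"
    return PredictionResult(probabilities=probs, masked=masked)
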