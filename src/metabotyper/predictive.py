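"""Metabolite-based biomass prediction: cross-validated random-forest
regression with genotype indicators, out-of-fold permutation importance,
and the feature-group ablation RMSE-increase statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .seeds import spawn_seed


@dataclass(frozen=True)
class PredictorConfig:
    n_estimators: int = 500
    # number of features tried per split: sqrt(p), p/3, p/10
    max_features_grid: tuple = ("sqrt", 0.3333, 0.1)
    importance_repeats: int = 5
    importance_kind: str = "permutation"  # or "impurity"


@dataclass
class PredictorResult:
    cv_rmse: float
    fold_rmse: list[float]
    importances: pd.Series
    best_params: dict
    fold_assignments: np.ndarray
    seed: int


@dataclass
class AblationResult:
    baseline_rmse: float
    ablated_rmse: float
    pct_increase: float
    group: str = ""


def _design_matrix(features: pd.DataFrame, genotypes) -> pd.DataFrame:
    """Features sorted by name plus genotype one-hots in appearance order.

    The canonical column ordering makes the fitted model invariant to the
    caller's column order and to renaming of genotype levels.
    """
    feats = features[sorted(features.columns)]
    geno = pd.Series(np.asarray(genotypes), index=features.index, name="genotype")
    levels = list(dict.fromkeys(geno))
    onehot = pd.DataFrame(
        {f"__geno_{i}": (geno == lvl).astype(float) for i, lvl in enumerate(levels)},
        index=features.index,
    )
    return pd.concat([feats, onehot], axis=1)


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def fit_biomass_predictor(
    features: pd.DataFrame,
    genotypes,
    target,
    n_folds: int = 5,
    seed: int = 0,
    config: PredictorConfig = PredictorConfig(),
) -> PredictorResult:
    """Tune and evaluate a random-forest biomass model by k-fold CV.

    The grid over ``max_features`` is scored by CV RMSE; the reported RMSE
    is the fold average for the winning setting. Importances are
    permutation importances computed on each held-out fold and averaged
    (or impurity importances from per-fold fits if configured).
    """
    if features.isna().any().any():
        raise ValueError("features contain missing values; impute upstream")
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError("n_samples must be >= n_folds")
    x = _design_matrix(features, genotypes)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=spawn_seed(seed, "folds"))
    folds = list(kf.split(x))
    fold_assign = np.empty(n, dtype=int)
    for fi, (_, test) in enumerate(folds):
        fold_assign[test] = fi

    def cv_eval(max_features):
        errs = []
        models = []
        for fi, (train, test) in enumerate(folds):
            model = RandomForestRegressor(
                n_estimators=config.n_estimators,
                max_features=max_features,
                random_state=spawn_seed(seed, f"rf_{max_features}_{fi}"),
                n_jobs=1,
            )
            model.fit(x.iloc[train], y[train])
            errs.append(_rmse(y[test], model.predict(x.iloc[test])))
            models.append(model)
        return errs, models

    best = None
    for mf in config.max_features_grid:
        errs, models = cv_eval(mf)
        score = float(np.mean(errs))
        if best is None or score < best[0]:
            best = (score, mf, errs, models)
    cv_rmse, best_mf, fold_errs, fold_models = best

    imp_acc = np.zeros(x.shape[1])
    for fi, (train, test) in enumerate(folds):
        model = fold_models[fi]
        if config.importance_kind == "impurity":
            imp_acc += model.feature_importances_
        else:
            pi = permutation_importance(
                model,
                x.iloc[test],
                y[test],
                n_repeats=config.importance_repeats,
                random_state=spawn_seed(seed, f"perm_imp_{fi}"),
                scoring="neg_root_mean_squared_error",
                n_jobs=1,
            )
            imp_acc += pi.importances_mean
    importances = pd.Series(imp_acc / len(folds), index=x.columns)

    return PredictorResult(
        cv_rmse=cv_rmse,
        fold_rmse=fold_errs,
        importances=importances,
        best_params={"max_features": best_mf, "n_estimators": config.n_estimators},
        fold_assignments=fold_assign,
        seed=seed,
    )


def ablation_rmse_delta(
    features: pd.DataFrame,
    genotypes,
    group_mask,
    target,
    n_folds: int = 5,
    seed: int = 0,
    config: PredictorConfig = PredictorConfig(),
    group: str = "",
) -> AblationResult:
    """Percent RMSE increase when the masked feature group is removed.

    ``group_mask`` is boolean over ``features.columns`` marking the group
    to drop; folds and seeds are shared between the baseline and ablated
    fits so the comparison isolates the feature group.
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.shape[0] != features.shape[1]:
        raise ValueError("group_mask length must equal the number of features")
    if mask.all():
        raise ValueError("group_mask must leave at least one feature")
    baseline = fit_biomass_predictor(
        features, genotypes, target, n_folds=n_folds, seed=seed, config=config
    )
    ablated_features = features.loc[:, ~mask]
    ablated = fit_biomass_predictor(
        ablated_features, genotypes, target, n_folds=n_folds, seed=seed, config=config
    )
    pct = 100.0 * (ablated.cv_rmse - baseline.cv_rmse) / baseline.cv_rmse
    return AblationResult(baseline.cv_rmse, ablated.cv_rmse, float(pct), group=group)
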