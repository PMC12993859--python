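"""Random-forest state estimation with tank-permutation cross-validation.

Eight response variables (RVs) — fresh weight, dry mass, and tissue
N/P/K/Ca/Mg/S concentrations — are regressed from vegetation-index
features.  Validation respects the experiment's grouping: a manual 27-fold
scheme enumerates every per-treatment choice of 2-of-3 test tanks (3^3
permutations), keeping the remaining tank of each treatment for training
(80%) and validation (20%), so no tank (hence no plant) ever appears on
both sides of a fold.  Images without destructive ground truth receive
pseudolabels: the mean RV of their tank's destructive samples on the
nearest sampling day (earlier day wins ties).  Feature selection runs in
three stages per fold — recursive feature elimination, low-importance
removal, correlation pruning — and survivors are aggregated across folds
by (frequency, median importance) into a fixed top-20 set.

The estimator follows the fit/results convention:
:class:`TankPermutationForest` wraps the data and configuration;
``cross_validate`` returns :class:`StateEstimationResults` with per-fold
R2/RMSE, out-of-fold predictions and ``summary()``; ``fit_full`` refits on
all labeled+pseudolabeled data for trajectory estimation (the RF-AE tier).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score

from .synthetic import RESPONSE_VARIABLES, RV_COLUMN, Trajectories

__all__ = [
    "FoldSpec",
    "enumerate_folds",
    "assign_pseudolabels",
    "RFConfig",
    "FeatureSelectionConfig",
    "select_features",
    "TankPermutationForest",
    "StateEstimationResults",
    "estimate_trajectories",
]

META_COLUMNS = ("plant_id", "tank_id", "treatment", "DAT")

# Final per-RV hyperparameters from the tuning study; the shared settings
# (min_samples_split=2, min_samples_leaf=1, max_features='sqrt',
# bootstrap=False, criterion='squared_error') are fixed below.
_FINAL_N_ESTIMATORS = {"N": 900, "P": 1300, "K": 900, "Ca": 900, "Mg": 900,
                       "S": 1300, "FW": 900, "DM": 900}
_FINAL_MAX_DEPTH = {"N": 14, "P": 12, "K": 14, "Ca": 14, "Mg": 14,
                    "S": 12, "FW": 14, "DM": 14}
SEARCH_GRID = {
    "n_estimators": list(range(500, 1700, 100)),
    "max_depth": list(range(5, 17)),
    "min_samples_split": [2, 3],
    "min_samples_leaf": [1, 2, 3],
    "max_features": ["sqrt", "log2"],
    "bootstrap": [True, False],
}


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters; defaults are the tuned per-RV settings.

    ``n_estimators``/``max_depth`` of None fall back to the per-RV tuned
    values; set them to integers for desk-scale runs.
    """

    n_estimators: int | None = None
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features: str = "sqrt"
    bootstrap: bool = False
    criterion: str = "squared_error"
    seed: int = 50
    validation_fraction: float = 0.2
    tune: bool = False  # grid search over SEARCH_GRID on the validation split

    def estimator(self, rv: str) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators or _FINAL_N_ESTIMATORS[rv],
            max_depth=self.max_depth or _FINAL_MAX_DEPTH[rv],
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            bootstrap=self.bootstrap,
            criterion=self.criterion,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass(frozen=True)
class FoldSpec:
    """One tank permutation: per-treatment test pair and train/val tank."""

    fold_id: int
    test_tanks: tuple[str, ...]
    train_tanks: tuple[str, ...]


def enumerate_folds(tank_roster: pd.DataFrame) -> list[FoldSpec]:
    """All 27 per-treatment choices of 2-of-3 test tanks.

    ``tank_roster`` needs columns ``tank_id`` and ``treatment`` with exactly
    three treatments of three tanks each.  Each tank serves as a test tank
    in 18 of the 27 folds, and each per-treatment test pair occurs in 9.
    """
    groups = {
        t: sorted(g["tank_id"]) for t, g in tank_roster.groupby("treatment", sort=True)
    }
    if len(groups) != 3 or any(len(tanks) != 3 for tanks in groups.values()):
        raise ValueError("fold enumeration requires exactly 3 treatments x 3 tanks")
    per_treatment_pairs = {
        t: list(itertools.combinations(tanks, 2)) for t, tanks in groups.items()
    }
    treatments = sorted(groups)
    folds = []
    for fold_id, combo in enumerate(
        itertools.product(*(per_treatment_pairs[t] for t in treatments)), start=1
    ):
        test = tuple(tank for pair in combo for tank in pair)
        train = tuple(
            tank for t, pair in zip(treatments, combo)
            for tank in groups[t] if tank not in pair
        )
        folds.append(FoldSpec(fold_id, test, train))
    return folds


def assign_pseudolabels(
    records: pd.DataFrame, ground_truth: pd.DataFrame,
    rvs: list[str] | None = None,
) -> pd.DataFrame:
    """Label every record with its tank's destructive-sample means.

    A record on a sampling day gets the mean RV of its tank's destructive
    samples from that day; on other days the nearest sampling day's mean is
    used (the earlier day wins ties).  Records whose own row carries ground
    truth keep it untouched upstream — this function only attaches the
    tank-mean label columns (``label_{rv}``) plus ``is_sampling_day``.
    Tanks with no ground truth are excluded with a warning.
    """
    rvs = rvs or RESPONSE_VARIABLES
    cols = [RV_COLUMN[rv] for rv in rvs]
    tank_means = ground_truth.groupby(["tank_id", "DAT"], as_index=False)[cols].mean()

    out = []
    for tank_id, grp in records.groupby("tank_id", sort=True):
        tm = tank_means[tank_means["tank_id"] == tank_id]
        if tm.empty:
            warnings.warn(f"tank {tank_id} has no ground truth; records excluded")
            continue
        days = tm["DAT"].to_numpy()
        by_day = tm.set_index("DAT")
        labeled = grp.copy()
        # nearest sampling day; on a distance tie, the earlier day wins
        dist = np.abs(labeled["DAT"].to_numpy()[:, None] - days[None, :])
        nearest = days[np.argmin(dist, axis=1)]  # argmin takes the first (earlier) min
        labeled["label_day"] = nearest
        labeled["is_sampling_day"] = labeled["DAT"].isin(days)
        for rv, col in zip(rvs, cols):
            labeled[f"label_{rv}"] = by_day.loc[nearest, col].to_numpy()
        out.append(labeled)
    if not out:
        raise ValueError("no tank has ground truth")
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class FeatureSelectionConfig:
    """Three-stage per-fold selection; defaults are package choices.

    Stage 1 (RFE) recursively drops the lowest-importance 10% of features
    until ``rfe_floor`` remain; stage 2 drops features below the
    ``importance_quantile`` of the remaining importances; stage 3 greedily
    drops the lower-ranked member of any pair with |r| > ``corr_cutoff``.
    """

    rfe_floor: int = 30
    rfe_step_frac: float = 0.1
    importance_quantile: float = 0.10
    corr_cutoff: float = 0.95
    top_k: int = 20
    n_estimators: int = 100  # selection forests are smaller than final fits


def _prune_correlated(X: pd.DataFrame, ranked: list[str], cutoff: float) -> list[str]:
    """Keep higher-ranked features; drop any later one with |r| > cutoff."""
    kept: list[str] = []
    corr = X[ranked].corr().abs()
    for name in ranked:
        if all(corr.loc[name, k] <= cutoff for k in kept):
            kept.append(name)
    return kept


def select_features(
    labeled: pd.DataFrame,
    rv: str,
    feature_columns: list[str],
    folds: list[FoldSpec],
    config: FeatureSelectionConfig | None = None,
    seed: int = 50,
) -> list[str]:
    """Aggregate per-fold three-stage survivors into a fixed top-k feature set.

    Per-fold survivors are counted across folds and ranked by (frequency,
    median importance); exactly ``top_k`` names are returned (all survivors,
    with a warning, when fewer remain).
    """
    config = config or FeatureSelectionConfig()
    survivors_per_fold: list[dict[str, float]] = []
    for fold in folds:
        pool = labeled[labeled["tank_id"].isin(fold.train_tanks)]
        X, y = pool[feature_columns], pool[f"label_{rv}"]
        current = list(feature_columns)

        def importances(cols):
            est = RandomForestRegressor(
                n_estimators=config.n_estimators, random_state=seed, n_jobs=1
            ).fit(X[cols], y)
            return pd.Series(est.feature_importances_, index=cols)

        # stage 1: recursive elimination to the floor
        imp = importances(current)
        while len(current) > config.rfe_floor:
            n_drop = max(1, int(len(current) * config.rfe_step_frac))
            n_drop = min(n_drop, len(current) - config.rfe_floor)
            current = list(imp.sort_values(ascending=False).index[: len(current) - n_drop])
            imp = importances(current)
        # stage 2: drop the low-importance tail
        floor = imp.quantile(config.importance_quantile)
        current = list(imp[imp >= floor].index)
        imp = imp[current]
        # stage 3: correlation pruning, higher-ranked member wins
        ranked = list(imp.sort_values(ascending=False).index)
        current = _prune_correlated(X, ranked, config.corr_cutoff)
        survivors_per_fold.append(imp[current].to_dict())

    freq: dict[str, int] = {}
    imps: dict[str, list[float]] = {}
    for surv in survivors_per_fold:
        for name, im in surv.items():
            freq[name] = freq.get(name, 0) + 1
            imps.setdefault(name, []).append(im)
    ranked = sorted(
        freq, key=lambda n: (freq[n], float(np.median(imps[n])), n), reverse=True
    )
    # the final-training correlation pruning, applied to the aggregate ranking
    ranked = _prune_correlated(labeled, ranked, config.corr_cutoff)
    if len(ranked) < config.top_k:
        warnings.warn(
            f"only {len(ranked)} features survived selection (requested {config.top_k})"
        )
        return ranked
    return ranked[: config.top_k]


class TankPermutationForest:
    """Random-forest state estimator over a VI feature table.

    Parameters
    ----------
    features : DataFrame
        Per-(plant, DAT) feature table with the ``META_COLUMNS`` plus
        feature columns (the single-designated-image data set).
    ground_truth : DataFrame
        Destructive-sample table (``STATE_COLUMNS`` layout).
    config : RFConfig
    feature_columns : list of str, optional
        Subset to use (e.g. a selected top-20 set); defaults to all
        non-meta columns.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        ground_truth: pd.DataFrame,
        config: RFConfig | None = None,
        feature_columns: list[str] | None = None,
    ):
        self.config = config or RFConfig()
        self.feature_columns = feature_columns or [
            c for c in features.columns if c not in META_COLUMNS
        ]
        self.ground_truth = ground_truth
        self.labeled = assign_pseudolabels(features, ground_truth)
        roster = features[["tank_id", "treatment"]].drop_duplicates()
        self.folds = enumerate_folds(roster)

    # -- fold plumbing ------------------------------------------------------

    def fold_split(self, fold: FoldSpec, rv: str):
        """(train+val records, test records) for one fold; leakage-free.

        Test records are restricted to genuinely labeled rows: plants
        destructively sampled on that day, labeled with their own tank-day
        mean (the measured value's sampling-day aggregate).
        """
        trainval = self.labeled[self.labeled["tank_id"].isin(fold.train_tanks)]
        gt_keys = set(zip(self.ground_truth["plant_id"], self.ground_truth["DAT"]))
        in_test_tanks = self.labeled["tank_id"].isin(fold.test_tanks)
        is_gt = [
            (p, d) in gt_keys
            for p, d in zip(self.labeled["plant_id"], self.labeled["DAT"])
        ]
        test = self.labeled[in_test_tanks & np.asarray(is_gt)]
        return trainval, test

    def _train_val(self, trainval: pd.DataFrame, fold_id: int):
        rng = np.random.default_rng(self.config.seed + fold_id)
        idx = rng.permutation(len(trainval))
        n_val = int(round(self.config.validation_fraction * len(trainval)))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        return trainval.iloc[train_idx], trainval.iloc[val_idx]

    # -- estimation ---------------------------------------------------------

    def cross_validate(
        self,
        rvs: list[str] | None = None,
        folds: list[FoldSpec] | None = None,
    ) -> "StateEstimationResults":
        """Per-fold fit and labeled-test evaluation for each response variable."""
        rvs = rvs or RESPONSE_VARIABLES
        folds = folds or self.folds
        metric_rows, oof_rows = [], []
        for rv in rvs:
            for fold in folds:
                trainval, test = self.fold_split(fold, rv)
                if test.empty:
                    raise ValueError(f"fold {fold.fold_id} has no labeled test records")
                train, val = self._train_val(trainval, fold.fold_id)
                est = self._fit_one(rv, train, val)
                # final per-fold model is refit on train+val with the chosen settings
                est.fit(trainval[self.feature_columns], trainval[f"label_{rv}"])
                pred = est.predict(test[self.feature_columns])
                truth = test[f"label_{rv}"].to_numpy()
                metric_rows.append({
                    "rv": rv, "fold": fold.fold_id,
                    "r2": r2_score(truth, pred),
                    "rmse": float(np.sqrt(mean_squared_error(truth, pred))),
                    "n_train": len(train), "n_val": len(val), "n_test": len(test),
                })
                for pid, dat, p, t in zip(test["plant_id"], test["DAT"], pred, truth):
                    oof_rows.append({"plant_id": pid, "DAT": dat, "rv": rv,
                                     "fold": fold.fold_id, "predicted": p, "actual": t})
        return StateEstimationResults(
            model=self,
            per_fold=pd.DataFrame(metric_rows),
            oof_predictions=pd.DataFrame(oof_rows),
        )

    def _fit_one(self, rv: str, train: pd.DataFrame, val: pd.DataFrame):
        cfg = self.config
        if cfg.tune and len(val):
            best, best_score = None, np.inf
            # coordinate search over the documented grid, scored on validation RMSE
            for n_est in SEARCH_GRID["n_estimators"][::4]:
                for depth in SEARCH_GRID["max_depth"][::4]:
                    cand = replace(cfg, n_estimators=n_est, max_depth=depth, tune=False)
                    est = cand.estimator(rv).fit(
                        train[self.feature_columns], train[f"label_{rv}"]
                    )
                    score = mean_squared_error(
                        val[f"label_{rv}"], est.predict(val[self.feature_columns])
                    )
                    if score < best_score:
                        best, best_score = cand, score
            cfg = best
        return cfg.estimator(rv).fit(train[self.feature_columns], train[f"label_{rv}"])

    def fit_full(self, rv: str) -> RandomForestRegressor:
        """Refit on all labeled+pseudolabeled records (for trajectory estimation)."""
        return self.config.estimator(rv).fit(
            self.labeled[self.feature_columns], self.labeled[f"label_{rv}"]
        )


@dataclass
class StateEstimationResults:
    """Cross-validation metrics and out-of-fold predictions."""

    model: TankPermutationForest
    per_fold: pd.DataFrame
    oof_predictions: pd.DataFrame

    def metrics(self) -> pd.DataFrame:
        """Cross-fold mean +/- SD of R2 and RMSE per response variable."""
        g = self.per_fold.groupby("rv")
        return pd.DataFrame({
            "r2_mean": g["r2"].mean(), "r2_sd": g["r2"].std(ddof=1),
            "rmse_mean": g["rmse"].mean(), "rmse_sd": g["rmse"].std(ddof=1),
            "n_folds": g.size(),
        })

    def oof_metrics(self) -> pd.DataFrame:
        """Aggregate R2/RMSE over the pooled out-of-fold predictions."""
        rows = []
        for rv, grp in self.oof_predictions.groupby("rv"):
            rows.append({
                "rv": rv,
                "r2": r2_score(grp["actual"], grp["predicted"]),
                "rmse": float(np.sqrt(mean_squared_error(grp["actual"], grp["predicted"]))),
                "n": len(grp),
            })
        return pd.DataFrame(rows).set_index("rv")

    def summary(self) -> str:
        m = self.metrics()
        lines = ["Tank-permutation random-forest state estimation",
                 f"  folds evaluated : {self.per_fold['fold'].nunique()}",
                 f"  features        : {len(self.model.feature_columns)}",
                 "  RV      R2 (mean+/-SD)      RMSE (mean+/-SD)"]
        for rv, row in m.iterrows():
            lines.append(
                f"  {rv:<6} {row.r2_mean:6.3f} +/- {row.r2_sd:5.3f}   "
                f"{row.rmse_mean:8.3f} +/- {row.rmse_sd:6.3f}"
            )
        return "\n".join(lines)


def estimate_trajectories(
    model: TankPermutationForest,
    daily_average_features: pd.DataFrame,
    rvs: list[str] | None = None,
) -> Trajectories:
    """RF-estimated response-variable trajectories from the daily-average set.

    A final model per RV (refit on all labeled+pseudolabeled single-image
    records) predicts each plant's RV at every DAT of the daily-average
    table — a data set not used for training — and the predictions are
    assembled into trajectories under the same truncation rules as the
    measured features.  These feed the anomaly tier unchanged (the RF-AE
    pathway).
    """
    rvs = rvs or RESPONSE_VARIABLES
    table = daily_average_features[list(META_COLUMNS)].copy()
    X = daily_average_features[model.feature_columns]
    for rv in rvs:
        table[rv] = model.fit_full(rv).predict(X)
    return Trajectories(table, feature_columns=rvs)
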