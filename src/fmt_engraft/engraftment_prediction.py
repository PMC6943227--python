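"""Per-taxon prediction of post-FMT community composition.

One classifier (presence) and one regressor (abundance) per taxon, trained
on the donor's species profile, the recipient's pre-FMT profile and the
recipient's clinical metadata.  With cohorts of ~15 recipients a held-out
test set is not an option, so every performance number is out-of-bag
(OOB): each sample is scored only by the trees whose bootstrap draw missed
it.  The ensemble is a bagged collection of scikit-learn decision trees
with an ``mtry``-style feature subsample per split, which keeps the OOB
votes, OOB AUC and OOB permutation importance all under direct control.

mtry is selected by k-fold cross-validation over a halving grid of feature
subset sizes (p, p/2, p/4, ... 1), ties going to the smaller value.
Feature importance is the permutation kind: the drop in OOB accuracy
(classification) or rise in OOB squared error (regression) when one
feature is shuffled among each tree's OOB rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import DegenerateTargetError, ValidationError
from .species_engraftment import DEFAULT_DETECTION_THRESHOLD, detect

logger = logging.getLogger(__name__)

PROVENANCE_LABELS = ("donor_profile", "recipient_profile", "recipient_clinical", "donor_meta")


@dataclass
class FeatureMatrix:
    """Predictor matrix for the per-taxon models.

    Rows are post-FMT recipient samples; every column carries a provenance
    label (donor_profile / recipient_profile / recipient_clinical /
    donor_meta).  No missing values remain after construction: clinical
    gaps are median-imputed, which is the only imputation in the package.
    """

    X: pd.DataFrame
    provenance: pd.Series

    def __post_init__(self) -> None:
        if not self.X.columns.equals(self.provenance.index):
            raise ValidationError("provenance must label every feature column")
        unknown = set(self.provenance) - set(PROVENANCE_LABELS)
        if unknown:
            raise ValidationError(f"unknown provenance label(s) {sorted(unknown)}")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix contains missing values")


def filter_rare_taxa(
    table,
    min_samples: int = 3,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
):
    """Drop taxa detected (>= threshold) in fewer than ``min_samples`` samples.

    Guards the presence models against targets that are almost always one
    class.  Returns a new AbundanceTable; may be empty (with a warning).
    """
    from .types import AbundanceTable

    detected = (table.data.to_numpy() >= threshold).sum(axis=1)
    keep = detected >= min_samples
    if not keep.any():
        logger.warning("filter_rare_taxa removed every taxon")
    return AbundanceTable(table.data.loc[keep].copy())


def build_feature_matrix(
    abundance,
    manifest,
    clinical=None,
    feature_taxa=None,
    include_donor_meta: bool = False,
) -> tuple[FeatureMatrix, pd.DataFrame, list[str]]:
    """Assemble predictors for every recipient with a donor and baseline.

    Returns (features, post-FMT abundance frame at the first post day per
    recipient, recipient order).  Donor and pre-FMT abundances enter raw;
    clinical values are the recipient's baseline visit, median-imputed.
    """
    rows = []
    recipients = []
    post_cols = {}
    for pair in manifest.pairs():
        if pair.donor_sample is None or pair.baseline_sample is None or not pair.post_samples:
            continue
        first_day = sorted(pair.post_samples)[0]
        donor_prof = abundance.sample(pair.donor_sample)
        pre_prof = abundance.sample(pair.baseline_sample)
        if feature_taxa is not None:
            donor_prof = donor_prof.loc[feature_taxa]
            pre_prof = pre_prof.loc[feature_taxa]
        row = {}
        for taxon, v in donor_prof.items():
            row[f"donor:{taxon}"] = float(v)
        for taxon, v in pre_prof.items():
            row[f"pre:{taxon}"] = float(v)
        rows.append(row)
        recipients.append(pair.recipient)
        post_cols[pair.recipient] = abundance.sample(pair.post_samples[first_day])
    if not rows:
        raise ValidationError("no recipient has donor, baseline and post-FMT samples")

    X = pd.DataFrame(rows, index=recipients)
    provenance = pd.Series(
        ["donor_profile" if c.startswith("donor:") else "recipient_profile" for c in X.columns],
        index=X.columns,
    )

    if clinical is not None:
        wide = clinical.wide(day=0)
        numeric = wide.apply(pd.to_numeric, errors="coerce")
        # one-hot any genuinely categorical index
        categorical = [c for c in wide.columns if numeric[c].isna().all()]
        if categorical:
            dummies = pd.get_dummies(wide[categorical].astype(str), prefix=categorical)
            numeric = pd.concat([numeric.drop(columns=categorical), dummies.astype(float)], axis=1)
        numeric = numeric.reindex(X.index)
        numeric = numeric.fillna(numeric.median()).fillna(0.0)
        numeric.columns = [f"clin:{c}" for c in numeric.columns]
        X = pd.concat([X, numeric], axis=1)
        provenance = pd.concat(
            [provenance, pd.Series("recipient_clinical", index=numeric.columns)]
        )

    post = pd.DataFrame(post_cols).T.reindex(X.index)
    return FeatureMatrix(X=X, provenance=provenance), post, recipients


# ---------------------------------------------------------------------------
# bagged OOB ensemble


class _BaggedTrees:
    """Bootstrap ensemble of decision trees with OOB bookkeeping."""

    def __init__(self, task: str, n_trees: int, max_features, seed: int):
        self.task = task
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.trees: list = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaggedTrees":
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        Tree = DecisionTreeClassifier if self.task == "presence" else DecisionTreeRegressor
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = Tree(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        return self

    def oob_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(per-sample OOB score, #OOB trees per sample).

        Classification: mean OOB vote for the positive class.
        Regression: mean OOB prediction.
        """
        n = X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            if self.task == "presence":
                proba = tree.predict_proba(X[oob])
                pos = proba[:, 1] if proba.shape[1] == 2 else proba[:, 0] * 0.0
            else:
                pos = tree.predict(X[oob])
            total[oob] += pos
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            score = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        return score, count

    def _tree_error(self, tree, X: np.ndarray, y: np.ndarray) -> float:
        pred = tree.predict(X)
        if self.task == "presence":
            return float(np.mean(pred != y))
        return float(np.mean((pred - y) ** 2))

    def permutation_importance(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        """Mean per-tree OOB error increase when each feature is permuted."""
        rng = np.random.default_rng(seed)
        p = X.shape[1]
        deltas = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            m = int(oob.sum())
            if m < 2:
                continue
            Xo = X[oob]
            yo = y[oob]
            base = self._tree_error(tree, Xo, yo)
            # one batched predict over all p permuted copies of the OOB block
            tiled = np.repeat(Xo[np.newaxis, :, :], p, axis=0)
            for j in range(p):
                tiled[j, :, j] = Xo[rng.permutation(m), j]
            pred = tree.predict(tiled.reshape(p * m, -1)).reshape(p, m)
            if self.task == "presence":
                errs = (pred != yo[np.newaxis, :]).mean(axis=1)
            else:
                errs = ((pred - yo[np.newaxis, :]) ** 2).mean(axis=1)
            deltas += errs - base
            n_used += 1
        return deltas / max(n_used, 1)


@dataclass
class PerTaxonModelResult:
    """OOB performance and importance of one per-taxon model."""

    taxon_id: str
    task: str  # 'presence' | 'abundance'
    auc: float | None
    oob_error: float
    chosen_mtry: int
    importance: pd.Series | None
    n_positive: int
    oob_predictions: np.ndarray = field(default=None, repr=False)
    observed: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValidationError(f"AUC out of range: {self.auc}")


def _halving_grid(p: int) -> list[int]:
    grid = []
    m = p
    while m >= 1:
        grid.append(m)
        if m == 1:
            break
        m //= 2
    return grid


def select_mtry(
    X: pd.DataFrame | np.ndarray,
    y,
    task: str = "presence",
    k: int = 5,
    n_trees: int = 100,
    seed: int = 0,
) -> int:
    """Pick the feature-subset size with lowest k-fold CV error.

    Evaluates the halving grid p, p/2, ..., 1; ties break to the smaller
    mtry.  With p = 1 no CV is run.  Classes smaller than k trigger a fold
    rebalancing warning and fewer splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p == 1:
        return 1
    if n < k:
        raise ValidationError(f"need >= {k} rows for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    if task == "presence":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise DegenerateTargetError("mtry selection needs two classes")
        if counts.min() < 2:
            # a lone positive/negative cannot be stratified; fall back
            logger.warning("class with a single member; skipping mtry CV")
            return max(1, int(np.sqrt(p)))
        n_splits = k
        if counts.min() < k:
            n_splits = max(2, int(counts.min()))
            logger.warning(
                "class with %d member(s) < %d folds; rebalancing to %d folds",
                counts.min(),
                k,
                n_splits,
            )
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    else:
        splitter = KFold(n_splits=min(k, n), shuffle=True, random_state=seed % 2**31)

    # plain k-fold CV needs no OOB bookkeeping, so sklearn's fast forests do
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    best_mtry, best_err = None, np.inf
    for m in _halving_grid(p):
        errs = []
        for train, test in splitter.split(X, y if task == "presence" else None):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            if task == "presence":
                forest = RandomForestClassifier(
                    n_estimators=n_trees, max_features=m, random_state=fold_seed
                ).fit(X[train], y[train])
                errs.append(float(np.mean(forest.predict(X[test]) != y[test])))
            else:
                forest = RandomForestRegressor(
                    n_estimators=n_trees, max_features=m, random_state=fold_seed
                ).fit(X[train], y[train])
                errs.append(float(np.mean((forest.predict(X[test]) - y[test]) ** 2)))
        err = float(np.mean(errs))
        # strict < keeps the smaller mtry on ties (grid is descending)
        if err < best_err or (err == best_err and (best_mtry is None or m < best_mtry)):
            best_err, best_mtry = err, m
    return int(best_mtry)


def fit_presence_model(
    features: FeatureMatrix | pd.DataFrame,
    y,
    taxon_id: str = "",
    mtry: int | None = None,
    n_trees: int = 500,
    seed: int = 0,
    compute_importance: bool = True,
) -> PerTaxonModelResult:
    """Bagged classification of one taxon's post-FMT presence.

    AUC comes from out-of-bag class votes; importance (optional) is the
    OOB permutation decrease in accuracy.  A single-class target raises
    DegenerateTargetError — drivers skip such taxa with a reason.
    """
    X_df = features.X if isinstance(features, FeatureMatrix) else features
    X = np.asarray(X_df, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateTargetError(f"taxon {taxon_id!r}: single-class presence target")
    if mtry is None:
        mtry = max(1, int(np.sqrt(X.shape[1])))
    forest = _BaggedTrees("presence", n_trees, int(mtry), seed).fit(X, y)
    score, count = forest.oob_scores(X)
    valid = count > 0
    auc = float(roc_auc_score(y[valid], score[valid]))
    oob_error = float(np.mean((score[valid] >= 0.5).astype(int) != y[valid]))
    importance = None
    if compute_importance:
        imp = forest.permutation_importance(X, y, seed=seed + 1)
        importance = pd.Series(imp, index=X_df.columns)
    result = PerTaxonModelResult(
        taxon_id=taxon_id,
        task="presence",
        auc=auc,
        oob_error=oob_error,
        chosen_mtry=int(mtry),
        importance=importance,
        n_positive=int(y.sum()),
        oob_predictions=score,
        observed=y.astype(float),
    )
    result._forest = forest  # retained so drivers can compute importance lazily
    result._importance_seed = seed + 1
    return result


def fit_abundance_model(
    features: FeatureMatrix | pd.DataFrame,
    y,
    taxon_id: str = "",
    mtry: int | None = None,
    n_trees: int = 500,
    seed: int = 0,
    compute_importance: bool = False,
) -> PerTaxonModelResult:
    """Bagged regression of one taxon's post-FMT abundance.

    OOB predictions are retained for cohort-level pooling; importance
    (optional) is the OOB permutation increase in squared error.  A target
    with fewer than three distinct values raises DegenerateTargetError.
    """
    X_df = features.X if isinstance(features, FeatureMatrix) else features
    X = np.asarray(X_df, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 3:
        raise DegenerateTargetError(f"taxon {taxon_id!r}: near-constant abundance target")
    if mtry is None:
        mtry = max(1, X.shape[1] // 3)
    forest = _BaggedTrees("abundance", n_trees, int(mtry), seed).fit(X, y)
    score, count = forest.oob_scores(X)
    valid = count > 0
    oob_error = float(np.mean((score[valid] - y[valid]) ** 2))
    importance = None
    if compute_importance:
        imp = forest.permutation_importance(X, y, seed=seed + 1)
        importance = pd.Series(imp, index=X_df.columns)
    return PerTaxonModelResult(
        taxon_id=taxon_id,
        task="abundance",
        auc=None,
        oob_error=oob_error,
        chosen_mtry=int(mtry),
        importance=importance,
        n_positive=int((y > 0).sum()),
        oob_predictions=np.where(valid, score, np.nan),
        observed=y,
    )


def pool_regression_performance(results) -> tuple[float | None, float | None]:
    """Spearman rho of pooled OOB predictions vs observed abundances."""
    preds, obs = [], []
    for res in results:
        if res.task != "abundance" or res.oob_predictions is None:
            continue
        valid = ~np.isnan(res.oob_predictions)
        preds.append(res.oob_predictions[valid])
        obs.append(res.observed[valid])
    if not preds:
        return None, None
    pred = np.concatenate(preds)
    ob = np.concatenate(obs)
    if pred.size < 2 or np.all(pred == pred[0]) or np.all(ob == ob[0]):
        return None, None
    rho, p = scipy.stats.spearmanr(pred, ob)
    return float(rho), float(p)


def aggregate_importance(
    results,
    provenance: pd.Series,
    auc_min: float = 0.9,
    top_k: int = 40,
) -> pd.DataFrame:
    """Rank features across well-performing presence models.

    Importances of models with AUC > ``auc_min`` are rank-normalised to
    [0, 1] within each model and averaged per feature; the ``top_k``
    features are returned with their provenance category.
    """
    qualifying = [
        r
        for r in results
        if r.task == "presence" and r.auc is not None and r.auc > auc_min and r.importance is not None
    ]
    if not qualifying:
        logger.warning("no model passed the AUC > %.2f screen", auc_min)
        return pd.DataFrame(columns=["feature", "score", "provenance", "n_models"])
    scores = []
    for r in qualifying:
        imp = r.importance
        ranks = scipy.stats.rankdata(imp.to_numpy())  # ascending: biggest importance = top rank
        norm = (ranks - 1) / max(len(ranks) - 1, 1)
        scores.append(pd.Series(norm, index=imp.index))
    mean_score = pd.concat(scores, axis=1).mean(axis=1).sort_values(ascending=False)
    top = mean_score.head(top_k)
    return pd.DataFrame(
        {
            "feature": top.index,
            "score": top.to_numpy(),
            "provenance": provenance.reindex(top.index).to_numpy(),
            "n_models": len(qualifying),
        }
    ).reset_index(drop=True)


def predict_cohort(
    abundance,
    manifest,
    clinical=None,
    min_samples: int = 3,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    n_trees: int = 500,
    select_mtry_cv: bool = True,
    mtry_cv_trees: int = 50,
    auc_min: float = 0.9,
    top_k: int = 40,
    seed: int = 0,
    compute_importance: bool = True,
) -> dict:
    """Fit presence + abundance models for every filtered taxon.

    Returns a dict with the per-taxon results, skipped taxa with reasons,
    pooled regression performance and the aggregated importance ranking.
    Cohorts smaller than 16 recipients are flagged as small-sample.
    """
    filtered = filter_rare_taxa(abundance, min_samples, threshold)
    features, post, recipients = build_feature_matrix(
        abundance, manifest, clinical, feature_taxa=filtered.taxon_ids
    )
    n = len(recipients)
    rng = np.random.default_rng(seed)
    results: list[PerTaxonModelResult] = []
    skipped: list[tuple[str, str]] = []
    for taxon in filtered.taxon_ids:
        target_abund = post[taxon].to_numpy(dtype=float)
        target_presence = (target_abund >= threshold).astype(int)
        model_seed = int(rng.integers(0, 2**31 - 1))
        try:
            if select_mtry_cv and len(np.unique(target_presence)) == 2:
                mtry = select_mtry(
                    features.X, target_presence, "presence", seed=model_seed, n_trees=mtry_cv_trees
                )
            else:
                mtry = None
            results.append(
                fit_presence_model(
                    features,
                    target_presence,
                    taxon_id=taxon,
                    mtry=mtry,
                    n_trees=n_trees,
                    seed=model_seed,
                    compute_importance=False,  # computed below, only where used
                )
            )
        except DegenerateTargetError as exc:
            skipped.append((taxon, str(exc)))
        try:
            results.append(
                fit_abundance_model(
                    features,
                    target_abund,
                    taxon_id=taxon,
                    n_trees=n_trees,
                    seed=model_seed + 1,
                    compute_importance=False,
                )
            )
        except DegenerateTargetError as exc:
            skipped.append((taxon, str(exc)))

    if compute_importance:
        # importance feeds only the AUC-screened ranking; skip the rest
        X_arr = np.asarray(features.X, dtype=float)
        for r in results:
            if r.task == "presence" and r.auc is not None and r.auc > auc_min:
                imp = r._forest.permutation_importance(
                    X_arr, r.observed.astype(int), seed=r._importance_seed
                )
                r.importance = pd.Series(imp, index=features.X.columns)

    rho, p = pool_regression_performance(results)
    importance = aggregate_importance(results, features.provenance, auc_min, top_k)
    aucs = [r.auc for r in results if r.task == "presence"]
    return {
        "results": results,
        "skipped": skipped,
        "n_recipients": n,
        "small_sample": n < 16,
        "n_presence_models": len(aucs),
        "mean_auc": float(np.mean(aucs)) if aucs else None,
        "pooled_rho": rho,
        "pooled_p": p,
        "importance": importance,
    }
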