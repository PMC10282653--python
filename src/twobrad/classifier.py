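"""Random-forest marker discovery and POD (probability of disease) scoring.

The workflow mirrors the common microbiome random-forest recipe:

1. restrict candidates to the most abundant taxa (top 30 by mean relative
   abundance by default);
2. rank candidates by out-of-bag permutation importance;
3. sweep nested marker sets (top-1, top-2, ... top-k by importance),
   scoring each with stratified cross-validated classification error, and
   pick the smallest set within one standard error of the minimum;
4. score each sample with POD — the fraction of trees voting the
   designated positive class (out-of-bag trees only for training samples);
5. evaluate PODs with the rank-based AUC (Mann-Whitney U / (n1*n2)) and a
   two-sided Wilcoxon rank-sum group test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sklearn.model_selection import StratifiedKFold

from .ecology import AbundanceTable

__all__ = [
    "ForestConfig",
    "ClassifierResult",
    "rank_importance",
    "select_markers_cv",
    "pod_scores",
    "evaluate_pod",
    "cv_auc",
    "run_classifier",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (sqrt-features splits, 500 trees)."""

    n_trees: int = 500
    max_features: str | float = "sqrt"

    def build(self, seed: int | None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=False,
            random_state=seed,
            n_jobs=1,
        )


def _check_two_groups(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs at least 2 samples")
    return groups.to_numpy(), labels


def _oob_index_sets(
    forest: RandomForestClassifier, n_samples: int
) -> list[np.ndarray]:
    """Out-of-bag sample indices for each fitted tree."""
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    return [
        _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        for tree in forest.estimators_
    ]


def rank_importance(
    table: AbundanceTable,
    top_n: int = 30,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Out-of-bag permutation importance over the top-N abundant taxa.

    Candidates are the ``top_n`` taxa by overall mean relative abundance.
    For every tree, accuracy on its out-of-bag samples is compared with
    accuracy after permuting one feature among those samples; a taxon's
    importance is the mean accuracy drop over trees.  Deterministic given
    the seed.
    """
    config = config or ForestConfig()
    y, _ = _check_two_groups(table.groups)
    top_n = min(top_n, len(table.taxa))
    candidates = (
        table.values.mean(axis=0).sort_values(ascending=False).index[:top_n].tolist()
    )
    X = table.values[candidates].to_numpy()
    n = X.shape[0]
    forest = config.build(seed).fit(X, y)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    drops = np.zeros((len(forest.estimators_), X.shape[1]))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for ti, (tree, oob) in enumerate(zip(forest.estimators_, _oob_index_sets(forest, n))):
        if len(oob) == 0:
            continue
        used[ti] = True
        X_oob, y_oob = X[oob], y[oob]
        base = (forest.classes_[tree.predict(X_oob).astype(int)] == y_oob).mean()
        for f in range(X.shape[1]):
            Xp = X_oob.copy()
            Xp[:, f] = Xp[rng.permutation(len(oob)), f]
            acc = (forest.classes_[tree.predict(Xp).astype(int)] == y_oob).mean()
            drops[ti, f] = base - acc
    if not used.any():
        raise RuntimeError("no tree had out-of-bag samples; increase n_trees")
    importance = drops[used].mean(axis=0)
    out = pd.DataFrame({"taxon": candidates, "importance": importance})
    return out.sort_values(
        ["importance", "taxon"], ascending=[False, True], ignore_index=True
    )


def select_markers_cv(
    table: AbundanceTable,
    ranking: pd.DataFrame,
    folds: int = 5,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Cross-validation error curve over nested marker sets; 1-SE selection.

    For k = 1..n_candidates, the top-k taxa by importance are scored with
    stratified k-fold CV misclassification error; the selected k is the
    smallest whose mean error is within one standard error of the global
    minimum.  Returns ``(selected_markers, curve)``.
    """
    config = config or ForestConfig()
    y, _ = _check_two_groups(table.groups)
    min_group = int(pd.Series(y).value_counts().min())
    if folds > min_group:
        folds = min_group  # cannot stratify more folds than the smaller group
    ordered = ranking["taxon"].tolist()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    rows = []
    for k in range(1, len(ordered) + 1):
        X = table.values[ordered[:k]].to_numpy()
        errors = []
        for fi, (train, test) in enumerate(splits):
            tree_seed = None if seed is None else seed + 1000 * k + fi
            model = config.build(tree_seed).fit(X[train], y[train])
            errors.append((model.predict(X[test]) != y[test]).mean())
        errors = np.asarray(errors)
        rows.append(
            {"k": k, "cv_error": errors.mean(), "se": errors.std(ddof=1) / np.sqrt(folds)}
        )
    curve = pd.DataFrame(rows)
    best = curve["cv_error"].idxmin()
    limit = curve.loc[best, "cv_error"] + curve.loc[best, "se"]
    k_sel = int(curve.loc[curve["cv_error"] <= limit, "k"].min())
    return ordered[:k_sel], curve


def pod_scores(
    forest: RandomForestClassifier,
    X: np.ndarray,
    positive: str,
    oob: bool = False,
) -> np.ndarray:
    """POD per sample: fraction of trees voting the positive class.

    With ``oob=True`` the rows of X are the forest's training samples and
    only each sample's out-of-bag trees vote, avoiding resubstitution
    optimism; a training sample seen by every tree raises an error.
    """
    classes = list(forest.classes_)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not in {classes}")
    pos = classes.index(positive)
    votes = np.stack(
        [tree.predict(X).astype(int) == pos for tree in forest.estimators_]
    )  # trees x samples
    if not oob:
        return votes.mean(axis=0)
    n = X.shape[0]
    mask = np.zeros_like(votes, dtype=bool)
    for ti, idx in enumerate(_oob_index_sets(forest, n)):
        mask[ti, idx] = True
    counts = mask.sum(axis=0)
    if (counts == 0).any():
        raise RuntimeError(
            "some training samples are in-bag for every tree; grow more trees"
        )
    return (votes & mask).sum(axis=0) / counts


def evaluate_pod(pods, groups, positive: str) -> tuple[float, float]:
    """AUC and group-difference p-value for POD scores.

    AUC is the Mann-Whitney U statistic divided by n_pos*n_neg (ties count
    half), i.e. the probability a random positive-group sample out-scores
    a random negative-group one; the p-value is the two-sided Wilcoxon
    rank-sum test of POD by group.
    """
    pods = np.asarray(pods, dtype=float)
    groups = np.asarray(groups)
    pos = pods[groups == positive]
    neg = pods[groups != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be represented")
    res = mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def cv_auc(
    table: AbundanceTable,
    markers: list[str],
    positive: str,
    folds: int = 5,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> float:
    """Stratified cross-validated AUC of out-of-fold POD scores."""
    config = config or ForestConfig()
    y, _ = _check_two_groups(table.groups)
    folds = min(folds, int(pd.Series(y).value_counts().min()))
    X = table.values[list(markers)].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pods = np.zeros(len(y))
    for fi, (train, test) in enumerate(skf.split(X, y)):
        model = config.build(None if seed is None else seed + fi).fit(X[train], y[train])
        pods[test] = pod_scores(model, X[test], positive)
    auc, _ = evaluate_pod(pods, y, positive)
    return auc


@dataclass
class ClassifierResult:
    ranking: pd.DataFrame
    cv_error_curve: pd.DataFrame
    selected_markers: list[str]
    pod: pd.Series
    auc: float
    pod_group_p: float
    extra: dict = field(default_factory=dict)


def run_classifier(
    table: AbundanceTable,
    positive: str,
    top_n: int = 30,
    folds: int = 5,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> ClassifierResult:
    """Full marker-discovery workflow on one abundance table."""
    config = config or ForestConfig()
    ranking = rank_importance(table, top_n=top_n, config=config, seed=seed)
    markers, curve = select_markers_cv(
        table, ranking, folds=folds, config=config, seed=seed
    )
    X = table.values[markers].to_numpy()
    y = table.groups.to_numpy()
    forest = config.build(None if seed is None else seed + 7).fit(X, y)
    pods = pod_scores(forest, X, positive, oob=True)
    auc, p = evaluate_pod(pods, y, positive)
    return ClassifierResult(
        ranking=ranking,
        cv_error_curve=curve,
        selected_markers=markers,
        pod=pd.Series(pods, index=table.samples, name="pod"),
        auc=auc,
        pod_group_p=p,
        extra={"positive": positive, "seed": seed},
    )
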