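"""Two-stage leave-one-mouse-out random-forest classification.

The experimental question is whether two groups of mice (e.g. genotype or
dose vs control) can be told apart from their beam-walk feature vectors.
Because each mouse contributes up to two trials per beam, cross-validation
must leave *mice* out, not trials: the outer loop holds out every trial of
one mouse for testing, and an inner leave-one-mouse-out loop inside each
outer training set performs feature selection and hyperparameter tuning,
so that nothing about a held-out mouse ever influences the model that is
evaluated on it.

Per inner split the recipe is: z-score the features with training-set
statistics; recursive feature elimination with a balanced random forest
down to ``n_select`` features (eliminating ``ceil(rfe_step * remaining)``
per round); an exhaustive grid search over the forest hyperparameters
scored on the inner-validation mouse; and a second elimination round with
the tuned hyperparameters, whose surviving features ranked by mean
decrease in impurity form the split's ranked list.  Ranked lists are
aggregated into a consensus (occurrence first, then mean rank, then name)
and hyperparameters by per-key mode; the resulting model is trained on the
full outer training set and scored on the held-out mouse's trials,
giving a per-animal accuracy in {0, 0.5, 1}.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .io_keypoints import BeamwalkError


class DesignError(BeamwalkError):
    """The dataset cannot support the requested cross-validation design."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ExperimentDataset:
    """Feature matrix plus per-trial labels and mouse identifiers.

    ``X`` is trials x features (columns are feature names); ``y`` the group
    label per trial; ``mouse_ids`` the animal each trial belongs to.  Every
    mouse must carry a single label and at most two trials (one analysis is
    run per beam).
    """

    X: pd.DataFrame
    y: np.ndarray
    mouse_ids: np.ndarray
    beam: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.mouse_ids = np.asarray(self.mouse_ids)
        if not (len(self.X) == len(self.y) == len(self.mouse_ids)):
            raise DesignError("X, y and mouse_ids must have equal length")
        for m in np.unique(self.mouse_ids):
            labels = set(self.y[self.mouse_ids == m])
            if len(labels) != 1:
                raise DesignError(f"mouse {m!r} carries multiple labels {labels}")
            if (self.mouse_ids == m).sum() > 2:
                raise DesignError(f"mouse {m!r} has more than two trials")

    @property
    def mice(self) -> np.ndarray:
        """Unique mice in order of first appearance."""
        _, idx = np.unique(self.mouse_ids, return_index=True)
        return self.mouse_ids[np.sort(idx)]

    def mouse_label(self, mouse) -> str:
        return self.y[self.mouse_ids == mouse][0]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class CVConfig:
    """Tunables of the nested cross-validation.

    ``rfe_step`` is the fraction of the remaining features eliminated per
    round (ceil, floor one feature); ``n_select`` the target feature count;
    ``hyper_grid`` an ordered mapping of forest hyperparameters to
    candidate values (order defines tie-breaking); ``rfe_params`` extra
    keyword arguments for the elimination-stage forest.  ``zscore_skip``
    lists binary columns excluded from standardisation (they pass through
    untouched).
    """

    n_select: int = 50
    rfe_step: float = 0.05
    hyper_grid: dict = field(default_factory=lambda: {
        "n_estimators": [100, 300],
        "max_depth": [3, 5, None],
        "min_samples_leaf": [1, 3],
    })
    rfe_params: dict = field(default_factory=dict)
    class_weight: str = "balanced"
    chance_level: float = 0.5
    seed: int = 0
    zscore_skip: tuple[str, ...] = ("sex",)

    def __post_init__(self) -> None:
        if not 0 < self.rfe_step < 1:
            raise ValueError("rfe_step must be in (0, 1)")
        if not self.hyper_grid:
            raise ValueError("hyper_grid must not be empty")


@dataclass
class SplitResult:
    """Selection and evaluation record of one outer split."""

    mouse: str
    consensus_features: list[str]
    hyperparams: dict
    accuracy: float
    n_test_trials: int


@dataclass
class CVResult:
    accuracies: dict            # mouse -> accuracy in {0, 0.5, 1}
    consensus_features: list[str]
    final_hyperparams: dict
    wilcoxon_W: float
    wilcoxon_p: float
    splits: list[SplitResult]
    hyperparam_ties: bool = False

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracies.values())))


# --------------------------------------------------------------------------
# Splitting and normalization
# --------------------------------------------------------------------------


def lomo_splits(dataset: ExperimentDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train indices, held-out indices) pair per mouse."""
    mice = dataset.mice
    if len(mice) < 3:
        raise DesignError(f"leave-one-mouse-out needs >= 3 mice, got {len(mice)}")
    labels = np.unique(dataset.y)
    counts = {lab: sum(dataset.mouse_label(m) == lab for m in mice) for lab in labels}
    if min(counts.values()) < 2:
        raise DesignError(
            f"every class needs >= 2 mice so it survives any held-out mouse; got {counts}"
        )
    splits = []
    for m in mice:
        test = np.flatnonzero(dataset.mouse_ids == m)
        train = np.flatnonzero(dataset.mouse_ids != m)
        splits.append((train, test))
    return splits


def zscore_fit_apply(
    train: np.ndarray, *others: np.ndarray, skip: np.ndarray | None = None
) -> tuple[np.ndarray, ...]:
    """Standardise with training-set statistics (mean, n-1 SD).

    Features with zero training SD map to 0 in every matrix.  ``skip`` is a
    boolean column mask of features passed through unchanged (e.g. the
    binary sex code).  Returns the transformed train matrix followed by the
    transformed ``others``.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise DesignError("z-scoring needs >= 2 training rows")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    if skip is None:
        skip = np.zeros(train.shape[1], dtype=bool)

    def transform(m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        z = (m - mu) / sd_safe
        z[:, constant] = 0.0
        z[:, skip] = m[:, skip]
        return z

    return tuple(transform(m) for m in (train, *others))


def _split_seed(master: int, *indices: int) -> int:
    """Deterministic per-split seed below 2**31 from the master seed and a
    counter tuple (outer index, inner index, stage)."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Feature elimination and ranking
# --------------------------------------------------------------------------


def _forest(config: CVConfig, params: Mapping, seed: int) -> RandomForestClassifier:
    kw = dict(params)
    kw.setdefault("class_weight", config.class_weight)
    kw["random_state"] = seed
    return RandomForestClassifier(**kw)


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    config: CVConfig,
    params: Mapping,
    seed: int,
    rank_final: bool = True,
) -> list[str]:
    """Recursive feature elimination down to ``n_select`` features.

    Each round fits a forest on the surviving features and drops the
    ``ceil(rfe_step * remaining)`` least important (never overshooting the
    target).  With ``rank_final`` the survivors are ordered by the
    impurity importance of a dedicated fit on exactly those features
    (most important first); without it -- used where only the selected
    *set* matters -- they keep the ordering of the last elimination fit.
    """
    names = list(feature_names)
    if config.n_select >= len(names):
        raise DesignError(
            f"n_select={config.n_select} must be below the feature count {len(names)}"
        )
    keep = np.arange(len(names))
    step = 0
    last_importances = None
    while len(keep) > config.n_select:
        clf = _forest(config, params, _split_seed(seed, step))
        clf.fit(X[:, keep], y)
        importances = clf.feature_importances_
        n_drop = min(
            max(1, int(np.ceil(config.rfe_step * len(keep)))),
            len(keep) - config.n_select,
        )
        # drop the n_drop least important; ties broken by column order
        order = np.argsort(importances, kind="stable")
        mask = np.ones(len(keep), dtype=bool)
        mask[order[:n_drop]] = False
        keep = keep[mask]
        last_importances = importances[mask]
        step += 1
    if rank_final or last_importances is None:
        clf = _forest(config, params, _split_seed(seed, step))
        clf.fit(X[:, keep], y)
        last_importances = clf.feature_importances_
    order = np.argsort(-np.asarray(last_importances), kind="stable")
    return [names[keep[i]] for i in order]


def _grid_combos(hyper_grid: Mapping) -> list[dict]:
    keys = list(hyper_grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(hyper_grid[k] for k in keys))]


def inner_select_and_tune(
    dataset: ExperimentDataset,
    train_idx: np.ndarray,
    config: CVConfig,
    outer_index: int = 0,
) -> tuple[list[list[str]], list[dict]]:
    """Inner leave-one-mouse-out selection and tuning on one training set.

    Returns one ranked feature list and one best-hyperparameter set per
    inner split.
    """
    sub_mice = dataset.mouse_ids[train_idx]
    _, first = np.unique(sub_mice, return_index=True)
    inner_mice = sub_mice[np.sort(first)]
    if len(inner_mice) < 2:
        raise DesignError("inner selection needs >= 2 training mice")
    names = dataset.feature_names
    skip = np.array([n in config.zscore_skip for n in names])
    Xall = dataset.X.to_numpy(dtype=float)
    ranked_lists: list[list[str]] = []
    best_params_list: list[dict] = []
    combos = _grid_combos(config.hyper_grid)

    for inner_index, val_mouse in enumerate(inner_mice):
        fit_idx = train_idx[sub_mice != val_mouse]
        val_idx = train_idx[sub_mice == val_mouse]
        X_fit, X_val = zscore_fit_apply(Xall[fit_idx], Xall[val_idx], skip=skip)
        y_fit, y_val = dataset.y[fit_idx], dataset.y[val_idx]
        seed0 = _split_seed(config.seed, outer_index, inner_index, 0)

        # (i) first elimination round with the base (untuned) forest; only
        # the selected set feeds the grid search, so skip the ranking fit
        selected = rfe_rank(X_fit, y_fit, names, config, config.rfe_params, seed0,
                            rank_final=False)
        sel_cols = [names.index(n) for n in selected]

        # (ii) exhaustive grid search on the selected features, scored by
        # accuracy on the inner-validation mouse; ties keep the earlier combo
        # (a single-point grid needs no scoring)
        best_acc, best_params = -1.0, combos[0]
        for c_i, combo in enumerate(combos if len(combos) > 1 else []):
            params = dict(config.rfe_params)
            params.update(combo)
            clf = _forest(config, params, _split_seed(config.seed, outer_index, inner_index, 1, c_i))
            clf.fit(X_fit[:, sel_cols], y_fit)
            acc = float((clf.predict(X_val[:, sel_cols]) == y_val).mean())
            if acc > best_acc:
                best_acc, best_params = acc, combo

        # (iii) second elimination round with the tuned hyperparameters over
        # all features; survivors ranked by final impurity importance
        params = dict(config.rfe_params)
        params.update(best_params)
        seed2 = _split_seed(config.seed, outer_index, inner_index, 2)
        ranked = rfe_rank(X_fit, y_fit, names, config, params, seed2)

        ranked_lists.append(ranked)
        best_params_list.append(dict(best_params))
    return ranked_lists, best_params_list


# --------------------------------------------------------------------------
# Consensus aggregation
# --------------------------------------------------------------------------


def consensus_rank(ranked_lists: Sequence[Sequence[str]], n_select: int) -> list[str]:
    """Aggregate per-split ranked lists into one consensus list.

    Features are ordered by occurrence count across lists (descending),
    then mean 1-based rank within the lists containing them (ascending),
    then name; the first ``n_select`` are returned.
    """
    if not ranked_lists:
        raise ValueError("need at least one ranked list")
    occurrence: Counter = Counter()
    rank_sum: Counter = Counter()
    for lst in ranked_lists:
        for r, name in enumerate(lst, start=1):
            occurrence[name] += 1
            rank_sum[name] += r
    scored = sorted(
        occurrence,
        key=lambda n: (-occurrence[n], rank_sum[n] / occurrence[n], n),
    )
    return scored[:n_select]


def mode_hyperparams(param_sets: Sequence[Mapping], hyper_grid: Mapping) -> tuple[dict, bool]:
    """Per-key most frequent value across splits.

    Ties are broken toward the value listed earlier in the grid's declared
    candidate order; the returned flag marks whether any tie occurred.
    """
    if not param_sets:
        raise ValueError("need at least one hyperparameter set")
    keys = set(param_sets[0])
    for ps in param_sets:
        if set(ps) != keys:
            raise ValueError("hyperparameter sets carry inconsistent keys")
    final: dict = {}
    tie = False
    for key in param_sets[0]:
        counts = Counter(ps[key] for ps in param_sets)
        best_count = max(counts.values())
        candidates = [v for v, c in counts.items() if c == best_count]
        if len(candidates) > 1:
            tie = True
            declared = list(hyper_grid.get(key, candidates))
            candidates.sort(key=lambda v: declared.index(v) if v in declared else len(declared))
        final[key] = candidates[0]
    return final, tie


# --------------------------------------------------------------------------
# Wilcoxon vs chance
# --------------------------------------------------------------------------


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact sign-flip p-value of the signed-rank statistic.

    Enumerates the 2^n equiprobable sign assignments by convolution over
    doubled (hence integer even with midranks) rank scores; valid with
    ties, unlike a table lookup.
    """
    scores = np.round(2 * ranks).astype(int)
    total = scores.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in scores:
        shifted = np.zeros_like(dist)
        shifted[s:] = dist[: len(dist) - s]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_ge = dist[w2:].sum()
    p_le = dist[: w2 + 1].sum()
    return float(min(1.0, 2 * min(p_ge, p_le)))


def wilcoxon_vs_chance(
    accuracies: Sequence[float], chance: float = 0.5
) -> tuple[float, float, bool]:
    """One-sample Wilcoxon signed-rank test of per-animal accuracies
    against chance.

    Zeros (accuracies exactly at chance) are dropped; W is the sum of the
    midranks of positive differences.  The two-sided p-value comes from the
    exact sign-flip distribution for n <= 25 (ties handled by midranks)
    and the normal approximation with tie correction above.  Returns
    ``(W, p, degenerate)`` where the flag marks the all-at-chance case
    (p = 1 by convention).
    """
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size < 6:
        raise DesignError(f"Wilcoxon test needs >= 6 animals, got {acc.size}")
    d = acc - chance
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        n = d.size
        mean = n * (n + 1) / 4
        # variance with tie correction over groups of equal |d|
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return w_plus, p, False


# --------------------------------------------------------------------------
# Nested cross-validation
# --------------------------------------------------------------------------


def run_nested_lomo(dataset: ExperimentDataset, config: CVConfig) -> CVResult:
    """Full two-stage leave-one-mouse-out cross-validation.

    For each outer split, feature consensus and hyperparameter mode are
    derived from inner splits of the training side only; the final forest
    is trained on the outer training trials (z-scored with training
    statistics, restricted to the consensus features) and scored on the
    held-out mouse's trials.  Per-animal accuracies are aggregated and
    tested against chance.
    """
    splits = lomo_splits(dataset)
    names = dataset.feature_names
    skip = np.array([n in config.zscore_skip for n in names])
    Xall = dataset.X.to_numpy(dtype=float)

    accuracies: dict = {}
    split_results: list[SplitResult] = []
    all_ranked: list[list[str]] = []
    all_params: list[dict] = []
    any_tie = False

    for outer_index, (train_idx, test_idx) in enumerate(splits):
        ranked_lists, params_list = inner_select_and_tune(
            dataset, train_idx, config, outer_index
        )
        consensus = consensus_rank(ranked_lists, config.n_select)
        params, tie = mode_hyperparams(params_list, config.hyper_grid)
        any_tie = any_tie or tie
        all_ranked.extend(ranked_lists)
        all_params.extend(params_list)

        X_train, X_test = zscore_fit_apply(Xall[train_idx], Xall[test_idx], skip=skip)
        cols = [names.index(n) for n in consensus]
        fit_params = dict(config.rfe_params)
        fit_params.update(params)
        clf = _forest(config, fit_params, _split_seed(config.seed, outer_index, 3))
        clf.fit(X_train[:, cols], dataset.y[train_idx])
        pred = clf.predict(X_test[:, cols])
        acc = float((pred == dataset.y[test_idx]).mean())

        mouse = dataset.mouse_ids[test_idx][0]
        accuracies[mouse] = acc
        split_results.append(
            SplitResult(
                mouse=str(mouse),
                consensus_features=consensus,
                hyperparams=params,
                accuracy=acc,
                n_test_trials=len(test_idx),
            )
        )

    final_consensus = consensus_rank(all_ranked, config.n_select)
    final_params, tie = mode_hyperparams(all_params, config.hyper_grid)
    any_tie = any_tie or tie
    if len(accuracies) >= 6:
        W, p, _ = wilcoxon_vs_chance(list(accuracies.values()), config.chance_level)
    else:  # too few animals for the test; accuracies still reported
        W, p = float("nan"), float("nan")
    return CVResult(
        accuracies=accuracies,
        consensus_features=final_consensus,
        final_hyperparams=final_params,
        wilcoxon_W=W,
        wilcoxon_p=p,
        splits=split_results,
        hyperparam_ties=any_tie,
    )


def transfer_predict(
    train_dataset: ExperimentDataset,
    test_dataset: ExperimentDataset,
    config: CVConfig,
) -> tuple[dict, list[str], dict]:
    """Train wholly within cohort A and predict every mouse of cohort B.

    Feature consensus and hyperparameters come from a full inner
    leave-one-mouse-out pass over cohort A; z-scoring is fitted on A.
    Returns per-animal accuracies on B plus the consensus features and
    hyperparameters used.
    """
    if train_dataset.feature_names != test_dataset.feature_names:
        raise DesignError("train and test cohorts carry different feature manifests")
    names = train_dataset.feature_names
    skip = np.array([n in config.zscore_skip for n in names])
    all_idx = np.arange(len(train_dataset.X))
    ranked_lists, params_list = inner_select_and_tune(train_dataset, all_idx, config, 0)
    consensus = consensus_rank(ranked_lists, config.n_select)
    params, _ = mode_hyperparams(params_list, config.hyper_grid)

    XA = train_dataset.X.to_numpy(dtype=float)
    XB = test_dataset.X.to_numpy(dtype=float)
    XA_z, XB_z = zscore_fit_apply(XA, XB, skip=skip)
    cols = [names.index(n) for n in consensus]
    fit_params = dict(config.rfe_params)
    fit_params.update(params)
    clf = _forest(config, fit_params, _split_seed(config.seed, 0, 4))
    clf.fit(XA_z[:, cols], train_dataset.y)
    pred = clf.predict(XB_z[:, cols])

    accuracies = {}
    for m in test_dataset.mice:
        sel = test_dataset.mouse_ids == m
        accuracies[m] = float((pred[sel] == test_dataset.y[sel]).mean())
    return accuracies, consensus, params
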