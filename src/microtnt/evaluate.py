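"""Split management, balanced-accuracy scoring and the grid-search protocol.

The evaluation protocol keeps a strict firewall between the
training-validation set and the holdout test set: hyperparameters are
compared by out-of-bag (OOB) balanced accuracy on the training set only,
across several pseudo-random splits, and the holdout set is touched exactly
once per split, after all hyperparameter choices are fixed. A guard object
makes accidental holdout-label access raise instead of silently leaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.oneway import anova_oneway

from . import features as feat
from .forest import HyperParams, predict, train_forest
from .io_model import CommunityTable, ResponseVector, TaxonomyTable, ValidationError


class LeakageError(RuntimeError):
    """Holdout information was requested during a training-only phase."""


@dataclass(frozen=True)
class Split:
    train_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]


@dataclass
class SplitSet:
    """k reproducible training/holdout partitions of the sample set."""

    splits: list[Split]
    seed: int
    holdout_fraction: float

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def _round_half_down(x: float) -> int:
    return math.ceil(x - 0.5)


def make_splits(
    sample_ids,
    holdout_fraction: float = 0.25,
    k: int = 6,
    seed: int = 0,
) -> SplitSet:
    """Draw ``k`` seeded 75/25-style splits without stratification.

    The training size is the round-half-down of n × (1 − fraction), so 150
    samples yield 112 training / 38 holdout. Splits are pairwise distinct
    with overwhelming probability but not enforced to be.
    """
    ids = sorted(map(str, sample_ids))
    n = len(ids)
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_train = _round_half_down(n * (1 - holdout_fraction))
    n_holdout = n - n_train
    if n_holdout < 1 or n_train < 1:
        raise ValidationError(f"{n} samples too few for a nonempty split")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(k):
        order = rng.permutation(n)
        train = tuple(sorted(ids[i] for i in order[:n_train]))
        holdout = tuple(sorted(ids[i] for i in order[n_train:]))
        splits.append(Split(train, holdout))
    return SplitSet(splits, seed=seed, holdout_fraction=holdout_fraction)


class GuardedResponse:
    """Response labels with a holdout firewall.

    During the training phase (``locked``), requesting the label of any
    holdout sample raises :class:`LeakageError`. ``unlock()`` is called by
    :func:`evaluate_holdout` once hyperparameters are fixed.
    """

    def __init__(self, response: ResponseVector, holdout_ids) -> None:
        self._response = response
        self._holdout = frozenset(holdout_ids)
        self._locked = True

    def unlock(self) -> None:
        self._locked = False

    def labels_for(self, ids) -> pd.Series:
        ids = list(ids)
        if self._locked:
            leaked = self._holdout.intersection(ids)
            if leaked:
                raise LeakageError(
                    f"holdout labels requested before holdout phase: {sorted(leaked)[:5]}"
                )
        return self._response.classes.loc[ids]


def balanced_accuracy(confusion) -> float:
    """(sensitivity + specificity) / 2 from a 2×2 confusion matrix.

    Rows are true classes, columns predicted classes, in the same order.
    """
    C = np.asarray(confusion, dtype=float)
    if C.shape != (2, 2):
        raise ValueError("confusion matrix must be 2×2")
    row_sums = C.sum(axis=1)
    if (row_sums == 0).any():
        raise ValidationError("a true class is absent; recall undefined")
    return float(np.mean(np.diag(C) / row_sums))


def balanced_accuracy_labels(y_true, y_pred) -> float:
    """Balanced accuracy straight from label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValidationError("balanced accuracy needs both classes in truth")
    C = np.array(
        [[np.sum((y_true == t) & (y_pred == p)) for p in classes] for t in classes]
    )
    return balanced_accuracy(C)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid over thresholds, ranks, tree counts, mtry factors."""

    thresholds: tuple = (0.08,)
    ranks: tuple = ("asv",)
    n_trees: tuple = (500,)
    mtry_factors: tuple = (1,)

    def combinations(self):
        for thr in self.thresholds:
            for rank in self.ranks:
                for trees in self.n_trees:
                    for factor in self.mtry_factors:
                        yield thr, rank, trees, factor


def full_community_grid() -> GridSpec:
    """The exhaustive community grid explored in the study."""
    return GridSpec(
        thresholds=feat.DEFAULT_THRESHOLDS,
        ranks=("asv",),
        n_trees=(100, 500, 1000, 5000, 10000, 20000),
        mtry_factors=(1, 3, 5, 7, 9, 11, 13),
    )


def chosen_preset() -> GridSpec:
    """The selected operating point: 10,000 trees, mtry factor 5, 0.08%."""
    return GridSpec(thresholds=(0.08,), ranks=("genus",), n_trees=(10000,), mtry_factors=(5,))


@dataclass
class GridResult:
    """Long-format record of every (combination × split × replicate) score."""

    records: pd.DataFrame

    COLUMNS = (
        "input_set",
        "threshold",
        "rank",
        "trees",
        "mtry_factor",
        "split",
        "replicate",
        "phase",
        "balanced_accuracy",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"grid result lacks columns {sorted(missing)}")
        scores = self.records["balanced_accuracy"].dropna()
        if ((scores < 0) | (scores > 1)).any():
            raise ValidationError("balanced accuracies outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return self.records[list(self.COLUMNS)]

    def mean_by_combination(self) -> pd.DataFrame:
        return (
            self.records.groupby(["input_set", "threshold", "rank", "trees", "mtry_factor"])[
                "balanced_accuracy"
            ]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def build_input_features(
    community: CommunityTable,
    taxonomy: TaxonomyTable | None,
    threshold: float,
    rank: str,
    env: pd.DataFrame | None = None,
    input_set: str = "community",
) -> feat.FeatureMatrix:
    """Assemble one grid-cell input: threshold at ASV rank, then agglomerate.

    ``input_set`` selects community-only, sediment(environment)-only, or
    combined features.
    """
    if input_set == "sediment":
        if env is None:
            raise ValidationError("sediment input set requires environmental data")
        return feat.environment_features(env)
    table = feat.filter_by_threshold(community, threshold)
    if rank != community.rank:
        if taxonomy is None:
            raise ValidationError("agglomeration requires a taxonomy table")
        table = feat.agglomerate_rank(table, taxonomy, rank)
    fm = feat.community_features(table)
    if input_set == "combined":
        if env is None:
            raise ValidationError("combined input set requires environmental data")
        fm = feat.combine_features(fm, feat.environment_features(env))
    elif input_set != "community":
        raise ValueError(f"unknown input set {input_set!r}")
    return fm


def grid_search(
    community: CommunityTable,
    taxonomy: TaxonomyTable | None,
    response: ResponseVector,
    splits: SplitSet,
    grid: GridSpec,
    models_per_combo: int = 50,
    env: pd.DataFrame | None = None,
    input_set: str = "community",
    seed: int = 0,
) -> GridResult:
    """Grid search scored by OOB balanced accuracy on the training sets only.

    For every hyperparameter combination and split, ``models_per_combo``
    forests are trained on the training partition; holdout samples are never
    touched (enforced through :class:`GuardedResponse`).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for thr, rank, trees, factor in grid.combinations():
        fm = build_input_features(community, taxonomy, thr, rank, env, input_set)
        for s_idx, split in enumerate(splits):
            guard = GuardedResponse(response, split.holdout_ids)
            X_train = fm.subset_samples(split.train_ids)
            y_train = guard.labels_for(split.train_ids)
            for rep in range(models_per_combo):
                hp = HyperParams(trees, factor, int(rng.integers(2**31 - 1)))
                model = train_forest(X_train, y_train, hp)
                rows.append(
                    {
                        "input_set": input_set,
                        "threshold": thr,
                        "rank": rank,
                        "trees": trees,
                        "mtry_factor": factor,
                        "split": s_idx,
                        "replicate": rep,
                        "phase": "validation",
                        "balanced_accuracy": model.oob_balanced_accuracy,
                    }
                )
    return GridResult(pd.DataFrame(rows, columns=list(GridResult.COLUMNS)))


@dataclass
class HoldoutResult:
    scores: pd.Series  # per split
    mean: float
    sd: float

    def to_frame(self) -> pd.DataFrame:
        frame = self.scores.rename("balanced_accuracy").to_frame()
        frame.index.name = "split"
        return frame


def evaluate_holdout(
    features_matrix: feat.FeatureMatrix,
    response: ResponseVector,
    hp: HyperParams,
    splits: SplitSet,
) -> HoldoutResult:
    """Score fixed hyperparameters on the holdout sets, one model per split."""
    rng = np.random.default_rng(hp.seed)
    scores = {}
    for s_idx, split in enumerate(splits):
        overlap = set(split.train_ids) & set(split.holdout_ids)
        if overlap:
            raise LeakageError(f"holdout ids inside training set: {sorted(overlap)[:5]}")
        guard = GuardedResponse(response, split.holdout_ids)
        X_train = features_matrix.subset_samples(split.train_ids)
        y_train = guard.labels_for(split.train_ids)
        model = train_forest(
            X_train, y_train, HyperParams(hp.n_trees, hp.mtry_factor, int(rng.integers(2**31 - 1)))
        )
        guard.unlock()
        X_hold = features_matrix.subset_samples(split.holdout_ids)
        y_hold = guard.labels_for(split.holdout_ids)
        pred, _ = predict(model, X_hold)
        scores[s_idx] = balanced_accuracy_labels(y_hold.to_numpy(), pred.to_numpy())
    series = pd.Series(scores)
    return HoldoutResult(series, float(series.mean()), float(series.std(ddof=1)))


# ---------------------------------------------------------------------------
# input-set comparison
# ---------------------------------------------------------------------------


@dataclass
class InputSetComparison:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group1, group2, mean_diff, p_adj, significant
    alpha_adjusted: float

    def to_frame(self) -> pd.DataFrame:
        return self.pairwise


def compare_input_sets(
    score_groups: dict[str, list], alpha_adjusted: float = 0.005
) -> InputSetComparison:
    """Welch one-way ANOVA plus Tukey HSD pairwise comparisons.

    Mirrors the study's comparison of validation/holdout score distributions
    between input sets: unequal-variance ANOVA followed by Tukey's multiple
    comparisons at 95% family-wise confidence, flagged at ``alpha_adjusted``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in score_groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValidationError("need >= 2 groups with >= 2 scores each")
    if all(np.var(v) == 0 for v in groups.values()):
        raise ValidationError("all groups have zero variance")
    names = sorted(groups)
    welch = anova_oneway(
        [groups[k] for k in names], use_var="unequal", welch_correction=True
    )
    values = np.concatenate([groups[k] for k in names])
    labels = np.concatenate([[k] * len(groups[k]) for k in names])
    tukey = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group1": table["group1"].astype(str),
            "group2": table["group2"].astype(str),
            "mean_diff": table["meandiff"].astype(float),
            "p_adj": np.asarray(tukey.pvalues, dtype=float),
        }
    )
    pairwise["significant"] = pairwise["p_adj"] < alpha_adjusted
    return InputSetComparison(
        anova_f=float(welch.statistic),
        anova_p=float(welch.pvalue),
        pairwise=pairwise,
        alpha_adjusted=alpha_adjusted,
    )
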