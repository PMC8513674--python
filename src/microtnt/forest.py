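"""Random-forest engine: training, OOB prediction, proximity, importance.

The forest layer wraps scikit-learn classification forests and adds the
pieces the workflow needs on top: the "mtry factor" convention (the
square-root default for the number of candidate split variables, scaled by
an integer factor), per-sample out-of-bag (OOB) predictions with a
deterministic tie rule, the proximity matrix (fraction of trees in which
two samples share a terminal node), unsupervised classification against a
column-shuffled synthetic copy of the data, and two variable-importance
schemes with p-values:

* corrected (Janitza-style) impurity importance — a signed score obtained
  by debiasing the Gini impurity reduction with matched shadow variables
  (a column-permuted copy of every feature competes in the same forest);
  p-values come from the mirrored empirical null built from all
  non-positive scores;
* Altmann permutation importance — observed OOB permutation importance
  compared against a null distribution obtained by re-training on
  response-permuted data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix
from .io_model import ResponseVector, ValidationError

UNDEFINED = "undefined"


@dataclass(frozen=True)
class HyperParams:
    """Forest hyperparameters: tree count, mtry factor and master seed."""

    n_trees: int = 500
    mtry_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry_factor < 1:
            raise ValueError("mtry_factor must be >= 1")


def derive_mtry(n_features: int, mtry_factor: int) -> int:
    """Candidate variables per split: floor(sqrt(p)) × factor, capped at p."""
    if n_features < 1 or mtry_factor < 1:
        raise ValueError("n_features and mtry_factor must be >= 1")
    return min(math.floor(math.sqrt(n_features)) * mtry_factor, n_features)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.data
    return X


def _as_labels(y) -> pd.Series:
    if isinstance(y, ResponseVector):
        return y.classes
    return pd.Series(y)


@dataclass
class ProximityMatrix:
    """n × n co-terminal-node fractions: symmetric, unit diagonal, in [0,1]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        P = np.asarray(self.values, dtype=float)
        if P.shape[0] != P.shape[1] or P.shape[0] != len(self.sample_ids):
            raise ValidationError("proximity matrix shape mismatch")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValidationError("proximity matrix not symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-12):
            raise ValidationError("proximity diagonal must be 1")
        if P.min() < -1e-12 or P.max() > 1 + 1e-12:
            raise ValidationError("proximity entries outside [0, 1]")
        self.values = P

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class ForestModel:
    """A trained ensemble plus its OOB bookkeeping."""

    clf: RandomForestClassifier
    hp: HyperParams
    feature_names: list[str]
    classes: list[str]
    y_train: pd.Series
    oob_votes: pd.DataFrame  # samples × classes, OOB vote counts
    oob_pred: pd.Series  # majority OOB class, "undefined" if never OOB
    oob_error: float
    oob_balanced_accuracy: float

    @property
    def prevalence_order(self) -> list[str]:
        """Classes ordered by descending training prevalence, ties lexicographic."""
        counts = self.y_train.value_counts()
        return sorted(self.classes, key=lambda c: (-counts.get(c, 0), c))

    def apply(self, X) -> np.ndarray:
        frame = _as_frame(X)
        self._check_features(frame)
        return self.clf.apply(frame.to_numpy(dtype=float))

    def _check_features(self, frame: pd.DataFrame) -> None:
        if list(frame.columns) != self.feature_names:
            raise ValidationError("feature names do not match training features")


def _majority(votes: np.ndarray, classes: list[str], prevalence_order: list[str]) -> str:
    """Majority vote; ties go to the more prevalent training class."""
    top = votes.max()
    tied = [c for c, v in zip(classes, votes) if v == top]
    if len(tied) == 1:
        return tied[0]
    for c in prevalence_order:
        if c in tied:
            return c
    return sorted(tied)[0]  # pragma: no cover - prevalence_order covers classes


def balanced_accuracy_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall; requires both true classes present."""
    classes = np.unique(y_true)
    recalls = [
        np.mean(np.asarray(y_pred)[y_true == c] == c) for c in classes
    ]
    return float(np.mean(recalls))


def train_forest(X, y, hp: HyperParams) -> ForestModel:
    """Train a classification forest and populate OOB predictions.

    Trees are fully grown (Gini criterion, minimum node size 1), each on a
    bootstrap sample, with ``derive_mtry`` candidate features per split.
    Fully reproducible from ``hp.seed``.
    """
    frame = _as_frame(X)
    labels = _as_labels(y).loc[frame.index]
    if frame.isna().to_numpy().any():
        raise ValidationError("missing values in feature matrix")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("response must contain at least two classes")

    mtry = derive_mtry(frame.shape[1], hp.mtry_factor)
    clf = RandomForestClassifier(
        n_estimators=hp.n_trees,
        criterion="gini",
        max_features=mtry,
        bootstrap=True,
        min_samples_leaf=1,
        random_state=hp.seed,
        n_jobs=1,
    )
    Xv = frame.to_numpy(dtype=float)
    yv = labels.to_numpy()
    clf.fit(Xv, yv)

    n = len(frame)
    votes = np.zeros((n, len(classes)))
    class_pos = {c: i for i, c in enumerate(classes)}
    all_idx = np.arange(n)
    for est, inbag in zip(clf.estimators_, clf.estimators_samples_):
        oob_mask = ~np.isin(all_idx, inbag)
        if not oob_mask.any():
            continue
        # sub-estimators predict encoded class indices into clf.classes_
        pred = clf.classes_[est.predict(Xv[oob_mask]).astype(int)]
        rows = all_idx[oob_mask]
        for r, p in zip(rows, pred):
            votes[r, class_pos[p]] += 1

    counts = labels.value_counts()
    prevalence_order = sorted(classes, key=lambda c: (-counts.get(c, 0), c))
    preds = []
    for i in range(n):
        if votes[i].sum() == 0:
            preds.append(UNDEFINED)
        else:
            preds.append(_majority(votes[i], classes, prevalence_order))
    oob_pred = pd.Series(preds, index=frame.index)
    defined = oob_pred != UNDEFINED
    if not defined.all():
        warnings.warn(
            f"{(~defined).sum()} samples never out-of-bag; excluded from OOB error",
            stacklevel=2,
        )
    yt = labels[defined].to_numpy()
    yp = oob_pred[defined].to_numpy()
    oob_error = float(np.mean(yp != yt)) if len(yt) else float("nan")
    if len(np.unique(yt)) == len(classes):
        oob_ba = balanced_accuracy_from_labels(yt, yp)
    else:  # degenerate tiny forests
        oob_ba = float("nan")
    return ForestModel(
        clf=clf,
        hp=hp,
        feature_names=list(frame.columns),
        classes=classes,
        y_train=labels,
        oob_votes=pd.DataFrame(votes, index=frame.index, columns=classes),
        oob_pred=oob_pred,
        oob_error=oob_error,
        oob_balanced_accuracy=oob_ba,
    )


def predict(model: ForestModel, X) -> tuple[pd.Series, pd.DataFrame]:
    """Majority-vote class and per-class vote fractions for new samples."""
    frame = _as_frame(X)
    model._check_features(frame)
    Xv = frame.to_numpy(dtype=float)
    votes = np.zeros((len(frame), len(model.classes)))
    class_pos = {c: i for i, c in enumerate(model.classes)}
    for est in model.clf.estimators_:
        pred = model.clf.classes_[est.predict(Xv).astype(int)]
        for r, p in enumerate(pred):
            votes[r, class_pos[p]] += 1
    fractions = votes / votes.sum(axis=1, keepdims=True)
    order = model.prevalence_order
    labels = pd.Series(
        [_majority(v, model.classes, order) for v in votes], index=frame.index
    )
    return labels, pd.DataFrame(fractions, index=frame.index, columns=model.classes)


def proximity_matrix(model: ForestModel, X) -> ProximityMatrix:
    """P_ij = fraction of trees in which samples i and j share a terminal node."""
    frame = _as_frame(X)
    leaves = model.apply(frame)  # n × n_trees
    n, n_trees = leaves.shape
    P = np.zeros((n, n))
    for t in range(n_trees):
        col = leaves[:, t]
        P += col[:, None] == col[None, :]
    P /= n_trees
    return ProximityMatrix(P, list(frame.index))


def shuffle_columns(frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Independently permute each column, breaking inter-variable structure."""
    rng = np.random.default_rng(seed)
    shuffled = {c: rng.permutation(frame[c].to_numpy()) for c in frame.columns}
    return pd.DataFrame(shuffled, index=frame.index)


def unsupervised_forest(X, hp: HyperParams) -> tuple[ForestModel, ProximityMatrix]:
    """Unsupervised classification: real vs column-shuffled synthetic data.

    A synthetic copy of the data with every column independently permuted is
    appended; a forest learns to separate real from synthetic rows, exposing
    the intrinsic correlation structure of the real data through its
    proximity matrix (returned for the real samples only).
    """
    frame = _as_frame(X)
    if len(frame) < 2:
        raise ValidationError("need at least two samples")
    synthetic = shuffle_columns(frame, hp.seed)
    synthetic.index = [f"synthetic::{s}" for s in frame.index]
    stacked = pd.concat([frame, synthetic], axis=0)
    labels = pd.Series(
        ["real"] * len(frame) + ["synthetic"] * len(frame), index=stacked.index
    )
    model = train_forest(stacked, labels, hp)
    leaves = model.apply(stacked.iloc[: len(frame)])
    n, n_trees = leaves.shape
    P = np.zeros((n, n))
    for t in range(n_trees):
        col = leaves[:, t]
        P += col[:, None] == col[None, :]
    P /= n_trees
    return model, ProximityMatrix(P, list(frame.index))


# ---------------------------------------------------------------------------
# variable importance with p-values
# ---------------------------------------------------------------------------


@dataclass
class ImportanceResult:
    """Per-feature importance scores and p-values for one method."""

    importance: pd.Series
    p_value: pd.Series
    method: str
    n_models: int = 1

    def __post_init__(self) -> None:
        if ((self.p_value <= 0) | (self.p_value > 1)).any():
            raise ValidationError("p-values must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.importance.index,
                "importance": self.importance.to_numpy(),
                "p_value": self.p_value.reindex(self.importance.index).to_numpy(),
                "method": self.method,
            }
        ).set_index("feature")


def _impurity_importance(clf: RandomForestClassifier) -> np.ndarray:
    """Mean unnormalised impurity decrease per feature across trees."""
    total = np.zeros(clf.n_features_in_)
    for est in clf.estimators_:
        total += est.tree_.compute_feature_importances(normalize=False)
    return total / len(clf.estimators_)


def _holdout_impurity(clf: RandomForestClassifier, X_eval: np.ndarray, Y_onehot: np.ndarray) -> np.ndarray:
    """Per-feature Gini decrease of a trained forest, evaluated on new samples.

    Every split carries an orientation fitted on the training half (which
    child is enriched for which class). On the evaluation half the split
    earns the signed, size-weighted class-enrichment difference between its
    children, multiplied by that orientation: a split whose direction
    generalises scores positive, a chance split scores symmetrically around
    zero (the orientation is independent of the evaluation labels, whose
    enrichment difference is itself mean-zero under exchangeability). The
    resulting per-feature score is signed, mean-zero for uninformative
    features, and suitable for the mirrored-null p-value construction.
    """
    p = clf.n_features_in_
    imp = np.zeros(p)
    n_eval = len(X_eval)
    for est in clf.estimators_:
        tree = est.tree_
        # training-half class composition per node -> split orientation
        train_counts = tree.value[:, 0, :].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            train_p1 = train_counts[:, 1] / train_counts.sum(axis=1)
        path = est.decision_path(X_eval)  # csr: n_eval × n_nodes
        counts = np.asarray(path.T @ Y_onehot, dtype=float)
        N = counts.sum(axis=1)
        left, right, feat = tree.children_left, tree.children_right, tree.feature
        # only splits exercised by the evaluation samples are informative:
        # both children must receive at least one sample
        idx = np.flatnonzero(left != -1)
        ok = (N[left[idx]] >= 1) & (N[right[idx]] >= 1)
        internal = idx[ok]
        l, r = left[internal], right[internal]
        orientation = np.sign(train_p1[l] - train_p1[r])
        eval_diff = counts[l, 1] / N[l] - counts[r, 1] / N[r]
        weight = N[l] * N[r] / N[internal]
        np.add.at(imp, feat[internal], orientation * weight * eval_diff / n_eval)
    return imp / len(clf.estimators_)


def _stratified_halves(labels: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    half_a, half_b = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        half_a.append(idx[: len(idx) // 2])
        half_b.append(idx[len(idx) // 2 :])
    return np.concatenate(half_a), np.concatenate(half_b)


def importance_corrected_janitza(
    X, y, hp: HyperParams, m_models: int = 100
) -> ImportanceResult:
    """Signed corrected-impurity importance with mirrored-null p-values.

    Per model the samples are split into two stratified halves; a forest
    grown on each half has every split's impurity reduction re-evaluated on
    the other half (chance splits score negative), and the two directions
    are averaged. Scores are averaged over ``m_models``. Because null
    scores are symmetric around zero, the p-value null distribution can be
    built by mirroring all non-positive averaged scores:
    M = {−s : s ≤ 0} ∪ {s : s ≤ 0} and
    p = (#{M ≥ observed} + 1) / (|M| + 1).
    """
    frame = _as_frame(X)
    labels = _as_labels(y).loc[frame.index]
    p = frame.shape[1]
    if p < 1:
        raise ValidationError("need at least one feature")
    Xv = frame.to_numpy(dtype=float)
    yv = labels.to_numpy()
    classes = np.unique(yv)
    Y_onehot = (yv[:, None] == classes[None, :]).astype(float)
    rng = np.random.default_rng(hp.seed)
    mtry = derive_mtry(p, hp.mtry_factor)
    trees_per_half = max(hp.n_trees // 2, 1)
    # one fixed half-partition per run: the two halves' chance associations
    # with the response are then independent, keeping the averaged score
    # symmetric under the null (fresh partitions per model would couple
    # them and skew the average)
    idx_a, idx_b = _stratified_halves(yv, rng)
    scores = np.zeros(p)
    for _ in range(m_models):
        model_score = np.zeros(p)
        for train_idx, eval_idx in ((idx_a, idx_b), (idx_b, idx_a)):
            clf = RandomForestClassifier(
                n_estimators=trees_per_half,
                max_features=mtry,
                bootstrap=True,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(Xv[train_idx], yv[train_idx])
            model_score += _holdout_impurity(clf, Xv[eval_idx], Y_onehot[eval_idx])
        scores += model_score / 2.0
    scores /= m_models

    nonpos = scores[scores <= 0]
    if nonpos.size == 0:
        raise ValidationError(
            "no non-positive importance scores to build the null distribution; "
            "use more features or models"
        )
    null = np.concatenate([nonpos, -nonpos])
    p_values = (np.sum(null[None, :] >= scores[:, None], axis=1) + 1) / (
        null.size + 1
    )
    return ImportanceResult(
        importance=pd.Series(scores, index=frame.columns),
        p_value=pd.Series(p_values, index=frame.columns),
        method="corrected_impurity_janitza",
        n_models=m_models,
    )


def oob_permutation_importance(
    model: ForestModel, X, y, seed: int = 0
) -> np.ndarray:
    """Breiman-style permutation importance from OOB accuracy drops."""
    frame = _as_frame(X)
    labels = _as_labels(y).loc[frame.index].to_numpy()
    classes = model.clf.classes_
    encoded = np.searchsorted(classes, labels)
    Xv = frame.to_numpy(dtype=float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    trees_used = 0
    all_idx = np.arange(n)
    for est, inbag in zip(model.clf.estimators_, model.clf.estimators_samples_):
        oob_mask = ~np.isin(all_idx, inbag)
        if not oob_mask.any():
            continue
        Xo = Xv[oob_mask]
        yo = encoded[oob_mask]
        acc0 = np.mean(est.predict(Xo).astype(int) == yo)
        perm = rng.permutation(len(Xo))
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[perm]
            imp[j] += acc0 - np.mean(est.predict(Xo).astype(int) == yo)
            Xo[:, j] = saved
        trees_used += 1
    if trees_used == 0:
        raise ValidationError("no tree had out-of-bag samples")
    return imp / trees_used


def importance_permutation_altmann(
    X, y, hp: HyperParams, n_perm: int = 1000
) -> ImportanceResult:
    """Permutation importance with response-permutation p-values.

    The observed score is the OOB permutation importance of a forest trained
    on the actual labels. The per-feature null is built by re-training on
    response-permuted data ``n_perm`` times; p = (r + 1)/(n_perm + 1) where
    r counts null scores ≥ the observed one, so p can never be 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    frame = _as_frame(X)
    labels = _as_labels(y).loc[frame.index]
    rng = np.random.default_rng(hp.seed)

    model = train_forest(frame, labels, hp)
    observed = oob_permutation_importance(
        model, frame, labels, seed=int(rng.integers(2**31 - 1))
    )

    exceed = np.zeros(frame.shape[1])
    for _ in range(n_perm):
        perm_seed = int(rng.integers(2**31 - 1))
        y_perm = pd.Series(
            np.random.default_rng(perm_seed).permutation(labels.to_numpy()),
            index=labels.index,
        )
        null_model = train_forest(
            frame, y_perm, HyperParams(hp.n_trees, hp.mtry_factor, perm_seed)
        )
        null_imp = oob_permutation_importance(null_model, frame, y_perm, seed=perm_seed)
        exceed += null_imp >= observed
    p_values = (exceed + 1) / (n_perm + 1)
    return ImportanceResult(
        importance=pd.Series(observed, index=frame.columns),
        p_value=pd.Series(p_values, index=frame.columns),
        method="permutation_altmann",
        n_models=1,
    )


def select_top_features(
    imp: ImportanceResult, importance_cutoff: float, p_cutoff: float
) -> list[str]:
    """Features with importance strictly above the cutoff and p below it.

    Ordered by importance, descending; e.g. the study's fingerprint rule of
    importance > 0.25 with p < 0.01 for genera.
    """
    mask = (imp.importance > importance_cutoff) & (imp.p_value < p_cutoff)
    selected = imp.importance[mask].sort_values(ascending=False)
    return list(selected.index)
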