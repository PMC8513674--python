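"""Classification robustness: repeated-model consistency, resilience, ANN.

Robustness is read in three ways: (1) per-sample misclassification rates
over many independently seeded forests, each trained on all samples and
evaluated out-of-bag (the only leak-free reading when training uses every
sample); (2) a false-positive "resilience" summary — samples without
detectable TNT but with its transformation products (ADNTs/DANTs) are
expected to be misclassified as contaminated more often, because the
community retains the contamination fingerprint after the compound itself
dissipated; (3) a cross-algorithm check with a small feed-forward neural
network under repeated k-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .features import FeatureMatrix
from .forest import UNDEFINED, HyperParams, train_forest
from .io_model import ResponseVector, SampleTable, ValidationError


@dataclass
class ConsistencyResult:
    """Per-sample misclassification rates (%) over M repeated models."""

    table: pd.DataFrame  # columns: rate, rate_rounded, rounded, truth, majority_pred
    n_models: int

    def __post_init__(self) -> None:
        r = self.table["rate"]
        if ((r < 0) | (r > 100)).any():
            raise ValidationError("rates must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return self.table


def round_rate(rate: float) -> float:
    """Round rates outside (0.5, 99.5) to 0 / 100; leave the rest untouched."""
    if rate < 0.5:
        return 0.0
    if rate > 99.5:
        return 100.0
    return rate


def consistency_analysis(
    X, y, hp: HyperParams, m_models: int = 1000
) -> ConsistencyResult:
    """Train ``m_models`` forests on all samples; record per-sample OOB errors.

    Every model uses a distinct seed derived from ``hp.seed``. A sample's
    rate is the percentage of models whose out-of-bag prediction for it was
    wrong (models where it was never out-of-bag do not count for it).
    """
    if m_models < 2:
        raise ValueError("m_models must be >= 2")
    labels = y.classes if isinstance(y, ResponseVector) else pd.Series(y)
    frame = X.data if isinstance(X, FeatureMatrix) else X
    labels = labels.loc[frame.index]
    rng = np.random.default_rng(hp.seed)
    wrong = pd.Series(0.0, index=frame.index)
    counted = pd.Series(0.0, index=frame.index)
    pred_counts: dict[str, dict[str, int]] = {s: {} for s in frame.index}
    for _ in range(m_models):
        model = train_forest(
            frame, labels, HyperParams(hp.n_trees, hp.mtry_factor, int(rng.integers(2**31 - 1)))
        )
        defined = model.oob_pred != UNDEFINED
        counted[defined] += 1
        wrong[defined] += (model.oob_pred[defined] != labels[defined]).astype(float)
        for s, p in model.oob_pred[defined].items():
            pred_counts[s][p] = pred_counts[s].get(p, 0) + 1
    if (counted == 0).any():
        raise ValidationError("some samples never out-of-bag in any model")
    rate = 100.0 * wrong / counted
    rounded = rate.map(round_rate)
    majority = pd.Series(
        {s: max(sorted(c), key=c.get) for s, c in pred_counts.items()}
    ).reindex(frame.index)
    table = pd.DataFrame(
        {
            "rate": rate,
            "rate_rounded": rounded,
            "rounded": rate != rounded,
            "truth": labels,
            "majority_pred": majority,
        }
    )
    return ConsistencyResult(table, n_models=m_models)


@dataclass
class ResilienceSummary:
    """False-positive rates partitioned by metabolite presence."""

    per_sample: pd.DataFrame  # false positives only: rate, metabolites_present
    summary: pd.DataFrame  # per partition: n, mean/min/max rate
    rate_metabolite_correlation: float  # Spearman rho, NaN if undefined
    correlation_p: float

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def false_positive_resilience(
    cons: ConsistencyResult, samples: SampleTable
) -> ResilienceSummary:
    """Summarise false-positive rates by TNT-metabolite presence.

    Considers samples whose truth is "absent" with a nonzero false-positive
    rate, split into metabolite-positive (any ADNT/DANT > 0) and clean
    partitions. Also reports the Spearman correlation of the rate with the
    summed metabolite concentration across the false positives.
    """
    if not samples.metabolite_columns:
        raise ValidationError("sample table declares no metabolite columns")
    table = cons.table
    met_sum = samples.metabolites().sum(axis=1).reindex(table.index)
    fp = table[(table["truth"] == "absent") & (table["rate"] > 0)].copy()
    fp["metabolites_present"] = met_sum.loc[fp.index] > 0
    fp["metabolite_sum"] = met_sum.loc[fp.index]
    if fp.empty:
        empty = pd.DataFrame(
            columns=["n", "mean_rate", "min_rate", "max_rate"],
            index=pd.Index([], name="partition"),
        )
        return ResilienceSummary(fp, empty, float("nan"), float("nan"))
    summary = (
        fp.groupby(fp["metabolites_present"].map({True: "metabolites", False: "clean"}))[
            "rate"
        ]
        .agg(n="count", mean_rate="mean", min_rate="min", max_rate="max")
        .rename_axis("partition")
    )
    if fp["metabolite_sum"].nunique() > 1 and len(fp) > 2:
        rho, p = stats.spearmanr(fp["rate"], fp["metabolite_sum"])
    else:
        rho, p = float("nan"), float("nan")
    return ResilienceSummary(fp, summary, float(rho), float(p))


# ---------------------------------------------------------------------------
# ANN cross-algorithm validator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnSpec:
    """Architecture of the cross-algorithm neural-network validator.

    Two rectified-linear hidden layers (50 and 40 nodes), sigmoid output,
    binary cross-entropy loss, Adam optimizer, mini-batches of 4, at most
    100 epochs with early stopping after 2 epochs without validation
    improvement, and no regularization.
    """

    hidden: tuple[int, ...] = (50, 40)
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 2
    early_stopping: bool = True  # stop when the loss stops improving


def cv_fit_count(repeats: int, folds: int) -> int:
    """Number of validated model fits in repeated k-fold cross-validation."""
    return repeats * folds


@dataclass
class AnnResult:
    rates: pd.Series  # per-sample misclassification rate, %
    n_fits: int
    n_validations_per_sample: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rate": self.rates, "n_validations": self.n_validations_per_sample}
        )


def _fit_ann(spec: AnnSpec, X: np.ndarray, y: np.ndarray, seed: int) -> MLPClassifier:
    # loss-plateau stopping with the configured patience; sklearn's
    # validation-score early stopping fires before training has started on
    # mini-batch training of small samples
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(spec.batch_size, len(X)),
        max_iter=spec.max_epochs,
        early_stopping=False,
        n_iter_no_change=spec.patience if spec.early_stopping else spec.max_epochs,
        shuffle=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def ann_cross_validate(
    X: FeatureMatrix,
    y,
    spec: AnnSpec | None = None,
    repeats: int = 333,
    folds: int = 3,
    seed: int = 0,
) -> AnnResult:
    """Repeated unstratified k-fold cross-validation of the ANN.

    Input must be z-scored (``encode_and_scale`` output). Each repeat draws
    a fresh random partition into ``folds`` near-equal subsets; each fold is
    predicted by a network trained on the remaining folds, so every sample
    is validated once per repeat and ``repeats × folds`` models are fit in
    total.
    """
    spec = spec or AnnSpec()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not isinstance(X, FeatureMatrix) or X.scaling != "zscored":
        raise ValidationError("ANN input must be a z-scored FeatureMatrix")
    labels = y.classes if isinstance(y, ResponseVector) else pd.Series(y)
    labels = labels.loc[X.data.index]
    Xv = X.values()
    yv = labels.to_numpy()
    n = len(Xv)
    rng = np.random.default_rng(seed)
    errors = np.zeros(n)
    validations = np.zeros(n)
    n_fits = 0
    for _ in range(repeats):
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % folds
        for f in range(folds):
            val = fold_of == f
            train = ~val
            fit_seed = int(rng.integers(2**31 - 1))
            clf = _fit_ann(spec, Xv[train], yv[train], fit_seed)
            pred = clf.predict(Xv[val])
            errors[val] += pred != yv[val]
            validations[val] += 1
            n_fits += 1
    rates = pd.Series(100.0 * errors / validations, index=X.data.index)
    return AnnResult(
        rates=rates,
        n_fits=n_fits,
        n_validations_per_sample=pd.Series(validations, index=X.data.index),
    )


@dataclass
class AgreementTable:
    contingency: pd.DataFrame  # RF wrong/right × ANN wrong/right counts
    sample_lists: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        return self.contingency


def cross_algorithm_agreement(
    rf: ConsistencyResult, ann_rates: pd.Series, wrong_threshold: float = 50.0
) -> AgreementTable:
    """Contingency of misclassification between the forest and the ANN.

    A sample counts as wrongly classified by a method when its
    misclassification rate exceeds ``wrong_threshold`` percent.
    """
    rf_rates = rf.table["rate"]
    if set(rf_rates.index) != set(ann_rates.index):
        raise ValidationError("sample sets differ between RF and ANN results")
    ann_rates = ann_rates.reindex(rf_rates.index)
    rf_wrong = rf_rates > wrong_threshold
    ann_wrong = ann_rates > wrong_threshold
    cells = {
        ("rf_wrong", "ann_wrong"): rf_wrong & ann_wrong,
        ("rf_wrong", "ann_right"): rf_wrong & ~ann_wrong,
        ("rf_right", "ann_wrong"): ~rf_wrong & ann_wrong,
        ("rf_right", "ann_right"): ~rf_wrong & ~ann_wrong,
    }
    contingency = pd.DataFrame(
        [[cells[("rf_wrong", "ann_wrong")].sum(), cells[("rf_wrong", "ann_right")].sum()],
         [cells[("rf_right", "ann_wrong")].sum(), cells[("rf_right", "ann_right")].sum()]],
        index=["rf_wrong", "rf_right"],
        columns=["ann_wrong", "ann_right"],
    )
    sample_lists = {
        f"{r}/{c}": sorted(rf_rates.index[mask]) for (r, c), mask in cells.items()
    }
    return AgreementTable(contingency, sample_lists)
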