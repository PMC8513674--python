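"""Feature engineering for community and environmental model inputs.

Pipeline order matters: abundance thresholding happens at ASV rank first,
and only the surviving ASVs are agglomerated to broader taxonomic ranks.
Random forests consume raw relative abundances; only the neural-network
path requires one-hot encoding and z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import (
    RANKS,
    CommunityTable,
    TaxonomyTable,
    ValidationError,
)

#: relative-abundance threshold grid (%) explored by the grid search
DEFAULT_THRESHOLDS = (0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class FeatureMatrix:
    """Samples × features numeric matrix with per-feature provenance.

    ``origin`` tags each column as ``taxon`` or ``environmental``; ``rank``
    records the taxonomic rank of taxon columns; ``scaling`` is ``raw`` or
    ``zscored``.
    """

    data: pd.DataFrame
    origin: pd.Series | None = None
    rank: str | None = None
    scaling: str = "raw"

    def __post_init__(self) -> None:
        if self.origin is None:
            self.origin = pd.Series("taxon", index=self.data.columns)
        self.origin = self.origin.reindex(self.data.columns)
        if self.origin.isna().any():
            raise ValidationError("origin tag missing for some features")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("non-finite feature values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_features(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(
            self.data[ids], self.origin[ids], rank=self.rank, scaling=self.scaling
        )

    def subset_samples(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(
            self.data.loc[ids], self.origin, rank=self.rank, scaling=self.scaling
        )


def community_features(community: CommunityTable) -> FeatureMatrix:
    """View a (percent) community table as a model-input feature matrix."""
    return FeatureMatrix(
        community.data.copy(),
        pd.Series("taxon", index=community.data.columns),
        rank=community.rank,
    )


def environment_features(env: pd.DataFrame) -> FeatureMatrix:
    return FeatureMatrix(
        env.astype(float), pd.Series("environmental", index=env.columns)
    )


def to_relative_abundance(community: CommunityTable) -> CommunityTable:
    """Convert counts to per-sample relative abundance in percent."""
    if community.unit == "percent":
        return community
    counts = community.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = community.data.index[totals <= 0].tolist()
        raise ValidationError(f"zero-sum sample rows: {bad}")
    rel = pd.DataFrame(
        100.0 * counts / totals[:, None],
        index=community.data.index,
        columns=community.data.columns,
    )
    return CommunityTable(rel, unit="percent", rank=community.rank)


def filter_by_threshold(
    community: CommunityTable, threshold_pct: float
) -> CommunityTable:
    """Keep features exceeding ``threshold_pct`` in at least one sample.

    The comparison is strict; surviving features are left unchanged (no
    renormalisation), so row sums may drop below 100 after filtering.
    """
    if threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    if community.unit != "percent":
        raise ValidationError("threshold filtering requires percent units")
    maxima = community.data.max(axis=0)
    kept = maxima.index[maxima > threshold_pct]
    return CommunityTable._unchecked(
        community.data[list(kept)], community.unit, community.rank
    )


def agglomerate_rank(
    community: CommunityTable, taxonomy: TaxonomyTable, rank: str
) -> CommunityTable:
    """Sum ASV abundances into taxa at ``rank`` (genus..phylum).

    ASVs lacking a label at ``rank`` are grouped under
    ``unclassified <deepest available parent>``; per-sample total abundance
    is conserved.
    """
    rank_name = rank.capitalize()
    if rank_name not in RANKS or rank_name == "Kingdom":
        raise ValueError(f"unknown agglomeration rank {rank!r}")
    # group by the full lineage prefix down to `rank` so same-named taxa in
    # different parents stay distinct; \x1f never occurs in taxon labels
    sep = "\x1f"
    labels = {}
    for fid in community.feature_ids:
        lineage = taxonomy.lineage(fid)
        depth = RANKS.index(rank_name)
        prefix = lineage[: depth + 1]
        labels[fid] = sep.join(prefix) + sep * 2 + taxonomy.label_at(fid, rank)
    grouped = community.data.T.groupby(
        pd.Series(labels).reindex(community.feature_ids)
    ).sum().T
    pretty = {key: key.rsplit(sep, 1)[1] for key in grouped.columns}
    # disambiguate label collisions across different lineages
    seen: dict[str, int] = {}
    renamed = {}
    for key in sorted(grouped.columns):
        name = pretty[key]
        if name in seen:
            seen[name] += 1
            renamed[key] = f"{name} ({seen[name]})"
        else:
            seen[name] = 0
            renamed[key] = name
    grouped = grouped.rename(columns=renamed)
    return CommunityTable._unchecked(
        grouped.sort_index(axis=1), community.unit, rank.lower()
    )


def remove_control_features(
    community: CommunityTable,
    control_sample_ids,
    max_control_reads: int = 35,
    exemptions=(),
) -> CommunityTable:
    """Drop features exceeding ``max_control_reads`` in any negative control.

    Control samples themselves are removed from the output. Features on the
    exemption list are kept regardless of their control read counts.
    """
    controls = list(control_sample_ids)
    missing = set(controls) - set(community.sample_ids)
    if missing:
        raise ValidationError(f"control samples absent from table: {sorted(missing)}")
    exempt = set(exemptions)
    if controls:
        control_max = community.data.loc[controls].max(axis=0)
        contaminated = set(control_max.index[control_max > max_control_reads])
    else:
        contaminated = set()
    keep_features = [
        f for f in community.feature_ids if f not in contaminated or f in exempt
    ]
    keep_samples = [s for s in community.sample_ids if s not in set(controls)]
    return CommunityTable(
        community.data.loc[keep_samples, keep_features],
        unit=community.unit,
        rank=community.rank,
    )


def combine_features(
    community: FeatureMatrix, environment: FeatureMatrix
) -> FeatureMatrix:
    """Column-concatenate community and environmental blocks."""
    if set(community.sample_ids) != set(environment.sample_ids):
        raise ValidationError("sample sets differ between feature blocks")
    env = environment.subset_samples(community.sample_ids)
    collisions = set(community.feature_ids) & set(env.feature_ids)
    if collisions:
        raise ValidationError(f"feature name collisions: {sorted(collisions)}")
    data = pd.concat([community.data, env.data], axis=1)
    origin = pd.concat([community.origin, env.origin])
    return FeatureMatrix(data, origin, rank=community.rank, scaling="raw")


def encode_and_scale(
    features: FeatureMatrix | pd.DataFrame, categorical_columns=()
) -> FeatureMatrix:
    """One-hot encode categoricals and z-score numeric columns.

    Z-scoring uses the population standard deviation (divide by n); constant
    columns are left at 0 with a warning. The result's ``scaling`` state is
    ``zscored``, the contract required by the neural-network validator.
    """
    if isinstance(features, FeatureMatrix):
        frame = features.data.copy()
        origin = features.origin.copy()
        rank = features.rank
    else:
        frame = features.copy()
        origin = pd.Series("environmental", index=frame.columns)
        rank = None

    categorical = list(categorical_columns)
    unknown = set(categorical) - set(frame.columns)
    if unknown:
        raise ValidationError(f"unknown categorical columns: {sorted(unknown)}")

    blocks, origins = [], []
    for col in frame.columns:
        if col in categorical:
            dummies = pd.get_dummies(frame[col], prefix=col).astype(float)
            blocks.append(dummies)
            origins.append(pd.Series(origin[col], index=dummies.columns))
        else:
            vals = frame[col].astype(float)
            sd = vals.std(ddof=0)
            if sd == 0:
                warnings.warn(f"constant column {col!r} left at 0", stacklevel=2)
                scaled = vals * 0.0
            else:
                scaled = (vals - vals.mean()) / sd
            blocks.append(scaled.to_frame())
            origins.append(pd.Series(origin[col], index=[col]))
    return FeatureMatrix(
        pd.concat(blocks, axis=1),
        pd.concat(origins),
        rank=rank,
        scaling="zscored",
    )
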