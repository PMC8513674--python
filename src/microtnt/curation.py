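"""Sample curation: replicate averaging, exclusion guideline, binarization.

Small field datasets contain contextual subsets (same cruise, experiment and
sampling area, stations metres apart) whose samples are more similar to each
other than to the rest of the data. When such a subset also carries only one
contamination class, a classifier can learn the subset instead of the
contamination signal. The exclusion guideline removes all but one
representative from every such subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    CommunityTable,
    ResponseVector,
    SampleTable,
    ValidationError,
)

EARTH_RADIUS_M = 6_371_000.0  # mean Earth radius, WGS84 sphere approximation

#: TNT detection limit in pmol per g wet sediment (0.01 ng·g⁻¹ at M = 227.13)
DETECTION_LIMIT_PMOL_G = 0.044

TNT_MOLAR_MASS_G_MOL = 227.13


@dataclass
class GuidelineParams:
    """Parameters of the subset-exclusion guideline.

    distance_threshold_m:
        Samples count as co-located when every pairwise horizontal distance
        within the subset is below this many metres.
    imbalance_rule:
        A subset is "strongly imbalanced" when its minority class has at
        most this many samples.
    retain_per_subset:
        How many representatives of a flagged subset to keep.
    """

    distance_threshold_m: float = 20.0
    imbalance_rule: int = 1
    retain_per_subset: int = 1

    def __post_init__(self) -> None:
        if self.distance_threshold_m <= 0:
            raise ValueError("distance_threshold_m must be positive")
        if self.retain_per_subset < 1:
            raise ValueError("retain_per_subset must be >= 1")


@dataclass
class CurationReport:
    kept_ids: list[str]
    removed_ids: list[str]
    rationale: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "status": "kept"} for s in self.kept_ids
        ] + [{"sample_id": s, "status": "removed"} for s in self.removed_ids]
        return pd.DataFrame(rows).set_index("sample_id").sort_index()


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on a spherical Earth."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def average_replicates(
    community: CommunityTable, samples: SampleTable
) -> CommunityTable:
    """Collapse technical-replicate libraries into one row per sediment.

    Each library is first converted to relative abundance (%) so unequal
    sequencing depths do not weight the mean; the replicate group's rows are
    then averaged arithmetically. Output rows sum to 100%.
    """
    if "replicate_group" not in samples.data.columns:
        raise ValidationError("sample table lacks 'replicate_group'")
    groups = samples.data.loc[community.sample_ids, "replicate_group"]
    counts = community.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = groups[zero].unique().tolist()
        raise ValidationError(f"replicate group(s) with zero total reads: {bad}")
    percent = pd.DataFrame(
        100.0 * counts / totals[:, None],
        index=community.data.index,
        columns=community.data.columns,
    )
    averaged = percent.groupby(groups).mean()
    averaged.index = averaged.index.astype(str)
    return CommunityTable(averaged.sort_index(), unit="percent", rank=community.rank)


def apply_exclusion_guideline(
    samples: SampleTable,
    response: ResponseVector,
    params: GuidelineParams | None = None,
) -> CurationReport:
    """Flag co-located single-class (or strongly imbalanced) subsets.

    A subset of samples is flagged iff all of the following hold: same
    cruise, same experiment, same area, all pairwise horizontal distances
    below the threshold, and either only one response class is present or
    the minority class has at most ``imbalance_rule`` members. From each
    flagged subset all but ``retain_per_subset`` samples are removed; the
    lowest sample ids are kept (deterministic).
    """
    params = params or GuidelineParams()
    frame = samples.data
    for col in ("cruise", "experiment", "area", "lat", "lon"):
        if col not in frame.columns:
            raise ValidationError(f"sample table lacks {col!r}")

    removed: list[str] = []
    rationale: list[dict] = []
    for (cruise, experiment, area), sub in frame.groupby(
        ["cruise", "experiment", "area"], sort=True
    ):
        ids = sorted(sub.index)
        lat = pd.to_numeric(sub.loc[ids, "lat"], errors="coerce")
        lon = pd.to_numeric(sub.loc[ids, "lon"], errors="coerce")
        located = [s for s in ids if np.isfinite(lat[s]) and np.isfinite(lon[s])]
        if len(located) < len(ids):
            warnings.warn(
                f"samples without coordinates excluded from distance grouping: "
                f"{sorted(set(ids) - set(located))}",
                stacklevel=2,
            )
        if len(located) < 2:
            continue
        la, lo = lat[located].to_numpy(), lon[located].to_numpy()
        dist = haversine_m(la[:, None], lo[:, None], la[None, :], lo[None, :])
        colocated = bool((dist < params.distance_threshold_m).all())
        classes = response.classes.loc[located]
        n_minority = classes.value_counts().min() if classes.nunique() > 1 else 0
        single_class = classes.nunique() == 1
        imbalanced = (not single_class) and n_minority <= params.imbalance_rule
        flagged = colocated and (single_class or imbalanced)
        rationale.append(
            {
                "cruise": cruise,
                "experiment": experiment,
                "area": area,
                "n_samples": len(located),
                "colocated": colocated,
                "single_class": single_class,
                "strong_imbalance": imbalanced,
                "flagged": flagged,
            }
        )
        if flagged:
            removed.extend(located[params.retain_per_subset :])

    kept = sorted(set(frame.index) - set(removed))
    return CurationReport(kept_ids=kept, removed_ids=sorted(removed), rationale=rationale)


def binarize_response(
    samples: SampleTable, detection_limit_pmol_g: float = DETECTION_LIMIT_PMOL_G
) -> ResponseVector:
    """Binary TNT status: absent iff concentration strictly below the limit."""
    if "tnt_pmol_g" not in samples.data.columns:
        raise ValidationError("sample table lacks 'tnt_pmol_g'")
    conc = pd.to_numeric(samples.data["tnt_pmol_g"], errors="coerce")
    if conc.isna().any():
        raise ValidationError("non-numeric TNT concentration")
    if (conc < 0).any():
        raise ValidationError("negative TNT concentration")
    classes = pd.Series(
        np.where(conc < detection_limit_pmol_g, "absent", "present"),
        index=conc.index,
    )
    return ResponseVector(classes, conc, detection_limit_pmol_g)


def ng_per_g_to_pmol_per_g(value_ng_g: float, molar_mass_g_mol: float) -> float:
    """Convert ng·g⁻¹ to pmol·g⁻¹ given the compound's molar mass."""
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    return value_ng_g / molar_mass_g_mol * 1000.0
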