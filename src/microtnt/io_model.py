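"""Domain types and readers/writers for community, taxonomy and sample tables.

The canonical interchange format is TSV (UTF-8, header row, ``.`` decimal
separator). BIOM 2.1 (HDF5) and the classic JSON dialect are supported for
community tables. All tables are indexed by string identifiers; row order is
never semantically meaningful and loading canonicalises it by sorting.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

#: taxonomic ranks from broadest to finest, as used in lineage tables
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")

#: ranks at which a community table's features may live
FEATURE_RANKS = ("asv", "genus", "family", "order", "class", "phylum")

SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """A table violates a structural invariant (duplicate ids, negative values...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CommunityTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and feature ids (ASVs or taxon
        labels) as columns; non-negative reads or relative abundances.
    unit:
        ``"counts"`` for raw reads, ``"percent"`` for relative abundance
        (each row sums to 100).
    rank:
        Taxonomic rank of the features, one of :data:`FEATURE_RANKS`.
    """

    data: pd.DataFrame
    unit: str = "counts"
    rank: str = "asv"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "percent"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.rank not in FEATURE_RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValidationError("negative abundance entries")
        if self.unit == "percent" and self.data.shape[1] > 0:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-6):
                bad = self.data.index[~np.isclose(sums, 100.0, atol=1e-6)]
                raise ValidationError(
                    f"percent rows must sum to 100: {list(bad[:5])}"
                )

    @classmethod
    def _unchecked(cls, data: pd.DataFrame, unit: str, rank: str) -> "CommunityTable":
        # thresholding removes abundance mass, so filtered percent tables
        # legitimately violate the row-sum-100 invariant checked above
        obj = cls.__new__(cls)
        obj.data = data
        obj.unit = unit
        obj.rank = rank
        return obj

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def sorted(self) -> "CommunityTable":
        """Canonical form: rows and columns sorted by id."""
        return CommunityTable._unchecked(
            self.data.sort_index(axis=0).sort_index(axis=1), self.unit, self.rank
        )


@dataclass
class TaxonomyTable:
    """Feature id → taxonomic lineage (Kingdom..Genus; missing ranks empty)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table lacks rank columns {missing}")
        _check_unique(self.data.index, "taxonomy feature ids")
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return tuple(self.data.loc[feature_id, list(RANKS)])

    def label_at(self, feature_id: str, rank: str) -> str:
        """Taxon label at ``rank``; ``unclassified <deepest parent>`` if missing."""
        rank_name = rank.capitalize()
        if rank_name not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        lineage = self.lineage(feature_id)
        depth = RANKS.index(rank_name)
        label = lineage[depth]
        if label:
            return label
        for parent in lineage[depth - 1 :: -1]:
            if parent:
                return f"unclassified {parent}"
        return "unclassified"


@dataclass
class SampleTable:
    """Per-sample metadata: contaminant concentrations, covariates, grouping.

    ``data`` is indexed by sample id. Recognised columns: ``tnt_pmol_g``,
    ``cruise``, ``experiment``, ``area``, ``lat``, ``lon``, ``date``,
    ``replicate_group``; metabolite concentrations and environmental
    covariates are declared through ``metabolite_columns`` / ``env_columns``.
    """

    data: pd.DataFrame
    env_columns: list[str] = field(default_factory=list)
    metabolite_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        for col in ("tnt_pmol_g", *self.metabolite_columns):
            if col in self.data.columns:
                vals = pd.to_numeric(self.data[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"negative concentrations in {col!r}")
        if "lat" in self.data.columns:
            lat = pd.to_numeric(self.data["lat"], errors="coerce").dropna()
            if ((lat < -90) | (lat > 90)).any():
                raise ValidationError("latitude outside [-90, 90]")
        if "lon" in self.data.columns:
            lon = pd.to_numeric(self.data["lon"], errors="coerce").dropna()
            if ((lon < -180) | (lon > 180)).any():
                raise ValidationError("longitude outside [-180, 180]")
        unknown_env = [c for c in self.env_columns if c not in self.data.columns]
        if unknown_env:
            raise ValidationError(f"declared env columns missing: {unknown_env}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def env(self) -> pd.DataFrame:
        """Numeric environmental covariate block (samples × variables)."""
        return self.data[self.env_columns].astype(float)

    def metabolites(self) -> pd.DataFrame:
        return self.data[self.metabolite_columns].astype(float)


@dataclass
class ResponseVector:
    """Binary contamination status per sample, keeping the concentration.

    ``classes`` maps sample id to ``"present"``/``"absent"``;
    ``concentration`` retains the underlying value (pmol·g⁻¹ wet sediment).
    """

    classes: pd.Series
    concentration: pd.Series
    detection_limit: float

    def __post_init__(self) -> None:
        _check_unique(self.classes.index, "response sample ids")
        bad = set(self.classes.unique()) - {"present", "absent"}
        if bad:
            raise ValidationError(f"unknown response classes {bad}")
        expected = np.where(
            self.concentration < self.detection_limit, "absent", "present"
        )
        if not (self.classes.to_numpy() == expected).all():
            raise ValidationError(
                "class labels inconsistent with concentrations and detection limit"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.classes.index)

    def subset(self, ids: Iterable[str]) -> "ResponseVector":
        ids = list(ids)
        return ResponseVector(
            self.classes.loc[ids], self.concentration.loc[ids], self.detection_limit
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, what: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{what} table {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate ids in {what} table {path}: {dups}")
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return frame


def read_community_tsv(path: str | Path, unit: str = "counts", rank: str = "asv") -> CommunityTable:
    """Read a samples × features TSV (first column = sample id)."""
    frame = _read_tsv(Path(path), "community")
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        line = frame[non_numeric[0]].map(lambda v: not _is_number(v)).idxmax()
        raise ParseError(
            f"community table {path}: non-numeric value in column "
            f"{non_numeric[0]!r}, row {line!r}"
        )
    return CommunityTable(frame, unit=unit, rank=rank).sorted()


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_taxonomy_tsv(path: str | Path) -> TaxonomyTable:
    frame = _read_tsv(Path(path), "taxonomy")
    return TaxonomyTable(frame.sort_index())


def read_samples_tsv(
    path: str | Path,
    env_columns: list[str] | None = None,
    metabolite_columns: list[str] | None = None,
) -> SampleTable:
    frame = _read_tsv(Path(path), "sample")
    env_cols = env_columns
    if env_cols is None:
        env_cols = [c for c in frame.columns if c.startswith("env_")]
    met_cols = metabolite_columns
    if met_cols is None:
        met_cols = [c for c in frame.columns if c.startswith("met_")]
    return SampleTable(frame.sort_index(), env_columns=env_cols, metabolite_columns=met_cols)


def load_dataset(
    community_path: str | Path,
    taxonomy_path: str | Path,
    samples_path: str | Path,
    format: str = "tsv",
    unit: str = "counts",
) -> tuple[CommunityTable, TaxonomyTable, SampleTable]:
    """Load and align the three canonical input tables.

    Community sample ids must be a subset of the sample-table ids; features
    without a taxonomy entry receive an all-missing lineage with a warning.
    """
    if format == "tsv":
        community = read_community_tsv(community_path, unit=unit)
    elif format == "biom":
        community = read_biom(community_path, unit=unit)
    else:
        raise ValueError(f"unknown format {format!r}")
    taxonomy = read_taxonomy_tsv(taxonomy_path)
    samples = read_samples_tsv(samples_path)

    missing_samples = set(community.sample_ids) - set(samples.sample_ids)
    if missing_samples:
        raise ValidationError(
            f"community samples absent from sample table: {sorted(missing_samples)}"
        )
    missing_tax = [f for f in community.feature_ids if f not in taxonomy.data.index]
    if missing_tax:
        warnings.warn(
            f"{len(missing_tax)} features lack taxonomy; assigned empty lineage",
            stacklevel=2,
        )
        filler = pd.DataFrame("", index=missing_tax, columns=list(RANKS))
        taxonomy = TaxonomyTable(pd.concat([taxonomy.data, filler]).sort_index())
    samples = SampleTable(
        samples.data.loc[sorted(samples.sample_ids)],
        env_columns=samples.env_columns,
        metabolite_columns=samples.metabolite_columns,
    )
    return community, taxonomy, samples


def write_community_tsv(table: CommunityTable, path: str | Path) -> Path:
    path = Path(path)
    table.sorted().data.to_csv(path, sep="\t", index_label="sample_id")
    return path


# -- BIOM -------------------------------------------------------------------
# Minimal BIOM 2.1 (HDF5) and classic JSON support written against the
# published schema; only dense community matrices are exchanged here.


def write_biom(table: CommunityTable, path: str | Path) -> Path:
    """Write a BIOM 2.1 (HDF5) file. Observations = features, columns = samples."""
    from scipy import sparse

    path = Path(path)
    table = table.sorted()
    mat = sparse.csr_matrix(table.data.to_numpy(dtype=float).T)  # obs × samples
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = "http://biom-format.org"
        fh.attrs["format-version"] = (2, 1)
        fh.attrs["generated-by"] = "microtnt"
        fh.attrs["creation-date"] = datetime.datetime.now().isoformat()
        fh.attrs["shape"] = mat.shape
        fh.attrs["nnz"] = mat.nnz
        str_dt = h5py.string_dtype("utf-8")
        obs = fh.create_group("observation")
        obs.create_dataset("ids", data=np.array(table.feature_ids, dtype=str_dt))
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data)
        om.create_dataset("indices", data=mat.indices.astype(np.int64))
        om.create_dataset("indptr", data=mat.indptr.astype(np.int64))
        obs.create_group("metadata")
        obs.create_group("group-metadata")
        smp = fh.create_group("sample")
        smp.create_dataset("ids", data=np.array(table.sample_ids, dtype=str_dt))
        csc = mat.tocsc()
        sm = smp.create_group("matrix")
        sm.create_dataset("data", data=csc.data)
        sm.create_dataset("indices", data=csc.indices.astype(np.int64))
        sm.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        smp.create_group("metadata")
        smp.create_group("group-metadata")
    return path


def read_biom(path: str | Path, unit: str = "counts", rank: str = "asv") -> CommunityTable:
    """Read a BIOM file (2.1 HDF5, or classic 1.0 JSON)."""
    from scipy import sparse

    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            try:
                feature_ids = [s.decode() if isinstance(s, bytes) else s for s in fh["observation/ids"][:]]
                sample_ids = [s.decode() if isinstance(s, bytes) else s for s in fh["sample/ids"][:]]
                mat = sparse.csr_matrix(
                    (
                        fh["observation/matrix/data"][:],
                        fh["observation/matrix/indices"][:],
                        fh["observation/matrix/indptr"][:],
                    ),
                    shape=(len(feature_ids), len(sample_ids)),
                )
            except KeyError as exc:
                raise ParseError(f"BIOM file {path}: missing dataset {exc}") from exc
        frame = pd.DataFrame(
            mat.toarray().T, index=sample_ids, columns=feature_ids
        )
    else:
        doc = json.loads(Path(path).read_text())
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        dense = np.zeros((len(feature_ids), len(sample_ids)))
        if doc.get("matrix_type") == "dense":
            dense = np.asarray(doc["data"], dtype=float)
        else:
            for i, j, v in doc["data"]:
                dense[int(i), int(j)] = v
        frame = pd.DataFrame(dense.T, index=sample_ids, columns=feature_ids)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CommunityTable(frame, unit=unit, rank=rank).sorted()


# -- result export ----------------------------------------------------------


def export_results(artifact, path: str | Path, format: str = "tsv") -> Path:
    """Serialise a result artifact deterministically.

    DataFrames (and objects exposing ``to_frame()``) are written as TSV with
    sorted row order preserved as given; mappings are written as JSON with
    sorted keys and a ``schema_version`` field. Round-tripping reproduces
    integers bitwise and floats to 1e-12.
    """
    path = Path(path)
    if hasattr(artifact, "to_frame") and not isinstance(artifact, (pd.Series, pd.DataFrame)):
        artifact = artifact.to_frame()
    if isinstance(artifact, pd.Series):
        artifact = artifact.to_frame()
    if isinstance(artifact, pd.DataFrame):
        if format == "tsv":
            artifact.to_csv(path, sep="\t", index=True, float_format="%.17g")
        elif format == "json":
            payload = {
                "schema_version": SCHEMA_VERSION,
                "columns": list(map(str, artifact.columns)),
                "index": list(map(str, artifact.index)),
                "data": artifact.to_numpy().tolist(),
            }
            path.write_text(json.dumps(payload, sort_keys=True, indent=1))
        else:
            raise ValueError(f"unknown format {format!r}")
    elif isinstance(artifact, Mapping):
        payload = {"schema_version": SCHEMA_VERSION, **artifact}
        path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=float))
    else:
        raise TypeError(f"cannot serialise {type(artifact).__name__}")
    return path
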