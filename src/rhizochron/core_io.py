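"""Data containers, readers/writers, normalization and prevalence filtering.

The central container is :class:`OtuTable`, a thin wrapper around a pandas
DataFrame oriented OTUs × samples, carrying a ``unit`` tag that is either
``"raw_counts"`` (non-negative integers) or ``"per_mille"`` (relative
abundance scaled so every sample column sums to 1000).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
PER_MILLE = "per_mille"

COMPARTMENT_POSITIONS = {
    "bulk_soil": 0,
    "rhizosphere": 1,
    "rhizoplane": 2,
    "endosphere": 3,
}

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus"}

REQUIRED_METADATA_COLUMNS = (
    "sample_id", "site", "season", "compartment", "position", "age_days",
    "genotype", "dev_stage", "treatment", "soil", "sequencing_run",
)


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass
class OtuTable:
    """OTU abundance matrix, rows = OTUs, columns = samples.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix indexed by OTU id with sample-id columns.
    unit : str
        ``"raw_counts"`` or ``"per_mille"``.
    """

    data: pd.DataFrame
    unit: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.unit not in (RAW_COUNTS, PER_MILLE):
            raise OtuTableError(f"unknown unit {self.unit!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise OtuTableError(f"duplicate otu_ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise OtuTableError(f"duplicate sample_ids: {dups}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise OtuTableError("negative abundance values")
        if self.unit == RAW_COUNTS and vals.size:
            if not np.allclose(vals, np.round(vals)):
                raise OtuTableError("raw_counts unit requires integer values")
        if self.unit == PER_MILLE and vals.size:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1000.0, atol=1e-6):
                bad = self.data.columns[~np.isclose(sums, 1000.0, atol=1e-6)]
                raise OtuTableError(
                    f"per_mille columns must sum to 1000; offending samples: "
                    f"{list(bad[:5])}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[:, list(sample_ids)], unit=self.unit)

    def select_otus(self, otu_ids) -> "OtuTable":
        """Row subset.  For per-mille tables the result is a
        subcomposition whose columns may sum to less than 1000, so the
        column-sum invariant is not re-checked."""
        sub = self.data.loc[list(otu_ids)]
        if self.unit == PER_MILLE:
            obj = object.__new__(OtuTable)
            obj.data = sub.astype(float)
            obj.unit = PER_MILLE
            return obj
        return OtuTable(sub, unit=self.unit)

    def copy(self) -> "OtuTable":
        return OtuTable(self.data.copy(), unit=self.unit)


@dataclass
class TaxonomyTable:
    """otu_id → ranked lineage parsed from Greengenes-style strings."""

    data: pd.DataFrame  # index otu_id, columns RANKS

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise OtuTableError("duplicate otu_ids in taxonomy")
        for r in RANKS:
            if r not in self.data.columns:
                raise OtuTableError(f"taxonomy missing rank column {r!r}")

    def lineage(self, otu_id: str) -> dict:
        return self.data.loc[otu_id].to_dict()


def parse_greengenes(lineage: str) -> dict:
    """Parse ``k__Bacteria; p__Proteobacteria; ...`` into a rank dict.

    Missing or empty ranks become ``"unassigned"``.
    """
    out = {r: "unassigned" for r in RANKS}
    for piece in str(lineage).split(";"):
        piece = piece.strip()
        if "__" not in piece:
            continue
        prefix, _, name = piece.partition("__")
        rank = _RANK_PREFIX.get(prefix.strip().lower())
        if rank is not None and name.strip():
            out[rank] = name.strip()
    return out


def read_taxonomy(path) -> TaxonomyTable:
    """Read a two-column tsv (otu_id, greengenes lineage string)."""
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise OtuTableError(f"{path}: expected two columns (otu_id, lineage)")
    otu_col, lin_col = raw.columns[:2]
    rows = {row[otu_col]: parse_greengenes(row[lin_col])
            for _, row in raw.iterrows()}
    data = pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]
    return TaxonomyTable(data)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    parts = []
    prefix = {v: k for k, v in _RANK_PREFIX.items()}
    for otu_id, row in taxonomy.data.iterrows():
        lineage = "; ".join(
            f"{prefix[r]}__{'' if row[r] == 'unassigned' else row[r]}"
            for r in RANKS)
        parts.append((otu_id, lineage))
    pd.DataFrame(parts, columns=["otu_id", "lineage"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table (rows = OTUs, columns = samples).

    ``format="tsv"``: first column holds OTU ids, header row sample ids.
    ``format="biom"``: BIOM 1.0 JSON, dense or sparse matrix_type.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise OtuTableError(f"{path}: empty OTU table file") from exc
    if df.shape[1] == 0:
        raise OtuTableError(f"{path}: no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise OtuTableError(
                f"{path}: non-numeric value at OTU {row!r}, sample {col!r}")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        i, j = np.argwhere(df.to_numpy() < 0)[0]
        raise OtuTableError(
            f"{path}: negative value at OTU {df.index[i]!r}, "
            f"sample {df.columns[j]!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df, unit=RAW_COUNTS)


def _read_biom_json(path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    return OtuTable(df, unit=RAW_COUNTS)


def write_otu_table(table: OtuTable, path) -> None:
    out = table.data.copy()
    if table.unit == RAW_COUNTS:
        out = out.astype(int)
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata tsv and validate the design columns."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(md)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    md = md.copy()
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise OtuTableError(f"metadata missing columns: {missing}")
    if md["sample_id"].duplicated().any():
        raise OtuTableError("duplicate sample_ids in metadata")
    expected = md["compartment"].map(COMPARTMENT_POSITIONS)
    if expected.isna().any():
        bad = md.loc[expected.isna(), "compartment"].unique().tolist()
        raise OtuTableError(f"unknown compartments: {bad}")
    if not (md["position"].astype(int) == expected).all():
        raise OtuTableError("position code inconsistent with compartment "
                            "(bulk_soil=0, rhizosphere=1, rhizoplane=2, "
                            "endosphere=3)")
    stage = pd.to_numeric(md["dev_stage"], errors="coerce")
    ok = stage.isna() | ((stage >= 1) & (stage <= 27))
    if not ok.all():
        raise OtuTableError("dev_stage outside [1, 27]")
    if (pd.to_numeric(md["age_days"]) <= 0).any():
        raise OtuTableError("age_days must be positive")
    return md.set_index("sample_id", drop=False)


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization / filtering / aggregation
# ---------------------------------------------------------------------------

def normalize_per_mille(table: OtuTable) -> OtuTable:
    """Convert raw counts to per-mille relative abundance.

    Each count is divided by its sample's total depth and multiplied by
    1000, so every column of the result sums to 1000.
    """
    if table.unit != RAW_COUNTS:
        raise OtuTableError("normalize_per_mille expects raw counts")
    depths = table.data.sum(axis=0)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0].tolist()
        raise OtuTableError(f"all-zero sample columns: {bad}")
    return OtuTable(table.data.div(depths, axis=1) * 1000.0, unit=PER_MILLE)


def filter_prevalence(table: OtuTable, min_fraction: float = 0.05,
                      ) -> tuple[OtuTable, int]:
    """Drop OTUs observed in fewer than ``min_fraction`` of samples.

    Presence means abundance > 0. An OTU is retained iff its prevalence
    fraction is >= ``min_fraction`` (removal is strictly-less-than).
    Returns the filtered table and the number of removed OTUs.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    prevalence = (table.data > 0).sum(axis=1) / table.n_samples
    keep = prevalence >= min_fraction
    removed = int((~keep).sum())
    if not keep.any():
        warnings.warn("prevalence filter removed every OTU")
    return OtuTable(table.data.loc[keep], unit=table.unit), removed


def aggregate_taxonomy(table: OtuTable, taxonomy: TaxonomyTable,
                       rank: str = "phylum",
                       split_proteobacteria: bool = False) -> OtuTable:
    """Sum per-mille abundances of OTUs sharing a taxon at ``rank``.

    With ``split_proteobacteria`` and ``rank="phylum"``, Proteobacteria
    OTUs are grouped by class instead, so no row is named Proteobacteria.
    Unassigned taxa collapse into ``unclassified_<rank>`` so per-sample
    totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = set(table.otu_ids) - set(taxonomy.data.index)
    if missing:
        raise OtuTableError(
            f"OTUs absent from taxonomy: {sorted(missing)[:5]}")
    tax = taxonomy.data.loc[table.otu_ids]
    labels = tax[rank].copy()
    if split_proteobacteria and rank == "phylum":
        is_proteo = labels == "Proteobacteria"
        cls = tax.loc[is_proteo, "class"]
        labels.loc[is_proteo] = cls.where(
            cls != "unassigned", "unclassified_Proteobacteria")
    labels = labels.where(labels != "unassigned", f"unclassified_{rank}")
    agg = table.data.groupby(labels.values).sum()
    agg.index = agg.index.astype(str)
    return OtuTable(agg, unit=table.unit)
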