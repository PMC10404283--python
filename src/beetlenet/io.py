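"""Core data containers and tabular/graph I/O.

The pipeline works on long-format survey tables (one row per sample ×
species observation, with an abundance count and a biomass measurement),
species metadata (ecological and functional group memberships) and sample
metadata (region, lake, habitat ranks and optional continuous covariates).
The wide samples × species matrix used by the correlation machinery is an
explicit pivot with absences encoded as 0 — correlation analysis needs
complete matrices, so a missing cell is always a true zero, never NA.

Identifiers are opaque strings: no taxonomic normalisation is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SurveyFormatError, ValidationError

SURVEY_COLUMNS = ("sample_id", "species_id", "count", "biomass")

ECOLOGICAL_GROUPS = ("eurytope", "tyrphophile", "argilophile", "potamophile")
FUNCTIONAL_GROUPS = ("predator", "shredder", "grazer_scraper", "polyphage")

#: ordinal sample covariates and their closed ranges (inclusive)
ORDINAL_RANGES = {
    "habitat": (1, 4),
    "stage": (1, 3),
    "detritus": (1, 4),
    "floating_matter": (1, 2),
    "shore": (1, 2),
    "place": (1, 3),
    "substratum": (1, 3),
    "trophic_rank": (1, 4),
}

#: edge attributes written to GraphML / edge lists, in column order
EDGE_ATTRS = ("pearson_r", "partial_corr", "p", "sign", "ebc")


@dataclass
class SurveyTable:
    """Long-format survey observations.

    ``records`` has exactly the columns of :data:`SURVEY_COLUMNS`, one row
    per distinct (sample, species) pair; duplicates have been summed.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = _validate_survey_frame(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BiomassMatrix:
    """Samples × species matrix of biomass (mg) or abundance counts.

    Rows are sample ids, columns species ids (lexicographic for
    deterministic downstream linear algebra); absences are explicit zeros.
    """

    values: pd.DataFrame
    value_kind: str = "biomass"

    def __post_init__(self) -> None:
        if self.value_kind not in ("biomass", "abundance"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample or species identifiers in matrix")
        if (self.values.values < 0).any():
            raise ValidationError("negative values in matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _validate_survey_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(SURVEY_COLUMNS)].copy()
    for col in ("count", "biomass"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"non-numeric {col} at row {row}")
        neg = vals < 0
        if neg.any():
            row = int(df.index[neg][0])
            raise ValidationError(f"negative {col} at row {row}")
        df[col] = vals
    df["count"] = df["count"].astype(np.int64)
    # biomass > 0 requires at least one individual; biomass == 0 means absent
    bad = (df["biomass"] > 0) & (df["count"] == 0)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"positive biomass with zero count at row {row}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["species_id"] = df["species_id"].astype(str)
    # repeated sub-samples for the same (sample, species) are summed
    df = (
        df.groupby(["sample_id", "species_id"], as_index=False, sort=True)[["count", "biomass"]]
        .sum()
    )
    return df


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_survey_table(path: str | Path, delimiter: str | None = None) -> SurveyTable:
    """Read a long-format survey table from delimited text (UTF-8, header row).

    The header must name the columns ``sample_id``, ``species_id``,
    ``count`` and ``biomass``. Comma and tab delimiters are auto-detected
    when ``delimiter`` is None. Duplicate (sample, species) rows — repeated
    sub-samples at one site — are summed additively.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SurveyTable(df)


def write_survey_table(table: SurveyTable, path: str | Path, delimiter: str = "\t") -> None:
    table.records.to_csv(path, sep=delimiter, index=False)


def read_species_meta(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read species metadata (species_id, ecological_group, functional_group[, family])."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return validate_species_meta(df)


def validate_species_meta(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("species_id", "ecological_group", "functional_group"):
        if col not in df.columns:
            raise SurveyFormatError(f"missing required column(s): {col}")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"duplicate species metadata for: {dups}")
    bad_eco = set(df["ecological_group"]) - set(ECOLOGICAL_GROUPS)
    if bad_eco:
        raise ValidationError(f"unknown ecological group(s): {sorted(bad_eco)}")
    bad_fun = set(df["functional_group"]) - set(FUNCTIONAL_GROUPS)
    if bad_fun:
        raise ValidationError(f"unknown functional group(s): {sorted(bad_fun)}")
    return df.set_index("species_id", drop=False)


def read_sample_meta(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read sample metadata (sample_id, region, lake_id, ordinal ranks, covariates)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    return validate_sample_meta(df)


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "region"):
        if col not in df.columns:
            raise SurveyFormatError(f"missing required column(s): {col}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample metadata")
    for col, (lo, hi) in ORDINAL_RANGES.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col])
            out = (vals < lo) | (vals > hi)
            if out.any():
                raise ValidationError(f"{col} outside [{lo}, {hi}] for some samples")
    share_cols = [c for c in ("Sm", "Di", "De", "A") if c in df.columns]
    if len(share_cols) == 4:
        tot = df[share_cols].astype(float).sum(axis=1)
        if (tot > 1.0 + 1e-6).any():
            raise ValidationError("littoral habitat shares Sm+Di+De+A exceed 1")
    return df.set_index("sample_id", drop=False)


def build_biomass_matrix(table: SurveyTable, value_kind: str = "biomass") -> BiomassMatrix:
    """Pivot a survey table to a samples × species matrix.

    One row per distinct sample, one (lexicographically ordered) column per
    distinct species; pairs never observed get an explicit 0.
    """
    if len(table) == 0:
        raise ValidationError("cannot pivot an empty survey table")
    value_col = {"biomass": "biomass", "abundance": "count"}.get(value_kind)
    if value_col is None:
        raise ValidationError(f"unknown value_kind {value_kind!r}")
    wide = table.records.pivot_table(
        index="sample_id", columns="species_id", values=value_col, fill_value=0.0, aggfunc="sum"
    )
    wide = wide.sort_index(axis=0).sort_index(axis=1).astype(float)
    wide.index.name = "sample_id"
    wide.columns.name = "species_id"
    return BiomassMatrix(wide, value_kind=value_kind)


def subset_by_region(
    matrix: BiomassMatrix, sample_meta: pd.DataFrame, region: str
) -> BiomassMatrix:
    """Restrict a matrix to one region's samples.

    Species never recorded in the region (all-zero columns in the subset)
    are dropped, matching per-region species pools.
    """
    meta = sample_meta.set_index(sample_meta["sample_id"].astype(str))
    unknown = [s for s in matrix.samples if s not in meta.index]
    if unknown:
        raise ValidationError(f"samples without metadata: {unknown[:5]}")
    if region not in set(meta["region"]):
        raise LookupError(f"unknown region {region!r}")
    keep = [s for s in matrix.samples if meta.at[s, "region"] == region]
    if not keep:
        raise LookupError(f"region {region!r} has no samples in the matrix")
    sub = matrix.values.loc[keep]
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    return BiomassMatrix(sub, value_kind=matrix.value_kind)


def matrix_to_survey(matrix: BiomassMatrix) -> pd.DataFrame:
    """Flatten the non-zero cells of a matrix back to long format (melt).

    Inverse of :func:`build_biomass_matrix` up to the value column kept.
    """
    long = matrix.values.stack().reset_index()
    long.columns = ["sample_id", "species_id", matrix.value_kind]
    return long[long[matrix.value_kind] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# network export / import


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a species network as GraphML or a tab-separated edge list.

    GraphML keeps every node attribute (centralities, group labels) and
    edge attribute (r, partial correlation, p, EBC, sign) and is readable
    by Cytoscape; the edge list carries the edge attributes only.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_list":
        rows = []
        for u, v, data in net.edges(data=True):
            row = {"source": u, "target": v}
            for attr in EDGE_ATTRS:
                if attr in data:
                    row[attr] = data[attr]
            rows.append(row)
        cols = ["source", "target"] + [a for a in EDGE_ATTRS if any(a in r for r in rows)]
        pd.DataFrame(rows, columns=cols if rows else ["source", "target"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read back a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(Path(path))
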