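"""Occurrence tables, stratification, and presence-absence community matrices.

A community matrix is a binary taxa x sites table built from long-format
occurrence records within one stratum: a (year, ecoregion, vegetation zone,
biological unit) combination.  Biological units are either trophic
(functional feeding groups) or taxonomic (families).  Matrix orientation is
fixed throughout the package: rows are taxa, columns are sites.

Matrices are cleaned of all-zero rows/columns (which are incompatible with
fixed-fixed randomization) and then screened by a minimum-size rule before
any null-model analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("coocc")

#: Great Lakes sub-basin ecoregion codes.
ECOREGIONS = frozenset(
    {"LS", "LMN", "LMS", "LHNE", "LHW", "LHSW", "LES", "LON", "LOS"}
)
#: Dominant vegetation zones sampled.
VEGETATION_ZONES = frozenset({"bulrush", "lily"})
#: Functional feeding groups (trophic guilds).
FFGS = frozenset({"collector", "grazer", "predator", "shredder"})
#: Biological unit types used for stratification.
UNIT_TYPES = ("trophic", "taxonomic")

DEFAULT_OCCURRENCE_COLUMNS = {
    "site": "site",
    "taxon": "taxon",
    "abundance": "abundance",
    "year": "year",
    "ecoregion": "ecoregion",
    "vegetation": "vegetation",
}


class VocabularyError(ValueError):
    """A closed-vocabulary column contains unknown codes."""


@dataclass(frozen=True)
class StratumKey:
    """Identity of one community matrix within the nested study design."""

    year: int
    ecoregion: str
    vegetation: str
    unit_type: str
    unit_label: str

    def __str__(self) -> str:
        return (
            f"{self.year}/{self.ecoregion}/{self.vegetation}"
            f"/{self.unit_type}/{self.unit_label}"
        )

    def slug(self) -> str:
        """Filesystem-safe identifier."""
        return str(self).replace("/", "_").replace(" ", "-")

    def to_dict(self) -> dict:
        return {
            "year": self.year,
            "ecoregion": self.ecoregion,
            "vegetation": self.vegetation,
            "unit_type": self.unit_type,
            "unit_label": self.unit_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StratumKey":
        return cls(
            year=int(d["year"]),
            ecoregion=str(d["ecoregion"]),
            vegetation=str(d["vegetation"]),
            unit_type=str(d["unit_type"]),
            unit_label=str(d["unit_label"]),
        )


@dataclass
class CommunityMatrix:
    """Binary taxa x sites presence-absence matrix with stratum metadata.

    ``cells[i, j] == 1`` means taxon ``taxa[i]`` was present at site
    ``sites[j]``.  Labels are kept in insertion order and must be unique.
    """

    key: StratumKey
    taxa: list[str]
    sites: list[str]
    cells: np.ndarray
    cleanup_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.sites)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.sites)} sites"
            )
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary (0/1)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_empty(self) -> bool:
        return self.n_taxa == 0 or self.n_sites == 0

    def row_totals(self) -> np.ndarray:
        """Number of occupied sites per taxon."""
        return self.cells.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        """Site richness (taxa per site)."""
        return self.cells.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.taxa, columns=self.sites)

    # -- on-disk format: TSV with first column = taxon_id + JSON sidecar --

    def write_tsv(self, path: str | Path) -> Path:
        """Write matrix as TSV and a JSON sidecar with key + cleanup log."""
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "taxon_id"
        frame.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"key": self.key.to_dict(), "cleanup_log": self.cleanup_log},
                indent=2,
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CommunityMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            key=StratumKey.from_dict(meta["key"]),
            taxa=[str(t) for t in frame.index],
            sites=[str(s) for s in frame.columns],
            cells=frame.to_numpy(),
            cleanup_log=meta.get("cleanup_log", {}),
        )


def read_occurrences(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format occurrence table.

    Parameters
    ----------
    path
        CSV/TSV file with one row per (site, taxon, year) observation.
    columns
        Mapping from canonical names (site, taxon, abundance, year,
        ecoregion, vegetation) to the file's header names.  Defaults to the
        canonical names themselves.
    sep
        Field separator; inferred from the file when None.

    Returns
    -------
    DataFrame with canonical columns, duplicated (site, taxon, year,
    ecoregion, vegetation) rows aggregated by summing abundance, and closed
    vocabularies validated.  Malformed rows raise with 1-based file line
    numbers (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_OCCURRENCE_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    df = df[list(DEFAULT_OCCURRENCE_COLUMNS)]

    bad_lines: list[str] = []
    for col, caster in (("abundance", float), ("year", int)):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        bad_lines += [f"line {i + 2}: non-numeric {col} {df[col][i]!r}" for i in bad]
        df[col] = converted
    if bad_lines:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(bad_lines))
    if (df["abundance"] < 0).any():
        rows = df.index[df["abundance"] < 0]
        raise ValueError(
            f"{path}: negative abundance at line(s) "
            + ", ".join(str(i + 2) for i in rows)
        )
    df["year"] = df["year"].astype(int)

    for col, vocab in (("ecoregion", ECOREGIONS), ("vegetation", VEGETATION_ZONES)):
        unknown = sorted(set(df[col]) - vocab)
        if unknown:
            raise VocabularyError(
                f"{path}: unknown {col} code(s): {', '.join(unknown)}"
            )

    group_cols = ["site", "taxon", "year", "ecoregion", "vegetation"]
    n_before = len(df)
    df = df.groupby(group_cols, as_index=False, sort=False)["abundance"].sum()
    if len(df) < n_before:
        logger.info(
            "read_occurrences: aggregated %d duplicate rows", n_before - len(df)
        )
    return df


def read_taxon_attributes(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the taxon-attribute table (family, ffg, tolerance, overwinters).

    Only ``taxon`` is required; attribute columns are optional.  Tolerance
    scores, when present, must lie on the 0-10 Hilsenhoff scale; FFGs must
    come from the closed vocabulary.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if "taxon" not in df.columns:
        raise ValueError(f"{path}: missing required column 'taxon'")
    if "ffg" in df.columns:
        known = df["ffg"].dropna()
        unknown = sorted(set(known) - FFGS)
        if unknown:
            raise VocabularyError(f"{path}: unknown ffg value(s): {', '.join(unknown)}")
    if "tolerance" in df.columns:
        tol = pd.to_numeric(df["tolerance"], errors="coerce")
        out = df["tolerance"].notna() & ((tol < 0) | (tol > 10))
        if out.any():
            raise ValueError(f"{path}: tolerance scores outside [0, 10]")
        df["tolerance"] = tol
    return df.set_index("taxon", drop=False)


def read_environment(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the site environmental table, keyed by (site, year)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("site", "year"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df["site"] = df["site"].astype(str)
    df["year"] = df["year"].astype(int)
    return df


def binarize(records: pd.DataFrame) -> pd.DataFrame:
    """Convert abundances to presence (1) / absence (0).

    Any positive abundance counts as a presence; there is no minimum-count
    filter.  Negative abundances are rejected.
    """
    if (records["abundance"] < 0).any():
        raise ValueError("negative abundance encountered")
    out = records.copy()
    out["abundance"] = (out["abundance"] > 0).astype(int)
    return out


def partition_matrices(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    unit_type: str,
) -> list[CommunityMatrix]:
    """Split occurrence records into per-stratum community matrices.

    One matrix per (year, ecoregion, vegetation, unit label) with at least
    one presence.  ``unit_type='trophic'`` groups taxa by functional feeding
    group; ``'taxonomic'`` groups by family (rows are the taxa within one
    family).  Taxa lacking the grouping attribute are excluded and logged.
    Matrices are returned raw (not degeneracy-cleaned, not size-filtered).
    """
    if unit_type not in UNIT_TYPES:
        raise ValueError(f"unit_type must be one of {UNIT_TYPES}")
    attr_col = "ffg" if unit_type == "trophic" else "family"
    if attr_col not in attributes.columns:
        raise ValueError(f"attribute table lacks required column '{attr_col}'")

    presence = binarize(records)
    presence = presence[presence["abundance"] > 0]

    label_map = attributes[attr_col].dropna()
    have = presence["taxon"].isin(label_map.index)
    excluded = sorted(set(presence.loc[~have, "taxon"]))
    if excluded:
        logger.info(
            "partition_matrices(%s): excluded %d taxa lacking %s: %s",
            unit_type, len(excluded), attr_col, ", ".join(excluded),
        )
    presence = presence[have].copy()
    presence["unit_label"] = presence["taxon"].map(label_map)

    matrices: list[CommunityMatrix] = []
    group_cols = ["year", "ecoregion", "vegetation", "unit_label"]
    for (year, eco, veg, label), grp in presence.groupby(group_cols, sort=True):
        pivot = (
            grp.pivot_table(
                index="taxon", columns="site", values="abundance",
                aggfunc="max", fill_value=0,
            )
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        key = StratumKey(int(year), eco, veg, unit_type, str(label))
        matrices.append(
            CommunityMatrix(
                key=key,
                taxa=[str(t) for t in pivot.index],
                sites=[str(s) for s in pivot.columns],
                cells=pivot.to_numpy(),
            )
        )
    return matrices


def clean_degenerate(matrix: CommunityMatrix) -> CommunityMatrix:
    """Remove all-zero rows and columns (degenerate margins).

    All-zero margins are incompatible with fixed-fixed randomization.  Label
    order of the survivors is preserved and removals are recorded in the
    cleanup log.  An everywhere-zero matrix comes back empty
    (``matrix.is_empty``), which downstream code treats as unusable.
    Idempotent: removing zero margins once cannot create new ones.
    """
    rows = matrix.row_totals() > 0
    cols = matrix.col_totals() > 0
    if rows.all() and cols.all():
        return matrix
    removed_taxa = [t for t, k in zip(matrix.taxa, rows) if not k]
    removed_sites = [s for s, k in zip(matrix.sites, cols) if not k]
    logger.info(
        "clean_degenerate(%s): removed %d taxa, %d sites",
        matrix.key, len(removed_taxa), len(removed_sites),
    )
    log = dict(matrix.cleanup_log)
    log["removed_taxa"] = log.get("removed_taxa", []) + removed_taxa
    log["removed_sites"] = log.get("removed_sites", []) + removed_sites
    return CommunityMatrix(
        key=matrix.key,
        taxa=[t for t, k in zip(matrix.taxa, rows) if k],
        sites=[s for s, k in zip(matrix.sites, cols) if k],
        cells=matrix.cells[np.ix_(rows, cols)],
        cleanup_log=log,
    )


def filter_size(
    matrix: CommunityMatrix, min_taxa: int = 5, min_sites: int = 4
) -> bool:
    """Keep/drop decision by minimum matrix size.

    Matrices below 5 taxa x 4 sites are too often degenerate to randomize
    reliably; they are dropped from analysis (decision logged).
    """
    keep = matrix.n_taxa >= min_taxa and matrix.n_sites >= min_sites
    logger.info(
        "filter_size(%s): %d taxa x %d sites -> %s",
        matrix.key, matrix.n_taxa, matrix.n_sites, "keep" if keep else "drop",
    )
    return keep


def prepare_matrices(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    unit_types: Sequence[str] = UNIT_TYPES,
    min_taxa: int = 5,
    min_sites: int = 4,
    discard_degenerate: bool = False,
) -> list[CommunityMatrix]:
    """Partition, clean, and size-filter matrices for all unit types.

    ``discard_degenerate=True`` drops any matrix that needed cleanup instead
    of repairing it (default is repair).
    """
    out: list[CommunityMatrix] = []
    for unit_type in unit_types:
        for m in partition_matrices(records, attributes, unit_type):
            cleaned = clean_degenerate(m)
            if discard_degenerate and cleaned is not m:
                continue
            if cleaned.is_empty:
                continue
            if filter_size(cleaned, min_taxa=min_taxa, min_sites=min_sites):
                out.append(cleaned)
    return out
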