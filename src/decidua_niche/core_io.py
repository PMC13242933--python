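"""Shared data model and on-disk formats for the spatial niche pipeline.

The pipeline works on Visium-style sections: a hexagonally packed array of
55-um capture spots, each with a gene expression profile and a per-cell-type
abundance ("distribution probability") estimated upstream by a deconvolution
tool.  This module defines the in-memory containers every stage consumes and
reads/writes their plain-text serialisations:

* expression  — MatrixMarket ``.mtx`` (features x barcodes, 10x convention)
  plus ``barcodes.tsv`` / ``features.tsv``
* positions   — 10x ``tissue_positions`` CSV dialect
* probabilities — TSV, header of cell-type names, first column spot id
* section metadata — YAML mapping section id to condition and gestational age

Coordinates are 0-based and spot order is barcode-file order throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SpotGrid",
    "GeneMatrix",
    "CellTypeProbabilities",
    "SingleCellReference",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_positions",
    "write_positions",
    "read_probabilities",
    "write_probabilities",
    "read_section_metadata",
    "write_section_metadata",
    "hex_adjacency",
]

CONDITIONS = ("healthy", "RPL")

#: Visium centre-to-centre pitch is 100 um; one array-column step is half of
#: that and one array-row step is 100*sqrt(3)/2 um on the hex lattice.
COL_STEP_UM = 50.0
ROW_STEP_UM = 86.60254037844386

#: hex-lattice neighbour offsets in (array_row, array_col) space
HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpotGrid:
    """Spot identities, hex-array coordinates and section metadata.

    ``spots`` is indexed by spot id (unique within the object) with columns
    ``array_row``, ``array_col``, ``x_um``, ``y_um``, ``section_id`` and an
    optional ``domain`` column with values ``IZ``/``GZ``.  ``sections`` is
    indexed by section id with columns ``condition`` and
    ``gestational_age`` (weeks).
    """

    spots: pd.DataFrame
    sections: pd.DataFrame

    def __post_init__(self) -> None:
        if self.spots.index.has_duplicates:
            dup = self.spots.index[self.spots.index.duplicated()][0]
            raise ValueError(f"duplicate spot id {dup!r}")
        missing = set(self.spots["section_id"]) - set(self.sections.index)
        if missing:
            raise ValueError(f"spots reference unknown sections: {sorted(missing)}")
        bad_cond = set(self.sections["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        if (self.sections["gestational_age"] <= 0).any():
            raise ValueError("gestational_age must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.spots.index)

    def condition_of(self, spot_ids=None) -> pd.Series:
        """Per-spot condition, via each spot's section."""
        sec = self.spots["section_id"] if spot_ids is None else self.spots.loc[spot_ids, "section_id"]
        return sec.map(self.sections["condition"])

    def gestational_age_of(self, spot_ids=None) -> pd.Series:
        sec = self.spots["section_id"] if spot_ids is None else self.spots.loc[spot_ids, "section_id"]
        return sec.map(self.sections["gestational_age"]).astype(float)

    def subset(self, spot_ids) -> "SpotGrid":
        return SpotGrid(spots=self.spots.loc[list(spot_ids)].copy(), sections=self.sections.copy())

    def concat(self, other: "SpotGrid") -> "SpotGrid":
        overlap = set(self.spots.index) & set(other.spots.index)
        if overlap:
            raise ValueError(f"overlapping spot ids: {sorted(overlap)[:3]}")
        sections = pd.concat([self.sections, other.sections[~other.sections.index.isin(self.sections.index)]])
        return SpotGrid(spots=pd.concat([self.spots, other.spots]), sections=sections)


@dataclass
class GeneMatrix:
    """Spots x genes expression values aligned to a :class:`SpotGrid`.

    Values are library-size-normalised, log1p-transformed by default
    (``raw_counts=True`` marks an un-normalised read).
    """

    values: np.ndarray
    genes: list[str]
    spot_ids: list[str]
    raw_counts: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (spots x genes)")
        if self.values.shape != (len(self.spot_ids), len(self.genes)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.genes)} genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.genes)

    def subset_spots(self, spot_ids) -> "GeneMatrix":
        pos = pd.Index(self.spot_ids).get_indexer(list(spot_ids))
        if (pos < 0).any():
            raise KeyError("unknown spot id in subset request")
        return replace(self, values=self.values[pos], spot_ids=list(spot_ids))


@dataclass
class CellTypeProbabilities:
    """Spots x cell-types distribution probabilities (raw or normalised)."""

    values: np.ndarray
    cell_types: list[str]
    spot_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("probability matrix shape mismatch")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell types must be unique")
        if np.any(self.values < 0):
            raise ValueError("distribution probabilities must be nonnegative")
        if self.normalized:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized probability rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.cell_types)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"cell type {cell_type!r} not present") from None
        return self.values[:, j]

    def subset_spots(self, spot_ids) -> "CellTypeProbabilities":
        pos = pd.Index(self.spot_ids).get_indexer(list(spot_ids))
        if (pos < 0).any():
            raise KeyError("unknown spot id in subset request")
        return replace(self, values=self.values[pos], spot_ids=list(spot_ids))


@dataclass
class SingleCellReference:
    """Single-cell reference: subset composition and mean expression profiles.

    ``subset_proportions`` are the fractions of each subset in the reference
    dataset (sum to 1); ``subset_mean_expression`` is a subsets x genes frame
    of mean expression used for LR-pair attribution and signature lookups.
    """

    subset_proportions: pd.Series
    subset_mean_expression: pd.DataFrame
    signature_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subset_proportions = self.subset_proportions.astype(float)
        if abs(self.subset_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("subset proportions must sum to 1")
        if (self.subset_proportions < 0).any():
            raise ValueError("subset proportions must be nonnegative")
        missing = set(self.subset_mean_expression.index) - set(self.subset_proportions.index)
        if missing:
            raise ValueError(f"profiles for subsets without a proportion: {sorted(missing)}")

    @property
    def subsets(self) -> list[str]:
        return list(self.subset_proportions.index)


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------

def normalize_expression(counts: np.ndarray, target_sum: float | None = None) -> np.ndarray:
    """Scale each spot to the median spot total (or ``target_sum``), log1p."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if target_sum is None:
        positive = totals[totals > 0]
        target_sum = float(np.median(positive)) if positive.size else 1.0
    scale = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(counts * scale[:, None])


def read_expression(matrix_path, barcodes_path, features_path, *,
                    raw: bool = False, target_sum: float | None = None) -> GeneMatrix:
    """Read a features x barcodes MatrixMarket triplet into a GeneMatrix.

    Spots come back in barcode-file order.  Unless ``raw`` is set, counts are
    normalised per spot to the median spot total and log1p-transformed.
    """
    matrix_path = Path(matrix_path)
    try:
        mat = spio.mmread(matrix_path)
    except Exception as exc:  # malformed header/entries
        raise FormatError(f"{matrix_path}: invalid MatrixMarket file ({exc})") from exc
    mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    barcodes = _read_single_column(barcodes_path)
    features = _read_single_column(features_path)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix has {mat.shape[0]} rows")
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {mat.shape[1]} columns")
    if np.any(mat < 0):
        raise ValueError(f"{matrix_path}: negative expression entries")
    counts = mat.T  # -> spots x genes
    values = counts if raw else normalize_expression(counts, target_sum=target_sum)
    return GeneMatrix(values=values, genes=features, spot_ids=barcodes, raw_counts=raw)


def _read_single_column(path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).tolist()


def write_expression(gm: GeneMatrix, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write a GeneMatrix as MTX + barcodes/features TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "barcodes": out_dir / f"{prefix}barcodes.tsv",
        "features": out_dir / f"{prefix}features.tsv",
    }
    spio.mmwrite(paths["matrix"], sparse.csr_matrix(gm.values.T), precision=17)
    pd.Series(gm.spot_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    pd.Series(gm.genes).to_csv(paths["features"], sep="\t", header=False, index=False)
    return paths


# ---------------------------------------------------------------------------
# positions / metadata I/O
# ---------------------------------------------------------------------------

_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_y", "pxl_x"]


def read_positions(csv_path, section_id: str, *, condition: str = "healthy",
                   gestational_age: float = 8.0, um_per_px: float = 1.0) -> SpotGrid:
    """Read a 10x tissue-positions CSV (with or without header) as a SpotGrid.

    Only ``in_tissue == 1`` spots are retained; pixel coordinates are scaled
    to micrometres by ``um_per_px``.
    """
    first = pd.read_csv(csv_path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower().startswith("barcode")
    df = pd.read_csv(csv_path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(f"{csv_path}: expected 6 tissue-position columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLS
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"{csv_path}: duplicate barcode {dup!r}")
    df = df[df["in_tissue"].astype(int) == 1]
    if df.empty:
        warnings.warn(f"{csv_path}: no in-tissue spots", stacklevel=2)
    spots = pd.DataFrame({
        "array_row": df["array_row"].astype(int).to_numpy(),
        "array_col": df["array_col"].astype(int).to_numpy(),
        "x_um": df["pxl_x"].astype(float).to_numpy() * um_per_px,
        "y_um": df["pxl_y"].astype(float).to_numpy() * um_per_px,
        "section_id": section_id,
    }, index=pd.Index(df["barcode"].astype(str), name="spot_id"))
    sections = pd.DataFrame(
        {"condition": [condition], "gestational_age": [float(gestational_age)]},
        index=pd.Index([section_id], name="section_id"))
    return SpotGrid(spots=spots, sections=sections)


def write_positions(grid: SpotGrid, csv_path) -> None:
    df = pd.DataFrame({
        "barcode": grid.spots.index,
        "in_tissue": 1,
        "array_row": grid.spots["array_row"].to_numpy(),
        "array_col": grid.spots["array_col"].to_numpy(),
        "pxl_y": grid.spots["y_um"].to_numpy(),
        "pxl_x": grid.spots["x_um"].to_numpy(),
    })
    df.to_csv(csv_path, index=False)


def read_section_metadata(yaml_path) -> pd.DataFrame:
    """Read section metadata YAML -> DataFrame indexed by section id."""
    with open(yaml_path) as fh:
        data = yaml.safe_load(fh)
    rows = {}
    for sec, meta in data.items():
        rows[sec] = {"condition": meta["condition"],
                     "gestational_age": float(meta["gestational_age_weeks"])}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "section_id"
    return df


def write_section_metadata(sections: pd.DataFrame, yaml_path) -> None:
    data = {
        str(sec): {"condition": str(row["condition"]),
                   "gestational_age_weeks": float(row["gestational_age"])}
        for sec, row in sections.iterrows()
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# probabilities I/O
# ---------------------------------------------------------------------------

def read_probabilities(tsv_path, reference: SingleCellReference | None = None) -> CellTypeProbabilities:
    """Read a spot x cell-type probability TSV (deconvolution output).

    Cell types are validated against ``reference`` subsets when given;
    unknown columns are kept with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{tsv_path}: negative distribution probability")
    cell_types = [str(c) for c in df.columns]
    if reference is not None:
        unknown = set(cell_types) - set(reference.subsets)
        if unknown:
            warnings.warn(
                f"{tsv_path}: cell types absent from reference kept as-is: {sorted(unknown)}",
                stacklevel=2)
    return CellTypeProbabilities(values=values, cell_types=cell_types,
                                 spot_ids=[str(s) for s in df.index], normalized=False)


def write_probabilities(probs: CellTypeProbabilities, tsv_path) -> None:
    probs.to_frame().rename_axis("spot_id").to_csv(tsv_path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# hex adjacency
# ---------------------------------------------------------------------------

def hex_adjacency(grid: SpotGrid) -> sparse.csr_matrix:
    """Spot adjacency on the Visium hex lattice (within-section only).

    Two spots are neighbours iff their (array_row, array_col) offset is one
    of the six hex offsets (0, +-2), (+-1, +-1).  Sections are different
    slides, so no edges cross sections.  When array coordinates are missing
    (negative sentinel or NaN) the fallback links spots closer than 1.2x the
    modal nearest-neighbour micron distance.
    """
    n = grid.n_spots
    rows_idx: list[int] = []
    cols_idx: list[int] = []
    spots = grid.spots
    have_array = not (spots["array_row"].isna().any() or spots["array_col"].isna().any())
    for _, sec_idx in spots.groupby("section_id", sort=False).indices.items():
        sec_idx = np.asarray(sec_idx)
        if have_array:
            coords = {
                (int(spots["array_row"].iloc[i]), int(spots["array_col"].iloc[i])): i
                for i in sec_idx
            }
            for (r, c), i in coords.items():
                for dr, dc in HEX_OFFSETS:
                    j = coords.get((r + dr, c + dc))
                    if j is not None:
                        rows_idx.append(i)
                        cols_idx.append(j)
        else:
            xy = spots[["x_um", "y_um"]].iloc[sec_idx].to_numpy(dtype=float)
            if len(sec_idx) < 2:
                continue
            from scipy.spatial import cKDTree
            tree = cKDTree(xy)
            nn_dist, _ = tree.query(xy, k=2)
            modal = float(np.median(nn_dist[:, 1]))
            pairs = tree.query_pairs(1.2 * modal)
            for a, b in pairs:
                rows_idx.extend([sec_idx[a], sec_idx[b]])
                cols_idx.extend([sec_idx[b], sec_idx[a]])
    data = np.ones(len(rows_idx))
    return sparse.csr_matrix((data, (rows_idx, cols_idx)), shape=(n, n))
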