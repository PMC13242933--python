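"""Within-spot cell-type colocalization matrices.

Per section, the Pearson correlation of every pair of cell-type probability
columns across spots; per cell type only the five (configurable) largest
coefficients are retained; per condition, section matrices are averaged and
the two condition averages are differenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CellTypeProbabilities

__all__ = ["ColocMatrix", "section_coloc", "retain_top_k",
           "condition_average", "coloc_difference"]


@dataclass
class ColocMatrix:
    """Cell-type x cell-type correlation coefficients (diagonal zeroed)."""

    values: pd.DataFrame
    condition: str | None = None
    retained: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValueError("colocalization matrix must be square with matching labels")
        arr = v.to_numpy(dtype=float)
        if np.nanmax(np.abs(arr)) > 1 + 1e-9:
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)


def section_coloc(probs: CellTypeProbabilities, condition: str | None = None) -> ColocMatrix:
    """Pearson correlation of pairwise cell-type probabilities across spots."""
    if len(probs.spot_ids) < 3:
        raise ValueError("section_coloc needs at least 3 spots")
    if len(probs.cell_types) < 2:
        raise ValueError("section_coloc needs at least 2 cell types")
    x = probs.values
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance cell types, correlations set to 0: "
            f"{[t for t, z in zip(probs.cell_types, flat) if z]}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    df = pd.DataFrame(corr, index=probs.cell_types, columns=probs.cell_types)
    return ColocMatrix(values=df, condition=condition)


def retain_top_k(m: ColocMatrix, k: int = 5) -> ColocMatrix:
    """Keep each cell type's k largest off-diagonal coefficients, zero the rest.

    Selection is by signed value (colocalization, not anti-colocalization);
    ties at the k-th value are all retained; an entry survives if either of
    its two cell types retains it, keeping the matrix symmetric.  The
    diagonal is never a candidate.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[0]
    if k >= n - 1:
        warnings.warn(f"k={k} >= {n - 1} candidates per cell type; matrix unchanged",
                      stacklevel=2)
        keep = ~np.eye(n, dtype=bool)
    else:
        keep = np.zeros((n, n), dtype=bool)
        for i in range(n):
            row = vals[i].copy()
            row[i] = -np.inf
            kth = np.sort(row)[::-1][k - 1]
            keep[i] = row >= kth - 1e-15
        keep |= keep.T  # union rescue keeps symmetry
    out = np.where(keep, vals, 0.0)
    np.fill_diagonal(out, 0.0)
    return ColocMatrix(values=pd.DataFrame(out, index=m.cell_types, columns=m.cell_types),
                       condition=m.condition,
                       retained=pd.DataFrame(keep, index=m.cell_types, columns=m.cell_types))


def _check_aligned(matrices: list[ColocMatrix]) -> list[str]:
    if not matrices:
        raise ValueError("need at least one matrix")
    types = matrices[0].cell_types
    for m in matrices[1:]:
        if set(m.cell_types) != set(types):
            diff = set(m.cell_types) ^ set(types)
            raise ValueError(f"cell-type sets differ: {sorted(diff)}")
    return types


def condition_average(matrices: list[ColocMatrix], condition: str | None = None) -> ColocMatrix:
    """Entrywise arithmetic mean of section matrices (aligned by cell type)."""
    types = _check_aligned(matrices)
    stack = np.stack([m.values.loc[types, types].to_numpy(dtype=float) for m in matrices])
    return ColocMatrix(values=pd.DataFrame(stack.mean(axis=0), index=types, columns=types),
                       condition=condition)


def coloc_difference(rpl: ColocMatrix, healthy: ColocMatrix) -> pd.DataFrame:
    """Difference matrix RPL minus healthy (aligned by cell type)."""
    types = _check_aligned([rpl, healthy])
    return rpl.values.loc[types, types] - healthy.values.loc[types, types]
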