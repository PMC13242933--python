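"""Spot-level projection of per-subset single-cell attributes.

Implements the enriched-spot rule (a spot is enriched for a cell type when
its distribution probability is at least the section average and at least
0.1), the retention filter for cells mapped into spot space, and the
probability-weighted projection of per-subset scalars (TF binding activity,
target-program expression) into spots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CellTypeProbabilities, SpotGrid

__all__ = ["enriched_spots", "filter_mapped_cells", "project_attribute"]

ENRICHMENT_FLOOR = 0.1


def enriched_spots(probs: CellTypeProbabilities, cell_type: str,
                   grid: SpotGrid | None = None, floor: float = ENRICHMENT_FLOOR) -> set[str]:
    """Spots enriched for a cell type.

    A spot qualifies when its probability is >= the average probability of
    that cell type and >= ``floor``.  The average is taken per section when
    a grid is supplied (sections are separate slides), otherwise over all
    spots given.
    """
    col = probs.column(cell_type)
    ids = np.asarray(probs.spot_ids, dtype=object)
    if grid is None:
        mean = np.full(col.shape, col.mean())
    else:
        section = grid.spots.loc[list(ids), "section_id"].to_numpy(dtype=object)
        mean = np.empty_like(col)
        for sec in pd.unique(section):
            mask = section == sec
            mean[mask] = col[mask].mean()
    keep = (col >= mean) & (col >= floor)
    return set(ids[keep])


def filter_mapped_cells(cell_to_spot: pd.Series, cell_subset: pd.Series,
                        probs: CellTypeProbabilities,
                        grid: SpotGrid | None = None) -> set[str]:
    """Retain cells mapped to spots enriched for their own subset.

    ``cell_to_spot`` maps cell id -> spot id; ``cell_subset`` maps cell id
    -> subset label.  A cell survives iff its spot is enriched for its
    subset.
    """
    known = set(probs.spot_ids)
    unknown = [c for c, s in cell_to_spot.items() if s not in known]
    if unknown:
        raise ValueError(f"cells mapped to unknown spots: {unknown[:5]}")
    retained: set[str] = set()
    for subset in cell_subset.unique():
        spots = enriched_spots(probs, subset, grid=grid)
        cells = cell_subset.index[cell_subset == subset]
        retained |= {c for c in cells if cell_to_spot[c] in spots}
    return retained


def project_attribute(probs: CellTypeProbabilities, attr: pd.Series,
                      subsets: list[str] | None = None) -> pd.Series:
    """Probability-weighted sum of a per-subset attribute at each spot.

    ``value[s] = sum_t prob[s, t] * attr[t]`` over the listed subsets, with
    no renormalisation — spots where the subsets are absent project to 0.
    """
    if subsets is None:
        subsets = list(attr.index)
    missing = [t for t in subsets if t not in attr.index]
    if missing:
        raise ValueError(f"attribute missing for subsets: {missing}")
    if not np.isfinite(attr.loc[subsets].to_numpy(dtype=float)).all():
        raise ValueError("attribute values must be finite")
    total = np.zeros(len(probs.spot_ids))
    for t in subsets:
        total = total + probs.column(t) * float(attr.loc[t])
    return pd.Series(total, index=pd.Index(probs.spot_ids, name="spot_id"), name="projected")
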