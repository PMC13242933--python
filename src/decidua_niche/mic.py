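"""Maximal information coefficient (MIC) via the MINE characteristic matrix.

MIC measures arbitrary functional association between two real vectors on a
0-1 scale.  For every grid of i columns by j rows with ``i*j <= B(n) =
n**alpha``, the mutual information of the induced 2-D histogram is maximised
over grid-line placements and normalised by ``log(min(i, j))``; MIC is the
maximum over all admissible grid sizes and both axis orientations.

The exact maximisation over both axes jointly is intractable, so the
standard approximation is used: one axis is equipartitioned into rows, and
the other axis is optimised exactly by dynamic programming over "clumps"
(runs of points that cannot profitably be split), with at most ``c * i``
superclumps retained as candidate boundaries.  Both orientations are
searched, which also makes the estimate symmetric in its arguments.

``mic_exhaustive`` is an independent brute-force reference for tiny n: with
the same equipartitioned row axis it enumerates *all* column-boundary
placements.  It exists so the dynamic program can be validated against it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import xlogy

__all__ = ["mic", "mic_exhaustive", "equipartition_axis"]

MIN_N = 10


def _check_inputs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < MIN_N:
        raise ValueError(f"MIC requires at least {MIN_N} points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("MIC inputs must be finite")
    return x, y


def equipartition_axis(values: np.ndarray, q: int) -> np.ndarray:
    """Assign each point to one of up to ``q`` rows with near-equal counts.

    Points sharing a value always land in the same row.  Returns the row
    index per point (original order).
    """
    n = values.size
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    # tie-group boundaries in sorted order
    change = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    rows_sorted = np.empty(n, dtype=np.int64)
    assigned = 0
    curr_row = 0
    curr_count = 0
    desired = n / q
    for s, e in zip(starts, ends):
        size = e - s
        if curr_count != 0 and curr_row < q - 1 and \
                abs(curr_count + size - desired) >= abs(curr_count - desired):
            curr_row += 1
            curr_count = 0
            desired = (n - assigned) / (q - curr_row)
        rows_sorted[s:e] = curr_row
        curr_count += size
        assigned += size
    rows = np.empty(n, dtype=np.int64)
    rows[order] = rows_sorted
    return rows


def _clump_histogram(x: np.ndarray, rows: np.ndarray, n_rows: int) -> np.ndarray:
    """Row histogram per clump, in x order.

    A clump is a maximal run of consecutive points (in x order) that either
    share an x value or all fall in the same row: column boundaries inside a
    clump can never improve the DP objective, so clump edges are the only
    candidate boundaries.
    """
    n = x.size
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    rs = rows[order]
    # collapse x-ties: runs of equal x become atomic; mixed-row runs get a
    # unique sentinel label so they are never merged with neighbours
    labels = np.empty(n, dtype=np.int64)
    i = 0
    sentinel = -1
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        block_rows = rs[i:j + 1]
        if np.all(block_rows == block_rows[0]):
            labels[i:j + 1] = block_rows[0]
        else:
            labels[i:j + 1] = sentinel
            sentinel -= 1
        i = j + 1
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    hist = np.zeros((len(starts), n_rows), dtype=np.int64)
    for k, (s, e) in enumerate(zip(starts, ends)):
        hist[k] = np.bincount(rs[s:e], minlength=n_rows)
    return hist


def _superclumps(hist: np.ndarray, k_hat: int) -> np.ndarray:
    """Merge consecutive clumps down to at most ``k_hat`` superclumps."""
    k = hist.shape[0]
    if k <= k_hat:
        return hist
    sizes = hist.sum(axis=1)
    n = int(sizes.sum())
    out = []
    acc = np.zeros(hist.shape[1], dtype=np.int64)
    assigned = 0
    curr_count = 0
    groups_done = 0
    desired = n / k_hat
    for i in range(k):
        size = int(sizes[i])
        if curr_count != 0 and groups_done < k_hat - 1 and \
                abs(curr_count + size - desired) >= abs(curr_count - desired):
            out.append(acc)
            acc = np.zeros(hist.shape[1], dtype=np.int64)
            groups_done += 1
            curr_count = 0
            desired = (n - assigned) / (k_hat - groups_done)
        acc = acc + hist[i]
        curr_count += size
        assigned += size
    out.append(acc)
    return np.asarray(out)


def _optimize_columns(hist: np.ndarray, max_cols: int) -> np.ndarray:
    """Best mutual information (nats) for 2..max_cols columns, fixed rows.

    ``hist`` gives the per-clump row histogram in x order.  Returns an array
    ``I`` with ``I[l]`` the maximum mutual information over column
    partitions into at most ``l`` columns whose boundaries lie on clump
    edges (exact by the clump-optimality argument).
    """
    n = int(hist.sum())
    k = hist.shape[0]
    cum = np.vstack([np.zeros(hist.shape[1], dtype=np.int64), np.cumsum(hist, axis=0)])
    cum_n = cum.sum(axis=1).astype(float)
    row_tot = cum[-1].astype(float)
    h_rows = -np.sum(xlogy(row_tot / n, row_tot / n))
    # F[s, t]: contribution of a column holding clumps s+1..t
    block = cum[None, :, :].astype(float) - cum[:, None, :].astype(float)
    col_n = cum_n[None, :] - cum_n[:, None]
    with np.errstate(invalid="ignore"):
        F = (xlogy(block, block).sum(axis=-1) - xlogy(col_n, col_n)) / n
    F[np.tril_indices(k + 1)] = -np.inf  # only s < t is a valid column
    max_cols = min(max_cols, k)
    best = np.full(max(max_cols + 1, 3), -np.inf)
    G = F[0, :].copy()  # exactly one column over clumps 1..t
    best[1] = h_rows + G[k]  # == 0 by construction
    for l in range(2, max_cols + 1):
        cand = G[l - 1:k, None] + F[l - 1:k, :]
        G = cand.max(axis=0)
        best[l] = h_rows + G[k]
    # grids may leave columns empty, so at-most-l is a running maximum
    return np.maximum.accumulate(best)


def _characteristic_entries(x: np.ndarray, y: np.ndarray, b: float, c: int):
    """Yield (n_cols, n_rows, I_nats) for one orientation (rows from y)."""
    max_q = int(b // 2)
    for q in range(2, max_q + 1):
        rows = equipartition_axis(y, q)
        n_rows = int(rows.max()) + 1
        if n_rows < 2:
            continue  # too few distinct values to split
        max_cols = int(b // q)
        hist = _clump_histogram(x, rows, n_rows)
        hist = _superclumps(hist, max(int(c * max_cols), 1))
        info = _optimize_columns(hist, max_cols)
        for l in range(2, min(max_cols, hist.shape[0]) + 1):
            yield l, q, info[l]


def mic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two equal-length vectors.

    Parameters follow the original MINE defaults: ``alpha`` sets the grid
    budget ``B(n) = n**alpha`` and ``c`` the superclump factor.  Both axis
    orientations are searched, so the statistic is symmetric and depends
    only on the rank/tie structure of each vector.
    """
    x, y = _check_inputs(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("MIC of a constant vector is 0", stacklevel=2)
        return 0.0
    n = x.size
    b = max(n ** alpha, 4.0)
    best = 0.0
    for a_vals, b_vals in ((x, y), (y, x)):
        for l, q, info in _characteristic_entries(a_vals, b_vals, b, c):
            denom = math.log(min(l, q))
            if denom > 0 and info > 0:
                best = max(best, info / denom)
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# brute-force reference (tiny n only)
# ---------------------------------------------------------------------------

def _grid_information(col_bins: np.ndarray, rows: np.ndarray) -> float:
    """Mutual information (nats) of the histogram induced by bin labels."""
    n = rows.size
    n_c = int(col_bins.max()) + 1
    n_r = int(rows.max()) + 1
    table = np.zeros((n_c, n_r))
    np.add.at(table, (col_bins, rows), 1.0)
    p = table / n
    pc = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(p, p) - xlogy(p, pc * pr)
    return float(np.nansum(terms))


def mic_exhaustive(x, y, alpha: float = 0.6) -> float:
    """Brute-force MIC for tiny n: all column-boundary placements enumerated.

    Rows come from the same equipartition rule as :func:`mic`; columns are
    searched exhaustively over every placement of up to ``i - 1`` cuts
    between distinct values (no clump shortcut, no superclumps, no dynamic
    program).  Exponential in n - intended for n around a dozen as an
    independent check of the optimisation path.
    """
    from itertools import combinations

    x, y = _check_inputs(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    n = x.size
    b = max(n ** alpha, 4.0)
    best = 0.0
    for a_vals, b_vals in ((x, y), (y, x)):
        order = np.argsort(a_vals, kind="mergesort")
        a_sorted = a_vals[order]
        cut_positions = [i for i in range(1, n) if a_sorted[i] != a_sorted[i - 1]]
        max_q = int(b // 2)
        for q in range(2, max_q + 1):
            rows = equipartition_axis(b_vals, q)[order]
            if rows.max() < 1:
                continue
            max_cols = int(b // q)
            for n_cols in range(2, max_cols + 1):
                denom = math.log(min(n_cols, q))
                for cuts in combinations(cut_positions, min(n_cols - 1, len(cut_positions))):
                    col_bins = np.zeros(n, dtype=np.int64)
                    for cut in cuts:
                        col_bins[cut:] += 1
                    info = _grid_information(col_bins, rows)
                    if denom > 0:
                        best = max(best, info / denom)
    return float(min(best, 1.0))
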