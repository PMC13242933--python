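"""Group-to-group transition confidence and its permutation test.

A velocity tool upstream produces a cell-by-cell transition matrix (row
stochastic: row i is the probability that cell i transitions to each other
cell) together with a subset label per cell.  The directed confidence that
subset A transforms into subset B is summarised as the mean, over cells of
A, of their total transition mass landing on cells of B.  Significance is
assessed by shuffling the subset labels (group sizes preserved) and
recomputing the statistic; the empirical one-sided P uses add-one
smoothing so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["TransitionGraph", "PermutationResult", "transition_confidence",
           "permutation_test", "stack_permutation_test"]


@dataclass
class TransitionGraph:
    """Cells x cells nonnegative transition weights with subset labels."""

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square and match label count")
        if np.any(self.weights < 0):
            raise ValueError("transition weights must be nonnegative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if len(set(self.labels)) < 2:
            raise ValueError("labels must cover at least 2 groups")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.labels, dtype=object) == group)
        if idx.size == 0:
            raise ValueError(f"group {group!r} is empty")
        return idx


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    null_values: np.ndarray


def transition_confidence(g: TransitionGraph, from_group: str, to_group: str) -> float:
    """Mean outgoing transition mass from ``from_group`` onto ``to_group``."""
    f_idx = g.group_indices(from_group)
    t_idx = g.group_indices(to_group)
    return float(g.weights[np.ix_(f_idx, t_idx)].sum(axis=1).mean())


def permutation_test(g: TransitionGraph, from_group: str, to_group: str,
                     n_perm: int = 1000, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> PermutationResult:
    """One-sided label-permutation test of the transition confidence.

    Labels are shuffled uniformly at random (group sizes preserved by
    construction) ``n_perm`` times; empirical P is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = transition_confidence(g, from_group, to_group)
    labels = np.asarray(g.labels, dtype=object)
    n = g.n_cells
    n_from = int((labels == from_group).sum())
    n_to = int((labels == to_group).sum())
    w = g.weights
    null_values = np.empty(n_perm)
    # vectorise in blocks: mass onto the permuted to-set per cell, then
    # average over the permuted from-set
    block = 256
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        to_mask = np.zeros((m, n))
        from_rows = np.empty((m, n_from), dtype=np.int64)
        for b in range(m):
            perm = rng.permutation(n)
            from_rows[b] = perm[:n_from]
            to_mask[b, perm[n_from:n_from + n_to]] = 1.0
        onto_to = w @ to_mask.T  # (n cells, m perms)
        for b in range(m):
            null_values[done + b] = onto_to[from_rows[b], b].mean()
        done += m
    p = (1.0 + np.count_nonzero(null_values >= observed - 1e-15)) / (1.0 + n_perm)
    return PermutationResult(observed=observed, p_value=float(p),
                             n_perm=n_perm, null_values=null_values)


def stack_permutation_test(graphs: list[TransitionGraph], from_group: str, to_group: str,
                           n_perm: int = 1000, seed: int | None = None) -> PermutationResult:
    """Median confidence and P across a stack of posterior transition matrices.

    Supports uncertainty propagation when the upstream velocity model emits
    several transition matrices sampled from its posterior.
    """
    rng = np.random.default_rng(seed)
    results = [permutation_test(g, from_group, to_group, n_perm=n_perm, rng=rng)
               for g in graphs]
    obs = float(np.median([r.observed for r in results]))
    p = float(np.median([r.p_value for r in results]))
    return PermutationResult(observed=obs, p_value=p, n_perm=n_perm,
                             null_values=np.concatenate([r.null_values for r in results]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_transition_graph(matrix_path, labels_path) -> TransitionGraph:
    """Read a transition matrix (MTX or dense TSV) plus a one-column label TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = spio.mmread(matrix_path)
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    else:
        mat = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy(dtype=float)
    labels = pd.read_csv(labels_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return TransitionGraph(weights=mat, labels=labels)


def write_transition_graph(g: TransitionGraph, matrix_path, labels_path) -> None:
    pd.DataFrame(g.weights).to_csv(matrix_path, sep="\t", header=False, index=False,
                                   float_format="%.17g")
    pd.Series(g.labels).to_csv(labels_path, sep="\t", header=False, index=False)
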