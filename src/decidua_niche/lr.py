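"""Ligand-receptor spatial coexpression screening and differential testing.

The screen asks whether a ligand and its receptor are expressed in the same
neighbourhoods of a section: expression is smoothed over each spot and its
directly adjacent hex neighbours, the smoothed ligand and receptor profiles
are correlated across spots (Pearson, two-sided P), and pairs with rho >= 0
and P < 0.05 are called spatially coexpressed.  A pair's per-spot
interaction score is the product of the smoothed ligand and receptor
values; score differences between spot groups (domains or conditions) are
tested by rank-sum with BH correction, and each pair is attributed to the
colocalized cell-type pair expressing it most highly.

Multi-subunit complexes are reduced to the per-spot minimum of their
subunits (limiting-subunit semantics) before all steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .coloc import ColocMatrix
from .core_io import GeneMatrix, SingleCellReference, SpotGrid, hex_adjacency
from .stats import bh_fdr

__all__ = ["LRCatalog", "read_lr_catalog", "write_lr_catalog", "neighbor_smooth",
           "coexpression_screen", "spot_score", "differential_lr", "attribute_pair"]


@dataclass
class LRCatalog:
    """Ligand-receptor pairs; each side may list several complex subunits."""

    pairs: pd.DataFrame  # index pair_id; columns ligand (tuple), receptor (tuple), pathway

    def __post_init__(self) -> None:
        if self.pairs.index.has_duplicates:
            raise ValueError("pair_id must be unique")
        for pid, row in self.pairs.iterrows():
            if not row["ligand"] or not row["receptor"]:
                raise ValueError(f"pair {pid!r} missing ligand or receptor genes")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.pairs.index)

    def genes_of(self, pair_id: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        row = self.pairs.loc[pair_id]
        return tuple(row["ligand"]), tuple(row["receptor"])


def read_lr_catalog(tsv_path) -> LRCatalog:
    """Read a catalog TSV: pair_id, ligand, receptor[, pathway]; commas split complexes."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"pair_id", "ligand", "receptor"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    pairs = pd.DataFrame({
        "ligand": [tuple(str(v).split(",")) for v in df["ligand"]],
        "receptor": [tuple(str(v).split(",")) for v in df["receptor"]],
        "pathway": df["pathway"] if "pathway" in df else pd.Series([""] * len(df)),
    }, index=pd.Index(df["pair_id"].astype(str), name="pair_id"))
    return LRCatalog(pairs=pairs)


def write_lr_catalog(catalog: LRCatalog, tsv_path) -> None:
    df = pd.DataFrame({
        "pair_id": catalog.pairs.index,
        "ligand": [",".join(v) for v in catalog.pairs["ligand"]],
        "receptor": [",".join(v) for v in catalog.pairs["receptor"]],
        "pathway": catalog.pairs["pathway"].to_numpy(),
    })
    df.to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# smoothing and screening
# ---------------------------------------------------------------------------

def neighbor_smooth(expr: GeneMatrix, grid: SpotGrid) -> GeneMatrix:
    """Average each spot with its directly adjacent spots (within-section).

    Linear operator: row s of the result is the mean of the expression rows
    of {s} and its hex neighbours; isolated spots map to themselves.
    """
    adj = hex_adjacency(grid)
    n = expr.n_spots
    if list(grid.spots.index) != list(expr.spot_ids):
        raise ValueError("expression and grid must list the same spots in order")
    op = adj + sparse.eye(n, format="csr")
    inv_deg = 1.0 / np.asarray(op.sum(axis=1)).ravel()
    smoothed = sparse.diags(inv_deg) @ op @ expr.values
    return replace(expr, values=np.asarray(smoothed))


def _complex_values(expr: GeneMatrix, genes: tuple[str, ...]) -> np.ndarray:
    cols = [expr.gene_values(g) for g in genes]
    return np.min(np.stack(cols), axis=0) if len(cols) > 1 else cols[0]


def _pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided t-approximation P; flat input -> (0, 1)."""
    n = a.size
    if a.std() == 0 or b.std() == 0 or n < 3:
        return 0.0, 1.0
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def _permutation_pearson_p(a: np.ndarray, b: np.ndarray, n_perm: int,
                           rng: np.random.Generator) -> float:
    r_obs = abs(np.corrcoef(a, b)[0, 1])
    count = sum(abs(np.corrcoef(a, rng.permutation(b))[0, 1]) >= r_obs - 1e-15
                for _ in range(n_perm))
    return (1.0 + count) / (1.0 + n_perm)


def coexpression_screen(smoothed: GeneMatrix, catalog: LRCatalog,
                        grid: SpotGrid | None = None, alpha: float = 0.05,
                        domain_labels=None, exact_permutation: int = 0,
                        seed: int | None = None) -> pd.DataFrame:
    """Screen every catalog pair for spatial coexpression, per section.

    Returns one row per (pair, section) with the smoothed-expression Pearson
    rho, its two-sided P, the coexpressed flag (rho >= 0 and P < alpha), and
    — when ``domain_labels`` is given — the domain whose spots carry the
    higher mean interaction score.  Pairs with genes missing from the matrix
    are skipped with a warning.  ``exact_permutation > 0`` switches the P
    value to a label-permutation estimate with that many permutations
    (small sections).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        section_of = pd.Series("all", index=pd.Index(smoothed.spot_ids))
    else:
        section_of = pd.Series(
            grid.spots.loc[list(smoothed.spot_ids), "section_id"].to_numpy(),
            index=pd.Index(smoothed.spot_ids))
    if domain_labels is not None:
        domain_labels = np.asarray(domain_labels, dtype=object)
    rows = []
    gene_set = set(smoothed.genes)
    for pid in catalog.pair_ids:
        lig, rec = catalog.genes_of(pid)
        missing = [g for g in lig + rec if g not in gene_set]
        if missing:
            warnings.warn(f"pair {pid}: genes absent, skipped: {missing}", stacklevel=2)
            continue
        lvals = _complex_values(smoothed, lig)
        rvals = _complex_values(smoothed, rec)
        score = lvals * rvals
        for sec in section_of.unique():
            mask = (section_of == sec).to_numpy()
            if mask.sum() < 10:
                raise ValueError(f"section {sec!r} has fewer than 10 spots")
            a, b = lvals[mask], rvals[mask]
            if exact_permutation:
                rho = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
                p = _permutation_pearson_p(a, b, exact_permutation, rng) \
                    if a.std() > 0 and b.std() > 0 else 1.0
            else:
                rho, p = _pearson_with_p(a, b)
            domain = ""
            if domain_labels is not None:
                sec_domains = domain_labels[mask]
                dom_means = {d: score[mask][sec_domains == d].mean()
                             for d in pd.unique(sec_domains)}
                domain = max(sorted(dom_means), key=lambda d: dom_means[d])
            rows.append({"pair_id": pid, "section_id": sec, "rho": rho, "p": p,
                         "coexpressed": bool(rho >= 0 and p < alpha), "domain": domain})
    return pd.DataFrame(rows)


def condition_pair_sets(screen: pd.DataFrame, sections: pd.DataFrame) -> dict[str, set[str]]:
    """Union of coexpressed pair ids across each condition's sections."""
    cond_of = sections["condition"]
    out: dict[str, set[str]] = {}
    for _, row in screen.iterrows():
        if row["coexpressed"]:
            cond = cond_of.get(row["section_id"], row["section_id"])
            out.setdefault(cond, set()).add(row["pair_id"])
    return out


def spot_score(smoothed: GeneMatrix, catalog: LRCatalog,
               pair_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-spot interaction score: smoothed ligand x smoothed receptor."""
    if pair_ids is None:
        pair_ids = catalog.pair_ids
    gene_set = set(smoothed.genes)
    cols = {}
    for pid in pair_ids:
        lig, rec = catalog.genes_of(pid)
        if any(g not in gene_set for g in lig + rec):
            warnings.warn(f"pair {pid}: genes absent, skipped", stacklevel=2)
            continue
        cols[pid] = _complex_values(smoothed, lig) * _complex_values(smoothed, rec)
    return pd.DataFrame(cols, index=pd.Index(smoothed.spot_ids, name="spot_id"))


def differential_lr(scores: pd.DataFrame, group_a_mask, lfc_min: float = 0.1,
                    p_max: float = 1e-5, eps: float = 1e-9) -> pd.DataFrame:
    """Differential interaction test of spot scores between two spot groups.

    Per pair: two-sided Wilcoxon rank-sum of scores in group A vs the rest,
    and log2FC of the group means (pseudocount ``eps``).  ``up`` marks pairs
    higher in group A (log2FC >= lfc_min, P < p_max), ``down`` pairs lower
    by the mirrored rule; BH-adjusted P is reported alongside.
    """
    mask = np.asarray(group_a_mask, dtype=bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both spot groups need at least 2 spots")
    vals = scores.to_numpy(dtype=float)
    mean_a = vals[mask].mean(axis=0)
    mean_b = vals[~mask].mean(axis=0)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.mannwhitneyu(vals[mask], vals[~mask], alternative="two-sided",
                               method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    p_adj = bh_fdr(p)
    return pd.DataFrame({
        "log2fc": log2fc, "p": p, "p_adj": p_adj,
        "up": (log2fc >= lfc_min) & (p < p_max),
        "down": (log2fc <= -lfc_min) & (p < p_max),
    }, index=scores.columns.rename("pair_id"))


def attribute_pair(pair_id: str, catalog: LRCatalog, reference: SingleCellReference,
                   coloc: ColocMatrix, corr_min: float = 0.1) -> tuple[str, str] | str:
    """Assign a coexpressed pair to the cell-type pair most likely signalling.

    Among ordered cell-type pairs (a, b) whose colocalization coefficient is
    at least ``corr_min`` (self-pairs count as fully colocalized), returns
    the pair maximising mean ligand expression in a times mean receptor
    expression in b from the single-cell reference; ties break
    lexicographically.  Returns ``"unassigned"`` when no pair qualifies.
    """
    lig, rec = catalog.genes_of(pair_id)
    expr = reference.subset_mean_expression
    missing = [g for g in lig + rec if g not in expr.columns]
    if missing:
        raise KeyError(f"reference profiles missing genes {missing}")
    lig_mean = expr[list(lig)].min(axis=1)
    rec_mean = expr[list(rec)].min(axis=1)
    types = [t for t in coloc.cell_types if t in expr.index]
    best: tuple[str, str] | None = None
    best_score = -np.inf
    tied = False
    for a in sorted(types):
        for b in sorted(types):
            cc = 1.0 if a == b else float(coloc.values.loc[a, b])
            if cc < corr_min:
                continue
            score = float(lig_mean.loc[a] * rec_mean.loc[b])
            if score > best_score + 1e-15:
                best, best_score, tied = (a, b), score, False
            elif abs(score - best_score) <= 1e-15 and best is not None:
                tied = True  # lexicographic winner already held
    if best is None:
        return "unassigned"
    if tied:
        warnings.warn(f"pair {pair_id}: attribution tie broken lexicographically",
                      stacklevel=2)
    return best
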