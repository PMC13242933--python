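"""Deconvolution post-processing and spatial-domain statistics.

Covers the steps that sit between an external deconvolution tool and the
figures: reference-proportion normalisation of distribution probabilities,
domain signature genes with Jaccard similarity between domains, and the
condition contrast adjusted for gestational age (ANCOVA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core_io import CellTypeProbabilities, GeneMatrix, SingleCellReference

__all__ = ["DomainSignature", "normalize_probabilities", "domain_markers",
           "jaccard", "condition_effect", "ConditionEffect"]

LOG2FC_EPS = 1e-9


@dataclass
class DomainSignature:
    """Signature genes of one spatial domain with their statistics."""

    domain: str
    genes: frozenset[str]
    stats: pd.DataFrame  # index gene; columns log2fc, p, p_adj


@dataclass(frozen=True)
class ConditionEffect:
    """Condition coefficient from the gestational-age-adjusted contrast."""

    effect: float
    p_value: float
    n: int
    method: str  # "ancova" or "t-test"


def normalize_probabilities(raw: CellTypeProbabilities,
                            reference: SingleCellReference) -> CellTypeProbabilities:
    """Normalise distribution probabilities by reference subset proportions.

    Each spot's probability for cell type t is divided by the proportion of
    t in the single-cell reference, then the row is renormalised to sum
    to 1, putting rare and abundant types on a common relative scale.
    """
    if raw.normalized:
        raise ValueError("input probabilities are already normalised")
    props = reference.subset_proportions
    missing = [t for t in raw.cell_types if t not in props.index]
    if missing:
        raise ValueError(f"no reference proportion for cell types: {missing}")
    denom = props.loc[raw.cell_types].to_numpy(dtype=float)
    zero_types = [t for t, d in zip(raw.cell_types, denom) if d <= 0]
    if zero_types:
        raise ValueError(f"reference proportion is zero for: {zero_types}")
    scaled = raw.values / denom[None, :]
    row_sums = scaled.sum(axis=1)
    empty = row_sums <= 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} all-zero spot rows emitted as uniform",
                      stacklevel=2)
        scaled[empty] = 1.0
        row_sums[empty] = len(raw.cell_types)
    return replace(raw, values=scaled / row_sums[:, None], normalized=True)


def domain_markers(expr: GeneMatrix, labels, lfc_min: float = 0.5,
                   p_max: float = 1e-10) -> dict[str, DomainSignature]:
    """Domain signature genes by fold change and rank-sum test.

    Per gene and domain: log2FC of the expm1 mean inside vs outside the
    domain (pseudocount 1e-9) and a two-sided Wilcoxon rank-sum P on the
    log values.  A gene enters a domain's signature iff it is upregulated
    there with ``|log2FC| >= lfc_min`` and ``P < p_max``; when thresholds
    are permissive a gene is assigned only to the domain where its mean is
    highest.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != expr.n_spots:
        raise ValueError("one domain label per spot required")
    domains = sorted(set(labels))
    lin = np.expm1(expr.values)
    out: dict[str, DomainSignature] = {}
    per_domain = {}
    for dom in domains:
        in_mask = labels == dom
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            raise ValueError(f"domain {dom!r} needs at least 2 spots on each side")
        mean_in = lin[in_mask].mean(axis=0)
        mean_out = lin[~in_mask].mean(axis=0)
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.mannwhitneyu(expr.values[in_mask], expr.values[~in_mask],
                                   alternative="two-sided", method="asymptotic", axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals[~np.isfinite(pvals)] = 1.0  # all-tied genes carry no evidence
        per_domain[dom] = (mean_in, log2fc, pvals)
    mean_matrix = np.vstack([per_domain[d][0] for d in domains])
    best_domain = np.argmax(mean_matrix, axis=0)
    from .stats import bh_fdr
    for di, dom in enumerate(domains):
        mean_in, log2fc, pvals = per_domain[dom]
        p_adj = bh_fdr(pvals)
        keep = (np.abs(log2fc) >= lfc_min) & (pvals < p_max) & (log2fc >= 0) \
            & (best_domain == di)
        genes = frozenset(g for g, k in zip(expr.genes, keep) if k)
        stats = pd.DataFrame({"log2fc": log2fc, "p": pvals, "p_adj": p_adj},
                             index=pd.Index(expr.genes, name="gene"))
        out[dom] = DomainSignature(domain=dom, genes=genes, stats=stats)
    return out


def jaccard(set_a, set_b) -> float:
    """Jaccard index |A n B| / |A u B|; 0 (with warning) when both empty."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(set_a & set_b) / len(union)


def condition_effect(values, condition, gestational_age) -> ConditionEffect:
    """Condition contrast with gestational age as covariate (ANCOVA).

    Ordinary least squares of ``value ~ intercept + 1[RPL] + age``; the
    reported effect is the RPL-vs-healthy coefficient with its two-sided
    t-test P.  Falls back to a two-sample t-test (with warning) when the
    covariate does not vary.
    """
    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition, dtype=object)
    age = np.asarray(gestational_age, dtype=float)
    if not (values.size == condition.size == age.size):
        raise ValueError("values, condition and gestational_age must align")
    present = set(condition)
    if not {"healthy", "RPL"} <= present:
        raise ValueError(f"both conditions required, got {sorted(present)}")
    indicator = (condition == "RPL").astype(float)
    if np.ptp(values) == 0:  # constant response carries no evidence
        return ConditionEffect(effect=0.0, p_value=1.0, n=values.size, method="ancova")
    if np.ptp(age) == 0:
        warnings.warn("gestational age is constant; falling back to a t-test",
                      stacklevel=2)
        a, b = values[indicator == 1], values[indicator == 0]
        t, p = sps.ttest_ind(a, b)
        return ConditionEffect(effect=float(a.mean() - b.mean()),
                               p_value=float(p), n=values.size, method="t-test")
    design = sm.add_constant(np.column_stack([indicator, age]))
    fit = sm.OLS(values, design).fit()
    p = float(fit.pvalues[1])
    if not np.isfinite(p):  # zero residual variance (e.g. constant response)
        p = 1.0
    return ConditionEffect(effect=float(fit.params[1]), p_value=p,
                           n=values.size, method="ancova")
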