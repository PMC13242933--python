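"""Orchestration: run every analysis stage on a dataset from one config.

``run_all`` executes domains -> colocalization -> LR interactions ->
ligand targets (MIC) -> spatial projection -> trajectory permutation on a
synthetic (or loaded) dataset and writes a machine-readable JSON report of
each stage's headline outputs and the parameters used.  Stages whose
inputs are unavailable are skipped and logged in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import domains as domains_mod
from . import lr as lr_mod
from .core_io import CellTypeProbabilities, GeneMatrix
from .ligand_targets import select_tracking_genes
from .projection import enriched_spots, project_attribute
from .synthetic import SyntheticDataset, generate_transitions
from .trajectory import permutation_test

logger = logging.getLogger("decidua_niche")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Thresholds and sizes for one pipeline run (defaults = study settings)."""

    seed: int = 0
    out_dir: str | Path | None = None
    lfc_domain: float = 0.5
    p_domain: float = 1e-10
    alpha_screen: float = 0.05
    lfc_lr: float = 0.1
    p_lr: float = 1e-5
    k_coloc: int = 5
    corr_min: float = 0.1
    mic_min: float = 0.9
    n_perm: int = 1000
    mic_max_spots: int = 600  # spots subsampled per section for the MIC screen
    mic_candidates: list[str] | None = None
    projection_attr: dict[str, float] = field(
        default_factory=lambda: {"dNK1": 1.0, "dNK2": 0.5, "dNK3": 0.2})

    def __post_init__(self) -> None:
        for name in ("p_domain", "p_lr", "alpha_screen"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0 <= self.mic_min <= 1:
            raise ValueError("mic_min must lie in [0, 1]")
        if self.k_coloc < 1 or self.n_perm < 100:
            raise ValueError("k_coloc >= 1 and n_perm >= 100 required")
        if self.lfc_domain < 0 or self.lfc_lr < 0:
            raise ValueError("fold-change thresholds must be nonnegative")


def _concat_sections(ds: SyntheticDataset):
    grid = ds.sections[0].grid
    for s in ds.sections[1:]:
        grid = grid.concat(s.grid)
    expr = GeneMatrix(
        values=np.vstack([s.expression.values for s in ds.sections]),
        genes=list(ds.sections[0].expression.genes),
        spot_ids=[sid for s in ds.sections for sid in s.expression.spot_ids])
    probs = CellTypeProbabilities(
        values=np.vstack([s.probabilities.values for s in ds.sections]),
        cell_types=list(ds.sections[0].probabilities.cell_types),
        spot_ids=[sid for s in ds.sections for sid in s.probabilities.spot_ids])
    domain = pd.concat([s.truth.domain for s in ds.sections])
    return grid, expr, probs, domain


def run_all(ds: SyntheticDataset, config: RunConfig | None = None) -> dict:
    """Execute all six analysis stages; returns (and optionally writes) the report."""
    config = config or RunConfig()
    rng_seed = config.seed
    report: dict = {"seed": rng_seed, "parameters": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}}
    grid, expr, probs_raw, domain = _concat_sections(ds)
    stages: dict[str, dict] = {}
    report["stages"] = stages

    # --- domains ---------------------------------------------------------
    probs_norm = domains_mod.normalize_probabilities(probs_raw, ds.reference)
    signatures = domains_mod.domain_markers(expr, domain.to_numpy(),
                                            lfc_min=config.lfc_domain,
                                            p_max=config.p_domain)
    cond = grid.condition_of().to_numpy()
    age = grid.gestational_age_of().to_numpy()
    ancova = {}
    iz_mask = (domain == "IZ").to_numpy()
    for ct in probs_norm.cell_types:
        vals = probs_norm.column(ct)[iz_mask]
        eff = domains_mod.condition_effect(vals, cond[iz_mask], age[iz_mask])
        ancova[ct] = {"effect": eff.effect, "p": eff.p_value}
    # per-section signatures -> cross-section Jaccard similarity
    sec_sigs = {}
    for s in ds.sections:
        sig = domains_mod.domain_markers(s.expression, s.truth.domain.to_numpy(),
                                         lfc_min=config.lfc_domain, p_max=config.p_domain)
        sec_sigs[s.grid.sections.index[0]] = sig
    jac_all, jac_healthy = [], []
    secs = list(sec_sigs)
    cond_of_sec = grid.sections["condition"]
    import warnings as _warnings
    for i, a in enumerate(secs):
        for b in secs[i + 1:]:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # empty RPL signatures are expected
                j = domains_mod.jaccard(sec_sigs[a]["IZ"].genes, sec_sigs[b]["IZ"].genes)
            jac_all.append(j)
            if cond_of_sec[a] == cond_of_sec[b] == "healthy":
                jac_healthy.append(j)
    stages["domains"] = {
        "signature_gene_counts": {d: len(sig.genes) for d, sig in signatures.items()},
        "mean_iz_signature_jaccard": float(np.mean(jac_all)) if jac_all else None,
        "mean_iz_signature_jaccard_healthy": float(np.mean(jac_healthy)) if jac_healthy else None,
        "iz_condition_effects": ancova,
    }

    # --- colocalization --------------------------------------------------
    per_condition: dict[str, list] = {"healthy": [], "RPL": []}
    for s in ds.sections:
        sec_probs = domains_mod.normalize_probabilities(s.probabilities, ds.reference)
        m = coloc_mod.retain_top_k(coloc_mod.section_coloc(sec_probs), k=config.k_coloc)
        per_condition[s.truth.condition].append(m)
    avg = {c: coloc_mod.condition_average(ms, condition=c)
           for c, ms in per_condition.items() if ms}
    diff = None
    if set(avg) == {"healthy", "RPL"}:
        diff = coloc_mod.coloc_difference(avg["RPL"], avg["healthy"])
    stages["colocalization"] = {
        "dNK1_dM2_difference": (float(diff.loc["dNK1", "dM2"]) if diff is not None else None),
        "n_sections": {c: len(ms) for c, ms in per_condition.items()},
    }

    # --- LR interactions -------------------------------------------------
    smoothed_secs = {s.grid.sections.index[0]: lr_mod.neighbor_smooth(s.expression, s.grid)
                     for s in ds.sections}
    screens = []
    for s in ds.sections:
        sid = s.grid.sections.index[0]
        screens.append(lr_mod.coexpression_screen(
            smoothed_secs[sid], ds.catalog, grid=s.grid, alpha=config.alpha_screen,
            domain_labels=s.truth.domain.to_numpy()))
    screen = pd.concat(screens, ignore_index=True)
    pair_sets = lr_mod.condition_pair_sets(screen, grid.sections)
    # differential interaction inside IZ: RPL vs healthy
    iz_scores = []
    iz_is_rpl = []
    for s in ds.sections:
        sid = s.grid.sections.index[0]
        sc = lr_mod.spot_score(smoothed_secs[sid], ds.catalog)
        m = (s.truth.domain == "IZ").to_numpy()
        iz_scores.append(sc.loc[m])
        iz_is_rpl.append(np.full(int(m.sum()), s.truth.condition == "RPL"))
    scores_iz = pd.concat(iz_scores)
    dlr = lr_mod.differential_lr(scores_iz, np.concatenate(iz_is_rpl),
                                 lfc_min=config.lfc_lr, p_max=config.p_lr)
    coloc_healthy = avg.get("healthy")
    attribution = {}
    if coloc_healthy is not None:
        for pid in dlr.index[dlr["up"] | dlr["down"]]:
            attribution[pid] = lr_mod.attribute_pair(
                pid, ds.catalog, ds.reference, coloc_healthy, corr_min=config.corr_min)
    stages["lr_interactions"] = {
        "coexpressed_per_condition": {c: sorted(v) for c, v in pair_sets.items()},
        "down_in_RPL_IZ": sorted(dlr.index[dlr["down"]]),
        "up_in_RPL_IZ": sorted(dlr.index[dlr["up"]]),
        "attribution": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in attribution.items()},
    }

    # --- ligand targets (MIC) -------------------------------------------
    first_healthy = next((s for s in ds.sections if s.truth.condition == "healthy"), None)
    if first_healthy is None:
        stages["ligand_targets"] = {"skipped": "no healthy section"}
        logger.info("ligand_targets skipped: no healthy section")
    else:
        sig = ds.reference.signature_genes
        candidates = config.mic_candidates or sorted(
            set(sig.get("dNK1", [])) | set(sig.get("dNK2", [])) | set(sig.get("dNK3", [])))
        sub_probs = domains_mod.normalize_probabilities(
            first_healthy.probabilities, ds.reference)
        sub = sub_probs.column("dNK1") if "dNK1" in sub_probs.cell_types else None
        if sub is None or not candidates:
            stages["ligand_targets"] = {"skipped": "no dNK1 probabilities or candidates"}
        else:
            rng = np.random.default_rng(rng_seed)
            n = first_healthy.expression.n_spots
            take = rng.choice(n, size=min(config.mic_max_spots, n), replace=False)
            sub_expr = GeneMatrix(values=first_healthy.expression.values[take],
                                  genes=first_healthy.expression.genes,
                                  spot_ids=[first_healthy.expression.spot_ids[i] for i in take])
            sel = select_tracking_genes(sub_expr, sub[take], candidates,
                                        mic_min=config.mic_min)
            stages["ligand_targets"] = {
                "n_candidates": len(candidates),
                "n_selected": int(sel.table["selected"].sum()),
                "retained_genes": sel.retained_genes,
            }

    # --- spatial projection ----------------------------------------------
    attr = pd.Series(config.projection_attr)
    subsets = [t for t in attr.index if t in probs_raw.cell_types]
    if not subsets:
        stages["spatial_projection"] = {"skipped": "no projectable subsets"}
    else:
        projected = project_attribute(probs_raw, attr.loc[subsets], subsets=subsets)
        enr = {t: len(enriched_spots(probs_raw, t, grid=grid)) for t in subsets}
        by_domain_cond = {}
        for c in ("healthy", "RPL"):
            m = iz_mask & (cond == c)
            by_domain_cond[c] = float(projected.to_numpy()[m].mean()) if m.any() else None
        stages["spatial_projection"] = {
            "enriched_spot_counts": enr,
            "mean_projected_IZ": by_domain_cond,
        }

    # --- trajectory permutation ------------------------------------------
    cfg = ds.config
    graph = generate_transitions(cfg.transition_groups, cfg.transition_flow,
                                 cfg.transition_from, cfg.transition_to,
                                 seed=rng_seed + 7)
    res = permutation_test(graph, cfg.transition_from, cfg.transition_to,
                           n_perm=config.n_perm, seed=rng_seed + 8)
    stages["trajectory"] = {
        "from": cfg.transition_from, "to": cfg.transition_to,
        "observed_confidence": res.observed, "permutation_p": res.p_value,
        "n_perm": res.n_perm,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
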