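"""Calibration, power and recovery benchmarks for the whole pipeline.

Each function runs one self-contained simulation experiment from scratch —
estimator against brute-force oracle, type-I calibration against an
exchangeable null, power against planted structure, or end-to-end recovery
of the planted disease effects — and returns the measured quantities.  The
test suite asserts on these numbers and ``scripts/acceptance.py`` reports
them.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import coloc as coloc_mod
from . import domains as domains_mod
from . import lr as lr_mod
from .core_io import GeneMatrix
from .mic import mic, mic_exhaustive
from .synthetic import default_config, generate_sections, generate_transitions
from .trajectory import permutation_test, transition_confidence

__all__ = ["mic_oracle_agreement", "lr_screen_calibration", "lr_screen_power",
           "permutation_calibration", "permutation_power", "ancova_recovery",
           "end_to_end_recovery"]


# ---------------------------------------------------------------------------
# MIC
# ---------------------------------------------------------------------------

def mic_oracle_agreement(n_instances: int = 50, n: int = 12, seed: int = 0) -> dict:
    """Dynamic program vs exhaustive grid search, saturation, invariance."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_instances):
        x, y = rng.normal(size=n), rng.normal(size=n)
        max_dev = max(max_dev, abs(mic(x, y) - mic_exhaustive(x, y)))
    x200 = rng.normal(size=200)
    noiseless = mic(x200, x200 ** 3)  # noiseless strictly monotone relationship
    xm, ym = rng.normal(size=120), rng.normal(size=120)
    invariance_dev = abs(mic(xm, ym) - mic(np.exp(xm), ym))
    return {"max_oracle_dev": float(max_dev), "noiseless_monotone_mic": float(noiseless),
            "monotone_invariance_dev": float(invariance_dev),
            "n_instances": n_instances, "n": n}


# ---------------------------------------------------------------------------
# LR screen
# ---------------------------------------------------------------------------

def _hex_grid(rows: int, cols: int, section: str = "bench", condition: str = "healthy"):
    from .synthetic import SyntheticConfig, _section_grid
    cfg = SyntheticConfig(grid_rows=rows, grid_cols=cols)
    return _section_grid(cfg, section, condition, 8.0)


def lr_screen_calibration(n_pairs: int = 1000, n_spots: int = 500, seed: int = 0) -> dict:
    """Fraction of independent white-noise pairs the screen flags (alpha=0.05)."""
    rng = np.random.default_rng(seed)
    rows = max(n_spots // 20, 3)
    grid, _ = _hex_grid(rows, n_spots // rows)
    n = grid.n_spots
    gm = GeneMatrix(values=np.abs(rng.normal(size=(n, 2 * n_pairs))),
                    genes=[f"g{i}" for i in range(2 * n_pairs)],
                    spot_ids=list(grid.spots.index))
    cat = lr_mod.LRCatalog(pairs=pd.DataFrame.from_dict(
        {f"p{i}": {"ligand": (f"g{2 * i}",), "receptor": (f"g{2 * i + 1}",), "pathway": ""}
         for i in range(n_pairs)}, orient="index").rename_axis("pair_id"))
    res = lr_mod.coexpression_screen(gm, cat, grid=grid, alpha=0.05)
    return {"flagged_fraction": float(res["coexpressed"].mean()),
            "n_pairs": n_pairs, "n_spots": n}


def lr_screen_power(n_seeds: int = 100, rho: float = 0.5, seed: int = 0) -> dict:
    """Sensitivity for a planted rho pair on 1000-spot sections across seeds."""
    cfg = default_config(grid_rows=25, grid_cols=40, n_genes=150,
                         n_sections_per_condition=1, signature_genes_per_subset=5,
                         deconv_noise=None)
    pair = dataclasses.replace(cfg.planted_lr_pairs[0], rho=rho)
    cfg = dataclasses.replace(cfg, planted_lr_pairs=(pair,), lr_condition_effect={})
    cat = lr_mod.LRCatalog(pairs=pd.DataFrame.from_dict(
        {pair.pair_id: {"ligand": (pair.ligand,), "receptor": (pair.receptor,),
                        "pathway": ""}}, orient="index").rename_axis("pair_id"))
    hits = 0
    for s in range(n_seeds):
        sec = generate_sections(cfg, seed=seed + s)[0]  # the healthy section
        sm = lr_mod.neighbor_smooth(sec.expression, sec.grid)
        res = lr_mod.coexpression_screen(sm, cat, grid=sec.grid, alpha=0.05)
        hits += int(bool(res.iloc[0]["coexpressed"]))
    return {"sensitivity": hits / n_seeds, "n_seeds": n_seeds,
            "rho": rho, "n_spots": cfg.grid_rows * cfg.grid_cols}


# ---------------------------------------------------------------------------
# trajectory permutation test
# ---------------------------------------------------------------------------

def permutation_calibration(n_datasets: int = 500, n_perm: int = 200,
                            seed: int = 0) -> dict:
    """Null (delta=0) uniformity of the empirical P and type-I rate."""
    groups = {"A": 60, "B": 60, "C": 60}
    ps = np.empty(n_datasets)
    for i in range(n_datasets):
        g = generate_transitions(groups, 0.0, "A", "B", seed=seed + i)
        ps[i] = permutation_test(g, "A", "B", n_perm=n_perm,
                                 seed=seed + 10_000 + i).p_value
    ks = sps.kstest(ps, "uniform").statistic
    return {"ks_d": float(ks), "type_i_rate": float((ps < 0.05).mean()),
            "n_datasets": n_datasets, "n_perm": n_perm}


def permutation_power(n_seeds: int = 100, delta: float = 0.8, n_perm: int = 200,
                      seed: int = 0) -> dict:
    """Fraction of planted-flow datasets with permutation P <= 0.01."""
    groups = {"dNK1": 100, "dNK2": 100}
    hits = 0
    for i in range(n_seeds):
        g = generate_transitions(groups, delta, "dNK2", "dNK1", seed=seed + i)
        p = permutation_test(g, "dNK2", "dNK1", n_perm=n_perm,
                             seed=seed + 20_000 + i).p_value
        hits += int(p <= 0.01)
    return {"frac_p_le_0.01": hits / n_seeds, "n_seeds": n_seeds, "delta": delta}


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def ancova_recovery(n: int = 2000, effect: float = 1.0, n_null: int = 500,
                    seed: int = 0) -> dict:
    """Recover a planted condition effect under a confounded covariate.

    The disease group's gestational age is shifted +1 week and age itself
    carries a slope of 0.3, so the marginal group difference is biased; the
    adjusted contrast should still recover the planted effect.  Also
    reports the null type-I rate and the worst deviation from a direct
    normal-equations solution.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    cond = np.array(["healthy"] * half + ["RPL"] * (n - half), dtype=object)
    age = np.r_[rng.uniform(6, 12, half), rng.uniform(7, 13, n - half)]
    values = 0.3 * age + effect * (cond == "RPL") + rng.normal(0, 1, n)
    est = domains_mod.condition_effect(values, cond, age)
    x = np.column_stack([np.ones(n), (cond == "RPL").astype(float), age])
    beta = np.linalg.solve(x.T @ x, x.T @ values)
    oracle_dev = abs(est.effect - beta[1])
    hits = 0
    m = 100
    cond_null = np.array(["healthy"] * (m // 2) + ["RPL"] * (m // 2), dtype=object)
    for _ in range(n_null):
        age_n = rng.uniform(6, 12, m)
        vals_n = 0.3 * age_n + rng.normal(size=m)
        if domains_mod.condition_effect(vals_n, cond_null, age_n).p_value < 0.05:
            hits += 1
    return {"recovered_effect": est.effect, "true_effect": effect,
            "p_value": est.p_value, "oracle_dev": float(oracle_dev),
            "null_type_i_rate": hits / n_null, "n": n, "n_null": n_null}


# ---------------------------------------------------------------------------
# end-to-end recovery of the planted disease phenotype
# ---------------------------------------------------------------------------

def end_to_end_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Default study conditions: dNK1 depletion, colocalization loss,
    LR score reduction and directed dNK2->dNK1 flow all recovered."""
    cfg = default_config()
    direction_ok = 0
    significant = 0
    for s in range(n_seeds):
        from .synthetic import generate_dataset
        ds = generate_dataset(cfg, seed=seed + s)
        effs = []
        vals, conds, ages = [], [], []
        for sec in ds.sections:
            probs = domains_mod.normalize_probabilities(sec.probabilities, ds.reference)
            m = (sec.truth.domain == "IZ").to_numpy()
            vals.append(probs.column("dNK1")[m])
            conds.append(np.full(int(m.sum()), sec.truth.condition, dtype=object))
            ages.append(np.full(int(m.sum()),
                                float(sec.grid.sections["gestational_age"].iloc[0])))
        eff = domains_mod.condition_effect(np.concatenate(vals), np.concatenate(conds),
                                           np.concatenate(ages))
        direction_ok += int(eff.effect < 0)
        significant += int(eff.effect < 0 and eff.p_value < 0.05)
        if s == 0:
            first = ds
    # (b) colocalization difference, (c) differential LR, (d) trajectory on seed 0
    per_condition: dict[str, list] = {"healthy": [], "RPL": []}
    scores_iz, is_rpl = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sec in first.sections:
            probs = domains_mod.normalize_probabilities(sec.probabilities, first.reference)
            per_condition[sec.truth.condition].append(
                coloc_mod.retain_top_k(coloc_mod.section_coloc(probs), k=5))
            sm = lr_mod.neighbor_smooth(sec.expression, sec.grid)
            sc = lr_mod.spot_score(sm, first.catalog)
            m = (sec.truth.domain == "IZ").to_numpy()
            scores_iz.append(sc.loc[m])
            is_rpl.append(np.full(int(m.sum()), sec.truth.condition == "RPL"))
    avg = {c: coloc_mod.condition_average(ms) for c, ms in per_condition.items()}
    diff = coloc_mod.coloc_difference(avg["RPL"], avg["healthy"])
    dlr = lr_mod.differential_lr(pd.concat(scores_iz), np.concatenate(is_rpl))
    planted = cfg.planted_lr_pairs[0].pair_id
    graph = generate_transitions(cfg.transition_groups, cfg.transition_flow,
                                 cfg.transition_from, cfg.transition_to, seed=seed + 7)
    perm = permutation_test(graph, cfg.transition_from, cfg.transition_to,
                            n_perm=1000, seed=seed + 8)
    return {
        "direction_correct_frac": direction_ok / n_seeds,
        "significant_frac": significant / n_seeds,
        "coloc_diff_dnk1_dm2": float(diff.loc["dNK1", "dM2"]),
        "planted_pair_down_in_rpl_iz": int(bool(dlr.loc[planted, "down"])),
        "transition_perm_p": perm.p_value,
        "transition_confidence": transition_confidence(graph, cfg.transition_from,
                                                       cfg.transition_to),
        "n_seeds": n_seeds,
    }
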