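"""Synthetic Visium-like decidua sections with planted ground truth.

Every downstream stage is exercised against data whose truth is known:

* two spatially contiguous domains on a hex grid — an implantation-zone
  band (IZ) of upper rows over a glandular-secretory zone (GZ);
* per-spot cell-type mixtures drawn from Dirichlet distributions whose
  concentrations depend on domain and condition (immunoregulatory dNK1 and
  dM2 macrophages enriched in healthy IZ and depleted under RPL, CD8 T
  elevated under RPL);
* spot expression as a proportion-weighted mixture of subset mean profiles
  with negative-binomial count noise, then median-depth normalised and
  log1p-transformed;
* planted spatially coexpressed ligand-receptor pairs: a shared smooth
  latent field (squared-exponential kernel) multiplied into both genes in
  the host domain, scaled so their neighbour-smoothed Pearson correlation
  targets a configured rho;
* an optional RPL effect that attenuates a planted pair's interaction
  score in the disease host domain;
* a directed cell-to-cell transition flow between two subsets for the
  trajectory permutation test.

Subset mean profiles are constructed so that every subset spends the same
total expression budget on its signature genes; background genes therefore
have identical relative expression in every subset and carry no
composition-driven correlation, which keeps non-planted catalog pairs null
by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (CellTypeProbabilities, GeneMatrix, SingleCellReference,
                      SpotGrid, COL_STEP_UM, ROW_STEP_UM, normalize_expression,
                      write_expression, write_positions, write_probabilities,
                      write_section_metadata)
from .lr import LRCatalog, neighbor_smooth, write_lr_catalog
from .trajectory import TransitionGraph

__all__ = ["PlantedLRPair", "SyntheticConfig", "SectionTruth", "SectionData",
           "SyntheticDataset", "default_config", "generate_reference",
           "generate_sections", "generate_dataset", "generate_transitions",
           "make_catalog", "write_dataset"]

DEFAULT_SUBSETS = ("dNK1", "dNK2", "dNK3", "dNKp", "dM1", "dM2",
                   "CD8T", "Treg", "dS1", "dS2", "Endo", "EVT")

DEFAULT_BASE_CONCENTRATION = {
    "dNK1": 2.0, "dNK2": 1.5, "dNK3": 1.0, "dNKp": 0.8, "dM1": 1.5, "dM2": 1.5,
    "CD8T": 0.8, "Treg": 0.6, "dS1": 5.0, "dS2": 5.0, "Endo": 1.5, "EVT": 1.0,
}

DEFAULT_DOMAIN_ENRICHMENT = {
    "IZ": {"dNK1": 4.0, "dNK2": 2.0, "dM2": 3.0, "EVT": 2.0},
    "GZ": {"dS1": 1.5, "dS2": 2.5},
}

# disease effect on IZ concentrations: dNK1/dM2 reduced 60%, CD8 T doubled
DEFAULT_RPL_EFFECTS = {"dNK1": 0.4, "dM2": 0.4, "CD8T": 2.0}

SPOT_PITCH_UM = 100.0


@dataclass(frozen=True)
class PlantedLRPair:
    pair_id: str
    ligand: str
    receptor: str
    rho: float
    host_domain: str = "IZ"


@dataclass
class SyntheticConfig:
    """Desk-scale study conditions for the synthetic sections."""

    grid_rows: int = 40
    grid_cols: int = 40
    n_sections_per_condition: int = 3
    iz_fraction: float = 0.4
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    base_concentration: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_CONCENTRATION))
    domain_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_DOMAIN_ENRICHMENT.items()})
    rpl_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RPL_EFFECTS))
    n_genes: int = 1200
    signature_genes_per_subset: int = 20
    signature_shift: float = 2.0  # log-space elevation of signature genes
    mean_counts_per_spot: float = 5000.0
    nb_dispersion: float = 10.0  # negative-binomial size; larger = closer to Poisson
    planted_lr_pairs: tuple[PlantedLRPair, ...] = ()
    lr_condition_effect: dict[str, float] = field(default_factory=dict)
    n_null_lr_pairs: int = 30
    field_length_scale: float = 3.0  # spot pitches
    deconv_noise: float | None = 50.0  # Dirichlet resampling concentration
    gestational_age_weeks: tuple[float, float] = (6.0, 12.0)
    # planted directed transition flow for the trajectory stage
    transition_groups: dict[str, int] = field(
        default_factory=lambda: {"dNK1": 100, "dNK2": 100, "dNK3": 100})
    transition_from: str = "dNK2"
    transition_to: str = "dNK1"
    transition_flow: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.iz_fraction < 1:
            raise ValueError("iz_fraction must lie in (0, 1)")
        if len(self.subsets) < 2 or self.n_genes < 10:
            raise ValueError("need at least 2 subsets and 10 genes")
        for t in self.subsets:
            if self.base_concentration.get(t, 1.0) <= 0:
                raise ValueError(f"concentration for {t!r} must be positive")
        for p in self.planted_lr_pairs:
            if not 0 <= p.rho < 1:
                raise ValueError(f"planted rho must lie in [0, 1): {p.rho}")
        n_sig = len(self.subsets) * self.signature_genes_per_subset
        if n_sig >= self.n_genes:
            raise ValueError("signature genes exhaust the gene panel")
        if not 0.0 <= self.transition_flow <= 1.0:
            raise ValueError("transition_flow must lie in [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def signature_assignment(self) -> dict[str, list[str]]:
        """Disjoint signature gene blocks, one per subset."""
        k = self.signature_genes_per_subset
        names = self.gene_names
        assign = {t: names[i * k:(i + 1) * k] for i, t in enumerate(self.subsets)}
        seen: set[str] = set()
        for t, genes in assign.items():
            dup = seen & set(genes)
            if dup:
                raise ValueError(f"signature gene in two subsets: {sorted(dup)}")
            seen |= set(genes)
        return assign

    def concentration_vector(self, domain: str, condition: str) -> np.ndarray:
        alpha = np.array([self.base_concentration.get(t, 1.0) for t in self.subsets])
        mult = self.domain_enrichment.get(domain, {})
        alpha = alpha * np.array([mult.get(t, 1.0) for t in self.subsets])
        if condition == "RPL" and domain == "IZ":
            alpha = alpha * np.array([self.rpl_effects.get(t, 1.0) for t in self.subsets])
        return alpha


def default_config(**overrides) -> SyntheticConfig:
    """Default study conditions including one planted coexpressed LR pair
    whose interaction score is halved in the RPL implantation zone."""
    cfg = SyntheticConfig(**{k: v for k, v in overrides.items()
                             if k not in {"planted_lr_pairs", "lr_condition_effect"}})
    if "planted_lr_pairs" in overrides:
        planted = overrides["planted_lr_pairs"]
    else:
        n_sig = len(cfg.subsets) * cfg.signature_genes_per_subset
        names = cfg.gene_names
        planted = (PlantedLRPair(pair_id="LRpair_planted", ligand=names[n_sig],
                                 receptor=names[n_sig + 1], rho=0.6, host_domain="IZ"),)
    effect = overrides.get("lr_condition_effect", {planted[0].pair_id: 0.5} if planted else {})
    return dataclasses.replace(cfg, planted_lr_pairs=tuple(planted),
                               lr_condition_effect=dict(effect))


@dataclass
class SectionTruth:
    """Ground truth emitted alongside each synthetic section."""

    proportions: pd.DataFrame  # spots x subsets, rows sum to 1
    domain: pd.Series  # spot -> IZ/GZ
    condition: str
    planted_pairs: tuple[PlantedLRPair, ...]
    lr_condition_effect: dict[str, float]


@dataclass
class SectionData:
    grid: SpotGrid
    expression: GeneMatrix
    probabilities: CellTypeProbabilities
    truth: SectionTruth


@dataclass
class SyntheticDataset:
    sections: list[SectionData]
    reference: SingleCellReference
    catalog: LRCatalog
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def generate_reference(config: SyntheticConfig, seed: int) -> SingleCellReference:
    """Subset mean-expression profiles and reference composition.

    Signature genes are elevated ``exp(signature_shift)``-fold in their own
    subset; each subset's total signature budget is equalised so background
    genes keep identical relative expression everywhere.
    """
    rng = np.random.default_rng(seed)
    assign = config.signature_assignment()
    names = config.gene_names
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    name_to_idx = {g: i for i, g in enumerate(names)}
    # equalise each subset's signature base total
    sig_sums = {t: base[[name_to_idx[g] for g in genes]].sum() for t, genes in assign.items()}
    target = float(np.mean(list(sig_sums.values())))
    for t, genes in assign.items():
        idx = [name_to_idx[g] for g in genes]
        base[idx] *= target / sig_sums[t]
    # planted LR genes sit in the background but at high baseline so their
    # log expression is comfortably above the count-noise floor
    planted_genes = {g for p in config.planted_lr_pairs for g in (p.ligand, p.receptor)}
    sig_all = {g for genes in assign.values() for g in genes}
    overlap = planted_genes & sig_all
    if overlap:
        raise ValueError(f"planted LR genes collide with signature genes: {sorted(overlap)}")
    if planted_genes:
        high = float(np.quantile(base, 0.95))
        for g in planted_genes:
            base[name_to_idx[g]] = high
    shift = np.exp(config.signature_shift)
    profiles = np.tile(base, (len(config.subsets), 1))
    for i, t in enumerate(config.subsets):
        idx = [name_to_idx[g] for g in assign[t]]
        profiles[i, idx] *= shift
    props = pd.Series({t: config.base_concentration.get(t, 1.0) for t in config.subsets})
    props = props / props.sum()
    return SingleCellReference(
        subset_proportions=props,
        subset_mean_expression=pd.DataFrame(profiles, index=list(config.subsets),
                                            columns=names),
        signature_genes=assign)


def make_catalog(config: SyntheticConfig, seed: int) -> LRCatalog:
    """Planted pairs plus null pairs drawn from background genes."""
    rng = np.random.default_rng(seed + 101)
    assign = config.signature_assignment()
    sig_all = {g for genes in assign.values() for g in genes}
    planted_genes = {g for p in config.planted_lr_pairs for g in (p.ligand, p.receptor)}
    background = [g for g in config.gene_names if g not in sig_all | planted_genes]
    chosen = rng.choice(background, size=2 * config.n_null_lr_pairs, replace=False)
    rows = {}
    for p in config.planted_lr_pairs:
        rows[p.pair_id] = {"ligand": (p.ligand,), "receptor": (p.receptor,), "pathway": "planted"}
    for i in range(config.n_null_lr_pairs):
        rows[f"LRpair_null{i:03d}"] = {"ligand": (chosen[2 * i],),
                                       "receptor": (chosen[2 * i + 1],), "pathway": "null"}
    return LRCatalog(pairs=pd.DataFrame.from_dict(rows, orient="index")
                     .rename_axis("pair_id"))


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def _section_grid(config: SyntheticConfig, section_id: str, condition: str,
                  gestational_age: float) -> tuple[SpotGrid, pd.Series]:
    rows, cols = config.grid_rows, config.grid_cols
    r_idx, c_idx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r_idx, c_idx = r_idx.ravel(), c_idx.ravel()
    array_col = 2 * c_idx + (r_idx % 2)
    ids = [f"{section_id}_s{i:05d}" for i in range(rows * cols)]
    spots = pd.DataFrame({
        "array_row": r_idx, "array_col": array_col,
        "x_um": array_col * COL_STEP_UM, "y_um": r_idx * ROW_STEP_UM,
        "section_id": section_id,
    }, index=pd.Index(ids, name="spot_id"))
    domain = pd.Series(np.where(r_idx < config.iz_fraction * rows, "IZ", "GZ"),
                       index=spots.index, name="domain")
    spots["domain"] = domain
    sections = pd.DataFrame({"condition": [condition],
                             "gestational_age": [gestational_age]},
                            index=pd.Index([section_id], name="section_id"))
    return SpotGrid(spots=spots, sections=sections), domain


def _latent_field(xy: np.ndarray, length_um: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth unit-variance field: white noise convolved with an SE kernel."""
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    kern = np.exp(-d2 / (2.0 * length_um ** 2))
    f = kern @ rng.standard_normal(xy.shape[0])
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _plant_lr_fields(values: np.ndarray, grid: SpotGrid, domain: pd.Series,
                     config: SyntheticConfig, gene_idx: dict[str, int],
                     rng: np.random.Generator) -> None:
    """Multiply a shared smooth field into each planted pair's genes (in place).

    The field amplitude is calibrated from the empirical smoothed variances
    so that the neighbour-smoothed Pearson correlation of the two genes
    across the whole section targets the configured rho.
    """
    for pair in config.planted_lr_pairs:
        if pair.rho <= 0:
            continue
        host = (domain == pair.host_domain).to_numpy()
        if host.sum() < 10:
            raise ValueError(f"host domain {pair.host_domain!r} too small for planting")
        li, ri = gene_idx[pair.ligand], gene_idx[pair.receptor]
        f = np.zeros(values.shape[0])
        xy = grid.spots.loc[host, ["x_um", "y_um"]].to_numpy(dtype=float)
        f[host] = _latent_field(xy, config.field_length_scale * SPOT_PITCH_UM, rng)
        probe = GeneMatrix(values=np.column_stack([values[:, li], values[:, ri], f - f.min()]),
                           genes=["_lig", "_rec", "_field"],
                           spot_ids=list(grid.spots.index))
        sm = neighbor_smooth(probe, grid).values
        v_noise = 0.5 * (sm[:, 0].var() + sm[:, 1].var())
        v_field = (sm[:, 2] - sm[:, 2].mean()).var()
        if v_field <= 0:
            continue
        s = np.sqrt(pair.rho * v_noise / ((1.0 - pair.rho) * v_field))
        bump = np.exp(s * f)
        for gi in (li, ri):
            values[:, gi] = np.log1p(np.expm1(values[:, gi]) * bump)


def generate_sections(config: SyntheticConfig, seed: int,
                      reference: SingleCellReference | None = None) -> list[SectionData]:
    """Generate all sections for both conditions under one seed."""
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = generate_reference(config, seed)
    profiles = reference.subset_mean_expression.loc[list(config.subsets)].to_numpy()
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    gene_idx = {g: i for i, g in enumerate(config.gene_names)}
    sections: list[SectionData] = []
    for condition in ("healthy", "RPL"):
        for s in range(config.n_sections_per_condition):
            section_id = f"{condition}_{s}"
            ga = float(np.round(rng.uniform(*config.gestational_age_weeks), 1))
            grid, domain = _section_grid(config, section_id, condition, ga)
            n = grid.n_spots
            props = np.empty((n, len(config.subsets)))
            for dom in ("IZ", "GZ"):
                mask = (domain == dom).to_numpy()
                alpha = config.concentration_vector(dom, condition)
                props[mask] = rng.dirichlet(alpha, size=int(mask.sum()))
            mu = config.mean_counts_per_spot * props @ profiles
            theta = config.nb_dispersion
            lam = rng.gamma(shape=theta, scale=mu / theta)
            counts = rng.poisson(lam).astype(float)
            values = normalize_expression(counts)
            _plant_lr_fields(values, grid, domain, config, gene_idx, rng)
            if condition == "RPL" and config.lr_condition_effect:
                by_id = {p.pair_id: p for p in config.planted_lr_pairs}
                for pid, factor in config.lr_condition_effect.items():
                    pair = by_id[pid]
                    host = (domain == pair.host_domain).to_numpy()
                    for g in (pair.ligand, pair.receptor):
                        values[host, gene_idx[g]] *= np.sqrt(factor)
            expr = GeneMatrix(values=values, genes=config.gene_names,
                              spot_ids=list(grid.spots.index))
            obs = props
            if config.deconv_noise:
                gam = rng.gamma(shape=config.deconv_noise * props + 1e-6, scale=1.0)
                obs = gam / gam.sum(axis=1, keepdims=True)
            probs = CellTypeProbabilities(values=obs, cell_types=list(config.subsets),
                                          spot_ids=list(grid.spots.index), normalized=False)
            truth = SectionTruth(
                proportions=pd.DataFrame(props, index=grid.spots.index,
                                         columns=list(config.subsets)),
                domain=domain, condition=condition,
                planted_pairs=config.planted_lr_pairs,
                lr_condition_effect=dict(config.lr_condition_effect))
            sections.append(SectionData(grid=grid, expression=expr,
                                        probabilities=probs, truth=truth))
    return sections


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    reference = generate_reference(config, seed)
    sections = generate_sections(config, seed, reference=reference)
    catalog = make_catalog(config, seed)
    return SyntheticDataset(sections=sections, reference=reference,
                            catalog=catalog, config=config)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def generate_transitions(n_cells_per_group: dict[str, int], flow_strength: float,
                         from_group: str, to_group: str, seed: int | None = None,
                         noise_shape: float | None = 5.0) -> TransitionGraph:
    """Cell-to-cell transition matrix with a planted directed flow.

    Rows of cells in ``from_group`` mix ``(1 - delta)`` of uniform mass with
    ``delta`` concentrated uniformly on ``to_group`` cells; all other rows
    are uniform.  Multiplicative gamma jitter (shape ``noise_shape``) with
    row renormalisation makes the matrix graph-like and the label
    permutation null non-degenerate; ``noise_shape=None`` disables it.
    """
    delta = float(flow_strength)
    if not 0.0 <= delta <= 1.0:
        raise ValueError("flow_strength must lie in [0, 1]")
    if len(n_cells_per_group) < 2:
        raise ValueError("need at least 2 groups")
    for g in (from_group, to_group):
        if n_cells_per_group.get(g, 0) < 1:
            raise ValueError(f"group {g!r} has no cells")
    rng = np.random.default_rng(seed)
    labels = [g for g, k in n_cells_per_group.items() for _ in range(k)]
    n = len(labels)
    lab = np.asarray(labels, dtype=object)
    to_idx = lab == to_group
    from_idx = lab == from_group
    w = np.full((n, n), 1.0 / n)
    target = np.where(to_idx, 1.0 / to_idx.sum(), 0.0)
    w[from_idx] = (1.0 - delta) / n + delta * target
    if noise_shape:
        w = w * rng.gamma(shape=noise_shape, scale=1.0, size=(n, n))
    w = w / w.sum(axis=1, keepdims=True)
    return TransitionGraph(weights=w, labels=labels)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Emit the standard on-disk formats plus a truth JSON per section."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.concat([s.grid.sections for s in ds.sections])
    write_section_metadata(meta, out_dir / "sections.yaml")
    write_lr_catalog(ds.catalog, out_dir / "lr_catalog.tsv")
    ds.reference.subset_proportions.rename("proportion").to_csv(
        out_dir / "reference_proportions.tsv", sep="\t")
    ds.reference.subset_mean_expression.rename_axis("subset").to_csv(
        out_dir / "reference_profiles.tsv", sep="\t", float_format="%.8g")
    for sec in ds.sections:
        sid = sec.grid.sections.index[0]
        sec_dir = out_dir / sid
        sec_dir.mkdir(exist_ok=True)
        write_expression(sec.expression, sec_dir)
        write_positions(sec.grid, sec_dir / "tissue_positions.csv")
        write_probabilities(sec.probabilities, sec_dir / "probabilities.tsv")
        sec.truth.proportions.rename_axis("spot_id").to_csv(
            sec_dir / "true_proportions.tsv", sep="\t", float_format="%.8g")
        truth = {
            "condition": sec.truth.condition,
            "domain_counts": sec.truth.domain.value_counts().to_dict(),
            "planted_pairs": [dataclasses.asdict(p) for p in sec.truth.planted_pairs],
            "lr_condition_effect": sec.truth.lr_condition_effect,
        }
        (sec_dir / "truth.json").write_text(json.dumps(truth, indent=1))
        sec.truth.domain.rename("domain").rename_axis("spot_id").to_csv(
            sec_dir / "domains.tsv", sep="\t")
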