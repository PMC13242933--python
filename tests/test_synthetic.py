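"""Generator contracts: determinism, planted structure, calibrated correlations."""

import numpy as np
import pytest

from decidua_niche import synthetic
from decidua_niche.lr import neighbor_smooth
from decidua_niche.synthetic import (PlantedLRPair, SyntheticConfig,
                                     default_config, generate_dataset,
                                     generate_reference, generate_sections,
                                     generate_transitions)


class TestReference:
    def test_signature_elevation_by_construction(self, small_config):
        ref = generate_reference(small_config, seed=3)
        shift = np.exp(small_config.signature_shift)
        for t, genes in ref.signature_genes.items():
            others = [u for u in ref.subsets if u != t]
            own = ref.subset_mean_expression.loc[t, genes].to_numpy()
            other = ref.subset_mean_expression.loc[others, genes].to_numpy()
            assert np.allclose(own / other, shift)

    def test_zero_shift_gives_identical_profiles(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, signature_shift=0.0)
        ref = generate_reference(cfg, seed=3)
        prof = ref.subset_mean_expression.to_numpy()
        assert np.allclose(prof, prof[0][None, :])

    def test_same_seed_reproduces(self, small_config):
        r1 = generate_reference(small_config, seed=9)
        r2 = generate_reference(small_config, seed=9)
        assert r1.subset_mean_expression.equals(r2.subset_mean_expression)
        assert r1.subset_proportions.equals(r2.subset_proportions)

    def test_planted_gene_collision_with_signature_rejected(self, small_config):
        import dataclasses
        bad = dataclasses.replace(
            small_config,
            planted_lr_pairs=(PlantedLRPair("bad", "G0000", "G0200", 0.5, "IZ"),))
        with pytest.raises(ValueError, match="collide"):
            generate_reference(bad, seed=0)


class TestSections:
    def test_domain_band_geometry(self, small_dataset, small_config):
        s = small_dataset.sections[0]
        rows = s.grid.spots["array_row"]
        iz_rows = rows[s.truth.domain == "IZ"]
        gz_rows = rows[s.truth.domain == "GZ"]
        assert iz_rows.max() < gz_rows.min()  # IZ is the upper band
        assert iz_rows.max() + 1 == pytest.approx(
            small_config.iz_fraction * small_config.grid_rows)

    def test_proportions_rows_sum_to_one(self, small_dataset):
        for s in small_dataset.sections:
            assert np.allclose(s.truth.proportions.sum(axis=1), 1.0)
            assert np.all(s.expression.values >= 0)

    def test_rpl_depletes_dnk1_in_iz(self, small_dataset):
        by_cond = {}
        for s in small_dataset.sections:
            m = (s.truth.domain == "IZ").to_numpy()
            by_cond[s.truth.condition] = s.truth.proportions["dNK1"].to_numpy()[m].mean()
        assert by_cond["RPL"] < by_cond["healthy"]

    def test_concentration_monotonicity(self, small_config):
        """Doubling a subset's IZ concentration raises its mean IZ proportion."""
        import dataclasses
        boosted = dataclasses.replace(
            small_config,
            domain_enrichment={**small_config.domain_enrichment,
                               "IZ": {**small_config.domain_enrichment["IZ"],
                                      "Treg": 2.0}})
        base = generate_sections(small_config, seed=5)[0]
        high = generate_sections(boosted, seed=5)[0]
        m = (base.truth.domain == "IZ").to_numpy()
        assert high.truth.proportions["Treg"].to_numpy()[m].mean() > \
            base.truth.proportions["Treg"].to_numpy()[m].mean()

    def test_determinism_under_fixed_seed(self, small_config):
        a = generate_sections(small_config, seed=21)[0]
        b = generate_sections(small_config, seed=21)[0]
        assert np.array_equal(a.expression.values, b.expression.values)
        assert np.array_equal(a.probabilities.values, b.probabilities.values)

    def test_zero_rho_pair_is_independent(self):
        cfg = default_config(grid_rows=20, grid_cols=16, n_genes=200,
                             n_sections_per_condition=1, signature_genes_per_subset=5)
        import dataclasses
        p = cfg.planted_lr_pairs[0]
        cfg = dataclasses.replace(
            cfg, planted_lr_pairs=(dataclasses.replace(p, rho=0.0),),
            lr_condition_effect={})
        rhos = []
        for seed in range(15):
            s = generate_sections(cfg, seed=seed)[0]
            sm = neighbor_smooth(s.expression, s.grid)
            rhos.append(np.corrcoef(sm.gene_values(p.ligand),
                                    sm.gene_values(p.receptor))[0, 1])
        assert abs(np.mean(rhos)) < 0.1

    def test_planted_rho_calibration(self):
        """Realized smoothed correlation tracks the target over many seeds."""
        cfg = default_config(grid_rows=50, grid_cols=40, n_genes=150,
                             n_sections_per_condition=1,
                             signature_genes_per_subset=5, deconv_noise=None)
        p = cfg.planted_lr_pairs[0]
        assert p.rho == 0.6
        rhos = []
        for seed in range(50):
            s = generate_sections(cfg, seed=seed)[0]  # healthy, 2000 spots
            sm = neighbor_smooth(s.expression, s.grid)
            rhos.append(np.corrcoef(sm.gene_values(p.ligand),
                                    sm.gene_values(p.receptor))[0, 1])
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)


class TestTransitions:
    def test_zero_flow_matches_uniform_null(self):
        g = generate_transitions({"A": 40, "B": 60}, 0.0, "A", "B",
                                 seed=0, noise_shape=None)
        from decidua_niche.trajectory import transition_confidence
        assert transition_confidence(g, "A", "B") == pytest.approx(0.6, abs=1e-12)

    def test_full_flow_concentrates_all_mass(self):
        g = generate_transitions({"dNK2": 30, "dNK1": 50, "dNK3": 20}, 1.0,
                                 "dNK2", "dNK1", seed=0, noise_shape=None)
        from decidua_niche.trajectory import transition_confidence
        assert transition_confidence(g, "dNK2", "dNK1") == pytest.approx(1.0, abs=1e-12)

    def test_half_flow_closed_form_expectation(self):
        """delta=0.5 -> confidence 0.5 + 0.5 * to-group fraction (averaged over jitter)."""
        from decidua_niche.trajectory import transition_confidence
        vals = [transition_confidence(
            generate_transitions({"dNK2": 60, "dNK1": 90, "dNK3": 50}, 0.5,
                                 "dNK2", "dNK1", seed=s), "dNK2", "dNK1")
            for s in range(30)]
        expected = 0.5 + 0.5 * (90 / 200)
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_invalid_flow_rejected(self):
        with pytest.raises(ValueError):
            generate_transitions({"A": 5, "B": 5}, 1.5, "A", "B")


class TestDatasetEmission:
    def test_write_dataset_round_trip(self, tmp_path):
        cfg = default_config(grid_rows=6, grid_cols=5, n_genes=60,
                             n_sections_per_condition=1,
                             signature_genes_per_subset=2, n_null_lr_pairs=3)
        ds = generate_dataset(cfg, seed=2)
        synthetic.write_dataset(ds, tmp_path)
        from decidua_niche import core_io, lr
        sid = ds.sections[0].grid.sections.index[0]
        back = core_io.read_expression(tmp_path / sid / "matrix.mtx",
                                       tmp_path / sid / "barcodes.tsv",
                                       tmp_path / sid / "features.tsv", raw=True)
        assert np.allclose(back.values, ds.sections[0].expression.values, atol=1e-12)
        cat = lr.read_lr_catalog(tmp_path / "lr_catalog.tsv")
        assert set(cat.pair_ids) == set(ds.catalog.pair_ids)
        meta = core_io.read_section_metadata(tmp_path / "sections.yaml")
        assert set(meta.index) == {s.grid.sections.index[0] for s in ds.sections}
        truth = (tmp_path / sid / "truth.json").read_text()
        assert "planted_pairs" in truth
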