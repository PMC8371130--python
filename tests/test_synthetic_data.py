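import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioscreen import synthetic_data as synth
from cardioscreen.validation_stats import _mannwhitney_p


class TestGenerateLibrary:
    def test_full_scale_matches_published_library_shape(self):
        lib = synth.generate_library(4625, seed=1)
        per_gene = lib.table.groupby("gene").size()
        assert len(per_gene) == 4625
        assert per_gene.median() == 6
        assert per_gene.between(1, 18).all()
        # ~27,500 shRNAs in total, within 4 SD of the sampler's mean
        sd = np.sqrt(4625 * 17 * 0.291 * 0.709)
        assert abs(lib.n_shrnas - 27_500) < 4 * sd + 50

    def test_degenerate_single_gene(self):
        lib = synth.generate_library(1, shrna_count_sampler=6, seed=0)
        assert lib.n_shrnas == 6
        assert lib.genes == ["GENE0000"]

    def test_deterministic_given_seed(self):
        a = synth.generate_library(50, seed=9).table
        b = synth.generate_library(50, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_n_genes(self):
        with pytest.raises(ValueError):
            synth.generate_library(0)


class TestSimulateShrnaCounts:
    def test_fold_change_recovered_in_mean_ratio(self):
        lib = synth.generate_library(20, shrna_count_sampler=6, seed=3)
        gene = lib.genes[0]
        ratios = []
        for rep in range(100):
            cfg = synth.SimulationConfig(seed=1000 + rep, depth=2_000_000, dispersion=0.1)
            counts = synth.simulate_shrna_counts(lib, [synth.EffectSpec(gene, "enriched", 4.0)], cfg)
            sub = counts[counts["gene"] == gene]
            ratios.append(sub["count_treatment"].sum() / sub["count_control"].sum())
        assert 3.0 <= np.mean(ratios) <= 5.0

    def test_null_log_ratios_centred_at_zero(self):
        lib = synth.generate_library(100, shrna_count_sampler=6, seed=4)
        cfg = synth.SimulationConfig(seed=5, depth=1_000_000, dispersion=0.1)
        counts = synth.simulate_shrna_counts(lib, [], cfg)
        lr = np.log2((counts["count_treatment"] + 0.5) / (counts["count_control"] + 0.5))
        assert abs(lr.mean()) < 0.05

    def test_samples_sum_to_depth(self):
        lib = synth.generate_library(30, seed=6)
        cfg = synth.SimulationConfig(seed=7, depth=500_000, dispersion=0.1)
        counts = synth.simulate_shrna_counts(lib, [], cfg)
        assert counts["count_control"].sum() == 500_000
        assert counts["count_treatment"].sum() == 500_000

    def test_unknown_effect_gene_rejected(self):
        lib = synth.generate_library(5, seed=0)
        cfg = synth.SimulationConfig(seed=0, depth=1000)
        with pytest.raises(ValueError, match="unknown gene"):
            synth.simulate_shrna_counts(lib, [synth.EffectSpec("NOPE", "enriched", 2.0)], cfg)

    def test_nb_mean_variance_relation(self):
        # dispersion law: var ~= mu + alpha mu^2 across replicate draws.  The
        # fixed-depth multinomial conditioning shrinks variances by O(1/K), so
        # the library must be large enough for the NB marginal approximation
        lib = synth.generate_library(30, shrna_count_sampler=6, seed=8)
        draws = []
        for rep in range(1000):
            cfg = synth.SimulationConfig(seed=rep, depth=100_000, dispersion=0.2)
            draws.append(synth.simulate_shrna_counts(lib, [], cfg)["count_control"].to_numpy())
        arr = np.vstack(draws)
        mu = arr.mean(axis=0)
        var = arr.var(axis=0, ddof=1)
        expected = mu + 0.2 * mu**2
        assert np.all(np.abs(var / expected - 1.0) < 0.2)

    def test_deterministic_given_config(self):
        lib = synth.generate_library(10, seed=1)
        cfg = synth.SimulationConfig(seed=42, depth=10_000)
        a = synth.simulate_shrna_counts(lib, [], cfg)
        b = synth.simulate_shrna_counts(lib, [], cfg)
        pd.testing.assert_frame_equal(a, b)


class TestEffectSpec:
    @pytest.mark.parametrize("direction,fold", [("enriched", 0.5), ("depleted", 2.0), ("sideways", 2.0)])
    def test_inconsistent_specs_rejected(self, direction, fold):
        with pytest.raises(ValueError):
            synth.EffectSpec("G", direction, fold)


class TestDrugPlates:
    def test_treated_controls_centred_at_viability_ratio(self):
        cfg = synth.SimulationConfig(seed=10, n_drugs=5)
        plates = synth.simulate_drug_plates(cfg)
        dmso = plates[plates["drug"] == "DMSO"]
        means = dmso.groupby("condition")["rlu"].mean()
        ratio = means["hypoxia_reoxygenation"] / means["normoxia"]
        assert ratio == pytest.approx(0.78, abs=0.03)

    def test_every_drug_has_full_design(self):
        cfg = synth.SimulationConfig(seed=11, n_drugs=4, dmso_wells=2)
        plates = synth.simulate_drug_plates(cfg)
        for _, sub in plates[plates["drug"] != "DMSO"].groupby("drug"):
            assert len(sub) == 8  # 4 concentrations x 2 conditions
            assert set(sub["condition"]) == {"normoxia", "hypoxia_reoxygenation"}

    def test_zero_drugs_gives_dmso_only(self):
        cfg = synth.SimulationConfig(seed=12, n_drugs=0, dmso_wells=3)
        plates = synth.simulate_drug_plates(cfg)
        assert set(plates["drug"]) == {"DMSO"}

    def test_zero_dmso_wells_rejected(self):
        cfg = synth.SimulationConfig(seed=12, n_drugs=1, dmso_wells=0)
        with pytest.raises(ValueError):
            synth.simulate_drug_plates(cfg)

    def test_protective_spike_exceeds_threshold_in_most_seeds(self):
        # a 1.2x treated boost should clear the DMSO mean + 1 SD rule nearly always
        from cardioscreen import drug_screen as ds
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = synth.SimulationConfig(seed=seed, n_drugs=1, dmso_wells=32)
            plates = synth.simulate_drug_plates(cfg, protective={"drug0000": 1.2})
            norm = ds.dmso_normalize(plates)
            dmso_t = norm[(norm["drug"] == "DMSO") & (norm["condition"] == "hypoxia_reoxygenation")]
            rep, _ = ds.representative_value(norm[norm["drug"] == "drug0000"])
            thr = dmso_t["relative_viability"].mean() + dmso_t["relative_viability"].std(ddof=1)
            hits += rep > thr
        assert hits / n_seeds > 0.9


class TestPpiAndPathways:
    def test_complete_graph(self):
        edges, _ = synth.generate_ppi_and_pathways(10, 1.0, 1, [3], seed=0)
        assert len(edges) == 45

    def test_empty_graph(self):
        edges, _ = synth.generate_ppi_and_pathways(10, 0.0, 1, [3], seed=0)
        assert edges == []

    def test_simple_graph_invariants(self):
        edges, pathways = synth.generate_ppi_and_pathways(40, 0.2, 5, (2, 10), seed=1)
        assert all(a < b for a, b in edges)
        assert len(set(edges)) == len(edges)
        universe = {f"P{i:04d}" for i in range(40)}
        for members in pathways.values():
            assert set(members) <= universe
            assert len(set(members)) == len(members)

    def test_oversized_pathway_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_ppi_and_pathways(5, 0.5, 1, [10], seed=0)


class TestEmbryoCohort:
    def test_certain_death_zeroes_readouts(self):
        df = synth.simulate_embryo_cohort({"g": 30.0}, 4.0, 12, death_probs=1.0, seed=1)
        assert (df["ef_percent"] == 0).all()
        assert (df["heart_rate_bpm"] == 0).all()
        assert (~df["alive"]).all()

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_embryo_cohort({"g": 30.0}, 4.0, -1, seed=1)

    def test_null_mwu_p_uniform_over_seeds(self):
        ps = []
        for seed in range(200):
            df = synth.simulate_embryo_cohort({"a": 33.0, "b": 33.0}, 4.0, 30, seed=seed)
            x = df.loc[df["group"] == "a", "ef_percent"].to_numpy()
            y = df.loc[df["group"] == "b", "ef_percent"].to_numpy()
            ps.append(_mannwhitney_p(x, y))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_published_effect_size_detected_with_power(self):
        hits = 0
        for seed in range(100):
            df = synth.simulate_embryo_cohort(
                {"normoxia": 37.2, "hypoxia_reoxygenation": 28.4}, 4.0,
                {"normoxia": 20, "hypoxia_reoxygenation": 30}, seed=seed)
            x = df.loc[df["group"] == "normoxia", "ef_percent"].to_numpy()
            y = df.loc[df["group"] == "hypoxia_reoxygenation", "ef_percent"].to_numpy()
            hits += _mannwhitney_p(x, y) < 0.05
        assert hits / 100 > 0.9
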