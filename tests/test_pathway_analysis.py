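import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioscreen import pathway_analysis as pa


def _counts_frame(genes, control, treatment):
    n = len(genes)
    return pd.DataFrame({
        "shrna_id": [f"sh{i}" for i in range(n)],
        "gene": genes,
        "count_control": np.asarray(control, float),
        "count_treatment": np.asarray(treatment, float),
        "plasmid_expected": np.full(n, 100.0),
    })


class TestFilterShrnaTargets:
    def test_thirty_percent_boundary_inclusive(self):
        # both samples sum to 30 so depth normalization is the identity
        df = _counts_frame(["A", "B", "C", "D"], [10, 10, 3, 7], [13, 12.9, 0.1, 4])
        res = pa.filter_shrna_targets(df, target=30.0).set_index("gene")
        assert bool(res.loc["A", "included"])       # exactly 30% up, inclusive
        assert not bool(res.loc["B", "included"])   # 29% up
        assert not bool(res.loc["C", "included"])

    def test_zero_control_positive_treatment_flagged_included(self):
        df = _counts_frame(["A", "B"], [0, 100], [50, 50])
        res = pa.filter_shrna_targets(df, target=100.0).set_index("gene")
        assert bool(res.loc["A", "included"])
        assert bool(res.loc["A", "flagged"])

    def test_matches_brute_force_median_scan(self):
        rng = np.random.default_rng(21)
        genes = [f"G{i // 4}" for i in range(200)]
        df = _counts_frame(genes, rng.integers(0, 300, 200), rng.integers(0, 300, 200))
        total = 20e6
        res = pa.filter_shrna_targets(df).set_index("gene")
        cn = df["count_control"] * total / df["count_control"].sum()
        tn = df["count_treatment"] * total / df["count_treatment"].sum()
        for gene in set(genes):
            mask = np.asarray(genes) == gene
            mc, mt = np.median(cn[mask]), np.median(tn[mask])
            expected = (mt > 0) and (mc == 0 or mt >= 1.3 * mc)
            assert bool(res.loc[gene, "included"]) == expected


class TestSelectDrugTargets:
    def _scores(self):
        return pd.DataFrame({
            "drug": ["a", "b", "c"],
            "representative_value": [0.9, 0.95, 0.7],
            "normoxic_at_representative": [1.0, 1.05, 0.99],
            "protective": [True, True, False],
        })

    def test_shared_target_appears_once_with_mean_value(self):
        ann = pd.DataFrame({"drug": ["a", "b", "c"], "target": ["X", "X", "Y"],
                            "interaction_term": ["inhibitor"] * 3})
        res = pa.select_drug_targets(self._scores(), ann)
        assert list(res["gene"]) == ["X"]
        assert res["value_treatment"].iloc[0] == pytest.approx((0.9 + 0.95) / 2)

    def test_no_protective_drugs_gives_empty_set(self):
        scores = self._scores().assign(protective=False)
        ann = pd.DataFrame({"drug": ["a"], "target": ["X"], "interaction_term": ["inhibitor"]})
        assert pa.select_drug_targets(scores, ann).empty

    def test_matches_brute_force_filter_join(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            drugs = [f"d{i}" for i in range(8)]
            scores = pd.DataFrame({
                "drug": drugs,
                "representative_value": rng.uniform(0.5, 1.5, 8),
                "normoxic_at_representative": rng.uniform(0.8, 1.2, 8),
                "protective": rng.random(8) < 0.5,
            })
            ann = pd.DataFrame({
                "drug": rng.choice(drugs, 15),
                "target": rng.choice([f"T{i}" for i in range(6)], 15),
                "interaction_term": "inhibitor",
            }).drop_duplicates(["drug", "target"])
            res = pa.select_drug_targets(scores, ann)
            prot = set(scores.loc[scores["protective"], "drug"])
            expected = sorted({t for d, t in zip(ann["drug"], ann["target"]) if d in prot})
            assert list(res["gene"]) == expected


class TestMcmlReduce:
    def test_identical_clouds_score_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        rc, rt = pa.mcml_reduce(x, x.copy())
        assert pa.pathway_score(rc, rt) == 0.0

    def test_one_dimensional_limit_preserves_separation(self):
        rng = np.random.default_rng(31)
        xc = rng.normal(0.0, 0.1, 20)
        xt = rng.normal(3.0, 0.1, 20)
        rc, rt = pa.mcml_reduce(xc, xt)
        raw = xt.mean() - xc.mean()
        assert abs(rt - rc) >= raw * (1 - 1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(32)
        xc, xt = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        perm = rng.permutation(15)
        a = pa.mcml_reduce(xc, xt)
        b = pa.mcml_reduce(xc[perm], xt[perm])
        assert a == pytest.approx(b, rel=1e-12)

    def test_condition_swap_flips_score_sign(self):
        rng = np.random.default_rng(33)
        xc, xt = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
        rc, rt = pa.mcml_reduce(xc, xt)
        rc2, rt2 = pa.mcml_reduce(xt, xc)
        assert pa.pathway_score(rc, rt) == pytest.approx(-pa.pathway_score(rc2, rt2))

    def test_multidimensional_projection_separates_classes(self):
        # separation lives on axis 0; axis 1 is shared noise the metric should discount
        rng = np.random.default_rng(34)
        xc = np.column_stack([rng.normal(0, 0.2, 25), rng.normal(0, 2.0, 25)])
        xt = np.column_stack([rng.normal(2, 0.2, 25), rng.normal(0, 2.0, 25)])
        rc, rt = pa.mcml_reduce(xc, xt)
        assert abs(rt - rc) > 1.0

    def test_singleton_uses_raw_values(self):
        rc, rt = pa.mcml_reduce([0.4], [0.9])
        assert (rc, rt) == (0.4, 0.9)

    def test_score_examples(self):
        assert pa.pathway_score(0.4, 0.4) == 0.0
        assert pa.pathway_score(0.2, 0.7) == pytest.approx(0.5)


class TestEpanechnikovKde:
    def test_cdf_monotone_zero_to_one(self):
        rng = np.random.default_rng(41)
        s = rng.normal(0, 1, 500)
        grid = np.linspace(-5, 5, 201)
        cdf = pa.epanechnikov_cdf(grid, s)
        assert cdf[0] == 0.0 and cdf[-1] == 1.0
        assert np.all(np.diff(cdf) >= 0)

    def test_cdf_tracks_empirical_cdf(self):
        rng = np.random.default_rng(42)
        s = rng.normal(0, 1, 10_000)
        grid = np.linspace(-2.5, 2.5, 41)
        emp = np.array([(s <= g).mean() for g in grid])
        assert np.abs(pa.epanechnikov_cdf(grid, s) - emp).max() < 0.02

    def test_median_observation_has_half_p(self):
        rng = np.random.default_rng(43)
        s = rng.normal(0, 1, 2000)
        p = pa.kde_tail_p(float(np.median(s)), s, "upper")
        assert p == pytest.approx(0.5, abs=0.05)

    def test_extreme_observation_clamped_small(self):
        rng = np.random.default_rng(44)
        s = rng.normal(0, 1, 10_000)
        p = pa.kde_tail_p(s.max() + 10, s, "upper")
        assert p <= 1 / 10_001 + 1e-12
        assert p < 0.01

    def test_degenerate_null_direct_comparison(self):
        assert pa.kde_tail_p(0.5, np.zeros(100), "upper") < 0.01
        assert pa.kde_tail_p(-0.5, np.zeros(100), "upper") == 1.0


class TestScoreNullP:
    @pytest.fixture(scope="class")
    def universe(self):
        rng = np.random.default_rng(51)
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(200)],
            "value_control": rng.normal(10, 2, 200),
            "value_treatment": rng.normal(10, 2, 200),
        })

    def test_null_pathways_give_uniformish_p(self, universe):
        rng = np.random.default_rng(52)
        ps = []
        for j in range(60):
            idx = rng.choice(200, 15, replace=False)
            rc, rt = pa.mcml_reduce(universe["value_control"].to_numpy()[idx],
                                    universe["value_treatment"].to_numpy()[idx])
            ps.append(pa.score_null_p(pa.pathway_score(rc, rt), universe, 15, 500, "shrna", seed=j))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tail_convention_upper_vs_lower(self, universe):
        big = 100.0
        assert pa.score_null_p(big, universe, 10, 200, "shrna", seed=0) < 0.01
        assert pa.score_null_p(big, universe, 10, 200, "drug", seed=0) > 0.99

    def test_too_few_permutations_rejected(self, universe):
        with pytest.raises(ValueError):
            pa.score_null_p(0.0, universe, 10, 50, "shrna", seed=0)


class TestFitnessP:
    def test_occupancy_arithmetic(self):
        members = [f"M{i}" for i in range(8)]
        hits = members[:3] + [f"H{i}" for i in range(20)]
        universe = members + [f"U{i}" for i in range(100)]
        p, found, length = pa.fitness_p(members, hits, universe, n_sets=100, seed=1)
        assert (found, length) == (3, 8)
        assert found / length == pytest.approx(0.375)

    def test_no_overlap_gives_large_p(self):
        members = ["A", "B", "C"]
        universe = members + [f"U{i}" for i in range(50)]
        p, found, _ = pa.fitness_p(members, [f"H{i}" for i in range(10)] + ["U1"], universe,
                                   n_sets=100, seed=2)
        assert found == 0
        assert p > 0.5

    def test_hypergeometric_expectation_gives_half_p(self):
        # observed occupancy equal to the sampling expectation should sit mid-null
        universe = [f"U{i}" for i in range(200)]
        members = universe[:40]  # with a 50-protein hit set, expected found = 40 * 50/200 = 10
        hit = members[:10] + universe[40:80]
        p, found, length = pa.fitness_p(members, hit, universe, n_sets=1000, seed=4)
        assert found / length == pytest.approx(50 / 200)
        assert p == pytest.approx(0.5, abs=0.1)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            pa.fitness_p([], ["A"], ["A", "B"], n_sets=10, seed=0)


class TestRankPathways:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["pathway", "genes_found", "pathway_length",
                                           "reduced_control", "reduced_treatment",
                                           "score", "p_value", "p_fitness"])

    def test_rounding_rules(self):
        df = self._scores([
            ("borderline_in", 3, 10, 0, 0, 0, 0.0504, 0.05),
            ("fitness_out", 3, 10, 0, 0, 0, 0.01, 0.101),
            ("clear_in", 3, 10, 0, 0, 0, 0.001, 0.001),
            ("score_out", 3, 10, 0, 0, 0, 0.0506, 0.05),
        ])
        out = pa.rank_pathways(df)
        assert list(out["pathway"]) == ["clear_in", "borderline_in"]

    def test_reported_schema(self):
        out = pa.rank_pathways(self._scores([("p", 2, 5, 0, 0, 0, 0.01, 0.01)]))
        assert list(out.columns) == ["pathway", "genes_found", "pathway_length", "p_value", "p_fitness"]
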