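"""The gamma-Poisson trio-cohort simulator and its invariants."""

import numpy as np
import pandas as pd
import pytest

from dnmcross import simulate as sim
from dnmcross.classify import classify
from dnmcross.simulate import ConfigurationError, SimulationConfig


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_genes == 2000
        assert cfg.per_trio_rate["LoF"] == pytest.approx(411 / 3391)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"control_trios": 0},
            {"dmis_fraction": 1.2},
            {"shared_pool_fraction": -0.1},
            {"beta": 0.0},
            {"gamma_bar": {"LoF": 0.5, "Dmis": 4.7}},
            {"per_trio_rate": {"LoF": 0.0, "mis": 0.5, "synonymous": 0.2}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip_reproduces_simulation(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_genes=100,
                               cohorts=[("A", 50), ("B", 40)],
                               pi={"A": 0.1, "B": 0.1})
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        cfg2 = SimulationConfig.from_yaml(path)
        uni1, cohorts1 = sim.simulate_study(cfg)
        uni2, cohorts2 = sim.simulate_study(cfg2)
        pd.testing.assert_frame_equal(uni1.mu, uni2.mu)
        assert [c.records for c in cohorts1] == [c.records for c in cohorts2]


class TestGeneUniverse:
    def test_single_gene_carries_the_whole_class_rate(self):
        cfg = SimulationConfig(
            n_genes=1, cohorts=[("A", 10)], pi={"A": 0.0},
            per_trio_rate={"LoF": 0.1, "mis": 0.5, "synonymous": 0.275},
        )
        uni = sim.build_gene_universe(cfg)
        assert 2 * uni.mu["synonymous"].iloc[0] == pytest.approx(0.275)

    def test_rate_conservation_across_classes(self):
        cfg = SimulationConfig(seed=3)
        uni = sim.build_gene_universe(cfg)
        assert 2 * uni.mu["LoF"].sum() == pytest.approx(411 / 3391, abs=1e-9)
        mis = cfg.per_trio_rate["mis"]
        assert 2 * (uni.mu["Dmis"] + uni.mu["Tmis"]).sum() == pytest.approx(mis, abs=1e-9)
        assert 2 * uni.mu["Dmis"].sum() == pytest.approx(mis * cfg.dmis_fraction, abs=1e-9)
        assert 2 * uni.mu["synonymous"].sum() == pytest.approx(932 / 3391, abs=1e-9)

    def test_same_seed_same_rates(self):
        cfg = SimulationConfig(seed=11)
        pd.testing.assert_frame_equal(
            sim.build_gene_universe(cfg).mu, sim.build_gene_universe(cfg).mu
        )


class TestRiskAssignment:
    def test_pi_zero_leaves_all_relative_risks_at_one(self, rng):
        cfg = SimulationConfig(n_genes=200, cohorts=[("A", 10)], pi={"A": 0.0})
        uni = sim.assign_risk_genes(sim.build_gene_universe(cfg), cfg, rng)
        assert not uni.risk_status.to_numpy().any()
        for cls in ("LoF", "Dmis"):
            assert (uni.rel_risk[cls].to_numpy() == 1.0).all()

    def test_full_sharing_gives_identical_risk_sets(self, rng):
        cfg = SimulationConfig(
            n_genes=500, cohorts=[("A", 10), ("B", 10)],
            pi={"A": 0.05, "B": 0.05}, shared_pool_fraction=1.0,
        )
        uni = sim.assign_risk_genes(sim.build_gene_universe(cfg), cfg, rng)
        a = set(uni.risk_status.index[uni.risk_status["A"]])
        b = set(uni.risk_status.index[uni.risk_status["B"]])
        assert a == b and len(a) == 25  # Jaccard exactly 1

    def test_pairwise_overlap_matches_hypergeometric_expectation(self):
        """With pi=0.05, n=2000, half-shared pools: each disorder draws 50 of
        its 100 risk genes from a 100-gene common pool, so the expected
        pairwise overlap is the hypergeometric mean 50*50/100 = 25."""
        obs = []
        for seed in range(200):
            uni = sim.build_universe(SimulationConfig(seed=seed))
            r = uni.risk_status
            obs.append(int((r["ASD"] & r["UDD"]).sum()))
        se = np.std(obs, ddof=1) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - 25.0) < 3 * se

    def test_tiny_pi_warns_and_assigns_none(self, rng, caplog):
        cfg = SimulationConfig(n_genes=10, cohorts=[("A", 10)], pi={"A": 0.05})
        with caplog.at_level("WARNING"):
            uni = sim.assign_risk_genes(sim.build_gene_universe(cfg), cfg, rng)
        assert not uni.risk_status["A"].any()


class TestSimulateCohort:
    def test_zero_trios_gives_no_records(self, rng):
        uni = sim.build_universe(SimulationConfig(n_genes=50, cohorts=[("A", 10)],
                                                  pi={"A": 0.0}))
        cohort = sim.simulate_cohort(uni, "A", 0, rng)
        assert cohort.records == []

    def test_unknown_disorder_rejected(self, rng):
        uni = sim.build_universe(SimulationConfig(n_genes=10, cohorts=[("A", 10)],
                                                  pi={"A": 0.0}))
        with pytest.raises(KeyError):
            sim.simulate_cohort(uni, "XYZ", 10, rng)

    def test_control_synonymous_total_near_published_marginal(self, rng):
        uni = sim.build_universe(SimulationConfig(seed=8))
        cohort = sim.simulate_cohort(uni, "control", 3391, rng)
        syn = sum(1 for r in cohort.records if r.consequence == "synonymous")
        assert abs(syn - 932) < 3 * np.sqrt(932)

    def test_single_gene_poisson_mean(self):
        """One gene with mu_LoF=0.01, gamma=20, N=100: mean count 2*100*0.01*20."""
        cfg = SimulationConfig(
            n_genes=1, cohorts=[("A", 100)], pi={"A": 1.0},
            per_trio_rate={"LoF": 0.02, "mis": 0.02, "synonymous": 0.02},
        )
        uni = sim.build_gene_universe(cfg)
        uni.risk_status.loc[:, "A"] = True
        uni.rel_risk["LoF"].loc[:, "A"] = 20.0
        rng = np.random.default_rng(2)
        counts = [
            int(sim.simulate_counts(uni, "A", 100, rng)["LoF"].iloc[0])
            for _ in range(1000)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 40.0) < 3 * se

    def test_records_classify_back_to_their_simulated_class(self, rng):
        uni = sim.build_universe(SimulationConfig(seed=5, n_genes=300,
                                                  cohorts=[("A", 400)], pi={"A": 0.05}))
        cohort = sim.simulate_cohort(uni, "A", 400, rng)
        counts = cohort.counts()
        expected = sim.simulate_counts  # noqa: F841 (class totals checked below)
        by_class = {"LoF": 0, "Dmis": 0, "Tmis": 0, "synonymous": 0}
        for rec in cohort.records:
            by_class[classify(rec)] += 1
        assert by_class["LoF"] == int(counts["LoF"].sum())
        assert by_class["Dmis"] == int(counts["Dmis"].sum())
        assert by_class["Tmis"] == int(counts["Tmis"].sum())

    def test_truth_table_ships_with_cohort(self, rng):
        uni = sim.build_universe(SimulationConfig(seed=5, n_genes=200,
                                                  cohorts=[("A", 100)], pi={"A": 0.1}))
        cohort = sim.simulate_cohort(uni, "A", 100, rng)
        assert (cohort.truth["disorder"] == "A").all()
        assert len(cohort.truth) == 2 * 20  # 20 risk genes x {LoF, Dmis}
        assert (cohort.truth["rel_risk"] > 0).all()


class TestExpression:
    def test_zero_noise_gives_perfect_within_module_correlation(self, rng):
        expr, labels = sim.simulate_expression(20, 30, [10, 10], rng, noise_sd=0.0)
        m1 = expr[labels == "M1"].to_numpy()
        r = np.corrcoef(m1)
        assert np.allclose(np.abs(r), 1.0)

    def test_module_recovery_purity(self, rng):
        from dnmcross.network import coexpression_edges

        expr, labels = sim.simulate_expression(60, 50, [25, 25], rng, noise_sd=0.2)
        edges = coexpression_edges(expr, 0.8)
        assert len(edges) > 50
        within = sum(
            labels[a] == labels[b] != "M0"
            for a, b in zip(edges.gene_a, edges.gene_b)
        )
        assert within / len(edges) > 0.9

    def test_within_exceeds_between_module_correlation(self, rng):
        expr, labels = sim.simulate_expression(30, 40, [15, 15], rng, noise_sd=0.5)
        r = np.corrcoef(expr.to_numpy())
        same = np.equal.outer(labels.to_numpy(), labels.to_numpy())
        iu = np.triu_indices(30, k=1)
        assert r[iu][same[iu]].mean() > r[iu][~same[iu]].mean()

    def test_determinism_and_size_checks(self):
        rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
        e1, _ = sim.simulate_expression(10, 8, [5], rng1)
        e2, _ = sim.simulate_expression(10, 8, [5], rng2)
        pd.testing.assert_frame_equal(e1, e2)
        with pytest.raises(ValueError):
            sim.simulate_expression(4, 8, [3, 3], np.random.default_rng(0))


class TestPPI:
    def test_zero_probabilities_give_no_edges(self, rng):
        _, labels = sim.simulate_expression(20, 10, [10, 10], rng)
        ppi = sim.simulate_ppi(list(labels.index), labels, 0.0, 0.0, rng)
        assert len(ppi) == 0

    def test_complete_within_module_graph(self, rng):
        genes = [f"G{i:05d}" for i in range(8)]
        labels = pd.Series("M1", index=genes)
        ppi = sim.simulate_ppi(genes, labels, 1.0, 0.0, rng)
        assert len(ppi) == 8 * 7 // 2
        assert (ppi.gene_a != ppi.gene_b).all()
        assert not ppi.duplicated(["gene_a", "gene_b"]).any()

    def test_realised_densities_match_probabilities(self, rng):
        genes = [f"G{i:05d}" for i in range(150)]
        labels = pd.Series([f"M{i // 50 + 1}" for i in range(150)], index=genes)
        ppi = sim.simulate_ppi(genes, labels, 0.3, 0.02, rng)
        same = ppi.apply(lambda r: labels[r.gene_a] == labels[r.gene_b], axis=1)
        n_within_pairs = 3 * (50 * 49 // 2)
        n_between_pairs = 150 * 149 // 2 - n_within_pairs
        d_within = same.sum() / n_within_pairs
        d_between = (~same).sum() / n_between_pairs
        assert abs(d_within - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n_within_pairs)
        assert abs(d_between - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n_between_pairs)

    def test_invalid_probability_order_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.simulate_ppi(["A", "B"], pd.Series({"A": "M1", "B": "M1"}),
                             0.1, 0.5, rng)


def test_write_study_is_byte_deterministic(tmp_path):
    cfg = SimulationConfig(seed=9, n_genes=60, cohorts=[("A", 30)], pi={"A": 0.1},
                           control_trios=30)
    p1 = sim.write_study(cfg, tmp_path / "run1")
    p2 = sim.write_study(cfg, tmp_path / "run2")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()
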