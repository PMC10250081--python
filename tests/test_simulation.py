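"""Synthetic cohort and network generators, and the replicated study."""

import numpy as np
import pytest
from scipy import stats

from multinep.evaluation import irs
from multinep.prioritization import test_scores as compute_pvalues
from multinep.simulation import (
    GroundTruth,
    NetworkTopology,
    SimulationConfig,
    build_correlation,
    default_features,
    make_truth,
    replicate_rng,
    run_study,
    simulate_network,
    simulate_omics,
    subsample_network,
    summarize_study,
)


def small_cfg(**kw):
    defaults = dict(
        n_genes=60, n_signal_genes=8, n_metabolites=12, n_signal_metabolites=3,
        n_cases=50, n_controls=50, seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_reference_defaults(self):
        cfg = SimulationConfig()
        assert (cfg.n_genes, cfg.n_signal_genes) == (5000, 175)
        assert (cfg.n_metabolites, cfg.n_signal_metabolites) == (60, 12)
        assert (cfg.n_cases, cfg.n_controls) == (100, 100)
        assert (cfg.mu_signal_gene, cfg.mu_noise_gene) == (6.15, 6.0)
        assert (cfg.sigma_gene, cfg.sigma_met) == (2.0, 2.5)
        assert cfg.rho_gg == (0.25, 0.20, 0.225)
        assert cfg.rho_mm == (0.30, 0.15, 0.225)

    @pytest.mark.parametrize(
        "kw", [{"n_signal_genes": 0}, {"n_signal_genes": 100, "n_genes": 50},
               {"sigma_gene": 0}, {"rho_gg": (1.0, 0.2, 0.2)}],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestCorrelation:
    def test_block_constant_structure(self):
        cfg = small_cfg()
        feats = default_features(cfg.n_genes, cfg.n_metabolites)
        truth = make_truth(cfg, feats, np.random.default_rng(0))
        R = build_correlation(cfg, feats, truth)
        sg = [i for i, g in enumerate(feats.genes) if g in truth.signal_genes]
        ngn = [i for i in range(cfg.n_genes) if i not in sg]
        # PSD repair may perturb entries slightly; structure must survive
        assert R[sg[0], sg[1]] == pytest.approx(0.25, abs=0.02)
        assert R[ngn[0], ngn[1]] == pytest.approx(0.20, abs=0.02)
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > -1e-10

    def test_infeasible_structure_rejected(self):
        # gm correlation far above what the within-omics blocks allow
        cfg = small_cfg(rho_gm=(0.9, 0.225, 0.225, 0.01))
        feats = default_features(cfg.n_genes, cfg.n_metabolites)
        truth = make_truth(cfg, feats, np.random.default_rng(0))
        with pytest.raises(ValueError, match="infeasible"):
            build_correlation(cfg, feats, truth)


class TestSimulateOmics:
    def test_signal_means_at_inflated_n(self):
        cfg = small_cfg(n_cases=10_000, n_controls=10)
        data, truth = simulate_omics(cfg)
        sg = next(iter(truth.signal_genes))
        col = data.feature_column(sg)[data.group == 1]
        se = cfg.sigma_gene / np.sqrt(10_000)
        assert abs(col.mean() - cfg.mu_signal_gene) < 3 * se
        nm = next(m for m in data.features.metabolites
                  if m not in truth.signal_metabolites)
        col = data.feature_column(nm)[data.group == 1]
        assert abs(col.mean() - cfg.mu_noise_met) < 3 * 2.5 / np.sqrt(10_000)

    def test_signal_metabolite_correlation_matches_target(self):
        # rho = 0.30 between signal metabolites, checked by Monte Carlo
        cfg = small_cfg(n_cases=10_000, n_controls=10)
        data, truth = simulate_omics(cfg)
        m1, m2 = sorted(truth.signal_metabolites)[:2]
        cases = data.group == 1
        r = np.corrcoef(data.feature_column(m1)[cases], data.feature_column(m2)[cases])[0, 1]
        assert r == pytest.approx(0.30, abs=0.02)

    def test_null_config_gives_uniform_pvalues(self):
        cfg = small_cfg(
            n_genes=990, n_metabolites=10, n_signal_genes=1, n_signal_metabolites=1,
            mu_signal_gene=6.0, mu_signal_met=0.0,
            rho_gg=(0.0, 0.0, 0.0), rho_mm=(0.0, 0.0, 0.0), rho_gm=(0, 0, 0, 0),
        )
        data, _ = simulate_omics(cfg)
        p = compute_pvalues(data)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_reproducible_given_seed(self):
        a, ta = simulate_omics(small_cfg(seed=42))
        b, tb = simulate_omics(small_cfg(seed=42))
        np.testing.assert_array_equal(a.values, b.values)
        assert ta.signal_genes == tb.signal_genes


class TestSimulateNetwork:
    def test_density_concentrates(self):
        feats = default_features(1000, 10)
        truth = GroundTruth([feats.genes[0]], [feats.metabolites[0]])
        topo = NetworkTopology(density_gg=0.05, signal_enrichment=1.0)
        net = simulate_network(1000, 10, truth, topo, seed=3)
        frac = np.count_nonzero(np.triu(net.gg, 1)) / (1000 * 999 / 2)
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_no_enrichment_is_exchangeable(self):
        # enrichment 1: expected IRS of signal features is 1
        feats = default_features(300, 20)
        truth = GroundTruth(feats.genes[:30], feats.metabolites[:4])
        # denser gm block keeps the Monte Carlo variance of the mean small
        topo = NetworkTopology(signal_enrichment=1.0, density_gm=0.2)
        means = []
        for seed in range(20):
            net = simulate_network(300, 20, truth, topo, seed=seed)
            scores = irs(net, "gm", "gene")
            means.append(scores.loc[list(truth.signal_genes)].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.15)

    def test_enrichment_elevates_signal_irs(self):
        # enrichment 3 on signal pairs: signal genes dominate gm connectivity
        feats = default_features(300, 20)
        truth = GroundTruth(feats.genes[:30], feats.metabolites[:4])
        topo = NetworkTopology(signal_enrichment=3.0)
        diffs = []
        for seed in range(20):
            net = simulate_network(300, 20, truth, topo, seed=seed)
            scores = irs(net, "gm", "gene")
            sig = scores.loc[list(truth.signal_genes)].mean()
            noise = scores.drop(list(truth.signal_genes)).mean()
            diffs.append(sig - noise)
        assert np.mean(diffs) > 0

    def test_weights_in_confidence_range(self):
        feats = default_features(50, 5)
        truth = GroundTruth([feats.genes[0]], [feats.metabolites[0]])
        net = simulate_network(50, 5, truth, seed=0)
        w = net.compose()[net.compose() > 0]
        assert w.min() >= 1 and w.max() <= 999


class TestSubsample:
    def test_keep_everything_is_identity(self, rng):
        feats = default_features(20, 5)
        truth = GroundTruth([feats.genes[0]], [feats.metabolites[0]])
        net = simulate_network(20, 5, truth, seed=1)
        sub = subsample_network(net, feats.genes, feats.metabolites)
        np.testing.assert_array_equal(sub.compose(), net.compose())

    def test_induced_subgraph_minor(self):
        feats = default_features(5, 2)
        truth = GroundTruth([feats.genes[0]], [feats.metabolites[0]])
        net = simulate_network(5, 2, truth, NetworkTopology(density_gg=1.0), seed=1)
        keep = [feats.genes[1], feats.genes[3]]
        sub = subsample_network(net, keep, list(feats.metabolites))
        assert sub.gg[0, 1] == net.gg[1, 3]
        assert sub.edge_count("gg") <= net.edge_count("gg")

    def test_unknown_identifier_rejected(self):
        feats = default_features(5, 2)
        truth = GroundTruth([feats.genes[0]], [feats.metabolites[0]])
        net = simulate_network(5, 2, truth, seed=1)
        with pytest.raises(KeyError):
            subsample_network(net, ["nope"], list(feats.metabolites))


class TestRunStudy:
    def test_multinep_unit_lambdas_equals_disnep(self):
        cfg = small_cfg()
        tab = run_study(cfg, [(1.0, 1.0)], n_reps=1, seed=5, ks=[10, 20])
        dis = tab[tab.method == "disnep"].reset_index(drop=True)
        mul = tab[tab.method == "multinep"].reset_index(drop=True)
        for col in ("true_signal_genes", "true_signal_metabolites", "combined"):
            np.testing.assert_array_equal(dis[col], mul[col])

    def test_table_bookkeeping(self):
        cfg = small_cfg()
        tab = run_study(cfg, [(0.05, 20.0), (1.0, 1.0)], n_reps=2, seed=5, ks=[10, 30])
        assert len(tab[tab.method == "multinep"]) == 2 * 2 * 2  # reps x grid x ks
        assert len(tab[tab.method == "general"]) == 2 * 2
        assert set(tab.columns) >= {
            "replicate", "method", "lambda_g", "lambda_m", "k",
            "true_signal_genes", "true_signal_metabolites", "combined",
        }

    def test_reproducible_from_master_seed(self):
        cfg = small_cfg()
        a = run_study(cfg, [(0.05, 20.0)], n_reps=2, seed=11, ks=[15])
        b = run_study(cfg, [(0.05, 20.0)], n_reps=2, seed=11, ks=[15])
        assert a.equals(b)

    def test_replicate_rngs_are_independent_streams(self):
        x = replicate_rng(3, 0).random(4)
        y = replicate_rng(3, 1).random(4)
        z = replicate_rng(3, 0).random(4)
        np.testing.assert_array_equal(x, z)
        assert not np.allclose(x, y)

    def test_summary_shapes(self):
        cfg = small_cfg()
        tab = run_study(cfg, [(0.05, 20.0)], n_reps=2, seed=5, ks=[10])
        s = summarize_study(tab)
        assert set(s.method) == {"general", "disnep", "multinep"}
        assert (s.n_reps == 2).all()
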