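"""Ordering genes, principal-tree pseudotime, spline dependence test,
binned profiles and the transgene correlation analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otoconv import synthetic as syn
from otoconv import trajectory as tj

from conftest import toy_dataset


class TestOrderingGenes:
    def test_mean_rule_excludes_low_expression(self):
        # Poisson-like dispersion but mean 0.05: excluded by the mean rule
        counts = np.zeros((1, 100), dtype=int)
        counts[0, :5] = 1
        ds = toy_dataset(counts)
        assert len(tj.select_ordering_genes(ds)) == 0

    def test_overdispersed_gene_included(self):
        # mean 2, variance 8 -> dispersion 4: included
        vals = np.concatenate([np.zeros(50), np.full(50, 4)])
        ds = toy_dataset(vals[None, :].astype(int))
        assert list(tj.select_ordering_genes(ds)) == ["g0"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(2, 0.3, size=(40, 80))
        ds = toy_dataset(counts)
        sel = set(tj.select_ordering_genes(ds))
        x = np.where(counts >= 0.5, counts, 0).astype(float)
        mean, var = x.mean(axis=1), x.var(axis=1)
        expected = {f"g{i}" for i in range(40)
                    if mean[i] >= 0.1 and var[i] / mean[i] >= 1.0}
        assert sel == expected


class TestPrincipalTree:
    def test_noiseless_line_gives_path_and_exact_order(self):
        # cells on a noiseless 1-D expression gradient: the tree is a
        # path and projected pseudotime preserves the order exactly
        pos = np.linspace(0, 1, 120)
        counts = np.vstack([
            np.round(5 + 200 * pos),
            np.round(205 - 200 * pos),
            np.full(120, 30),
        ]).astype(int)
        ds = toy_dataset(counts)
        traj = tj.fit_principal_tree(ds, ds.gene_names, n_centroids=6, seed=0)
        deg = traj.node_degrees()
        assert deg.max() == 2 and (deg == 1).sum() == 2  # a path
        tau = tj.assign_pseudotime(traj, "P",
                                   np.array(["P"] * 8 + ["x"] * 112))
        rho = stats.spearmanr(tau, pos).statistic
        assert rho > 0.99

    def test_deterministic_under_seed(self, continuum_preprocessed):
        ds = continuum_preprocessed
        genes = tj.select_ordering_genes(ds)
        a = tj.fit_principal_tree(ds, genes, seed=5)
        b = tj.fit_principal_tree(ds, genes, seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.edges == b.edges
        assert np.array_equal(a.cell_edge, b.cell_edge)

    def test_y_shape_has_one_branch_node(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 1, 90)
        arms = [np.column_stack([t, np.zeros(90)]),
                np.column_stack([1 + t, t]),
                np.column_stack([1 + t, -t])]
        pts = np.vstack(arms) * 10 + rng.normal(0, 0.05, (270, 2))
        counts = np.clip(np.round(pts - pts.min() + 1), 0, None).astype(int)
        ds = toy_dataset(counts.T)
        traj = tj.fit_principal_tree(ds, ds.gene_names, n_centroids=9, seed=0)
        deg = traj.node_degrees()
        assert (deg >= 3).sum() == 1

    def test_too_few_centroids_rejected(self, continuum_preprocessed):
        with pytest.raises(ValueError, match="n_centroids"):
            tj.fit_principal_tree(continuum_preprocessed,
                                  continuum_preprocessed.gene_names,
                                  n_centroids=1)


@pytest.fixture(scope="module")
def fitted(continuum_preprocessed):
    ds = continuum_preprocessed
    genes = tj.select_ordering_genes(ds)
    traj = tj.fit_principal_tree(ds, genes, seed=2)
    tau = tj.assign_pseudotime(traj, "SC1", ds.cell_meta["true_population"])
    return ds, traj, tau


class TestPseudotime:
    def test_root_cells_near_zero(self, fitted):
        ds, traj, tau = fitted
        root_tau = tau[ds.cell_meta["true_population"] == "SC1"]
        assert root_tau.median() < 0.25

    def test_recovers_latent_coordinate(self, fitted):
        ds, traj, tau = fitted
        rho = stats.spearmanr(tau, ds.cell_meta["true_latent"]).statistic
        assert abs(rho) >= 0.9

    def test_mean_tau_increases_along_continuum(self, fitted):
        ds, _, tau = fitted
        means = tau.groupby(ds.cell_meta["true_population"]).mean()
        order = [means[p] for p in syn.CONTINUUM_POPULATIONS]
        assert np.all(np.diff(order) > 0)

    def test_reversed_root_flips_ordering(self, fitted):
        ds, traj, tau = fitted
        tau_rev = tj.assign_pseudotime(traj, "cHC3",
                                       ds.cell_meta["true_population"])
        rho = stats.spearmanr(tau, tau_rev).statistic
        assert rho < -0.8

    def test_range_zero_one(self, fitted):
        _, _, tau = fitted
        assert tau.min() >= 0.0 and np.isclose(tau.max(), 1.0)


class TestPseudotimeDependence:
    def test_null_pvalues_uniform(self):
        # 400 flat genes: p-values consistent with U(0, 1) by KS at 1%
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, size=(400, 300))
        ds = toy_dataset(counts)
        tau = rng.uniform(0, 1, 300)
        res = tj.test_pseudotime_dependence(ds, tau)
        ks_p = stats.kstest(res.table["p"], "uniform").pvalue
        assert ks_p > 0.01

    def test_monotone_gene_detected(self):
        rng = np.random.default_rng(4)
        tau = np.sort(rng.uniform(0, 1, 200))
        counts = rng.poisson(5.0, size=(50, 200))
        counts[0] = rng.poisson(2 + 40 * tau)
        ds = toy_dataset(counts)
        res = tj.test_pseudotime_dependence(ds, tau)
        fdr = res.table.set_index("gene").loc["g0", "FDR"]
        assert fdr < 0.01

    def test_permuting_tau_destroys_signal(self):
        rng = np.random.default_rng(5)
        tau = np.sort(rng.uniform(0, 1, 200))
        counts = rng.poisson(5.0, size=(30, 200))
        counts[0] = rng.poisson(2 + 40 * tau)
        ds = toy_dataset(counts)
        perm = rng.permutation(tau)
        res = tj.test_pseudotime_dependence(ds, perm)
        assert res.table.set_index("gene").loc["g0", "FDR"] > 0.05

    def test_constant_gene_not_significant(self):
        counts = np.vstack([np.full(100, 7), np.arange(100)]).astype(int)
        ds = toy_dataset(counts)
        res = tj.test_pseudotime_dependence(ds, np.linspace(0, 1, 100))
        assert res.table.set_index("gene").loc["g0", "p"] == 1.0


class TestBinnedProfiles:
    def test_single_bin_is_overall_mean(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(4.0, size=(5, 50))
        ds = toy_dataset(counts)
        tau = rng.uniform(0, 1, 50)
        prof = tj.bin_pseudotime_profiles(ds, tau, n_bins=1)
        assert np.allclose(prof.iloc[:, 0],
                           np.log2(counts + 1.0).mean(axis=1))

    def test_bin_means_match_brute_force(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(4.0, size=(4, 200))
        ds = toy_dataset(counts)
        tau = rng.uniform(0, 1, 200)
        n_bins = 10
        prof = tj.bin_pseudotime_profiles(ds, tau, n_bins=n_bins)
        log = np.log2(counts + 1.0)
        edges = np.linspace(0, 1, n_bins + 1)
        for b in range(n_bins):
            mask = (tau >= edges[b]) & (tau < edges[b + 1])
            if b == n_bins - 1:
                mask |= tau == 1.0
            if mask.any():
                assert np.allclose(prof.iloc[:, b], log[:, mask].mean(axis=1))

    def test_linear_gene_monotone_profile(self):
        rng = np.random.default_rng(8)
        tau = rng.uniform(0, 1, 2000)
        counts = rng.poisson(2 + 60 * tau)[None, :]
        ds = toy_dataset(counts.astype(int))
        prof = tj.bin_pseudotime_profiles(ds, tau, n_bins=20)
        diffs = np.diff(prof.iloc[0].to_numpy())
        assert (diffs > 0).mean() > 0.85

    def test_empty_bins_interpolated_and_scaled(self):
        counts = np.array([[0, 10, 20]])
        ds = toy_dataset(counts)
        tau = np.array([0.0, 0.5, 1.0])
        prof = tj.bin_pseudotime_profiles(ds, tau, n_bins=100, scale=True)
        assert not prof.isna().any().any()
        assert prof.iloc[0].min() == 0.0 and prof.iloc[0].max() == 1.0


class TestTransgeneCorrelation:
    def test_duplicated_feature_r2_one(self):
        rng = np.random.default_rng(9)
        base = rng.poisson(20.0, 100)
        counts = np.vstack([base, base, rng.poisson(5.0, 100)])
        ds = toy_dataset(counts, gene_names=["Atoh1", "Atoh1-HA", "g2"],
                         populations=["cHC1"] * 50 + ["cHC3"] * 50,
                         special={"Atoh1_endogenous": "Atoh1",
                                  "Atoh1_HA": "Atoh1-HA"})
        out = tj.transgene_correlation(ds, ds.cell_meta["true_population"])
        assert np.isclose(out["r2"], 1.0)

    def test_independent_features_r2_small(self):
        rng = np.random.default_rng(10)
        counts = np.vstack([rng.poisson(20.0, 1000),
                            rng.poisson(20.0, 1000)])
        ds = toy_dataset(counts, gene_names=["Atoh1", "Atoh1-HA"],
                         populations=["cHC1"] * 500 + ["cHC3"] * 500,
                         special={"Atoh1_endogenous": "Atoh1",
                                  "Atoh1_HA": "Atoh1-HA"})
        out = tj.transgene_correlation(ds, ds.cell_meta["true_population"])
        assert out["r2"] < 0.01

    def test_fold_change_arithmetic(self):
        # cluster means 6.58 vs 2.0 -> fold 3.29
        ha = np.array([6.58] * 50 + [2.0] * 50) * 100
        counts = np.vstack([np.full(100, 50), ha]).astype(int)
        ds = toy_dataset(counts, gene_names=["Atoh1", "Atoh1-HA"],
                         populations=["cHC3"] * 50 + ["cHC1"] * 50,
                         special={"Atoh1_endogenous": "Atoh1",
                                  "Atoh1_HA": "Atoh1-HA"})
        out = tj.transgene_correlation(ds, ds.cell_meta["true_population"])
        assert np.isclose(out["fold_change"], 3.29)

    def test_continuum_preset_strong_coupling(self, continuum_preprocessed):
        ds = continuum_preprocessed
        out = tj.transgene_correlation(ds, ds.cell_meta["true_population"])
        assert out["r2"] > 0.4
        assert out["fold_change"] > 1.5
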