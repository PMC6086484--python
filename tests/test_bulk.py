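"""TMM normalization, FPKM, moderated-t DE and cell-type distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otoconv import bulk as bk
from otoconv import synthetic as syn


# ---------------------------------------------------------------------------
# Independent direct implementation of the doubly-trimmed weighted
# M-value mean, coded from the normalization formula (oracle for TMM)
# ---------------------------------------------------------------------------

def direct_tmm_factor(obs, ref, n_obs=None, n_ref=None,
                      trim_m=0.3, trim_a=0.05):
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    n_obs = obs.sum() if n_obs is None else n_obs
    n_ref = ref.sum() if n_ref is None else n_ref
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    m = np.log2(obs / n_obs) - np.log2(ref / n_ref)
    a = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(m)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = ((rm >= n * trim_m + 1) & (rm <= n * (1 - trim_m))
           & (ra >= n * trim_a + 1) & (ra <= n * (1 - trim_a)))
    return 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [60], [200], [35]], (1, 4)))
        f = bk.tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_uniform_double_expression_pre_rescale_ratio(self):
        # sample 1 expresses every gene 2x at the same library size:
        # the pre-rescale factor against the reference is 2
        rng = np.random.default_rng(0)
        ref = rng.integers(10, 500, 100).astype(float)
        counts = pd.DataFrame({"ref": ref, "double": 2 * ref})
        f = bk.tmm_factors(counts, lib_sizes=[ref.sum(), ref.sum()],
                           ref_sample="ref")
        assert np.isclose(f["double"] / f["ref"], 2.0)

    def test_matches_independent_direct_implementation(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(300, 4)),
            columns=list("abcd"))
        f = bk.tmm_factors(counts, ref_sample="a")
        lib = counts.sum(axis=0).to_numpy(float)
        raw = np.array([
            1.0 if c == "a" else
            direct_tmm_factor(counts[c], counts["a"], lib[i], lib[0])
            for i, c in enumerate(counts.columns)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_scaling_one_library_moves_only_its_factor(self):
        rng = np.random.default_rng(2)
        base = rng.negative_binomial(8, 0.02, size=(400, 3)).astype(float)
        counts = pd.DataFrame(base, columns=list("abc"))
        scaled = counts.copy()
        scaled["c"] = (scaled["c"] * 4).astype(int)
        f1 = bk.tmm_factors(counts, ref_sample="a")
        f2 = bk.tmm_factors(scaled, ref_sample="a")
        # a global scalar on one library leaves M-values untouched:
        # factors are unchanged up to small integer-rounding effects
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=0.02)

    def test_geometric_mean_one(self, bulk_eset):
        f = bulk_eset.tmm()
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)
        assert (f > 0).all()


class TestFpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s": [50, 0]}, index=["g1", "g2"])
        counts.loc["g3"] = 10 ** 6 - 50
        lengths = pd.Series([2000, 1000, 1000], index=["g1", "g2", "g3"])
        fpkm = bk.compute_fpkm(counts, lengths)
        assert np.isclose(fpkm.loc["g1", "s"], 25.0)
        assert fpkm.loc["g2", "s"] == 0.0

    def test_doubling_length_halves_fpkm(self):
        counts = pd.DataFrame({"s": [100, 100]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        fpkm = bk.compute_fpkm(counts, lengths)
        assert np.isclose(fpkm.loc["a", "s"], 2 * fpkm.loc["b", "s"])


def _null_eset(seed, n_genes=500, n_groups=2, n_reps=3):
    rng = np.random.default_rng(seed)
    mu = np.exp2(rng.normal(6, 1.5, n_genes))
    cols, types = {}, {}
    for g in range(n_groups):
        for r in range(n_reps):
            s = f"G{g}_r{r}"
            noise = rng.normal(0, 0.3, n_genes)
            cols[s] = rng.poisson(mu * np.exp2(noise))
            types[s] = f"G{g}"
    counts = pd.DataFrame(cols)
    sheet = pd.DataFrame({"cell_type": pd.Series(types)})
    lengths = pd.Series(1500, index=counts.index)
    return bk.BulkExpressionSet(counts, lengths, sheet)


class TestDifferentialExpression:
    def test_identical_groups_zero_log2fc(self):
        counts = pd.DataFrame(
            {"a1": [100, 50, 10], "a2": [120, 55, 12],
             "b1": [100, 50, 10], "b2": [120, 55, 12]},
            index=["g1", "g2", "g3"])
        sheet = pd.DataFrame({"cell_type": ["A", "A", "B", "B"]},
                             index=counts.columns)
        eset = bk.BulkExpressionSet(counts, pd.Series(1000, index=counts.index),
                                    sheet)
        de = bk.differential_expression(eset, use_weights=False, trim=False)
        assert np.allclose(de.table["log2FC"], 0.0)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"a1": [10, 20], "b1": [10, 20], "b2": [12, 21]})
        sheet = pd.DataFrame({"cell_type": ["A", "B", "B"]},
                             index=counts.columns)
        eset = bk.BulkExpressionSet(counts, pd.Series(1000, index=counts.index),
                                    sheet)
        with pytest.raises(ValueError, match="replicates"):
            bk.differential_expression(eset, trim=False)

    def test_null_simulation_controls_fdr(self):
        n_disc = []
        for seed in range(5):
            de = bk.differential_expression(_null_eset(seed))
            n_disc.append(len(de.significant(0.05)))
        assert np.median(n_disc) <= 1

    def test_fourfold_genes_detected(self, bulk_truth, bulk_eset):
        de = bk.differential_expression(bulk_eset)
        sig = set(de.significant(0.05))
        programmed = set(bulk_truth.de_genes["gene"]) & set(
            bulk_eset.trimmed().counts.index)
        sens = len(sig & programmed) / len(programmed)
        assert sens >= 0.8

    def test_log2fc_recovery(self, bulk_truth, bulk_eset):
        de = bk.differential_expression(bulk_eset)
        t = de.table.set_index(["gene", "contrast"])
        truth = bulk_truth.group_log2_means
        hits = 0
        total = 0
        for _, row in bulk_truth.de_genes.iloc[:300].iterrows():
            a, b = row["contrast"].split("_vs_")
            key = (row["gene"], f"{a}_vs_{b}")
            if key not in t.index:
                continue
            est = t.loc[key, "log2FC"]
            want = truth.loc[row["gene"], a] - truth.loc[row["gene"], b]
            total += 1
            hits += abs(est - want) <= 0.75
        assert total > 50 and hits / total >= 0.9

    def test_fdr_monotone_with_p(self, bulk_eset):
        de = bk.differential_expression(bulk_eset)
        for _, grp in de.table.groupby("contrast"):
            g = grp.sort_values("p")
            assert (np.diff(g["FDR"]) >= -1e-12).all()


class TestTfSubset:
    def test_empty_tf_list_gives_empty(self, bulk_eset):
        de = bk.differential_expression(bulk_eset)
        assert len(bk.subset_tf_de(de, [])) == 0

    def test_matches_brute_force_intersection(self, bulk_truth, bulk_eset):
        de = bk.differential_expression(bulk_eset)
        cts = ["SC_P26", "cHC_P33", "OHC_P22"]
        out = bk.subset_tf_de(de, bulk_truth.tf_genes, cell_types=cts)
        tf = {g.lower() for g in bulk_truth.tf_genes}
        expected = de.table[
            (de.table["FDR"] < 0.05)
            & de.table["gene"].str.lower().isin(tf)
            & de.table["contrast"].isin(
                [f"{a}_vs_{b}" for a in cts for b in cts if a != b])]
        assert set(out["gene"]) == set(expected["gene"])


class TestConcordanceAndDistances:
    def test_duplicated_sample_correlation_one(self):
        counts = pd.DataFrame({"a": [10, 30, 5], "b": [10, 30, 5]})
        sheet = pd.DataFrame({"cell_type": ["X", "X"]}, index=["a", "b"])
        eset = bk.BulkExpressionSet(counts, pd.Series(1000, index=counts.index),
                                    sheet)
        conc = bk.replicate_concordance(eset)
        assert np.isclose(conc.loc["a", "b"], 1.0)
        assert np.allclose(conc, conc.T)
        assert np.allclose(np.diag(conc), 1.0)

    def test_identical_profiles_zero_distance(self):
        counts = pd.DataFrame({"a1": [10, 30, 5, 80], "a2": [10, 30, 5, 80],
                               "b1": [10, 30, 5, 80], "b2": [10, 30, 5, 80]},
                              index=["g0", "g1", "g2", "g3"])
        sheet = pd.DataFrame({"cell_type": ["A", "A", "B", "B"]},
                             index=counts.columns)
        eset = bk.BulkExpressionSet(counts, pd.Series(1000, index=counts.index),
                                    sheet)
        dist = bk.distance_suite(eset, ["g0", "g1"], [("A", "B")])
        assert np.allclose(dist.to_numpy(), 0.0, atol=1e-10)

    def test_spearman_invariant_to_monotone_transform(self, bulk_eset,
                                                      bulk_truth):
        pairs = [("cHC_P33", "SC_P26")]
        d1 = bk.distance_suite(bulk_eset, bulk_truth.tf_genes, pairs)
        cubed = bk.BulkExpressionSet(bulk_eset.counts ** 2,
                                     bulk_eset.gene_lengths,
                                     bulk_eset.sample_sheet)
        d2 = bk.distance_suite(cubed, bulk_truth.tf_genes, pairs)
        # squaring counts is monotone per sample: rank-based distances move
        # only through mean-profile averaging across duplicates
        assert abs(d1.iloc[0]["spearman_all"] - d2.iloc[0]["spearman_all"]) < 0.05

    def test_converted_cells_closest_to_immature_ohc(self, bulk_eset,
                                                     bulk_truth):
        pairs = [("cHC_P33", other) for other in
                 ("OHC_P7", "SC_P26", "OHC_P22", "IHC_P74")]
        dist = bk.distance_suite(bulk_eset, bulk_truth.tf_genes, pairs)
        ref = dist.loc["cHC_P33-OHC_P7"]
        for other in ("SC_P26", "OHC_P22", "IHC_P74"):
            row = dist.loc[f"cHC_P33-{other}"]
            assert (row > ref).all()
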