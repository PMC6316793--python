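"""TMM factors (global and stratified) against brute-force and edgeR oracles."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from _oracles import tmm_brute
from decaynorm.normalize import (
    TmmParams, adjust_counts, choose_reference, quantile_bins, stratified_tmm,
    tmm_factor, tmm_factors,
)


def _random_counts(rng, n_genes, n_samples=2):
    return rng.negative_binomial(5, 0.05, size=(n_genes, n_samples)) + 1


class TestTmmFactor:
    def test_identity(self):
        x = np.array([5, 10, 200, 31, 42, 999, 12, 7, 80, 15, 64, 33])
        assert tmm_factor(x, x) == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = _random_counts(rng, 30)[:, 0]
        assert tmm_factor(3 * x, x) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_counts(rng, int(rng.integers(6, 51)))
        got = tmm_factor(m[:, 0], m[:, 1])
        assert got == pytest.approx(tmm_brute(m[:, 0], m[:, 1]), abs=1e-10)

    def test_matches_edger(self, tmp_path):
        """Independent cross-check against edgeR::calcNormFactors."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        m = _random_counts(rng, 200)
        f = tmp_path / "m.tsv"
        np.savetxt(f, m, fmt="%d", delimiter="\t")
        out = subprocess.run(
            ["Rscript", "-e",
             "suppressMessages(library(edgeR));"
             f"m<-as.matrix(read.table('{f}'));"
             "f<-calcNormFactors(m,refColumn=1,method='TMM');"
             "cat(sprintf('%.15f', f[2]/f[1]))"],
            capture_output=True, text=True, check=True)
        assert tmm_factor(m[:, 1], m[:, 0]) == pytest.approx(
            float(out.stdout), abs=1e-9)

    def test_few_genes_returns_one(self):
        with pytest.warns(UserWarning):
            assert tmm_factor([1, 2, 3], [3, 2, 1]) == 1.0

    def test_explicit_library_sizes(self):
        rng = np.random.default_rng(3)
        m = _random_counts(rng, 40)
        got = tmm_factor(m[:, 0], m[:, 1], lib_obs=1e5, lib_ref=2e5)
        assert got == pytest.approx(
            tmm_brute(m[:, 0], m[:, 1], lib_obs=1e5, lib_ref=2e5), abs=1e-10)


class TestChooseReference:
    def test_recomputed_rule(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.negative_binomial(2, 0.02, size=(300, 5)),
                              columns=list("abcde"))
        libs = counts.sum(axis=0)
        uq = {s: np.quantile(counts[s] / libs[s] * 1e6, 0.75) for s in counts}
        target = np.mean(list(uq.values()))
        expected = min(counts.columns, key=lambda s: abs(uq[s] - target))
        assert choose_reference(counts) == expected

    def test_tie_first_by_order(self):
        counts = pd.DataFrame({"s1": [1, 5, 9], "s2": [1, 5, 9]})
        assert choose_reference(counts) == "s1"

    def test_zero_sample_excluded(self):
        counts = pd.DataFrame({"s1": [0, 0, 0], "s2": [1, 5, 9], "s3": [2, 4, 9]})
        assert choose_reference(counts) in {"s2", "s3"}


class TestQuantileBins:
    def test_twenty_values_ten_bins(self):
        v = pd.Series(np.arange(1, 21), index=[f"g{i:02d}" for i in range(20)])
        bins = quantile_bins(v, 10)
        assert list(bins.value_counts().sort_index()) == [2] * 10
        assert bins["g00"] == 0 and bins["g19"] == 9

    def test_all_equal_still_balanced(self):
        v = pd.Series(np.ones(20), index=[f"g{i:02d}" for i in range(20)])
        bins = quantile_bins(v, 10)
        assert list(bins.value_counts().sort_index()) == [2] * 10

    def test_uneven_sizes(self):
        v = pd.Series(np.arange(2003), index=[f"g{i:04d}" for i in range(2003)])
        sizes = set(quantile_bins(v, 10).value_counts())
        assert sizes == {200, 201}

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            quantile_bins(pd.Series([1.0, 2.0]), 10)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(11)
    n = 600
    counts = pd.DataFrame(
        rng.negative_binomial(10, 0.02, size=(n, 2)) + 1,
        index=[f"g{i:04d}" for i in range(n)], columns=["A", "B"])
    lengths = pd.Series(rng.integers(300, 6000, size=n), index=counts.index,
                        dtype=float)
    return counts, lengths


class TestStratifiedTmm:
    def test_identical_samples_all_factors_one(self, toy_matrix):
        counts, lengths = toy_matrix
        counts = counts.assign(B=counts["A"])
        res = stratified_tmm(counts, lengths, n_bins=5, min_bin_genes=50)
        np.testing.assert_allclose(res.factors.to_numpy(), 1.0, atol=1e-12)
        np.testing.assert_allclose(res.adjusted.to_numpy(),
                                   counts.to_numpy(), atol=1e-9)

    def test_one_bin_equals_global_tmm(self, toy_matrix):
        counts, lengths = toy_matrix
        res = stratified_tmm(counts, lengths, n_bins=1)
        glob = tmm_factors(counts)
        np.testing.assert_allclose(res.factors.iloc[0].to_numpy(),
                                   glob.to_numpy(), atol=1e-10)

    def test_recentering(self, toy_matrix):
        counts, lengths = toy_matrix
        res = stratified_tmm(counts, lengths, n_bins=5, min_bin_genes=50)
        logsum = np.log(res.factors.to_numpy()).sum(axis=1)
        np.testing.assert_allclose(logsum, 0.0, atol=1e-10)

    def test_inflated_short_bin_recovered(self, toy_matrix):
        """Doubling the shortest-length decile of one sample is detected as a
        bin factor ~ 2 / sqrt(2) and the adjustment re-equalizes the bin."""
        counts, lengths = toy_matrix
        # keep the inflated bin a small share of the library
        bins = quantile_bins(lengths, 10)
        short = bins.index[bins == 0]
        inflated = counts.copy()
        inflated.loc[short, "B"] *= 2
        res = stratified_tmm(inflated, lengths, n_bins=10, min_bin_genes=50)
        lib_ratio = inflated["B"].sum() / inflated["A"].sum()
        fB, fA = res.factors.loc[0, "B"], res.factors.loc[0, "A"]
        assert fB / fA == pytest.approx(2.0 / lib_ratio, rel=0.1)
        adj = res.adjusted
        ratio = (adj.loc[short, "B"].sum() / adj.loc[short, "A"].sum())
        assert ratio == pytest.approx(lib_ratio, rel=0.05)

    def test_small_bins_merged(self, toy_matrix):
        counts, lengths = toy_matrix
        res = stratified_tmm(counts.head(120), lengths.head(120), n_bins=10,
                             min_bin_genes=50)
        sizes = res.bins.value_counts()
        assert (sizes >= 50).all()

    def test_zeros_preserved(self, toy_matrix):
        counts, lengths = toy_matrix
        counts = counts.copy()
        counts.iloc[::7, 0] = 0
        res = stratified_tmm(counts, lengths, n_bins=5, min_bin_genes=50)
        assert (res.adjusted.to_numpy()[::7, 0] == 0).all()
        assert (res.adjusted_int.to_numpy()[::7, 0] == 0).all()


class TestTwoStage:
    def test_balanced_matrix_roundtrips(self, toy_matrix):
        counts, lengths = toy_matrix
        counts = counts.assign(B=counts["A"])
        res = adjust_counts(counts, lengths, n_bins=5)
        np.testing.assert_allclose(res.adjusted.to_numpy(),
                                   counts.to_numpy(), rtol=1e-9)
        assert res.adjusted_int.equals(counts.astype(np.int64))

    def test_stage_order_not_commutative(self, toy_matrix):
        """Length-then-CPM differs from CPM-then-length on a biased matrix."""
        counts, lengths = toy_matrix
        bins = quantile_bins(lengths, 10)
        biased = counts.copy()
        biased.loc[bins.index[bins == 0], "B"] *= 2
        fwd = adjust_counts(biased, lengths, n_bins=10)
        # swapped order: stratify by CPM of the raw matrix first, then length
        from decaynorm.normalize import stratified_tmm as stmm
        from decaynorm.quantify import cpm as cpm_of
        s1 = stmm(biased, cpm_of(biased).mean(axis=1), 10, min_bin_genes=50)
        s2 = stmm(s1.adjusted, lengths, 10, min_bin_genes=50)
        assert not np.allclose(fwd.adjusted.to_numpy(), s2.adjusted.to_numpy(),
                               rtol=1e-6)

    def test_removes_length_bias_of_confounded_null(self):
        """RIN-confounded null: after truncation + two-stage stratified TMM the
        length-logFC correlation is negligible."""
        from scipy.stats import spearmanr
        from decaynorm.gene_model import binning_length, select_major_transcript
        from decaynorm.syndata import (
            simulate_annotation, simulate_counts, simulate_truth,
        )
        ann = simulate_annotation(2000, seed=60)
        truth = simulate_truth(sorted(ann.genes), n_per_group=3,
                               rin_by_condition={"A": 9.5, "B": 6.0},
                               phi=0.1, mean_libsize=5e5, seed=61)
        sim = simulate_counts(ann, truth, seed=62)
        lengths = pd.Series({g: binning_length(ann.genes[g])
                             for g in sim.counts_truncated.index})
        res = adjust_counts(sim.counts_truncated, lengths, n_bins=10)
        c = res.adjusted / res.adjusted.sum(axis=0) * 1e6
        logfc = np.log2((c.iloc[:, 3:].mean(axis=1) + 0.5)
                        / (c.iloc[:, :3].mean(axis=1) + 0.5))
        rho = spearmanr(logfc, lengths.loc[c.index]).statistic
        assert abs(rho) < 0.05
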