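"""Degradation model, simulated annotations, and count/read coherence."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import chi2, spearmanr

from decaynorm.gene_model import select_major_transcript, write_gtf
from decaynorm.syndata import (
    DegradationModel, capture_weight, simulate_annotation, simulate_counts,
    simulate_truth, survival_fraction,
)

MODEL = DegradationModel()


class TestSurvival:
    def test_preserved_window(self):
        assert survival_fraction(0, 2.0) == 1.0
        assert survival_fraction(750, 6.0) == 1.0
        assert survival_fraction(300, 9.9) == 1.0

    def test_exponential_tail(self):
        # lam(6) = 400, so S(1150) = e^-1
        assert survival_fraction(1150, 6.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_monotone_in_distance_and_rin(self):
        d = np.arange(0, 4000, 25)
        s_low = survival_fraction(d, 3.0)
        s_high = survival_fraction(d, 9.0)
        assert np.all(np.diff(s_low[d > 750]) < 0)
        assert np.all(s_high >= s_low)
        assert np.all((s_low > 0) & (s_low <= 1))

    def test_rin_out_of_range(self):
        with pytest.raises(ValueError):
            survival_fraction(100, 0.5)
        with pytest.raises(ValueError):
            survival_fraction(100, 10.5)

    def test_negative_distance(self):
        with pytest.raises(ValueError):
            survival_fraction(-1, 6.0)


class TestCaptureWeight:
    def test_fully_preserved_region(self):
        assert capture_weight(750, [(0, 750)], 2.0) == pytest.approx(750.0)
        assert capture_weight(3000, [(0, 750)], 5.0) == pytest.approx(750.0)

    @pytest.mark.parametrize("rin,length", [(6.0, 3000), (4.0, 2000), (9.5, 6000)])
    def test_matches_quadrature(self, rin, length):
        expected, _ = integrate.quad(
            lambda d: survival_fraction(d, rin), 0, length, limit=200,
            points=[MODEL.preserved_window])
        assert capture_weight(length, [(0, length)], rin) == pytest.approx(
            expected, rel=1e-8)

    def test_disjoint_region(self):
        w = capture_weight(3000, [(100, 200), (900, 1000)], 6.0)
        q1, _ = integrate.quad(lambda d: survival_fraction(d, 6.0), 100, 200)
        q2, _ = integrate.quad(lambda d: survival_fraction(d, 6.0), 900, 1000)
        assert w == pytest.approx(q1 + q2, rel=1e-8)

    def test_empty_region_warns(self):
        with pytest.warns(UserWarning):
            assert capture_weight(1000, [], 6.0) == 0.0


class TestSimulateAnnotation:
    def test_deterministic_gtf(self):
        a = write_gtf(simulate_annotation(10, seed=1))
        b = write_gtf(simulate_annotation(10, seed=1))
        assert a == b

    def test_lengths_in_range_and_disjoint(self):
        ann = simulate_annotation(500, length_range=(300, 6000), seed=9)
        lens = [t.spliced_length for t in ann.transcripts()]
        assert all(300 <= l <= 6000 for l in lens)
        spans = sorted((g.start, g.end) for g in ann.genes.values())
        assert all(b1 >= e0 for (_, e0), (b1, _) in zip(spans, spans[1:]))

    def test_mixed_strands_and_exon_counts(self):
        ann = simulate_annotation(200, seed=4)
        strands = {t.strand for t in ann.transcripts()}
        n_exons = {len(t.exons) for t in ann.transcripts()}
        assert strands == {"+", "-"}
        assert n_exons <= {1, 2, 3} and len(n_exons) > 1


class TestSimulateCounts:
    def test_symmetric_null_count_ratio(self):
        """Equal RIN/libsize Poisson null: conditional binomial GOF."""
        ann = simulate_annotation(2000, seed=30)
        truth = simulate_truth(sorted(ann.genes), n_per_group=1,
                               rin_by_condition={"A": 8.0, "B": 8.0}, phi=0.0,
                               mean_libsize=5e5, libsize_sigma=0.0, seed=31)
        sim = simulate_counts(ann, truth, seed=32)
        y = sim.counts_full.to_numpy()
        tot = y.sum(axis=1)
        keep = tot > 0
        stat = float(np.sum((y[keep, 0] - y[keep, 1]) ** 2 / tot[keep]))
        p = chi2.sf(stat, df=int(keep.sum()))
        assert p > 0.001

    def test_fully_preserved_gene_mean(self):
        """Single 750-bp gene, pi=1: expected count = N at any RIN."""
        from decaynorm.gene_model import Annotation, Transcript
        ann = Annotation()
        ann.add(Transcript("T1", "G1", "chrS", "+", [(100, 850)]))
        truth = simulate_truth(["G1"], n_per_group=1,
                               rin_by_condition={"A": 9.5, "B": 2.0}, phi=0.0,
                               mean_libsize=10000, libsize_sigma=0.0, seed=1)
        sim = simulate_counts(ann, truth, seed=2)
        assert np.allclose(sim.mu_full.to_numpy(), 10000.0)
        assert np.allclose(sim.mu_truncated.to_numpy(), 10000.0)

    def test_nb_moments(self):
        """Mean/variance of NB draws match mu and mu + phi*mu^2."""
        from decaynorm.gene_model import Annotation, Transcript
        ann = Annotation()
        ann.add(Transcript("T1", "G1", "chrS", "+", [(0, 750)]))
        truth = simulate_truth(["G1"], n_per_group=5000,
                               rin_by_condition={"A": 9.0, "B": 9.0}, phi=0.1,
                               mean_libsize=1e4, libsize_sigma=0.0, seed=8)
        sim = simulate_counts(ann, truth, seed=9)
        y = sim.counts_full.to_numpy().ravel().astype(float)
        mu, phi = 1e4, 0.1
        assert y.mean() == pytest.approx(mu, rel=0.01)
        assert y.var() == pytest.approx(mu + phi * mu ** 2, rel=0.06)

    def test_expected_length_bias_full_but_not_truncated(self):
        """Expected-count log-ratios across RINs: constant under truncation,
        monotone in transcript length under full-length counting."""
        ann = simulate_annotation(300, length_range=(300, 6000), seed=40)
        truth = simulate_truth(sorted(ann.genes), n_per_group=1,
                               rin_by_condition={"A": 9.5, "B": 6.0}, phi=0.0,
                               mean_libsize=1e5, libsize_sigma=0.0, seed=41)
        sim = simulate_counts(ann, truth, seed=42)
        major = select_major_transcript(ann, {})
        lens = np.array([ann.genes[g].transcripts[major[g]].spliced_length
                         for g in sim.mu_full.index])
        lr_trunc = np.log2(sim.mu_truncated.iloc[:, 0] / sim.mu_truncated.iloc[:, 1])
        lr_full = np.log2(sim.mu_full.iloc[:, 0] / sim.mu_full.iloc[:, 1])
        assert np.ptp(lr_trunc.to_numpy()) < 1e-9
        rho = spearmanr(lr_full, lens).statistic
        assert rho > 0.95  # high-RIN sample retains relatively more of long genes

    def test_naive_logfc_length_correlation(self):
        """Confounded RIN, full-length counting: short transcripts appear
        overexpressed in the degraded group."""
        ann = simulate_annotation(2000, seed=50)
        truth = simulate_truth(sorted(ann.genes), n_per_group=3,
                               rin_by_condition={"A": 9.5, "B": 6.0}, phi=0.1,
                               mean_libsize=5e5, seed=51)
        sim = simulate_counts(ann, truth, seed=52)
        cpm = sim.counts_full / sim.counts_full.sum(axis=0) * 1e6
        a = cpm.iloc[:, :3].mean(axis=1)
        b = cpm.iloc[:, 3:].mean(axis=1)
        logfc = np.log2((b + 0.5) / (a + 0.5))  # degraded vs intact
        major = select_major_transcript(ann, {})
        lens = [ann.genes[g].transcripts[major[g]].spliced_length for g in cpm.index]
        assert spearmanr(logfc, lens).statistic < -0.3

    def test_reads_counts_coherent(self, null_sim):
        """Emitted-read tallies define the count matrices."""
        ann, truth, major, sim = null_sim
        reads = sim.reads
        tallies = reads.groupby(["gene_id", "sample"]).size().unstack(fill_value=0)
        tallies = tallies.reindex(index=sim.counts_full.index,
                                  columns=sim.counts_full.columns, fill_value=0)
        assert tallies.equals(sim.counts_full)
        assert (sim.counts_truncated <= sim.counts_full).all().all()

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            simulate_truth(["G1"], phi=-0.1, seed=1)

    def test_bit_reproducible(self):
        ann = simulate_annotation(50, seed=5)
        truth = simulate_truth(sorted(ann.genes), seed=6)
        s1 = simulate_counts(ann, truth, seed=7)
        s2 = simulate_counts(ann, truth, seed=7)
        assert s1.counts_full.equals(s2.counts_full)
        assert s1.counts_truncated.equals(s2.counts_truncated)


class TestTruth:
    def test_pi_normalized_and_null_genes_proportional(self):
        truth = simulate_truth([f"g{i}" for i in range(500)], de_frac=0.1,
                               de_min_cpm=0.0, seed=3)
        assert truth.pi.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0])
        null = ~truth.is_de
        ratio = truth.pi.loc[null, "B"] / truth.pi.loc[null, "A"]
        assert np.ptp(ratio.to_numpy()) < 1e-12
        de = truth.true_log2fc[truth.is_de]
        assert set(np.abs(de)) == {2.0}
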