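# decaynorm

Degradation-aware differential expression for bulk RNA-seq when samples have
unequal RNA integrity (RIN).

## The problem

In oligo-dT-selected libraries, partially degraded transcripts keep their
poly-A-anchored 3' end, so read coverage decays with distance from the 3'
end — faster the lower the RIN. When the compared groups differ in RIN, a
naive analysis mistakes this technical loss for biology: short transcripts
appear over-expressed in the degraded group and long transcripts appear
suppressed.

`decaynorm` implements the correction pipeline and a synthetic-data module
that reproduces the phenomenon so every stage can be validated without any
external data:

1. **Coverage profiling** — per-sample coverage as a function of distance
   `d` (bp) from the transcript 3' end, and detection of the preserved
   window (the largest `D` such that all bins up to `D` stay above a
   fraction τ of the maximum in every sample).
2. **Truncated gene model** — the most abundant transcript per gene is
   selected, the rest discarded, and each transcript is truncated to its
   3'-most 750 bp (a new GTF is emitted). Counting on the truncated model
   makes expected counts independent of transcript length under degradation.
3. **Stratified TMM** — genes are split into 10 quantile bins by average
   transcript length and a TMM factor
   `log2 f = Σ w_g M_g / Σ w_g` (M = log count ratio, double-trimmed 30%
   by M and 5% by A, precision-weighted) is computed per bin and sample;
   the same procedure is repeated with bins by average CPM.
4. **NB exact test** — a common dispersion φ (variance = μ + φμ²) is
   estimated by conditional maximum likelihood, and each gene is tested
   with the conditional two-sample exact test on group sums,
   `Y₁ ~ NB(n₁μ, φ/n₁)` vs `Y₂ ~ NB(n₂μ, φ/n₂)` given `Y₁+Y₂`. Genes pass
   the DEG filter when FC > 2 or < 0.5, CPM > 4 and BH-FDR < 0.01.
5. **Reporting** — top-N (50/100/250/500/1000) hypergeometric
   over-representation against GMT gene sets, marker-panel logFC tables
   across comparisons, and a ΔΔCt helper for qPCR cross-checks.

## Worked example

Simulate a 2000-gene null experiment (no true DE) where the two groups of
three samples differ only in RNA integrity (RIN 9.5 vs 6.0), then analyse
it both naively (full-length counts, one global TMM factor) and with the
correction:

```python
from decaynorm.pipeline import RunConfig, run

cfg = RunConfig(mode="both", seed=1, de_frac=0.0)   # RIN 9.5 vs 6.0 default
print(run(cfg, write=False).summary)
```

```
{'corrected': {'logfc_length_spearman': 0.036, 'deg_passes': 0,
               'fdr_passes': 0, 'n_genes': 2000, 'fpr': 0.0, 'tpr': None},
 'naive':     {'logfc_length_spearman': -0.835, 'deg_passes': 122,
               'fdr_passes': 122, 'n_genes': 2000, 'fpr': 0.061, 'tpr': None},
 'dispersion': {'corrected': 0.103, 'naive': 0.102}}
```

Read: with no true differential expression, the naive analysis calls 122
genes significant and its fold changes correlate strongly with transcript
length (Spearman ρ = −0.84, long genes spuriously "down" in the degraded
group); the corrected pipeline calls none, the length correlation is gone
(ρ = 0.04), and the simulated dispersion (0.1) is recovered.

The same pipeline is available from the shell:

```sh
decaynorm init                         # write a config with all defaults
decaynorm run --seed 1 --mode both --outdir results/run1
decaynorm simulate --n-genes 2000 --rin A:9.5,B:6.0 --de-frac 0.1 \
    --emit-reads --seed 1 --outdir sim/
decaynorm build-model --gtf sim/annotation.gtf --abundance sim/abundance.tsv \
    --out-gtf model.gtf --out-bed model.bed
decaynorm count --reads sim/reads.bed --model-bed model.bed --out counts.tsv
```

## Layout

- `src/decaynorm/syndata.py` — degradation model and simulator
- `src/decaynorm/gene_model.py` — GTF I/O, major transcripts, 3'-truncation
- `src/decaynorm/coverage.py` — 3'-anchored coverage profiles
- `src/decaynorm/quantify.py` — overlap counting, CPM
- `src/decaynorm/normalize.py` — TMM, stratified TMM
- `src/decaynorm/detest.py` — dispersion, exact test, BH, DEG filter
- `src/decaynorm/downstream.py` — enrichment, marker panels, ΔΔCt
- `src/decaynorm/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
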