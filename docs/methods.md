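# Methods

## Degradation model

Poly-A-selected libraries sequence fragments of whatever transcript material
still carries a poly-A tail, so degradation erodes coverage from the 5' side.
We model the survival probability of a transcript position at distance `d`
(bp) from the 3' end as

```
S(d) = 1                              d ≤ L0
S(d) = exp(−(d − L0) / λ(RIN))        d > L0
λ(RIN) = λ0 · exp(α · (RIN − 6))
```

with a hard preserved window `L0 = 750` bp, `λ0 = 400` bp and `α = 0.9`.
These defaults make a RIN-6 sample lose most coverage within ~1 kb of the
window while a RIN ≥ 9.5 sample is near-intact (λ ≈ 9.3 kb) — the regime the
pipeline is designed for. λ is strictly increasing in RIN; RIN outside
[1, 10] is rejected. The two-parameter exponential is the simplest law with
a preserved window and a tunable decay rate; real degradation profiles are
not exactly exponential, and nothing downstream depends on that shape —
only on the window being preserved.

## Simulation

Per-gene relative expression is log-normal (σ = 1.2, normalized to sum 1
per condition), emulating the orders-of-magnitude dynamic range of bulk
RNA-seq. Expected counts are

```
μ_gs = N_s · π_g · W_g(region, RIN_s) / Σ_h π_h · W_h(full, RIN_s)
```

where `W = ∫ S` over the counted region (closed form, exercised against
numerical quadrature in the tests). Counts are gamma-Poisson draws, i.e.
NB with common dispersion φ (default 0.1, a typical bulk-RNA-seq value for
cell lines); φ = 0 gives Poisson. Because binomial thinning preserves the
gamma-Poisson form, counts on the 750-bp truncated region are obtained by
thinning the full-length counts and remain exactly NB with the same φ —
full and truncated matrices from one run are coherent.

Read placements, when emitted, anchor each read at its 3'-most base, drawn
with density ∝ S by exact inverse-CDF sampling, extending 75 bp toward 5'
(clipped at the 5' end and at the exon boundary of the anchor: reads are
single-end, unspliced). Anchoring at the 3' base makes the ≥1-bp-overlap
counting rule on a 3'-prefix region coincide exactly with "anchor inside
region", so emitted-read tallies, the μ formula and `quantify.count_reads`
agree without approximation. Randomness flows from one master seed through
`SeedSequence.spawn`, one substream per sample; all outputs are
bit-reproducible for a fixed seed.

Default study conditions: 2000 genes on one chromosome (non-overlapping,
spliced lengths 300–6000 bp, 1–3 exons), 3 samples per condition, library
sizes log-normal around 5×10⁵ (15% CV), RIN 9.5 vs 6.0 in the confounded
design. When true DE is planted (`de_frac`, default effect |log2FC| = 2,
half up, half down), DE genes are drawn among genes with baseline
abundance ≥ 16 CPM so the planted effects are detectable at the CPM > 4
filter; renormalization of π means non-DE genes keep a constant ratio
across conditions rather than identical values — the composition effect
TMM is built to absorb. What the simulator does *not* model: fragment-size
and GC biases, sequencing error, spliced alignment, multimapping,
gene-gene correlation. Passing tests therefore demonstrate correctness of
the method's logic under its own assumptions, not robustness to every
artifact of real libraries.

## Coverage profiles and the preserved window

Profiles accumulate per-base coverage by bp-distance from the 3' end
(bin width 50, range 0–3000 bp), aggregated over the selected major
transcripts only and normalized to the maximum bin. Two choices matter:

* Only transcripts spanning the profiled range (spliced length ≥ `max_d`)
  contribute, otherwise the transcript-length distribution itself produces
  a decline indistinguishable from degradation.
* Per-base coverage is divided by the positional availability
  `min(x+1, read_len)/read_len` before binning; positions within one read
  length of the 3' terminus can be covered by fewer distinct placements,
  and without this correction the first 1–2 bins ramp up purely
  geometrically.

`detect_preserved_window(profiles, τ)` returns the largest `D` (multiple of
the bin width) such that every bin with upper edge ≤ `D` has normalized
coverage ≥ τ in every sample. The default is τ = 0.95: "preserved" means
near-full coverage, and a permissive threshold (say 0.8) systematically
overshoots the true window whenever decay beyond it is gradual — at RIN 6
(λ = 400 bp) survival only crosses 0.8 around d ≈ 840, so a τ = 0.8
detector would report ≥ 850 bp no matter how precisely it measured.
Localization to ±50 bp additionally requires the decay scale to be
comparable to a bin: validation uses a strongly degraded sample (RIN 4,
λ ≈ 66 bp) alongside an intact one, where detection lands on 750 exactly.
The 75-bp read extent smooths any transition over roughly one bin; that is
a floor on achievable localization, not a bug.

## Gene model

Internal coordinates are 0-based half-open; GTF I/O converts to and from
1-based inclusive. The most abundant transcript per gene is kept (ties:
longer transcript, then lexicographically smaller id; all-zero abundance
falls back to the longest, logged) and truncated to its 3'-most 750
spliced bp by a strand-aware walk across exons; transcripts shorter than
750 bp are kept whole — truncation is a cap, not a requirement. The
per-gene length used for stratification is the mean of the annotated
transcript lengths (`--bin-length-mode major` switches to the selected
transcript's length).

## Counting

featureCounts-style defaults for an unstranded library: a read counts for
a gene iff it overlaps that gene's counting region by ≥ 1 bp; reads
overlapping the regions of more than one gene are ambiguous and dropped;
library size is the column sum of the counted matrix.

## Normalization

`tmm_factor` implements the trimmed mean of M-values with the standard
defaults (30% two-sided trim on M, 5% on A, inverse delta-method variance
weights, genes with a zero in either column excluded). Trimming uses
average ranks so exact ties trim symmetrically; fewer than 10 surviving
genes yields factor 1 with a warning. One unit test cross-checks the
implementation against edgeR's `calcNormFactors` to 1e-9.

Stratified TMM bins genes into 10 near-equal quantile bins (stable sort,
ties by gene id; bins under 50 genes are merged into their smaller
neighbor for factor stability) and computes per-bin, per-sample factors
against the global reference sample (the one whose upper-quartile CPM is
closest to the across-sample mean), using whole-column library sizes.
Factors are re-centered to geometric mean 1 across samples within each
bin — without re-centering the bin factors are only identified up to a
per-bin scale — and counts are rescaled (`raw / factor`), preserving
zeros. Stage 2 repeats the procedure stratifying by per-gene mean CPM
computed *after* the length stage (the stages do not commute; length
first). The exact test is count-based, so the adjusted matrix is also
provided rounded half-to-even; the continuous matrix is retained. With a
single bin the procedure reduces to global TMM to 1e-10.

## Differential expression

Columns are first scaled to a common effective library size (geometric
mean; effective size = column sum × global TMM factor in naive mode, plain
column sum after stratified adjustment, whose factors are already folded
into the counts). The common dispersion maximizes the equal-library-size
conditional NB log-likelihood

```
Σ_genes Σ_groups [ Σ_i ln Γ(y_i + r) − n ln Γ(r) + ln Γ(nr) − ln Γ(z + nr) ],  r = 1/φ
```

over log10 φ ∈ [−4, 1] (bounded scalar minimization, tolerance 1e-4). This
is a deliberate simplification of quantile-adjusted conditional ML:
stratified normalization has already equalized effective library sizes, so
the quantile-adjustment step is dropped.

The exact test conditions the NB group sums on their total and sums the
conditional probabilities of all outcomes whose mass does not exceed the
observed one (ties included via a 1e-8 log-scale slack); φ = 0 reduces to
the conditional binomial test. `t = 0` gives p = 1. Fold changes are
`log2((CPM̄₂ + 0.5)/(CPM̄₁ + 0.5))` — the 0.5 prior bounds logFC at zero
counts. BH adjustment is delegated to statsmodels. The DEG filter applies
strict inequalities: FC > 2 or FC < 0.5, average CPM > 4, FDR < 0.01.

## Downstream

Top-N lists (N ∈ {50, 100, 250, 500, 1000}) rank genes of the requested
sign by ascending p, ties by |logFC| descending then gene id, so lists are
reproducible. Over-representation uses the upper-tail hypergeometric
probability against the tested universe with BH across sets; graph-aware
ontology algorithms and GSEA are out of scope. ΔΔCt assumes amplification
efficiency 2.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at 2000 genes × 3 vs 3
samples (5×10⁵ reads per sample) for the DE properties, and 200 long genes
at 2×10⁶ reads per sample for the coverage-window check — sizes at which
every acceptance property is stable across seeds while the whole suite
runs in well under a minute of compute per property.

## Known limitations

* The preserved window and the truncation length are treated as global
  constants; per-sample windows are not fit.
* Counts are rescaled rather than carried as model offsets; the exact test
  then treats adjusted counts as NB, which is an approximation (documented
  above; calibration is verified empirically on the null).
* Only the common-dispersion exact test is provided — no tagwise/trended
  dispersion, no GLM covariates.
* The quasi-likelihood F-test arm of the original analysis is not
  implemented.
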