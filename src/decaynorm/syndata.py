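"""Synthetic data with RIN-dependent 3'-bias, NB counts and known DE truth.

The degradation model: in oligo-dT selected libraries, partially degraded
transcripts keep their poly-A anchored 3' end, so the probability that a
transcript position survives into the sequenced library depends on its
distance ``d`` from the 3' end.  We model a hard preserved window of
``L0`` bp (survival 1) followed by exponential loss with a RIN-dependent
scale::

    S(d) = 1                        for d <= L0
    S(d) = exp(-(d - L0) / lam)     for d >  L0,   lam(RIN) = lam0 * exp(alpha*(RIN-6))

Counts and read placements are generated coherently: the per-gene count on
any 3'-prefix region equals the number of emitted reads whose 3'-most base
falls inside it, and its expectation follows

    mu_gs = N_s * pi_g * W_g(region, RIN_s) / sum_h pi_h * W_h(full, RIN_s)

with W the integral of S over the counted region.  Overdispersion is
introduced as a gamma-Poisson mixture, so counts on any sub-region are
negative binomial with the same dispersion phi (binomial thinning of a
gamma-Poisson mixture preserves the mixture form).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_model import Annotation, Interval, Transcript, select_major_transcript

READ_LENGTH = 75  # single-end read length emulated throughout


# ---------------------------------------------------------------------------
# Degradation model

@dataclass(frozen=True)
class DegradationModel:
    """Positional survival of transcript material as a function of RIN.

    Parameters
    ----------
    preserved_window:
        bp from the 3' end with full survival (default 750).
    lambda0:
        exponential decay scale at RIN 6, in bp.
    alpha:
        log-scale sensitivity of the decay scale to RIN; ``lam`` is strictly
        increasing in RIN so higher integrity decays more slowly.
    """

    preserved_window: float = 750.0
    lambda0: float = 400.0
    alpha: float = 0.9

    def decay_scale(self, rin) -> np.ndarray | float:
        rin = np.asarray(rin, dtype=float)
        if np.any((rin < 1.0) | (rin > 10.0)):
            raise ValueError(f"RIN must lie in [1, 10], got {rin}")
        lam = self.lambda0 * np.exp(self.alpha * (rin - 6.0))
        return lam if lam.ndim else float(lam)


DEFAULT_DEGRADATION = DegradationModel()


def survival_fraction(d3, rin, model: DegradationModel = DEFAULT_DEGRADATION):
    """Survival probability S(d3) at distance *d3* bp from the 3' end."""
    d3 = np.asarray(d3, dtype=float)
    if np.any(d3 < 0):
        raise ValueError("distance from 3' end must be >= 0")
    lam = model.decay_scale(rin)
    s = np.where(d3 <= model.preserved_window,
                 1.0,
                 np.exp(-(d3 - model.preserved_window) / lam))
    return s if s.ndim else float(s)


def _prefix_weight(d, lam, L0):
    """Integral of S over [0, d) given decay scale lam (vectorized)."""
    d = np.asarray(d, dtype=float)
    inside = np.minimum(d, L0)
    beyond = np.maximum(d - L0, 0.0)
    return inside + lam * (1.0 - np.exp(-beyond / lam))


def capture_weight(
    transcript_length: float,
    region: list[Interval],
    rin,
    model: DegradationModel = DEFAULT_DEGRADATION,
) -> float:
    """Effective surviving bp, W = integral of S over *region*.

    *region* is an interval set in 3'-distance coordinates and must lie
    within ``[0, transcript_length)``.
    """
    lam = model.decay_scale(rin)
    total = 0.0
    if not region:
        warnings.warn("capture_weight of an empty region is 0")
        return 0.0
    for a, b in region:
        if not (0 <= a <= b <= transcript_length):
            raise ValueError(f"region ({a},{b}) outside [0,{transcript_length})")
        total += float(_prefix_weight(b, lam, model.preserved_window)
                       - _prefix_weight(a, lam, model.preserved_window))
    return total


def _sample_distances(n: int, L: float, lam: float, L0: float, rng) -> np.ndarray:
    """Draw n 3'-distances in [0, L) with density proportional to S."""
    W = float(_prefix_weight(L, lam, L0))
    u = rng.random(n) * W
    head = np.minimum(L, L0)
    d = np.where(u <= head, u, L0 - lam * np.log1p(-(u - head) / lam))
    return np.minimum(np.floor(d), L - 1).astype(np.int64)


# ---------------------------------------------------------------------------
# Simulation truth

@dataclass
class SimTruth:
    """Ground truth of a two-condition simulation.

    ``pi`` holds per-gene relative expression per condition (columns sum
    to 1); non-DE genes keep a constant ratio across conditions.
    """

    pi: pd.DataFrame                      # genes x conditions, columns sum to 1
    is_de: pd.Series                      # bool per gene
    true_log2fc: pd.Series                # nominal log2 FC (condition2 vs condition1)
    dispersion: float
    lib_sizes: pd.Series                  # per sample
    rin: pd.Series                        # per sample
    condition: pd.Series                  # per sample
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.pi.index)

    @property
    def samples(self) -> list[str]:
        return list(self.lib_sizes.index)

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.samples,
            "condition": self.condition.values,
            "rin": self.rin.values,
            "libsize": self.lib_sizes.values,
        })

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "true_log2fc": self.true_log2fc.values,
            "is_de": self.is_de.astype(int).values,
        })


def simulate_truth(
    gene_ids: list[str],
    *,
    n_per_group: int = 3,
    conditions: tuple[str, str] = ("A", "B"),
    rin_by_condition: dict[str, float] | None = None,
    phi: float = 0.1,
    de_frac: float = 0.0,
    de_log2fc: float = 2.0,
    mean_libsize: float = 5e5,
    libsize_sigma: float = 0.15,
    pi_sigma: float = 1.2,
    de_min_cpm: float = 16.0,
    seed: int = 0,
) -> SimTruth:
    """Draw per-gene relative expression, DE assignments and sample metadata.

    Baseline relative expression is log-normal (sigma ``pi_sigma``),
    emulating the orders-of-magnitude spread of bulk RNA-seq.  DE genes are
    drawn among genes whose baseline abundance corresponds to at least
    ``de_min_cpm`` CPM, half up- and half down-regulated at ``de_log2fc``;
    library sizes are log-normal around ``mean_libsize``.
    """
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    if n_per_group < 1:
        raise ValueError("need at least one sample per condition")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    x = rng.lognormal(mean=0.0, sigma=pi_sigma, size=n)
    pi_a = x / x.sum()

    lfc = np.zeros(n)
    is_de = np.zeros(n, dtype=bool)
    if de_frac > 0:
        n_de = int(round(de_frac * n))
        eligible = np.flatnonzero(1e6 * pi_a >= de_min_cpm)
        if len(eligible) < n_de:
            raise ValueError("not enough genes above de_min_cpm to host DE genes")
        chosen = rng.choice(eligible, size=n_de, replace=False)
        is_de[chosen] = True
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[chosen] = signs * de_log2fc
    pi_b = pi_a * 2.0 ** lfc
    pi_b = pi_b / pi_b.sum()

    cond_a, cond_b = conditions
    if rin_by_condition is None:
        rin_by_condition = {cond_a: 9.5, cond_b: 9.5}
    samples = [f"{cond_a}{i+1}" for i in range(n_per_group)] + \
              [f"{cond_b}{i+1}" for i in range(n_per_group)]
    cond = [cond_a] * n_per_group + [cond_b] * n_per_group
    libs = np.round(mean_libsize * np.exp(
        rng.normal(0.0, libsize_sigma, size=2 * n_per_group) - libsize_sigma ** 2 / 2
    )).astype(np.int64)

    return SimTruth(
        pi=pd.DataFrame({cond_a: pi_a, cond_b: pi_b}, index=gene_ids),
        is_de=pd.Series(is_de, index=gene_ids),
        true_log2fc=pd.Series(lfc, index=gene_ids),
        dispersion=float(phi),
        lib_sizes=pd.Series(libs, index=samples),
        rin=pd.Series([rin_by_condition[c] for c in cond], index=samples, dtype=float),
        condition=pd.Series(cond, index=samples),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Annotation simulation

def simulate_annotation(
    n_genes: int,
    isoforms_per_gene: int = 1,
    length_range: tuple[int, int] = (300, 6000),
    seed: int = 0,
    chrom: str = "chrS",
    intergenic_gap: tuple[int, int] = (200, 1000),
) -> Annotation:
    """A single-chromosome annotation of non-overlapping genes.

    Each transcript has 1-3 exons, a spliced length uniform in
    ``length_range``, and introns of 50-500 bp; strands are mixed.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 100:
        raise ValueError("transcript lengths must be >= 100 bp")
    rng = np.random.default_rng(seed)
    ann = Annotation()
    cursor = 1000
    for gi in range(n_genes):
        gid = f"SIMG{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_end = cursor
        for ti in range(isoforms_per_gene):
            tid = f"{gid}.T{ti + 1}"
            splen = int(rng.integers(lo, hi + 1))
            n_exons = int(rng.integers(1, 4))
            # split spliced length into n_exons parts of >= 50 bp each
            while n_exons > 1 and splen < 50 * n_exons:
                n_exons -= 1
            if n_exons == 1:
                parts = [splen]
            else:
                extra = splen - 50 * n_exons
                cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1))
                parts = (50 + np.diff(np.concatenate([[0], cuts, [extra]]))).tolist()
            exons = []
            pos = cursor
            for k, plen in enumerate(parts):
                exons.append((pos, pos + int(plen)))
                pos += int(plen)
                if k < len(parts) - 1:
                    pos += int(rng.integers(50, 501))
            ann.add(Transcript(tid, gid, chrom, strand, exons))
            gene_end = max(gene_end, pos)
        cursor = gene_end + int(rng.integers(*intergenic_gap))
    return ann


def simulate_abundance(annotation: Annotation, seed: int = 0) -> dict[str, float]:
    """Random positive per-transcript abundances (for major-transcript selection)."""
    rng = np.random.default_rng(seed)
    return {t.transcript_id: float(rng.lognormal(2.0, 1.0))
            for t in annotation.transcripts()}


# ---------------------------------------------------------------------------
# Count / read simulation

@dataclass
class SimResult:
    counts_full: pd.DataFrame
    counts_truncated: pd.DataFrame
    mu_full: pd.DataFrame
    mu_truncated: pd.DataFrame
    reads: pd.DataFrame | None
    truth: SimTruth
    major: dict[str, str]
    model: DegradationModel
    truncate_bp: int


def _emit_reads_for_gene(
    t: Transcript, d: np.ndarray, sample: str, read_length: int
) -> pd.DataFrame:
    """Genomic read blocks for 3'-distances *d* on major transcript *t*.

    Reads run from the 3'-most base toward 5' for ``read_length`` bp,
    clipped at the transcript 5' end and at the exon boundary of the
    3'-most base (reads are unspliced).
    """
    L = t.spliced_length
    p3 = L - 1 - d                                      # spliced pos (5'-based) of 3' base
    offs = t.exon_offsets_5to3()
    exs = t.exons_5to3()
    lens = np.array([e - s for s, e in exs], dtype=np.int64)
    j = np.searchsorted(offs, p3, side="right") - 1
    lo = np.maximum(p3 - (read_length - 1), offs[j])
    hi = p3 + 1
    starts = np.empty_like(lo)
    ends = np.empty_like(lo)
    ex_starts = np.array([s for s, _ in exs], dtype=np.int64)
    ex_ends = np.array([e for _, e in exs], dtype=np.int64)
    if t.strand == "+":
        starts = ex_starts[j] + (lo - offs[j])
        ends = ex_starts[j] + (hi - offs[j])
    else:
        starts = ex_ends[j] - (hi - offs[j])
        ends = ex_ends[j] - (lo - offs[j])
    del lens
    return pd.DataFrame({
        "chrom": t.chrom,
        "start": starts,
        "end": ends,
        "strand": t.strand,
        "sample": sample,
        "gene_id": t.gene_id,
    })


def simulate_counts(
    annotation: Annotation,
    truth: SimTruth,
    *,
    model: DegradationModel = DEFAULT_DEGRADATION,
    major: dict[str, str] | None = None,
    truncate_bp: int = 750,
    read_length: int = READ_LENGTH,
    emit_reads: bool = False,
    seed: int | None = None,
) -> SimResult:
    """Simulate NB counts (full-length and 3'-truncated models) and reads.

    Expression is placed on each gene's major transcript.  With
    ``emit_reads`` the counts are the tallies of emitted read placements;
    otherwise counts on the truncated region are a binomial thinning of the
    full-length counts, which is distributionally identical.
    """
    if truth.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if major is None:
        major = select_major_transcript(annotation, {})
    genes = truth.gene_ids
    missing = [g for g in genes if g not in annotation.genes]
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:5]}...")
    transcripts = {g: annotation.genes[g].transcripts[major[g]] for g in genes}
    L = np.array([transcripts[g].spliced_length for g in genes], dtype=float)
    T = np.minimum(float(truncate_bp), L)

    samples = truth.samples
    n_samples = len(samples)
    master = np.random.SeedSequence(truth.seed if seed is None else seed)
    streams = [np.random.default_rng(s) for s in master.spawn(n_samples)]

    phi = truth.dispersion
    counts_full = np.zeros((len(genes), n_samples), dtype=np.int64)
    counts_trunc = np.zeros_like(counts_full)
    mu_full = np.zeros((len(genes), n_samples))
    mu_trunc = np.zeros_like(mu_full)
    read_frames: list[pd.DataFrame] = []

    for si, s in enumerate(samples):
        rng = streams[si]
        rin = float(truth.rin[s])
        lam = model.decay_scale(rin)
        W_full = np.asarray(_prefix_weight(L, lam, model.preserved_window))
        W_trunc = np.asarray(_prefix_weight(T, lam, model.preserved_window))
        pi = truth.pi[truth.condition[s]].loc[genes].to_numpy()
        denom = float(np.sum(pi * W_full))
        N = float(truth.lib_sizes[s])
        mu_f = N * pi * W_full / denom
        mu_full[:, si] = mu_f
        mu_trunc[:, si] = N * pi * W_trunc / denom

        if phi > 0:
            gamma = rng.gamma(shape=1.0 / phi, scale=phi, size=len(genes))
        else:
            gamma = np.ones(len(genes))
        n_f = rng.poisson(gamma * mu_f)
        counts_full[:, si] = n_f

        if emit_reads:
            for gi, g in enumerate(genes):
                if n_f[gi] == 0:
                    continue
                d = _sample_distances(int(n_f[gi]), L[gi], lam,
                                      model.preserved_window, rng)
                counts_trunc[gi, si] = int(np.sum(d < T[gi]))
                read_frames.append(
                    _emit_reads_for_gene(transcripts[g], d, s, read_length))
        else:
            p = np.clip(W_trunc / W_full, 0.0, 1.0)
            counts_trunc[:, si] = rng.binomial(n_f, p)

    reads = None
    if emit_reads:
        reads = pd.concat(read_frames, ignore_index=True) if read_frames else \
            pd.DataFrame(columns=["chrom", "start", "end", "strand", "sample", "gene_id"])
        reads = reads.reset_index(drop=True)
        reads["read_id"] = [f"r{i}" for i in range(len(reads))]

    def frame(a):
        return pd.DataFrame(a, index=pd.Index(genes, name="gene_id"), columns=samples)

    return SimResult(
        counts_full=frame(counts_full),
        counts_truncated=frame(counts_trunc),
        mu_full=frame(mu_full),
        mu_truncated=frame(mu_trunc),
        reads=reads,
        truth=truth,
        major=dict(major),
        model=model,
        truncate_bp=int(truncate_bp),
    )


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)

def write_reads_bed(reads: pd.DataFrame, path: str) -> None:
    """6-column BED (0-based half-open), name = sample:read_id."""
    out = pd.DataFrame({
        "chrom": reads["chrom"],
        "start": reads["start"],
        "end": reads["end"],
        "name": reads["sample"].astype(str) + ":" + reads["read_id"].astype(str),
        "score": 0,
        "strand": reads["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_reads_sam(reads: pd.DataFrame, annotation: Annotation, path: str) -> None:
    """Minimal unspliced single-end SAM (MAPQ 255, sequence omitted)."""
    import pysam

    chrom_len: dict[str, int] = {}
    for g in annotation.genes.values():
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(chrom_len.items())],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        tid_of = {c: i for i, c in enumerate(sorted(chrom_len))}
        for r in reads.itertuples():
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"{r.sample}:{r.read_id}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid_of[r.chrom]
            a.reference_start = int(r.start)
            a.mapping_quality = 255
            a.cigartuples = [(0, int(r.end) - int(r.start))]
            fh.write(a)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
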