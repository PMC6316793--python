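"""Per-sample read coverage as a function of distance from the transcript 3' end.

Unlike percentile-based gene-body profiles, distances are kept in bp because
the preserved window of degraded poly-A libraries is a length in bp, not a
fraction of each transcript.  Only the selected major transcript of each
gene contributes, mirroring the quantification model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_model import Annotation, Transcript


@dataclass
class CoverageProfile:
    sample_id: str
    bin_width: int
    max_d: int
    #: normalized per-bin coverage, max bin = 1
    values: np.ndarray
    n_transcripts: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(0, self.max_d, self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        starts = self.bin_starts
        return pd.DataFrame({
            "sample_id": self.sample_id,
            "bin_start": starts,
            "bin_end": np.minimum(starts + self.bin_width, self.max_d),
            "normalized_coverage": self.values,
        })


def _exon_table(annotation: Annotation, major: dict[str, str], min_length: int):
    """Per-chrom sorted exon arrays of the profiled major transcripts.

    Each exon row carries (start, end, spliced offset of its 5'-most base,
    transcript length, strand, transcript index).  Returns None if exons
    overlap (caller falls back to an interval tree)."""
    rows: dict[str, list] = {}
    tids: list[str] = []
    for gid in sorted(major):
        t = annotation.genes[gid].transcripts[major[gid]]
        if t.spliced_length < min_length:
            continue
        ti = len(tids)
        tids.append(t.transcript_id)
        offs = t.exon_offsets_5to3()
        for k, (s, e) in enumerate(t.exons_5to3()):
            rows.setdefault(t.chrom, []).append(
                (s, e, int(offs[k]), t.spliced_length, t.strand == "+", ti))
    tables = {}
    for chrom, lst in rows.items():
        lst.sort()
        arr = {k: np.array(v) for k, v in zip(
            ("start", "end", "off", "L", "fwd", "ti"), zip(*lst))}
        if np.any(arr["start"][1:] < arr["end"][:-1]):
            return None, tids  # overlapping exons: no vectorized path
        tables[chrom] = arr
    return tables, tids


def _exon_tree(annotation: Annotation, major: dict[str, str], min_length: int):
    """Interval trees of major-transcript exons, keyed by chrom."""
    trees: dict[str, IntervalTree] = {}
    txs: dict[str, Transcript] = {}
    for gid, tid in major.items():
        t = annotation.genes[gid].transcripts[tid]
        if t.spliced_length < min_length:
            continue
        txs[gid] = t
        tree = trees.setdefault(t.chrom, IntervalTree())
        offs = t.exon_offsets_5to3()
        order = t.exons_5to3()
        for k, (s, e) in enumerate(order):
            tree.addi(s, e, (gid, int(offs[k]), s, e))
    return trees, txs


def coverage_profile(
    reads: pd.DataFrame,
    annotation: Annotation,
    major: dict[str, str],
    bin_width: int = 50,
    max_d: int = 3000,
    read_length: int | None = None,
    min_length: int | None = None,
) -> dict[str, CoverageProfile]:
    """Aggregate per-base coverage by 3'-distance for each sample.

    A read contributes iff its interval lies entirely inside one exon of a
    major transcript.  Only transcripts of spliced length >= ``min_length``
    (default: ``max_d``) are profiled, so the decline of the transcript-
    length distribution does not masquerade as coverage loss.  With
    ``read_length`` given, per-base coverage is divided by the positional
    availability ``min(x+1, read_length) / read_length`` before binning:
    positions within one read length of the 3' terminus can be covered by
    fewer distinct placements, and without the correction the first bins
    ramp up for purely geometric reasons.
    """
    if min_length is None:
        min_length = max_d
    tables, tids = _exon_table(annotation, major, min_length)
    if not tids:
        raise ValueError(f"no major transcript is >= {min_length} bp; "
                         "lower min_length or max_d")
    samples = sorted(reads["sample"].unique())
    cov = {s: np.zeros(max_d + 1) for s in samples}
    n_tx_hit = {s: set() for s in samples}
    assigned = 0
    if tables is not None:
        sample_codes, sample_levels = pd.factorize(reads["sample"])
        for chrom, sub_idx in reads.groupby("chrom").indices.items():
            tab = tables.get(chrom)
            if tab is None:
                continue
            rs = reads["start"].to_numpy()[sub_idx]
            re_ = reads["end"].to_numpy()[sub_idx]
            sc = sample_codes[sub_idx]
            j = np.searchsorted(tab["start"], rs, side="right") - 1
            ok = (j >= 0)
            jj = np.clip(j, 0, None)
            ok &= (rs >= tab["start"][jj]) & (re_ <= tab["end"][jj])
            j, rs, re_, sc = jj[ok], rs[ok], re_[ok], sc[ok]
            L = tab["L"][j]
            off = tab["off"][j]
            p_lo = np.where(tab["fwd"][j], off + rs - tab["start"][j],
                            off + tab["end"][j] - re_)
            p_hi = p_lo + (re_ - rs)
            d_lo = np.clip(L - p_hi, 0, max_d)
            d_hi = np.clip(L - p_lo, 0, max_d)
            for si, s in enumerate(sample_levels):
                sel = sc == si
                if not sel.any():
                    continue
                np.add.at(cov[s], d_lo[sel], 1)
                np.add.at(cov[s], d_hi[sel], -1)
                n_tx_hit[s].update(tids[k] for k in np.unique(tab["ti"][j][sel]))
            assigned += int(ok.sum())
    else:
        trees, txs = _exon_tree(annotation, major, min_length)
        for r in reads.itertuples():
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            hit = None
            for iv in tree.overlap(r.start, r.end):
                if iv.begin <= r.start and r.end <= iv.end:
                    hit = iv.data
                    break
            if hit is None:
                continue
            gid, exon_off, ex_s, ex_e = hit
            t = txs[gid]
            L = t.spliced_length
            if t.strand == "+":
                p_lo = exon_off + (r.start - ex_s)
            else:
                p_lo = exon_off + (ex_e - r.end)
            p_hi = p_lo + (r.end - r.start)
            # spliced 5'-positions [p_lo, p_hi) -> 3'-distances [L-p_hi, L-p_lo)
            d_lo = max(L - p_hi, 0)
            d_hi = min(L - p_lo, max_d)
            if d_lo < d_hi:
                cov[r.sample][d_lo] += 1
                cov[r.sample][d_hi] -= 1
            n_tx_hit[r.sample].add(t.transcript_id)
            assigned += 1
    if assigned == 0:
        raise ValueError("no reads assignable to major-transcript exons")

    n_bins = int(np.ceil(max_d / bin_width))
    profiles = {}
    for s in samples:
        base = np.cumsum(cov[s][:-1])
        if read_length is not None:
            avail = np.minimum(np.arange(max_d) + 1, read_length) / read_length
            base = base / avail
        binned = np.add.reduceat(base, np.arange(0, max_d, bin_width))
        # average per-base coverage within the bin (last bin may be short)
        widths = np.diff(np.append(np.arange(0, max_d, bin_width), max_d))
        binned = binned / widths
        m = binned.max()
        values = binned / m if m > 0 else binned
        profiles[s] = CoverageProfile(s, bin_width, max_d, values, len(n_tx_hit[s]))
    return profiles


def detect_preserved_window(
    profiles: list[CoverageProfile] | dict[str, CoverageProfile],
    tau: float = 0.95,
) -> int:
    """Largest distance D (multiple of the bin width) such that every bin
    with upper edge <= D has normalized coverage >= *tau* in every profile.

    ``tau`` should sit close to 1: the window is meant to capture the region
    of essentially full coverage, and a permissive threshold overshoots the
    true boundary whenever decay beyond it is gradual.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if not profiles:
        raise ValueError("need at least one coverage profile")
    D = None
    for p in profiles:
        below = np.flatnonzero(p.values < tau)
        d_p = p.max_d if below.size == 0 else int(below[0] * p.bin_width)
        D = d_p if D is None else min(D, d_p)
    if D == 0:
        warnings.warn("no bin satisfies the preserved-coverage threshold in "
                      "some sample; returning 0")
    return int(D)


def write_profiles_tsv(profiles: dict[str, CoverageProfile], path: str) -> None:
    pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True) \
        .to_csv(path, sep="\t", index=False)


def plot_profiles(profiles: dict[str, CoverageProfile], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for s, p in sorted(profiles.items()):
        ax.plot(p.bin_starts + p.bin_width / 2, p.values, label=s)
    ax.set_xlabel("distance from 3' end (bp)")
    ax.set_ylabel("normalized coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
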