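"""Read counting on a gene model and CPM computation.

Counting follows featureCounts defaults: a read is assigned to a gene if it
overlaps that gene's counting region by at least 1 bp, reads overlapping
the regions of more than one gene are discarded as ambiguous, and strand is
ignored (unstranded library).
"""
from __future__ import annotations

import re

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_model import TruncatedModel


def _region_table(regions) -> pd.DataFrame:
    if isinstance(regions, TruncatedModel):
        return regions.region_table()
    return regions


def count_reads(reads: pd.DataFrame, regions, samples: list[str] | None = None
                ) -> pd.DataFrame:
    """Count reads per gene per sample on *regions* (a TruncatedModel or a
    DataFrame with columns chrom/start/end/gene_id)."""
    tab = _region_table(regions)
    trees: dict[str, IntervalTree] = {}
    for r in tab.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene_id)

    unknown = sorted(set(reads["chrom"]) - set(trees))
    if unknown:
        raise ValueError(f"reads on chromosomes absent from the gene model: {unknown}")

    genes = sorted(tab["gene_id"].unique())
    if samples is None:
        samples = sorted(reads["sample"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    out = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for r in reads.itertuples():
        hits = {iv.data for iv in trees[r.chrom].overlap(r.start, r.end)}
        if len(hits) == 1:
            out[gi[hits.pop()], si[r.sample]] += 1
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"), columns=samples)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; library size is the column sum of the matrix."""
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return counts / libs * 1e6


# ---------------------------------------------------------------------------
# Read-set readers (counterparts of the syndata writers)

def read_reads_bed(path: str) -> pd.DataFrame:
    """Read a 6-column BED read set (name encoded as sample:read_id)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    sample, read_id = zip(*(n.split(":", 1) for n in df["name"].astype(str)))
    return pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "strand": df["strand"], "sample": list(sample), "read_id": list(read_id),
    })


def read_reads_sam(path: str) -> pd.DataFrame:
    """Read a minimal single-end SAM read set written by the simulator."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            sample, _, read_id = a.query_name.partition(":")
            rows.append((a.reference_name, a.reference_start, a.reference_end,
                         "-" if a.is_reverse else "+", sample, read_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "sample", "read_id"])


def read_reads(path: str) -> pd.DataFrame:
    if re.search(r"\.sam$", path):
        return read_reads_sam(path)
    return read_reads_bed(path)
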