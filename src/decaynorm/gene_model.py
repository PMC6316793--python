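"""Gene models: annotation parsing, major-transcript selection, 3'-truncation.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the 1-based inclusive convention of the format.  A transcript's "3'-distance"
coordinate system measures spliced base pairs from the transcript 3' end
(position 0 is the 3'-most base), which is the natural frame for poly-A
selected libraries where degradation erodes coverage from the 5' side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    #: genomic exon intervals, 0-based half-open, sorted by start, disjoint
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"({s0},{e0}) and ({s1},{e1})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_5to3(self) -> list[Interval]:
        """Exons in transcription (5'→3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_offsets_5to3(self) -> np.ndarray:
        """Cumulative spliced start offset of each exon in 5'→3' order."""
        lens = [e - s for s, e in self.exons_5to3()]
        return np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)

    def spliced_to_genomic(self, lo: int, hi: int) -> list[Interval]:
        """Map a spliced interval [lo, hi) (5'-based) to genomic intervals."""
        if not (0 <= lo < hi <= self.spliced_length):
            raise ValueError(f"spliced interval [{lo},{hi}) outside transcript")
        out: list[Interval] = []
        offset = 0
        for s, e in self.exons_5to3():
            elen = e - s
            a, b = max(lo, offset), min(hi, offset + elen)
            if a < b:
                if self.strand == "+":
                    out.append((s + (a - offset), s + (b - offset)))
                else:
                    out.append((e - (b - offset), e - (a - offset)))
            offset += elen
        return sorted(out)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())


@dataclass
class Annotation:
    genes: dict[str, Gene] = field(default_factory=dict)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts.values()

    def get_transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts():
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def add(self, t: Transcript) -> None:
        g = self.genes.setdefault(t.gene_id, Gene(t.gene_id, t.chrom, t.strand))
        if (g.chrom, g.strand) != (t.chrom, t.strand):
            raise ValueError(f"transcript {t.transcript_id} disagrees with gene {t.gene_id}")
        g.transcripts[t.transcript_id] = t

    def sorted_genes(self) -> list[Gene]:
        return sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return {t.transcript_id: (t.gene_id, t.chrom, t.strand, tuple(t.exons))
                for t in self.transcripts()} == \
               {t.transcript_id: (t.gene_id, t.chrom, t.strand, tuple(t.exons))
                for t in other.transcripts()}


# ---------------------------------------------------------------------------
# GTF I/O

def read_gtf(path: str) -> Annotation:
    """Parse an Ensembl-dialect GTF into an :class:`Annotation`.

    Only ``exon`` features are used; gene/transcript structure is derived
    from their ``gene_id``/``transcript_id`` attributes.  Errors name the
    offending line number.
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"line {lineno}: cannot parse GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            tid = attrs["transcript_id"][0]
            rec = exons.setdefault(
                tid,
                {"gene_id": attrs["gene_id"][0], "chrom": feat.seqid,
                 "strand": feat.strand, "exons": [], "lineno": lineno},
            )
            # GTF is 1-based inclusive
            rec["exons"].append((feat.start - 1, feat.end))
    ann = Annotation()
    for tid, rec in exons.items():
        try:
            ann.add(Transcript(tid, rec["gene_id"], rec["chrom"], rec["strand"], rec["exons"]))
        except ValueError as exc:
            raise GtfParseError(
                f"line {rec['lineno']}: invalid transcript {tid}: {exc}"
            ) from exc
    return ann


def write_gtf(annotation: Annotation, path: str | None = None) -> str:
    """Serialize to GTF text (1-based inclusive); optionally write to *path*."""
    lines = []
    for gene in annotation.sorted_genes():
        gattr = f'gene_id "{gene.gene_id}";'
        lines.append("\t".join([
            gene.chrom, "decaynorm", "gene", str(gene.start + 1), str(gene.end),
            ".", gene.strand, ".", gattr,
        ]))
        for tid in sorted(gene.transcripts):
            t = gene.transcripts[tid]
            tattr = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
            lines.append("\t".join([
                t.chrom, "decaynorm", "transcript", str(t.start + 1), str(t.end),
                ".", t.strand, ".", tattr,
            ]))
            for i, (s, e) in enumerate(t.exons, start=1):
                eattr = tattr + f' exon_number "{i}";'
                lines.append("\t".join([
                    t.chrom, "decaynorm", "exon", str(s + 1), str(e),
                    ".", t.strand, ".", eattr,
                ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Major transcript selection and truncation

def select_major_transcript(
    annotation: Annotation, abundance: Mapping[str, float]
) -> dict[str, str]:
    """Pick the most abundant transcript per gene; the rest are discarded.

    Missing abundance entries count as zero.  Ties go to the longer
    transcript, then to the lexicographically smaller transcript id.  Genes
    whose transcripts all have zero abundance fall back to the longest
    transcript (logged).
    """
    major: dict[str, str] = {}
    for gene in annotation.genes.values():
        ts = list(gene.transcripts.values())
        scored = [(float(abundance.get(t.transcript_id, 0.0)), t) for t in ts]
        if all(a == 0.0 for a, _ in scored):
            log.info("gene %s: all abundances zero, falling back to longest transcript",
                     gene.gene_id)
        best = min(scored, key=lambda at: (-at[0], -at[1].spliced_length, at[1].transcript_id))
        major[gene.gene_id] = best[1].transcript_id
    return major


def truncate_3prime(transcript: Transcript, L: int = 750) -> list[Interval]:
    """Genomic intervals of the 3'-most *L* spliced bp of *transcript*.

    Walks exons from the 3' end (strand-aware) accumulating spliced length.
    Transcripts shorter than *L* are returned whole.
    """
    if transcript.spliced_length <= L:
        return list(transcript.exons)
    need = L
    pieces: list[Interval] = []
    if transcript.strand == "+":
        # 3' end is the highest coordinate
        for s, e in reversed(transcript.exons):
            take = min(need, e - s)
            pieces.append((e - take, e))
            need -= take
            if need == 0:
                break
    else:
        # 3' end is the lowest coordinate
        for s, e in transcript.exons:
            take = min(need, e - s)
            pieces.append((s, s + take))
            need -= take
            if need == 0:
                break
    return sorted(pieces)


def binning_length(gene: Gene) -> float:
    """Average annotated spliced transcript length of *gene* (bp)."""
    lens = [t.spliced_length for t in gene.transcripts.values()]
    return float(np.mean(lens))


@dataclass
class TruncatedModel:
    """Per-gene single-transcript counting model truncated at the 3' end."""

    annotation: Annotation
    major: dict[str, str]                 # gene_id -> transcript_id
    regions: dict[str, list[Interval]]    # gene_id -> genomic counting region
    truncate_bp: int
    bin_lengths: dict[str, float]         # gene_id -> length used for binning

    def major_transcript(self, gene_id: str) -> Transcript:
        return self.annotation.genes[gene_id].transcripts[self.major[gene_id]]

    def region_table(self) -> pd.DataFrame:
        rows = []
        for gid, ivs in self.regions.items():
            g = self.annotation.genes[gid]
            for s, e in ivs:
                rows.append((g.chrom, s, e, gid, g.strand))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
        return df.sort_values(["chrom", "start", "end", "gene_id"]).reset_index(drop=True)

    def to_bed(self, path: str | None = None) -> str:
        tab = self.region_table()
        lines = [
            "\t".join([r.chrom, str(r.start), str(r.end),
                       f"{r.gene_id}:{self.major[r.gene_id]}", "0", r.strand])
            for r in tab.itertuples()
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_annotation(self) -> Annotation:
        """The truncated model as an annotation (one transcript per gene)."""
        ann = Annotation()
        for gid, tid in self.major.items():
            t = self.major_transcript(gid)
            ann.add(Transcript(tid, gid, t.chrom, t.strand, list(self.regions[gid])))
        return ann

    def to_gtf(self, path: str | None = None) -> str:
        return write_gtf(self.to_annotation(), path)


def build_truncated_model(
    annotation: Annotation,
    abundance: Mapping[str, float],
    truncate_bp: int = 750,
    bin_length_mode: str = "mean",
) -> TruncatedModel:
    """Select major transcripts and truncate each to its 3'-most *truncate_bp* bp.

    ``bin_length_mode`` chooses the per-gene length later used for
    length-stratified normalization: ``"mean"`` (mean of annotated transcript
    lengths) or ``"major"`` (length of the selected transcript).
    """
    if bin_length_mode not in ("mean", "major"):
        raise ValueError("bin_length_mode must be 'mean' or 'major'")
    major = select_major_transcript(annotation, abundance)
    regions = {}
    bin_lengths = {}
    for gid, tid in major.items():
        t = annotation.genes[gid].transcripts[tid]
        regions[gid] = truncate_3prime(t, truncate_bp)
        if bin_length_mode == "mean":
            bin_lengths[gid] = binning_length(annotation.genes[gid])
        else:
            bin_lengths[gid] = float(t.spliced_length)
    return TruncatedModel(annotation, major, regions, truncate_bp, bin_lengths)


def read_abundance(path: str) -> dict[str, float]:
    """Read a two-column transcript abundance TSV (transcript_id, abundance)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("abundance table needs >=2 columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
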