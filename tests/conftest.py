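import numpy as np
import pandas as pd
import pytest

from decaynorm.gene_model import Transcript, select_major_transcript
from decaynorm.syndata import simulate_annotation, simulate_counts, simulate_truth


@pytest.fixture(scope="session")
def small_annotation():
    return simulate_annotation(60, isoforms_per_gene=2, length_range=(300, 4000), seed=3)


@pytest.fixture(scope="session")
def null_sim():
    """Equal-RIN, no-DE simulation with reads, small enough for unit tests."""
    ann = simulate_annotation(120, length_range=(300, 4000), seed=21)
    truth = simulate_truth(sorted(ann.genes), n_per_group=1,
                           rin_by_condition={"A": 9.5, "B": 9.5}, phi=0.0,
                           mean_libsize=3e4, libsize_sigma=0.0, seed=22)
    major = select_major_transcript(ann, {})
    sim = simulate_counts(ann, truth, major=major, emit_reads=True, seed=23)
    return ann, truth, major, sim


def single_exon_transcript(strand="+", start=1000, end=4000, tid="T1", gid="G1"):
    return Transcript(tid, gid, "chr1", strand, [(start, end)])
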