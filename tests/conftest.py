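import numpy as np
import pandas as pd
import pytest

from gistint.models import TranscriptModel

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@pytest.fixture
def plus_model():
    """Three-exon plus-strand coding gene with known codon layout.

    Exons 101-190, 301-390, 501-590 (90 bp each, codons aligned to exon
    boundaries); CDS covers the full exon span.  Exon 1 is ATG + 29x TGG,
    exon 2 is CGT + 29x TGG, exon 3 is 29x TGG + TAA.
    """
    exon1 = "ATG" + "TGG" * 29
    exon2 = "CGT" + "TGG" * 29
    exon3 = "TGG" * 29 + "TAA"
    seq = exon1 + "T" * 110 + exon2 + "T" * 110 + exon3
    return TranscriptModel("GENEP", "chr1", "+",
                           ((101, 190), (301, 390), (501, 590)),
                           cds_start=101, cds_end=590, sequence=seq)


@pytest.fixture
def minus_model():
    """Single-exon minus-strand gene; the transcript (reverse complement of
    the genomic span) is ATG + 28x TGG + TAA."""
    cds = "ATG" + "TGG" * 28 + "TAA"
    return TranscriptModel("GENEM", "chr2", "-", ((101, 190),),
                           cds_start=101, cds_end=190, sequence=revcomp(cds))


@pytest.fixture
def toy_gene_models():
    """Gene collection for read-through tests: A and B are adjacent
    same-strand neighbours on chr11, D sits between them on the opposite
    strand, C is far downstream, E is on another chromosome."""
    mk = lambda gid, chrom, strand, s, e: TranscriptModel(
        gid, chrom, strand, ((s, e),))
    return {
        "A": mk("A", "chr11", "+", 1000, 2000),
        "D": mk("D", "chr11", "-", 2100, 2200),
        "B": mk("B", "chr11", "+", 2500, 3500),
        "C": mk("C", "chr11", "+", 9_000_000, 9_001_000),
        "E": mk("E", "chr7", "+", 1000, 2000),
    }


@pytest.fixture
def fusion_calls():
    def call(sample, caller, g5, c5, g3, c3, spanning, junction):
        return {"sample": sample, "caller": caller,
                "gene5": g5, "chrom5": c5, "strand5": "+",
                "breakpoint5": 100, "gene3": g3, "chrom3": c3,
                "strand3": "+", "breakpoint3": 200,
                "spanning_pairs": spanning, "junction_reads": junction}
    return pd.DataFrame([
        call("s1", "DF", "A", "chr11", "B", "chr11", 5, 2),
        call("s1", "CS", "A", "chr11", "B", "chr11", 3, 4),
        call("s1", "DF", "A", "chr11", "C", "chr11", 2, 1),
    ])
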