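"""Packaged reference tables for a nine-tumor GIST sequencing cohort.

Three curated summary tables ship with the package: clinicopathologic
sample descriptors, per-sample counts of private and recurrent fusion
transcripts, and the curated candidate-fusion call list (with caller
provenance, partner fold-change flags and read-through annotation).  They
are small, load in milliseconds, and exercise the cohort-level fusion and
CNA summaries end to end without any sequencing data.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as gio

_DATA = resources.files("gistint") / "data"


def load_clinical_table() -> pd.DataFrame:
    """Sample descriptors: location, genotype, risk, recurrence status."""
    return gio.read_inputs(str(_DATA / "gist9_clinical.tsv"), "sample_info")


def load_fusion_count_table() -> pd.DataFrame:
    """Per-sample counts of private/recurrent fusion transcripts, the genes
    involved, and how many are read-throughs."""
    columns = ["sample", "private_fusions", "private_genes",
               "private_readthrough", "recurrent_fusions", "recurrent_genes",
               "recurrent_readthrough"]
    dtypes = {c: int for c in columns if c != "sample"}
    return gio._read_typed_tsv(str(_DATA / "gist9_fusion_counts.tsv"),
                               columns, dtypes)


def load_candidate_fusion_table() -> pd.DataFrame:
    """Curated candidate fusion transcripts with caller provenance.

    ``tools`` is a comma-joined subset of {DF, CS}; ``fold_change5/3`` are
    the partner RPKM fold changes where they reached 2, empty otherwise;
    ``read_through`` is boolean.
    """
    columns = ["sample", "tools", "gene5", "chrom5", "fold_change5",
               "gene3", "chrom3", "fold_change3", "read_through"]
    raw = gio._read_typed_tsv(str(_DATA / "gist9_candidate_fusions.tsv"),
                              columns, {"read_through": bool})
    for col in ("fold_change5", "fold_change3"):
        raw[col] = pd.to_numeric(raw[col].replace("", pd.NA))
    return raw


def per_sample_fusion_totals(counts: pd.DataFrame | None = None) -> dict:
    """Total fusions per sample (private + recurrent) from the fusion-count
    table."""
    if counts is None:
        counts = load_fusion_count_table()
    return {r["sample"]: int(r["private_fusions"] + r["recurrent_fusions"])
            for _, r in counts.iterrows()}
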