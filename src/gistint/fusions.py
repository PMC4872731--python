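"""Dual-caller fusion-transcript consensus and annotation.

Two fusion callers' outputs per sample are merged with union semantics on
the ordered (5', 3') gene pair, keeping tool provenance and the maximum
read support seen for the pair.  Consensus records are then filtered on
spanning-pair/junction-read support, annotated as read-through transcripts
when the partners are adjacent same-strand genes, classified as private or
recurrent across the cohort, checked for partner overexpression against an
RPKM matrix, and tabulated per chromosome pair for Circos-style display.
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AnnotationError, DomainError
from .models import ExpressionMatrix, TranscriptModel

CALL_COLUMNS = ["sample", "caller", "gene5", "chrom5", "strand5",
                "breakpoint5", "gene3", "chrom3", "strand3", "breakpoint3",
                "spanning_pairs", "junction_reads"]
CONSENSUS_COLUMNS = ["sample", "gene5", "gene3", "tools", "chrom5", "strand5",
                     "breakpoint5", "chrom3", "strand3", "breakpoint3",
                     "spanning_pairs", "junction_reads"]


def merge_caller_outputs(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge one sample's caller-level records into consensus records.

    Records are grouped by the ordered (gene5, gene3) pair; the ``tools``
    field accumulates contributing callers (comma-joined, sorted) and the
    support counts are per-group maxima.  Union semantics: a pair reported
    by a single caller is retained.
    """
    if calls.empty:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    if calls["sample"].nunique() > 1:
        raise DomainError("merge_caller_outputs expects a single sample")
    tool_col = "caller" if "caller" in calls.columns else "tools"
    rows = []
    for (g5, g3), block in calls.groupby(["gene5", "gene3"], sort=True):
        first = block.iloc[0]
        tools = sorted(set(t for entry in block[tool_col]
                           for t in str(entry).replace("/", ",").split(",")
                           if t.strip()))
        rows.append({
            "sample": first["sample"], "gene5": g5, "gene3": g3,
            "tools": ",".join(t.strip() for t in tools),
            "chrom5": first["chrom5"], "strand5": first["strand5"],
            "breakpoint5": first["breakpoint5"],
            "chrom3": first["chrom3"], "strand3": first["strand3"],
            "breakpoint3": first["breakpoint3"],
            "spanning_pairs": int(block["spanning_pairs"].max()),
            "junction_reads": int(block["junction_reads"].max()),
        })
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)


def merge_all_samples(calls: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`merge_caller_outputs` per sample and concatenate."""
    parts = [merge_caller_outputs(block)
             for _, block in calls.groupby("sample", sort=True)]
    if not parts:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def filter_fusion_support(fusions: pd.DataFrame, min_pairs: int = 2,
                          min_junction: int = 1) -> pd.DataFrame:
    """Keep fusions with >= ``min_pairs`` spanning pairs AND
    >= ``min_junction`` junction-spanning reads."""
    if min_pairs < 0 or min_junction < 0:
        raise DomainError("support thresholds must be >= 0")
    keep = (fusions["spanning_pairs"] >= min_pairs) & (
        fusions["junction_reads"] >= min_junction)
    return fusions[keep].reset_index(drop=True)


def is_readthrough(gene5: str, gene3: str,
                   models: Mapping[str, TranscriptModel],
                   max_gap: int = 200_000) -> bool:
    """Read-through rule for one gene pair.

    True iff both genes share chromosome and strand, the 3' partner is the
    nearest same-strand gene downstream of the 5' partner in its
    transcription direction, and the intergenic gap is at most ``max_gap``
    bp.  Read-throughs arise from transcription running past a gene
    boundary into the neighbour, not from genomic rearrangement.
    """
    for g in (gene5, gene3):
        if g not in models:
            raise AnnotationError(f"gene {g!r} absent from the gene model")
    m5, m3 = models[gene5], models[gene3]
    if m5.chrom != m3.chrom or m5.strand != m3.strand:
        return False
    if m5.strand == "+":
        if m3.span_start <= m5.span_end:
            return False
        gap = m3.span_start - m5.span_end - 1

        def downstream(m):
            return m.span_start > m5.span_end
        def distance(m):
            return m.span_start - m5.span_end
    else:
        if m3.span_end >= m5.span_start:
            return False
        gap = m5.span_start - m3.span_end - 1

        def downstream(m):
            return m.span_end < m5.span_start
        def distance(m):
            return m5.span_start - m.span_end
    if gap > max_gap:
        return False
    nearest = None
    for m in models.values():
        if m.gene_id == gene5 or m.chrom != m5.chrom or m.strand != m5.strand:
            continue
        if downstream(m) and (nearest is None
                              or distance(m) < distance(nearest)):
            nearest = m
    return nearest is not None and nearest.gene_id == gene3


def annotate_readthrough(fusions: pd.DataFrame,
                         models: Mapping[str, TranscriptModel],
                         max_gap: int = 200_000) -> pd.DataFrame:
    """Add a boolean ``read_through`` column to consensus records."""
    out = fusions.copy()
    out["read_through"] = [
        is_readthrough(g5, g3, models, max_gap)
        for g5, g3 in zip(out["gene5"], out["gene3"])]
    return out


def classify_recurrence(
        consensus: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level recurrence of consensus fusions.

    Returns ``(pair_counts, per_sample)``: one row per gene pair with the
    number of distinct samples carrying it (``recurrent`` iff >= 2), and
    per-sample counts of private and recurrent fusions (each pair counted
    once per sample).
    """
    if consensus.empty:
        empty_pairs = pd.DataFrame(
            columns=["gene5", "gene3", "n_samples", "recurrent"])
        empty_samples = pd.DataFrame(
            columns=["sample", "private", "recurrent", "total"])
        return empty_pairs, empty_samples
    dedup = consensus.drop_duplicates(["sample", "gene5", "gene3"])
    pair_counts = (dedup.groupby(["gene5", "gene3"])["sample"].nunique()
                   .rename("n_samples").reset_index())
    pair_counts["recurrent"] = pair_counts["n_samples"] >= 2
    keyed = dedup.merge(pair_counts, on=["gene5", "gene3"])
    per_sample = (keyed.groupby("sample")["recurrent"]
                  .agg(private=lambda s: int((~s).sum()),
                       recurrent=lambda s: int(s.sum()))
                  .reset_index())
    per_sample["total"] = per_sample["private"] + per_sample["recurrent"]
    return (pair_counts.sort_values(["gene5", "gene3"]).reset_index(drop=True),
            per_sample.sort_values("sample").reset_index(drop=True))


def summarize_fusions_by_group(per_sample_totals: Mapping[str, int],
                               groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean (1 decimal), min and max of per-sample fusion totals per group
    label.  Every sample must be labelled."""
    unlabelled = [s for s in per_sample_totals if s not in groups]
    if unlabelled:
        raise DomainError(f"unlabelled samples: {unlabelled}")
    df = pd.DataFrame({
        "sample": list(per_sample_totals),
        "total": [per_sample_totals[s] for s in per_sample_totals],
        "group": [groups[s] for s in per_sample_totals],
    })
    rows = []
    for label, block in df.groupby("group", sort=True):
        rows.append({
            "group": label,
            "n_samples": len(block),
            "mean": round(float(block["total"].mean()), 1),
            "min": int(block["total"].min()),
            "max": int(block["total"].max()),
        })
    return pd.DataFrame(rows, columns=["group", "n_samples", "mean", "min",
                                       "max"])


def flag_partner_overexpression(fusions: pd.DataFrame,
                                expr: ExpressionMatrix,
                                min_fold: float = 2.0) -> pd.DataFrame:
    """Flag fusion partner genes overexpressed in the fusion's sample.

    A partner is flagged when its RPKM in that sample is at least
    ``min_fold`` times its mean RPKM across all samples.  Genes absent from
    the matrix are left unflagged with a warning.
    """
    if expr.value_kind != "rpkm":
        raise DomainError("partner overexpression requires an RPKM matrix")
    means = expr.values.mean(axis=1)
    out = fusions.copy()
    for end in ("5", "3"):
        fold = np.full(len(out), np.nan)
        flag = np.zeros(len(out), dtype=bool)
        for k, (gene, sample) in enumerate(zip(out[f"gene{end}"],
                                               out["sample"])):
            if gene not in expr.values.index:
                warnings.warn(f"gene {gene!r} absent from expression matrix; "
                              "left unflagged")
                continue
            mean = means[gene]
            value = expr.values.at[gene, sample]
            fold[k] = value / mean if mean > 0 else np.nan
            flag[k] = mean > 0 and value >= min_fold * mean
        out[f"fold_change{end}"] = fold
        out[f"overexpressed{end}"] = flag
    return out


def interchromosomal_counts(fusions: pd.DataFrame) -> pd.DataFrame:
    """Symmetric fusion counts per unordered chromosome pair, excluding
    read-through transcripts (a Circos-style table)."""
    sel = fusions
    if "read_through" in fusions.columns:
        sel = fusions[~fusions["read_through"].astype(bool)]
    if sel.empty:
        return pd.DataFrame(columns=["chrom_a", "chrom_b", "count"])
    pairs = [tuple(sorted((str(c5), str(c3))))
             for c5, c3 in zip(sel["chrom5"], sel["chrom3"])]
    counts = pd.Series(pairs).value_counts().sort_index()
    return pd.DataFrame(
        [{"chrom_a": a, "chrom_b": b, "count": int(n)}
         for (a, b), n in counts.items()],
        columns=["chrom_a", "chrom_b", "count"])
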