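"""Gene-level copy-number calling from exon-level log2 ratios.

Exon-level calls (an upstream exon-capture caller's output, or whole-genome
segments rasterized onto exons) are summarized per gene: when at least
``min_fraction`` of a gene's exons carry a significant call, the median log2
ratio of the significant exons decides gain (> ``gain_cut``), loss
(< ``loss_cut``) or, when significant exons sit on both sides of the cutoffs
without a decisive median, a mixed state.  Separate helpers detect
intragenic (strict-subset) exon deletions, summarize cross-sample
recurrence, call chromosome arms, and measure cross-platform concordance.
"""
from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DomainError
from .models import GeneCnaCall, TranscriptModel

EXON_COLUMNS = ["sample", "gene", "exon_index", "chrom", "start", "end",
                "log2_ratio", "significant"]


def round_half_up(x: float) -> int:
    """Percentage rounding to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5))


def call_gene_cna(exons: pd.DataFrame, gain_cut: float = 0.3,
                  loss_cut: float = -0.3,
                  min_fraction: float = 0.2) -> GeneCnaCall:
    """Call one sample-gene from its exon-level records.

    ``exons`` holds the rows of a single (sample, gene); order is
    irrelevant.  Below ``min_fraction`` significant exons the gene is
    neutral; otherwise the median log2 of the significant exons sets the
    state, and ``affected_exons`` lists the significant exons consistent
    with it.
    """
    if exons.empty:
        raise DomainError("call_gene_cna requires at least one exon")
    if not (gain_cut > 0 > loss_cut):
        raise DomainError("need gain_cut > 0 > loss_cut")
    if not (0 < min_fraction <= 1):
        raise DomainError("min_fraction must lie in (0, 1]")
    samples = exons["sample"].unique()
    genes = exons["gene"].unique()
    if len(samples) != 1 or len(genes) != 1:
        raise DomainError("call_gene_cna expects a single sample-gene block")
    exons = exons.sort_values("exon_index")
    sig = exons[exons["significant"].astype(bool)]
    fraction = len(sig) / len(exons)
    sample_id, gene_id = samples[0], genes[0]
    if fraction < min_fraction:
        return GeneCnaCall(sample_id, gene_id, "neutral", fraction, (), 0.0)
    summary = float(np.median(sig["log2_ratio"]))
    gain_side = sig[sig["log2_ratio"] > gain_cut]
    loss_side = sig[sig["log2_ratio"] < loss_cut]
    if summary > gain_cut:
        state, affected = "gain", gain_side
    elif summary < loss_cut:
        state, affected = "loss", loss_side
    elif len(gain_side) and len(loss_side):
        state = "mixed"
        affected = pd.concat([gain_side, loss_side]).sort_values("exon_index")
    else:
        return GeneCnaCall(sample_id, gene_id, "neutral", fraction, (), summary)
    return GeneCnaCall(sample_id, gene_id, state, fraction,
                       tuple(int(i) for i in affected["exon_index"]), summary)


def call_gene_cna_table(exon_calls: pd.DataFrame, gain_cut: float = 0.3,
                        loss_cut: float = -0.3,
                        min_fraction: float = 0.2) -> pd.DataFrame:
    """Apply :func:`call_gene_cna` to every (sample, gene) block."""
    rows = []
    for (sample, gene), block in exon_calls.groupby(["sample", "gene"],
                                                    sort=True):
        call = call_gene_cna(block, gain_cut, loss_cut, min_fraction)
        rows.append({
            "sample": sample, "gene": gene, "state": call.state,
            "significant_fraction": call.significant_fraction,
            "summary_log2": call.summary_log2,
            "affected_exons": ",".join(map(str, call.affected_exons)),
        })
    return pd.DataFrame(
        rows, columns=["sample", "gene", "state", "significant_fraction",
                       "summary_log2", "affected_exons"])


def detect_intragenic_deletion(exons: pd.DataFrame,
                               loss_cut: float = -0.3) -> list[int]:
    """Exon indices lost inside an otherwise retained gene.

    Returns the significantly lost exons only when they form a non-empty
    strict subset of the gene's exons — a whole-gene loss is not an
    intragenic deletion.
    """
    if exons.empty:
        return []
    lost = exons[exons["significant"].astype(bool)
                 & (exons["log2_ratio"] < loss_cut)]
    if lost.empty or len(lost) == len(exons):
        return []
    return sorted(int(i) for i in lost["exon_index"])


def recurrent_cna_summary(gene_calls: pd.DataFrame,
                          cohort_size: int | None = None) -> pd.DataFrame:
    """Per-gene, per-state sample counts with integer cohort percentages.

    One row per (gene, non-neutral state) with the number of distinct
    samples carrying it and ``percent = round(100 * n / cohort_size)``
    (half-up, reproducing e.g. 56% for 5 of 9 and 67% for 6 of 9).
    ``cohort_size`` defaults to the number of distinct samples in the input.
    """
    if cohort_size is None:
        cohort_size = gene_calls["sample"].nunique()
    if cohort_size < 1:
        raise DomainError("cohort_size must be >= 1")
    alt = gene_calls[gene_calls["state"] != "neutral"]
    if alt.empty:
        return pd.DataFrame(columns=["gene", "state", "n_samples", "percent"])
    counts = (alt.groupby(["gene", "state"])["sample"].nunique()
              .rename("n_samples").reset_index())
    counts["percent"] = [round_half_up(100.0 * n / cohort_size)
                         for n in counts["n_samples"]]
    return counts.sort_values(["gene", "state"]).reset_index(drop=True)


def platform_concordance(calls_a: pd.DataFrame,
                         calls_b: pd.DataFrame) -> float:
    """Percent of (sample, gene) keys whose state matches between two call
    sets (e.g. whole-genome vs exome calls on the same tumors)."""
    a = calls_a.set_index(["sample", "gene"])["state"]
    b = calls_b.set_index(["sample", "gene"])["state"]
    if set(a.index) != set(b.index):
        missing = sorted(set(a.index) ^ set(b.index))
        raise DomainError(f"call sets cover different keys: {missing[:5]}")
    if a.empty:
        raise DomainError("cannot compute concordance on empty call sets")
    b = b.reindex(a.index)
    return float(100.0 * (a == b).mean())


def rasterize_segments(segments: pd.DataFrame,
                       models: Mapping[str, TranscriptModel],
                       gain_cut: float = 0.3,
                       loss_cut: float = -0.3) -> pd.DataFrame:
    """Project SEG-style segments onto gene-model exons.

    Each exon receives the log2 ratio of the segment overlapping it most
    (in bp); exons with no overlapping segment get log2 0.  The significance
    flag of an exon-capture caller has no analogue in segment input, so an
    exon is marked significant when its assigned log2 ratio lies beyond
    either cutoff.  Output matches the exon-call table schema, giving
    whole-genome and exome inputs one downstream code path.
    """
    trees: dict[tuple, IntervalTree] = {}
    for _, seg in segments.iterrows():
        key = (seg["sample"], seg["chrom"])
        trees.setdefault(key, IntervalTree()).addi(
            int(seg["start"]), int(seg["end"]) + 1, float(seg["log2_ratio"]))
    rows = []
    samples = sorted(segments["sample"].unique())
    for sample in samples:
        for gene_id in sorted(models):
            m = models[gene_id]
            tree = trees.get((sample, m.chrom))
            for idx, (s, e) in enumerate(m.exons, start=1):
                log2 = 0.0
                if tree is not None:
                    hits = tree.overlap(s, e + 1)
                    if hits:
                        best = max(hits, key=lambda iv: min(iv.end - 1, e)
                                   - max(iv.begin, s))
                        log2 = best.data
                rows.append({
                    "sample": sample, "gene": gene_id, "exon_index": idx,
                    "chrom": m.chrom, "start": s, "end": e,
                    "log2_ratio": log2,
                    "significant": bool(log2 > gain_cut or log2 < loss_cut),
                })
    return pd.DataFrame(rows, columns=EXON_COLUMNS)


def call_arm_cna(segments: pd.DataFrame, arms: pd.DataFrame,
                 gain_cut: float = 0.3, loss_cut: float = -0.3,
                 min_cover: float = 0.5) -> pd.DataFrame:
    """Arm-level gain/loss calls from segments.

    ``arms`` carries (arm, chrom, start, end).  An arm is called when
    segments beyond a cutoff cover at least ``min_cover`` of its length;
    ties between gain and loss coverage resolve to the larger one.
    """
    rows = []
    for _, arm in arms.iterrows():
        arm_len = arm["end"] - arm["start"] + 1
        for sample, block in segments.groupby("sample"):
            sel = block[block["chrom"] == arm["chrom"]]
            cover = {"gain": 0, "loss": 0}
            for _, seg in sel.iterrows():
                ov = (min(seg["end"], arm["end"])
                      - max(seg["start"], arm["start"]) + 1)
                if ov <= 0:
                    continue
                if seg["log2_ratio"] > gain_cut:
                    cover["gain"] += ov
                elif seg["log2_ratio"] < loss_cut:
                    cover["loss"] += ov
            state = "neutral"
            best = max(cover, key=lambda s: cover[s])
            if cover[best] / arm_len >= min_cover:
                state = best
            rows.append({"sample": sample, "arm": arm["arm"], "state": state})
    return pd.DataFrame(rows, columns=["sample", "arm", "state"])
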