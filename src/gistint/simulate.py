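"""Seeded generators for every upstream input, with ground truth.

Each generator emulates the statistical structure of one upstream data
source — binomially sampled tumor/normal allele counts under a stated
purity and depth, exon-level log2 ratios with planted whole-gene and
single-exon events, two noisy fusion-caller outputs over a shared truth
list, and log-normal expression counts with planted outlier and
group-effect genes — and returns the simulated table together with a
:class:`SyntheticTruth` carrying per-record labels, the parameters, and the
seed.  Regenerating with the same seed and parameters is bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .fusions import is_readthrough
from .io import EXON_CNA_COLUMNS, FUSION_COLUMNS, SITE_COLUMNS
from .models import ExpressionMatrix, TranscriptModel

#: per-base sequencing error rate used for all count simulation
ERROR_RATE = 1e-3

#: sample ids of the default nine-tumor cohort layout
GIST9_SAMPLES = ("01", "02", "03", "04", "05", "07", "08", "09", "10")


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside a simulated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    site_labels: pd.DataFrame | None = None
    cna_events: pd.DataFrame | None = None
    fusion_truth: pd.DataFrame | None = None
    outlier_genes: pd.DataFrame | None = None
    group_effect_genes: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# gene models

_BASES = np.array(list("ACGT"))


def simulate_gene_model(n_genes: int = 40, min_exons: int = 3,
                        max_exons: int = 6, exon_length: int = 90,
                        intron_length: int = 300, intergenic_gap: int = 5000,
                        chrom: str = "chr1", seed: int = 0) -> dict:
    """A synthetic single-chromosome gene model with sequences.

    Genes are laid head to tail with a fixed intergenic gap (small enough
    that same-strand neighbours qualify as read-through partners), strands
    alternate pseudo-randomly, exon lengths are multiples of 3 and the CDS
    covers the full exon span, so every model supports consequence
    annotation.
    """
    if min_exons < 1 or max_exons < min_exons:
        raise DomainError("need 1 <= min_exons <= max_exons")
    rng = np.random.default_rng(seed)
    models: dict[str, TranscriptModel] = {}
    cursor = 1000
    for k in range(n_genes):
        gene_id = f"G{k + 1:03d}"
        n_ex = int(rng.integers(min_exons, max_exons + 1))
        exons = []
        pos = cursor
        for _ in range(n_ex):
            exons.append((pos, pos + exon_length - 1))
            pos += exon_length + intron_length
        strand = "+" if rng.random() < 0.5 else "-"
        span = exons[-1][1] - exons[0][0] + 1
        seq = "".join(rng.choice(_BASES, size=span))
        models[gene_id] = TranscriptModel(
            gene_id, chrom, strand, tuple(exons),
            cds_start=exons[0][0], cds_end=exons[-1][1], sequence=seq)
        cursor = exons[-1][1] + intergenic_gap
    return models


# ---------------------------------------------------------------------------
# tumor/normal allele counts

def simulate_tumor_normal_sites(n_sites: int = 1000, depth_mean: float = 100,
                                purity: float = 0.8,
                                somatic_fraction: float = 0.02,
                                germline_fraction: float = 0.3,
                                seed: int = 0, sample_id: str = "S1",
                                chrom: str = "chr1"
                                ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tumor/normal ref/alt counts at somatic, germline-het and reference
    sites.

    Somatic sites have true tumor VAF ``purity / 2`` (one mutant copy in a
    diploid tumor diluted by normal cells) and normal VAF equal to the
    sequencing error rate; germline heterozygotes have VAF 0.5 in both;
    reference sites have the error rate in both.  Depths are Poisson around
    ``depth_mean`` (floored at 1) and counts binomial.
    """
    for name, frac in (("somatic_fraction", somatic_fraction),
                       ("germline_fraction", germline_fraction)):
        if not 0 <= frac <= 1:
            raise DomainError(f"{name} must lie in [0, 1]")
    if somatic_fraction + germline_fraction > 1:
        raise DomainError("class fractions must sum to at most 1")
    if not 0 < purity <= 1:
        raise DomainError("purity must lie in (0, 1]")
    if depth_mean <= 0:
        raise DomainError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        ["somatic", "germline_het", "reference"], size=n_sites,
        p=[somatic_fraction, germline_fraction,
           1.0 - somatic_fraction - germline_fraction])
    vaf_t = np.where(classes == "somatic", purity / 2,
                     np.where(classes == "germline_het", 0.5, ERROR_RATE))
    vaf_n = np.where(classes == "germline_het", 0.5, ERROR_RATE)
    t_depth = np.maximum(rng.poisson(depth_mean, n_sites), 1)
    n_depth = np.maximum(rng.poisson(depth_mean, n_sites), 1)
    t_alt = rng.binomial(t_depth, vaf_t)
    n_alt = rng.binomial(n_depth, vaf_n)
    ref_base = rng.choice(_BASES, size=n_sites)
    alt_base = np.array([
        rng.choice([b for b in "ACGT" if b != r]) for r in ref_base])
    sites = pd.DataFrame({
        "sample": sample_id, "chrom": chrom,
        "pos": np.arange(1, n_sites + 1) * 100,
        "ref": ref_base, "alt": alt_base,
        "t_ref": t_depth - t_alt, "t_alt": t_alt,
        "n_ref": n_depth - n_alt, "n_alt": n_alt,
    }, columns=SITE_COLUMNS)
    truth = SyntheticTruth(
        seed=seed,
        params={"n_sites": n_sites, "depth_mean": depth_mean,
                "purity": purity, "somatic_fraction": somatic_fraction,
                "germline_fraction": germline_fraction,
                "error_rate": ERROR_RATE},
        site_labels=pd.DataFrame({"pos": sites["pos"], "label": classes}))
    return sites, truth


# ---------------------------------------------------------------------------
# exon-level copy number

def simulate_exon_cna(models: Mapping[str, TranscriptModel],
                      n_gain_genes: int = 5, n_loss_genes: int = 5,
                      n_single_exon_losses: int = 2,
                      effect_log2: float = 1.0, noise_sd: float = 0.15,
                      seed: int = 0, sample_id: str = "S1"
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Exon-level log2 ratios with planted whole-gene and single-exon events.

    Unaffected exons draw from ``Normal(0, noise_sd)``; event exons from
    ``Normal(+/-effect_log2, noise_sd)`` and are flagged significant.
    Single-exon losses (the intragenic-deletion scenario) pick one random
    exon of a gene with 3-5 exons, so one lost exon still clears the 20%
    significant-exon fraction downstream.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    n_events = n_gain_genes + n_loss_genes + n_single_exon_losses
    gene_ids = sorted(models)
    if n_events > len(gene_ids):
        raise DomainError("more events requested than genes available")
    rng = np.random.default_rng(seed)
    eligible_single = [g for g in gene_ids
                       if 3 <= models[g].n_exons <= 5]
    if n_single_exon_losses > len(eligible_single):
        raise DomainError("not enough 3-5 exon genes for single-exon losses")
    single_hosts = list(rng.choice(eligible_single,
                                   size=n_single_exon_losses, replace=False))
    remaining = [g for g in gene_ids if g not in set(single_hosts)]
    whole = list(rng.choice(remaining, size=n_gain_genes + n_loss_genes,
                            replace=False))
    gains, losses = whole[:n_gain_genes], whole[n_gain_genes:]
    events = {}
    for g in gains:
        events[g] = ("whole_gene_gain", effect_log2,
                     tuple(range(1, models[g].n_exons + 1)))
    for g in losses:
        events[g] = ("whole_gene_loss", -effect_log2,
                     tuple(range(1, models[g].n_exons + 1)))
    for g in single_hosts:
        exon = int(rng.integers(1, models[g].n_exons + 1))
        events[g] = ("single_exon_loss", -effect_log2, (exon,))
    rows = []
    for g in gene_ids:
        m = models[g]
        kind, effect, affected = events.get(g, (None, 0.0, ()))
        for idx, (s, e) in enumerate(m.exons, start=1):
            hit = idx in affected
            log2 = rng.normal(effect if hit else 0.0, noise_sd)
            rows.append({"sample": sample_id, "gene": g, "exon_index": idx,
                         "chrom": m.chrom, "start": s, "end": e,
                         "log2_ratio": log2, "significant": hit})
    truth_rows = [{"gene": g, "kind": kind,
                   "state": "gain" if "gain" in kind else "loss",
                   "affected_exons": ",".join(map(str, affected))}
                  for g, (kind, _, affected) in sorted(events.items())]
    truth = SyntheticTruth(
        seed=seed,
        params={"n_gain_genes": n_gain_genes, "n_loss_genes": n_loss_genes,
                "n_single_exon_losses": n_single_exon_losses,
                "effect_log2": effect_log2, "noise_sd": noise_sd},
        cna_events=pd.DataFrame(
            truth_rows, columns=["gene", "kind", "state", "affected_exons"]))
    return pd.DataFrame(rows, columns=EXON_CNA_COLUMNS), truth


# ---------------------------------------------------------------------------
# fusion call sets

def default_true_fusions(models: Mapping[str, TranscriptModel],
                         samples: Sequence[str] = GIST9_SAMPLES,
                         n_pairs: int = 8, n_readthrough: int = 2,
                         present_prob: float = 0.5,
                         seed: int = 0) -> pd.DataFrame:
    """A shared cohort truth list of fusion pairs.

    ``n_readthrough`` pairs are adjacent same-strand neighbours (true
    read-throughs); the rest are distant pairs.  Each pair is present in
    each sample with ``present_prob`` (at least one sample guaranteed).
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(models.values(), key=lambda m: m.span_start)
    rt_pairs = []
    for i, m in enumerate(ordered):
        for other in ordered[i + 1:]:
            if other.strand == m.strand:
                five, three = (m, other) if m.strand == "+" else (other, m)
                if is_readthrough(five.gene_id, three.gene_id, models):
                    rt_pairs.append((five.gene_id, three.gene_id))
                break
    if len(rt_pairs) < n_readthrough:
        raise DomainError("gene model offers too few adjacent same-strand "
                          "pairs for the requested read-throughs")
    chosen_rt = [rt_pairs[i] for i in
                 rng.choice(len(rt_pairs), size=n_readthrough, replace=False)]
    gene_ids = sorted(models)
    distant = []
    while len(distant) < n_pairs - n_readthrough:
        g5, g3 = rng.choice(gene_ids, size=2, replace=False)
        pair = (str(g5), str(g3))
        if pair not in distant and pair not in chosen_rt \
                and not is_readthrough(*pair, models):
            distant.append(pair)
    rows = []
    for g5, g3 in chosen_rt + distant:
        carriers = [s for s in samples if rng.random() < present_prob]
        if not carriers:
            carriers = [str(rng.choice(list(samples)))]
        for s in carriers:
            rows.append({"sample": s, "gene5": g5, "gene3": g3})
    return pd.DataFrame(rows, columns=["sample", "gene5", "gene3"])


def simulate_fusion_callsets(true_fusions: pd.DataFrame,
                             models: Mapping[str, TranscriptModel],
                             detect_prob_df: float = 0.9,
                             detect_prob_cs: float = 0.8,
                             fp_per_sample: int = 3,
                             support_range: tuple = (2, 30),
                             seed: int = 0
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        SyntheticTruth]:
    """Two noisy caller outputs over a shared truth list.

    Each true (sample, gene5, gene3) record is detected independently by
    each caller with its probability and receives spanning-pair support in
    ``support_range`` (junction reads >= 1).  Per-sample false positives
    draw random gene pairs with support deliberately below the default
    consensus thresholds.
    """
    for p in (detect_prob_df, detect_prob_cs):
        if not 0 <= p <= 1:
            raise DomainError("detection probabilities must lie in [0, 1]")
    if not models:
        raise DomainError("empty gene model")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(models)

    def record(sample, g5, g3, caller, spanning, junction):
        m5, m3 = models[g5], models[g3]
        return {
            "sample": sample, "caller": caller,
            "gene5": g5, "chrom5": m5.chrom, "strand5": m5.strand,
            "breakpoint5": m5.span_end if m5.strand == "+" else m5.span_start,
            "gene3": g3, "chrom3": m3.chrom, "strand3": m3.strand,
            "breakpoint3": m3.span_start if m3.strand == "+" else m3.span_end,
            "spanning_pairs": int(spanning), "junction_reads": int(junction),
        }

    df_rows, cs_rows, truth_rows = [], [], []
    lo, hi = support_range
    for _, r in true_fusions.iterrows():
        det_df = rng.random() < detect_prob_df
        det_cs = rng.random() < detect_prob_cs
        for detected, rows, caller in ((det_df, df_rows, "DF"),
                                       (det_cs, cs_rows, "CS")):
            if detected:
                spanning = rng.integers(lo, hi + 1)
                junction = rng.integers(1, max(2, hi // 3))
                rows.append(record(r["sample"], r["gene5"], r["gene3"],
                                   caller, spanning, junction))
        truth_rows.append({
            "sample": r["sample"], "gene5": r["gene5"], "gene3": r["gene3"],
            "read_through": is_readthrough(r["gene5"], r["gene3"], models),
            "detected_df": det_df, "detected_cs": det_cs,
        })
    samples = sorted(true_fusions["sample"].unique())
    truth_pairs = set(zip(true_fusions["gene5"], true_fusions["gene3"]))
    for sample in samples:
        for _ in range(fp_per_sample):
            while True:
                g5, g3 = (str(g) for g in
                          rng.choice(gene_ids, size=2, replace=False))
                if (g5, g3) not in truth_pairs:
                    break
            caller = "DF" if rng.random() < 0.5 else "CS"
            # below-threshold support: too few spanning pairs or no junction
            if rng.random() < 0.5:
                spanning, junction = rng.integers(0, 2), rng.integers(1, 4)
            else:
                spanning, junction = rng.integers(2, 6), 0
            (df_rows if caller == "DF" else cs_rows).append(
                record(sample, g5, g3, caller, spanning, junction))
    truth = SyntheticTruth(
        seed=seed,
        params={"detect_prob_df": detect_prob_df,
                "detect_prob_cs": detect_prob_cs,
                "fp_per_sample": fp_per_sample,
                "support_range": support_range},
        fusion_truth=pd.DataFrame(
            truth_rows, columns=["sample", "gene5", "gene3", "read_through",
                                 "detected_df", "detected_cs"]))
    return (pd.DataFrame(df_rows, columns=FUSION_COLUMNS),
            pd.DataFrame(cs_rows, columns=FUSION_COLUMNS), truth)


# ---------------------------------------------------------------------------
# expression counts

def simulate_expression_matrix(n_genes: int = 500,
                               samples: Sequence[str] = GIST9_SAMPLES,
                               n_outlier_genes: int = 10,
                               outlier_samples_per_gene: int = 2,
                               outlier_multiplier: float = 8.0,
                               groups: Mapping[str, str] | None = None,
                               n_group_effect_genes: int = 0,
                               group_log2_effect: float = 1.0,
                               up_label: str | None = None,
                               noise_sd: float = 0.3, seed: int = 0
                               ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-normal expression counts with planted outliers and group effects.

    Per-gene baseline rates are log-normal across genes; per-observation
    rates get multiplicative log-normal noise (``noise_sd`` on the natural
    log scale) and Poisson sampling.  Planted outlier genes are multiplied
    by ``outlier_multiplier`` in a random subset of samples; group-effect
    genes by ``2**group_log2_effect`` in samples labelled ``up_label``.
    Gene lengths and library sizes (column sums) are emitted for RPKM.
    """
    samples = [str(s) for s in samples]
    if n_outlier_genes > n_genes:
        raise DomainError("more outlier genes than genes")
    if outlier_samples_per_gene >= len(samples):
        raise DomainError("outlier sample subset must be a proper subset")
    if n_group_effect_genes:
        if groups is None or up_label is None:
            raise DomainError("group effects need groups and up_label")
        missing = [s for s in samples if s not in groups]
        if missing:
            raise DomainError(f"unlabelled samples: {missing}")
        if up_label not in set(groups.values()):
            raise DomainError(f"no sample carries label {up_label!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{k + 1:04d}" for k in range(n_genes)]
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    rate = np.outer(base, np.ones(len(samples)))
    chosen = rng.choice(n_genes, size=n_outlier_genes + n_group_effect_genes,
                        replace=False)
    outlier_idx = chosen[:n_outlier_genes]
    group_idx = chosen[n_outlier_genes:]
    outlier_rows = []
    for gi in outlier_idx:
        cols = rng.choice(len(samples), size=outlier_samples_per_gene,
                          replace=False)
        rate[gi, cols] *= outlier_multiplier
        outlier_rows.append({
            "gene": gene_ids[gi],
            "outlier_samples": ",".join(samples[c] for c in sorted(cols))})
    group_rows = []
    for gi in group_idx:
        cols = [k for k, s in enumerate(samples) if groups[s] == up_label]
        rate[gi, cols] *= 2.0 ** group_log2_effect
        group_rows.append({"gene": gene_ids[gi], "up_label": up_label,
                           "log2_effect": group_log2_effect})
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=rate.shape)
    counts = rng.poisson(rate * noise).astype(float)
    values = pd.DataFrame(counts, index=gene_ids, columns=samples)
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes),
                        index=gene_ids)
    libsizes = values.sum(axis=0).clip(lower=1).astype(int)
    expr = ExpressionMatrix(values, "counts", gene_lengths=lengths,
                            library_sizes=libsizes)
    truth = SyntheticTruth(
        seed=seed,
        params={"n_genes": n_genes, "n_outlier_genes": n_outlier_genes,
                "outlier_samples_per_gene": outlier_samples_per_gene,
                "outlier_multiplier": outlier_multiplier,
                "n_group_effect_genes": n_group_effect_genes,
                "group_log2_effect": group_log2_effect,
                "noise_sd": noise_sd},
        outlier_genes=pd.DataFrame(
            outlier_rows, columns=["gene", "outlier_samples"]),
        group_effect_genes=pd.DataFrame(
            group_rows, columns=["gene", "up_label", "log2_effect"]))
    return expr, truth
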