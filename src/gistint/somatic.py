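"""Tumor/normal somatic variant analysis.

The core test models the latent tumor and normal variant allele fractions
(VAFs) with independent beta posteriors under uniform Beta(1,1) priors,

    p_T ~ Beta(t_alt + 1, t_ref + 1),   p_N ~ Beta(n_alt + 1, n_ref + 1),

and reports the posterior probability ``P(p_T > p_N)``.  A site is called
somatic when that probability clears a threshold and the observed normal VAF
is low enough to exclude germline heterozygotes.  Downstream helpers classify
coding consequences against a transcript model, tabulate the six-class
substitution spectrum, find recurrently mutated genes, and check expression
support in an RPKM matrix.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import betaln
from Bio.Seq import Seq

from .errors import ConfigurationError, DomainError
from .models import (PROTEIN_ALTERING, SPECTRUM_CLASSES, ExpressionMatrix,
                     TranscriptModel)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def vaf_posterior_diff(t_alt: int, t_ref: int, n_alt: int, n_ref: int) -> float:
    """Posterior probability that the tumor VAF exceeds the normal VAF.

    Evaluates ``P(p_T > p_N)`` for ``p_T ~ Beta(t_alt+1, t_ref+1)`` and
    ``p_N ~ Beta(n_alt+1, n_ref+1)`` using the exact finite-series form of
    the beta-beta exceedance probability (valid for the integer shape
    parameters read counts produce).  Symmetric inputs return exactly 0.5.

    Raises
    ------
    DomainError
        If either sample has zero total depth or any count is negative.
    """
    counts = (t_alt, t_ref, n_alt, n_ref)
    if any(c < 0 for c in counts):
        raise DomainError(f"negative read count in {counts}")
    if t_alt + t_ref == 0 or n_alt + n_ref == 0:
        raise DomainError("zero total depth in tumor or normal sample")
    a_t, b_t = t_alt + 1, t_ref + 1
    a_n, b_n = n_alt + 1, n_ref + 1
    if (a_t, b_t) == (a_n, b_n):
        return 0.5
    # P(p_T > p_N) = sum_{i=0}^{a_T-1} B(a_N+i, b_N+b_T) /
    #                [(b_T+i) B(1+i, b_T) B(a_N, b_N)]
    i = np.arange(a_t)
    log_terms = (
        betaln(a_n + i, b_n + b_t)
        - np.log(b_t + i)
        - betaln(1 + i, b_t)
        - betaln(a_n, b_n)
    )
    p = float(np.exp(log_terms).sum())
    return min(max(p, 0.0), 1.0)


def call_somatic_sites(sites: pd.DataFrame, p_threshold: float = 0.99,
                       max_normal_vaf: float = 0.03) -> pd.DataFrame:
    """Score every site and flag the somatic ones.

    ``sites`` must carry columns ``sample, chrom, pos, ref, alt, t_ref,
    t_alt, n_ref, n_alt``.  Returns a copy with ``p_diff``, ``normal_vaf``
    and ``somatic`` columns; all sites are returned, flagged or not.  A site
    is somatic iff ``p_diff >= p_threshold`` and
    ``n_alt/(n_alt+n_ref) <= max_normal_vaf``.
    """
    for name, value in (("p_threshold", p_threshold),
                        ("max_normal_vaf", max_normal_vaf)):
        if not 0 < value < 1:
            raise DomainError(f"{name} must lie in (0, 1), got {value}")
    out = sites.copy()
    # identical posteriors are common (e.g. 0/DP vs 0/DP): cache by count tuple
    cache: dict[tuple, float] = {}
    p_diff = np.empty(len(out))
    for k, (ta, tr, na, nr) in enumerate(
            zip(out["t_alt"], out["t_ref"], out["n_alt"], out["n_ref"])):
        key = (ta, tr, na, nr)
        if key not in cache:
            cache[key] = vaf_posterior_diff(ta, tr, na, nr)
        p_diff[k] = cache[key]
    out["p_diff"] = p_diff
    out["normal_vaf"] = out["n_alt"] / (out["n_alt"] + out["n_ref"])
    out["somatic"] = (out["p_diff"] >= p_threshold) & (
        out["normal_vaf"] <= max_normal_vaf)
    return out


def _splice_site_hit(pos: int, model: TranscriptModel, window: int = 2) -> bool:
    """True when ``pos`` lies within ``window`` bp of an internal exon
    boundary on the intron side."""
    for idx, (s, e) in enumerate(model.exons):
        if idx > 0 and s - window <= pos <= s - 1:
            return True
        if idx < model.n_exons - 1 and e + 1 <= pos <= e + window:
            return True
    return False


def annotate_consequence(chrom: str, pos: int, ref: str, alt: str,
                         model: TranscriptModel,
                         splice_window: int = 2) -> str:
    """Classify a variant against one transcript model.

    Rules, in order: any indel inside the CDS is ``indel``; an SNV within
    ``splice_window`` intronic bases of an internal exon boundary is
    ``splice_site``; a CDS SNV is translated through the spliced reading
    frame (minus-strand models on the reverse complement) and classified as
    ``synonymous``/``missense``/``nonsense``/``stop_loss``; anything else in
    the model span is ``noncoding``.  The reference codon is taken from the
    transcript sequence, so a ``ref`` that disagrees with the model sequence
    is classified relative to the model.
    """
    if chrom != model.chrom or not (model.span_start <= pos <= model.span_end):
        raise DomainError(
            f"site {chrom}:{pos} outside span of {model.gene_id}")
    if model.sequence is None:
        raise ConfigurationError(
            f"{model.gene_id}: consequence annotation requires a sequence")
    is_indel = len(ref) != len(alt) or len(ref) > 1
    cds_pos = model.cds_genomic_positions()
    in_cds = cds_pos.size and pos in cds_pos
    if is_indel:
        if in_cds:
            return "indel"
        if _splice_site_hit(pos, model, splice_window):
            return "splice_site"
        return "noncoding"
    if _splice_site_hit(pos, model, splice_window):
        return "splice_site"
    if not in_cds:
        return "noncoding"
    # spliced CDS in transcription orientation
    cds_seq = "".join(model.base_at(p) for p in cds_pos)
    idx = int(np.searchsorted(cds_pos, pos))
    alt_base = alt
    if model.strand == "-":
        cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
        idx = len(cds_pos) - 1 - idx
        alt_base = alt.translate(_COMPLEMENT)
    frame = idx // 3
    ref_codon = cds_seq[3 * frame:3 * frame + 3]
    offset = idx - 3 * frame
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    if aa_ref == "*":
        return "stop_loss"
    return "missense"


def annotate_calls(calls: pd.DataFrame,
                   models: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    """Attach ``gene_id`` and ``consequence`` columns wherever a transcript
    model covers the site; uncovered sites keep missing values."""
    out = calls.copy()
    out["gene_id"] = pd.NA
    out["consequence"] = pd.NA
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models.values():
        by_chrom.setdefault(m.chrom, []).append(m)
    for k, row in out.iterrows():
        for m in by_chrom.get(row["chrom"], ()):
            if m.span_start <= row["pos"] <= m.span_end:
                out.at[k, "gene_id"] = m.gene_id
                out.at[k, "consequence"] = annotate_consequence(
                    row["chrom"], int(row["pos"]), row["ref"], row["alt"], m)
                break
    return out


def _is_snv(ref: str, alt: str) -> bool:
    return (len(ref) == 1 and len(alt) == 1 and ref != alt
            and ref in "ACGT" and alt in "ACGT")


def mutation_spectrum(calls: pd.DataFrame) -> pd.Series:
    """Six-class strand-collapsed substitution spectrum.

    Purine-reference substitutions are mapped to the complementary
    pyrimidine class, so e.g. G>A counts as C>T/G>A.  Non-SNV records are
    ignored; the class counts sum to the number of SNVs.
    """
    counts = pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=int)
    for ref, alt in zip(calls["ref"], calls["alt"]):
        if not _is_snv(ref, alt):
            continue
        r, a = ref, alt
        if r in "AG":
            r, a = r.translate(_COMPLEMENT), a.translate(_COMPLEMENT)
        for cls in SPECTRUM_CLASSES:
            if cls.startswith(f"{r}>{a}"):
                counts[cls] += 1
                break
    return counts


def recurrent_mutated_genes(calls: pd.DataFrame,
                            min_samples: int = 2) -> pd.Series:
    """Genes with protein-altering calls in at least ``min_samples`` distinct
    samples, with their sample counts.

    Only missense, nonsense, stop-loss, splice-site and indel calls count;
    a gene is counted once per sample regardless of multiplicity.
    """
    if min_samples < 2:
        raise DomainError("min_samples must be >= 2")
    altering = calls[calls["consequence"].isin(PROTEIN_ALTERING)
                     & calls["gene_id"].notna()]
    if altering.empty:
        return pd.Series(dtype=int)
    per_gene = altering.groupby("gene_id")["sample"].nunique()
    per_gene = per_gene[per_gene >= min_samples].astype(int)
    return per_gene.sort_values(ascending=False)


def expression_support(calls: pd.DataFrame, expr: ExpressionMatrix,
                       rpkm_min: float = 1.0) -> tuple[pd.DataFrame, float]:
    """Flag calls whose gene is expressed (RPKM >= ``rpkm_min``, inclusive)
    in the call's sample.

    Returns the calls with ``covered`` (gene and sample present in the
    matrix) and ``expressed`` columns, plus the expressed fraction among
    covered calls (NaN when nothing is covered).
    """
    if expr.value_kind != "rpkm":
        raise DomainError("expression_support requires an RPKM matrix")
    out = calls.copy()
    covered = np.zeros(len(out), dtype=bool)
    expressed = np.zeros(len(out), dtype=bool)
    for k, (gene, sample) in enumerate(zip(out["gene_id"], out["sample"])):
        if pd.isna(gene) or gene not in expr.values.index \
                or sample not in expr.values.columns:
            continue
        covered[k] = True
        expressed[k] = expr.values.at[gene, sample] >= rpkm_min
    out["covered"] = covered
    out["expressed"] = expressed
    fraction = float(expressed[covered].mean()) if covered.any() else float("nan")
    return out, fraction
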