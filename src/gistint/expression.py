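"""RPKM normalization, outlier-sum statistics, CNA integration and
fold-change differential expression.

The outlier-sum (OS) statistic targets genes with generally low expression
but marked overexpression in a fraction of samples: values are robustly
standardized with the median and the median absolute deviation (MAD), and
the statistic sums the standardized values of samples exceeding the 75th
percentile plus one interquartile range.  The one-group form is used here
(the cohort has no normal-tissue expression arm).
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .models import ExpressionMatrix, OutlierResult

#: ratio of the IQR of a normal distribution to its standard deviation,
#: used to put the IQR fallback on the MAD-free scale
IQR_TO_SD = 1.349


def compute_rpkm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = counts[g, s] * 1e9 / (library_size[s] * gene_length[g])``
    """
    if expr.value_kind != "counts":
        raise DomainError("compute_rpkm requires a counts matrix")
    lengths = expr.gene_lengths.astype(float)
    libs = expr.library_sizes.astype(float)
    if (lengths <= 0).any() or (libs <= 0).any():
        raise DomainError("gene lengths and library sizes must be positive")
    rpkm = expr.values.mul(1e9).div(libs, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(rpkm, "rpkm", gene_lengths=expr.gene_lengths,
                            library_sizes=expr.library_sizes)


def outlier_sum(values: Sequence[float], sample_ids: Sequence[str] | None = None,
                gene_id: str = "") -> OutlierResult:
    """Outlier-sum statistic for one gene's expression vector.

    Values are standardized as ``(x - median) / MAD``; samples whose
    standardized value exceeds ``q75 + IQR`` of the standardized vector
    (quantiles by linear interpolation) are outliers, and OS is the sum of
    their standardized values.  When the MAD is zero the scale falls back
    to ``IQR / 1.349``; when every scale is zero the vector is degenerate
    and OS is 0 with no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DomainError("outlier_sum requires at least 4 samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(x.size)]
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    fallback = False
    scale = mad
    if scale == 0:
        q75, q25 = np.percentile(x, [75, 25])
        scale = (q75 - q25) / IQR_TO_SD
        fallback = True
    if scale == 0:
        return OutlierResult(gene_id, 0.0, (), scale_fallback_used=True)
    z = (x - med) / scale
    zq75, zq25 = np.percentile(z, [75, 25])
    cutoff = zq75 + (zq75 - zq25)
    mask = z > cutoff
    if not mask.any():
        return OutlierResult(gene_id, 0.0, (), scale_fallback_used=fallback)
    return OutlierResult(
        gene_id, float(z[mask].sum()),
        tuple(s for s, m in zip(sample_ids, mask) if m),
        scale_fallback_used=fallback)


def cohort_outliers(expr: ExpressionMatrix,
                    log_transform: bool = True) -> list[OutlierResult]:
    """Outlier-sum results for every gene of an RPKM matrix.

    By default the statistic is computed on ``log2(rpkm + 1)``, the scale on
    which expression noise is approximately symmetric; the outlier sample
    set is unaffected by monotone per-gene rescaling only in the affine
    case, so the transform is part of the documented default.
    """
    if expr.value_kind != "rpkm":
        raise DomainError("cohort_outliers requires an RPKM matrix")
    mat = np.log2(expr.values + 1.0) if log_transform else expr.values
    return [outlier_sum(mat.loc[g], expr.sample_ids, gene_id=g)
            for g in mat.index]


def outlier_table(results: Iterable[OutlierResult]) -> pd.DataFrame:
    rows = [{"gene": r.gene_id, "os_statistic": r.os_statistic,
             "outlier_samples": ",".join(r.outlier_samples),
             "scale_fallback_used": r.scale_fallback_used}
            for r in results]
    return pd.DataFrame(rows, columns=["gene", "os_statistic",
                                       "outlier_samples",
                                       "scale_fallback_used"])


def integrate_outliers_with_cna(outliers: Iterable[OutlierResult],
                                gene_calls: pd.DataFrame) -> pd.DataFrame:
    """Genes whose outlier samples coincide with copy-number gain.

    For each outlier gene, reports the samples that are both expression
    outliers and carry a gain call for the same gene; genes with an empty
    intersection are dropped.
    """
    gains = gene_calls[gene_calls["state"] == "gain"]
    gain_samples = gains.groupby("gene")["sample"].agg(set).to_dict()
    rows = []
    for r in outliers:
        support = sorted(set(r.outlier_samples) & gain_samples.get(r.gene_id,
                                                                   set()))
        if support:
            rows.append({"gene": r.gene_id, "os_statistic": r.os_statistic,
                         "supporting_samples": ",".join(support)})
    return pd.DataFrame(rows, columns=["gene", "os_statistic",
                                       "supporting_samples"])


def fold_change_de(expr: ExpressionMatrix, group_a: Iterable[str],
                   group_b: Iterable[str], min_fc: float = 2.0,
                   pseudocount: float = 0.1) -> pd.DataFrame:
    """Pseudocount-guarded fold-change filter between two sample groups.

    ``fc = (mean_a + pseudocount) / (mean_b + pseudocount)``; a gene is
    selected when ``fc >= min_fc`` or ``fc <= 1/min_fc``, with ``direction``
    ``up_a``/``up_b`` accordingly.  Swapping the groups maps fc to 1/fc and
    preserves the selected set.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise DomainError("both groups must be non-empty")
    if a & b:
        raise DomainError(f"groups overlap: {sorted(a & b)}")
    missing = (a | b) - set(expr.sample_ids)
    if missing:
        raise DomainError(f"samples absent from matrix: {sorted(missing)}")
    if min_fc <= 1:
        raise DomainError("min_fc must exceed 1")
    mean_a = expr.values[sorted(a)].mean(axis=1)
    mean_b = expr.values[sorted(b)].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    selected = (fc >= min_fc) | (fc <= 1.0 / min_fc)
    direction = np.where(fc >= min_fc, "up_a",
                         np.where(fc <= 1.0 / min_fc, "up_b", "none"))
    return pd.DataFrame({"gene": expr.gene_ids, "fc": fc.values,
                         "direction": direction, "selected": selected.values})
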