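"""Shared domain types.

All genomic coordinates are 1-based inclusive (VCF/GTF convention) once data
has been ingested; BED-style half-open inputs are converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ValidationError


class Location(str, Enum):
    gastric = "gastric"
    small_intestine = "small_intestine"


class Genotype(str, Enum):
    wild_type = "wild_type"
    KIT_mutant = "KIT_mutant"
    PDGFRA_mutant = "PDGFRA_mutant"


class Risk(str, Enum):
    low = "low"
    high = "high"


class RecurrenceStatus(str, Enum):
    primary = "primary"
    recurrent = "recurrent"


#: protein-altering consequence classes used for recurrence filtering
PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "stop_loss", "splice_site", "indel"}
)

#: the six strand-collapsed single-nucleotide substitution classes
SPECTRUM_CLASSES = (
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)


@dataclass(frozen=True)
class SampleInfo:
    """Clinicopathologic descriptors of one tumor sample."""

    sample_id: str
    location: Location
    genotype: Genotype
    risk: Risk
    recurrence_status: RecurrenceStatus = RecurrenceStatus.primary

    @property
    def group(self) -> str:
        """Analysis stratum: wild-type tumors form one group regardless of
        site; mutants are split by anatomic location."""
        if self.genotype is Genotype.wild_type:
            return "wild_type"
        if self.location is Location.small_intestine:
            return "small_intestine"
        return "gastric_kit_mutant"


@dataclass
class TranscriptModel:
    """A single-transcript gene model on genomic coordinates.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals sorted by
    start and non-overlapping.  ``sequence``, when present, is the plus-strand
    genomic sequence spanning ``span_start..span_end`` (introns included), so
    position ``p`` maps to ``sequence[p - span_start]``.  The CDS interval,
    when present, must lie within the exon union and have spliced length
    divisible by 3 whenever a sequence is attached.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int | None = None
    cds_end: int | None = None
    sequence: str | None = None

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        last_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s <= last_end:
                raise ValidationError(
                    f"{self.gene_id}: exons unsorted or overlapping at {s}-{e}"
                )
            last_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.gene_id}: partial CDS interval")
        if self.cds_start is not None:
            if not (self.span_start <= self.cds_start <= self.cds_end <= self.span_end):
                raise ValidationError(f"{self.gene_id}: CDS outside exon span")
            if not self._pos_in_exon(self.cds_start) or not self._pos_in_exon(self.cds_end):
                raise ValidationError(f"{self.gene_id}: CDS boundary not exonic")
        if self.sequence is not None:
            if len(self.sequence) != self.span_end - self.span_start + 1:
                raise ValidationError(
                    f"{self.gene_id}: sequence length {len(self.sequence)} does not "
                    f"match span {self.span_end - self.span_start + 1}"
                )
            if self.cds_start is not None and len(self.cds_genomic_positions()) % 3:
                raise ValidationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def span_start(self) -> int:
        return self.exons[0][0]

    @property
    def span_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def _pos_in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def base_at(self, pos: int) -> str:
        if self.sequence is None:
            raise ValidationError(f"{self.gene_id}: no sequence attached")
        return self.sequence[pos - self.span_start]

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions inside the CDS, ascending (plus-strand order)."""
        if self.cds_start is None:
            return np.empty(0, dtype=int)
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append(np.arange(lo, hi + 1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    set_id: str
    description: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


class ExpressionMatrix:
    """Gene-by-sample expression values with the metadata RPKM needs.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    When ``value_kind == 'counts'`` both ``gene_lengths`` (bp) and
    ``library_sizes`` (mapped reads) must be present and positive.
    """

    def __init__(self, values: pd.DataFrame, value_kind: str,
                 gene_lengths: pd.Series | None = None,
                 library_sizes: pd.Series | None = None):
        if value_kind not in ("counts", "rpkm"):
            raise ValidationError(f"unknown value_kind {value_kind!r}")
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample ids")
        if value_kind == "counts":
            if gene_lengths is None or library_sizes is None:
                raise ValidationError(
                    "counts matrices require gene_lengths and library_sizes"
                )
        if gene_lengths is not None:
            gene_lengths = gene_lengths.reindex(values.index)
            if gene_lengths.isna().any():
                missing = list(gene_lengths.index[gene_lengths.isna()][:3])
                raise ValidationError(f"gene_lengths missing for {missing}")
            if (gene_lengths <= 0).any():
                raise ValidationError("gene_lengths must be positive")
            gene_lengths = gene_lengths.astype(int)
        if library_sizes is not None:
            library_sizes = library_sizes.reindex(values.columns)
            if library_sizes.isna().any():
                missing = list(library_sizes.index[library_sizes.isna()][:3])
                raise ValidationError(f"library_sizes missing for {missing}")
            if (library_sizes <= 0).any():
                raise ValidationError("library_sizes must be positive")
            library_sizes = library_sizes.astype(int)
        self.values = values
        self.value_kind = value_kind
        self.gene_lengths = gene_lengths
        self.library_sizes = library_sizes

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def __repr__(self):
        return (f"ExpressionMatrix({len(self.gene_ids)} genes x "
                f"{len(self.sample_ids)} samples, {self.value_kind})")

    def __eq__(self, other):
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        same_meta = (
            (self.gene_lengths is None) == (other.gene_lengths is None)
            and (self.library_sizes is None) == (other.library_sizes is None)
        )
        if not same_meta or self.value_kind != other.value_kind:
            return False
        if not np.allclose(self.values, other.values.reindex(
                index=self.values.index, columns=self.values.columns)):
            return False
        if self.gene_lengths is not None and not self.gene_lengths.equals(
                other.gene_lengths.reindex(self.gene_lengths.index)):
            return False
        if self.library_sizes is not None and not self.library_sizes.equals(
                other.library_sizes.reindex(self.library_sizes.index)):
            return False
        return True


@dataclass
class GeneCnaCall:
    """Gene-level copy-number state derived from exon-level calls."""

    sample_id: str
    gene_id: str
    state: str                      # gain | loss | neutral | mixed
    significant_fraction: float
    affected_exons: tuple
    summary_log2: float

    def __post_init__(self):
        if self.state not in ("gain", "loss", "neutral", "mixed"):
            raise ValidationError(f"unknown CNA state {self.state!r}")
        if self.state == "neutral" and self.affected_exons:
            raise ValidationError("neutral call cannot list affected exons")


@dataclass
class OutlierResult:
    """Outlier-sum result for one gene across a cohort."""

    gene_id: str
    os_statistic: float
    outlier_samples: tuple
    scale_fallback_used: bool = False

    def __post_init__(self):
        if (self.os_statistic == 0) != (len(self.outlier_samples) == 0):
            raise ValidationError(
                "os_statistic must be zero exactly when no outliers are flagged"
            )
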