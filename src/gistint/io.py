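"""Readers and writers for every tabular dialect the pipeline touches.

All coordinates are 1-based inclusive after ingestion; BED-style inputs are
converted on read.  Writers emit deterministic column order and sort rows by
the table's primary key, so writing the same collection twice is
byte-identical and ``read(write(x)) == x``.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ValidationError
from .models import (ExpressionMatrix, GeneSet, Genotype, Location,
                     RecurrenceStatus, Risk, SampleInfo, TranscriptModel)

SITE_COLUMNS = ["sample", "chrom", "pos", "ref", "alt",
                "t_ref", "t_alt", "n_ref", "n_alt"]
EXON_CNA_COLUMNS = ["sample", "gene", "exon_index", "chrom", "start", "end",
                    "log2_ratio", "significant"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]
FUSION_COLUMNS = ["sample", "caller", "gene5", "chrom5", "strand5",
                  "breakpoint5", "gene3", "chrom3", "strand3", "breakpoint3",
                  "spanning_pairs", "junction_reads"]
SAMPLE_COLUMNS = ["sample", "location", "genotype", "risk",
                  "recurrence_status"]

_PRIMARY_KEYS = {
    "sites": ["sample", "chrom", "pos", "ref", "alt"],
    "exon_cna": ["sample", "gene", "exon_index"],
    "segments": ["sample", "chrom", "start", "end"],
    "fusions": ["sample", "caller", "gene5", "gene3"],
    "sample_info": ["sample"],
}
_SCHEMAS = {
    "sites": (SITE_COLUMNS,
              {"pos": int, "t_ref": int, "t_alt": int,
               "n_ref": int, "n_alt": int}),
    "exon_cna": (EXON_CNA_COLUMNS,
                 {"exon_index": int, "start": int, "end": int,
                  "log2_ratio": float, "significant": bool}),
    "segments": (SEGMENT_COLUMNS,
                 {"start": int, "end": int, "log2_ratio": float}),
    "fusions": (FUSION_COLUMNS,
                {"breakpoint5": int, "breakpoint3": int,
                 "spanning_pairs": int, "junction_reads": int}),
    "sample_info": (SAMPLE_COLUMNS, {}),
}

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _read_typed_tsv(path, columns, dtypes) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(path, 1, "file has no header")
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    raw = raw[columns]
    out = {}
    for col in columns:
        kind = dtypes.get(col, str)
        series = raw[col]
        if kind is str:
            out[col] = series
            continue
        if kind is bool:
            vals = []
            for idx, v in enumerate(series):
                token = v.strip().lower()
                if token in _TRUE:
                    vals.append(True)
                elif token in _FALSE:
                    vals.append(False)
                else:
                    raise ParseError(path, idx + 2,
                                     f"non-boolean value {v!r} in {col!r}")
            out[col] = pd.Series(vals, dtype=bool)
            continue
        coerced = pd.to_numeric(series.str.strip(), errors="coerce")
        bad = coerced.isna()
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ParseError(path, idx + 2,
                             f"non-numeric value {series.iloc[idx]!r} "
                             f"in {col!r}")
        if kind is int:
            if not (coerced == coerced.round()).all():
                idx = int(np.flatnonzero(coerced != coerced.round())[0])
                raise ParseError(path, idx + 2,
                                 f"non-integer value in {col!r}")
            coerced = coerced.astype(int)
        out[col] = coerced
    return pd.DataFrame(out, columns=columns)


def _validate(kind: str, df: pd.DataFrame) -> pd.DataFrame:
    if kind == "sites":
        for col in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if (df[col] < 0).any():
                raise ValidationError(f"negative counts in {col}")
        bad = df[df["ref"] == df["alt"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"ref == alt at {r['sample']} {r['chrom']}:{r['pos']}")
        depth0 = df[(df["t_ref"] + df["t_alt"] == 0)
                    | (df["n_ref"] + df["n_alt"] == 0)]
        if len(depth0):
            r = depth0.iloc[0]
            raise ValidationError(
                f"zero depth at {r['sample']} {r['chrom']}:{r['pos']}")
    elif kind == "exon_cna":
        if not np.isfinite(df["log2_ratio"]).all():
            raise ValidationError("non-finite log2_ratio")
        dup = df.duplicated(["sample", "gene", "exon_index"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate exon_index {r['exon_index']} for "
                f"{r['sample']}/{r['gene']}")
    elif kind == "fusions":
        same = df[df["gene5"] == df["gene3"]]
        if len(same):
            raise ValidationError(
                f"gene5 == gene3 for {same.iloc[0]['gene5']!r}")
        for col in ("spanning_pairs", "junction_reads"):
            if (df[col] < 0).any():
                raise ValidationError(f"negative counts in {col}")
    elif kind == "sample_info":
        if df["sample"].duplicated().any():
            dup = df[df["sample"].duplicated()].iloc[0]["sample"]
            raise ValidationError(f"duplicate sample id {dup!r}")
        enums = {"location": Location, "genotype": Genotype, "risk": Risk,
                 "recurrence_status": RecurrenceStatus}
        for col, enum in enums.items():
            allowed = {e.value for e in enum}
            bad = df[~df[col].isin(allowed)]
            if len(bad):
                raise ValidationError(
                    f"sample {bad.iloc[0]['sample']!r}: {col} "
                    f"{bad.iloc[0][col]!r} not in {sorted(allowed)}")
    return df


def read_inputs(path, kind: str):
    """Read one input file of the given dialect into its typed collection.

    ``kind`` is one of ``sites, exon_cna, segments, fusions, expression,
    gene_model, gene_sets, sample_info``.
    """
    if kind in _SCHEMAS:
        columns, dtypes = _SCHEMAS[kind]
        return _validate(kind, _read_typed_tsv(path, columns, dtypes))
    if kind == "expression":
        return read_expression(path)
    if kind == "gene_model":
        return read_gene_model(path)
    if kind == "gene_sets":
        return read_gene_sets(path)
    raise DomainError(f"unknown input kind {kind!r}")


def write_outputs(collection, path, kind: str | None = None):
    """Write a typed collection losslessly; see module docstring for the
    determinism contract."""
    if isinstance(collection, ExpressionMatrix):
        return write_expression(collection, path)
    if isinstance(collection, Mapping) and collection and all(
            isinstance(v, TranscriptModel) for v in collection.values()):
        return write_gene_model(collection, path)
    if isinstance(collection, (list, tuple)) and collection and all(
            isinstance(v, GeneSet) for v in collection):
        return write_gene_sets(collection, path)
    if not isinstance(collection, pd.DataFrame):
        raise DomainError(f"cannot write {type(collection).__name__}")
    if kind is None:
        kind = _infer_kind(collection)
    columns, _ = _SCHEMAS[kind]
    df = collection[columns].sort_values(_PRIMARY_KEYS[kind],
                                         kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
    return path


def _infer_kind(df: pd.DataFrame) -> str:
    for kind, (columns, _) in _SCHEMAS.items():
        if set(columns) <= set(df.columns):
            return kind
    raise DomainError("cannot infer table kind from columns "
                      f"{list(df.columns)}")


# ---------------------------------------------------------------------------
# expression matrix + sidecar

def read_expression(path, sidecar=None) -> ExpressionMatrix:
    path = Path(path)
    if sidecar is None:
        candidate = Path(str(path) + ".meta.tsv")
        sidecar = candidate if candidate.exists() else None
    value_kind = "rpkm"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#value_kind="):
        value_kind = first.strip().split("=", 1)[1]
    mat = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    mat.index.name = "gene"
    lengths = libsizes = None
    if sidecar is not None:
        meta = _read_typed_tsv(sidecar, ["kind", "id", "value"],
                               {"value": float})
        lg = meta[meta["kind"] == "gene_length"]
        ls = meta[meta["kind"] == "library_size"]
        if len(lg):
            lengths = pd.Series(lg["value"].values.astype(int),
                                index=lg["id"].values)
        if len(ls):
            libsizes = pd.Series(ls["value"].values.astype(int),
                                 index=ls["id"].values)
    if value_kind == "counts" and (lengths is None or libsizes is None):
        raise ValidationError(
            f"{path}: counts matrix requires a gene-length/library-size "
            "sidecar")
    return ExpressionMatrix(mat, value_kind, gene_lengths=lengths,
                            library_sizes=libsizes)


def write_expression(expr: ExpressionMatrix, path) -> Path:
    path = Path(path)
    mat = expr.values.sort_index()
    mat = mat[sorted(mat.columns)]
    with open(path, "w") as fh:
        fh.write(f"#value_kind={expr.value_kind}\n")
        mat.to_csv(fh, sep="\t", index_label="gene")
    if expr.gene_lengths is not None or expr.library_sizes is not None:
        rows = []
        if expr.gene_lengths is not None:
            rows += [{"kind": "gene_length", "id": g, "value": int(v)}
                     for g, v in expr.gene_lengths.sort_index().items()]
        if expr.library_sizes is not None:
            rows += [{"kind": "library_size", "id": s, "value": int(v)}
                     for s, v in expr.library_sizes.sort_index().items()]
        pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
            str(path) + ".meta.tsv", sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# gene models (GTF or BED12, optional FASTA for sequences)

def read_gene_model(path, fasta=None) -> dict:
    """Read transcript models from GTF or 12-column BED.

    With ``fasta`` (a genome FASTA), each model carries the plus-strand
    sequence of its exon span.  Returns ``{gene_id: TranscriptModel}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        models = _read_bed12(path)
    else:
        models = _read_gtf(path)
    if fasta is not None:
        from Bio import SeqIO
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(fasta), "fasta")}
        for gene_id, m in models.items():
            if m.chrom not in genome:
                raise ValidationError(
                    f"{gene_id}: chromosome {m.chrom!r} absent from FASTA")
            seq = genome[m.chrom][m.span_start - 1:m.span_end]
            models[gene_id] = TranscriptModel(
                m.gene_id, m.chrom, m.strand, m.exons,
                m.cds_start, m.cds_end, seq)
    return models


def _parse_gtf_attributes(field: str) -> dict:
    out = {}
    for part in field.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path) -> dict:
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno,
                                 f"expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            gene_id = _parse_gtf_attributes(attrs).get("gene_id")
            if not gene_id:
                raise ParseError(path, lineno, "missing gene_id attribute")
            meta.setdefault(gene_id, (chrom, strand))
            if feature == "exon":
                exons.setdefault(gene_id, []).append((start_i, end_i))
            else:
                cds.setdefault(gene_id, []).append((start_i, end_i))
    models = {}
    for gene_id, (chrom, strand) in meta.items():
        if gene_id not in exons:
            raise ValidationError(f"{gene_id}: CDS without exons")
        ivals = sorted(exons[gene_id])
        cds_start = cds_end = None
        if gene_id in cds:
            cds_start = min(s for s, _ in cds[gene_id])
            cds_end = max(e for _, e in cds[gene_id])
        models[gene_id] = TranscriptModel(gene_id, chrom, strand,
                                          tuple(ivals), cds_start, cds_end)
    return models


def _read_bed12(path) -> dict:
    models = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(path, lineno,
                                 f"expected 12 BED columns, got {len(fields)}")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name, strand = fields[3], fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "malformed BED12 numeric field")
            # half-open 0-based blocks -> 1-based inclusive exons
            exons = tuple((chrom_start + off + 1, chrom_start + off + size)
                          for off, size in zip(starts, sizes))
            cds_start = thick_start + 1 if thick_start < thick_end else None
            cds_end = thick_end if thick_start < thick_end else None
            models[name] = TranscriptModel(name, chrom, strand, exons,
                                           cds_start, cds_end)
    return models


def write_gene_model(models: Mapping[str, TranscriptModel], path,
                     fasta_path=None) -> Path:
    """Write models as GTF (exon + CDS features); optionally write each
    chromosome's sequence (reconstructed from model spans, intergenic gaps
    padded with N) to ``fasta_path``."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            attrs = f'gene_id "{m.gene_id}";'
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tgistint\texon\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\t{attrs}\n")
                if m.cds_start is not None:
                    lo, hi = max(s, m.cds_start), min(e, m.cds_end)
                    if lo <= hi:
                        fh.write(f"{m.chrom}\tgistint\tCDS\t{lo}\t{hi}\t.\t"
                                 f"{m.strand}\t.\t{attrs}\n")
    if fasta_path is not None:
        chrom_len: dict[str, int] = {}
        for m in models.values():
            chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.span_end)
        chrom_seq = {c: bytearray(b"N" * n) for c, n in chrom_len.items()}
        for m in models.values():
            if m.sequence is not None:
                chrom_seq[m.chrom][m.span_start - 1:m.span_end] = \
                    m.sequence.encode()
        with open(fasta_path, "w") as fh:
            for chrom in sorted(chrom_seq):
                fh.write(f">{chrom}\n")
                seq = chrom_seq[chrom].decode()
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path) -> list[GeneSet]:
    sets = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno,
                                 "GMT line needs set id, description and "
                                 "at least one gene")
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            if len(genes) != len(set(genes)):
                raise ValidationError(
                    f"gene set {set_id!r} contains duplicate gene ids")
            if set_id in seen:
                raise ValidationError(f"duplicate gene set id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, description, frozenset(genes)))
    return sets


def write_gene_sets(sets, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in sorted(sets, key=lambda g: g.set_id):
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.set_id}\t{gs.description}\t{genes}\n")
    return path


# ---------------------------------------------------------------------------
# sample info

def sample_info_records(df: pd.DataFrame) -> list[SampleInfo]:
    """Typed SampleInfo records from a validated sample-info table."""
    return [SampleInfo(r["sample"], Location(r["location"]),
                       Genotype(r["genotype"]), Risk(r["risk"]),
                       RecurrenceStatus(r["recurrence_status"]))
            for _, r in df.iterrows()]


def sample_groups(df: pd.DataFrame) -> dict:
    """Map sample id -> analysis stratum label."""
    return {r.sample_id: r.group for r in sample_info_records(df)}


# ---------------------------------------------------------------------------
# optional real-VCF ingestion (AD format fields)

def read_sites_vcf(path, tumor: str, normal: str,
                   sample_id: str | None = None) -> pd.DataFrame:
    """Read a paired tumor/normal VCF with per-sample AD fields into the
    site-count table.  Multi-allelic records are skipped."""
    import pysam
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            t_ad = rec.samples[tumor].get("AD")
            n_ad = rec.samples[normal].get("AD")
            if t_ad is None or n_ad is None:
                continue
            rows.append({
                "sample": sample_id or tumor, "chrom": rec.chrom,
                "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                "t_ref": int(t_ad[0]), "t_alt": int(t_ad[1]),
                "n_ref": int(n_ad[0]), "n_alt": int(n_ad[1]),
            })
    return _validate("sites", pd.DataFrame(rows, columns=SITE_COLUMNS))
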