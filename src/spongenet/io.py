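"""Reading, validation, filtering and partitioning of pipeline inputs.

The pipeline consumes three kinds of input, all plain text:

* expression matrices (genes x samples, TSV, ``NA`` for missing) of
  normalized abundance for mRNAs, lncRNAs and mature miRNAs measured on
  the same samples;
* a gene annotation table assigning each gene a biotype
  (``protein_coding`` / ``lncRNA`` / ``miRNA``);
* FASTA files of mature miRNA sequences, mRNA 3'UTRs and lncRNA
  transcript (cDNA) sequences.

Matched designs (e.g. tumor and adjacent normal tissue from the same
individuals) are handled through a sample-metadata table mapping sample
ids to a condition label; the pipeline is then run once per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "miRNA")
SEQUENCE_ROLES = ("mature_mirna", "utr3", "lnc_transcript")
_ALPHABET = frozenset("ACGTUN")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A genes x samples grid of normalized expression values.

    Missing measurements are stored as ``NaN`` and are distinct from
    zero abundance. Gene and sample identifiers must be unique; every
    non-missing value must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup_genes = self.data.index[self.data.index.duplicated()]
        if len(dup_genes):
            raise ValidationError(f"duplicate gene id(s): {sorted(set(dup_genes))}")
        dup_samples = self.data.columns[self.data.columns.duplicated()]
        if len(dup_samples):
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup_samples))}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ValidationError("expression values must be finite or missing (NA)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def missing_fraction(self) -> pd.Series:
        """Per-gene fraction of missing samples."""
        return self.data.isna().mean(axis=1)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def log2_transform(self) -> "ExpressionMatrix":
        """Return log2(x + 1)-transformed copy (for count-scale inputs)."""
        return ExpressionMatrix(np.log2(self.data + 1.0))


@dataclass
class GeneAnnotation:
    """Gene id -> (symbol, biotype) table; one row per gene."""

    table: pd.DataFrame  # index gene_id; columns symbol, biotype

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate annotation gene id(s): {sorted(set(dup))}")
        bad = set(self.table["biotype"]) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotype value(s): {sorted(bad)}")

    def biotype_of(self, gene_id: str) -> str:
        return str(self.table.at[gene_id, "biotype"])

    def genes_with_biotype(self, biotype: str) -> set[str]:
        return set(self.table.index[self.table["biotype"] == biotype])


@dataclass
class SequenceSet:
    """Named nucleotide sequences with a declared role.

    Sequences may be in DNA or RNA alphabet (plus N); U and T are
    treated as equivalent on comparison. Matching helpers in
    :mod:`spongenet.seedmatch` normalize to DNA.
    """

    records: dict[str, str]
    role: str

    def __post_init__(self) -> None:
        if self.role not in SEQUENCE_ROLES:
            raise ValidationError(f"unknown sequence role {self.role!r}")
        for rid, seq in self.records.items():
            if not seq:
                raise ValidationError(f"empty sequence for record {rid!r}")
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValidationError(
                    f"record {rid!r} contains non-nucleotide characters {sorted(bad)}"
                )

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> str | None:
        return self.records.get(record_id)

    def lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.records.items()}


# ---------------------------------------------------------------------------
# readers / writers


def _check_header_duplicates(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValidationError(f"duplicate sample id {s!r} in {path}")
        seen.add(s)


def read_expression(
    path,
    condition_filter: str | None = None,
    metadata_path=None,
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The first column holds gene ids, the header row sample ids, and
    ``NA`` marks missing values. If *condition_filter* is given, a
    sample-metadata table (``sample_id``, ``condition``) restricts the
    matrix to samples with that condition label.
    """
    _check_header_duplicates(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw = raw.replace({"NA": np.nan, "": np.nan})
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene = numeric.index[rows[0]]
        sample = numeric.columns[cols[0]]
        raise ValidationError(
            f"non-numeric expression value {raw.iat[rows[0], cols[0]]!r} "
            f"at gene {gene!r}, sample {sample!r} in {path}"
        )
    # final conversion via float() semantics (correctly rounded, unlike
    # pandas' fast parser) so the TSV round-trip is bit-identical
    matrix = ExpressionMatrix(
        pd.DataFrame(
            raw.to_numpy(dtype=object).astype(float),
            index=raw.index,
            columns=raw.columns,
        )
    )
    if condition_filter is not None:
        if metadata_path is None:
            raise ValidationError("condition_filter requires a sample metadata table")
        meta = read_sample_metadata(metadata_path)
        keep = [s for s in matrix.sample_ids if meta.get(s) == condition_filter]
        logger.info(
            "condition filter %r: kept %d/%d samples",
            condition_filter,
            len(keep),
            matrix.n_samples,
        )
        matrix = ExpressionMatrix(matrix.data[keep])
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write an expression TSV (round-trips bit-identically)."""
    out = matrix.data.copy()
    out.index.name = "gene_id"
    # shortest round-trip float repr so write(read(f)) is bit-identical
    out.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: repr(float(v)))


def read_sample_metadata(path) -> dict[str, str]:
    """Read a sample_id -> condition mapping from TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in table.columns:
            raise ValidationError(f"sample metadata {path} lacks column {col!r}")
    dup = table["sample_id"][table["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample id(s) in metadata: {sorted(set(dup))}")
    return dict(zip(table["sample_id"], table["condition"]))


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "symbol", "biotype"):
        if col not in table.columns:
            raise ValidationError(f"annotation {path} lacks column {col!r}")
    return GeneAnnotation(table.set_index("gene_id"))


def write_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_fasta(path, role: str) -> SequenceSet:
    """Read a multi-record FASTA into a :class:`SequenceSet`."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return SequenceSet(records, role)


def write_fasta(seqs: SequenceSet, path) -> None:
    recs = [
        SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# filters and partitioning


def filter_missing(
    matrix: ExpressionMatrix, max_missing_frac: float = 0.10
) -> ExpressionMatrix:
    """Drop genes whose fraction of missing samples exceeds the threshold.

    The comparison is strict: a gene at exactly the threshold is kept.
    Idempotent; an empty result is legal and logged as a warning.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValidationError("max_missing_frac must lie in [0, 1]")
    frac = matrix.missing_fraction()
    keep = frac <= max_missing_frac
    removed = int((~keep).sum())
    logger.info("filter_missing: removed %d/%d genes", removed, matrix.n_genes)
    result = ExpressionMatrix(matrix.data.loc[keep])
    if result.n_genes == 0:
        logger.warning("filter_missing: no genes remain")
    return result


def partition_by_biotype(
    matrix: ExpressionMatrix, annotation: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Split a matrix into (mRNA, lncRNA, miRNA) class matrices.

    Genes missing from the annotation are dropped from all three
    classes; the drop count is logged.
    """
    known = set(annotation.table.index)
    dropped = [g for g in matrix.gene_ids if g not in known]
    if dropped:
        logger.info("partition_by_biotype: dropped %d unannotated genes", len(dropped))
    parts = []
    for biotype in BIOTYPES:
        genes = [
            g for g in matrix.gene_ids if g in known and annotation.biotype_of(g) == biotype
        ]
        parts.append(ExpressionMatrix(matrix.data.loc[genes]))
    return parts[0], parts[1], parts[2]


def filter_by_utr(
    mrnas: ExpressionMatrix, utrs: SequenceSet, min_len: int = 500
) -> ExpressionMatrix:
    """Keep only mRNAs with an available 3'UTR of length >= *min_len* nt."""
    if utrs.role != "utr3":
        raise ValidationError(f"expected sequences with role 'utr3', got {utrs.role!r}")
    lengths = utrs.lengths()
    keep = [g for g in mrnas.gene_ids if lengths.get(g, 0) >= min_len]
    logger.info(
        "filter_by_utr: kept %d/%d mRNAs (3'UTR >= %d nt)",
        len(keep),
        mrnas.n_genes,
        min_len,
    )
    return ExpressionMatrix(mrnas.data.loc[keep])
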