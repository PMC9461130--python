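"""Readers and writers for the tabular and sequence dialects used by the pipeline.

All tables are plain TSV/CSV with a header row; missing values are written as
``NA``.  GFF3 is 1-based with inclusive ends; FASTA is wrapped at 60 columns on
write.  Parsing is strict: a malformed line raises :class:`FormatError` carrying
the offending line number rather than silently coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NA = "NA"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class GeneModel:
    """A genomic feature: protein-coding gene, transcription factor or miRNA.

    Coordinates are 1-based and inclusive on both ends (GFF3 convention).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "gene"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"feature {self.id}: start must be >= 1")


# ---------------------------------------------------------------------------
# genotype / map
# ---------------------------------------------------------------------------

def write_genotypes(geno: pd.DataFrame, path) -> None:
    """Write a lines x markers genotype matrix (codes 0/2) as CSV."""
    geno.to_csv(path, index_label="line")


def read_genotypes(path) -> pd.DataFrame:
    geno = pd.read_csv(path, index_col="line")
    bad = set(pd.unique(geno.values.ravel())) - {0, 2}
    if bad:
        raise FormatError(path, 0, f"genotype codes outside {{0,2}}: {sorted(bad)}")
    return geno.astype(int)


def write_genetic_map(gmap: pd.DataFrame, path) -> None:
    """Write a marker map TSV with columns marker, chrom, cM, bp."""
    gmap.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_genetic_map(path) -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t")
    required = {"marker", "chrom", "cM", "bp"}
    if not required.issubset(gmap.columns):
        raise FormatError(path, 1, f"map header must contain {sorted(required)}")
    return gmap


# ---------------------------------------------------------------------------
# phenotypes (long form: line, environment, variable, value)
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["line", "environment", "variable", "value"]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.loc[:, PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(path, 1, f"phenotype header missing columns {sorted(missing)}")
    return table


def pivot_phenotypes(table: pd.DataFrame, aggregate: str | None = None) -> pd.DataFrame:
    """Pivot a long phenotype table to lines x variables.

    With replicated measurements pass ``aggregate='mean'`` to average over the
    environment/replicate column; otherwise the table must be unambiguous.
    """
    if aggregate is None:
        wide = table.pivot(index="line", columns="variable", values="value")
    else:
        wide = table.pivot_table(
            index="line", columns="variable", values="value", aggfunc=aggregate
        )
    return wide.sort_index()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(features: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tmdgnet\t{f.biotype}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    features: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(path, lineno, "non-integer coordinates") from None
            if end_i < start_i:
                raise FormatError(path, lineno, f"end {end_i} < start {start_i}")
            feature_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    feature_id = item[3:]
            if feature_id is None:
                raise FormatError(path, lineno, "attributes lack ID=")
            features.append(
                GeneModel(feature_id, chrom, start_i, end_i, strand, ftype)
            )
    return features


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# expression / PPI / ledger
# ---------------------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes x samples expression matrix as TSV."""
    expr.to_csv(path, sep="\t", index_label="gene", na_rep=NA)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", na_values=[NA])


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.loc[:, ["gene_a", "gene_b", "score"]].to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_ppi(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(edges.columns):
        raise FormatError(path, 1, f"PPI header must contain {sorted(required)}")
    return edges


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
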