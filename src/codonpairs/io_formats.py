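"""Readers and writers for the formats the pipeline touches.

Coding sequences arrive as FASTA (one record per ORF, SGD-style headers
where the first whitespace-delimited token is the systematic gene name),
expression measurements as TSV tables with a header row, codon weights as
a three-column TSV (``codon``, ``w``, ``optimal_flag``), and 3'UTRs either
as a per-gene FASTA or as BED6 intervals against a genome FASTA.

Records that violate the coding-sequence invariants (non-ACGT characters,
length not a multiple of 3) are excluded with a logged warning rather than
repaired, so downstream gene counts always refer to a well-defined set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("codonpairs")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Canonical expression-table columns, in display order.  Units: synthesis
#: rate in molecules/min/cell, decay rates in 1/min, the two translation
#: efficiency proxies dimensionless.
EXPRESSION_COLUMNS = (
    "synthesis_rate",
    "decay_rate",
    "protein_per_mrna",
    "ribosome_occupancy",
    "protein_decay_rate",
)

_VALID_NT = frozenset("ACGT")


@dataclass
class GeneRecord:
    """One ORF: identifier, coding sequence, optional 3'UTR and status.

    The coding sequence is stored 5'->3' with the first codon at position
    0; a terminal stop codon may be present and is stripped by the feature
    layer, not here.
    """

    gene_id: str
    cds: str
    utr3: str | None = None
    status: str | None = None
    description: str = ""

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            problems.append(f"length {len(self.cds)} not a positive multiple of 3")
        bad = set(self.cds) - _VALID_NT
        if bad:
            problems.append(f"non-ACGT characters {sorted(bad)}")
        return problems


@dataclass
class CodonWeightTable:
    """tAI relative-adaptiveness weights for the 61 sense codons.

    ``weights`` maps each sense codon to its relative adaptiveness
    w (0 < w <= 1); ``optimal_set`` is the subset classified as optimal.
    Strictly positive weights are required because gene-level tAI is a
    geometric mean.
    """

    weights: dict[str, float]
    optimal_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        keys = set(self.weights)
        if keys & STOP_CODONS:
            raise ValueError("codon weight table must not contain stop codons")
        if len(keys) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(keys)}")
        for codon, w in self.weights.items():
            if len(codon) != 3 or set(codon) - _VALID_NT:
                raise ValueError(f"invalid codon {codon!r}")
            if not (w > 0):
                raise ValueError(f"non-positive weight for {codon}: {w}")
        self.optimal_set = frozenset(self.optimal_set)
        if self.optimal_set - keys:
            raise ValueError("optimal_set contains codons absent from weights")


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a FASTA file into GeneRecords, excluding invalid sequences.

    The identifier is the header token up to the first whitespace; the
    remainder is kept as the description.  Sequences are upper-cased and
    multi-line records concatenated.  Duplicate identifiers are a hard
    error; records failing the coding-sequence invariants are dropped with
    a warning.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_excluded = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        gr = GeneRecord(
            gene_id=gene_id,
            cds=str(rec.seq).upper(),
            description=rec.description[len(rec.id):].strip(),
        )
        problems = gr.validate()
        if problems:
            n_excluded += 1
            logger.warning("excluding %s: %s", gene_id, "; ".join(problems))
            continue
        records.append(gr)
    if n_excluded:
        logger.warning("%d record(s) excluded from %s", n_excluded, path)
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 60) -> None:
    """Write GeneRecords as FASTA (coding sequences only)."""
    seq_records = [
        SeqRecord(Seq(r.cds), id=r.gene_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def filter_verified(
    records: list[GeneRecord],
    annotation: Mapping[str, str] | pd.DataFrame,
    status: str = "Verified",
) -> list[GeneRecord]:
    """Keep records whose annotation status equals ``status``.

    ``annotation`` maps gene_id to an annotation class ("Verified",
    "Dubious", ...); a DataFrame with ``gene_id``/``status`` columns is
    also accepted.  Missing status is treated as non-verified.  The kept
    records carry their status; the retained count is logged.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(zip(annotation["gene_id"], annotation["status"]))
    kept = []
    for rec in records:
        st = annotation.get(rec.gene_id)
        if st == status:
            rec.status = st
            kept.append(rec)
    logger.info("filter_verified: %d of %d records retained", len(kept), len(records))
    return kept


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV (gene_id, status) annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "status"} <= set(df.columns):
        raise ValueError("annotation table needs gene_id and status columns")
    return df


def read_expression_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-gene expression TSV into canonical columns.

    ``column_map`` maps file headers to canonical column names
    (``gene_id`` plus any of EXPRESSION_COLUMNS).  With no map, headers
    already matching canonical names are used as-is.  Empty cells and
    "NA" become missing; non-numeric cells become missing with a warning;
    a negative rate is a hard error naming the offending gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        missing = [src for src in column_map if src not in df.columns]
        if missing:
            raise ValueError(f"column(s) {missing} not found in {path}")
        df = df.rename(columns=dict(column_map))
    if "gene_id" not in df.columns:
        raise ValueError(f"no gene_id column in {path}")
    keep = ["gene_id"] + [c for c in EXPRESSION_COLUMNS if c in df.columns]
    if len(keep) == 1:
        raise ValueError(f"no recognized expression columns in {path}")
    df = df[keep]
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id(s) in {path}: {dups[:5]}")
    out = df[["gene_id"]].copy()
    for col in keep[1:]:
        raw = df[col].replace({"": None, "NA": None, "NaN": None})
        vals = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & vals.isna()
        if bad.any():
            for g in df.loc[bad, "gene_id"]:
                logger.warning("non-numeric %s for gene %s set to missing", col, g)
        neg = vals < 0
        if neg.any():
            gene = df.loc[neg, "gene_id"].iloc[0]
            raise ValueError(f"negative {col} for gene {gene} in {path}")
        out[col] = vals
    logger.info(
        "read_expression_table: %d rows from %s; missing per column: %s",
        len(out), path,
        {c: int(out[c].isna().sum()) for c in out.columns if c != "gene_id"},
    )
    return out


def read_codon_weights(path: str | Path) -> CodonWeightTable:
    """Read a codon-weight TSV with columns codon, w, optimal_flag."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str})
    required = {"codon", "w", "optimal_flag"}
    if not required <= set(df.columns):
        raise ValueError(f"codon weight table needs columns {sorted(required)}")
    weights = dict(zip(df["codon"].str.upper(), df["w"].astype(float)))
    optimal = frozenset(
        df.loc[df["optimal_flag"].astype(int) == 1, "codon"].str.upper()
    )
    return CodonWeightTable(weights=weights, optimal_set=optimal)


def write_codon_weights(table: CodonWeightTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "codon": sorted(table.weights),
            "w": [table.weights[c] for c in sorted(table.weights)],
            "optimal_flag": [int(c in table.optimal_set) for c in sorted(table.weights)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read per-gene 3'UTR sequences from FASTA, collapsing isoforms.

    Several annotation sets report multiple UTR isoforms per gene; the
    longest isoform is kept (the original collapsing rule of the source
    annotations is not recoverable, so the most inclusive sequence is
    used).
    """
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id not in utrs or len(seq) > len(utrs[rec.id]):
            utrs[rec.id] = seq
    return utrs


def read_utr_bed(bed_path: str | Path, genome_fasta: str | Path) -> dict[str, str]:
    """Extract 3'UTR sequences from BED6 intervals against a genome FASTA.

    Intervals are 0-based half-open; minus-strand intervals are
    reverse-complemented.  The BED name field is the gene_id; multiple
    intervals per gene collapse to the longest.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    utrs: dict[str, str] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 line with {len(parts)} fields: {line!r}")
            chrom, start, end, name, _score, strand = parts[:6]
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} absent from genome FASTA")
            seq = genome[chrom][int(start):int(end)]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            if name not in utrs or len(seq) > len(utrs[name]):
                utrs[name] = seq
    return utrs


def attach_utrs(records: list[GeneRecord], utrs: Mapping[str, str]) -> int:
    """Attach UTR sequences to records in place; return how many matched."""
    n = 0
    for rec in records:
        seq = utrs.get(rec.gene_id)
        if seq:
            rec.utr3 = seq
            n += 1
    logger.info("attach_utrs: %d of %d records have a 3'UTR", n, len(records))
    return n
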