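"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython.  Count matrices travel as TSV (contig_id +
one column per library) with a sidecar TSV mapping library -> condition,
replicate.  Pre-computed match tables use the 12-column BLAST tabular
convention (qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore; pident on the 0-100 scale, 1-based inclusive
coordinates).  GO mappings are two-column TSV with comma-separated term
lists.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParameterError, UnknownIdError
from .expression import CountMatrix
from .redundancy import Contig, PairwiseMatch

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_go_mapping",
    "write_go_mapping",
]

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_fasta(path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: list[Contig], path) -> None:
    records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def write_counts(cm: CountMatrix, counts_path, design_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="contig_id")
    cm.design.to_csv(design_path, sep="\t", index_label="library")


def read_counts(counts_path, design_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="contig_id")
    design = None
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", index_col="library")
    return CountMatrix(counts, design)


def read_blast_tabular(path, contig_lengths: dict[str, int]) -> list[PairwiseMatch]:
    """Parse a 12-column BLAST tabular match table into PairwiseMatch records.

    Coverage is derived from the aligned spans and the supplied contig
    lengths, so every id in the table must be present in
    ``contig_lengths``.  Self-hits are skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    matches = []
    for row in df.itertuples():
        if row.qseqid == row.sseqid:
            continue
        for cid in (row.qseqid, row.sseqid):
            if cid not in contig_lengths:
                raise UnknownIdError(f"match table references unknown contig {cid!r}")
        qs, qe = sorted((int(row.qstart), int(row.qend)))
        ss, se = sorted((int(row.sstart), int(row.send)))
        qspan = qe - qs + 1
        sspan = se - ss + 1
        matches.append(
            PairwiseMatch(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                identity=float(row.pident) / 100.0,
                match_len=int(row.length),
                query_start=qs - 1,
                query_end=qe,
                subject_start=ss - 1,
                subject_end=se,
                query_cov=qspan / contig_lengths[row.qseqid],
                subject_cov=sspan / contig_lengths[row.sseqid],
            )
        )
    return matches


def write_blast_tabular(matches: list[PairwiseMatch], path) -> None:
    rows = []
    for m in matches:
        mismatches = round(m.match_len * (1.0 - m.identity))
        rows.append(
            {
                "qseqid": m.query_id,
                "sseqid": m.subject_id,
                "pident": round(100.0 * m.identity, 3),
                "length": m.match_len,
                "mismatch": mismatches,
                "gapopen": 0,
                "qstart": m.query_start + 1,
                "qend": m.query_end,
                "sstart": m.subject_start + 1,
                "send": m.subject_end,
                "evalue": 0.0,
                "bitscore": float(m.score),
            }
        )
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def write_go_mapping(ann: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgo_terms\n")
        for cid in sorted(ann):
            fh.write(f"{cid}\t{','.join(sorted(ann[cid]))}\n")


def read_go_mapping(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t")
    if not {"contig_id", "go_terms"}.issubset(df.columns):
        raise ParameterError("GO mapping TSV needs columns contig_id, go_terms")
    out: dict[str, set] = {}
    for row in df.itertuples():
        terms = {t for t in str(row.go_terms).split(",") if t}
        if terms:
            out[row.contig_id] = terms
    return out
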