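"""File formats: FASTA/FASTQ reads, sample sheets, TSV tables, truth JSON.

All tables are tab-separated with a header row; floats are written with a
fixed general format so that re-running a pipeline with the same seed
produces byte-identical files.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assign import CountMatrix
from .simulate import FOCAL, OrthologTranscriptomes, ReadSet

FLOAT_FORMAT = "%.10g"


def write_transcriptomes(transcriptomes: OrthologTranscriptomes, focal_path, spike_path):
    """Two FASTA files with matching record ids, one per species."""
    for path, species in ((focal_path, FOCAL), (spike_path, "spike")):
        records = [
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in transcriptomes.sequences(species).items()
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_fastq(read_set: ReadSet, path):
    """FASTQ with constant quality 'I'; the read id carries no truth labels."""
    records = []
    for read_id, seq in zip(read_set.reads["read_id"], read_set.reads["sequence"]):
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads(path) -> pd.DataFrame:
    """Reads from FASTQ or FASTA -> DataFrame(read_id, sequence)."""
    path = Path(path)
    fmt = "fastq" if path.suffix in (".fastq", ".fq") else "fasta"
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    return pd.DataFrame(rows, columns=["read_id", "sequence"])


def write_table(df: pd.DataFrame, path, index_label=None):
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_count_matrix(cm: CountMatrix, counts_path, totals_path):
    write_table(cm.counts, counts_path, index_label="gene")
    write_table(cm.totals, totals_path, index_label="sample")


def read_count_matrix(counts_path, totals_path, assay: str) -> CountMatrix:
    return CountMatrix(
        assay=assay,
        counts=read_table(counts_path),
        totals=read_table(totals_path),
    )


def write_truth(truth: dict, path):
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
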