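"""Readers and writers for the pipeline's plain-text formats.

Counts: TSV, first column gene_id, one column per sample.
Sample sheet: TSV with sample_id, colony_id, phase.
GO map: TSV with gene_id, go_code, go_name, go_domain.
Transcripts: FASTA.
Hit table: 12-column tab-separated alignment records (outfmt-6 style)
plus a 13th taxon column, no header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .pairwise_de import CountExperiment
from .transcript_recovery import HIT_TABLE_COLUMNS, TranscriptRecord


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    counts = counts.astype(int)
    samples = pd.read_csv(
        samples_path, sep="\t", dtype={"sample_id": str, "colony_id": str, "phase": str}
    )
    missing = {"sample_id", "colony_id", "phase"} - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return CountExperiment(counts=counts, samples=samples)


def read_go_map(path: str | Path) -> pd.DataFrame:
    go_map = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "go_code", "go_name", "go_domain"} - set(go_map.columns)
    if missing:
        raise ValueError(f"GO map lacks columns: {sorted(missing)}")
    return go_map


def read_hit_table(path: str | Path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t", header=None, names=HIT_TABLE_COLUMNS)
    return hits


def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(transcript_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_transcript_truth(path: str | Path) -> pd.DataFrame:
    """Recover ``true_class`` labels from FASTA descriptions written by the
    synthetic generator (``>id true_class=complete``)."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        for token in rec.description.split():
            if token.startswith("true_class="):
                rows.append((rec.id, token.split("=", 1)[1]))
    return pd.DataFrame(rows, columns=["transcript_id", "true_class"])


def read_truth_de(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "comparison": str, "status": str})
    return truth
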