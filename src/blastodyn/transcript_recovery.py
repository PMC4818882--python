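"""Transcript recovery: ORF completeness classes and best-hit taxonomy.

Assembled contigs that fail to map onto the reference genome are triaged by
(i) classifying their best open reading frame as complete, open at the 5'
end, open at the 3' end, or open at both ends, and (ii) letting each
transcript inherit the taxon of its best significant alignment hit, which
flags likely contaminants among the recovered sequences.

Candidate ORFs are start-anchored: within every reading frame, each
stop-bounded segment yields a candidate from its first ATG to the bounding
stop (complete) or to the 3' terminus (open3).  Only when no start-anchored
candidate reaches ``min_aa`` anywhere does the scan fall back to startless
stretches that begin at the 5' terminus, classified open5 (terminated by a
stop) or open_both (running off both ends).  Coordinates are 0-based
half-open on the scanned strand and include the stop codon when present;
``aa_length`` excludes the stop.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger("blastodyn.transcript_recovery")

Completeness = Literal["complete", "open5", "open3", "open_both", "none"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

HIT_TABLE_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "taxon",
]


@dataclass(frozen=True)
class TranscriptRecord:
    """A nucleotide transcript; the sequence is uppercase-normalized."""

    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty sequence")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"non-nucleotide characters in {self.transcript_id}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class OrfCall:
    transcript_id: str
    frame: int
    strand: str
    start: int
    end: int
    aa_length: int
    completeness: Completeness


def _frame_codons(seq: str, frame: int) -> list[str]:
    return [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]


def _scan_strand(
    transcript_id: str, seq: str, min_aa: int, strand: str
) -> tuple[list[OrfCall], list[OrfCall]]:
    """Return (start-anchored candidates, startless fallback candidates)."""
    anchored: list[OrfCall] = []
    startless: list[OrfCall] = []
    for frame in range(3):
        codons = _frame_codons(seq, frame)
        if not codons:
            continue
        seg_start = 0  # codon index where the current segment begins
        i = 0
        n = len(codons)
        while seg_start < n:
            # advance to the bounding stop or the end of the frame
            i = seg_start
            while i < n and codons[i] not in STOP_CODONS:
                i += 1
            has_stop = i < n
            segment = codons[seg_start:i]
            try:
                atg = segment.index(START_CODON)
            except ValueError:
                atg = -1
            if atg >= 0:
                aa = len(segment) - atg
                if aa >= min_aa:
                    start_nt = frame + 3 * (seg_start + atg)
                    end_nt = frame + 3 * (i + 1) if has_stop else frame + 3 * i
                    anchored.append(
                        OrfCall(
                            transcript_id=transcript_id,
                            frame=frame,
                            strand=strand,
                            start=start_nt,
                            end=end_nt,
                            aa_length=aa,
                            completeness="complete" if has_stop else "open3",
                        )
                    )
            elif seg_start == 0 and segment:
                # startless stretch reaching the 5' terminus of this frame
                aa = len(segment)
                if aa >= min_aa:
                    end_nt = frame + 3 * (i + 1) if has_stop else frame + 3 * i
                    startless.append(
                        OrfCall(
                            transcript_id=transcript_id,
                            frame=frame,
                            strand=strand,
                            start=frame,
                            end=end_nt,
                            aa_length=aa,
                            completeness="open5" if has_stop else "open_both",
                        )
                    )
            seg_start = i + 1
    return anchored, startless


def find_orfs(
    record: TranscriptRecord, min_aa: int = 100, both_strands: bool = False
) -> list[OrfCall]:
    """Candidate ORFs of at least ``min_aa`` codons (standard genetic code).

    Start-anchored candidates (ATG..stop or ATG..3' end) take precedence;
    startless 5'-terminal stretches are reported only when no start-anchored
    candidate survives the length filter.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    strands = [("+", record.sequence)]
    if both_strands:
        strands.append(("-", str(Seq(record.sequence).reverse_complement())))
    anchored: list[OrfCall] = []
    startless: list[OrfCall] = []
    for strand, seq in strands:
        a, s = _scan_strand(record.transcript_id, seq, min_aa, strand)
        anchored.extend(a)
        startless.extend(s)
    return anchored if anchored else startless


def classify_completeness(
    record: TranscriptRecord, min_aa: int = 100, both_strands: bool = False
) -> OrfCall:
    """Best ORF call for a transcript; ``completeness`` "none" if nothing passes.

    The best candidate is the longest in amino acids; ties break toward the
    smaller start coordinate, then the lower frame index, then the forward
    strand.
    """
    candidates = find_orfs(record, min_aa=min_aa, both_strands=both_strands)
    if not candidates:
        return OrfCall(
            transcript_id=record.transcript_id,
            frame=0,
            strand="+",
            start=0,
            end=0,
            aa_length=0,
            completeness="none",
        )
    return min(
        candidates, key=lambda c: (-c.aa_length, c.start, c.frame, c.strand != "+")
    )


@dataclass(frozen=True)
class TaxonomySummary:
    """Per-taxon assignment counts with proportions over assigned transcripts."""

    counts: Mapping[str, int]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "TaxonomySummary":
        for taxon, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {taxon}")
        return cls(counts=dict(counts), total=sum(counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {t: n / self.total for t, n in self.counts.items()}

    def percent(self, taxon: str) -> int:
        """Whole-percent share of one taxon, for report tables."""
        return round(100 * self.counts.get(taxon, 0) / self.total) if self.total else 0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "taxon": [t for t, _ in rows],
                "count": [n for _, n in rows],
                "proportion": [n / self.total if self.total else math.nan for _, n in rows],
            }
        )


def assign_taxonomy(
    hits: pd.DataFrame, evalue_max: float = 1e-5
) -> dict[str, str]:
    """Best-hit taxon per transcript from a 13-column alignment table.

    Hits with e-value above ``evalue_max`` are discarded; among the rest each
    query inherits the taxon of the lowest-e-value hit (ties: highest
    bitscore, then first occurrence).  Malformed rows are skipped with a
    warning.  Queries with no surviving hit are absent from the result.
    """
    best: dict[str, tuple[float, float, int, str]] = {}
    n_bad = 0
    for order, row in enumerate(hits.itertuples(index=False)):
        try:
            query = str(row.query)
            evalue = float(row.evalue)
            bitscore = float(row.bitscore)
            taxon = str(row.taxon)
            if not query or math.isnan(evalue) or math.isnan(bitscore) or taxon == "nan":
                raise ValueError
        except (ValueError, AttributeError, TypeError):
            n_bad += 1
            continue
        if evalue > evalue_max:
            continue
        key = (evalue, -bitscore, order)
        incumbent = best.get(query)
        if incumbent is None or key < incumbent[:3]:
            best[query] = (evalue, -bitscore, order, taxon)
    if n_bad:
        logger.warning("skipped %d malformed hit records", n_bad)
    return {q: v[3] for q, v in sorted(best.items())}


def summarize_taxonomy(assignments: Mapping[str, str]) -> TaxonomySummary:
    """Tally per-taxon assignment counts over the assigned transcripts."""
    return TaxonomySummary.from_counts(Counter(assignments.values()))
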