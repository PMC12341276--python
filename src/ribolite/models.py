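"""Core domain types shared across the pipeline.

A reference transcriptome is represented as a list of :class:`TranscriptModel`
records in one of three tiers: ``contaminant`` (rRNA/tRNA/sno-snRNA-like
species removed before counting), ``coding`` (protein-coding transcripts with
annotated CDS bounds) and ``noncoding`` (everything else). Processed riboseq
reads carry their extracted UMI alongside the insert sequence.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGT")

STOP_CODONS = ("TAA", "TAG", "TGA")


class Tier(str, enum.Enum):
    """Reference tier used for hierarchical filtering/alignment."""

    CONTAMINANT = "contaminant"
    CODING = "coding"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class TranscriptModel:
    """A reference transcript: the unit of mapping and counting.

    CDS bounds are 0-based half-open positions on the transcript and are
    present iff the transcript is in the coding tier.
    """

    transcript_id: str
    gene_id: str
    tier: Tier
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id or not self.gene_id:
            raise ValueError("transcript_id and gene_id must be non-empty")
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        tier = Tier(self.tier)
        object.__setattr__(self, "tier", tier)
        has_cds = self.cds_start is not None or self.cds_end is not None
        if tier is Tier.CODING:
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.transcript_id}: coding transcript requires CDS bounds")
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(f"{self.transcript_id}: CDS bounds out of range")
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
        elif has_cds:
            raise ValueError(f"{self.transcript_id}: CDS bounds only allowed on coding tier")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProcessedRead:
    """An adapter-trimmed insert plus its extracted UMI: the unit of dedup."""

    read_id: str
    insert: str
    umi: str


# ---------------------------------------------------------------------------
# Reference I/O: FASTA for sequences, TSV for the annotation table.
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "tier", "cds_start", "cds_end"]


def annotation_frame(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Tabulate transcript annotation (tier, gene, 0-based half-open CDS)."""
    rows = []
    for t in transcripts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "tier": t.tier.value,
                "cds_start": "" if t.cds_start is None else t.cds_start,
                "cds_end": "" if t.cds_end is None else t.cds_end,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    annotation_frame(transcripts).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str, "tier": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    return df


def write_transcripts_fasta(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts(fasta: str | Path, annotation: str | Path) -> list[TranscriptModel]:
    """Load a tiered transcriptome from FASTA + annotation TSV."""
    ann = read_annotation(annotation).set_index("transcript_id")
    out: list[TranscriptModel] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in ann.index:
            raise ValueError(f"transcript {rec.id} absent from annotation")
        row = ann.loc[rec.id]
        cds_start = None if pd.isna(row["cds_start"]) else int(row["cds_start"])
        cds_end = None if pd.isna(row["cds_end"]) else int(row["cds_end"])
        out.append(
            TranscriptModel(
                transcript_id=rec.id,
                gene_id=str(row["gene_id"]),
                tier=Tier(row["tier"]),
                sequence=str(rec.seq).upper(),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return out


def gene_map(transcripts: Iterable[TranscriptModel]) -> dict[str, str]:
    """transcript_id -> gene_id over all tiers."""
    return {t.transcript_id: t.gene_id for t in transcripts}
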