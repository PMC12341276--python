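"""Riboseq read-anatomy parsing, contaminant filtering and UMI collapsing.

Raw riboseq reads look like

    <untemplated prefix (3 nt)> <insert> <UMI (8 nt)> <3' adapter>

The parser strips the prefix, locates the adapter (exact match of its first
12 nt, then at most one mismatch over the remaining overlap), takes the 8
bases immediately 5' of the adapter as the UMI and the remainder as the
insert. Reads are then filtered against the contaminant references
(rRNA/tRNA/sno-snRNA) and PCR duplicates are collapsed on the
(insert, UMI) key -- in that order, since collapsing is only meaningful on
the molecules that enter the transcriptome alignment.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import ProcessedRead, TranscriptModel

ADAPTER_SEED_LEN = 12

REJECTION_REASONS = ("no_adapter", "too_short", "too_long", "ambiguous_base_in_umi")


@dataclass(frozen=True)
class ReadStructure:
    """Positional anatomy of a raw riboseq read."""

    untemplated_prefix_len: int = 3
    umi_len: int = 8
    adapter: str = "AGATCGGAAGAGCACACGTCTGAA"
    min_insert: int = 20
    max_insert: int = 45

    def __post_init__(self) -> None:
        if self.untemplated_prefix_len < 0:
            raise ValueError("untemplated_prefix_len must be >= 0")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        if len(self.adapter) < 10:
            raise ValueError("adapter must be at least 10 nt")
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert must be <= max_insert")


@dataclass(frozen=True)
class Rejection:
    """A read excluded from the library, with its reason."""

    read_id: str
    reason: str


def find_adapter(seq: str, adapter: str, start: int = 0) -> int:
    """Leftmost adapter occurrence: exact seed (first 12 nt) plus <= 1
    mismatch over whatever remains of the adapter within the read.

    Returns the 0-based position of the adapter start, or -1.
    """
    seed = adapter[:ADAPTER_SEED_LEN]
    pos = seq.find(seed, start)
    while pos != -1:
        rest = adapter[ADAPTER_SEED_LEN:]
        overlap = min(len(rest), len(seq) - pos - len(seed))
        mismatches = sum(
            1 for a, b in zip(rest[:overlap], seq[pos + len(seed) : pos + len(seed) + overlap]) if a != b
        )
        if mismatches <= 1:
            return pos
        pos = seq.find(seed, pos + 1)
    return -1


def parse_read(
    read_id: str, seq: str, structure: ReadStructure = ReadStructure()
) -> ProcessedRead | Rejection:
    """Split a raw read into (insert, UMI) or reject it with a named reason."""
    seq = seq.upper()
    apos = find_adapter(seq, structure.adapter)
    if apos == -1:
        return Rejection(read_id, "no_adapter")
    umi_start = apos - structure.umi_len
    insert_start = structure.untemplated_prefix_len
    if umi_start < insert_start:
        return Rejection(read_id, "too_short")
    insert = seq[insert_start:umi_start]
    umi = seq[umi_start:apos]
    if len(insert) < structure.min_insert:
        return Rejection(read_id, "too_short")
    if len(insert) > structure.max_insert:
        return Rejection(read_id, "too_long")
    if "N" in umi:
        return Rejection(read_id, "ambiguous_base_in_umi")
    return ProcessedRead(read_id=read_id, insert=insert, umi=umi)


def parse_fastq(
    path: str | Path, structure: ReadStructure = ReadStructure()
) -> tuple[list[ProcessedRead], Counter]:
    """Parse a raw riboseq FASTQ; returns kept reads and rejection counts."""
    reads: list[ProcessedRead] = []
    rejections: Counter = Counter()
    index = 0
    try:
        with open(path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                index += 1
                result = parse_read(title.split()[0], seq, structure)
                if isinstance(result, Rejection):
                    rejections[result.reason] += 1
                else:
                    reads.append(result)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at record {index + 1}: {exc}") from exc
    return reads, rejections


def filter_contaminants(
    reads: Sequence[ProcessedRead],
    contaminant_refs: Sequence[TranscriptModel],
    max_mismatches: int = 3,
) -> tuple[list[ProcessedRead], list[ProcessedRead]]:
    """Partition reads into (kept, removed): a read is removed iff its insert
    aligns full-length (forward strand, Hamming) to any contaminant reference
    with at most ``max_mismatches`` mismatches."""
    from .mapcount import TranscriptIndex, has_hit  # deferred: avoid import cycle

    if not contaminant_refs:
        raise ValueError("contaminant_refs must be non-empty")
    index = TranscriptIndex(contaminant_refs)
    kept: list[ProcessedRead] = []
    removed: list[ProcessedRead] = []
    for r in reads:
        (removed if has_hit(r.insert, index, max_mismatches) else kept).append(r)
    return kept, removed


def collapse_umis(reads: Sequence[ProcessedRead]) -> list[ProcessedRead]:
    """Keep the first read per distinct (insert, UMI) pair, preserving order."""
    seen: set[tuple[str, str]] = set()
    out: list[ProcessedRead] = []
    for r in reads:
        key = (r.insert, r.umi)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def write_processed_fastq(reads: Iterable[ProcessedRead], path: str | Path) -> None:
    """Emit inserts as FASTQ with the UMI appended to the identifier
    (``@<id>_<UMI>`` dialect)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}_{r.umi}\n{r.insert}\n+\n{'I' * len(r.insert)}\n")


def read_processed_fastq(path: str | Path) -> list[ProcessedRead]:
    out: list[ProcessedRead] = []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            rid, _, umi = title.split()[0].rpartition("_")
            out.append(ProcessedRead(read_id=rid, insert=seq, umi=umi))
    return out


# ---------------------------------------------------------------------------
# RNAseq mates: plain 3' adapter trimming, no UMI handling.
# ---------------------------------------------------------------------------

RNASEQ_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
RNASEQ_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


def trim_adapter(seq: str, adapter: str) -> str:
    """Cut the read at the adapter start (same seed + <=1 mismatch rule);
    returns the read unchanged when no adapter is found."""
    pos = find_adapter(seq.upper(), adapter)
    return seq[:pos] if pos != -1 else seq


def trim_rnaseq_fastq(
    path: str | Path, out_path: str | Path, adapter: str = RNASEQ_ADAPTER_R1, min_len: int = 20
) -> tuple[int, int]:
    """Adapter-trim an RNAseq mate file; returns (kept, dropped_too_short)."""
    kept = dropped = 0
    with open(path) as fh, open(out_path, "w") as out:
        for title, seq, qual in FastqGeneralIterator(fh):
            trimmed = trim_adapter(seq, adapter)
            if len(trimmed) < min_len:
                dropped += 1
                continue
            kept += 1
            out.write(f"@{title}\n{trimmed}\n+\n{qual[: len(trimmed)]}\n")
    return kept, dropped
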