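"""Hierarchical transcriptome alignment and weighted gene counting.

The aligner is exhaustive seed-and-extend under full-read Hamming distance:
a read is reported at every transcript offset where it matches with at most
``max_mismatches`` substitutions (forward strand by default), and suppressed
entirely when it has more than ``max_loci`` such placements. Candidate
offsets come from pigeonhole seeding -- the read is split into
``max_mismatches + 1`` chunks and each chunk's leading k-mer is looked up in
the index, so any placement within the mismatch budget is guaranteed to be
found; the result is identical to a brute-force scan of every offset of
every transcript.

Reads are aligned to the protein-coding tier first and only reads with zero
reportable coding hits are tried against the non-coding tier. A read mapping
to k distinct genes contributes 1/k to each (uniquely mapping reads count 1),
so per-sample totals are conserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .models import ProcessedRead, Tier, TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AlignPolicy:
    """Mismatch budget, multi-mapping cap and strand policy."""

    max_mismatches: int = 3
    max_loci: int = 100
    forward_only: bool = True
    seed_length: int = 25  # minimum insert length accepted by the aligner

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_loci < 1:
            raise ValueError("max_loci must be >= 1")
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One placement of an insert on a transcript (0-based 5' offset)."""

    transcript_id: str
    position: int
    mismatches: int
    strand: str = "+"


class TranscriptIndex:
    """Exact k-mer index over one reference tier.

    ``k`` is the internal seed size used for candidate generation; it is
    deliberately small so that pigeonhole seeding stays exhaustive for the
    shortest accepted inserts.
    """

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        tier: Tier | str | None = None,
        k: int = 6,
    ) -> None:
        if tier is not None:
            tier = Tier(tier)
            transcripts = [t for t in transcripts if t.tier is tier]
            if not transcripts:
                raise ValueError(f"no transcripts in tier {tier.value!r}")
        if not transcripts:
            raise ValueError("no transcripts to index")
        ids = [t.transcript_id for t in transcripts]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dup}")
        self.k = k
        self.tier = tier
        self.ids: list[str] = ids
        self.gene_ids: list[str] = [t.gene_id for t in transcripts]
        self.seqs: list[np.ndarray] = [
            np.frombuffer(t.sequence.encode(), dtype=np.uint8) for t in transcripts
        ]
        kmap: dict[bytes, list[tuple[int, int]]] = {}
        for ti, arr in enumerate(self.seqs):
            raw = arr.tobytes()
            for pos in range(len(raw) - k + 1):
                kmap.setdefault(raw[pos : pos + k], []).append((ti, pos))
        self._kmap = kmap

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Exact occurrences of a k-mer of the index's seed size."""
        if len(kmer) != self.k:
            raise ValueError(f"lookup expects a {self.k}-mer, got length {len(kmer)}")
        return [(self.ids[ti], pos) for ti, pos in self._kmap.get(kmer.encode(), [])]

    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs)


def build_index(
    transcripts: Sequence[TranscriptModel], tier: Tier | str, k: int = 6
) -> TranscriptIndex:
    """Index the transcripts of one tier (errors if the tier is empty)."""
    return TranscriptIndex(transcripts, tier=tier, k=k)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignResult:
    status: str  # mapped | unmapped | suppressed | too_short_for_seed
    hits: tuple[AlignmentHit, ...] = ()


def _candidate_offsets(ins: bytes, index: TranscriptIndex, n_chunks: int) -> set[tuple[int, int]]:
    """Pigeonhole candidates: (transcript_idx, start_offset) pairs."""
    L = len(ins)
    k = index.k
    chunk = L // n_chunks
    cands: set[tuple[int, int]] = set()
    if chunk >= k:
        for i in range(n_chunks):
            off = i * chunk
            for ti, pos in index._kmap.get(ins[off : off + k], []):
                start = pos - off
                if 0 <= start <= len(index.seqs[ti]) - L:
                    cands.add((ti, start))
    else:  # read too short for pigeonhole seeding: scan every offset
        for ti, seq in enumerate(index.seqs):
            for start in range(len(seq) - L + 1):
                cands.add((ti, start))
    return cands


def _hits_oriented(
    insert: str, index: TranscriptIndex, max_mismatches: int, strand: str
) -> list[AlignmentHit]:
    ins = insert.encode()
    arr = np.frombuffer(ins, dtype=np.uint8)
    L = len(arr)
    hits = []
    for ti, start in sorted(_candidate_offsets(ins, index, max_mismatches + 1)):
        mm = int(np.count_nonzero(index.seqs[ti][start : start + L] != arr))
        if mm <= max_mismatches:
            hits.append(AlignmentHit(index.ids[ti], start, mm, strand))
    return hits


def align_read(insert: str, index: TranscriptIndex, policy: AlignPolicy = AlignPolicy()) -> AlignResult:
    """All placements of the insert within the mismatch budget, or a
    suppression/rejection flag.

    Equivalent to Hamming-scanning every offset of every indexed transcript.
    """
    insert = insert.upper()
    if len(insert) < policy.seed_length:
        return AlignResult("too_short_for_seed")
    hits = _hits_oriented(insert, index, policy.max_mismatches, "+")
    if not policy.forward_only:
        rc = insert.translate(_COMPLEMENT)[::-1]
        hits += _hits_oriented(rc, index, policy.max_mismatches, "-")
        hits.sort(key=lambda h: (h.transcript_id, h.position, h.strand))
    if not hits:
        return AlignResult("unmapped")
    if len(hits) > policy.max_loci:
        return AlignResult("suppressed")
    return AlignResult("mapped", tuple(hits))


def has_hit(insert: str, index: TranscriptIndex, max_mismatches: int) -> bool:
    """Does the insert align anywhere within the budget? (early exit)"""
    ins = insert.upper().encode()
    arr = np.frombuffer(ins, dtype=np.uint8)
    L = len(arr)
    for ti, start in _candidate_offsets(ins, index, max_mismatches + 1):
        if np.count_nonzero(index.seqs[ti][start : start + L] != arr) <= max_mismatches:
            return True
    return False


def brute_force_hits(
    insert: str, transcripts: Sequence[TranscriptModel], max_mismatches: int
) -> list[AlignmentHit]:
    """Reference scan of every offset of every transcript (forward strand)."""
    arr = np.frombuffer(insert.upper().encode(), dtype=np.uint8)
    L = len(arr)
    hits = []
    for t in transcripts:
        seq = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        if len(seq) < L:
            continue
        windows = sliding_window_view(seq, L)
        mism = (windows != arr[None, :]).sum(axis=1)
        for start in np.nonzero(mism <= max_mismatches)[0]:
            hits.append(AlignmentHit(t.transcript_id, int(start), int(mism[start])))
    return hits


# ---------------------------------------------------------------------------
# Hierarchical assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Where one read ended up in the coding-then-noncoding hierarchy."""

    read_id: str
    category: str  # coding | noncoding | unmapped
    hits: tuple[AlignmentHit, ...] = ()
    suppressed: bool = False
    insert_len: int = 0


def hierarchical_assign(
    read: ProcessedRead,
    coding_index: TranscriptIndex,
    noncoding_index: TranscriptIndex | None,
    policy: AlignPolicy = AlignPolicy(),
) -> Assignment:
    """Coding-tier alignment first; the non-coding tier is attempted only
    when the coding tier yields zero reportable hits."""
    L = len(read.insert)
    res = align_read(read.insert, coding_index, policy)
    if res.status == "mapped":
        return Assignment(read.read_id, "coding", res.hits, insert_len=L)
    suppressed = res.status == "suppressed"
    if noncoding_index is not None and res.status in ("unmapped", "suppressed"):
        res2 = align_read(read.insert, noncoding_index, policy)
        if res2.status == "mapped":
            return Assignment(read.read_id, "noncoding", res2.hits, insert_len=L)
        suppressed = suppressed or res2.status == "suppressed"
    return Assignment(read.read_id, "unmapped", suppressed=suppressed, insert_len=L)


class AssignmentCache:
    """Memoized hierarchical assignment keyed by insert sequence."""

    def __init__(
        self,
        coding_index: TranscriptIndex,
        noncoding_index: TranscriptIndex | None,
        policy: AlignPolicy = AlignPolicy(),
    ) -> None:
        self.coding_index = coding_index
        self.noncoding_index = noncoding_index
        self.policy = policy
        self._cache: dict[str, Assignment] = {}

    def assign(self, read: ProcessedRead) -> Assignment:
        cached = self._cache.get(read.insert)
        if cached is None:
            cached = hierarchical_assign(
                read, self.coding_index, self.noncoding_index, self.policy
            )
            self._cache[read.insert] = cached
        if cached.read_id != read.read_id:
            cached = Assignment(
                read.read_id, cached.category, cached.hits, cached.suppressed, cached.insert_len
            )
        return cached

    def assign_all(self, reads: Iterable[ProcessedRead]) -> list[Assignment]:
        return [self.assign(r) for r in reads]


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def distinct_genes(assignment: Assignment, gene_map: Mapping[str, str]) -> list[str]:
    genes: list[str] = []
    for h in assignment.hits:
        if h.transcript_id not in gene_map:
            raise KeyError(f"hit references unknown transcript {h.transcript_id!r}")
        g = gene_map[h.transcript_id]
        if g not in genes:
            genes.append(g)
    return genes


def weight_counts(
    assignments: Sequence[Assignment],
    gene_map: Mapping[str, str],
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """One sample's gene counts: each mapped read spreads weight 1/k over the
    k distinct genes it hits, so the column total equals the number of
    mapped, non-suppressed reads."""
    totals: dict[str, float] = {}
    for a in assignments:
        if not a.hits:
            continue
        gs = distinct_genes(a, gene_map)
        w = 1.0 / len(gs)
        for g in gs:
            totals[g] = totals.get(g, 0.0) + w
    if genes is None:
        genes = sorted(set(gene_map.values()))
    return pd.Series([totals.get(g, 0.0) for g in genes], index=pd.Index(genes, name="gene_id"))


def transcript_weight_counts(
    assignments: Sequence[Assignment], transcript_ids: Sequence[str] | None = None
) -> pd.Series:
    """Per-transcript counts under the same 1/k rule over distinct transcripts."""
    totals: dict[str, float] = {}
    for a in assignments:
        if not a.hits:
            continue
        txs = list(dict.fromkeys(h.transcript_id for h in a.hits))
        w = 1.0 / len(txs)
        for t in txs:
            totals[t] = totals.get(t, 0.0) + w
    if transcript_ids is None:
        transcript_ids = sorted(totals)
    return pd.Series(
        [totals.get(t, 0.0) for t in transcript_ids],
        index=pd.Index(transcript_ids, name="transcript_id"),
    )


def assignments_table(
    assignments: Sequence[Assignment], gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-read log: category, number of distinct genes hit, gene list."""
    rows = []
    for a in assignments:
        gs = distinct_genes(a, gene_map) if a.hits else []
        rows.append(
            {
                "read_id": a.read_id,
                "category": a.category,
                "suppressed": a.suppressed,
                "k": len(gs),
                "genes": ",".join(gs),
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "category", "suppressed", "k", "genes"])


def hits_table(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Per-hit table for QC/profiles; each read's hits share weight
    1/(number of hits)."""
    rows = []
    for a in assignments:
        if not a.hits:
            continue
        w = 1.0 / len(a.hits)
        for h in a.hits:
            rows.append(
                {
                    "read_id": a.read_id,
                    "transcript_id": h.transcript_id,
                    "position": h.position,
                    "length": a.insert_len,
                    "mismatches": h.mismatches,
                    "weight": w,
                }
            )
    return pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "position", "length", "mismatches", "weight"]
    )


def reads_breakdown(
    assignments: Sequence[Assignment], n_contaminant: int = 0
) -> dict[str, float]:
    """Proportions over {contaminant, coding, noncoding, unmapped} for one
    sample (contaminant removals happen upstream, so their count is passed
    in). Proportions sum to 1."""
    counts = {"contaminant": n_contaminant, "coding": 0, "noncoding": 0, "unmapped": 0}
    for a in assignments:
        counts[a.category] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("reads_breakdown on zero reads")
    return {k: v / total for k, v in counts.items()}
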