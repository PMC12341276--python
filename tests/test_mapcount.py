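"""Aligner and counting tests, anchored by an independent brute-force
Hamming-scan oracle implemented here in the test module."""
import numpy as np
import pytest

from ribolite.models import ProcessedRead, Tier, TranscriptModel
from ribolite.mapcount import (
    AlignPolicy,
    Assignment,
    AlignmentHit,
    TranscriptIndex,
    align_read,
    build_index,
    hierarchical_assign,
    reads_breakdown,
    weight_counts,
)


def naive_hits(insert: str, transcripts, max_mismatches: int):
    """Oracle: Hamming distance at every offset of every transcript."""
    out = set()
    for t in transcripts:
        for start in range(len(t.sequence) - len(insert) + 1):
            window = t.sequence[start : start + len(insert)]
            mm = sum(1 for a, b in zip(window, insert) if a != b)
            if mm <= max_mismatches:
                out.add((t.transcript_id, start, mm))
    return out


def random_transcripts(rng, n, length_range=(60, 300), tier=Tier.CODING):
    out = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        length -= length % 3
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if tier is Tier.CODING:
            seq = seq[:9] + "ATG" + seq[12:-6] + "AAATAA"
            out.append(
                TranscriptModel(f"t{i}", f"g{i}", tier, seq, cds_start=9, cds_end=len(seq) - 3)
            )
        else:
            out.append(TranscriptModel(f"t{i}", f"g{i}", tier, seq))
    return out


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


def test_index_rejects_duplicates_and_empty_tier(rng):
    ts = random_transcripts(rng, 2)
    with pytest.raises(ValueError, match="duplicate"):
        TranscriptIndex(ts + [ts[0]])
    with pytest.raises(ValueError, match="noncoding"):
        build_index(ts, Tier.NONCODING)


def test_index_lookup_matches_naive_substring_scan(rng):
    ts = random_transcripts(rng, 3)
    idx = build_index(ts, Tier.CODING, k=6)
    for t in ts:
        for start in range(0, len(t.sequence) - 6, 7):
            kmer = t.sequence[start : start + 6]
            expected = {
                (u.transcript_id, p)
                for u in ts
                for p in range(len(u.sequence) - 5)
                if u.sequence[p : p + 6] == kmer
            }
            assert set(idx.lookup(kmer)) == expected


def test_index_prefix_lookup_returns_position_zero(rng):
    t = random_transcripts(rng, 1)[0]
    idx = TranscriptIndex([t])
    assert (t.transcript_id, 0) in idx.lookup(t.sequence[: idx.k])


# ---------------------------------------------------------------------------
# Alignment vs oracle
# ---------------------------------------------------------------------------


def test_align_read_equals_brute_force_oracle(rng):
    """Seeded alignment must equal the all-offsets Hamming scan for every
    read and every mismatch budget 0-3."""
    transcripts = random_transcripts(rng, 12, (80, 400))
    idx = TranscriptIndex(transcripts)
    reads = []
    for _ in range(60):
        t = transcripts[int(rng.integers(len(transcripts)))]
        L = int(rng.integers(25, 31))
        start = int(rng.integers(0, len(t.sequence) - L + 1))
        insert = list(t.sequence[start : start + L])
        for pos in rng.choice(L, size=int(rng.integers(0, 5)), replace=False):
            insert[pos] = "ACGT"[int(rng.integers(4))]
        reads.append("".join(insert))
    for mm in range(4):
        policy = AlignPolicy(max_mismatches=mm, max_loci=10_000)
        for insert in reads:
            res = align_read(insert, idx, policy)
            got = {(h.transcript_id, h.position, h.mismatches) for h in res.hits}
            assert got == naive_hits(insert, transcripts, mm)


def test_align_read_max_loci_suppression_boundary():
    unit = "ACGTACGTACGTACGTACGTACGTAC"  # 26-mer
    t = TranscriptModel("rep", "rep", Tier.NONCODING, "ACGT" * 40)
    idx = TranscriptIndex([t])
    n_hits = len(naive_hits(unit, [t], 0))
    assert n_hits > 1
    at_cap = align_read(unit, idx, AlignPolicy(max_mismatches=0, max_loci=n_hits))
    assert at_cap.status == "mapped" and len(at_cap.hits) == n_hits
    over_cap = align_read(unit, idx, AlignPolicy(max_mismatches=0, max_loci=n_hits - 1))
    assert over_cap.status == "suppressed" and not over_cap.hits


def test_align_read_rejects_short_inserts(rng):
    idx = TranscriptIndex(random_transcripts(rng, 1))
    assert align_read("ACGTACGT", idx, AlignPolicy()).status == "too_short_for_seed"


def test_four_mismatches_is_unmapped(rng):
    transcripts = random_transcripts(rng, 3, (200, 300))
    idx = TranscriptIndex(transcripts)
    t = transcripts[0]
    insert = list(t.sequence[20:48])
    for pos in (0, 7, 14, 27):
        insert[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[insert[pos]]
    res = align_read("".join(insert), idx, AlignPolicy(max_mismatches=3))
    oracle = naive_hits("".join(insert), transcripts, 3)
    assert {(h.transcript_id, h.position, h.mismatches) for h in res.hits} == oracle


# ---------------------------------------------------------------------------
# Hierarchy and counting
# ---------------------------------------------------------------------------


@pytest.fixture
def two_tier(rng):
    coding = random_transcripts(rng, 3, (120, 240), Tier.CODING)
    noncoding = random_transcripts(rng, 2, (120, 240), Tier.NONCODING)
    # shared sequence present in both tiers
    shared = coding[0].sequence[30:58]
    nc_seq = noncoding[0].sequence[:60] + shared + noncoding[0].sequence[60:]
    noncoding[0] = TranscriptModel("t0", "g0", Tier.NONCODING, nc_seq)
    coding_idx = TranscriptIndex(coding)
    noncoding_idx = TranscriptIndex(
        [TranscriptModel(f"nc{t.transcript_id}", f"ncg{t.gene_id}", t.tier, t.sequence) for t in noncoding]
    )
    return coding, noncoding, coding_idx, noncoding_idx, shared


def test_hierarchical_prefers_coding(two_tier):
    coding, noncoding, cidx, nidx, shared = two_tier
    a = hierarchical_assign(ProcessedRead("r0", shared, "A" * 8), cidx, nidx)
    assert a.category == "coding"
    assert all(h.transcript_id in {t.transcript_id for t in coding} for h in a.hits)


def test_hierarchical_noncoding_and_unmapped(two_tier, rng):
    coding, noncoding, cidx, nidx, _ = two_tier
    nc_only = noncoding[1].sequence[10:38]
    a = hierarchical_assign(ProcessedRead("r1", nc_only, "A" * 8), cidx, nidx)
    assert a.category == "noncoding"
    nothing = "".join(rng.choice(list("ACGT"), size=28))
    b = hierarchical_assign(ProcessedRead("r2", nothing, "A" * 8), cidx, nidx)
    assert b.category == "unmapped"


def test_weight_counts_fractional_rule():
    hits_one_gene = tuple(AlignmentHit(f"t{i}", 0, 0) for i in range(3))
    gene_map = {"t0": "gA", "t1": "gA", "t2": "gA", "t3": "gB"}
    a1 = Assignment("r1", "coding", hits_one_gene, insert_len=28)
    counts = weight_counts([a1], gene_map)
    assert counts["gA"] == 1.0  # 3 transcripts, 1 gene -> full count
    a2 = Assignment("r2", "coding", (AlignmentHit("t0", 0, 0), AlignmentHit("t3", 5, 1)), insert_len=28)
    counts = weight_counts([a1, a2], gene_map)
    assert counts["gA"] == 1.5 and counts["gB"] == 0.5
    a3 = [Assignment(f"u{i}", "coding", (AlignmentHit("t3", 2, 0),), insert_len=28) for i in range(10)]
    counts = weight_counts(a3, gene_map)
    assert counts["gB"] == 10.0


def test_weight_counts_unknown_transcript_errors():
    with pytest.raises(KeyError, match="unknown transcript"):
        weight_counts([Assignment("r", "coding", (AlignmentHit("tX", 0, 0),))], {"t0": "g"})


def test_count_conservation_on_random_assignments(rng):
    transcripts = random_transcripts(rng, 10, (100, 200))
    gene_map = {t.transcript_id: t.gene_id for t in transcripts}
    idx = TranscriptIndex(transcripts)
    assignments = []
    for i in range(150):
        t = transcripts[int(rng.integers(10))]
        L = 28
        start = int(rng.integers(0, len(t.sequence) - L + 1))
        res = align_read(t.sequence[start : start + L], idx, AlignPolicy())
        if res.hits:
            assignments.append(Assignment(f"r{i}", "coding", res.hits, insert_len=L))
    counts = weight_counts(assignments, gene_map)
    assert counts.sum() == pytest.approx(len(assignments), abs=1e-9)


def test_reads_breakdown_sums_to_one():
    asn = [Assignment(f"r{i}", "coding", (AlignmentHit("t", 0, 0),)) for i in range(6)]
    asn += [Assignment("r6", "noncoding", (AlignmentHit("n", 0, 0),)),
            Assignment("r7", "unmapped")]
    props = reads_breakdown(asn, n_contaminant=2)
    assert props == pytest.approx(
        {"contaminant": 0.2, "coding": 0.6, "noncoding": 0.1, "unmapped": 0.1}
    )
    with pytest.raises(ValueError):
        reads_breakdown([], n_contaminant=0)
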