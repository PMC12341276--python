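"""Riboseq quality control: triplet periodicity, read-length distribution,
metagene profiles, and library-size-normalized transcript coverage.

All metrics are computed from raw 5' ends of ribosome-protected fragments
(no P-site offsetting is applied by default; a fixed offset can be passed).
Multi-mapped hits contribute their fractional alignment weight, consistent
with counting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .models import TranscriptModel


@dataclass(frozen=True)
class QCSummary:
    """Frame phasing and insert-length distribution of in-CDS 5' ends.

    With fractional (multi-map) weights the histogram stores weighted counts;
    they sum to ``n_reads_used`` exactly when all contributing reads map
    uniquely, and to the total contributing weight otherwise.
    """

    frame_fractions: tuple[float, float, float]
    length_histogram: dict[int, float]
    n_reads_used: int


@dataclass(frozen=True)
class MetageneProfile:
    """Mean transcript-normalized 5'-end density around a codon anchor."""

    anchor: str  # start_codon | stop_codon
    window: int
    values: np.ndarray  # length 2*window + 1
    n_transcripts: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


@dataclass(frozen=True)
class TranscriptProfile:
    """Per-position 5'-end coverage of one transcript in one sample."""

    transcript_id: str
    raw: np.ndarray
    normalization_factor: float
    aligned_read_total: int

    @property
    def normalized(self) -> np.ndarray:
        return self.raw / self.normalization_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.raw)),
                "raw": self.raw,
                "normalized": self.normalized,
            }
        )


def _cds_bounds(annotation: pd.DataFrame) -> dict[str, tuple[int, int]]:
    out = {}
    for _, row in annotation.iterrows():
        if row["tier"] == "coding":
            out[row["transcript_id"]] = (int(row["cds_start"]), int(row["cds_end"]))
    return out


def periodicity(
    hits: pd.DataFrame, annotation: pd.DataFrame, p_site_offset: int = 0
) -> QCSummary:
    """Fraction of in-CDS 5' ends in each reading frame, plus the length
    histogram of the contributing reads.

    The frame of a hit is ``(position + p_site_offset - cds_start) mod 3``.
    """
    cds = _cds_bounds(annotation)
    frame_w = np.zeros(3)
    length_hist: dict[int, float] = {}
    used_weight = 0.0
    for _, h in hits.iterrows():
        bounds = cds.get(h["transcript_id"])
        if bounds is None:
            continue
        start, end = bounds
        pos = int(h["position"]) + p_site_offset
        if not start <= pos < end:
            continue
        w = float(h["weight"])
        frame_w[(pos - start) % 3] += w
        length = int(h["length"])
        length_hist[length] = length_hist.get(length, 0.0) + w
        used_weight += w
    if used_weight == 0:
        raise ValueError("no hits with 5' ends inside a CDS")
    fractions = tuple(frame_w / used_weight)
    return QCSummary(
        frame_fractions=fractions,
        length_histogram=dict(sorted(length_hist.items())),
        n_reads_used=int(round(used_weight)),
    )


def metagene(
    hits: pd.DataFrame,
    annotation: pd.DataFrame,
    anchor: str = "start_codon",
    window: int = 30,
    min_hits: float = 1.0,
    transcript_lengths: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Average 5'-end density around the start or stop codon.

    Per eligible coding transcript (total hit weight >= ``min_hits``) the
    per-offset density is divided by the transcript's hit total, then offsets
    are averaged across transcripts; offsets falling outside a transcript are
    excluded from that transcript's contribution. The stop-codon anchor is
    the first nucleotide of the stop codon.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"anchor must be start_codon or stop_codon, got {anchor!r}")
    cds = _cds_bounds(annotation)
    sums = np.zeros(2 * window + 1)
    counts = np.zeros(2 * window + 1)
    n_transcripts = 0
    for tid, sub in hits.groupby("transcript_id"):
        bounds = cds.get(tid)
        if bounds is None:
            continue
        total = float(sub["weight"].sum())
        if total < min_hits:
            continue
        start, end = bounds
        anchor_pos = start if anchor == "start_codon" else end - 3
        per_pos = sub.groupby("position")["weight"].sum()
        tx_len = None if transcript_lengths is None else transcript_lengths.get(tid)
        n_transcripts += 1
        for i, off in enumerate(range(-window, window + 1)):
            pos = anchor_pos + off
            if pos < 0 or (tx_len is not None and pos >= tx_len):
                continue  # truncated at transcript bounds: excluded from the mean
            counts[i] += 1
            sums[i] += float(per_pos.get(pos, 0.0)) / total
    if n_transcripts == 0:
        raise ValueError("no eligible coding transcripts with sufficient hits")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return MetageneProfile(anchor=anchor, window=window, values=values, n_transcripts=n_transcripts)


def normalization_factor(library_sizes: Mapping[str, float], sample_id: str) -> float:
    """Library-size factor: sample total over the geometric mean of all
    sample totals (1.0 for a single sample)."""
    if sample_id not in library_sizes:
        raise KeyError(f"unknown sample {sample_id!r}")
    sizes = np.array(list(library_sizes.values()), dtype=float)
    if (sizes <= 0).any() or library_sizes[sample_id] <= 0:
        raise ValueError("library sizes must be positive")
    geo = math.exp(np.log(sizes).mean())
    return float(library_sizes[sample_id] / geo)


def transcript_profile(
    hits: pd.DataFrame,
    transcript: TranscriptModel,
    library_sizes: Mapping[str, float],
    sample_id: str,
) -> TranscriptProfile:
    """Per-position 5'-end counts on one transcript, scaled by the sample's
    library-size factor; the raw aligned-read total is reported alongside."""
    factor = normalization_factor(library_sizes, sample_id)
    raw = np.zeros(len(transcript.sequence))
    sub = hits[hits["transcript_id"] == transcript.transcript_id]
    for _, h in sub.iterrows():
        pos = int(h["position"])
        if not 0 <= pos < len(raw):
            raise ValueError(
                f"hit position {pos} outside transcript {transcript.transcript_id}"
            )
        raw[pos] += float(h["weight"])
    return TranscriptProfile(
        transcript_id=transcript.transcript_id,
        raw=raw,
        normalization_factor=factor,
        aligned_read_total=int(round(sub["weight"].sum())),
    )


def qc_summary_dict(summary: QCSummary) -> dict:
    return {
        "frame_fractions": list(summary.frame_fractions),
        "length_histogram": {str(k): v for k, v in summary.length_histogram.items()},
        "n_reads_used": summary.n_reads_used,
    }
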