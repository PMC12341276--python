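"""Synthetic transcriptome / count / FASTQ generator with planted ground truth.

The generator emulates a lysis-artifact study design: two assays (riboseq,
RNAseq) x two conditions x replicates, with designated gene classes carrying
planted log2 fold changes. ``depleted_target`` genes emulate cytoskeletal
mRNAs lost under the reference condition (recovered in condition B in both
assays, with a stronger riboseq response); ``membrane_enriched`` genes emulate
mitochondrial/ER-bound mRNAs enriched under the reference condition in both
assays equally.

Riboseq reads follow the library anatomy

    <3 nt untemplated prefix> <insert> <8 nt UMI> <3' adapter>

with RPF 5' ends placed at frame-0 CDS positions (an off-frame noise
probability is exposed), insert lengths in the nuclease-protected 28-30 nt
band, PCR duplicates as exact copies sharing (insert, UMI), and a configurable
contaminant (rRNA-like) read fraction. RNAseq reads are adapter-terminated
paired fragments without UMIs.

Every simulated read records its source transcript, and per-sample template
molecule counts are written alongside the FASTQ so that UMI collapsing and
counting can be checked exactly against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    STOP_CODONS,
    Tier,
    TranscriptModel,
    annotation_frame,
    write_annotation,
    write_transcripts_fasta,
)
from .difftrans import classify_flags

ADAPTER = "AGATCGGAAGAGCACACGTCTGAA"
RNASEQ_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
RNASEQ_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

GENE_CLASSES = ("background", "depleted_target", "membrane_enriched")
ASSAYS = ("riboseq", "rnaseq")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Planted effects (log2, condition B vs A). depleted_target responds in both
#: assays with a stronger riboseq change (translational + transcriptional,
#: same direction -> concordant/violet); membrane_enriched changes equally in
#: both assays (transcription/blue); background is null.
DEFAULT_PLANTED_LOG2FC: dict[str, dict[str, float]] = {
    "background": {"riboseq": 0.0, "rnaseq": 0.0},
    "depleted_target": {"riboseq": 3.5, "rnaseq": 1.5},
    "membrane_enriched": {"riboseq": -2.0, "rnaseq": -2.0},
}


def _default_classes() -> dict[str, int]:
    return {"background": 40, "depleted_target": 8, "membrane_enriched": 8}


def _default_lfc() -> dict[str, dict[str, float]]:
    return {c: dict(v) for c, v in DEFAULT_PLANTED_LOG2FC.items()}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    ``mean_expression`` is the NB mean template count per gene per sample in
    the reference condition; ``nb_dispersion`` the NB dispersion alpha
    (Var = mu + alpha mu^2). If ``reads_per_sample`` is set it overrides
    ``mean_expression`` so that the expected total template count per sample
    (mRNA + contaminant) matches it.
    """

    n_genes_per_class: dict[str, int] = field(default_factory=_default_classes)
    mean_expression: float = 200.0
    nb_dispersion: float = 0.05
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=_default_lfc)
    n_replicates: int = 3
    reads_per_sample: int | None = None
    pcr_duplication_rate: float = 0.3
    contaminant_fraction: float = 0.15
    insert_length_range: tuple[int, int] = (28, 30)
    untemplated_prefix_len: int = 3
    umi_len: int = 8
    adapter: str = ADAPTER
    frame0_prob: float = 1.0
    rna_fragment_range: tuple[int, int] = (30, 60)
    n_noncoding: int = 2
    conditions: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        for cls, n in self.n_genes_per_class.items():
            if cls not in GENE_CLASSES:
                raise ValueError(f"n_genes_per_class: unknown class {cls!r}")
            if n < 1:
                raise ValueError(f"n_genes_per_class[{cls}]: count must be >= 1, got {n}")
        if self.mean_expression <= 0:
            raise ValueError(f"mean_expression must be positive, got {self.mean_expression}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        for cls in self.n_genes_per_class:
            if cls not in self.planted_log2fc:
                raise ValueError(f"planted_log2fc missing class {cls!r}")
            for assay in ASSAYS:
                if assay not in self.planted_log2fc[cls]:
                    raise ValueError(f"planted_log2fc[{cls}] missing assay {assay!r}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.reads_per_sample is not None and self.reads_per_sample < 1:
            raise ValueError(f"reads_per_sample must be >= 1, got {self.reads_per_sample}")
        if not 0.0 <= self.pcr_duplication_rate < 1.0:
            raise ValueError(
                f"pcr_duplication_rate must be in [0, 1), got {self.pcr_duplication_rate}"
            )
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError(
                f"contaminant_fraction must be in [0, 1), got {self.contaminant_fraction}"
            )
        lo, hi = self.insert_length_range
        if not (20 <= lo <= hi <= 45):
            raise ValueError(f"insert_length_range must lie within [20, 45], got {lo, hi}")
        if self.untemplated_prefix_len < 0:
            raise ValueError("untemplated_prefix_len must be >= 0")
        if self.umi_len < 1:
            raise ValueError(f"umi_len must be >= 1, got {self.umi_len}")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be an ACGT string")
        if not 0.0 <= self.frame0_prob <= 1.0:
            raise ValueError(f"frame0_prob must be in [0, 1], got {self.frame0_prob}")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError(f"conditions must be two distinct labels, got {self.conditions}")

    @property
    def n_genes(self) -> int:
        return sum(self.n_genes_per_class.values())

    def effective_mean_expression(self) -> float:
        if self.reads_per_sample is None:
            return self.mean_expression
        mrna_total = self.reads_per_sample * (1.0 - self.contaminant_fraction)
        return mrna_total / self.n_genes

    def gene_classes(self) -> list[tuple[str, str]]:
        """Deterministic (gene_id, class) assignment."""
        out = []
        i = 0
        for cls in GENE_CLASSES:
            for _ in range(self.n_genes_per_class.get(cls, 0)):
                out.append((f"gene{i:04d}", cls))
                i += 1
        return out


@dataclass
class GroundTruth:
    """Planted per-gene effects and the regulatory class they imply."""

    genes: pd.DataFrame  # gene_id, class, true_log2fc_ribo, true_log2fc_rna, true_class_call

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Derive the per-gene truth table from the planted effect map.

    The class call applies the downstream classification rule to the planted
    pair with idealized flags: an assay is "significant" iff its planted
    log2fc is nonzero, and the TE flag is set iff the two planted effects
    differ.
    """
    config.validate()
    rows = []
    for gene_id, cls in config.gene_classes():
        lr = config.planted_log2fc[cls]["riboseq"]
        ln = config.planted_log2fc[cls]["rnaseq"]
        call = classify_flags(
            ribo_sig=lr != 0.0,
            rna_sig=ln != 0.0,
            te_sig=lr != ln,
            sign_ribo=float(np.sign(lr)),
            sign_rna=float(np.sign(ln)),
        )
        rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "true_log2fc_ribo": lr,
                "true_log2fc_rna": ln,
                "true_class_call": call,
            }
        )
    return GroundTruth(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: rRNA-like stand-ins for the contaminant tier (id, length).
_CONTAMINANT_SPECS = [("rRNA_18S_like", 1500), ("rRNA_28S_like", 2500), ("snoRNA_like", 300)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate a three-tier reference: one coding transcript per gene,
    rRNA-like contaminants, and a few non-coding transcripts.

    Coding transcripts have a 5' UTR, an ATG-initiated stop-terminated CDS
    free of internal in-frame stops, and a 3' UTR long enough that every
    frame-0 CDS position accommodates the longest simulated insert.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    transcripts: list[TranscriptModel] = []
    for gene_id, _cls in config.gene_classes():
        utr5 = _random_seq(rng, int(rng.integers(30, 61)))
        n_codons = int(rng.integers(100, 151))
        codons = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_NONSTOP_CODONS[i] for i in codons)
        cds += str(rng.choice(STOP_CODONS))
        utr3 = _random_seq(rng, int(rng.integers(60, 101)))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                tier=Tier.CODING,
                sequence=utr5 + cds + utr3,
                cds_start=len(utr5),
                cds_end=len(utr5) + len(cds),
            )
        )
    for name, length in _CONTAMINANT_SPECS:
        transcripts.append(
            TranscriptModel(
                transcript_id=name,
                gene_id=name,
                tier=Tier.CONTAMINANT,
                sequence=_random_seq(rng, length),
            )
        )
    for i in range(config.n_noncoding):
        gid = f"ncgene{i:03d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                tier=Tier.NONCODING,
                sequence=_random_seq(rng, int(rng.integers(400, 801))),
            )
        )
    return transcripts, annotation_frame(transcripts)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def sample_design(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: one row per (assay, condition, replicate)."""
    rows = []
    for assay in ASSAYS:
        short = "ribo" if assay == "riboseq" else "rna"
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{short}_{cond}_{rep}",
                        "assay": assay,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw NB-distributed per-gene template counts for every sample.

    Returns ``(counts, design)`` where counts is genes x samples. The planted
    log2 fold change of each gene's class is applied in the second condition.
    """
    config.validate()
    genes = truth.genes
    missing = set(g for g, _ in config.gene_classes()) - set(genes["gene_id"])
    if missing:
        raise ValueError(f"ground truth does not cover genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng([config.seed, 202])
    design = sample_design(config)
    base = config.effective_mean_expression()
    cols = {}
    for _, s in design.iterrows():
        lfc_col = "true_log2fc_ribo" if s["assay"] == "riboseq" else "true_log2fc_rna"
        lfc = genes[lfc_col].to_numpy(dtype=float)
        mean = base * np.where(s["condition"] == config.conditions[1], 2.0**lfc, 1.0)
        cols[s["sample_id"]] = _nb_draw(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes["gene_id"], name="gene_id"))
    return counts, design


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fastq_record(read_id: str, seq: str) -> str:
    return f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n"


@dataclass
class SimOutput:
    """File layout produced by :func:`simulate_fastq`."""

    outdir: Path
    fasta: Path
    annotation: Path
    design: Path
    counts: Path
    truth_genes: Path
    truth_templates: Path
    truth_reads: Path
    ribo_fastq: dict[str, Path]
    rna_fastq: dict[str, tuple[Path, Path]]


def _frame0_positions(t: TranscriptModel, insert_len: int) -> np.ndarray:
    stop = min(t.cds_end, len(t.sequence) - insert_len + 1)
    return np.arange(t.cds_start, stop, 3)


def simulate_fastq(
    counts: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
    outdir: str | Path,
    design: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    per_read_truth: bool = True,
) -> SimOutput:
    """Emit raw FASTQ for every sample plus reference and truth files.

    Riboseq samples get single-end reads with the full library anatomy and
    PCR duplicates (extra exact copies per template ~ Poisson(rate)); RNAseq
    samples get adapter-terminated paired fragments. Distinct template
    molecules are guaranteed distinct (insert, UMI) dedup keys within a
    sample, so UMI collapsing recovers template counts exactly.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = sample_design(config)
    if truth is None:
        truth = make_ground_truth(config)
    rng = np.random.default_rng([config.seed, 303])

    by_gene: dict[str, list[TranscriptModel]] = {}
    contaminants: list[TranscriptModel] = []
    for t in transcripts:
        if t.tier is Tier.CONTAMINANT:
            contaminants.append(t)
        elif t.tier is Tier.CODING:
            by_gene.setdefault(t.gene_id, []).append(t)
    if not contaminants:
        raise ValueError("transcriptome has no contaminant-tier transcripts")
    for g in counts.index:
        if g not in by_gene:
            raise ValueError(f"counts reference gene {g} with no coding transcript")

    lo, hi = config.insert_length_range
    lens = np.arange(lo, hi + 1)
    frame0 = {
        t.transcript_id: {int(l): _frame0_positions(t, int(l)) for l in lens}
        for ts in by_gene.values()
        for t in ts
    }

    ribo_paths: dict[str, Path] = {}
    rna_paths: dict[str, tuple[Path, Path]] = {}
    template_rows = []
    read_rows: list[tuple[str, str, str, int]] = []  # sample, read_id, transcript, pos

    for _, s in design.iterrows():
        sample = s["sample_id"]
        gene_counts = counts[sample]
        total_mrna = int(gene_counts.sum())
        cf = config.contaminant_fraction
        n_cont = int(round(total_mrna * cf / (1.0 - cf))) if cf > 0 else 0

        if s["assay"] == "riboseq":
            reads = _riboseq_sample_reads(
                sample, gene_counts, by_gene, contaminants, frame0, config, rng, read_rows
            )
            n_reads = len(reads)
            order = rng.permutation(n_reads)
            path = outdir / f"{sample}.fastq"
            with open(path, "w") as fh:
                for i in order:
                    fh.write(reads[i])
            ribo_paths[sample] = path
        else:
            reads1, reads2 = _rnaseq_sample_reads(
                sample, gene_counts, by_gene, contaminants, config, rng, read_rows
            )
            n_reads = len(reads1)
            order = rng.permutation(n_reads)
            p1 = outdir / f"{sample}_R1.fastq"
            p2 = outdir / f"{sample}_R2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for i in order:
                    f1.write(reads1[i])
                    f2.write(reads2[i])
            rna_paths[sample] = (p1, p2)
        template_rows.append(
            {
                "sample_id": sample,
                "n_templates_mrna": total_mrna,
                "n_templates_contaminant": n_cont,
                "n_reads": n_reads,
            }
        )

    fasta = outdir / "transcripts.fasta"
    annotation = outdir / "annotation.tsv"
    write_transcripts_fasta(list(transcripts), fasta)
    write_annotation(list(transcripts), annotation)
    design_path = outdir / "design.tsv"
    design.to_csv(design_path, sep="\t", index=False)
    counts_path = outdir / "true_gene_templates.tsv"
    counts.to_csv(counts_path, sep="\t")
    truth_genes = outdir / "truth_genes.tsv"
    truth.to_tsv(truth_genes)
    truth_templates = outdir / "truth_templates.tsv"
    pd.DataFrame(template_rows).to_csv(truth_templates, sep="\t", index=False)
    truth_reads = outdir / "truth_reads.tsv"
    if per_read_truth:
        pd.DataFrame(
            read_rows, columns=["sample_id", "read_id", "transcript_id", "position"]
        ).to_csv(truth_reads, sep="\t", index=False)
    return SimOutput(
        outdir=outdir,
        fasta=fasta,
        annotation=annotation,
        design=design_path,
        counts=counts_path,
        truth_genes=truth_genes,
        truth_templates=truth_templates,
        truth_reads=truth_reads,
        ribo_fastq=ribo_paths,
        rna_fastq=rna_paths,
    )


def _riboseq_sample_reads(
    sample: str,
    gene_counts: pd.Series,
    by_gene: Mapping[str, Sequence[TranscriptModel]],
    contaminants: Sequence[TranscriptModel],
    frame0: Mapping[str, Mapping[int, np.ndarray]],
    config: SimConfig,
    rng: np.random.Generator,
    read_rows: list,
) -> list[str]:
    lo, hi = config.insert_length_range
    seen_keys: set[tuple[str, str]] = set()
    reads: list[str] = []
    serial = 0

    def emit(insert: str, source: TranscriptModel, pos: int) -> None:
        nonlocal serial
        umi = _random_seq(rng, config.umi_len)
        while (insert, umi) in seen_keys:
            umi = _random_seq(rng, config.umi_len)
        seen_keys.add((insert, umi))
        prefix = "".join(rng.choice(["C", "G"], size=config.untemplated_prefix_len))
        seq = prefix + insert + umi + config.adapter
        n_copies = 1 + int(rng.poisson(config.pcr_duplication_rate))
        for _ in range(n_copies):
            serial += 1
            rid = f"{sample}.r{serial:07d}"
            reads.append(_fastq_record(rid, seq))
            read_rows.append((sample, rid, source.transcript_id, pos))

    for gene_id, n in gene_counts.items():
        txs = by_gene[gene_id]
        for _ in range(int(n)):
            t = txs[int(rng.integers(len(txs)))] if len(txs) > 1 else txs[0]
            length = int(rng.integers(lo, hi + 1))
            positions = frame0[t.transcript_id][length]
            if positions.size == 0:  # insert longer than usable CDS span: resample length
                length = lo
                positions = frame0[t.transcript_id][length]
            pos = int(positions[rng.integers(positions.size)])
            if rng.random() >= config.frame0_prob:
                shift = int(rng.integers(1, 3))
                if pos + shift + length <= len(t.sequence):
                    pos += shift
            emit(t.sequence[pos : pos + length], t, pos)

    total_mrna = int(gene_counts.sum())
    cf = config.contaminant_fraction
    n_cont = int(round(total_mrna * cf / (1.0 - cf))) if cf > 0 else 0
    for _ in range(n_cont):
        t = contaminants[int(rng.integers(len(contaminants)))]
        length = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(0, len(t.sequence) - length + 1))
        emit(t.sequence[pos : pos + length], t, pos)
    return reads


def _rnaseq_sample_reads(
    sample: str,
    gene_counts: pd.Series,
    by_gene: Mapping[str, Sequence[TranscriptModel]],
    contaminants: Sequence[TranscriptModel],
    config: SimConfig,
    rng: np.random.Generator,
    read_rows: list,
) -> tuple[list[str], list[str]]:
    lo, hi = config.rna_fragment_range
    reads1: list[str] = []
    reads2: list[str] = []
    serial = 0

    def emit(t: TranscriptModel) -> None:
        nonlocal serial
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(t.sequence))
        pos = int(rng.integers(0, len(t.sequence) - length + 1))
        frag = t.sequence[pos : pos + length]
        serial += 1
        rid = f"{sample}.r{serial:07d}"
        reads1.append(_fastq_record(rid, frag + RNASEQ_ADAPTER_R1))
        reads2.append(_fastq_record(rid, _revcomp(frag) + RNASEQ_ADAPTER_R2))
        read_rows.append((sample, rid, t.transcript_id, pos))

    for gene_id, n in gene_counts.items():
        txs = by_gene[gene_id]
        for _ in range(int(n)):
            t = txs[int(rng.integers(len(txs)))] if len(txs) > 1 else txs[0]
            emit(t)
    total_mrna = int(gene_counts.sum())
    cf = config.contaminant_fraction
    n_cont = int(round(total_mrna * cf / (1.0 - cf))) if cf > 0 else 0
    for _ in range(n_cont):
        emit(contaminants[int(rng.integers(len(contaminants)))])
    return reads1, reads2


def simulate(config: SimConfig, outdir: str | Path) -> SimOutput:
    """One-call simulation: transcriptome + truth + counts + FASTQ."""
    config.validate()
    transcripts, _ann = simulate_transcriptome(config)
    truth = make_ground_truth(config)
    counts, design = simulate_counts(truth, config)
    return simulate_fastq(counts, transcripts, config, outdir, design=design, truth=truth)
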