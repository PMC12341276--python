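"""End-to-end in-silico experiments: simulate -> preprocess -> map/count ->
QC -> differential tests -> classification -> set statistics.

Two experiment templates mirror a lysis-artifact study design:

* ``lysis_titration`` -- condition ST (reference) vs LT; cytoskeleton-like
  ``depleted_target`` genes are recovered in LT in both assays (riboseq more
  strongly), membrane-associated genes are enriched in ST in both assays.
* ``clarification`` -- clarified (reference) vs non-clarified lysate;
  ``depleted_target`` genes are recovered when centrifugation is omitted.

Every run writes a manifest with per-file SHA-256 hashes and a config
snapshot; deterministic stages reproduce identical fingerprints for
identical configs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import difftrans, mapcount, readprep, riboqc, setstats
from .models import Tier, read_transcripts
from .readprep import ReadStructure
from .mapcount import AlignPolicy
from .simdata import SimConfig, simulate

log = logging.getLogger("ribolite")

EXPERIMENTS = ("lysis_titration", "clarification")

_BIOTIN_TAG = "/5Biosg/"


# ---------------------------------------------------------------------------
# Packaged subtraction-oligo panel
# ---------------------------------------------------------------------------


def load_oligo_panel(path: str | Path | None = None) -> pd.DataFrame:
    """Load the human rRNA subtraction-oligo panel (name, target rRNA,
    1-based inclusive start/end on the rRNA, sequence with the 5' biotin tag
    stripped)."""
    if path is None:
        source = resources.files("ribolite").joinpath("data/rrna_subtraction_oligos.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["name", "rrna", "start", "end", "sequence"]
    if list(df.columns) != expected:
        raise ValueError(f"oligo panel must have columns {expected}, got {list(df.columns)}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"oligo panel row {i}: non-integer coordinates") from exc
        if not 1 <= start <= end:
            raise ValueError(f"oligo panel row {i}: invalid interval {start}-{end}")
        seq = str(row.sequence)
        if seq.startswith(_BIOTIN_TAG):
            seq = seq[len(_BIOTIN_TAG) :]
        if set(seq) - set("ACGT"):
            raise ValueError(f"oligo panel row {i}: non-ACGT sequence")
        if len(seq) != end - start + 1:
            raise ValueError(
                f"oligo panel row {i}: sequence length {len(seq)} does not match "
                f"interval {start}-{end}"
            )
        rows.append({"name": row.name, "rrna": row.rrna, "start": start, "end": end, "sequence": seq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one in-silico experiment."""

    experiment: str = "lysis_titration"
    seed: int = 0
    alpha: float = 0.05
    report_min_fold_change: float = 2.0
    report_max_padj: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)
    structure: ReadStructure = field(default_factory=ReadStructure)
    policy: AlignPolicy = field(default_factory=AlignPolicy)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            for key in ("insert_length_range", "rna_fragment_range", "conditions"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        structure = d.pop("structure", {})
        if isinstance(structure, dict):
            structure = ReadStructure(**structure)
        policy = d.pop("policy", {})
        if isinstance(policy, dict):
            policy = AlignPolicy(**policy)
        return cls(sim=sim, structure=structure, policy=policy, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def experiment_config(experiment: str, seed: int = 0, **overrides: Any) -> PipelineConfig:
    """Default configuration for one of the two experiment templates."""
    if experiment == "lysis_titration":
        sim = SimConfig(conditions=("ST", "LT"), seed=seed)
    elif experiment == "clarification":
        planted = {
            "background": {"riboseq": 0.0, "rnaseq": 0.0},
            "depleted_target": {"riboseq": 3.5, "rnaseq": 1.5},
            "membrane_enriched": {"riboseq": 0.0, "rnaseq": 0.0},
        }
        sim = SimConfig(conditions=("clarified", "nonclarified"), planted_log2fc=planted, seed=seed)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    sim_overrides = overrides.pop("sim", {})
    if sim_overrides:
        sim = dataclasses.replace(sim, **sim_overrides)
    return PipelineConfig(experiment=experiment, seed=seed, sim=sim, **overrides)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Per-run provenance: config snapshot, tool version and file hashes.

    The fingerprint covers config + hashes only, so re-running a
    deterministic configuration reproduces it even though the timestamp
    differs.
    """

    version: str
    timestamp: str
    config: dict[str, Any]
    files: dict[str, str]

    def fingerprint(self) -> str:
        payload = json.dumps({"config": self.config, "files": self.files}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "fingerprint": self.fingerprint(),
                    "config": self.config,
                    "files": self.files,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def collect(cls, config: PipelineConfig, outdir: Path) -> "Manifest":
        from . import __version__

        files = {}
        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                files[str(p.relative_to(outdir))] = _sha256(p)
        return cls(
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
            config=config.to_dict(),
            files=files,
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_experiment(config: PipelineConfig, outdir: str | Path) -> tuple[dict, Manifest]:
    """Run the full pipeline on simulated data; returns (summary, manifest).

    Writes counts, per-assay differential-expression tables, TE tests,
    regulatory classes, QC JSON, a summary JSON and the manifest under
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simdir = outdir / "sim"

    log.info("stage simulate: experiment=%s seed=%d", config.experiment, config.seed)
    sim = simulate(config.sim, simdir)
    transcripts = read_transcripts(sim.fasta, sim.annotation)
    design = pd.read_csv(sim.design, sep="\t")
    truth_genes = pd.read_csv(sim.truth_genes, sep="\t")
    truth_templates = pd.read_csv(sim.truth_templates, sep="\t").set_index("sample_id")

    contaminant_refs = [t for t in transcripts if t.tier is Tier.CONTAMINANT]
    coding_index = mapcount.build_index(transcripts, Tier.CODING)
    noncoding = [t for t in transcripts if t.tier is Tier.NONCODING]
    noncoding_index = mapcount.TranscriptIndex(noncoding) if noncoding else None
    contaminant_index = mapcount.TranscriptIndex(contaminant_refs)
    cache = mapcount.AssignmentCache(coding_index, noncoding_index, config.policy)
    gene_map = {t.transcript_id: t.gene_id for t in transcripts if t.tier is not Tier.CONTAMINANT}
    genes = sorted(set(gene_map.values()))
    tx_lengths = {t.transcript_id: len(t.sequence) for t in transcripts}

    counts_cols: dict[str, pd.Series] = {}
    accounting: dict[str, dict] = {}
    breakdowns: dict[str, dict] = {}
    dedup: dict[str, dict] = {}
    first_ribo_hits: pd.DataFrame | None = None

    for _, s in design.iterrows():
        sample = s["sample_id"]
        if s["assay"] == "riboseq":
            reads, rejections = readprep.parse_fastq(sim.ribo_fastq[sample], config.structure)
            kept, removed = _filter_contaminants_indexed(
                reads, contaminant_index, config.policy.max_mismatches
            )
            collapsed = readprep.collapse_umis(kept)
            assignments = cache.assign_all(collapsed)
            dedup[sample] = {
                "collapsed": len(collapsed),
                "true_templates_mrna": int(truth_templates.loc[sample, "n_templates_mrna"]),
            }
            breakdowns[sample] = mapcount.reads_breakdown(assignments, n_contaminant=len(removed))
            accounting[sample] = {
                "raw": len(reads) + sum(rejections.values()),
                "parsed": len(reads),
                "rejections": dict(rejections),
                "contaminant": len(removed),
                "collapsed": len(collapsed),
            }
            if first_ribo_hits is None:
                first_ribo_hits = mapcount.hits_table(assignments)
        else:
            reads = _load_rnaseq_mate1(sim.rna_fastq[sample][0], config.structure)
            kept, removed = _filter_contaminants_indexed(
                reads, contaminant_index, config.policy.max_mismatches
            )
            assignments = cache.assign_all(kept)
            breakdowns[sample] = mapcount.reads_breakdown(assignments, n_contaminant=len(removed))
            accounting[sample] = {
                "raw": len(reads),
                "parsed": len(reads),
                "contaminant": len(removed),
            }
        counts_cols[sample] = mapcount.weight_counts(assignments, gene_map, genes=genes)
        accounting[sample]["counted"] = float(counts_cols[sample].sum())
        log.info("stage mapcount: %s %s", sample, accounting[sample])

    counts = pd.DataFrame(counts_cols)
    counts.index.name = "gene_id"
    counts_path = outdir / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")

    log.info("stage qc")
    annotation = pd.read_csv(sim.annotation, sep="\t")
    qc_summary = riboqc.periodicity(first_ribo_hits, annotation)
    meta_start = riboqc.metagene(
        first_ribo_hits, annotation, "start_codon", window=30, transcript_lengths=tx_lengths
    )
    qc_payload = {
        "periodicity": riboqc.qc_summary_dict(qc_summary),
        "metagene_start": list(meta_start.values),
        "reads_breakdown": breakdowns,
    }
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc_payload, fh, indent=2, sort_keys=True)

    log.info("stage detest")
    ribo_res = difftrans.nb_fit_test(counts, design, "riboseq")
    rna_res = difftrans.nb_fit_test(counts, design, "rnaseq")
    te_res = difftrans.te_from_results(ribo_res, rna_res)
    classes = difftrans.classify_regulation(ribo_res, rna_res, te_res, alpha=config.alpha)
    ribo_res.to_csv(outdir / "de_riboseq.tsv", sep="\t", index=False)
    rna_res.to_csv(outdir / "de_rnaseq.tsv", sep="\t", index=False)
    te_res.to_csv(outdir / "te.tsv", sep="\t", index=False)
    classes.to_csv(outdir / "classes.tsv", sep="\t", index=False)

    log.info("stage classify/enrich")
    report_filter = difftrans.EnrichFilter(
        min_fold_change=config.report_min_fold_change,
        max_padj=config.report_max_padj,
        direction="up",
    )
    enriched_ribo = difftrans.filter_enriched(ribo_res, report_filter)
    enriched_rna = difftrans.filter_enriched(rna_res, report_filter)
    alpha = config.alpha
    up_both = {
        g
        for g in ribo_res["gene_id"]
        if _sig_up(ribo_res, g, alpha) and _sig_up(rna_res, g, alpha)
    }
    truth_by_class = truth_genes.groupby("class")["gene_id"].apply(set).to_dict()
    depleted_truth = truth_by_class.get("depleted_target", set())
    testable = set(ribo_res.loc[~ribo_res["untestable"], "gene_id"]) & set(
        rna_res.loc[~rna_res["untestable"], "gene_id"]
    )
    universe = testable | up_both | depleted_truth
    overlap = (
        setstats.overlap_enrichment(up_both, depleted_truth, universe)
        if up_both and depleted_truth
        else None
    )
    merged = classes.rename(columns={"class": "called_class"}).merge(truth_genes, on="gene_id")
    recovery = float((merged["called_class"] == merged["true_class_call"]).mean())
    ribo_lfc = ribo_res.set_index("gene_id")["log2fc"]
    mw = setstats.mann_whitney(
        [ribo_lfc[g] for g in sorted(depleted_truth) if g in ribo_lfc.index],
        [ribo_lfc[g] for g in sorted(truth_by_class.get("background", set())) if g in ribo_lfc.index],
    )

    recovered_depleted = sorted(up_both & depleted_truth)
    class_counts = classes["class"].value_counts().to_dict()
    summary = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_genes": int(len(truth_genes)),
        "class_counts": class_counts,
        "class_recovery_fraction": recovery,
        "depleted_truth_size": len(depleted_truth),
        "recovered_depleted_genes": recovered_depleted,
        "depleted_recovery_fraction": (
            len(recovered_depleted) / len(depleted_truth) if depleted_truth else None
        ),
        "enriched_in_b_riboseq": sorted(enriched_ribo),
        "enriched_in_b_rnaseq": sorted(enriched_rna),
        "overlap": dataclasses.asdict(overlap) if overlap else None,
        "mann_whitney_depleted_vs_background": dataclasses.asdict(mw),
        "frame_fractions": list(qc_summary.frame_fractions),
        "reads_accounting": accounting,
        "dedup_check": dedup,
        "mean_mrna_mapped_proportion": float(
            np.mean([b["coding"] for s, b in breakdowns.items() if s.startswith("ribo")])
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = Manifest.collect(config, outdir)
    manifest.to_json(outdir / "manifest.json")
    return summary, manifest


def _sig_up(res: pd.DataFrame, gene: str, alpha: float) -> bool:
    row = res.loc[res["gene_id"] == gene].iloc[0]
    return bool(row["padj"] < alpha and row["log2fc"] > 0)


def _filter_contaminants_indexed(reads, contaminant_index, max_mismatches):
    kept, removed = [], []
    for r in reads:
        if mapcount.has_hit(r.insert, contaminant_index, max_mismatches):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def _load_rnaseq_mate1(path: Path, structure: ReadStructure):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    from .models import ProcessedRead

    out = []
    with open(path) as fh:
        for title, seq, _q in FastqGeneralIterator(fh):
            trimmed = readprep.trim_adapter(seq, readprep.RNASEQ_ADAPTER_R1)
            if len(trimmed) >= structure.min_insert:
                out.append(ProcessedRead(read_id=title.split()[0], insert=trimmed, umi=""))
    return out
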