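"""End-to-end orchestration: simulate -> preprocess -> cluster -> consensus
-> call -> report, with one seed, stage accounting and reproducible outputs.

Every run writes a resolved-config snapshot (config.json), the stage
outputs (reads, UMI pairs, cluster map, per-cluster FASTQ, consensus
FASTA, variant table, report tables) and a summary.json whose read
accounting is conservative: every input read lands in exactly one of
{clustered, length_filtered, unoriented, umi_rejected, chimeric,
unassigned, below_depth}.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .consensus_align import (
    MoleculeConsensus,
    align_cluster,
    build_pileup,
    call_consensus,
    default_band_width,
)
from .mut_report import aggregate_rates, mutation_rate, mutation_spectrum, partition_by_sharing
from .preprocess import Read, UmiPair, preprocess_reads, umi_pairs_to_frame, default_min_length
from .primers import PrimerDesign, DEFAULT_DESIGN, design_for_reference
from .simdata import SimConfig, TruthManifest, simulate_dataset
from .umi_cluster import ClusterResult, build_molecule_clusters
from .variant_call import FilterConfig, Variant, apply_tiering, call_variants, variants_to_frame

logger = logging.getLogger("longumi")

#: bases of margin kept around the amplicon interior when trimming reads
TRIM_MARGIN = 6


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    outdir: str = "longumi_run"
    seed: int = 0
    # inputs: either simulate, or read these paths
    simulate: SimConfig | None = None
    reads_fastq: str | None = None
    reference_fasta: str | None = None
    # preprocessing
    min_length: int | None = None  # default: expected fragment length - 300
    orient_max_edit_fraction: float = 0.3
    max_flank_edit_fraction: float = 0.2
    umi_length_window: tuple[int, int] = (21, 27)
    # clustering
    lcs_threshold: float = 0.125
    min_depth: int = 20
    refine_centroids: bool = True
    # consensus
    band_width: int | None = None  # default: per-read |len diff| + 100
    # calling
    wildtype_max_support: float = 0.2
    retention_threshold: float = 0.8
    require_both_strands: bool = True
    substitutions_only: bool = False
    # outputs
    write_cluster_fastq: bool = True
    write_pileup_tsv: bool = False

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            wildtype_max_support=self.wildtype_max_support,
            retention_threshold=self.retention_threshold,
            require_both_strands=self.require_both_strands,
            substitutions_only=self.substitutions_only,
        )

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        d["umi_length_window"] = list(self.umi_length_window)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: str
    clusters: ClusterResult
    consensuses: list[MoleculeConsensus]
    variants: list[Variant]
    summary: dict
    manifest: TruthManifest | None = None
    outdir: Path = field(default_factory=lambda: Path("."))


def trim_to_insert(read: Read, pair: UmiPair, margin: int = TRIM_MARGIN) -> Read:
    """Cut an oriented read down to its amplicon interior (+/- margin)."""
    start = max(0, pair.insert_start - margin)
    end = min(len(read.bases), pair.insert_end + margin)
    return Read(
        read_id=read.read_id,
        bases=read.bases[start:end],
        qualities=list(read.qualities)[start:end],
        orientation=read.orientation,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; returns in-memory results and writes the run directory."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    # --- stage 0: inputs -------------------------------------------------
    manifest = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        reference, design, reads, manifest = simulate_dataset(sim)
        io.write_fasta(outdir / "reference.fasta", {"ref": reference})
        io.write_fastq(outdir / "reads.fastq", reads)
        io.write_json(outdir / "truth.json", manifest.to_json())
    elif config.reads_fastq and config.reference_fasta:
        reads = io.read_fastq(config.reads_fastq)
        reference = next(iter(io.read_fasta(config.reference_fasta).values()))
        design = design_for_reference(reference, DEFAULT_DESIGN)
    else:
        raise ValueError("config must request simulation or provide input paths")
    io.write_json(outdir / "config.json", config.to_json())
    logger.info("inputs: %d reads, %d bp reference (%.1fs)", len(reads), len(reference), time.time() - t0)

    # --- stage 1: preprocess --------------------------------------------
    t1 = time.time()
    min_length = (
        config.min_length
        if config.min_length is not None
        else default_min_length(design, len(reference))
    )
    pre = preprocess_reads(
        reads,
        design,
        min_length=min_length,
        max_edit_fraction=config.orient_max_edit_fraction,
        max_flank_edit_fraction=config.max_flank_edit_fraction,
        umi_length_window=config.umi_length_window,
    )
    io.write_tsv(outdir / "umi_pairs.tsv", umi_pairs_to_frame(pre.pairs))
    logger.info(
        "preprocess: %d/%d reads yielded UMI pairs (%.1fs)",
        len(pre.pairs), len(reads), time.time() - t1,
    )
    if not pre.pairs:
        raise RuntimeError("preprocess produced no UMI pairs; cannot cluster")

    # --- stage 2: cluster ------------------------------------------------
    t2 = time.time()
    clusters = build_molecule_clusters(
        pre.pairs,
        threshold=config.lcs_threshold,
        min_depth=config.min_depth,
        refine_centroids=config.refine_centroids,
    )
    cluster_rows = []
    for c in clusters.clusters:
        for rid in c.read_ids:
            cluster_rows.append({"read_id": rid, "cluster_id": c.cluster_id, "chimera_flag": False})
    for rid in clusters.chimeric_read_ids:
        cluster_rows.append({"read_id": rid, "cluster_id": "", "chimera_flag": True})
    io.write_tsv(outdir / "clusters.tsv", pd.DataFrame(cluster_rows))
    if config.write_cluster_fastq:
        cdir = outdir / "clusters"
        cdir.mkdir(exist_ok=True)
        for c in clusters.clusters:
            io.write_fastq(cdir / f"{c.cluster_id}.fastq", [pre.oriented_reads[r] for r in c.read_ids])
    logger.info(
        "cluster: %d molecules (depth >= %d), %d chimeric reads removed (%.1fs)",
        len(clusters.clusters), config.min_depth, len(clusters.chimeric_read_ids), time.time() - t2,
    )

    # --- stage 3: consensus ---------------------------------------------
    t3 = time.time()
    pairs_by_id = {p.read_id: p for p in pre.pairs}
    consensuses: list[MoleculeConsensus] = []
    consensus_fasta: dict[str, str] = {}
    for c in clusters.clusters:
        trimmed = [
            trim_to_insert(pre.oriented_reads[rid], pairs_by_id[rid]) for rid in c.read_ids
        ]
        alignments = align_cluster(trimmed, reference, config.band_width)
        columns = build_pileup(alignments, reference, {r.read_id: r for r in trimmed})
        cons = call_consensus(columns, cluster_id=c.cluster_id)
        consensuses.append(cons)
        consensus_fasta[c.cluster_id] = cons.sequence
        if config.write_pileup_tsv:
            _write_pileup_tsv(outdir / "pileup" / f"{c.cluster_id}.tsv", columns)
    if consensus_fasta:
        io.write_fasta(outdir / "consensus.fasta", consensus_fasta)
    logger.info("consensus: %d molecules polished (%.1fs)", len(consensuses), time.time() - t3)

    # --- stage 4: variants ----------------------------------------------
    t4 = time.time()
    fc = config.filter_config()
    variants: list[Variant] = []
    for cons in consensuses:
        variants.extend(apply_tiering(call_variants(cons, reference, fc), fc))
    vframe = variants_to_frame(variants)
    io.write_tsv(outdir / "variants.tsv", vframe)
    logger.info("call: %d variants (%.1fs)", len(variants), time.time() - t4)

    # --- stage 5: report -------------------------------------------------
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    reports = []
    for cons in consensuses:
        n = sum(v.cluster_id == cons.cluster_id for v in variants)
        reports.append(
            mutation_rate(n, coverage=len(reference), genome_length=len(reference),
                          cluster_id=cons.cluster_id)
        )
    io.write_tsv(
        report_dir / "molecule_rates.tsv",
        pd.DataFrame([dataclasses.asdict(r) for r in reports]),
    )
    subs = [v for v in variants if v.alt_allele in "ACGT"]
    io.write_tsv(report_dir / "spectrum.tsv", mutation_spectrum(subs, reference))
    if not vframe.empty:
        shared = partition_by_sharing(vframe)
        io.write_tsv(report_dir / "variants_sharing.tsv", shared)
        poly = shared.loc[shared["SHARING"] == "polymorphic", "SUPPORT"]
        hetero = shared.loc[shared["SHARING"] == "heteroplasmic", "SUPPORT"]
        if len(poly) >= 2 and len(hetero) >= 2:
            from .mut_report import compare_support_groups

            cmp_out = compare_support_groups(poly.tolist(), hetero.tolist())
            io.write_tsv(
                report_dir / "support_comparison.tsv",
                pd.DataFrame(
                    [
                        {"group": "polymorphic", "n": cmp_out.n_a,
                         "mean_support": cmp_out.mean_a, "sem": cmp_out.sem_a,
                         "p_value": cmp_out.p_value},
                        {"group": "heteroplasmic", "n": cmp_out.n_b,
                         "mean_support": cmp_out.mean_b, "sem": cmp_out.sem_b,
                         "p_value": cmp_out.p_value},
                    ]
                ),
            )

    summary = {
        "seed": config.seed,
        "reference_length": len(reference),
        "reads": {
            "input": pre.n_input,
            "length_filtered": pre.n_length_filtered,
            "unoriented": pre.n_unoriented,
            "umi_rejected": pre.n_umi_rejected,
            "chimeric": len(clusters.chimeric_read_ids),
            "unassigned": len(clusters.unassigned_read_ids),
            "below_depth": len(clusters.below_depth_read_ids),
            "clustered": sum(c.depth for c in clusters.clusters),
        },
        "clusters": {
            "n": len(clusters.clusters),
            "min_depth": config.min_depth,
            "mean_depth": (
                round(sum(c.depth for c in clusters.clusters) / len(clusters.clusters), 3)
                if clusters.clusters
                else 0.0
            ),
        },
        "variants": {
            "total": len(variants),
            "retained": sum(v.tier == "retained" for v in variants),
            "intermediate": sum(v.tier == "intermediate" for v in variants),
            "excluded": sum(v.tier == "excluded" for v in variants),
        },
        "mutation_rate": aggregate_rates(reports),
    }
    accounted = sum(summary["reads"].values()) - summary["reads"]["input"]
    if accounted != summary["reads"]["input"]:
        logger.warning(
            "stage accounting mismatch: %d accounted vs %d input",
            accounted, summary["reads"]["input"],
        )
    io.write_json(outdir / "summary.json", summary)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return PipelineResult(
        config=config,
        reference=reference,
        clusters=clusters,
        consensuses=consensuses,
        variants=variants,
        summary=summary,
        manifest=manifest,
        outdir=outdir,
    )


def _write_pileup_tsv(path: Path, columns) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for col in columns:
        row = {"position": col.reference_position, "ref": col.ref_base, "depth": col.depth}
        for allele in ("A", "C", "G", "T", "DEL"):
            row[allele] = col.counts[allele]
            row[f"{allele}_fwd"] = col.strand_counts["forward"][allele]
            row[f"{allele}_rev"] = col.strand_counts["reverse"][allele]
        rows.append(row)
    io.write_tsv(path, pd.DataFrame(rows))
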