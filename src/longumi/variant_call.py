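"""Per-molecule variant calling and support-fraction filtering.

A site becomes a candidate variant when the wild-type (reference) allele's
base-called support fraction drops below 0.2; the variant allele is the
consensus (plurality) allele. Candidates are then tiered: variants
supported on only one strand are excluded outright, variants with
base-called support >= 0.8 on both strands are retained, and everything in
between is intermediate (kept for manual inspection).

"Base-called support" is the fraction of the cluster's aligned reads
carrying the allele. The original workflow complements this with raw
signal-level support from the sequencer's current traces; no such signal
exists here, so an explicitly non-equivalent, quality-weighted proxy is
provided and labelled PROXY in every output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .consensus_align import (
    ConsensusColumn,
    MoleculeConsensus,
    plurality_allele,
    support_fraction,
)

RETAINED = "retained"
INTERMEDIATE = "intermediate"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class FilterConfig:
    """The fixed support-fraction thresholds of the calling stage."""

    wildtype_max_support: float = 0.2
    retention_threshold: float = 0.8
    require_both_strands: bool = True
    substitutions_only: bool = False


@dataclass(frozen=True)
class Variant:
    """A called difference from the reference on one molecule."""

    cluster_id: str
    position: int  # 1-based reference position
    ref_allele: str
    alt_allele: str
    base_called_support: float
    forward_support_reads: int
    reverse_support_reads: int
    proxy_quality_support: float | None = None
    tier: str = INTERMEDIATE


def proxy_quality_support(column: ConsensusColumn, allele: str) -> float:
    """Quality-weighted support: sum(1 - 10^(-q/10)) over supporting reads
    divided by the same sum over all reads. NOT a signal-level measure —
    a base-quality proxy only; equals the base-called support when all
    qualities are equal."""
    if column.depth < 1:
        raise ValueError("proxy support undefined for an empty column")
    if allele not in column.quality_weights:
        raise ValueError(f"unknown allele {allele!r}")
    total = sum(column.quality_weights.values())
    if total <= 0:
        return support_fraction(column, allele)
    return column.quality_weights[allele] / total


def call_variants(
    consensus: MoleculeConsensus,
    reference: str,
    filter_config: FilterConfig = FilterConfig(),
) -> list[Variant]:
    """Candidate variants of one molecule consensus vs the reference.

    A column is a candidate when the reference allele's support fraction is
    below ``wildtype_max_support`` and the plurality allele differs from
    the reference. Each candidate carries its base-called support and
    per-strand supporting read counts; tiers are not assigned here.
    """
    if not consensus.columns:
        raise ValueError("consensus has no pileup columns")
    if len(consensus.columns) != len(reference):
        raise ValueError("pileup columns do not match the reference length")
    variants: list[Variant] = []
    for col in consensus.columns:
        if support_fraction(col, col.ref_base) >= filter_config.wildtype_max_support:
            continue
        alt = plurality_allele(col)
        if alt == col.ref_base:
            continue
        if filter_config.substitutions_only and alt == "DEL":
            continue
        variants.append(
            Variant(
                cluster_id=consensus.cluster_id,
                position=col.reference_position,
                ref_allele=col.ref_base,
                alt_allele=alt,
                base_called_support=support_fraction(col, alt),
                forward_support_reads=col.strand_counts["forward"][alt],
                reverse_support_reads=col.strand_counts["reverse"][alt],
                proxy_quality_support=proxy_quality_support(col, alt),
            )
        )
    return variants


def apply_tiering(
    variants: Iterable[Variant],
    filter_config: FilterConfig = FilterConfig(),
) -> list[Variant]:
    """Assign retained / intermediate / excluded tiers.

    Single-strand variants (zero supporting reads on one orientation) are
    excluded when both strands are required; remaining variants are
    retained at support >= ``retention_threshold`` and intermediate below.
    """
    out = []
    for v in variants:
        single_strand = min(v.forward_support_reads, v.reverse_support_reads) == 0
        if filter_config.require_both_strands and single_strand:
            tier = EXCLUDED
        elif v.base_called_support >= filter_config.retention_threshold:
            tier = RETAINED
        else:
            tier = INTERMEDIATE
        out.append(replace(v, tier=tier))
    return out


def variants_to_frame(variants: Sequence[Variant], reference_name: str = "ref") -> pd.DataFrame:
    """VCF-like table (CHROM, POS, REF, ALT, CLUSTER, SUPPORT, FWD, REV,
    PROXY, TIER); POS is 1-based."""
    return pd.DataFrame(
        [
            {
                "CHROM": reference_name,
                "POS": v.position,
                "REF": v.ref_allele,
                "ALT": v.alt_allele,
                "CLUSTER": v.cluster_id,
                "SUPPORT": round(v.base_called_support, 6),
                "FWD": v.forward_support_reads,
                "REV": v.reverse_support_reads,
                "PROXY": None if v.proxy_quality_support is None else round(v.proxy_quality_support, 6),
                "TIER": v.tier,
            }
            for v in variants
        ],
        columns=["CHROM", "POS", "REF", "ALT", "CLUSTER", "SUPPORT", "FWD", "REV", "PROXY", "TIER"],
    )
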