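"""Banded semiglobal alignment, pileup and per-molecule consensus.

Each cluster's reads (trimmed to the amplicon interior) are aligned to the
reference under unit edit costs, semiglobally: the reference must be fully
spanned while read overhangs at either end are free. The dynamic program
is restricted to a diagonal band |i - j| <= band_width and is optimal
within the band; tie-breaking is deterministic (diagonal over gaps, and a
reference-consuming deletion over an insertion). Alignments are stacked
into per-position allele counts split by strand, and the consensus is the
plurality allele per column with ties resolved toward the reference.
Insertions are emitted when a single inserted string is supported by more
than half of the column's reads.

Majority voting across >= 20 independent reads is what pushes the ~15%
per-read error down to the 1e-4 consensus scale; homopolymer runs get no
special treatment and remain the weak spot, as for any base-space method.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import Read, FORWARD
from .util import phred_to_prob

_BIG = np.int32(1 << 28)
ALLELES = ("A", "C", "G", "T", "DEL")


@dataclass
class Alignment:
    """A read-vs-reference alignment as a list of (op, length, read_bases).

    Ops are 'match', 'mismatch', 'insertion' (read bases absent from the
    reference) and 'deletion' (reference bases absent from the read).
    ``read_start`` is the first aligned read position (leading read
    overhang is soft-clipped, not part of the ops).
    """

    read_id: str
    reference_start: int
    ops: list[tuple[str, int, str]]
    strand: str = FORWARD
    edit_distance: int = 0
    read_start: int = 0

    @property
    def reference_span(self) -> int:
        return sum(n for op, n, _ in self.ops if op in ("match", "mismatch", "deletion"))

    def cigar(self) -> str:
        sym = {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}
        return "".join(f"{n}{sym[op]}" for op, n, _ in self.ops)


@dataclass
class ConsensusColumn:
    """Per-reference-position allele counts, split by strand."""

    reference_position: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: {a: 0 for a in ALLELES})
    strand_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "forward": {a: 0 for a in ALLELES},
            "reverse": {a: 0 for a in ALLELES},
        }
    )
    insertions_after: dict[str, int] = field(default_factory=dict)
    quality_weights: dict[str, float] = field(default_factory=lambda: {a: 0.0 for a in ALLELES})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class MoleculeConsensus:
    cluster_id: str
    sequence: str
    columns: list[ConsensusColumn]
    mean_depth: float


def banded_align(
    read: Read | str,
    reference: str,
    band_width: int,
    strand: str | None = None,
) -> Alignment:
    """Semiglobal edit-distance alignment within a diagonal band.

    The reference is aligned end-to-end; leading/trailing read bases may be
    soft-clipped for free. Optimal within the band; raises ValueError when
    the band cannot connect the endpoints.
    """
    if isinstance(read, Read):
        bases, read_id = read.bases, read.read_id
        strand = strand or read.orientation
    else:
        bases, read_id = read, ""
    if strand not in (FORWARD, "reverse"):
        strand = FORWARD  # unresolved provenance counts as forward
    m, n = len(bases), len(reference)
    if band_width < 1 or n - m > band_width:
        raise ValueError("band too narrow to connect alignment endpoints")
    if n == 0:
        raise ValueError("empty reference")

    q = np.frombuffer(bases.encode(), dtype=np.uint8)
    t = np.frombuffer(reference.encode(), dtype=np.uint8)
    D = np.full((m + 1, n + 1), _BIG, dtype=np.int32)
    D[0, : min(n, band_width) + 1] = np.arange(min(n, band_width) + 1, dtype=np.int32)
    D[:, 0] = 0  # free leading read overhang (soft clip state)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        lo, hi = max(1, i - band_width), min(n, i + band_width)
        if lo > hi:
            continue
        prev = D[i - 1]
        # diagonal / vertical candidates on the band slice only
        cand = np.minimum(
            prev[lo - 1 : hi] + (t[lo - 1 : hi] != q[i - 1]), prev[lo : hi + 1] + 1
        )
        # horizontal (deletion) chains: row[j] = min_{k<=j} cand[k] + (j-k),
        # done as a prefix-min over cand[j] - j; the free clip column at
        # j = 0 seeds the chain only while it still touches the band
        vals = cand - idx[lo : hi + 1]
        if lo == 1:
            vals[0] = min(vals[0], 0)  # f(j=0) = 0 - 0
        np.minimum.accumulate(vals, out=vals)
        D[i, lo : hi + 1] = vals + idx[lo : hi + 1]

    ends = D[:, n].astype(np.int64)
    ends[np.abs(np.arange(m + 1) - n) > band_width] = _BIG
    best = int(ends.min())
    if best >= _BIG:
        raise ValueError("band too narrow to connect alignment endpoints")
    # on ties prefer the largest end row (fewest clipped trailing bases)
    best_i = int(np.nonzero(ends == best)[0][-1])

    ops_rev: list[tuple[str, str]] = []
    i, j = best_i, n
    while j > 0:
        here = D[i, j]
        if i > 0 and here == D[i - 1, j - 1] + (bases[i - 1] != reference[j - 1]):
            ops_rev.append(("match" if bases[i - 1] == reference[j - 1] else "mismatch", bases[i - 1]))
            i, j = i - 1, j - 1
        elif here == D[i, j - 1] + 1:
            ops_rev.append(("deletion", ""))
            j -= 1
        elif i > 0 and here == D[i - 1, j] + 1:
            ops_rev.append(("insertion", bases[i - 1]))
            i -= 1
        else:  # pragma: no cover - defensive
            raise AssertionError("traceback failed")

    ops: list[tuple[str, int, str]] = []
    for op, base in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            prev_op, prev_n, prev_b = ops[-1]
            ops[-1] = (prev_op, prev_n + 1, prev_b + base)
        else:
            ops.append((op, 1, base))
    edit = sum(length for op, length, _ in ops if op != "match")
    return Alignment(
        read_id=read_id,
        reference_start=0,
        ops=ops,
        strand=strand,
        edit_distance=edit,
        read_start=i,
    )


def default_band_width(read_length: int, reference_length: int, slack: int = 100) -> int:
    """Band policy: the length difference plus generous indel slack."""
    return abs(read_length - reference_length) + slack


def build_pileup(
    alignments: Iterable[Alignment],
    reference: str,
    reads_by_id: Mapping[str, Read] | None = None,
) -> list[ConsensusColumn]:
    """Stack alignments into per-position allele/strand counts.

    When the originating reads are supplied, per-observation quality
    weights 1 - 10**(-q/10) are accumulated alongside the counts (used
    only by the quality-weighted support proxy).
    """
    columns = [
        ConsensusColumn(reference_position=j + 1, ref_base=reference[j])
        for j in range(len(reference))
    ]
    for aln in alignments:
        quals: Sequence[int] | None = None
        if reads_by_id is not None and aln.read_id in reads_by_id:
            quals = reads_by_id[aln.read_id].qualities
        i, j = aln.read_start, aln.reference_start
        strand = aln.strand
        last_q = 15
        for op, length, read_bases in aln.ops:
            if op in ("match", "mismatch"):
                for k in range(length):
                    col = columns[j + k]
                    b = read_bases[k]
                    col.counts[b] += 1
                    col.strand_counts[strand][b] += 1
                    if quals is not None:
                        last_q = quals[i + k]
                        col.quality_weights[b] += float(phred_to_prob(last_q))
                i += length
                j += length
            elif op == "deletion":
                w = float(phred_to_prob(last_q))
                for k in range(length):
                    col = columns[j + k]
                    col.counts["DEL"] += 1
                    col.strand_counts[strand]["DEL"] += 1
                    col.quality_weights["DEL"] += w
                j += length
            else:  # insertion, keyed to the preceding reference position
                if j > 0:
                    col = columns[j - 1]
                    col.insertions_after[read_bases] = (
                        col.insertions_after.get(read_bases, 0) + 1
                    )
                i += length
    return columns


def support_fraction(column: ConsensusColumn, allele: str) -> float:
    """Fraction of the column's reads carrying `allele` (counts / depth)."""
    if allele not in ALLELES:
        raise ValueError(f"allele must be one of {ALLELES}")
    depth = column.depth
    if depth < 1:
        raise ValueError("support fraction undefined for an empty column")
    return column.counts[allele] / depth


def plurality_allele(column: ConsensusColumn) -> str:
    """Plurality allele of a column; ties break toward the reference."""
    top = max(column.counts.values())
    winners = [a for a in ALLELES if column.counts[a] == top]
    if column.ref_base in winners:
        return column.ref_base
    return winners[0]


def call_consensus(columns: Sequence[ConsensusColumn], cluster_id: str = "") -> MoleculeConsensus:
    """Plurality consensus over pileup columns.

    DEL winners omit the base; an insertion is emitted after a column when
    one inserted string is supported by more than 50% of the column's
    reads. Columns are preserved for support-fraction computations.
    """
    if any(col.depth < 1 for col in columns):
        raise ValueError("every column must have depth >= 1")
    out: list[str] = []
    for col in columns:
        allele = plurality_allele(col)
        if allele != "DEL":
            out.append(allele)
        if col.insertions_after:
            ins, count = max(col.insertions_after.items(), key=lambda kv: (kv[1], kv[0]))
            if count > col.depth / 2:
                out.append(ins)
    mean_depth = float(np.mean([col.depth for col in columns])) if columns else 0.0
    return MoleculeConsensus(
        cluster_id=cluster_id,
        sequence="".join(out),
        columns=list(columns),
        mean_depth=mean_depth,
    )


def align_cluster(
    reads: Sequence[Read],
    reference: str,
    band_width: int | None = None,
) -> list[Alignment]:
    """Align every read of a cluster to the reference (banded semiglobal)."""
    out = []
    for r in reads:
        bw = band_width or default_band_width(len(r.bases), len(reference))
        out.append(banded_align(r, reference, bw))
    return out


def alignments_to_sam(
    alignments: Iterable[Alignment],
    reference_name: str,
    reference_length: int,
    reads_by_id: Mapping[str, Read] | None = None,
) -> str:
    """Minimal SAM-format dump of alignments, for inspection in samtools."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{reference_name}\tLN:{reference_length}",
    ]
    for a in alignments:
        flag = 0 if a.strand == FORWARD else 16
        seq = "*"
        cigar = a.cigar()
        if a.read_start:
            cigar = f"{a.read_start}S" + cigar
        if reads_by_id is not None and a.read_id in reads_by_id:
            read = reads_by_id[a.read_id]
            seq = read.bases
            trailing = len(read.bases) - a.read_start - sum(
                n for op, n, _ in a.ops if op in ("match", "mismatch", "insertion")
            )
            if trailing > 0:
                cigar += f"{trailing}S"
        lines.append(
            "\t".join(
                [
                    a.read_id,
                    str(flag),
                    reference_name,
                    str(a.reference_start + 1),
                    "60",
                    cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    "*",
                    f"NM:i:{a.edit_distance}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
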