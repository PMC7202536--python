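"""Read filtering, orientation and UMI extraction.

Raw long reads carry the amplicon flanked by the two primer scaffolds:

    [5' synthetic code][UMI5][amplicon][revcomp(UMI3)][revcomp(3' code)]

with roughly half of the reads sequenced from the opposite strand. This
module (1) drops reads too short to be complete fragments, (2) orients each
read by locating both terminal scaffolds and reverse-complements the
reverse ones, and (3) extracts the two UMIs by fuzzy (semiglobal) matching
of the fixed flanks that bracket them: the 16-nt secondary bar-code on the
outside and the first 10 nt of the gene-specific tail on the inside. A
guanine-free UMI bracketed by G-containing anchors makes the flanks easy to
pin down even at long-read error rates.

Flank matching uses edlib's infix (semiglobal) search; per-side flank edit
fractions above ``max_flank_edit_fraction`` (default 0.2; located flanks are best-fit
alignments whose measured edit distance runs below the generative error
count, so this still passes typical reads at ~15% error while rejecting
scrambled or missing flanks) or UMI lengths outside ``umi_length_window`` (default 24 +/- 3)
reject the read. Real UMI quality control happens later, in clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib

from .primers import PrimerDesign, UMI_LENGTH
from .util import revcomp

FORWARD = "forward"
REVERSE = "reverse"
UNRESOLVED = "unresolved"

#: bases of slack allowed when searching for a scaffold/flank near a read end
_SEARCH_PAD = 50
#: inner flank anchor length (first bases of the gene-specific tail)
INNER_ANCHOR_LENGTH = 10

DEFAULT_MAX_FLANK_EDIT_FRACTION = 0.2
DEFAULT_UMI_LENGTH_WINDOW = (UMI_LENGTH - 3, UMI_LENGTH + 3)
DEFAULT_ORIENT_MAX_EDIT_FRACTION = 0.3


@dataclass
class Read:
    """One sequencing read with per-base qualities and provenance."""

    read_id: str
    bases: str
    qualities: Sequence[int]
    orientation: str = UNRESOLVED

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Read":
        return replace(
            self, bases=revcomp(self.bases), qualities=list(self.qualities)[::-1]
        )


@dataclass(frozen=True)
class UmiPair:
    """The two UMIs extracted from one oriented read.

    ``umi3`` is reported on the reverse-primer strand (the strand it was
    drawn on), so both UMIs are guanine-free when error-free.
    ``insert_start``/``insert_end`` delimit the amplicon interior of the
    oriented read (0-based half-open) for downstream alignment.
    """

    read_id: str
    umi5: str
    umi3: str
    flank_edit_5: int
    flank_edit_3: int
    orientation: str = FORWARD
    insert_start: int = 0
    insert_end: int = 0


@dataclass(frozen=True)
class UmiRejection:
    read_id: str
    reason: str


def filter_by_length(reads: Iterable[Read], min_length: int) -> list[Read]:
    """Keep reads of length >= ``min_length``, preserving input order."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [r for r in reads if len(r) >= min_length]


def default_min_length(design: PrimerDesign, amplicon_length: int) -> int:
    """Length cutoff: 300 bp shorter than the expected full fragment."""
    return max(0, design.expected_fragment_length(amplicon_length) - 300)


def _best_hit(query: str, target: str) -> tuple[int, int, int]:
    """(edit_distance, start, end_exclusive) of the best semiglobal match.

    Returns (large, -1, -1) when the target is shorter than useful.
    """
    if not target or not query:
        return (len(query) or 1, -1, -1)
    res = edlib.align(query, target, mode="HW", task="locations")
    start, end = res["locations"][0]
    if start is None:
        start = 0
    return res["editDistance"], start, end + 1


def orient_read(
    read: Read,
    design: PrimerDesign,
    max_edit_fraction: float = DEFAULT_ORIENT_MAX_EDIT_FRACTION,
) -> Read:
    """Resolve read orientation from the two terminal synthetic codes.

    A read is oriented only when both terminal scaffolds are found within
    the edit tolerance (reads must carry adapters on both ends); reverse
    reads are returned reverse-complemented so downstream stages see a
    single orientation. Anything else is flagged ``unresolved``.
    """
    code5 = design.forward.synthetic_code_5p
    code3 = design.reverse.synthetic_code_5p
    head = read.bases[: max(len(code5), len(code3)) + _SEARCH_PAD]
    tail = read.bases[-(max(len(code5), len(code3)) + _SEARCH_PAD) :]

    def _score(head_anchor: str, tail_anchor: str) -> tuple[bool, int]:
        ed_h, _, _ = _best_hit(head_anchor, head)
        ed_t, _, _ = _best_hit(tail_anchor, tail)
        ok = ed_h <= max_edit_fraction * len(head_anchor) and ed_t <= max_edit_fraction * len(
            tail_anchor
        )
        return ok, ed_h + ed_t

    ok_f, score_f = _score(code5, revcomp(code3))
    ok_r, score_r = _score(code3, revcomp(code5))

    if ok_f and (not ok_r or score_f < score_r):
        return replace(read, orientation=FORWARD)
    if ok_r and (not ok_f or score_r < score_f):
        return replace(read.reverse_complement(), orientation=REVERSE)
    return replace(read, orientation=UNRESOLVED)


def extract_umi_pair(
    oriented_read: Read,
    design: PrimerDesign,
    max_flank_edit_fraction: float = DEFAULT_MAX_FLANK_EDIT_FRACTION,
    umi_length_window: tuple[int, int] = DEFAULT_UMI_LENGTH_WINDOW,
) -> UmiPair | UmiRejection:
    """Locate the fixed flanks bracketing each UMI and cut out the interior.

    The per-side flank edit fraction pools the outer (secondary bar-code)
    and inner (gene-tail prefix) anchor edit distances over their combined
    length; sides above the threshold, out-of-window UMI lengths, or
    overlapping flanks reject the read with a reason code.
    """
    if oriented_read.orientation not in (FORWARD, REVERSE):
        return UmiRejection(oriented_read.read_id, "unoriented")
    bases = oriented_read.bases
    lo, hi = umi_length_window

    # --- 5' UMI ---------------------------------------------------------
    outer5 = design.forward.secondary_barcode
    inner5 = design.forward.gene_specific_3p[:INNER_ANCHOR_LENGTH]
    head = bases[: len(design.forward.synthetic_code_5p) + _SEARCH_PAD]
    ed5o, _, end5o = _best_hit(outer5, head)
    if end5o < 0:
        return UmiRejection(oriented_read.read_id, "flank5_missing")
    window5 = bases[end5o : end5o + hi + INNER_ANCHOR_LENGTH + 8]
    ed5i, s5i, _ = _best_hit(inner5, window5)
    if s5i < 0:
        return UmiRejection(oriented_read.read_id, "flank5_missing")
    umi5_start, umi5_end = end5o, end5o + s5i
    flank_edit_5 = ed5o + ed5i
    if flank_edit_5 > max_flank_edit_fraction * (len(outer5) + len(inner5)):
        return UmiRejection(oriented_read.read_id, "flank5_edit")
    if umi5_end <= umi5_start:
        return UmiRejection(oriented_read.read_id, "flank5_overlap")
    umi5 = bases[umi5_start:umi5_end]
    if not lo <= len(umi5) <= hi:
        return UmiRejection(oriented_read.read_id, "umi5_length")

    # --- 3' UMI (read tail holds revcomp(UMI3)) -------------------------
    outer3 = revcomp(design.reverse.secondary_barcode)
    inner3 = revcomp(design.reverse.gene_specific_3p[:INNER_ANCHOR_LENGTH])
    tail_len = len(design.reverse.synthetic_code_5p) + hi + INNER_ANCHOR_LENGTH + _SEARCH_PAD
    tail_off = max(0, len(bases) - tail_len)
    ed3o, s3o, _ = _best_hit(outer3, bases[tail_off:])
    if s3o < 0:
        return UmiRejection(oriented_read.read_id, "flank3_missing")
    s3o += tail_off
    win_start = max(0, s3o - (hi + INNER_ANCHOR_LENGTH + 8))
    ed3i, _, e3i = _best_hit(inner3, bases[win_start:s3o])
    if e3i < 0:
        return UmiRejection(oriented_read.read_id, "flank3_missing")
    umi3_start = win_start + e3i
    flank_edit_3 = ed3o + ed3i
    if flank_edit_3 > max_flank_edit_fraction * (len(outer3) + len(inner3)):
        return UmiRejection(oriented_read.read_id, "flank3_edit")
    if s3o <= umi3_start:
        return UmiRejection(oriented_read.read_id, "flank3_overlap")
    umi3 = revcomp(bases[umi3_start:s3o])
    if not lo <= len(umi3) <= hi:
        return UmiRejection(oriented_read.read_id, "umi3_length")

    return UmiPair(
        read_id=oriented_read.read_id,
        umi5=umi5,
        umi3=umi3,
        flank_edit_5=flank_edit_5,
        flank_edit_3=flank_edit_3,
        orientation=oriented_read.orientation,
        insert_start=umi5_end,
        insert_end=umi3_start,
    )


@dataclass
class PreprocessResult:
    """Outcome of length filter + orientation + UMI extraction on a batch."""

    pairs: list[UmiPair] = field(default_factory=list)
    oriented_reads: dict[str, Read] = field(default_factory=dict)
    rejections: list[UmiRejection] = field(default_factory=list)
    n_input: int = 0
    n_length_filtered: int = 0
    n_unoriented: int = 0
    n_umi_rejected: int = 0


def preprocess_reads(
    reads: Iterable[Read],
    design: PrimerDesign,
    min_length: int,
    max_edit_fraction: float = DEFAULT_ORIENT_MAX_EDIT_FRACTION,
    max_flank_edit_fraction: float = DEFAULT_MAX_FLANK_EDIT_FRACTION,
    umi_length_window: tuple[int, int] = DEFAULT_UMI_LENGTH_WINDOW,
) -> PreprocessResult:
    """Run the whole preprocessing stage over a read batch."""
    result = PreprocessResult()
    reads = list(reads)
    result.n_input = len(reads)
    kept = filter_by_length(reads, min_length)
    result.n_length_filtered = result.n_input - len(kept)
    for read in kept:
        oriented = orient_read(read, design, max_edit_fraction)
        if oriented.orientation == UNRESOLVED:
            result.n_unoriented += 1
            continue
        out = extract_umi_pair(
            oriented, design, max_flank_edit_fraction, umi_length_window
        )
        if isinstance(out, UmiRejection):
            result.n_umi_rejected += 1
            result.rejections.append(out)
            continue
        result.pairs.append(out)
        result.oriented_reads[oriented.read_id] = oriented
    return result


def umi_pairs_to_frame(pairs: Iterable[UmiPair]):
    """6+ column table of extracted UMI pairs (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": p.read_id,
                "umi5": p.umi5,
                "umi3": p.umi3,
                "flank_edit_5": p.flank_edit_5,
                "flank_edit_3": p.flank_edit_3,
                "orientation": p.orientation,
            }
            for p in pairs
        ]
    )
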