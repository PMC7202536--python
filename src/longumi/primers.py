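"""Barcoding-primer design records.

A barcoding primer has three regions, 5' to 3': a synthetic code (64-73 nt,
ending in a 16-nt secondary bar-code), a 24-nt random UMI drawn from the
H alphabet {A, C, T} (guanine-free, so that sequencing errors that introduce
a G are immediately recognisable), and a gene-specific tail (28-37 nt) that
anneals to the target. The matching synthetic primer is the first 29 nt of
the barcoding primer and is what drives the bulk of the amplification after
the barcoding primer has been diluted away.

The default forward/reverse designs shipped here target a mouse mtDNA
amplicon; for synthetic references, :func:`design_for_reference` keeps the
synthetic codes and swaps in gene tails copied from the reference ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .util import revcomp

UMI_LENGTH = 24
SYNTHETIC_PRIMER_LENGTH = 29
SECONDARY_BARCODE_LENGTH = 16

_UMI_RE = re.compile(r"^[ACT]{%d}$" % UMI_LENGTH)

# Default barcoding primers (5'->3', H = A/C/T), mouse mtDNA design.
DEFAULT_FORWARD_PRIMER = (
    "CCACTACTCACACACCAATTCCTCTCATTACCACGCACTACCTATTAGATGCTGATGACGCGCT"
    + "H" * UMI_LENGTH
    + "CTCCATTCTATGATCAGGATGAGCCTCAAACTCCAAA"
)
DEFAULT_REVERSE_PRIMER = (
    "CCCACACTACAAAACCCACTCATATACACTACACTCTATCAACATACTATCATGCGAGACTATCGCGA"
    + "H" * UMI_LENGTH
    + "GCCCATTTCTTCCCATTTCATTGGCTACACCTT"
)


@dataclass(frozen=True)
class PrimerSide:
    """One side (forward or reverse) of the dual-UMI primer design."""

    synthetic_code_5p: str
    umi_template: str
    gene_specific_3p: str

    def __post_init__(self):
        if len(self.umi_template) != UMI_LENGTH or set(self.umi_template) != {"H"}:
            raise ValueError("umi_template must be exactly %d 'H' positions" % UMI_LENGTH)
        if not 28 <= len(self.gene_specific_3p) <= 120:
            raise ValueError("gene-specific tail length out of range")
        if len(self.synthetic_code_5p) < SYNTHETIC_PRIMER_LENGTH:
            raise ValueError("synthetic code shorter than the synthetic primer")

    @property
    def synthetic_primer(self) -> str:
        """First 29 nt of the barcoding primer's 5' end."""
        return self.synthetic_code_5p[:SYNTHETIC_PRIMER_LENGTH]

    @property
    def secondary_barcode(self) -> str:
        """The 16 nt of synthetic code immediately upstream of the UMI."""
        return self.synthetic_code_5p[-SECONDARY_BARCODE_LENGTH:]

    @classmethod
    def from_primer(cls, primer: str) -> "PrimerSide":
        """Split a full barcoding-primer string on its 24-H UMI template."""
        idx = primer.find("H" * UMI_LENGTH)
        if idx < 0:
            raise ValueError("primer does not contain a %d-H UMI template" % UMI_LENGTH)
        return cls(
            synthetic_code_5p=primer[:idx],
            umi_template="H" * UMI_LENGTH,
            gene_specific_3p=primer[idx + UMI_LENGTH :],
        )


@dataclass(frozen=True)
class PrimerDesign:
    """The forward and reverse barcoding-primer sides of one amplicon design."""

    forward: PrimerSide
    reverse: PrimerSide

    @property
    def scaffold_length(self) -> int:
        """Total non-amplicon bases added to the fragment by both primers."""
        return (
            len(self.forward.synthetic_code_5p)
            + len(self.reverse.synthetic_code_5p)
            + 2 * UMI_LENGTH
        )

    def expected_fragment_length(self, amplicon_length: int) -> int:
        return amplicon_length + self.scaffold_length


DEFAULT_DESIGN = PrimerDesign(
    forward=PrimerSide.from_primer(DEFAULT_FORWARD_PRIMER),
    reverse=PrimerSide.from_primer(DEFAULT_REVERSE_PRIMER),
)


def is_valid_umi(umi: str) -> bool:
    """True iff `umi` is a 24-nt guanine-free (H-alphabet) string."""
    return bool(_UMI_RE.match(umi))


def design_to_file(design: PrimerDesign, path) -> None:
    """Write a design as a flat KEY=VALUE config file."""
    lines = []
    for side_name, side in (("forward", design.forward), ("reverse", design.reverse)):
        lines.append(f"{side_name}_synthetic_code_5p={side.synthetic_code_5p}")
        lines.append(f"{side_name}_umi_template={side.umi_template}")
        lines.append(f"{side_name}_gene_specific_3p={side.gene_specific_3p}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def design_from_file(path) -> PrimerDesign:
    """Read a design written by :func:`design_to_file`."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
    sides = {}
    for side in ("forward", "reverse"):
        sides[side] = PrimerSide(
            synthetic_code_5p=kv[f"{side}_synthetic_code_5p"],
            umi_template=kv[f"{side}_umi_template"],
            gene_specific_3p=kv[f"{side}_gene_specific_3p"],
        )
    return PrimerDesign(forward=sides["forward"], reverse=sides["reverse"])


def design_for_reference(
    reference: str,
    base: PrimerDesign = DEFAULT_DESIGN,
    forward_tail_length: int | None = None,
    reverse_tail_length: int | None = None,
) -> PrimerDesign:
    """Retarget a design to `reference` by copying its ends as gene tails.

    The synthetic codes (and hence synthetic primers and secondary bar-codes)
    are kept; the forward tail becomes the first bases of the reference and
    the reverse tail the reverse complement of its last bases, which is what
    a primer pair designed against this reference would look like.
    """
    ftl = forward_tail_length or len(base.forward.gene_specific_3p)
    rtl = reverse_tail_length or len(base.reverse.gene_specific_3p)
    if len(reference) < ftl + rtl:
        raise ValueError("reference shorter than the two gene tails")
    return PrimerDesign(
        forward=PrimerSide(base.forward.synthetic_code_5p, "H" * UMI_LENGTH, reference[:ftl]),
        reverse=PrimerSide(
            base.reverse.synthetic_code_5p, "H" * UMI_LENGTH, revcomp(reference[-rtl:])
        ),
    )
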