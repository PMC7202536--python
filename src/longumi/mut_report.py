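"""Mutation-rate, spectrum, synonymity and support-distribution analytics.

Operates on per-molecule variant tables. The per-molecule mutation rate is
the number of mutations divided by the molecule's aligned consensus
coverage (and optionally rescaled to mutations per genome); the mutational
spectrum gives, for each reference base, the proportion of its mutated
positions going to each alternative base; synonymity classifies coding
substitutions under the vertebrate mitochondrial genetic code (NCBI table
2 by default); and support-fraction groups (e.g. polymorphic vs
heteroplasmic variants) are compared with Welch's two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .util import revcomp
from .variant_call import Variant

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"

_SUBSTITUTIONS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


@dataclass(frozen=True)
class MoleculeReport:
    """Mutation burden of one molecule."""

    cluster_id: str
    n_mutations: int
    coverage: int
    rate_per_bp: float
    rate_per_genome: float


@dataclass(frozen=True)
class CdsRecord:
    """One coding region: 1-based inclusive coordinates, frame in {0,1,2}."""

    gene: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0
    genetic_code_id: int = 2  # vertebrate mitochondrial

    def __post_init__(self):
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.end < self.start:
            raise ValueError("end before start")


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    p_value: float


def mutation_rate(
    variants: Sequence[Variant] | int,
    coverage: int,
    genome_length: int | None = None,
    cluster_id: str = "",
) -> MoleculeReport:
    """Per-molecule mutation rate: mutations / coverage (and per genome).

    `variants` may be the molecule's variant list or a plain count.
    `genome_length` defaults to the coverage (for whole-amplicon runs the
    reference length), making rate_per_genome = expected mutations per
    reference copy.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    n = variants if isinstance(variants, int) else len(list(variants))
    if genome_length is None:
        genome_length = coverage
    rate = n / coverage
    return MoleculeReport(
        cluster_id=cluster_id,
        n_mutations=n,
        coverage=coverage,
        rate_per_bp=rate,
        rate_per_genome=rate * genome_length,
    )


def aggregate_rates(reports: Sequence[MoleculeReport]) -> dict:
    """Mean +/- SEM of the per-molecule rates."""
    rates = np.array([r.rate_per_bp for r in reports], dtype=float)
    return {
        "n_molecules": len(rates),
        "mean_rate_per_bp": float(rates.mean()) if len(rates) else float("nan"),
        "sem_rate_per_bp": float(stats.sem(rates)) if len(rates) > 1 else float("nan"),
        "mean_rate_per_genome": float(
            np.mean([r.rate_per_genome for r in reports])
        ) if len(rates) else float("nan"),
    }


def mutation_spectrum(
    variants: Iterable[Variant],
    reference: str,
) -> pd.DataFrame:
    """Proportional mutational spectrum over the 12 ordered substitutions.

    For each reference base, the (ref, alt) proportion is the number of
    ref>alt mutations divided by the number of mutated positions whose
    reference base is ref; mutated positions are counted once per
    (molecule, position). Rows for reference bases with no mutated
    positions are NaN.
    """
    counts = {key: 0 for key in _SUBSTITUTIONS}
    seen = set()
    for v in variants:
        if v.alt_allele not in "ACGT" or len(v.alt_allele) != 1:
            raise ValueError("mutation_spectrum expects substitution variants only")
        key = (v.cluster_id, v.position)
        if key in seen:
            continue
        seen.add(key)
        if reference and reference[v.position - 1] != v.ref_allele:
            raise ValueError("variant reference allele disagrees with the reference")
        counts[(v.ref_allele, v.alt_allele)] += 1
    rows = []
    for ref_base in "ACGT":
        total = sum(counts[(ref_base, a)] for a in "ACGT" if a != ref_base)
        for alt in "ACGT":
            if alt == ref_base:
                continue
            rows.append(
                {
                    "ref_base": ref_base,
                    "alt_base": alt,
                    "count": counts[(ref_base, alt)],
                    "proportion": counts[(ref_base, alt)] / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def classify_synonymity(
    variant: Variant,
    cds_annotation: Sequence[CdsRecord],
    reference: str,
) -> str:
    """Synonymous / nonsynonymous / noncoding status of a substitution.

    The codon is reconstructed from the reference using the CDS record's
    strand and frame and translated under its genetic code (vertebrate
    mitochondrial by default); equal amino acids mean synonymous.
    """
    pos = variant.position
    if not 1 <= pos <= len(reference):
        raise ValueError("variant position outside the reference")
    if variant.alt_allele not in "ACGT":
        return NONCODING  # indels are not classified
    for cds in cds_annotation:
        if not cds.start <= pos <= cds.end:
            continue
        table = CodonTable.unambiguous_dna_by_id[cds.genetic_code_id]
        if cds.strand == "+":
            offset = (pos - cds.start - cds.frame) % 3
            codon_start = pos - offset  # 1-based
            if codon_start < cds.start or codon_start + 2 > cds.end:
                return NONCODING  # partial codon at the CDS edge
            codon = reference[codon_start - 1 : codon_start + 2]
            mutated = list(codon)
            mutated[pos - codon_start] = variant.alt_allele
        else:
            offset = (cds.end - pos - cds.frame) % 3
            codon_end = pos + offset  # 1-based, first base of codon on + strand view
            if codon_end > cds.end or codon_end - 2 < cds.start:
                return NONCODING
            fwd = reference[codon_end - 3 : codon_end]
            mutated_fwd = list(fwd)
            mutated_fwd[pos - (codon_end - 2)] = variant.alt_allele
            codon = revcomp(fwd)
            mutated = list(revcomp("".join(mutated_fwd)))
        if reference[pos - 1] != variant.ref_allele:
            raise ValueError("variant reference allele disagrees with the reference")
        aa_ref = str(Seq("".join(codon)).translate(table=table.id))
        aa_alt = str(Seq("".join(mutated)).translate(table=table.id))
        return SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
    return NONCODING


def synonymity_table(
    variants: Iterable[Variant],
    cds_annotation: Sequence[CdsRecord],
    reference: str,
) -> pd.DataFrame:
    """Counts and proportions of synonymity classes over a variant set."""
    classes = [classify_synonymity(v, cds_annotation, reference) for v in variants]
    counts = pd.Series(classes).value_counts()
    coding = counts.get(SYNONYMOUS, 0) + counts.get(NONSYNONYMOUS, 0)
    rows = []
    for cls in (SYNONYMOUS, NONSYNONYMOUS, NONCODING):
        n = int(counts.get(cls, 0))
        rows.append(
            {
                "class": cls,
                "count": n,
                "proportion_of_coding": n / coding if coding and cls != NONCODING else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compare_support_groups(
    group_a_supports: Sequence[float],
    group_b_supports: Sequence[float],
) -> GroupComparison:
    """Mean, SEM and Welch two-sample t-test P between two support groups."""
    a = np.asarray(group_a_supports, dtype=float)
    b = np.asarray(group_b_supports, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(a.mean(), b.mean()):
        p = 1.0  # degenerate identical groups
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        n_b=len(b),
        p_value=p,
    )


def partition_by_sharing(
    variant_frame: pd.DataFrame,
    n_molecules: int | None = None,
) -> pd.DataFrame:
    """Label variants polymorphic (present in every molecule) vs heteroplasmic.

    Works on the VCF-like variant table; a (POS, REF, ALT) site is
    polymorphic when it appears in all `n_molecules` clusters (default:
    the number of distinct clusters in the table).
    """
    if variant_frame.empty:
        return variant_frame.assign(SHARING=pd.Series(dtype=str))
    if n_molecules is None:
        n_molecules = variant_frame["CLUSTER"].nunique()
    site_counts = variant_frame.groupby(["POS", "REF", "ALT"])["CLUSTER"].nunique()
    labels = variant_frame.apply(
        lambda row: "polymorphic"
        if site_counts[(row["POS"], row["REF"], row["ALT"])] >= n_molecules
        else "heteroplasmic",
        axis=1,
    )
    return variant_frame.assign(SHARING=labels)


def read_cds_gff3(path) -> list[CdsRecord]:
    """Read CDS lines from a GFF3 file (1-based inclusive coordinates).

    The genetic code is taken from a ``transl_table`` attribute when
    present, defaulting to the vertebrate mitochondrial table (2).
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.partition("=")[::2]
                for kv in (fields[8].split(";") if len(fields) > 8 else [])
                if kv
            )
            records.append(
                CdsRecord(
                    gene=attrs.get("ID", attrs.get("Parent", f"cds{len(records)}")),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                    frame=int(fields[7]) if fields[7] in "012" else 0,
                    genetic_code_id=int(attrs.get("transl_table", 2)),
                )
            )
    return records


def read_cds_table(path) -> list[CdsRecord]:
    """Read a 6-column CDS annotation TSV (gene, start, end, strand, frame,
    genetic_code_id); coordinates 1-based inclusive."""
    frame = pd.read_csv(path, sep="\t")
    return [
        CdsRecord(
            gene=str(r.gene),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            frame=int(r.frame),
            genetic_code_id=int(r.genetic_code_id),
        )
        for r in frame.itertuples()
    ]
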