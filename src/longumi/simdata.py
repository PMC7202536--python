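"""Synthetic amplicon, molecule and long-read simulator with ground truth.

The generator emulates the statistical structure the rest of the pipeline
assumes: a pool of template molecules each carrying its own mutation
pattern (plus optional shared polymorphisms), dual guanine-free 24-nt UMIs
embedded between the fixed primer scaffolds, PCR-jumping chimeras that
splice the 5' half of one molecule onto the 3' half of another, and noisy
ONT-style reads (independent per-base substitutions/insertions/deletions,
~15% combined by default) at a per-molecule depth drawn from a truncated
Poisson. Every read is recorded in a :class:`TruthManifest` so recovery can
be scored exactly.

Defaults are calibrated to the regime the pipeline targets: mutation rate
8e-4 /bp (mutator-mouse mtDNA scale), depth mean 42 reads/molecule with a
minimum-depth working point of 20, and 0.10/0.025/0.025 sub/ins/del rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import Read, FORWARD, REVERSE
from .primers import PrimerDesign, UMI_LENGTH, DEFAULT_DESIGN, design_for_reference
from .util import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_H_ALPHABET = np.frombuffer(b"ACT", dtype="S1")

#: Phred levels of the two-level quality model (correct base / injected error)
QUALITY_HIGH = 20
QUALITY_LOW = 7


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Rates are per base; ``depth_mean`` is the Poisson mean of reads per
    molecule, truncated below at ``depth_min``. Chimeras are late-PCR
    products and get their own (low) depth mean.
    """

    reference_length: int = 2000
    n_molecules: int = 100
    mutation_rate: float = 8e-4
    depth_mean: float = 42.0
    depth_min: int = 1
    sub_rate: float = 0.10
    ins_rate: float = 0.025
    del_rate: float = 0.025
    chimera_fraction: float = 0.05
    chimera_depth_mean: float = 2.0
    n_polymorphisms: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("error rates must be >= 0")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("combined error rate must be < 1")
        if not 0 <= self.chimera_fraction <= 1:
            raise ValueError("chimera_fraction must be in [0, 1]")
        if self.n_molecules < 1 or self.reference_length < 100:
            raise ValueError("need >= 1 molecule and a reference of >= 100 bp")


@dataclass
class TrueMolecule:
    """One template molecule of the simulated pool."""

    molecule_id: str
    umi5: str
    umi3: str
    mutations: list[tuple[int, str, str]]  # (1-based position, ref, alt)
    is_chimera: bool = False
    parent_ids: tuple[str, str] | tuple = ()
    breakpoint: int | None = None

    def sequence(self, reference: str) -> str:
        """The molecule's amplicon sequence (reference + its mutations)."""
        seq = list(reference)
        for pos, ref, alt in self.mutations:
            if seq[pos - 1] != ref:
                raise ValueError(f"mutation {pos}{ref}>{alt} disagrees with reference")
            seq[pos - 1] = alt
        return "".join(seq)


@dataclass
class TruthManifest:
    """Ground truth: molecules, planted polymorphisms, read provenance."""

    molecules: list[TrueMolecule]
    read_assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    polymorphic_positions: list[tuple[int, str, str]] = field(default_factory=list)

    def molecule(self, molecule_id: str) -> TrueMolecule:
        return next(m for m in self.molecules if m.molecule_id == molecule_id)

    def to_json(self) -> dict:
        return {
            "molecules": [asdict(m) for m in self.molecules],
            "read_assignments": {k: list(v) for k, v in self.read_assignments.items()},
            "polymorphic_positions": [list(p) for p in self.polymorphic_positions],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TruthManifest":
        mols = []
        for m in obj["molecules"]:
            m = dict(m)
            m["mutations"] = [tuple(t) for t in m["mutations"]]
            m["parent_ids"] = tuple(m.get("parent_ids") or ())
            mols.append(TrueMolecule(**m))
        return cls(
            molecules=mols,
            read_assignments={k: tuple(v) for k, v in obj["read_assignments"].items()},
            polymorphic_positions=[tuple(p) for p in obj.get("polymorphic_positions", [])],
        )


def generate_reference(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random A/C/G/T reference of exactly `length` bases at the given GC."""
    if length < 100:
        raise ValueError("reference length must be >= 100")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _draw_umi(rng: np.random.Generator) -> str:
    return rng.choice(_H_ALPHABET, size=UMI_LENGTH).tobytes().decode()


def _draw_unique_umi(rng: np.random.Generator, seen: set[str]) -> str:
    # 3^24 possibilities; collisions are negligible but resampled anyway
    while True:
        umi = _draw_umi(rng)
        if umi not in seen:
            seen.add(umi)
            return umi


def _mutate_position(reference: str, pos0: int, rng: np.random.Generator) -> tuple[int, str, str]:
    ref = reference[pos0]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return (pos0 + 1, ref, alt)


def generate_molecules(reference: str, config: SimConfig) -> tuple[list[TrueMolecule], list[tuple[int, str, str]]]:
    """Draw the molecule pool: unique UMI pairs and per-molecule mutations.

    Mutation counts are Binomial(reference_length, mutation_rate) with
    positions uniform without replacement. If ``config.n_polymorphisms`` is
    positive, that many shared variants are planted in every molecule
    (polymorphic sites), on top of each molecule's private (heteroplasmic)
    mutations. Returns (molecules, polymorphic_sites).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = len(reference)
    seen5: set[str] = set()
    seen3: set[str] = set()

    poly_positions = rng.choice(L, size=config.n_polymorphisms, replace=False) if config.n_polymorphisms else []
    polymorphisms = sorted(_mutate_position(reference, int(p), rng) for p in poly_positions)
    poly_pos_set = {p for p, _, _ in polymorphisms}

    molecules = []
    for i in range(config.n_molecules):
        n_mut = rng.binomial(L, config.mutation_rate)
        private = []
        if n_mut:
            candidates = rng.choice(L, size=n_mut, replace=False)
            private = [
                _mutate_position(reference, int(p), rng)
                for p in candidates
                if int(p) + 1 not in poly_pos_set
            ]
        molecules.append(
            TrueMolecule(
                molecule_id=f"mol{i:04d}",
                umi5=_draw_unique_umi(rng, seen5),
                umi3=_draw_unique_umi(rng, seen3),
                mutations=sorted(private + polymorphisms),
            )
        )
    return molecules, polymorphisms


def inject_chimeras(
    molecules: list[TrueMolecule],
    chimera_fraction: float,
    breakpoint_policy: str = "uniform",
    seed: int = 0,
    reference_length: int | None = None,
) -> list[TrueMolecule]:
    """Append PCR-jumping chimeras splicing two distinct parent molecules.

    Each chimera takes the 5' segment (UMI5 and upstream mutations) of one
    parent and the 3' segment (UMI3 and downstream mutations) of another at
    a random internal breakpoint. round(chimera_fraction * n) chimeras are
    added; the input molecules are returned unchanged at the head.
    """
    if breakpoint_policy != "uniform":
        raise ValueError("only the uniform breakpoint policy is implemented")
    parents = [m for m in molecules if not m.is_chimera]
    if chimera_fraction > 0 and len(parents) < 2:
        raise ValueError("need at least 2 non-chimeric parents to form chimeras")
    n_chim = round(chimera_fraction * len(parents))
    if n_chim == 0:
        return list(molecules)
    if reference_length is None:
        reference_length = max(
            (p for m in parents for p, _, _ in m.mutations), default=1000
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out = list(molecules)
    for k in range(n_chim):
        i, j = rng.choice(len(parents), size=2, replace=False)
        p1, p2 = parents[int(i)], parents[int(j)]
        bp = int(rng.integers(1, reference_length))  # split index, 0-based
        muts = [m for m in p1.mutations if m[0] <= bp] + [
            m for m in p2.mutations if m[0] > bp
        ]
        out.append(
            TrueMolecule(
                molecule_id=f"chimera{k:04d}",
                umi5=p1.umi5,
                umi3=p2.umi3,
                mutations=sorted(muts),
                is_chimera=True,
                parent_ids=(p1.molecule_id, p2.molecule_id),
                breakpoint=bp,
            )
        )
    return out


def _corrupt(
    template: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Apply independent per-base errors; two-level qualities by error status."""
    n = len(template)
    tarr = np.frombuffer(template.encode(), dtype="S1")
    u = rng.random(n)
    deleted = u < config.del_rate
    substituted = (~deleted) & (u < config.del_rate + config.sub_rate)
    inserted = rng.random(n) < config.ins_rate  # insertion after each base

    out: list[bytes] = []
    quals: list[int] = []
    shift = rng.integers(1, 4, size=n)  # substitution offset in base ring
    ins_base = rng.choice(_BASES, size=n)
    base_index = {b: i for i, b in enumerate(_BASES)}
    for i in range(n):
        if deleted[i]:
            pass
        elif substituted[i]:
            b = _BASES[(base_index[tarr[i]] + shift[i]) % 4]
            out.append(b)
            quals.append(QUALITY_LOW)
        else:
            out.append(tarr[i])
            quals.append(QUALITY_HIGH)
        if inserted[i]:
            out.append(ins_base[i])
            quals.append(QUALITY_LOW)
    return b"".join(out).decode(), quals


def simulate_reads(
    molecules: list[TrueMolecule],
    reference: str,
    primer_design: PrimerDesign | None,
    config: SimConfig,
) -> tuple[list[Read], TruthManifest]:
    """Emit noisy reads of each molecule's full barcoded template.

    The template is ``code5 + UMI5 + amplicon + revcomp(UMI3) +
    revcomp(code3)``; each molecule yields ``depth ~ Poisson(depth_mean)``
    reads (truncated at ``depth_min``; chimeras use ``chimera_depth_mean``
    truncated at 1), each independently corrupted and emitted on a random
    strand. Deterministic for a fixed ``config.seed``.
    """
    if primer_design is None:
        primer_design = design_for_reference(reference, DEFAULT_DESIGN)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    reads: list[Read] = []
    manifest = TruthManifest(molecules=list(molecules))
    code5 = primer_design.forward.synthetic_code_5p
    code3 = primer_design.reverse.synthetic_code_5p
    for mol in molecules:
        template = code5 + mol.umi5 + mol.sequence(reference) + revcomp(mol.umi3) + revcomp(code3)
        mean = config.chimera_depth_mean if mol.is_chimera else config.depth_mean
        dmin = 1 if mol.is_chimera else max(1, config.depth_min)
        # left-truncated Poisson, realised by clamping; at the default
        # settings the clamp mass is negligible
        depth = max(dmin, int(rng.poisson(mean)))
        for j in range(depth):
            bases, quals = _corrupt(template, config, rng)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            read_id = f"{mol.molecule_id}/{j}"
            if strand == REVERSE:
                bases, quals = revcomp(bases), quals[::-1]
            reads.append(Read(read_id=read_id, bases=bases, qualities=quals))
            manifest.read_assignments[read_id] = (mol.molecule_id, strand)
    return reads, manifest


def simulate_dataset(
    config: SimConfig,
    reference: str | None = None,
    primer_design: PrimerDesign | None = None,
    gc_fraction: float = 0.45,
) -> tuple[str, PrimerDesign, list[Read], TruthManifest]:
    """Convenience wrapper: reference -> molecules -> chimeras -> reads."""
    if reference is None:
        reference = generate_reference(config.reference_length, gc_fraction, config.seed)
    if primer_design is None:
        primer_design = design_for_reference(reference, DEFAULT_DESIGN)
    molecules, polymorphisms = generate_molecules(reference, config)
    molecules = inject_chimeras(
        molecules, config.chimera_fraction, "uniform", config.seed, len(reference)
    )
    reads, manifest = simulate_reads(molecules, reference, primer_design, config)
    manifest.polymorphic_positions = polymorphisms
    return reference, primer_design, reads, manifest
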