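# Methods

`longumi` reconstructs individual long DNA molecules from noisy
amplicon reads by exploiting dual molecular barcodes: every template
molecule receives a random 24-nt unique molecular identifier (UMI) at its
5' end and an independent one at its 3' end before amplification, so all
reads descending from one molecule share a UMI pair. Aggregating reads by
that pair and taking a per-position majority vote cancels independent PCR
and sequencing errors while preserving the molecule's true mutations, and
the *pair* structure additionally exposes PCR-jumping chimeras as reads
whose two UMIs belong to different molecules.

## Primer design and read anatomy

Each barcoding primer is `[synthetic code (64-73 nt)][24-nt UMI from the
H alphabet {A,C,T}][gene-specific tail (28-37 nt)]`. The UMI is
guanine-free by construction; the 16 nt of synthetic code immediately
upstream of it (the "secondary bar-code") and the first 10 nt of the gene
tail are G-containing fixed anchors, which makes the G-free interior easy
to delimit even on error-rich reads. A full-length read is therefore

    [5' code][UMI5][amplicon][revcomp(UMI3)][revcomp(3' code)]

on the forward strand, or its reverse complement. The shipped default
design targets a mouse mtDNA amplicon; `design_for_reference` retargets
it to any reference by copying the reference ends as gene tails.

## Pipeline stages

**Length filter.** Reads shorter than the expected fragment length minus
300 bp are dropped. The expected length is computed from the design and
the reference (scaffolds + UMIs + amplicon), so the rule scales from the
2-kb desk profile to 13.7-kb fragments unchanged.

**Orientation.** Both terminal synthetic codes must be found (edlib
semiglobal search, edit fraction <= 0.3 per scaffold); reads matching the
reverse configuration are reverse-complemented, everything else is
excluded as unoriented. 0.3 sits far above the ~0.15 expected edit
fraction of a real scaffold copy and far below the ~0.5+ of an unrelated
sequence.

**UMI extraction.** Each UMI is cut out between the best semiglobal
matches of its outer (16-nt secondary bar-code) and inner (10-nt gene-tail
prefix) anchors. A side is rejected when its pooled anchor edit fraction
exceeds 0.2 or the interior length leaves the 24 +/- 3 window. The 0.2
default reflects that located flanks are *best-fit* alignments whose
measured distance runs two to three edits below the generative error
count; at the 15%-error study conditions ~68% of reads yield both UMIs
(cf. ~25% on the original real data), while a scrambled flank (~30%
corruption) is still rejected. Genuine UMI quality control happens in
clustering, not here.

**UMI clustering.** Distances between UMIs are metric LCS,
`1 - |LCS(a,b)| / max(|a|,|b|)` — a true metric on strings. Each side is
clustered greedily: distinct UMIs sorted by read support (ties
lexicographic) join the first centroid within 0.125, the threshold that
tolerates at most three differences on a 24-mer, else found a new
centroid. Because an error-free UMI copy is rare at 15% read error
(P ~ 0.85^24 ~ 0.02), the greedy seed is usually itself an errored copy;
clusters with support >= 3 are therefore re-centred on their
support-weighted medoid, medoids within 0.125 of a stronger medoid are
merged, and all UMIs are reassigned (two iterations). The 0.125 radius is
never widened.

**Molecule building and chimera removal.** A bipartite graph links 5' and
3' centroids co-occurring on reads. Each centroid's *dominant partner* is
the opposite-side centroid it shares the most reads with; mutually
dominant pairs define molecules, and any other centroid inherits the
molecule of its dominant partner (its reads overwhelmingly co-occur with
that partner). A read whose two sides resolve to two *different*
molecules links two real templates — the signature of PCR jumping — and
is flagged chimeric and removed; candidate clusters that are mostly
(>50%) chimera-flagged are dropped whole. Surviving clusters need >= 20
reads (`min_depth`), the working point at which majority voting reaches
the 1e-4 scale. Attrition through extraction and the fixed 0.125 radius
means a cluster typically retains ~55-65% of its molecule's raw reads, so
molecules near the raw-depth cutoff can fall under `min_depth`; analyses
that need a fixed amount of consensus sequence should simulate enough
molecules (the acceptance checks add whole batches until the measured
span is reached).

**Consensus.** Cluster reads are trimmed to the amplicon interior
(+/- 6 nt) using the extraction coordinates and aligned to the reference
with a banded semiglobal dynamic program under unit edit costs: the
reference is spanned end-to-end, read overhangs are free, and the DP is
exact within a diagonal band of half-width `|len(read) - len(ref)| + 100`
by default (~10 sigma of the indel random walk on a 2-kb read).
Tie-breaking is deterministic: diagonal over gaps, deletion over
insertion. Pileup columns count A/C/G/T/deletion per strand; insertions
are keyed to the preceding reference position. The consensus takes the
plurality allele per column (ties toward the reference), omits
majority-deletion columns and emits an insertion when one inserted string
is carried by more than half of the column's reads. At depth >= 20 and
independent ~15% errors the expected per-column majority error is far
below 1e-6; the realised weakness is homopolymer-adjacent indel wobble,
which depresses support fractions but rarely flips a plurality.

**Variant calling.** A column is a candidate variant when the reference
allele's base-called support (reads carrying it / column depth) falls
below 0.2; the alternative allele is the consensus allele. Candidates
with support on only one strand are excluded; candidates at support
>= 0.8 on both strands are retained; the rest are intermediate, kept for
manual review. Raw signal-level support is not available without
sequencer trace files, so a quality-weighted proxy
(sum of 1-10^(-q/10) over supporting reads / over all reads) is computed
instead and labelled PROXY in all outputs; it is a base-quality summary,
not a signal measure, and is never used by the filters.

**Reports.** Per-molecule mutation rate = called variants / aligned
consensus coverage ("coverage" is read as aligned consensus length; the
amplicon-length alternative would differ only at unaligned edges), with
`rate_per_genome = rate_per_bp * genome_length` (genome length defaults
to the reference length). The mutational spectrum gives, per reference
base, the proportion of its mutated positions (counted once per molecule
and position) going to each alternative base; rows renormalise after any
subset filter. Synonymity reconstructs the codon from reference, strand
and frame and translates under the record's genetic code (vertebrate
mitochondrial, table 2, by default). Support-fraction groups (e.g.
polymorphic sites — present in all molecules — vs heteroplasmic ones) are
compared with Welch's two-sample t-test, a deliberate choice where plain
"Student's t-test" would assume equal variances.

## Simulator

The generator is the package's definition of the study conditions.
Defaults: 2,000-bp reference (GC 0.45), 100 molecules, private mutations
at 8e-4/bp (Binomial positions, uniform alternative base — the
mutator-mouse mtDNA scale), optional shared polymorphisms planted in
every molecule, depth per molecule Poisson(42) (left-truncated, realised
as a clamp whose excess mass is negligible at these settings), per-base
errors 0.10 substitution / 0.025 insertion / 0.025 deletion (~15%
combined, the long-read regime), ~half of reads on the reverse strand,
and 5% chimeras splicing the 5' segment (UMI and upstream mutations) of
one molecule onto the 3' segment of another at a uniform internal
breakpoint. Chimeras are late-amplification products and get a low depth
(Poisson mean 2, >= 1). Qualities follow a two-level model (Phred 20 for
clean bases, 7 for injected errors) used only by the PROXY statistic. All
randomness derives from a single seed through named `SeedSequence`
streams, so identical configurations reproduce byte-identical outputs.

What the simulator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: context-dependent base-calling error
(homopolymer compression), strand- or position-dependent error profiles,
PCR-cycle-resolved amplification (first-cycle polymerase errors shared by
all descendants), raw signal traces, carrier DNA or adapter chimeras, and
the forward/reverse read-count asymmetry seen on real flow cells.

## Numerical and design choices

- Metric-LCS is implemented as the distance form; the similarity form is
  inconsistent with both the pruning direction and the three-difference
  gloss of the 0.125 threshold.
- "Largest UMI in the cluster" means highest read support, not longest
  string.
- Greedy support-ordered clustering (not connected components) prevents
  chain-merging of distinct molecules; the medoid/merge refinement is this
  package's addition and is switchable (`refine_centroids=False` gives the
  plain greedy pass).
- The >50%-of-spanning-reads rule for consensus insertions and the
  pooled-per-side flank edit fraction are this package's concretisations
  where the procedure is otherwise underdetermined.
- Indel variants flow through the same support logic (DEL alleles and the
  insertion registry); `substitutions_only` restricts calling to
  substitutions, and the spectrum/synonymity reports accept substitutions
  only.
- Degenerate inputs: empty UMI interiors, bands too narrow to span the
  reference, empty pileup columns and double-empty LCS arguments raise
  `ValueError` rather than guessing.
- Problem sizes in the test-suite: the accuracy battery uses 2-kb
  amplicons with 100-molecule batches (the desk-scale profile); the
  13.7-kb regime is a parameter, not a separate code path.

## Known limitations

Homopolymer indels are not specially modelled, matching the known
weakness of base-space long-read consensus. Chimeras whose reads recover
only one UMI are absorbed into a parent cluster (diluted by depth rather
than removed). The clustering refinement assumes molecule UMIs are well
separated (~0.3 apart for random 24-mers), which holds for random H-UMIs
but not for designed barcode sets with small edit distances.
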