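# Methods

`glia` analyzes a tandemly duplicated prolamin gene cluster — the α-gliadin
family of the wheat Gli-2 loci — at desk scale.  This note records the
models, rules and numerical choices the package makes, what the synthetic
generator does and does not emulate, and the known limitations.

## Gene model and classification

α-gliadin genes are treated as intron-less CDSs (the family convention).
A gene is **intact** when it starts with ATG, ends with a single terminal
stop, translates without internal stops or ambiguous residues, and its
product falls in a 250–400-residue window.  The window is derived from the
family's 30–36 kDa preprotein range at ~110 Da/residue and is configurable
(`ClassificationConfig.min/max_protein_len`).

Non-intact genes carry one or more **defects**:

- **Premature stops** are in-frame TAA/TAG/TGA strictly before the final
  codon.  Mechanism attribution aligns the gene against an intact
  reference paralog and reads the aligned reference codon: a stop is
  flagged `c_to_t` when the reference codon is a glutamine codon (CAA/CAG)
  and the observed codon is TAA/TAG — the C→T transition that dominates
  pseudogenization in this family.  Attribution requires ≥50 % alignment
  identity; below that the gene is annotated reference-free (stops
  reported without `c_to_t` flags).
- **Frameshift indels** are alignment gaps whose length is not divisible
  by 3; in-frame gaps (e.g. the 21-nt events in the repetitive domain) are
  deliberately excluded.
- **TE insertions** are found by library matching: full-length exact
  matches by default, or ≥95 %-identity infix search (edlib) when
  configured.  Each hit is checked for a flanking direct repeat (target
  site duplication, default 4–12 bp search, 8 bp being the family's
  canonical size); the element plus one TSD copy is excised so that the
  restored sequence equals the pre-insertion gene.  Nested structures are
  resolved by excise-and-rescan: an interrupted outer element only becomes
  matchable after the inner element is removed, after which the inner
  event is re-anchored to the outer insertion point and flagged `nested`.
- **Truncation**: a CDS below 50 % of its reference length is a
  **fragment** (the partial-coding-region category), even when stops are
  also present; without a reference, a short clean ORF (< 250 aa, no other
  defect) is likewise a fragment.  A non-ATG start alone makes a
  pseudogene (`no_start`), a conservative choice.

When TE insertion, stops and frameshifts co-occur the gene's `note` field
records that the initiating mechanism cannot be ordered.  References are
auto-selected as the closest intact paralog by alignment identity (ties:
lexicographically smallest gene id), pooled across all loci so old gene
copies shared between genomes find their true homolog.

Locus summaries report raw counts alongside integer-rounded percentages;
mechanism counts tally pseudogenes per defect kind and may sum to more
than the pseudogene count.

## Protein architecture

The canonical architecture is signal peptide → repetitive domain →
polyQ I → unique I → polyQ II → unique II.  The signal peptide is a fixed
20-residue prefix (configurable); no predictor is used because the
family's signal peptides are highly conserved.

PolyQ tracts are delimited by a seed-and-merge rule: maximal glutamine
runs of ≥ 4 seed a tract; neighboring Q-runs of ≥ 2 merge across gaps of
≤ 2 non-Q residues; single glutamines never merge (they belong to the
P/Q repeat vocabulary, and absorbing them would chain a tract through the
repetitive domain).  A cluster is a tract only if it contains a seed.
PolyQ I is the first tract after the signal peptide with ≥ 8 Q, polyQ II
the next with ≥ 5 Q; fewer than two qualifying tracts is a non-canonical
architecture error.  Q counts are the number of glutamines in the tract,
not the tract span.  All thresholds live in `SegmentationConfig`.

Molecular weight is the sum of average-isotope residue masses plus one
water (18.0153 Da), via Biopython's mass table; the signal peptide can be
excluded.  Isoelectric point solves Henderson–Hasselbalch net charge = 0
by bisection on [0, 14] to |charge| < 1e-4; since net charge is strictly
decreasing in pH the root is unique.  The pKa set is fixed in
configuration (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1).  No claim is made that these reproduce any
particular external tool's values; comparisons are range- and
property-based.

Genome-wise polyQ means are rounded half-up to integers, matching how the
published averages are printed.

## Epitope scanning

The catalog carries the five major celiac-disease epitopes
(DQ2.5-glia-α1a PFPQPQLPY, α1b PYPQPQLPY, α2 PQPQLPYPQ, α3 FRPQQPYPQ,
and the shared DQ8/DQ8.5-glia-α1 peptide QGSFQPSQQ) plus the 33-mer
LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF and the C-terminal CSTT motif.  The
single most important scanner decision is that **overlapping occurrences
are counted** (a sliding window at every start position): non-overlapping
matching would report two α2 sites in the 33-mer instead of the correct
three.  Counts are global per protein.  The 33-mer detector is a Hamming
scan with a configurable mismatch allowance (default 0, since the
characteristic counts use exact matches).  CSTT is flagged when it occurs
within the final 15 residues.  The catalog is data (YAML), not code.

## Alignment and phylogeny

Pairwise alignment is an in-house Needleman–Wunsch with affine gaps
(Gotoh three-state recursion; numba kernels).  Defaults: match +2,
mismatch −1, gap open −8, gap extend −1; a gap of length L costs
`open + (L−1)·extend`.  Tie-breaking is fixed — prefer diagonal, then
up, then left — so alignments are bit-reproducible.  'N' never counts as
a match.  External aligners are deliberately not wrapped; trees may
therefore differ in detail from ones built with other toolchains, and all
tree-level claims are structural (clade purity), not topology-identical.

Distances are p-distances (mismatches over gap-free columns, pairwise
deletion) with an optional Jukes–Cantor correction.  UPGMA merges the
closest pair (ties: lexicographically smallest min-leaf-label pair), with
size-weighted average linkage and node height d/2, yielding deterministic
ultrametric trees serialized as Newick.  p-distance is not a metric;
triangle-inequality violations are accepted.  Bootstrap support is out of
scope.  The progressive MSA builds a UPGMA guide tree from pairwise
p-distances and merges profiles by profile–profile NW with sum-of-pairs
column scores (gap column vs residue scores as a mismatch; gap–gap 0).

Pseudogenes enter the phylogeny after TE excision.  Clade extraction
reports maximal single-genome clades plus the minimal nodes joining more
than one genome.

The 33-mer-origin analysis aligns two homologous CDSs, extracts maximal
gap runs as indel events (in-frame iff length ≡ 0 mod 3), translates and
scans both, and associates epitope-content changes (including 33-mer
gain/loss) with the overlapping indels.

## Expression

FPKM = counts × 10⁹ / (total mapped × gene length nt).  Transcript
fractions are reported to one decimal under two denominators — reads
mapped to annotated genes, and total reads — because both conventions
are in use and they differ whenever unmapped reads exist.

The stringent read assigner mirrors high-similarity short-read mapping:
candidates prefiltered by exact 15-mers, scored by a fitting alignment
with mismatch cost 2 and indel cost 3, accepted iff the aligned read
fraction is ≥ 0.9 and identity ≥ 0.99.  Identity is matches over
alignment columns including gap columns.  Reads tied between equal-best
genes are discarded by default (reproducible, and provably never inflates
a gene's count above its true origin count) or distributed uniformly at
random under an explicit seed.  Real sequencing-archive processing is out
of scope; the module consumes count tables or synthetic reads.
"Peak expression" is the maximum FPKM across samples and is labeled as
such in reports.

## Synthetic locus generator

The generator emulates the statistical structure of the real loci so
every stage is testable without external data: per-genome ancestors
derived from a common base, tandem duplication with per-duplication
substitution (default 2 % per site, an exposed choice — the family's
paralog divergence is not published), 45 % pseudogenization with a
mechanism mix of 13:1:3:4 over stop-gain : frameshift : TE : truncation
(the printed mechanism tallies, with the one unattributed case assigned
to frameshift), 8-bp TSDs, per-genome intergenic spacing at 1/10 scale
(A ≈ 7 kb, B ≈ 1 kb, D ≈ 4 kb), gene counts 10/26/11 for A/B/D (the B
locus's 24 plus its two translocated copies), and one shared ancestral
copy per genome to reproduce the single mixed clade.

Design choices that keep the planted truth exact:

- polyQ tracts are homogeneous CAA runs; the codon mix inside a
  microsatellite carries no downstream signal, and uniform tracts make
  tract-length differences align as one contiguous in-frame gap instead
  of spuriously fragmenting into frameshift calls.
- Per-copy tract lengths are drawn per tract (I: 11–36, II: 6–45) with a
  joint budget of 18–64 total glutamines, mirroring the family's observed
  totals; unconstrained joint extremes would push preproteins outside the
  30–36 kDa window the generator is meant to emulate.
- Point substitutions avoid the tracts (with a one-codon margin) and are
  redrawn if they would break the ORF of an intended-intact copy; tract
  variation is carried by the length redraws instead.  Planted stop-gains
  avoid the tracts because a stop inside a homopolymer has no uniquely
  aligned reference codon.
- The 33-mer scenario plants a 26-residue context (the 33-mer minus one
  PQPQLPY) in the D-genome ancestor, shields it from substitution, and
  gives one D gene a nucleotide-exact 21-nt repeat-unit insertion.
- Repeat units come from the epitope peptides and epitope-free scrambled
  variants with no Q-run of 4, so segmentation and scanning recover
  planted counts exactly; truth epitope counts are recomputed from the
  final mutated protein by direct window counting.
- Expression is log-normal (ln-scale mean 4, sd 1) with a 0.01 penalty
  factor for non-intact genes; reads are fixed-length (100 nt), uniform
  within each CDS, error-free by default.

What the generator does **not** emulate: intron-containing gene models,
recombination and unequal crossing-over, autonomous TE proliferation,
promoter/epigenetic expression divergence, and sequencing error models
beyond uniform substitution.  Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under the family's
event structure, not performance on raw survey sequence.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
47-gene three-genome loci for recovery (three seeds), 1000 planted genes
for rate calibration, 50–100 random matrices for tree properties, and
≥ 1000 randomized cases per brute-force oracle.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; reruns
are byte-identical.

## Known limitations

- Mechanism attribution inherits reference divergence: when the closest
  intact paralog no longer carries the ancestral glutamine codon, a
  genuine C→T stop-gain cannot be flagged `c_to_t` (the stop itself is
  still reported).  This mirrors the real ambiguity of inferring
  ancestral states from a single reference.
- The percentage discrepancy in the published mechanism tally (13 of 21
  described as 59 %) is left as-is: reports always show raw counts next
  to computed percentages.
- Indel positions inside repeats are degenerate up to gap placement; the
  recovery checks use a ±30-nt window for frameshift positions.
- MW/pI are predictions from fixed tables; no external tool's output is
  reproduced digit-for-digit.
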