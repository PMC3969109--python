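# Methods

This note documents the models, algorithms and numerical choices
behind `hybpipe`, and what the synthetic benchmarks do and do not
demonstrate.

## Read preprocessing

**Demultiplexing.** 5′ barcodes are composite patterns over
`{A,C,G,T,N}`: fixed positions form the multiplex code, `N` positions
are random tags used downstream to recognize PCR duplicates.  A lookup
table of *every* read prefix compatible with some barcode is
enumerated up front (optionally tolerating one substitution, in code
positions only, never indels), so classifying a read is one substring
extraction and one hash lookup — no per-read comparisons.  Barcode
codes must differ at more than twice the mismatch allowance, which
makes ambiguous assignment impossible by construction; anything
unmatched goes to an `unassigned` stream, so demultiplexing is an
exact partition of the input.

**Adapter trimming.** The built-in 3′ trimmer removes the longest read
suffix matching a prefix of the linker with at most one mismatch per
10 aligned nucleotides (floor), subject to a minimum match length
(`min`, default 4 nt; 0 disables trimming); a full internal linker
occurrence removes everything 3′ of its start.  This approximates the
behaviour of dedicated trimmers (the trimming backend is pluggable:
`qc=none` accepts externally trimmed reads).  Quality trimming uses
the BWA-style running-sum rule at threshold `trim` (default Phred 30);
reads shorter than `len` (default 17 nt) are dropped; a minimum
mean-quality filter (`filt`) exists but defaults to off.

**Collapsing.** Identical sequences collapse to one record carrying
`count` (occurrences, summed over already-collapsed input so the
operation is idempotent) and, when random tags are present,
`n_barcodes` (distinct tags).  Records are ranked by count descending,
ties broken lexicographically by sequence (the tie-break is a
package choice; any deterministic rule would do), and serialized as
`K-L_M` / `K_M` identifiers.  Downstream stages weight reads by the
`M` they carry.

## Local alignment

The built-in aligner indexes every word-length (default 11 nt)
substring of the database.  Exact word matches on either strand
nominate candidate transcripts; each candidate is then scored with a
*full* affine-gap Smith–Waterman dynamic program over the read ×
transcript matrix (numba-compiled), so reported scores are exact local
optima rather than heuristic extensions — the seeding step can only
miss alignments that contain no exact word, which at the default
scoring (match +1, mismatch −2, gap open 5, extend 1, minimum score
15) requires pathologically fragmented matches.  Further
non-overlapping alignments per transcript are found by masking the
read positions of earlier ones and re-running the DP.  Hit lists are
sorted by score with a deterministic (subject, position) tie-break and
capped at 20, mirroring common external-aligner defaults.

**E-values.**  `E = m·n·2^(−bits)` with
`bits = (λS − ln K)/ln 2`; λ is the unique positive root of
`Σᵢⱼ pᵢpⱼ e^{λ·s(i,j)} = 1` under uniform base composition, solved by
bisection to 1e−9 (λ = 1.3327058 for +1/−2).  K uses the published
ungapped nucleotide-search values for known score schemes (0.621 for
+1/−2) with a conservative fallback of 0.5 otherwise: the exact value
of K shifts all e-values by a constant factor and only matters for
hits near the score floor, far below the default `hval` threshold for
real fragments.  The database length `n` is the total nucleotide
count with no effective-length correction, keeping the statistic
exactly linear in both lengths and fully deterministic.  External
aligner e-values are used verbatim.

## Chimera calling

Per read, hits with e-value ≤ `hval` (default 0.1) are processed in
descending score order.  The *recorded* set comprises the top hit, all
hits tying the top score, and every hit whose gap or overlap with the
union of previously recorded read intervals is at most `gmax`
(default 4 nt).  "Previously matched area" is operationalized as that
interval union, with the distance being the largest overlap if any
interval overlaps, else the smallest gap.

The `hmax` multi-mapping filter (default 10) counts, for each hit, the
distinct (subject, strand, subject-interval) locations among hits
whose read intervals overlap it by ≥ 75% of the shorter interval —
i.e. alternative placements of the same fragment.  Fragments exceeding
`hmax` locations are excluded entirely; with transcript databases this
removes fragments from genes represented by many near-identical
isoforms.

Candidates are all recorded pairs with |gap/overlap| ≤ `gmax`, neither
fragment containing the other in the read.  A read whose best hit
covers ≥ read length − `gmax` nucleotides is non-chimeric (contiguous
full-length match) and yields nothing; the `gmax` slack is the natural
tolerance for edge effects of local alignment.

One call per read is selected lexicographically: (1) maximum fragment
score sum; (2) with `pref=mim`, pairs of exactly one microRNA and one
mRNA first; (3) best (then worst) transcript rank of the pair, where
transcripts are ranked by total mapped reads (weighted by collapse
count) — a ranking that can be saved and shared across samples as a
common alignment reference; (4) transcript-id/coordinate tie-break, so
output is invariant to hit ordering.  Antisense fragments are rejected
unless `anti=1` (genomic databases); antisense calls are written with
ascending coordinates plus a `strandN=-;` annotation so `.hyb` files
always satisfy start ≤ end.  With `type=mim`, only miRNA–mRNA pairs
are eligible, the miRNA fragment is extended to the full mature
sequence, and target coordinates are widened by 25 nt (clamped),
compensating for reads that do not span the whole chimeric cDNA.

## Duplex folding

Fragments are folded as an intermolecular duplex: only pairs between
the two strands (no hairpins), Watson–Crick plus GU wobble, N never
pairs.  The energy model is a Turner-style nearest-neighbor stack
table for RNA at 37 °C (1 M NaCl convention): the ten canonical
Watson–Crick stacking free energies, with GU-containing stacks
represented by two constants (−1.3 kcal/mol with one wobble, −0.5 with
two) — a documented simplification of the full wobble table.  Interior
and bulge loops cost an affine penalty `2.0 + 0.5·nt` with at most
30 unpaired nt per strand; duplex initiation costs +4.09 kcal/mol.
The MFE structure is computed by the standard two-sequence
hybridization recursion (O(n·m·L²) with the loop bound) and reported
in dot-bracket notation; structures with non-negative optimum are
reported empty with ΔG = 0, so ΔG ≤ 0 always and ΔG = 0 iff nothing
pairs.  The model is symmetric under exchanging the strands, and the
reported energy always equals an independent rescoring of the reported
structure.  Absolute energies depend on this parameterization and are
*not* comparable to other folding engines; ranking and QC contrasts
(cognate vs shuffled pairs) are.  Externally produced foldings can be
imported from viennad files instead.

Folding always uses database sequences at the called (possibly
extended) coordinates, never read sequences, because CLASH reads carry
crosslinking-induced substitutions and deletions irrelevant to
in-vivo pairing; calls with identical extended coordinates therefore
receive identical energies (the fold is cached on the sequence pair).

## Merging and QC

Two calls merge when they join the same transcript pair (regardless
of fragment order in the read) and their fragment intervals overlap by
≥ 1 nt on *both* transcripts; merging is the transitive closure, with
coordinate envelopes, chimera and read counts, mean ΔG (over folded
members) and sorted supporting identifiers reported per interaction.
Merging operates on the coordinates as called — extended ones when
extension was enabled.  The construction is idempotent and invariant
under input permutation.

QC reports mean ΔG, the fraction of chimeras with zero gap/overlap,
and — for miRNA–mRNA calls — the fraction whose target fragment
contains a seed match, defined minimally as an exact occurrence of the
Watson–Crick complement of miRNA nt 2–7 (the canonical 6-mer seed).

## Synthetic libraries and what the benchmarks show

The generator emulates the *structure* of CLASH data with uniform
i.i.d. base composition: random mRNAs (500–1500 nt) and 22-nt miRNAs;
fusion reads = mature miRNA ⧺ 30-nt mRNA fragment (either order,
optional 3′ linker); contiguous 50-nt mRNA segments as non-chimeric
background; multiplexed libraries with composite barcodes, PCR
duplicates sharing their parent's random tag, and natural duplicates
drawing fresh tags.  Isoform redundancy is controlled by giving a
fraction of genes (default a tenth) a configurable number of
near-identical isoform copies (1% divergence), reproducing the
multi-mapping that real transcript databases show for multi-isoform
genes.  A seeded-library variant plants the complement of miRNA
nt 2–8 into target regions of a database copy so folding/seed QC has
true positives.

The benchmark conditions are 10,000 fusion reads against a 60-gene /
30-miRNA database with 12 isoforms for a tenth of the genes; detection
with default parameters recovers ≈ 89% of planted pairs, with the
losses dominated — by design — by reads from redundant genes whose
mRNA fragment maps to more than `hmax` locations, plus occasional
reads whose fragment flanks happen to extend the alignment past the
breakpoint beyond `gmax`.  Contiguous libraries yield exactly zero
calls.  These results demonstrate the calling logic under controlled
conditions; uniform random sequences have no repeat structure,
paralogy, splicing or expression bias, so recovery on real libraries
depends additionally on database curation and aligner choice.

## Determinism and limitations

All randomness is owned by the generators and seeded; alignment,
calling, folding and merging are deterministic with explicit
tie-breaks, and identical pipeline invocations produce byte-identical
outputs (up-to-date intermediates are reused via parameter
fingerprints).  Known limitations: one call per read (no
three-fragment chimeras); no spliced or quality-aware alignment; the
ungapped e-value statistic is an approximation for gapped local hits;
the folding model omits tabulated loop energies, dangling ends and
intramolecular structure.
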