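# Methods

This note records the models and procedures behind `paleofossil`, the
assumptions they make, the parameters that matter, and what the tests do
and do not establish.

## The alignment model

A fossil is aligned to a protein at codon resolution.  Alignment columns
are codon↔amino-acid (3 nt, 1 aa), codon↔gap (3 nt), gap↔amino-acid
(1 aa), and ±1-nucleotide frameshifts, which may occur only between two
codon columns and carry a flat cost; a +1 shift skips one extra
nucleotide, a −1 shift re-reads one.  Gaps are affine per maximal
same-type run; an alignment begins and ends with a codon column.  This
column grammar is exactly what the exhaustive-enumeration oracle in the
test suite scores, and the dynamic program is held to integer equality
with it on random small instances.

Substitution scores are integer log-odds at temperature `scale_t`
(default 3.0): `s(c,a) = round(t·ln(P(c,a)/(p_c·q_a)))`.  The default
column distribution `P` is the analytic *decay channel*: a source amino
acid emits a usage-weighted synonymous codon with probability `1−r` and a
usage-draw over all 64 codons otherwise, with `r` solved so the expected
amino-acid identity equals the training target (default 0.5, the
"focus on old fossils" setting).  Because the simulator decays fossils
with the same channel, the default model is matched to the data it is
asked to find — mirroring the practice of training alignment parameters
on the genome-vs-protein comparison itself.  `model_from_counts` also
accepts arbitrary observed counts, so externally trained parameters can
be used.  Stops are a first-class 21st symbol: proteins are
stop-augmented, and a fossil's in-frame stop codons can align to the
terminal `*` or appear as premature stops (a disruption).

Gap and frameshift costs come from event frequencies by the same
log-odds rule; defaults (open 14, extend 4, frameshift 17) make one
frameshift cheaper than an open+extend pair, so single-nucleotide loss is
explained as a frameshift, not a gap.

Degenerate bases: a codon containing N scores as the minimum over its
expansions, so hard-masking can only lower scores.  Soft-masking is
honored as a seeding contract: no alignment may consist solely of
lowercase sequence (exhaustive path) and seeds are never taken in
lowercase runs (genome path); extension into masked runs is allowed.

## Genome-scale search

The exact DP is quadratic, so genome scans use the classical
seed-and-extend layout: exact amino-acid 4-mers between the six reading
frames and the protein set; a two-hit filter (two seeds for one protein
on nearby diagonals, ≤450 nt apart, diagonal bucket 24 nt); a gapless
X-drop extension through one seed of each cluster (threshold 45, X-drop
20) as cheap verification; then the exact DP replayed on the candidate
window (cluster span capped at 1.5 kb, extension beyond outer seeds
capped at 450 nt).  All heuristic parameters live on `SearchParams`.
Sensitivity was checked against planted fossils: at 50% target identity
the missed fraction is a few percent, dominated by short heavily
frameshifted fossils whose gapless segments fall below the verification
threshold.  The brute-force path (`align_local`) has no seeding and is
the reference for small inputs.

## Significance

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` per
chromosome, rescaled per genome by `genome_len/chrom_len`; the rescaled
value is independent of chromosome, so one integer minimum score
implements a genome-wide threshold exactly.  The default threshold is
one expected chance hit per 10⁹ bp of searched DNA.

λ and K are *not* taken from the ungapped stationarity equation: the
gapped, frameshift-aware, seeded search has a measurably flatter score
tail (fitted λ ≈ 0.70·λ_ungapped for the default model).  Instead both
are fitted by weighted least squares to hit counts of the full search on
800 kb of shuffled DNA against the real protein set, from the gapless
verification threshold upward (below it, seeding truncates the tail).
This makes the reported E-values describe the search actually performed;
the reversed-genome decoy control then lands inside a 3× Poisson band of
the threshold expectation, which the acceptance suite verifies over 20
seeds.  The calibration is seeded and cached per protein set.

## Fossil-call rules and their boundaries

The chain is fixed: exclude exapted-named proteins → align →
significance filter → keep the strongest of overlapping homologies
(strand-agnostic: one locus, one best explanation) → remove calls >10%
covered by coding annotation → remove host-gene calls >10% covered by
non-simple TE annotation.  Coverage is per-base over the union of
annotations.  Boundary semantics are deliberate and tested: 10% coding
coverage is kept (the rule is *greater than* 10%), 30.0% alignment
coverage is conserved (*at least* 30%), novelty tolerates *at most* 10%,
and "not new" triggers on a single shared same-strand, same-class base.
The novelty rules are strand-specific; the overlap-resolution rule is
not — the strand qualifier belongs to annotation comparison, not to
locus ownership.

## Inter-genome dating

One-to-one reduction is greedy best-first over block scores with
rejection on either genome; the linked-alignment filter connects two
blocks when, in both genomes, they sit on the same sequence within 1 Mb
(end-to-start gap, 0 when touching) with at most five other blocks
strictly between them in midpoint order, and retains connected
components of at least three blocks.  Strand is not required to match
for linking (inversions are real); the intervening-block count uses the
same input set being filtered.  Both choices are configuration-exposed.
A fossil's age is the oldest clade label among genomes where coverage by
the surviving blocks reaches 30%; fossils conserved nowhere get "—".
Age labels are an ordered ladder (`CladeMap`), and adding a conserved
genome can only age a fossil, never rejuvenate it (property-tested).

Interval projection between genomes is block-level with outward-rounded
proportional clipping, so projecting and back-projecting always contains
the original interval.

## The simulated world

The generator's defaults are the stated study conditions: two ~1 Mb
descendant genomes, 50 ancestral fossils decayed to 50% amino-acid
identity (Poisson(1) frameshifts and premature stops each, 1% per-codon
in-frame indels), 50 young lineage-specific fossils at 70% identity,
neutral divergence of 10% substitutions per lineage with small indels at
0.002/bp, conserved segments (anchors every 8 kb and the exapted fossils
themselves) at 2%.  Values the study leaves open were chosen once as
field-plausible: anchor spacing/length give each fossil several linkable
neighbours within 1 Mb, as real conserved noncoding density does; young
fossils at 70% identity are detectable but clearly post-divergence.

Three engineered scenarios exercise the hard parts.  *Splits*: ancestral
fossils cut by a 30–120 kb insertion in one lineage, whose halves must
re-appear as tectonic pairs.  *Traps*: one TE family inserted
independently at homologous positions of both lineages on scaffold pairs
whose non-TE flanks are regenerated per lineage — at desk scale a 1 Mb
chromosome cannot contain a 1 Mb empty flank, so "no conserved flanking
blocks" is realised by scaffold isolation; the emitted alignment set
includes the trap homology block, which the link filter must reject.
*Decoy genes*: two-exon NM_/XR_ gene models, a few engineered to cover a
planted fossil at 8% (kept) or 20% (removed), probing the >10% boundary.

True orthologous blocks are emitted only for conserved segments — the
simulator's world says neutral DNA between distant genomes is
unalignable, which is why a lineage-specific fossil has no coverage and
must come out undated.

What a green end-to-end test does *not* establish: performance on real
genome alignments (with overshoot, paralogy and missing data), realistic
TE sequence structure (proteins are i.i.d. draws, not real families),
GC/composition heterogeneity, or behaviour beyond ~10 Mb inputs.

## Numerical choices

Integer scores throughout; all coordinates 0-based half-open on the
forward strand, converted at every format boundary.  Ties in greedy
selections break by (E-value, start, protein id) for calls and by
(coordinates, strand) for alignments, making every run deterministic;
byte-level determinism of the whole pipeline is an acceptance test.
Fraction comparisons at rule boundaries are computed as exact ratios of
integers against the literal thresholds.  Empty inputs return empty
results except where the contract demands an error (no genome, no
NM_ genes, empty protein for stop augmentation).

## Known limitations

The seeded search trades a few percent sensitivity at ≤50% identity for
tractability; the E-value fit assumes a single exponential tail, which
slightly underestimates extreme-tail counts; the one-to-one reduction is
greedy whole-block selection rather than split-alignment dynamic
programming, so ingesting externally produced one-to-one alignments is
preferred when exact parity with such tools matters; and the two-taxon
simulated world exercises the age machinery through a single genome
pair, with the full clade ladder covered by direct unit tests.
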