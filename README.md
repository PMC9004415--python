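# paleofossil

Genomes are full of *protein fossils*: fragments of formerly
protein-coding DNA, descended from transposable-element (TE) proteins or
from host genes, that no longer code for anything.  Old fossils are hard
to find — they have drifted far below the amino-acid conservation that
ordinary protein search assumes, and they accumulate frameshifts and
premature stop codons that break codon structure.  `paleofossil` is a
library for detecting, filtering and dating such fossils, aimed at
researchers studying TE evolution, exaptation and genome history, and
exercised end-to-end on simulated genomes with planted ground truth.

## What it does

**Frameshift-aware translated alignment.**  DNA is compared to proteins
with a 64×21 integer log-odds matrix indexed by (codon, amino acid or
stop `*`), so `aac` can prefer asparagine over a serine codon — something
a 20×20 matrix cannot express.  Local alignments allow affine gaps and
±1-nucleotide frameshifts between codon columns:

    s(c, a) = round(t · ln P(c,a) / (p_c · q_a))          (column scores)
    E       = K · m · n · e^(−λS)                          (significance)

The E-value scale (λ, K) is fitted empirically by running the *same
seeded search* on shuffled DNA, so the reversed-genome decoy control and
the threshold semantics (default: one expected chance hit per 10⁹ bp)
agree by construction.  Each protein is stop-augmented (`MKL` → `MKL*`)
so fossil stop codons can be matched explicitly.

**Fossil-call rules.**  Exapted genes hiding in TE protein libraries are
excluded by name (`_HSgene`, `_Hsa_`, `UN-GIN`, `_Xtr_eg_tp`); when
homologies overlap in the genome only the strongest is kept; calls >10%
covered by coding annotation are removed; host-gene calls >10% covered by
TE annotation (other than simple/low-complexity) are dropped as
true-but-unwanted homologies.  Novelty rules ("at most 10%" same-strand
known-class coverage; "not new" on any same-strand same-class overlap)
are implemented with their exact boundary semantics.

**Dating by inter-genome homology.**  Pairwise genome alignments are
reduced to one-to-one blocks, pruned of anything touching coding
annotation, and passed through a *linked-alignment filter*: a block is
trusted only if it is linked (≤1 Mb apart and ≤5 blocks intervening, in
both genomes) directly or indirectly to at least two others.  This
defeats the classic trap where one TE family inserts independently at
homologous loci of two genomes — the inserts are homologs but the
insertions are not.  A fossil is conserved relative to a genome when
≥30% of it is covered by the surviving blocks; its age is the oldest
conserved clade (e.g. Amniote → Tetrapod → Sarcopterygian →
Gnathostome).

**Results machinery.**  Same-family fossil pairs separated by 30–3,000 kb
("genome tectonics", candidate fragments of one rifted element), typing
of class-"Unknown" repeats from consistent fossil overlaps, nearest-gene
context (NM_ accessions; intronic vs intergenic), and disruption
statistics (fraction of calls with a frameshift or premature stop).

**Simulator.**  `SimConfig`/`build_world` generate an ancestral genome
with conserved anchors and planted fossils decayed to a target amino-acid
identity (default 50%), evolve two descendant lineages, add young
lineage-specific insertions, split some ancestral fossils with 30–120 kb
insertions, and plant the non-homologous-insertion trap on scaffolds
whose conserved flanks are lost.  Every planted feature is recorded in a
truth registry; one integer seed determines every emitted byte.

## A worked example

```
$ python examples/01_find_fossils.py
per-stage counts: {'proteins_in': 32, 'proteins_after_exclusion': 30,
 'alignments_significant': 18, 'after_drop_weaker_overlaps': 18,
 'after_remove_coding_overlaps': 18, 'after_filter_hostgene_vs_te': 18}
minimum score for E <= 0.00028: 80
18 fossil calls; first five:
  chrA:16649-17287 (+)  NP_900001.1              host_gene            score=398  E=1.5e-49 disrupted=True
  chrA:20982-21558 (-)  CR1-13_SIM_pol           TE:LINE/CR1          score=415  E=5.7e-52 disrupted=True
  chrA:32786-33253 (+)  hAT-9_SIM_pol            TE:DNA/hAT-Tip100    score=508  E=3.4e-65 disrupted=True
  chrA:54725-55484 (-)  Penelope-19_SIM_pol      TE:Penelope/Penelope score=493  E=4.6e-63 disrupted=True
  chrA:72154-72643 (+)  DIRS-18_SIM_pol          TE:LTR/DIRS          score=344  E=7.1e-42 disrupted=True

planted fossils recovered: 17/17
```

Each line is one genomic interval explained by one decayed protein: its
coordinates and strand, the source protein and its TE class/family, the
integer alignment score, the genome-wide E-value (expected chance hits of
that strength in this whole search), and whether the alignment carries a
frameshift or premature stop.  `examples/02_date_fossils.py` continues to
dating (ages from a genome pair, traps left undated),
`examples/03_decoy_control.py` runs the reversed-genome false-positive
control, and `examples/04_tectonics_and_unknown_repeats.py` reports
rifted fossil pairs and types unknown repeats.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the simulated world from the seed, runs fossil finding, dating
and the decoy control end to end, prints the per-stage counts and summary
statistics to stderr, and writes the results file.

## Layout

```
src/paleofossil/
  io_formats.py      FASTA / RepeatMasker (.out, rmsk table) / GFF3 / MAF
  scoring.py         64x21 log-odds model, E-values, calibration targets
  align.py           frameshift DP, seeded genome search, decoy control
  fossil_calls.py    exclusion, overlap resolution, coding/TE filters, novelty
  genome_pairs.py    one-to-one reduction, coding pruning, link filter
  ancient_ages.py    conservation dating, tectonics, unknown repeats, genes
  synthetic_data.py  ground-truthed genome simulation
  pipeline.py        run_find / run_ages / run_decoy orchestration
docs/methods.md      model assumptions, parameters, limitations
examples/            one narrative script per capability
tests/               unit, property and acceptance suites
```
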