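"""Genome tectonics and unknown-repeat classification.

Two fragments of one ancestral TE can drift 30-3,000 kb apart as younger
insertions pile up between them; same-family fossil pairs at such
separations are candidate markers of that rifting.  Separately, repeats
annotated with class "Unknown" can be typed when they consistently
overlap TE protein fossils of one family.
"""

from paleofossil import PipelineConfig, SimConfig, build_world, run_ages, run_find
from paleofossil.io_formats import AnnotationRecord
from paleofossil.synthetic_data import protein_classes

world = build_world(SimConfig(seed=11, genome_length=400_000,
                              n_ancestral_fossils=20, n_lineage_fossils=10,
                              n_split_fossils=2, split_gap_range=(40_000, 80_000)))

def cds(genes):
    return [AnnotationRecord(g.seq_id, s, e, g.strand, g.gene_name, "CDS")
            for g in genes for (s, e) in g.cds]

pcfg = PipelineConfig(seed=11)
find = run_find(world.genome_A, world.proteins, protein_classes(world.proteins),
                cds=cds(world.genes_A), rmsk=world.rmsk_A, cfg=pcfg)
ages = run_ages(find.calls, world.truth.all_blocks(),
                cds(world.genes_A), cds(world.genes_B), world.clade_map,
                "genomeB", cfg=pcfg, rmsk=world.rmsk_A, genes=world.genes_A)

print(f"{len(ages.tectonics)} same-family pairs separated by 30-3,000 kb; nearest:")
for p in ages.tectonics[:5]:
    print(f"  {p.call_a.class_family:20s} {p.call_a.seq_id}:{p.call_a.start:>9,} / "
          f"{p.call_b.start:>9,}   gap {p.separation_bp:,} bp")

split = [f for f in world.truth.fossils if f.split_partner and f.interval_A]
print(f"\nsimulator split-fossil halves planted: {len(split)}"
      " (their pairs should appear above)")

print("\nunknown-repeat classification:")
for name, te_type in ages.unknown_types.items():
    print(f"  {name} -> {te_type or 'unclassified'}")
print("A family is typed only when >= 3 instances overlap fossils >= 100 bp")
print("and >= 80% of those overlaps agree on one TE class/family.")
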