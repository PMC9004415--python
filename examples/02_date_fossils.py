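"""Date fossils by conservation across a genome pair.

Runs the full chain on a simulated two-genome world: find fossils in
genome A, reduce the A-B alignments (coding pruning + linked-alignment
filter), and assign each fossil an age from its alignment coverage.
Independently inserted TEs at homologous loci (the non-homologous
insertion trap) must come out undated.
"""

from paleofossil import PipelineConfig, SimConfig, build_world, run_ages, run_find
from paleofossil.io_formats import AnnotationRecord
from paleofossil.synthetic_data import protein_classes

cfg = SimConfig(
    seed=7, genome_length=200_000, n_ancestral_fossils=12, n_lineage_fossils=8,
    n_te_proteins=24, n_host_proteins=8, n_split_fossils=1, n_trap_insertions=1,
)
world = build_world(cfg)

def cds(genes):
    return [AnnotationRecord(g.seq_id, s, e, g.strand, g.gene_name, "CDS")
            for g in genes for (s, e) in g.cds]

pcfg = PipelineConfig(seed=7)
find = run_find(world.genome_A, world.proteins, protein_classes(world.proteins),
                cds=cds(world.genes_A), rmsk=world.rmsk_A, cfg=pcfg)
ages = run_ages(find.calls, world.truth.all_blocks(),
                cds(world.genes_A), cds(world.genes_B),
                world.clade_map, "genomeB", cfg=pcfg,
                rmsk=world.rmsk_A, genes=world.genes_A)

print("block filtering:", ages.stage_counts)
print("\nage report (first rows):")
print(ages.report.head(8).to_string(index=False))

n_old = sum(p.age == "old" for p in ages.profiles)
n_undated = sum(p.age == "—" for p in ages.profiles)
print(f"\n{n_old} fossils dated to the common ancestor, {n_undated} undated.")
trap = [p for p in ages.profiles if p.call.seq_id.startswith("trap")]
print(f"trap-scaffold fossils: {len(trap)}, all undated: "
      f"{all(p.age == '—' for p in trap)}")
print("An 'old' age means >= 30% of the fossil is covered by linked,")
print("coding-free alignments to the other genome; '—' means no such support.")
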