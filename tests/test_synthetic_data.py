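import hashlib

import numpy as np
import pytest

from paleofossil import SimConfig, build_world, emit
from paleofossil.io_formats import (
    SeqRecord,
    read_cds,
    read_fasta,
    read_maf,
    read_repeatmasker,
)
from paleofossil.scoring import GENETIC_CODE, aa_background, codon_usage
from paleofossil.synthetic_data import (
    decay_mix_fraction,
    evolve_pair,
    make_ancestor,
    make_fossil_dna,
    make_protein_library,
    plant_fossil,
    protein_classes,
)


def small_cfg(**kw):
    base = dict(
        seed=9, genome_length=60_000, n_te_proteins=12, n_host_proteins=4,
        protein_length=(100, 180), n_ancestral_fossils=5, n_lineage_fossils=4,
        n_split_fossils=1, split_gap_range=(30_000, 31_000),
        n_trap_insertions=1, anchor_spacing=5_000, n_decoy_genes=4,
    )
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# protein library


def test_library_is_deterministic_and_sized():
    cfg = small_cfg()
    lib1 = make_protein_library(cfg)
    lib2 = make_protein_library(cfg)
    assert [(p.id, p.residues) for p in lib1] == [(p.id, p.residues) for p in lib2]
    assert len(lib1) == cfg.n_te_proteins + cfg.n_host_proteins
    classes = protein_classes(lib1)
    assert sum(v == "host_gene" for v in classes.values()) == cfg.n_host_proteins


def test_library_amino_acid_composition():
    """Composition tracks the generator's stated frequencies (3 sigma)."""
    cfg = small_cfg(n_te_proteins=60, n_host_proteins=20, protein_length=(200, 400))
    lib = make_protein_library(cfg)
    residues = "".join(p.residues for p in lib)
    n = len(residues)
    assert n >= 10_000
    q = aa_background(codon_usage(cfg.gc))[:20]
    q = q / q.sum()
    for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        obs = residues.count(aa)
        exp = n * q[i]
        sigma = np.sqrt(n * q[i] * (1 - q[i]))
        assert abs(obs - exp) <= 3 * sigma, aa


def test_exapted_names_present_for_exclusion_exercise():
    lib = make_protein_library(small_cfg(n_te_proteins=40, exapted_name_frac=0.2))
    tagged = [p for p in lib if any(t in p.id for t in
              ("_HSgene", "_Hsa_", "UN-GIN", "_Xtr_eg_tp"))]
    assert len(tagged) == 8


# ---------------------------------------------------------------------------
# fossil decay


def test_identity_limit_translates_back_exactly():
    cfg = small_cfg(indel_rate=0.0, frameshift_per_fossil=0.0, stop_per_fossil=0.0)
    rng = np.random.default_rng(1)
    prot = "MKVLLEDAKRN*"
    dna, disrupted, n_fs, n_stop = make_fossil_dna(prot, cfg, rng, target_identity=1.0)
    assert not disrupted and n_fs == 0 and n_stop == 0
    back = "".join(GENETIC_CODE[dna[i : i + 3]] for i in range(0, len(dna), 3))
    assert back == prot


def test_realized_identity_tracks_target():
    cfg = small_cfg(indel_rate=0.0, frameshift_per_fossil=0.0, stop_per_fossil=0.0)
    rng = np.random.default_rng(2)
    prot = "".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300)
    ) + "*"
    idents = []
    for _ in range(200):
        dna, *_ = make_fossil_dna(prot, cfg, rng, target_identity=0.5)
        back = "".join(GENETIC_CODE[dna[i : i + 3]] for i in range(0, len(dna), 3))
        idents.append(np.mean([a == b for a, b in zip(back, prot)]))
    assert abs(np.mean(idents) - 0.5) <= 0.05


def test_forced_frameshifts_mark_disruption():
    cfg = small_cfg(frameshift_per_fossil=0.0, stop_per_fossil=0.0)
    rng = np.random.default_rng(3)
    # Poisson(0) -> never disrupted by frameshift/stop
    _, disrupted, n_fs, n_stop = make_fossil_dna("MKVLLE*", cfg, rng)
    assert not disrupted
    cfg2 = small_cfg(frameshift_per_fossil=8.0)
    _, disrupted2, n_fs2, _ = make_fossil_dna("MKVLLEDAKRNMKVLLEDAKRN*", cfg2, rng)
    assert n_fs2 > 0 and disrupted2


def test_decay_mix_fraction_bounds():
    assert decay_mix_fraction(1.0, 0.41) == 0.0
    assert 0 < decay_mix_fraction(0.5, 0.41) < 1


# ---------------------------------------------------------------------------
# planting


def test_plant_fossil_respects_forbidden_zones():
    cfg = small_cfg()
    rng = np.random.default_rng(4)
    genome = SeqRecord("chr", "ACGT" * 2500)
    prot = SeqRecord("L1-1_SIM_pol", "MKVLLEDAKRN" * 10, "protein")
    from paleofossil.io_formats import append_stop

    newg, truth = plant_fossil(genome, append_stop(prot), cfg, rng)
    _, s, e = truth.interval_A
    assert len(newg.residues) == len(genome.residues) + (e - s)
    assert truth.source_class == "TE:LINE/L1"
    # fully forbidden genome -> error
    with pytest.raises(RuntimeError):
        plant_fossil(genome, append_stop(prot), cfg, rng,
                     forbidden=[(0, len(genome.residues) + 1)])


# ---------------------------------------------------------------------------
# lineage evolution


def test_zero_divergence_limit():
    cfg = small_cfg(
        divergence_subst_rate=0.0, divergence_indel_rate=0.0,
        conserved_subst_rate=0.0, n_lineage_fossils=0, n_split_fossils=0,
        n_trap_insertions=0,
    )
    rng = np.random.default_rng(cfg.seed)
    lib = make_protein_library(cfg, rng)
    anc = make_ancestor(cfg, lib, rng)
    ga, gb, truth = evolve_pair(anc, cfg, lib, rng)
    assert ga[0].residues == gb[0].residues  # identical genomes
    for f in truth.fossils:
        assert f.age_true == "old"
        assert f.interval_A[1:] == f.interval_B[1:]
    # ancestral fossils fully covered by emitted blocks
    for f in truth.fossils:
        _, s, e = f.interval_A
        cov = sum(
            min(b.g1_end, e) - max(b.g1_start, s)
            for b in truth.blocks
            if b.g1_seq == "chrA" and b.g1_start < e and s < b.g1_end
        )
        assert cov == e - s


def test_substitution_counts_within_3_sigma():
    cfg = small_cfg(genome_length=200_000, n_ancestral_fossils=0,
                    n_lineage_fossils=0, n_split_fossils=0, n_trap_insertions=0,
                    divergence_indel_rate=0.0)
    rng = np.random.default_rng(cfg.seed)
    lib = make_protein_library(cfg, rng)
    anc = make_ancestor(cfg, lib, rng)
    ga, _, _ = evolve_pair(anc, cfg, lib, rng)
    # with no indels the genomes align column-wise to the ancestor
    a = np.frombuffer(ga[0].residues.encode(), dtype=np.uint8)
    anc_letters = np.frombuffer(b"ACGT", dtype=np.uint8)[anc.seq]
    assert len(a) == len(anc_letters)
    n_sub = int((a != anc_letters).sum())
    cons = np.zeros(len(a), dtype=bool)
    for s, e in anc.conserved:
        cons[s:e] = True
    n_neutral = int((~cons).sum())
    # substitutions hit a different base with probability 1, so expected
    # count is rate * length per regime
    exp = n_neutral * cfg.divergence_subst_rate + cons.sum() * cfg.conserved_subst_rate
    sigma = np.sqrt(exp)
    assert abs(n_sub - exp) <= 3 * sigma


def test_split_fossils_are_partner_pairs_with_gap_in_range():
    cfg = small_cfg(genome_length=120_000, n_split_fossils=2,
                    split_gap_range=(30_000, 40_000))
    rng = np.random.default_rng(cfg.seed)
    lib = make_protein_library(cfg, rng)
    anc = make_ancestor(cfg, lib, rng)
    _, _, truth = evolve_pair(anc, cfg, lib, rng)
    split = [f for f in truth.fossils if f.split_partner]
    assert len(split) == 4  # two pairs
    by_id = {f.fossil_id: f for f in split}
    seen = set()
    for f in split:
        if f.fossil_id in seen:
            continue
        p = by_id[f.split_partner]
        seen |= {f.fossil_id, p.fossil_id}
        assert p.split_partner == f.fossil_id
        assert f.source_class == p.source_class
        first, second = sorted([f.interval_A, p.interval_A], key=lambda iv: iv[1])
        gap = second[1] - first[2]
        assert 30_000 <= gap <= 40_000


def test_trap_blocks_are_isolated_from_true_blocks():
    cfg = small_cfg()
    rng = np.random.default_rng(cfg.seed)
    lib = make_protein_library(cfg, rng)
    anc = make_ancestor(cfg, lib, rng)
    _, _, truth = evolve_pair(anc, cfg, lib, rng)
    trap_seqs = {b.g1_seq for b in truth.trap_blocks}
    assert trap_seqs  # traps exist
    for b in truth.blocks:
        assert b.g1_seq not in trap_seqs  # no orthologous block on a trap scaffold
    traps = [f for f in truth.fossils if f.is_trap]
    assert all(f.age_true == "lineage" for f in traps)


# ---------------------------------------------------------------------------
# emission


def _checksums(paths):
    return {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
    }


def test_emit_is_byte_deterministic(tmp_path):
    cfg = small_cfg()
    p1 = emit(build_world(cfg), tmp_path / "a")
    p2 = emit(build_world(cfg), tmp_path / "b")
    assert _checksums(p1) == _checksums(p2)


def test_emitted_files_round_trip(tmp_path):
    cfg = small_cfg()
    w = build_world(cfg)
    paths = emit(w, tmp_path / "out")

    ga = read_fasta(paths["genome_A"])
    assert [(r.id, len(r.residues)) for r in ga] == [
        (r.id, len(r.residues)) for r in w.genome_A
    ]
    prots = read_fasta(paths["proteins"])
    assert [(p.id, p.residues) for p in prots] == [
        (p.id, p.residues) for p in w.proteins
    ]
    rmsk = read_repeatmasker(paths["rmsk_A"], "out")
    assert [(r.seq_id, r.start, r.end, r.strand, r.class_family) for r in rmsk] == [
        (r.seq_id, r.start, r.end, r.strand, r.class_family) for r in w.rmsk_A
    ]
    blocks = read_maf(paths["maf"])
    want = w.truth.all_blocks()
    key = lambda b: (b.g1_seq, b.g1_start, b.g1_end, b.g2_seq, b.g2_start, b.g2_end)
    assert sorted(map(key, blocks)) == sorted(map(key, want))
    cds, genes = read_cds(paths["genes_A"])
    assert {g.accession for g in genes} == {g.accession for g in w.genes_A}
    got = {(g.accession, tuple(g.cds)) for g in genes}
    assert got == {(g.accession, tuple(g.cds)) for g in w.genes_A}
    # truth intervals round-trip through the TSV
    import pandas as pd

    truth_df = pd.read_csv(paths["truth"], sep="\t")
    in_a = truth_df[truth_df.seq_A.notna()]
    by_id = {f.fossil_id: f for f in w.truth.fossils}
    for _, row in in_a.iterrows():
        f = by_id[row.fossil_id]
        assert (row.seq_A, int(row.start_A), int(row.end_A)) == f.interval_A
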