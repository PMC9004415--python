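import numpy as np
import pytest

from paleofossil import (
    PipelineConfig,
    SimConfig,
    build_world,
    default_model,
    run_ages,
    run_find,
)
from paleofossil.io_formats import AnnotationRecord
from paleofossil.synthetic_data import protein_classes


def cds_records(genes):
    return [
        AnnotationRecord(g.seq_id, s, e, g.strand, g.gene_name, "CDS")
        for g in genes
        for (s, e) in g.cds
    ]


@pytest.fixture(scope="session")
def model():
    """Uncalibrated default scoring model."""
    return default_model()


@pytest.fixture(scope="session")
def small_world():
    """A scaled-down simulated world for unit-level pipeline tests."""
    cfg = SimConfig(
        seed=5,
        genome_length=150_000,
        n_te_proteins=24,
        n_host_proteins=8,
        protein_length=(120, 250),
        n_ancestral_fossils=10,
        n_lineage_fossils=10,
        n_split_fossils=1,
        split_gap_range=(30_000, 35_000),
        n_trap_insertions=1,
        anchor_spacing=6_000,
        n_decoy_genes=8,
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def acc_world():
    """The stated end-to-end world: ~2 x 1 Mb, 50 ancestral + 50 lineage
    fossils decayed to 50% amino-acid identity."""
    return build_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def acc_run(acc_world):
    """Find + ages executed once on the end-to-end world."""
    w = acc_world
    pcfg = PipelineConfig(seed=1)
    find = run_find(
        w.genome_A,
        w.proteins,
        protein_classes(w.proteins),
        cds=cds_records(w.genes_A),
        rmsk=w.rmsk_A,
        cfg=pcfg,
    )
    ages = run_ages(
        find.calls,
        w.truth.all_blocks(),
        cds_records(w.genes_A),
        cds_records(w.genes_B),
        w.clade_map,
        "genomeB",
        cfg=pcfg,
        rmsk=w.rmsk_A,
        genes=w.genes_A,
    )
    return {"world": w, "cfg": pcfg, "find": find, "ages": ages}


def truth_overlap(call, interval):
    _, s, e = interval
    return max(0, min(call.end, e) - max(call.start, s))


def is_recovered(truth_fossil, calls, min_frac=0.3):
    """A planted fossil counts as recovered when some call overlaps it by
    at least ``min_frac`` of its length (the package's own 30% coverage
    convention)."""
    seq, s, e = truth_fossil.interval_A
    best = max(
        (truth_overlap(c, truth_fossil.interval_A) for c in calls if c.seq_id == seq),
        default=0,
    )
    return best >= min_frac * (e - s)
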