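"""Shared fixtures: toy alignments and a small simulated genome pair."""

import pytest

from scramblekit import (
    AlignmentBlock,
    AlignmentSet,
    ChromosomeLayout,
    GenomeLayout,
    SimulationConfig,
    emit_alignments,
    evolve,
    make_ancestral_genome,
)
from scramblekit.synthetic_data import ChromSpec


def make_aln(blocks, t_lengths, q_lengths):
    """AlignmentSet from raw block tuples and chromosome-length dicts."""
    t = GenomeLayout([ChromosomeLayout(n, ln) for n, ln in t_lengths.items()])
    q = GenomeLayout([ChromosomeLayout(n, ln) for n, ln in q_lengths.items()])
    return AlignmentSet(
        [AlignmentBlock(*b, id=i) for i, b in enumerate(blocks)], t, q
    )


@pytest.fixture
def toy_chain_aln():
    """Two collinear blocks with an unaligned gap between them (one chain,
    one bridge, one trailing breakpoint) on a 40-base chromosome."""
    return make_aln(
        [("t1", 0, 10, "q1", 0, 10, "+"), ("t1", 20, 30, "q1", 20, 30, "+")],
        {"t1": 40},
        {"q1": 40},
    )


@pytest.fixture(scope="session")
def small_cfg():
    """A compact two-chromosome config that keeps simulator tests fast."""
    return SimulationConfig(
        seed=7,
        chromosomes=[
            ChromSpec("chr1", 600_000, 250_000),
            ChromSpec("chr2", 400_000, 150_000),
        ],
        n_genes=300,
        n_events=12,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """Ancestor, two evolved descendants and their true alignment."""
    anc = make_ancestral_genome(small_cfg)
    ga, log_a = evolve(anc, small_cfg, "A")
    gb, log_b = evolve(anc, small_cfg, "B")
    aln = emit_alignments(anc, ga, gb)
    return {"ancestor": anc, "A": ga, "B": gb, "log_A": log_a, "log_B": log_b,
            "aln": aln}
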