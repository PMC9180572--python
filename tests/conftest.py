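"""Shared fixtures: seeded synthetic studies reused across test modules.

Everything is generated programmatically; the expensive simulations are
session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from siblingscaf import lift, scaffold, simdata, triage


@pytest.fixture(scope="session")
def demo_sim():
    """A small two-chromosome sibling-genome study at 2% divergence.

    Mirrors the bundled demo: planted satellite arrays (two isolated as
    satellite-only contigs, one embedded), TE insertions, N-gaps in the
    reference, sheared contigs and a triplicated mitogenome contig.
    """
    cfg = simdata.SimConfig(
        n_chromosomes=2,
        chrom_length=150_000,
        n_genes_per_chrom=15,
        gene_length=2_000,
        divergence=0.02,
        array_lengths=(150, 200, 100),
        te_families=(
            simdata.TEFamily("Tc1", "DNA/TcMar-Tc1", 1300, 8),
            simdata.TEFamily("IS3EU", "DNA/IS3EU", 900, 6),
            simdata.TEFamily("L2A", "LINE/L2", 2500, 3),
        ),
        n_gap_spec=((0, 40_000, 200), (0, 101_000, 400), (1, 77_000, 300)),
        contig_break_spec=simdata.ContigBreakSpec(isolate_min_bp=20_000),
        read_length_mean=12_000,
        read_length_sd=1_200,
        coverage=20.0,
        seed=7,
    )
    reference, annotation, sibling, contigs, reads, truth = simdata.simulate_all(cfg)
    return {
        "config": cfg,
        "reference": reference,
        "annotation": annotation,
        "sibling": sibling,
        "contigs": contigs,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def demo_lift(demo_sim):
    """Liftover + UMF counts + triage + placements on the demo study."""
    lifted = lift.lift_features(
        demo_sim["reference"], demo_sim["annotation"], demo_sim["contigs"]
    )
    counts = lift.count_umfs(lifted)
    result = triage.filter_contigs(demo_sim["contigs"], counts)
    retained = {n: demo_sim["contigs"][n] for n in result.retained}
    placements = scaffold.place_contigs(retained, demo_sim["reference"])
    groups, unplaced = scaffold.build_linkage_groups(
        placements, retained, demo_sim["reference"]
    )
    return {
        "lifted": lifted,
        "umf_counts": counts,
        "triage": result,
        "placements": placements,
        "groups": groups,
        "unplaced": unplaced,
        "retained": retained,
    }


@pytest.fixture(scope="session")
def megabase_sim():
    """A ~1-Mb single-chromosome genome with 20% planted satellite at 30x.

    Used for genome-size recovery and gap-filling accuracy: 3 arrays of 400
    monomers (199.2 kb satellite), no TEs, ten 200-bp N-gaps planted in the
    reference, 30x reads of the sibling.
    """
    cfg = simdata.SimConfig(
        n_chromosomes=1,
        chrom_length=800_000,
        n_genes_per_chrom=40,
        gene_length=2_000,
        divergence=0.02,
        array_lengths=(400, 400, 400),
        te_families=(),
        n_gap_spec=tuple((0, p, 200) for p in range(60_000, 760_000, 70_000)),
        coverage=30.0,
        seed=11,
    )
    reference, annotation, truth = simdata.make_reference(cfg)
    sibling, truth = simdata.derive_sibling(reference, truth, cfg)
    reads = simdata.simulate_reads(sibling, cfg)
    return {
        "config": cfg,
        "reference": reference,
        "annotation": annotation,
        "sibling": sibling,
        "reads": reads,
        "truth": truth,
    }


def sibling_offset(truth: simdata.TruthRecord, chrom: str, pos: int) -> int:
    """Cumulative inserted bp before reference position ``pos`` on ``chrom``.

    Reconstructs pre-insertion positions from the final truth intervals so
    reference coordinates can be mapped into the sibling. Asserts that no
    insertion falls strictly inside the queried position's interval usage.
    """
    ins = sorted(
        [(a["start"], a["end"]) for a in truth.arrays if a["chrom"] == chrom]
        + [(t["start"], t["end"]) for t in truth.tes if t["chrom"] == chrom]
    )
    delta = cum = 0
    for fs, fe in ins:
        pre = fs - cum
        if pre <= pos:
            delta += fe - fs
            cum += fe - fs
        else:
            break
    return delta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
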