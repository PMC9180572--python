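"""Simulator correctness: determinism, truth bookkeeping, conservation laws."""

import numpy as np
import pytest

from siblingscaf import simdata
from siblingscaf.util import revcomp


def small_cfg(**kw):
    base = dict(
        n_chromosomes=1,
        chrom_length=100_000,
        n_genes_per_chrom=10,
        array_lengths=(50,),
        seed=1,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


class TestMakeReference:
    def test_deterministic_and_contained(self):
        cfg = small_cfg()
        ref1, ann1, truth1 = simdata.make_reference(cfg)
        ref2, ann2, _ = simdata.make_reference(cfg)
        assert ref1 == ref2
        assert ann1 == ann2
        genes = [f for f in ann1 if f.type == "gene"]
        assert len(genes) == 10
        assert all(0 <= f.start < f.end <= 100_000 for f in ann1)
        # genes do not overlap
        ivs = sorted((f.start, f.end) for f in genes)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_gap_spec_inserts_exact_n_run(self):
        cfg = small_cfg(n_gap_spec=((50_000, 100),))
        ref, _, truth = simdata.make_reference(cfg)
        seq = ref["chr1"]
        assert seq[50_000:50_100] == "N" * 100
        assert seq.count("N") == 100
        assert truth.gaps == [{"chrom": "chr1", "start": 50_000, "end": 50_100}]

    def test_genome_size_is_sum_of_chromosomes(self):
        cfg = small_cfg(n_chromosomes=3)
        ref, _, truth = simdata.make_reference(cfg)
        assert truth.genome_size == sum(len(s) for s in ref.values())

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            cfg = small_cfg(n_genes_per_chrom=60, gene_length=2_000)
            simdata.make_reference(cfg)


class TestDeriveSibling:
    def test_zero_divergence_no_insertions_is_identity(self):
        cfg = small_cfg(divergence=0.0, array_lengths=(), te_families=())
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        assert sib == ref
        assert t2.repeat_fraction == 0.0

    def test_substitution_count_in_binomial_band(self):
        """Brute-force base diff against Binomial(n, p) expectation (3 sigma)."""
        cfg = small_cfg(divergence=0.02, array_lengths=(), te_families=())
        ref, _, truth = simdata.make_reference(cfg)
        sib, _ = simdata.derive_sibling(ref, truth, cfg)
        n = len(ref["chr1"])
        diffs = sum(a != b for a, b in zip(ref["chr1"], sib["chr1"]))
        mean = n * 0.02
        sigma = (n * 0.02 * 0.98) ** 0.5
        assert abs(diffs - mean) < 3 * sigma

    def test_insertion_length_conservation(self):
        cfg = small_cfg(divergence=0.0, array_lengths=(100,), te_families=(),
                        satellite_monomer_length=166)
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        assert len(sib["chr1"]) == len(ref["chr1"]) + 100 * 166
        (arr,) = t2.arrays
        assert arr["end"] - arr["start"] == 16_600
        # planted array bp is recomputable from truth intervals
        planted = sum(a["end"] - a["start"] for a in t2.arrays) + sum(
            t["end"] - t["start"] for t in t2.tes
        )
        assert t2.repeat_fraction == planted / t2.sibling_size

    def test_shifted_features_match_sibling_sequence(self):
        """At zero divergence each shifted gene reads the same bases."""
        cfg = small_cfg(divergence=0.0)
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        for f0, f1 in zip(truth.ref_features, t2.sibling_features):
            a = truth.clean_ref[f0["chrom"]][f0["start"] : f0["end"]]
            b = sib[f1["chrom"]][f1["start"] : f1["end"]]
            assert a == b


class TestShearContigs:
    def test_explicit_thirds_round_trip(self):
        cfg = small_cfg(
            divergence=0.0, array_lengths=(), te_families=(),
            contig_break_spec=simdata.ContigBreakSpec(
                explicit={"chr1": (33_000, 66_000)}, rc_fraction=0.5
            ),
        )
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        tigs, t3 = simdata.shear_contigs(sib, t2, cfg)
        assert len(tigs) == 3
        restored = []
        for c in t3.contigs:
            s = tigs[c["name"]]
            restored.append(revcomp(s) if c["orientation"] == "-" else s)
        assert "".join(restored) == sib["chr1"]

    def test_truth_tiles_chromosome_exactly(self, demo_sim):
        truth = demo_sim["truth"]
        for chrom, seq in demo_sim["sibling"].items():
            ivs = sorted(
                (c["start"], c["end"]) for c in truth.contigs if c["chrom"] == chrom
            )
            assert ivs[0][0] == 0 and ivs[-1][1] == len(seq)
            assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))

    def test_array_cut_contig_marked_satellite(self, demo_sim):
        truth = demo_sim["truth"]
        sat = [c for c in truth.contigs if c["satellite_dominated"]]
        assert sat, "demo plants isolated arrays"
        assert all(not c["gene_ids"] for c in sat)

    def test_zero_breaks_one_contig_per_chromosome(self):
        cfg = small_cfg(
            array_lengths=(), te_families=(),
            contig_break_spec=simdata.ContigBreakSpec(
                n_random_breaks=0, isolate_arrays=False, rc_fraction=0.0
            ),
        )
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        tigs, _ = simdata.shear_contigs(sib, t2, cfg)
        assert len(tigs) == cfg.n_chromosomes

    def test_breakpoint_outside_sequence_errors(self):
        cfg = small_cfg(
            contig_break_spec=simdata.ContigBreakSpec(explicit={"chr1": (10**7,)})
        )
        ref, _, truth = simdata.make_reference(cfg)
        sib, t2 = simdata.derive_sibling(ref, truth, cfg)
        with pytest.raises(ValueError, match="breakpoint"):
            simdata.shear_contigs(sib, t2, cfg)


class TestSimulateReads:
    def test_coverage_contract(self):
        cfg = small_cfg(coverage=30.0)
        ref, _, truth = simdata.make_reference(cfg)
        sib, _ = simdata.derive_sibling(ref, truth, cfg)
        reads = simdata.simulate_reads(sib, cfg)
        total = sum(len(r) for r in reads.values())
        genome = sum(len(s) for s in sib.values())
        assert 0.95 * 30 <= total / genome <= 1.05 * 30

    def test_error_free_reads_are_exact_substrings(self):
        """Brute-force substring oracle at error rate 0."""
        cfg = small_cfg(
            chrom_length=30_000, coverage=3.0, read_error_rate=0.0,
            read_length_mean=4_000, read_length_sd=300,
            array_lengths=(), te_families=(),
        )
        ref, _, truth = simdata.make_reference(cfg)
        sib, _ = simdata.derive_sibling(ref, truth, cfg)
        reads = simdata.simulate_reads(sib, cfg)
        genome = sib["chr1"]
        genome_rc = revcomp(genome)
        assert reads
        for r in reads.values():
            assert r in genome or r in genome_rc

    def test_fixed_seed_byte_identical(self):
        cfg = small_cfg()
        ref, _, truth = simdata.make_reference(cfg)
        sib, _ = simdata.derive_sibling(ref, truth, cfg)
        assert simdata.simulate_reads(sib, cfg) == simdata.simulate_reads(sib, cfg)


class TestMakeMitoContig:
    def test_exact_copies_length(self):
        cfg = small_cfg()
        unit = simdata._random_seq(np.random.default_rng(5), 15_000)
        contig, truth = simdata.make_mito_contig(unit, 3, 0.0, cfg)
        (seq,) = contig.values()
        assert len(seq) == 45_000
        assert seq == truth.mito_unit * 3

    def test_single_copy_is_rotated_unit(self):
        cfg = small_cfg()
        unit = simdata._random_seq(np.random.default_rng(5), 2_000)
        contig, truth = simdata.make_mito_contig(unit, 1, 0.0, cfg)
        (seq,) = contig.values()
        assert seq == truth.mito_unit
        off = truth.mito_rotation
        assert seq == unit[off:] + unit[:off]

    def test_near_identical_copies(self):
        from siblingscaf.anchors import align_identity

        cfg = small_cfg()
        unit = simdata._random_seq(np.random.default_rng(5), 15_000)
        contig, truth = simdata.make_mito_contig(unit, 3, 0.0001, cfg)
        (seq,) = contig.values()
        copies = [seq[i * 15_000 : (i + 1) * 15_000] for i in range(3)]
        for a in copies:
            for b in copies:
                assert align_identity(a, b) >= 99.9

    def test_rejects_destructive_divergence(self):
        with pytest.raises(ValueError):
            simdata.make_mito_contig("ACGT" * 100, 3, 0.6, small_cfg())
        with pytest.raises(ValueError):
            simdata.make_mito_contig("ACGT" * 100, 0, 0.0, small_cfg())


def test_simulate_all_deterministic(demo_sim):
    cfg = demo_sim["config"]
    reference, annotation, sibling, contigs, reads, truth = simdata.simulate_all(cfg)
    assert reference == demo_sim["reference"]
    assert contigs == demo_sim["contigs"]
    assert reads == demo_sim["reads"]
    assert truth.repeat_fraction == demo_sim["truth"].repeat_fraction


def test_config_validation():
    with pytest.raises(ValueError):
        small_cfg(divergence=1.5)
    with pytest.raises(ValueError):
        small_cfg(satellite_monomer_length=10)
    with pytest.raises(ValueError):
        small_cfg(coverage=0.0)
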