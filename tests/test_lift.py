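"""Liftover: exact-copy round trips, UMF distinctness, retention arithmetic,
location retention against a recount oracle."""

import pytest

from siblingscaf import lift, simdata
from siblingscaf.annotations import AnnotationFeature
from siblingscaf.util import revcomp


@pytest.fixture(scope="module")
def exact_tile_sim():
    """Zero divergence, contigs = exact chromosome tiles (no insertions)."""
    cfg = simdata.SimConfig(
        n_chromosomes=2, chrom_length=60_000, n_genes_per_chrom=5,
        divergence=0.0, array_lengths=(), te_families=(),
        contig_break_spec=simdata.ContigBreakSpec(
            n_random_breaks=1, isolate_arrays=False, rc_fraction=0.5
        ),
        seed=21,
    )
    ref, ann, truth = simdata.make_reference(cfg)
    sib, t2 = simdata.derive_sibling(ref, truth, cfg)
    tigs, t3 = simdata.shear_contigs(sib, t2, cfg)
    return ref, ann, tigs, t3


class TestLiftFeatures:
    def test_exact_window_copy_shifts_coordinates(self):
        cfg = simdata.SimConfig(
            n_chromosomes=1, chrom_length=40_000, n_genes_per_chrom=2,
            divergence=0.0, array_lengths=(), te_families=(), seed=2,
        )
        ref, ann, _ = simdata.make_reference(cfg)
        gene = next(f for f in ann if f.type == "gene" and f.start >= 10_000)
        window = ref["chr1"][10_000:35_000]
        lifted = lift.lift_features(ref, [gene], {"win": window})
        assert len(lifted) == 1
        lf = lifted[0]
        assert lf.identity == 100.0 and lf.coverage == 100.0
        assert lf.start == gene.start - 10_000
        assert lf.end == gene.end - 10_000
        assert lf.strand == gene.strand

    def test_no_shared_minimizers_zero_lifts(self, rng):
        ref = {"chr1": simdata._random_seq(rng, 5_000)}
        ann = [AnnotationFeature("g1", "gene", "chr1", 1_000, 3_000)]
        other = {"tig": simdata._random_seq(rng, 5_000)}
        assert lift.lift_features(ref, ann, other) == []

    def test_round_trip_exact_tiles(self, exact_tile_sim):
        """Zero divergence: every feature inside a tile lifts at 100/100 to it."""
        ref, ann, tigs, t3 = exact_tile_sim
        lifted = lift.lift_features(ref, ann, tigs)
        host = {
            fid: c["name"] for c in t3.contigs for fid in c["feature_ids"]
        }
        by_id = {}
        for lf in lifted:
            by_id.setdefault(lf.source_id, []).append(lf)
        for f in ann:
            if f.id not in host:
                continue
            assert f.id in by_id, f"{f.id} not lifted"
            best = by_id[f.id][0]
            assert best.contig == host[f.id]
            assert best.identity == 100.0
            assert best.coverage == 100.0

    def test_minus_strand_contig_flips_feature_strand(self):
        cfg = simdata.SimConfig(
            n_chromosomes=1, chrom_length=30_000, n_genes_per_chrom=2,
            divergence=0.0, array_lengths=(), te_families=(), seed=9,
        )
        ref, ann, _ = simdata.make_reference(cfg)
        gene = next(f for f in ann if f.type == "gene")
        tig = revcomp(ref["chr1"])
        (lf,) = lift.lift_features(ref, [gene], {"rc": tig})
        assert lf.strand == ("-" if gene.strand == "+" else "+")
        assert lf.start == len(tig) - gene.end
        assert lf.end == len(tig) - gene.start

    def test_feature_beyond_chromosome_rejected(self, rng):
        ref = {"chr1": simdata._random_seq(rng, 1_000)}
        bad = [AnnotationFeature("g", "gene", "chr1", 500, 2_000)]
        with pytest.raises(ValueError, match="bounds"):
            lift.lift_features(ref, bad, {"t": ref["chr1"]})

    def test_diverged_sim_gene_recovery(self, demo_sim, demo_lift):
        """At 2% divergence, nearly all genes on gene-bearing contigs lift to
        the correct contig."""
        truth = demo_sim["truth"]
        host = {g: c["name"] for c in truth.contigs for g in c["gene_ids"]}
        lifted_map = {}
        for lf in demo_lift["lifted"]:
            if lf.type == "gene" and lf.copy_index == 0:
                lifted_map[lf.source_id] = lf.contig
        hits = sum(1 for g, tig in host.items() if lifted_map.get(g) == tig)
        assert hits / len(host) >= 0.95


class TestCountUmfs:
    def test_copies_collapse_to_one(self):
        lfs = [
            lift.LiftedFeature("g1", "gene", "tigA", 0, 10, "+", i, 99.0, 99.0)
            for i in range(3)
        ]
        assert lift.count_umfs(lfs) == {"tigA": 1}

    def test_empty(self):
        assert lift.count_umfs([]) == {}

    def test_matches_truth_feature_counts_at_zero_divergence(self, exact_tile_sim):
        ref, ann, tigs, t3 = exact_tile_sim
        counts = lift.count_umfs(lift.lift_features(ref, ann, tigs))
        for c in t3.contigs:
            assert counts.get(c["name"], 0) == len(c["feature_ids"])


class TestRetention:
    @pytest.mark.parametrize(
        "total,n_lifted,expected",
        [(14_467, 13_845, 95.70), (171_320, 149_045, 87.00), (220, 144, 65.45),
         (10, 0, 0.00)],
    )
    def test_percentages_round_half_up_2dp(self, total, n_lifted, expected):
        assert lift.retention_pct(total, n_lifted) == expected

    def test_report_omits_absent_types(self):
        ann = [AnnotationFeature("g1", "gene", "c", 0, 10)]
        rows = lift.retention_report(ann, [])
        assert [r.type for r in rows] == ["gene"]
        assert rows[0].retained_pct == 0.00


class TestLocationRetention:
    def test_all_correct_gives_one(self, demo_sim, demo_lift):
        truth = demo_sim["truth"]
        placements = {
            c["name"]: c["chrom"] for c in truth.contigs if c["gene_ids"]
        }
        fractions, overall = lift.location_retention(
            demo_lift["lifted"], placements, demo_sim["annotation"]
        )
        assert overall == 1.0
        assert all(v == 1.0 for g, v in fractions.items() if g != "unplaced")

    def test_recount_oracle_with_forced_misplacement(self, demo_sim, demo_lift):
        truth = demo_sim["truth"]
        placements = {
            c["name"]: c["chrom"] for c in truth.contigs if c["gene_ids"]
        }
        victim = next(c for c in truth.contigs if c["gene_ids"])
        wrong = "chr2" if victim["chrom"] == "chr1" else "chr1"
        placements[victim["name"]] = wrong
        fractions, overall = lift.location_retention(
            demo_lift["lifted"], placements, demo_sim["annotation"]
        )
        # brute-force recount
        src = {f.id: f.chrom for f in demo_sim["annotation"] if f.type == "gene"}
        seen = set()
        total = match = 0
        for lf in demo_lift["lifted"]:
            if lf.type != "gene" or (lf.source_id, lf.contig) in seen:
                continue
            seen.add((lf.source_id, lf.contig))
            grp = placements.get(lf.contig, "unplaced")
            if grp == "unplaced":
                continue
            total += 1
            match += src[lf.source_id] == grp
        assert overall == pytest.approx(match / total)
        assert overall < 1.0

    def test_empty(self):
        assert lift.location_retention([], {}, []) == ({}, 0.0)


def test_distinctness_invariant(demo_lift):
    counts = demo_lift["umf_counts"]
    distinct = {lf.source_id for lf in demo_lift["lifted"]}
    assert sum(counts.values()) >= len(distinct)


def test_lifted_gff3_round_trip(tmp_path, demo_lift):
    from siblingscaf.annotations import read_gff3

    path = tmp_path / "lifted.gff3"
    lift.write_lifted_gff3(demo_lift["lifted"], path)
    back = read_gff3(path)
    assert len(back) == len(demo_lift["lifted"])
    assert back[0].attributes["copy_num"] == "0"
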