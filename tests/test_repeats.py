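"""Satellite/repeat engine: tandem hit recovery against a sliding-window
oracle, the five-consecutive-monomer array criterion, summaries, library
annotation, comparisons, density tracks."""

import numpy as np
import pytest

import edlib

from siblingscaf import repeats, simdata
from siblingscaf.util import revcomp


@pytest.fixture(scope="module")
def monomer():
    return simdata._random_seq(np.random.default_rng(42), 166)


class TestFindMonomerHits:
    def test_exact_tandem_copies(self, monomer, rng):
        pad = simdata._random_seq(rng, 500)
        target = {"t": pad + monomer * 10 + pad}
        hits = repeats.find_monomer_hits(target, monomer)
        assert len(hits) == 10
        assert all(h.identity == 100.0 and h.coverage == 100.0 for h in hits)
        assert all(h.strand == "+" for h in hits)

    def test_reverse_strand_detection(self, monomer, rng):
        pad = simdata._random_seq(rng, 500)
        target = {"t": pad + revcomp(monomer * 6) + pad}
        hits = repeats.find_monomer_hits(target, monomer)
        assert len(hits) == 6
        assert all(h.strand == "-" for h in hits)

    def test_no_similarity_no_hits(self, monomer, rng):
        target = {"t": simdata._random_seq(rng, 5_000)}
        assert repeats.find_monomer_hits(target, monomer) == []

    def test_strict_thresholds(self, monomer, rng):
        """A hit exactly at the threshold is rejected (> not >=)."""
        pad = simdata._random_seq(rng, 300)
        target = {"t": pad + monomer * 3 + pad}
        assert repeats.find_monomer_hits(target, monomer, min_identity=100.0) == []
        assert repeats.find_monomer_hits(target, monomer, min_coverage=100.0) == []

    def test_mutated_copies_vs_sliding_oracle(self, monomer):
        """5% mutated copies: hit count within +-1 of plant, and on short
        targets the hit set matches a brute-force all-positions oracle."""
        mut_rng = np.random.default_rng(77)
        copies = [simdata._mutate(monomer, 0.05, mut_rng) for _ in range(8)]
        target_seq = (
            simdata._random_seq(mut_rng, 200) + "".join(copies)
            + simdata._random_seq(mut_rng, 200)
        )
        hits = repeats.find_monomer_hits({"t": target_seq}, monomer)
        assert abs(len(hits) - 8) <= 1
        # oracle: best alignment at every candidate start on a <=2 kb target
        m = len(monomer)
        oracle_positions = []
        for s in range(0, len(target_seq) - m // 2):
            window = target_seq[s : s + m + 10]
            if len(window) < m // 2:
                continue
            res = edlib.align(monomer, window, mode="HW")
            ident = 100.0 * (m - res["editDistance"]) / m
            if ident > 70.0:
                oracle_positions.append(s)
        # every accepted hit lies in an oracle-supported region
        for h in hits:
            assert any(abs(h.start - s) <= 10 for s in oracle_positions)

    def test_non_acgt_monomer_rejected(self):
        with pytest.raises(ValueError):
            repeats.find_monomer_hits({"t": "ACGT" * 100}, "ACGTN" * 10)


class TestMergeArrays:
    def test_ten_contiguous_hits_one_array(self, monomer, rng):
        target = {"t": monomer * 10}
        hits = repeats.find_monomer_hits(target, monomer)
        arrays = repeats.merge_arrays(hits, len(monomer))
        assert len(arrays) == 1
        assert arrays[0].n_monomers == 10
        assert arrays[0].end - arrays[0].start == 1_660

    def test_four_copy_boundary_yields_nothing(self, monomer, rng):
        pad = simdata._random_seq(rng, 400)
        hits = repeats.find_monomer_hits({"t": pad + monomer * 4 + pad}, monomer)
        assert len(hits) == 4
        assert repeats.merge_arrays(hits, len(monomer)) == []

    def test_five_copy_boundary_yields_one(self, monomer, rng):
        pad = simdata._random_seq(rng, 400)
        hits = repeats.find_monomer_hits({"t": pad + monomer * 5 + pad}, monomer)
        arrays = repeats.merge_arrays(hits, len(monomer))
        assert len(arrays) == 1 and arrays[0].n_monomers == 5

    def test_insertion_splits_chains(self, monomer, rng):
        spacer = simdata._random_seq(rng, 1_000)
        target = {"t": monomer * 6 + spacer + monomer * 7}
        hits = repeats.find_monomer_hits(target, monomer)
        arrays = repeats.merge_arrays(hits, len(monomer))
        assert [a.n_monomers for a in arrays] == [6, 7]
        # recount oracle: hits on each side of the spacer
        left = sum(1 for h in hits if h.end <= 6 * 166 + 10)
        right = len(hits) - left
        assert (left, right) == (6, 7)


class TestArraySummary:
    def test_fraction_arithmetic(self, monomer):
        arrays = [repeats.RepeatArray("t", 0, 1_660, 10, 100.0, "+")]
        s = repeats.array_summary(arrays, {"t": "A" * 10_000})
        assert s.genome_fraction_pct == 16.6
        assert s.total_bp == 1_660
        assert s.max_array_bp == 1_660

    def test_empty(self):
        s = repeats.array_summary([], {"t": "A" * 100})
        assert s.genome_fraction_pct == 0.0 and s.histogram == {}

    def test_planted_bp_recovered(self, demo_sim):
        truth = demo_sim["truth"]
        hits = repeats.find_monomer_hits(demo_sim["contigs"], truth.monomer)
        arrays = repeats.merge_arrays(hits, len(truth.monomer))
        found_bp = sum(a.end - a.start for a in arrays)
        truth_bp = sum(a["end"] - a["start"] for a in truth.arrays)
        assert abs(found_bp - truth_bp) / truth_bp <= 0.02


class TestAnnotateLibrary:
    def test_planted_family_counts(self, demo_sim):
        truth = demo_sim["truth"]
        ann = repeats.annotate_library(demo_sim["contigs"], truth.te_library)
        fam_counts = {k: v[0] for k, v in ann.per_family().items()}
        planted = {}
        for t in truth.tes:
            planted[t["family"]] = planted.get(t["family"], 0) + 1
        for fam, n in planted.items():
            assert fam_counts.get(fam, 0) == n

    def test_diverged_fragment_excluded_by_70_rule(self, rng):
        consensus = simdata._random_seq(rng, 400)
        mut_rng = np.random.default_rng(3)
        degraded = simdata._mutate(consensus, 0.40, mut_rng)
        genome = {"t": simdata._random_seq(rng, 500) + degraded}
        ann = repeats.annotate_library(genome, {"el#LINE/L2": consensus})
        assert ann.elements == []

    def test_empty_library(self):
        assert repeats.annotate_library({"t": "ACGT" * 100}, {}).elements == []

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            repeats.annotate_library(
                {"t": "ACGT"}, {"a#DNA": "ACGTACGTACGTACGTACGTACGT",
                                "a#LINE": "ACGTACGTACGTACGTACGTACGT"}
            )


class TestCompareRepeats:
    def _annot(self, fam_class_counts):
        ann = repeats.RepeatAnnotation()
        for (fam, cls), n in fam_class_counts.items():
            for i in range(n):
                ann.elements.append(
                    repeats.RepeatElement(fam, cls, "t", i * 100, i * 100 + 50, "+", 99.0)
                )
        return ann

    def test_identical_all_zero(self):
        a = self._annot({("Tc1", "DNA"): 3})
        diff = repeats.compare_repeats(a, a)
        assert all(v == (0, 0) for v in diff["class"].values())
        assert all(v == (0, 0) for v in diff["family"].values())

    def test_planted_extra_copies(self):
        a = self._annot({("Tc1", "DNA"): 3})
        b = self._annot({("Tc1", "DNA"): 103})
        diff = repeats.compare_repeats(a, b)
        assert diff["family"]["Tc1"][0] == -100

    def test_one_sided_family(self):
        a = self._annot({("Tc1", "DNA"): 5})
        b = self._annot({})
        assert repeats.compare_repeats(a, b)["family"]["Tc1"] == (5, 250)


class TestDensityTracks:
    def test_conservation_and_binning(self):
        ivs = [("c", i * 1_000, i * 1_000 + 100) for i in range(10)]
        tracks = repeats.density_tracks(ivs, {"c": 10_000}, 2_000)
        assert tracks["c"].sum() == 10
        assert tracks["c"].size == 5

    def test_single_bin(self):
        ivs = [("c", 0, 10), ("c", 20, 30)]
        tracks = repeats.density_tracks(ivs, {"c": 10_000}, 10_000)
        assert tracks["c"].tolist() == [2]

    def test_bad_bin_rejected(self):
        with pytest.raises(ValueError):
            repeats.density_tracks([], {"c": 10}, 0)


def test_low_complexity_flags_homopolymer(rng):
    seq = simdata._random_seq(rng, 500) + "A" * 200 + simdata._random_seq(rng, 500)
    els = repeats.find_low_complexity({"t": seq})
    assert len(els) == 1
    assert els[0].start >= 400 and els[0].end <= 800
    assert els[0].class_label == "Low_complexity"


def test_satellite_funnel_echo(demo_sim, demo_lift):
    """Assembly-wide satellite fraction never exceeds the all-contigs fraction
    once satellite contigs are discarded."""
    truth = demo_sim["truth"]
    all_tigs = demo_sim["contigs"]
    hits_all = repeats.find_monomer_hits(all_tigs, truth.monomer)
    arrays_all = repeats.merge_arrays(hits_all, len(truth.monomer))
    frac_all = repeats.array_summary(arrays_all, all_tigs).genome_fraction_pct
    scafs = {g.name: g.sequence for g in demo_lift["groups"]}
    hits_s = repeats.find_monomer_hits(scafs, truth.monomer)
    arrays_s = repeats.merge_arrays(hits_s, len(truth.monomer))
    frac_s = repeats.array_summary(arrays_s, scafs).genome_fraction_pct
    assert frac_all >= frac_s
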