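"""Composition features, clustering, and the five inclusion criteria."""

import itertools

import numpy as np
import pytest

from eukfinder._kmers import revcomp
from eukfinder.binning import (
    ClusterAssignment,
    ContigEvidence,
    apply_inclusion_criteria,
    cluster_contigs,
    composition_vector,
    consensus_membership,
    estimate_depth,
    filter_marker_calls,
    flag_euk_clusters,
    flag_mitochondrial,
    scan_marker_templates,
)
from eukfinder.io_formats import AlignmentHit, DepthRecord, MarkerCall, SeqRecord
from eukfinder.simulate import _markov_sequence, marker_templates
from eukfinder.taxonomy import TaxCategory


class TestCompositionVector:
    def test_poly_a_single_feature(self):
        v = composition_vector(SeqRecord("c", "A" * 100), kset=(4,))
        assert v.values.sum() == pytest.approx(1.0)
        assert (v.values > 0).sum() == 1

    def test_revcomp_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        v1 = composition_vector(SeqRecord("c", seq), kset=(5, 6))
        v2 = composition_vector(SeqRecord("c", revcomp(seq)), kset=(5, 6))
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-12)

    def test_block_dimensions_and_sums(self, rng):
        # canonical k-mer counts: (4^k + 4^(k/2))/2 for even k, 4^k/2 for odd
        seq = "".join(rng.choice(list("ACGT"), size=300))
        v = composition_vector(SeqRecord("c", seq), kset=(5, 6))
        assert v.values.size == 512 + 2080
        assert v.values[:512].sum() == pytest.approx(1.0, abs=1e-9)
        assert v.values[512:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_contig_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            composition_vector(SeqRecord("c", "ACGT"), kset=(5, 6))


class TestClusterContigs:
    def test_planted_two_genomes_recovered(self):
        """Contigs from GC 30% vs 65% genomes separate at ≥95% purity."""
        rng = np.random.default_rng(42)
        contigs, truth = [], []
        for gi, gc in enumerate((0.30, 0.65)):
            genome = _markov_sequence(np.random.default_rng(100 + gi), 120_000, gc)
            for j in range(50):
                start = int(rng.integers(0, len(genome) - 2000))
                contigs.append(SeqRecord(f"g{gi}c{j}", genome[start : start + 2000]))
                truth.append(gi)
        vectors = [composition_vector(c, (4,)) for c in contigs]
        assignment = cluster_contigs(vectors, "k4", seed=1234)
        labels = np.array([assignment.labels[c.id] for c in contigs])
        truth = np.array(truth)
        purity = 0
        for lab in np.unique(labels):
            counts = np.bincount(truth[labels == lab])
            purity += counts.max()
        assert purity / len(contigs) >= 0.95

    def test_two_contigs_no_crash(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(2)]
        vectors = [composition_vector(SeqRecord(f"c{i}", s), (4,)) for i, s in enumerate(seqs)]
        a = cluster_contigs(vectors, "k4")
        assert set(a.labels) == {"c0", "c1"}

    def test_identical_vectors_single_cluster(self):
        vectors = [composition_vector(SeqRecord(f"c{i}", "ACGT" * 100), (4,)) for i in range(5)]
        with pytest.warns(UserWarning, match="identical"):
            a = cluster_contigs(vectors, "k4")
        assert set(a.labels.values()) == {0}

    def test_determinism(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(30)]
        vectors = [composition_vector(SeqRecord(f"c{i}", s), (4,)) for i, s in enumerate(seqs)]
        a1 = cluster_contigs(vectors, "k4", seed=9)
        a2 = cluster_contigs(vectors, "k4", seed=9)
        assert a1.labels == a2.labels


class TestEstimateDepth:
    def test_uniform_depth_arithmetic(self, rng):
        contig = SeqRecord("c1", "".join(rng.choice(list("ACGT"), size=1000)))
        reads = [SeqRecord(f"r{i}", contig.sequence[i * 90 : i * 90 + 100]) for i in range(10)]
        depth = estimate_depth(reads, [contig])
        assert depth[0].mean_depth == pytest.approx(1.0)

    def test_unmatched_contig_zero(self, rng):
        c1 = SeqRecord("c1", "".join(rng.choice(list("ACGT"), size=1000)))
        c2 = SeqRecord("c2", "".join(rng.choice(list("ACGT"), size=1000)))
        reads = [SeqRecord("r0", c1.sequence[100:200])]
        depth = {d.contig_id: d.mean_depth for d in estimate_depth(reads, [c1, c2])}
        assert depth["c2"] == 0.0 and depth["c1"] > 0

    def test_agrees_with_truth_based_depth(self, tiny_communities, tiny_refs, tiny_db):
        """Internal k-mer depth vs per-interval truth accounting, within 10%."""
        from eukfinder.simulate import perfect_assembly_fixture

        community = tiny_communities[-1]
        euk_reads = [
            r
            for p in community.pairs
            for r in p
            if community.truth.reads[r.id].genome_id == "euk01"
        ]
        contigs, ctruth = perfect_assembly_fixture(
            community.truth.reads, tiny_refs, read_ids=[r.id for r in euk_reads], min_len=1000
        )
        got = {d.contig_id: d.mean_depth for d in estimate_depth(euk_reads, contigs)}
        for cid, t in ctruth.items():
            truth_bases = sum(
                min(t.end, r.end) - max(t.start, r.start)
                for r in (community.truth.reads[x.id] for x in euk_reads)
                if r.replicon == t.replicon and r.genome_id == t.genome_id
                and min(t.end, r.end) > max(t.start, r.start)
            )
            expected = truth_bases / (t.end - t.start)
            if expected > 0.5:  # skip sliver contigs where a single read flips the ratio
                assert got[cid] == pytest.approx(expected, rel=0.10)


class TestMarkerCalls:
    @pytest.mark.parametrize(
        "aln,pident,kept",
        [(300, 95.0, False), (301, 90.1, True), (301, 90.0, False), (1000, 95.0, True)],
    )
    def test_filter_strict_thresholds(self, aln, pident, kept):
        calls = [MarkerCall("c", "SSU", pident, aln, "Eukaryota;x")]
        assert bool(filter_marker_calls(calls)) is kept

    def test_filter_empty(self):
        assert filter_marker_calls([]) == []

    def test_template_scan_finds_planted_marker(self, rng):
        templates = marker_templates()
        flank = "".join(rng.choice(list("ACGT"), size=800))
        contig = SeqRecord("c", flank + templates["SSU"] + flank)
        calls = scan_marker_templates([contig], templates)
        ssu = [c for c in calls if c.marker == "SSU"]
        assert ssu and ssu[0].aln_length == len(templates["SSU"])

    def test_template_scan_detects_revcomp(self, rng):
        templates = marker_templates()
        contig = SeqRecord("c", revcomp(templates["MITO"]))
        calls = scan_marker_templates([contig], templates)
        assert any(c.marker == "MITO" for c in calls)


def _assignments(flag_map):
    """Build three clusterings from {contig: (f_k4, f_k5, f_k56)} flag patterns.

    Each contig sits in its own cluster per clustering; the flags say whether
    that cluster is eukaryote-flagged.
    """
    out = []
    for ci, cid in enumerate(("k4", "k5", "k56")):
        labels = {c: i for i, c in enumerate(flag_map)}
        flags = {labels[c]: bool(flag_map[c][ci]) for c in flag_map}
        out.append(ClusterAssignment(cid, labels, flags))
    return out


class TestConsensus:
    @pytest.mark.parametrize(
        "pattern,kept",
        [((1, 1, 0), True), ((0, 0, 1), False), ((1, 1, 1), True), ((0, 0, 0), False)],
    )
    def test_at_least_twice(self, pattern, kept):
        assignments = _assignments({"c1": pattern})
        assert ("c1" in consensus_membership(assignments)) is kept

    def test_exhaustive_patterns_match_brute_force(self):
        patterns = {f"c{i}": p for i, p in enumerate(itertools.product((0, 1), repeat=3))}
        got = consensus_membership(_assignments(patterns))
        expected = {c for c, p in patterns.items() if sum(p) >= 2}
        assert got == expected

    def test_requires_three_clusterings(self):
        with pytest.raises(ValueError, match="3"):
            consensus_membership(_assignments({"c": (1, 1, 1)})[:2])


class TestFlagEukClusters:
    def _assignment(self, members):
        labels = {}
        for lab, cids in members.items():
            for c in cids:
                labels[c] = lab
        return ClusterAssignment("k4", labels)

    def test_majority_flags(self):
        a = self._assignment({0: ["e1", "e2", "e3", "b1"]})
        ev = {
            "e1": ContigEvidence(routing_category=TaxCategory.EUKARYOTE),
            "e2": ContigEvidence(routing_category=TaxCategory.EUKARYOTE),
            "e3": ContigEvidence(routing_category=TaxCategory.EUKARYOTE),
            "b1": ContigEvidence(routing_category=TaxCategory.BACTERIA),
        }
        assert flag_euk_clusters(a, ev).euk_flags[0] is True

    def test_tie_not_flagged(self):
        a = self._assignment({0: ["e1", "e2", "b1", "b2"]})
        ev = {
            "e1": ContigEvidence(routing_category=TaxCategory.EUKARYOTE),
            "e2": ContigEvidence(routing_category=TaxCategory.EUKARYOTE),
            "b1": ContigEvidence(routing_category=TaxCategory.BACTERIA),
            "b2": ContigEvidence(routing_category=TaxCategory.BACTERIA),
        }
        assert flag_euk_clusters(a, ev).euk_flags[0] is False

    def test_unknown_cluster_with_euk_ssu_flagged(self):
        a = self._assignment({0: ["u1", "u2"]})
        ssu = MarkerCall("u1", "SSU", 99.0, 1200, "Eukaryota;x")
        ev = {"u1": ContigEvidence(markers=[ssu]), "u2": ContigEvidence()}
        assert flag_euk_clusters(a, ev).euk_flags[0] is True

    def test_unlabeled_cluster_not_flagged(self):
        a = self._assignment({0: ["u1", "u2"]})
        ev = {"u1": ContigEvidence(), "u2": ContigEvidence()}
        assert flag_euk_clusters(a, ev).euk_flags[0] is False


def _prok_hit(pident, aln):
    return AlignmentHit("q", "bact.chrom", pident, aln, 1e-30, 2.0 * aln, 0, aln, 0, aln,
                        subject_taxid=562)


class TestInclusionCriteria:
    """A hand-built 12-contig fixture exercising every rejection reason."""

    SSU_CAP = 20.0

    def _fixture(self):
        euk = TaxCategory.EUKARYOTE
        mito_hit = AlignmentHit("q", "euk01.mito", 100.0, 5000, 1e-40, 1e4, 0, 5000, 0, 5000,
                                subject_taxid=9002)
        ssu = MarkerCall("ssu_anchor", "SSU", 99.0, 1200, "Eukaryota;x")
        mito_marker = lambda c: MarkerCall(c, "MITO", 99.0, 600, "Eukaryota;x")

        def ev(depth, routing=euk, best=None, best_cat=None, markers=(), is_mito=False):
            return ContigEvidence(
                depth=DepthRecord("x", 5000, depth),
                markers=list(markers),
                best_hit=best,
                best_hit_category=best_cat,
                best_hit_is_mito=is_mito,
                routing_category=routing,
            )

        evidence = {
            # the SSU anchor itself (defines the cap)
            "ssu_anchor": ev(self.SSU_CAP, markers=[ssu]),
            # depth cap boundary: one over, one exactly at the cap
            "depth_over": ev(self.SSU_CAP + 1),
            "depth_at_cap": ev(self.SSU_CAP),
            # prokaryote best-hit 2x2 boundary grid
            "prok_91_1200": ev(5.0, best=_prok_hit(91.0, 1200), best_cat=TaxCategory.BACTERIA),
            "prok_91_800": ev(5.0, best=_prok_hit(91.0, 800), best_cat=TaxCategory.BACTERIA),
            "prok_90_1200": ev(5.0, best=_prok_hit(90.0, 1200), best_cat=TaxCategory.BACTERIA),
            "prok_90_800": ev(5.0, best=_prok_hit(90.0, 800), best_cat=TaxCategory.BACTERIA),
            # consensus: flagged in only 1 of 3 clusterings
            "consensus_1of3": ev(5.0),
            "consensus_2of3": ev(5.0),
            # mitochondrial conjunction
            "mito_both": ev(80.0, markers=[mito_marker("mito_both")], best=mito_hit,
                            best_cat=euk, is_mito=True),
            "mito_marker_only": ev(5.0, markers=[mito_marker("mito_marker_only")]),
            # labeled non-eukaryote, non-rejecting hit -> conflicting taxonomy
            "conflict": ev(5.0, routing=TaxCategory.UNKNOWN,
                           best=_prok_hit(80.0, 500), best_cat=TaxCategory.BACTERIA),
        }
        flags = {c: (1, 1, 1) for c in evidence}
        flags["consensus_1of3"] = (1, 0, 0)
        flags["consensus_2of3"] = (1, 1, 0)
        return evidence, _assignments(flags)

    def test_expected_membership_and_reasons(self):
        evidence, assignments = self._fixture()
        candidates = consensus_membership(assignments)
        assert "consensus_1of3" not in candidates and "consensus_2of3" in candidates
        result = apply_inclusion_criteria(
            candidates, evidence, self.SSU_CAP, assignments, all_ids=evidence.keys()
        )
        assert result.rejected == {
            "consensus_1of3": "CONSENSUS_LT2",
            "depth_over": "DEPTH_GT_SSU",
            "prok_91_1200": "PROK_HIT",
            "conflict": "CONFLICTING_TAXONOMY",
        }
        assert result.mito_bin == {"mito_both"}  # above the cap yet kept: exempt
        nuclear = set().union(*result.nuclear_bins.values())
        assert nuclear == {
            "ssu_anchor", "depth_at_cap", "prok_91_800", "prok_90_1200",
            "prok_90_800", "consensus_2of3", "mito_marker_only",
        }
        result.check_partition(evidence.keys())

    def test_partition_and_single_reason(self):
        evidence, assignments = self._fixture()
        result = apply_inclusion_criteria(
            consensus_membership(assignments), evidence, self.SSU_CAP, assignments,
            all_ids=evidence.keys(),
        )
        # every contig appears exactly once across bins + rejections
        ids = sorted(
            list(result.rejected)
            + list(result.mito_bin)
            + [c for ids in result.nuclear_bins.values() for c in ids]
        )
        assert ids == sorted(evidence.keys())

    def test_no_binned_contig_violates_criteria_post_hoc(self):
        evidence, assignments = self._fixture()
        result = apply_inclusion_criteria(
            consensus_membership(assignments), evidence, self.SSU_CAP, assignments,
            all_ids=evidence.keys(),
        )
        for ids in result.nuclear_bins.values():
            for cid in ids:
                ev = evidence[cid]
                assert ev.mean_depth() <= self.SSU_CAP
                assert not (
                    ev.best_hit is not None
                    and ev.best_hit_category in (TaxCategory.BACTERIA, TaxCategory.ARCHAEA,
                                                 TaxCategory.VIRUS)
                    and ev.best_hit.pident > 90.0
                    and ev.best_hit.aln_length >= 1000
                )

    def test_missing_ssu_skips_depth_cap(self):
        evidence, assignments = self._fixture()
        with pytest.warns(UserWarning, match="depth cap skipped"):
            result = apply_inclusion_criteria(
                consensus_membership(assignments), evidence, None, assignments,
                all_ids=evidence.keys(),
            )
        assert "depth_over" not in result.rejected


class TestFlagMitochondrial:
    def test_conjunction_required(self):
        ev = {
            "both": ContigEvidence(markers=[MarkerCall("both", "MITO", 99.0, 500, "Eukaryota;x")],
                                   best_hit_is_mito=True),
            "marker_only": ContigEvidence(
                markers=[MarkerCall("marker_only", "MITO", 99.0, 500, "Eukaryota;x")]
            ),
            "hit_only": ContigEvidence(best_hit_is_mito=True),
        }
        assert flag_mitochondrial(ev.keys(), ev) == {"both"}

    def test_empty_markers_empty_bin(self):
        assert flag_mitochondrial(["c"], {"c": ContigEvidence()}) == set()
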