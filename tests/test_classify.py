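"""Routing rules: read prep, alignment thresholds, five-way rounds, pairs."""

import numpy as np
import pytest

from eukfinder.classify import (
    RoutingThresholds,
    apply_alignment_thresholds,
    classify_round,
    prepare_reads,
    reconcile_pairs,
    select_eunk,
)
from eukfinder.io_formats import AlignmentHit, ClassifierHit, SeqRecord
from eukfinder.taxonomy import TaxCategory

TH_SHORT = RoutingThresholds.short_reads()
TH_LONG = RoutingThresholds.long_or_contigs()


def _read(rid, n=100, q=30, pair=None, mate=None):
    return SeqRecord(rid, "A" * n, qualities=[q] * n, pair_id=pair, mate=mate)


class TestPrepareReads:
    def test_high_quality_read_unchanged(self):
        r1, r2 = _read("a/1", pair="a", mate=1), _read("a/2", pair="a", mate=2)
        out1, out2, un = prepare_reads([(r1, r2)])
        assert out1[0].sequence == r1.sequence and not un

    def test_read_trimmed_below_40bp_is_dropped(self):
        # 39 good bases then garbage: trimming leaves 39 < 40 -> dropped
        quals = [30] * 39 + [2] * 61
        r1 = SeqRecord("a/1", "A" * 100, qualities=quals, pair_id="a", mate=1)
        r2 = _read("a/2", pair="a", mate=2)
        out1, out2, un = prepare_reads([(r1, r2)])
        assert not out1 and len(un) == 1 and un[0].id == "a/2"

    def test_surviving_mate_moves_to_unpaired(self):
        r1 = SeqRecord("a/1", "A" * 100, qualities=[2] * 100, pair_id="a", mate=1)
        r2 = _read("a/2", pair="a", mate=2)
        _, _, un = prepare_reads([(r1, r2)])
        assert [u.id for u in un] == ["a/2"]
        assert un[0].pair_id is None  # no longer paired

    def test_both_end_trimming(self):
        quals = [2] * 10 + [35] * 60 + [2] * 10
        rec = SeqRecord("u", "G" * 80, qualities=quals)
        _, _, un = prepare_reads([], [rec])
        assert len(un[0]) == 60

    def test_fasta_input_rejected(self):
        with pytest.raises(ValueError, match="contig/long"):
            prepare_reads([], [SeqRecord("c", "ACGT" * 100)])


class TestAlignmentThresholds:
    def _hit(self, pident=90.0, aln=50, evalue=1e-3, bitscore=100.0, taxid=562, subject="s1"):
        return AlignmentHit("q", subject, pident, aln, evalue, bitscore, 0, aln, 0, aln,
                            subject_taxid=taxid)

    def test_identity_just_below_70_is_unknown(self, toy_taxmap):
        cat = apply_alignment_thresholds([self._hit(pident=69.9)], 100, TH_SHORT, toy_taxmap)
        assert cat is TaxCategory.UNKNOWN

    def test_boundaries_inclusive(self, toy_taxmap):
        hit = self._hit(pident=70.0, aln=30, evalue=0.01)  # qcov exactly 30%
        cat = apply_alignment_thresholds([hit], 100, TH_SHORT, toy_taxmap)
        assert cat is TaxCategory.BACTERIA

    def test_no_hits_unknown(self, toy_taxmap):
        assert apply_alignment_thresholds([], 100, TH_SHORT, toy_taxmap) is TaxCategory.UNKNOWN

    def test_best_by_bitscore_then_evalue_then_subject(self, toy_taxmap):
        hits = [
            self._hit(bitscore=50.0, taxid=562, subject="b"),
            self._hit(bitscore=80.0, taxid=4932, subject="a"),
        ]
        assert apply_alignment_thresholds(hits, 100, TH_SHORT, toy_taxmap) is TaxCategory.EUKARYOTE

    def test_bad_query_length(self, toy_taxmap):
        with pytest.raises(ValueError):
            apply_alignment_thresholds([], 0, TH_SHORT, toy_taxmap)


def _brute_force_route(item, classifier_hits, aln_hits, th, taxmap):
    """Independent evaluation of the stated routing rules."""
    rows = [h for h in classifier_hits if h.query_id == item.id and h.taxid != 0]
    category = TaxCategory.UNKNOWN
    if rows:
        best = max(h.hit_length for h in rows)
        if best >= th.min_hit_length:
            cats = {taxmap.category(h.taxid) for h in rows if h.hit_length == best}
            if len(cats) == 1:
                category = cats.pop()
    if category is TaxCategory.UNKNOWN:
        surviving = [
            h
            for h in aln_hits
            if h.query_id == item.id
            and h.evalue <= th.aln_max_evalue
            and h.pident >= th.aln_min_pident
            and 100.0 * h.aln_length / len(item) >= th.aln_min_qcov
        ]
        if surviving:
            best_hit = sorted(surviving, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))[0]
            if best_hit.subject_taxid is not None:
                category = taxmap.category(best_hit.subject_taxid)
    return category


def _random_routing_fixture(rng, toy_taxmap, n_items, th):
    taxids = [562, 2287, 10710, 4932, 49977, 7777, 31337]
    items, chits, ahits = [], [], []
    for i in range(n_items):
        length = int(rng.integers(60, 2000))
        item = SeqRecord(f"it{i}", "A" * length)
        items.append(item)
        if rng.random() < 0.85:
            n_rows = int(rng.integers(1, 4))
            # near-threshold hit lengths to exercise the boundary
            base = int(rng.choice([th.min_hit_length - 1, th.min_hit_length,
                                   th.min_hit_length + 1, int(rng.integers(0, length))]))
            for j in range(n_rows):
                hl = min(max(base if j == 0 else int(rng.integers(0, length)), 0), length)
                taxid = int(rng.choice(taxids + [0]))
                chits.append(
                    ClassifierHit(item.id, f"ref{j}", taxid, float(hl), hl, length,
                                  0 if taxid == 0 else n_rows)
                )
        for _ in range(int(rng.integers(0, 3))):
            aln = int(rng.integers(1, length))
            ahits.append(
                AlignmentHit(
                    item.id, f"s{int(rng.integers(0, 5))}",
                    float(rng.choice([69.9, 70.0, 70.1, 50.0, 95.0])), aln,
                    float(rng.choice([0.005, 0.01, 0.02, 1e-10])),
                    float(rng.integers(10, 500)), 0, aln, 0, aln,
                    subject_taxid=int(rng.choice(taxids)),
                )
            )
    return items, chits, ahits


@pytest.mark.parametrize("profile_th", [TH_SHORT, TH_LONG], ids=["short40", "long100"])
def test_classify_round_matches_brute_force_oracle(toy_taxmap, profile_th):
    """Rule-table equivalence on randomized fixtures + partition invariant."""
    rng = np.random.default_rng(11)
    items, chits, ahits = _random_routing_fixture(rng, toy_taxmap, 250, profile_th)
    cs = classify_round(items, chits, ahits, profile_th, toy_taxmap, "contig")
    cs.check_partition([it.id for it in items])
    for it in items:
        expected = _brute_force_route(it, chits, ahits, profile_th, toy_taxmap)
        assert cs.categories[it.id] is expected, it.id


class TestClassifyRound:
    def test_hit_length_39_no_alignment_is_unknown(self, toy_taxmap):
        item = SeqRecord("r1", "A" * 100)
        hit = ClassifierHit("r1", "ref", 562, 39.0, 39, 100, 1)
        cs = classify_round([item], [hit], [], TH_SHORT, toy_taxmap)
        assert cs.categories["r1"] is TaxCategory.UNKNOWN

    def test_long_profile_contig_at_100(self, toy_taxmap):
        item = SeqRecord("c1", "A" * 1500)
        hit = ClassifierHit("c1", "ref", 562, 100.0, 100, 1500, 1)
        cs = classify_round([item], [hit], [], TH_LONG, toy_taxmap)
        assert cs.categories["c1"] is TaxCategory.BACTERIA

    def test_ambiguous_ties_stay_unknown(self, toy_taxmap):
        item = SeqRecord("r1", "A" * 100)
        hits = [
            ClassifierHit("r1", "a", 562, 80.0, 80, 100, 2),
            ClassifierHit("r1", "b", 4932, 80.0, 80, 100, 2),
        ]
        cs = classify_round([item], hits, [], TH_SHORT, toy_taxmap)
        assert cs.categories["r1"] is TaxCategory.UNKNOWN

    def test_concordant_ties_keep_category(self, toy_taxmap):
        item = SeqRecord("r1", "A" * 100)
        hits = [
            ClassifierHit("r1", "a", 4932, 80.0, 80, 100, 2),
            ClassifierHit("r1", "b", 49977, 80.0, 80, 100, 2),
        ]
        cs = classify_round([item], hits, [], TH_SHORT, toy_taxmap)
        assert cs.categories["r1"] is TaxCategory.EUKARYOTE

    def test_duplicate_item_ids_rejected(self, toy_taxmap):
        items = [SeqRecord("x", "A" * 50), SeqRecord("x", "C" * 50)]
        with pytest.raises(ValueError, match="duplicate"):
            classify_round(items, [], [], TH_SHORT, toy_taxmap)

    def test_tightening_thresholds_only_grows_unknown(self, toy_taxmap):
        """Monotonicity: stricter alignment thresholds never grow a non-Unknown set."""
        rng = np.random.default_rng(5)
        items, chits, ahits = _random_routing_fixture(rng, toy_taxmap, 120, TH_SHORT)
        loose = classify_round(items, chits, ahits, TH_SHORT, toy_taxmap)
        tight_th = RoutingThresholds(
            min_hit_length=TH_SHORT.min_hit_length,
            aln_max_evalue=1e-5, aln_min_pident=90.0, aln_min_qcov=60.0,
        )
        tight = classify_round(items, chits, ahits, tight_th, toy_taxmap)
        for cat in (TaxCategory.ARCHAEA, TaxCategory.BACTERIA, TaxCategory.VIRUS,
                    TaxCategory.EUKARYOTE):
            assert tight.ids_in(cat) <= loose.ids_in(cat)
        assert loose.ids_in(TaxCategory.UNKNOWN) <= tight.ids_in(TaxCategory.UNKNOWN)


class TestPairsAndSelection:
    def _pair_cs(self, c1, c2):
        items = [
            SeqRecord("p/1", "A" * 50, pair_id="p", mate=1),
            SeqRecord("p/2", "A" * 50, pair_id="p", mate=2),
        ]
        from eukfinder.classify import ClassifiedSet

        return ClassifiedSet(
            categories={"p/1": c1, "p/2": c2}, pairs={"p": ("p/1", "p/2")}
        )

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            (TaxCategory.EUKARYOTE, TaxCategory.EUKARYOTE, TaxCategory.EUKARYOTE),
            (TaxCategory.BACTERIA, TaxCategory.UNKNOWN, TaxCategory.UNKNOWN),
            (TaxCategory.BACTERIA, TaxCategory.BACTERIA, TaxCategory.BACTERIA),
            (TaxCategory.BACTERIA, TaxCategory.ARCHAEA, TaxCategory.UNKNOWN),
            (TaxCategory.EUKARYOTE, TaxCategory.UNKNOWN, TaxCategory.UNKNOWN),
        ],
    )
    def test_reconcile(self, c1, c2, expected):
        out = reconcile_pairs(self._pair_cs(c1, c2))
        assert out.categories["p/1"] is expected and out.categories["p/2"] is expected

    def test_select_eunk(self):
        from eukfinder.classify import ClassifiedSet

        cs = ClassifiedSet(
            categories={
                "e1": TaxCategory.EUKARYOTE, "e2": TaxCategory.EUKARYOTE,
                "e3": TaxCategory.EUKARYOTE, "u1": TaxCategory.UNKNOWN,
                "u2": TaxCategory.UNKNOWN, "b1": TaxCategory.BACTERIA,
                "v1": TaxCategory.VIRUS, "a1": TaxCategory.ARCHAEA,
            }
        )
        sel = select_eunk(cs)
        assert sel == {"e1", "e2", "e3", "u1", "u2"}
        assert not sel & cs.ids_in(TaxCategory.BACTERIA, TaxCategory.VIRUS, TaxCategory.ARCHAEA)

    def test_select_eunk_all_bacterial_empty(self):
        from eukfinder.classify import ClassifiedSet

        cs = ClassifiedSet(categories={f"b{i}": TaxCategory.BACTERIA for i in range(5)})
        assert select_eunk(cs) == set()

    def test_lenient_profile_values(self):
        th = RoutingThresholds.long_or_contigs(profile="lenient")
        assert (th.aln_max_evalue, th.aln_min_pident, th.aln_min_qcov) == (0.1, 50.0, 10.0)
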