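"""Five-way taxonomic routing of reads and contigs.

The routing combines two evidence layers per round:

1. k-mer classifier hits — a sequence whose best hit covers at least
   ``min_hit_length`` query bases (40 bp for short reads, 100 bp for contigs
   and long reads) is routed by its hit taxid; equal-best hits that disagree
   at the category level leave the sequence Unknown.
2. alignment fallback — sequences still Unknown are re-routed by their best
   surviving tabular alignment hit, applying e-value ≤ 0.01, identity ≥ 70%
   and query coverage ≥ 30% (all boundaries inclusive: the thresholds are
   stated as equalities).

Short-read data goes through two rounds (reads → assembly of the
Eukaryote+Unknown pool → reclassification of contigs ≥ 1,000 bp); contigs
and long reads go through a single round with the longer 100 bp minimum hit
length.  The Eukaryote ∪ Unknown ("EUnk") output is the input to binning.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .io_formats import AlignmentHit, ClassifierHit, SeqRecord
from .taxonomy import MiniRefDB, TaxCategory, TaxonomyMap, classify_batch

logger = logging.getLogger(__name__)

CATEGORIES = (
    TaxCategory.ARCHAEA,
    TaxCategory.BACTERIA,
    TaxCategory.VIRUS,
    TaxCategory.EUKARYOTE,
    TaxCategory.UNKNOWN,
)


@dataclass(frozen=True)
class RoutingThresholds:
    """Thresholds for one classification round.

    ``min_hit_length`` is 40 bp for short reads and 100 bp for contigs/long
    reads; the alignment fallback keeps hits with e-value ≤ ``aln_max_evalue``,
    identity ≥ ``aln_min_pident`` and query coverage ≥ ``aln_min_qcov``
    percent.  Contigs shorter than ``min_contig_len`` never enter a contig
    round.
    """

    min_hit_length: int = 40
    aln_max_evalue: float = 0.01
    aln_min_pident: float = 70.0
    aln_min_qcov: float = 30.0
    min_contig_len: int = 1000
    profile: str = "strict"

    def __post_init__(self):
        if self.min_hit_length < 1:
            raise ValueError("min_hit_length must be >= 1")
        for name in ("aln_max_evalue", "aln_min_pident", "aln_min_qcov", "min_contig_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def short_reads(cls, profile: str = "strict") -> "RoutingThresholds":
        return cls._preset(min_hit_length=40, profile=profile)

    @classmethod
    def long_or_contigs(cls, profile: str = "strict") -> "RoutingThresholds":
        return cls._preset(min_hit_length=100, profile=profile)

    @classmethod
    def _preset(cls, min_hit_length: int, profile: str) -> "RoutingThresholds":
        if profile == "strict":
            return cls(min_hit_length=min_hit_length, profile="strict")
        if profile == "lenient":
            # Relaxed preset for divergent communities. These defaults are
            # package stand-ins, not values with external provenance; tune
            # them to your data.
            return cls(
                min_hit_length=min_hit_length,
                aln_max_evalue=1e-1,
                aln_min_pident=50.0,
                aln_min_qcov=10.0,
                profile="lenient",
            )
        raise ValueError(f"unknown profile {profile!r}")


@dataclass
class ClassifiedSet:
    """A five-way partition of sequence ids with an evidence trail.

    ``pairs`` maps pair_id -> (mate1 id, mate2 id) when the classified items
    are paired reads.
    """

    categories: dict[str, TaxCategory]
    evidence: dict[str, str] = field(default_factory=dict)
    pairs: Optional[dict[str, tuple[str, str]]] = None

    def ids_in(self, *cats: TaxCategory) -> set[str]:
        wanted = set(cats)
        return {i for i, c in self.categories.items() if c in wanted}

    def counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in CATEGORIES}
        for c in self.categories.values():
            out[c.value] += 1
        return out

    def check_partition(self, input_ids: Iterable[str]) -> None:
        ids = set(input_ids)
        if ids != set(self.categories):
            missing = ids - set(self.categories)
            extra = set(self.categories) - ids
            raise AssertionError(
                f"partition violated: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )


# ---------------------------------------------------------------------------
# read preparation
# ---------------------------------------------------------------------------


def _trim_record(rec: SeqRecord, min_qual: int, window: int) -> Optional[SeqRecord]:
    if min(rec.qualities) >= min_qual:  # fast path: nothing to trim
        return rec
    q = np.asarray(rec.qualities, dtype=float)
    n = q.size
    if n < window:
        return rec if q.mean() >= min_qual else None
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    ok = np.flatnonzero(means >= min_qual)
    if ok.size == 0:
        return None
    start = int(ok[0])
    end = int(ok[-1]) + window
    # per-base cleanup of the window edges
    while start < end and q[start] < min_qual:
        start += 1
    while end > start and q[end - 1] < min_qual:
        end -= 1
    if start >= end:
        return None
    if (start, end) == (0, n):
        return rec
    return replace(rec, sequence=rec.sequence[start:end], qualities=rec.qualities[start:end])


def prepare_reads(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]],
    unpaired: Sequence[SeqRecord] = (),
    min_qual: int = 25,
    min_len: int = 40,
    window: int = 4,
) -> tuple[list[SeqRecord], list[SeqRecord], list[SeqRecord]]:
    """Quality-trim and length-filter reads (the "read_prep" stage).

    Sliding windows of ``window`` bases are trimmed from both ends while the
    window mean quality is below ``min_qual`` (Q25); reads shorter than
    ``min_len`` (40 bp) after trimming are dropped.  Three outputs mirror the
    two-paired-plus-unpaired file convention: a surviving read whose mate was
    dropped moves to the unpaired output.
    """
    for rec in [r for p in pairs for r in p] + list(unpaired):
        if rec.qualities is None:
            raise ValueError(
                f"record {rec.id!r} has no qualities; quality trimming applies to "
                "FASTQ short reads — use the contig/long workflow for FASTA input"
            )

    def keep(rec: SeqRecord) -> Optional[SeqRecord]:
        trimmed = _trim_record(rec, min_qual, window)
        if trimmed is None or len(trimmed) < min_len:
            return None
        return trimmed

    out1: list[SeqRecord] = []
    out2: list[SeqRecord] = []
    out_un: list[SeqRecord] = []
    for r1, r2 in pairs:
        k1, k2 = keep(r1), keep(r2)
        if k1 is not None and k2 is not None:
            out1.append(k1)
            out2.append(k2)
        elif k1 is not None:
            out_un.append(replace(k1, mate=None, pair_id=None))
        elif k2 is not None:
            out_un.append(replace(k2, mate=None, pair_id=None))
    for rec in unpaired:
        k = keep(rec)
        if k is not None:
            out_un.append(k)
    return out1, out2, out_un


# ---------------------------------------------------------------------------
# per-round routing
# ---------------------------------------------------------------------------


def apply_alignment_thresholds(
    hits: Sequence[AlignmentHit],
    query_length: int,
    th: RoutingThresholds,
    taxmap: TaxonomyMap,
) -> TaxCategory:
    """Route one query by its best surviving alignment hit.

    Hits must share a single query.  Surviving = e-value ≤ max, identity ≥
    min, and aligned length ≥ min_qcov percent of the query (inclusive
    boundaries).  Best = highest bitscore, ties by lowest e-value then lowest
    subject_id.  No survivors → UNKNOWN.
    """
    if query_length <= 0:
        raise ValueError(f"query_length must be positive, got {query_length}")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    surviving = [
        h
        for h in hits
        if h.evalue <= th.aln_max_evalue
        and h.pident >= th.aln_min_pident
        and 100.0 * h.aln_length / query_length >= th.aln_min_qcov
    ]
    if not surviving:
        return TaxCategory.UNKNOWN
    best = min(surviving, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    if best.subject_taxid is None:
        return TaxCategory.UNKNOWN
    return taxmap.category(best.subject_taxid)


def _classifier_category(
    rows: Sequence[ClassifierHit], th: RoutingThresholds, taxmap: TaxonomyMap
) -> tuple[TaxCategory, str]:
    """Stage-1 category from (possibly tied) classifier rows for one query."""
    informative = [r for r in rows if r.taxid != 0]
    if not informative:
        return TaxCategory.UNKNOWN, "classifier:no-hit"
    best_len = max(r.hit_length for r in informative)
    if best_len < th.min_hit_length:
        return TaxCategory.UNKNOWN, f"classifier:hit_length<{th.min_hit_length}"
    tied = [r for r in informative if r.hit_length == best_len]
    cats = {taxmap.category(r.taxid) for r in tied}
    if len(cats) == 1:
        cat = cats.pop()
        return cat, f"classifier:hl={best_len}"
    return TaxCategory.UNKNOWN, "classifier:ambiguous-ties"


def classify_round(
    items: Sequence[SeqRecord],
    classifier_hits: Sequence[ClassifierHit],
    aln_hits: Sequence[AlignmentHit],
    th: RoutingThresholds,
    taxmap: TaxonomyMap,
    item_kind: str = "read",
) -> ClassifiedSet:
    """One round of five-way routing over ``items``.

    Stage 1 routes by classifier best hits (min hit length, category-level
    tie consensus); everything else is provisionally Unknown.  Stage 2 runs
    the alignment fallback on the provisional Unknowns only.  The result is
    a partition of the input ids.
    """
    ids = [it.id for it in items]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate item ids: {sorted(dups)[:5]}")
    by_query: dict[str, list[ClassifierHit]] = defaultdict(list)
    for h in classifier_hits:
        by_query[h.query_id].append(h)
    aln_by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in aln_hits:
        aln_by_query[h.query_id].append(h)

    categories: dict[str, TaxCategory] = {}
    evidence: dict[str, str] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for it in items:
        cat, why = _classifier_category(by_query.get(it.id, ()), th, taxmap)
        if cat is TaxCategory.UNKNOWN and it.id in aln_by_query:
            aln_cat = apply_alignment_thresholds(aln_by_query[it.id], len(it), th, taxmap)
            if aln_cat is not TaxCategory.UNKNOWN:
                cat, why = aln_cat, "alignment:best-hit"
            else:
                why += "+alignment:none-surviving"
        categories[it.id] = cat
        evidence[it.id] = why
        if it.pair_id is not None and it.mate is not None:
            slot = pairs.setdefault(it.pair_id, ("", ""))
            slot = (it.id, slot[1]) if it.mate == 1 else (slot[0], it.id)
            pairs[it.pair_id] = slot

    cs = ClassifiedSet(
        categories=categories,
        evidence=evidence,
        pairs={p: m for p, m in pairs.items() if m[0] and m[1]} or None
        if item_kind == "read"
        else None,
    )
    cs.check_partition(ids)
    return cs


def reconcile_pairs(cs: ClassifiedSet) -> ClassifiedSet:
    """Resolve mate-pair disagreements.

    Concordant pairs keep their category; any disagreement demotes the pair
    to Unknown, so a pair with one Eukaryote or Unknown mate is retained for
    assembly while concordantly prokaryotic/viral pairs stay excluded.
    """
    if not cs.pairs:
        return cs
    categories = dict(cs.categories)
    evidence = dict(cs.evidence)
    for pair_id, (id1, id2) in cs.pairs.items():
        c1, c2 = categories[id1], categories[id2]
        if c1 is not c2:
            categories[id1] = categories[id2] = TaxCategory.UNKNOWN
            evidence[id1] = evidence[id2] = f"pair:discordant({c1.value},{c2.value})"
    return ClassifiedSet(categories=categories, evidence=evidence, pairs=cs.pairs)


def select_eunk(cs: ClassifiedSet) -> set[str]:
    """Eukaryote ∪ Unknown ids, pair-complete for reads."""
    selected = cs.ids_in(TaxCategory.EUKARYOTE, TaxCategory.UNKNOWN)
    if cs.pairs:
        for id1, id2 in cs.pairs.values():
            if id1 in selected or id2 in selected:
                selected.add(id1)
                selected.add(id2)
    return selected


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

Assembler = Callable[[Sequence[tuple[SeqRecord, SeqRecord]], Sequence[SeqRecord]], list[SeqRecord]]


@dataclass
class WorkflowResult:
    round1: ClassifiedSet
    round2: Optional[ClassifiedSet]
    eunk_contigs: list[SeqRecord]
    eunk_read_ids: set[str]
    counts: dict[str, dict[str, int]]


def run_short_workflow(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]],
    unpaired: Sequence[SeqRecord],
    db: MiniRefDB,
    taxmap: TaxonomyMap,
    assembler: Assembler,
    th_reads: Optional[RoutingThresholds] = None,
    th_contigs: Optional[RoutingThresholds] = None,
    read_hits: Optional[Sequence[ClassifierHit]] = None,
    aln_hits_reads: Sequence[AlignmentHit] = (),
    aln_hits_contigs: Sequence[AlignmentHit] = (),
    contig_hits: Optional[Sequence[ClassifierHit]] = None,
) -> WorkflowResult:
    """The two-round short-read workflow.

    Round 1 routes reads (min hit length 40), mates are reconciled, the
    Eukaryote+Unknown pool is assembled, contigs < 1,000 bp are dropped, and
    round 2 re-routes the surviving contigs (min hit length 100).  Pass
    ``read_hits``/``contig_hits`` to reuse precomputed classifier tables
    (e.g. real Centrifuge output) instead of the built-in mini classifier.
    """
    th_reads = th_reads or RoutingThresholds.short_reads()
    th_contigs = th_contigs or RoutingThresholds.long_or_contigs()
    reads = [r for p in pairs for r in p] + list(unpaired)
    if read_hits is None:
        read_hits = classify_batch(reads, db)
    round1 = classify_round(reads, read_hits, aln_hits_reads, th_reads, taxmap, "read")
    round1 = reconcile_pairs(round1)
    selected = select_eunk(round1)
    counts = {"round1": round1.counts()}
    logger.info("round 1 category counts: %s", counts["round1"])

    sel_pairs = [(r1, r2) for r1, r2 in pairs if r1.id in selected]
    sel_unpaired = [r for r in unpaired if r.id in selected]
    if not sel_pairs and not sel_unpaired:
        logger.info("no Eukaryote/Unknown reads after round 1; empty EUnk output")
        return WorkflowResult(round1, None, [], selected, counts)

    contigs = [c for c in assembler(sel_pairs, sel_unpaired) if len(c) >= th_contigs.min_contig_len]
    if not contigs:
        return WorkflowResult(round1, None, [], selected, counts)
    if contig_hits is None:
        contig_hits = classify_batch(contigs, db)
    round2 = classify_round(contigs, contig_hits, aln_hits_contigs, th_contigs, taxmap, "contig")
    counts["round2"] = round2.counts()
    logger.info("round 2 category counts: %s", counts["round2"])
    eunk_ids = select_eunk(round2)
    eunk_contigs = [c for c in contigs if c.id in eunk_ids]
    return WorkflowResult(round1, round2, eunk_contigs, selected, counts)


def run_long_workflow(
    contigs: Sequence[SeqRecord],
    db: MiniRefDB,
    taxmap: TaxonomyMap,
    th: Optional[RoutingThresholds] = None,
    contig_hits: Optional[Sequence[ClassifierHit]] = None,
    aln_hits: Sequence[AlignmentHit] = (),
) -> WorkflowResult:
    """Single-round workflow for contigs or long reads (min hit length 100)."""
    th = th or RoutingThresholds.long_or_contigs()
    kept = [c for c in contigs if len(c) >= th.min_contig_len]
    if not kept:
        empty = ClassifiedSet(categories={})
        return WorkflowResult(empty, None, [], set(), {"round1": empty.counts()})
    if contig_hits is None:
        contig_hits = classify_batch(kept, db)
    rnd = classify_round(kept, contig_hits, aln_hits, th, taxmap, "contig")
    counts = {"round1": rnd.counts()}
    logger.info("long workflow category counts: %s", counts["round1"])
    eunk_ids = select_eunk(rnd)
    return WorkflowResult(rnd, None, [c for c in kept if c.id in eunk_ids], eunk_ids, counts)
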