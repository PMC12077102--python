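"""End-to-end composition of the pipeline stages on simulated communities.

This is the wiring the CLI and the test-bench use: route reads through the
two-round short workflow (with the perfect-assembly stand-in as assembler),
collect the binning evidence layers (depth, markers, nt pseudo-alignments),
run consensus binning, and score the result against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .binning import (
    BinResult,
    ClusterAssignment,
    ContigEvidence,
    estimate_depth,
    filter_marker_calls,
    run_binning,
    scan_marker_templates,
)
from .classify import ClassifiedSet, WorkflowResult, run_short_workflow
from .evaluate import genome_fraction, ng50_lg50, weighted_scg
from .io_formats import AlignmentHit, ClassifierHit, DepthRecord, MarkerCall, SeqRecord
from .simulate import (
    Community,
    CommunityReferences,
    TruthRow,
    marker_templates,
    perfect_assembly_fixture,
    scg_templates,
)
from .taxonomy import MiniRefDB, TaxCategory, TaxonomyMap, kmer_pseudo_align


def make_perfect_assembler(
    read_truth: Mapping[str, TruthRow],
    refs: CommunityReferences,
    min_len: int = 1000,
):
    """An assembler stand-in backed by ground truth.

    Returns (assembler, contig_truth): the dict is filled in place when the
    assembler runs, mapping each emitted contig to its source interval.
    """
    contig_truth: dict[str, TruthRow] = {}

    def assembler(pairs, unpaired):
        ids = [r.id for p in pairs for r in p] + [r.id for r in unpaired]
        contigs, ctruth = perfect_assembly_fixture(
            read_truth, refs, read_ids=ids, min_len=min_len
        )
        contig_truth.clear()
        contig_truth.update(ctruth)
        return contigs

    return assembler, contig_truth


def build_evidence(
    contigs: Sequence[SeqRecord],
    routing: Optional[ClassifiedSet],
    depth_records: Sequence[DepthRecord],
    marker_calls: Sequence[MarkerCall],
    nt_hits: Sequence[AlignmentHit],
    taxmap: TaxonomyMap,
    mito_ref_ids: Sequence[str] = (),
) -> dict[str, ContigEvidence]:
    """Assemble the per-contig evidence bundle the binning criteria consume.

    The best nt hit per contig is the highest-bitscore alignment; its
    subject taxid gives the hit category and membership of ``mito_ref_ids``
    marks mitochondrial references.
    """
    mito_refs = set(mito_ref_ids)
    depth_by_id = {d.contig_id: d for d in depth_records}
    markers_by_id: dict[str, list[MarkerCall]] = {}
    for m in marker_calls:
        markers_by_id.setdefault(m.contig_id, []).append(m)
    best_by_id: dict[str, AlignmentHit] = {}
    for h in nt_hits:
        cur = best_by_id.get(h.query_id)
        if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
            best_by_id[h.query_id] = h
    evidence = {}
    for c in contigs:
        best = best_by_id.get(c.id)
        evidence[c.id] = ContigEvidence(
            depth=depth_by_id.get(
                c.id, DepthRecord(contig_id=c.id, contig_len=len(c), mean_depth=0.0)
            ),
            markers=markers_by_id.get(c.id, []),
            best_hit=best,
            best_hit_category=(
                taxmap.category(best.subject_taxid)
                if best is not None and best.subject_taxid is not None
                else None
            ),
            best_hit_is_mito=best is not None and best.subject_id in mito_refs,
            routing_category=(
                routing.categories.get(c.id, TaxCategory.UNKNOWN)
                if routing is not None
                else TaxCategory.UNKNOWN
            ),
        )
    return evidence


@dataclass
class CommunityRun:
    """Everything one end-to-end community run produced."""

    workflow: WorkflowResult
    contigs: list[SeqRecord]
    contig_truth: dict[str, TruthRow]
    evidence: dict[str, ContigEvidence]
    bin_result: BinResult
    assignments: list[ClusterAssignment]
    depth: list[DepthRecord]
    metrics: dict[str, float] = field(default_factory=dict)


def run_community_short(
    community: Community,
    refs: CommunityReferences,
    db: MiniRefDB,
    seed: int = 1234,
    read_hits: Optional[Sequence[ClassifierHit]] = None,
) -> CommunityRun:
    """Short workflow + binning + scoring on one mock community.

    ``read_hits`` may carry precomputed classifier rows (the background
    reads are identical across a titration series, so classifying them once
    and reusing the rows is exact, not an approximation).
    """
    assembler, contig_truth = make_perfect_assembler(community.truth.reads, refs)
    wf = run_short_workflow(
        pairs=community.pairs,
        unpaired=[],
        db=db,
        taxmap=refs.taxmap,
        assembler=assembler,
        read_hits=read_hits,
    )
    contigs = wf.eunk_contigs
    contig_truth = {cid: t for cid, t in contig_truth.items() if cid in {c.id for c in contigs}}
    if not contigs:
        return CommunityRun(wf, [], {}, {}, BinResult({}, set(), {}), [], [], {})

    selected_reads = [
        r for p in community.pairs for r in p if r.id in wf.eunk_read_ids
    ]
    depth = estimate_depth(selected_reads, contigs)
    markers = filter_marker_calls(scan_marker_templates(contigs, marker_templates()))
    nt_hits = kmer_pseudo_align(contigs, db)
    evidence = build_evidence(
        contigs,
        wf.round2,
        depth,
        markers,
        nt_hits,
        refs.taxmap,
        mito_ref_ids=refs.mito_ref_ids(),
    )
    bin_result, assignments = run_binning(contigs, evidence, seed=seed)
    run = CommunityRun(wf, contigs, contig_truth, evidence, bin_result, assignments, depth)
    run.metrics = summarize_run(run, refs)
    return run


def summarize_run(run: CommunityRun, refs: CommunityReferences) -> dict[str, float]:
    """Truth-based scores of one run (percent scales where applicable)."""
    euk_genomes = refs.euk_genome_ids()
    lengths = {c.id: len(c) for c in run.contigs}
    euk_ids = {cid for cid, t in run.contig_truth.items() if t.genome_id in euk_genomes}
    prok_ids = set(run.contig_truth) - euk_ids
    binned = run.bin_result.binned_ids()
    euk_bases = sum(lengths[i] for i in euk_ids)
    prok_bases = sum(lengths[i] for i in prok_ids)
    euk_binned = sum(lengths[i] for i in euk_ids & binned)
    prok_binned = sum(lengths[i] for i in prok_ids & binned)

    euk = next(g for g in refs.genomes if g.genome_id in euk_genomes)
    chrom_len = len(euk.replicons["chrom"].sequence)
    chrom_intervals = [
        (t.start, t.end)
        for cid, t in run.contig_truth.items()
        if cid in binned and t.genome_id == euk.genome_id and t.replicon == "chrom"
    ]
    binned_lengths = [lengths[i] for i in binned]
    ng50, lg50 = ng50_lg50(binned_lengths, euk.length()) if binned_lengths else (None, None)
    scg = weighted_scg(
        [c.sequence for c in run.contigs if c.id in binned], scg_templates()
    )
    return {
        "n_contigs": float(len(run.contigs)),
        "euk_contig_bases": float(euk_bases),
        "prok_contig_bases": float(prok_bases),
        "euk_bases_binned_pct": 100.0 * euk_binned / euk_bases if euk_bases else 0.0,
        "prok_bases_binned_pct": 100.0 * prok_binned / prok_bases if prok_bases else 0.0,
        "contamination_of_bins_pct": (
            100.0 * prok_binned / (euk_binned + prok_binned) if euk_binned + prok_binned else 0.0
        ),
        "genome_fraction_nuclear_pct": genome_fraction(chrom_intervals, chrom_len),
        "ng50": float(ng50) if ng50 is not None else float("nan"),
        "lg50": float(lg50) if lg50 is not None else float("nan"),
        "weighted_scg": scg,
        "n_nuclear_bins": float(len(run.bin_result.nuclear_bins)),
        "n_mito_contigs": float(len(run.bin_result.mito_bin)),
    }
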