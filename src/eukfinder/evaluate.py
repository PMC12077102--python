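"""Performance measures for recovered genomes.

Precision = TP/(TP+FP) and recall = TP/(TP+FN) over predicted vs true
target contigs, at both contig-count and base-pair granularity (contig-level
is primary).  NG50/LG50 use half the *reference* length as the threshold on
the descending cumulative contig lengths.  Genome fraction is the percent
of reference bases covered by the recovered contigs, overlaps counted once.
Weighted SCG sums per-gene completeness fractions (matched template length /
template length) rather than counting presence/absence; matching is exact
k-mer anchoring, which tolerates roughly one mismatch per 100 bp for the
default anchor size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class PRResult:
    precision: Optional[float]  # None (NA) when nothing was predicted
    recall: float
    counts: ConfusionCounts
    precision_bp: Optional[float] = None
    recall_bp: Optional[float] = None


def precision_recall(
    predicted: Iterable[str],
    truth_positives: Iterable[str],
    universe: Iterable[str],
    lengths: Optional[Mapping[str, int]] = None,
) -> PRResult:
    """Confusion counts of a predicted contig set against truth.

    ``predicted`` and ``truth_positives`` must be subsets of ``universe``.
    Empty prediction → precision None (NA), recall 0.  Pass per-contig
    ``lengths`` to also get base-pair-weighted precision/recall.
    """
    predicted, truth, universe = set(predicted), set(truth_positives), set(universe)
    if not predicted <= universe:
        raise ValueError(f"predicted ids outside universe: {sorted(predicted - universe)[:5]}")
    if not truth <= universe:
        raise ValueError(f"truth ids outside universe: {sorted(truth - universe)[:5]}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe - predicted - truth)
    precision = tp / (tp + fp) if predicted else None
    recall = tp / (tp + fn) if truth else 0.0
    p_bp = r_bp = None
    if lengths is not None:
        tp_bp = sum(lengths[i] for i in predicted & truth)
        fp_bp = sum(lengths[i] for i in predicted - truth)
        fn_bp = sum(lengths[i] for i in truth - predicted)
        p_bp = tp_bp / (tp_bp + fp_bp) if predicted else None
        r_bp = tp_bp / (tp_bp + fn_bp) if truth else 0.0
    return PRResult(precision, recall, ConfusionCounts(tp, fp, fn, tn), p_bp, r_bp)


def ng50_lg50(
    contig_lengths: Sequence[int], ref_length: int
) -> tuple[Optional[int], Optional[int]]:
    """NG50 and LG50 of an assembly against a reference length.

    Sort lengths descending; NG50 is the length at which the cumulative sum
    first reaches half the reference, LG50 its 1-based rank.  (None, None)
    when the assembly never reaches ref_length/2.
    """
    if ref_length < 1:
        raise ValueError("ref_length must be >= 1")
    lengths = sorted(contig_lengths, reverse=True)
    half = ref_length / 2
    cum = 0
    for rank, length in enumerate(lengths, start=1):
        cum += length
        if cum >= half:
            return length, rank
    return None, None


def genome_fraction(intervals: Iterable[tuple[int, int]], genome_length: int) -> float:
    """Percent of the reference covered by recovered intervals (union)."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    merged: list[tuple[int, int]] = []
    for s, e in sorted((max(0, s), min(genome_length, e)) for s, e in intervals):
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    covered = sum(e - s for s, e in merged)
    return 100.0 * covered / genome_length


def _template_coverage(template: str, contig_kmers: set, k: int) -> float:
    if len(template) < k:
        return 0.0
    hit = [i for i in range(len(template) - k + 1) if template[i : i + k] in contig_kmers]
    if not hit:
        return 0.0
    covered, last_end = 0, -1
    for p in hit:
        covered += min(k, p + k - max(last_end, p))
        last_end = p + k
    return covered / len(template)


def weighted_scg(
    bin_sequences: Iterable[str],
    scg_templates: Mapping[str, str],
    k: int = 21,
) -> float:
    """Sum over genes of max-per-contig completeness fractions.

    Completeness of a gene = fraction of its template bases covered by
    k-mers shared (either strand) with some one bin contig.
    """
    if not scg_templates:
        raise ValueError("empty SCG template set")
    from ._kmers import revcomp

    contig_kmer_sets = []
    for seq in bin_sequences:
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        rc = revcomp(seq)
        kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
        contig_kmer_sets.append(kmers)
    total = 0.0
    for template in scg_templates.values():
        best = 0.0
        for kmers in contig_kmer_sets:
            best = max(best, _template_coverage(template, kmers, k))
        total += best
    return total
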