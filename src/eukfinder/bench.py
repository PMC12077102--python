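"""Desk-scale reproduction bench: titration series + database ablation.

Runs the full pipeline (simulate → two-round routing → consensus binning →
truth-based scoring) over the default titration design, classifying the
shared background and eukaryote pools once and reusing the rows per
community (the communities share those reads, so this is exact).  The
ablation rebuilds the reference database without the eukaryote genome and
re-runs the top-level community, measuring how much recovered eukaryote
sequence the Eukaryote+Unknown pathway preserves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .pipeline import CommunityRun, run_community_short
from .simulate import (
    MockCommunitySpec,
    build_titration_series,
    generate_genomes,
    simulate_background,
    simulate_euk_pool,
)
from .taxonomy import TaxCategory, classify_batch, build_kmer_index

logger = logging.getLogger(__name__)


@dataclass
class TitrationSummary:
    levels: list[int]
    genome_fraction_by_level: dict[int, list[float]]
    top_metrics: dict[str, float]
    ablation_metrics: Optional[dict[str, float]] = None
    ablation_unknown_contig_fraction: Optional[float] = None
    runs: dict[tuple[int, int], CommunityRun] = field(default_factory=dict)

    def mean_fraction(self, level: int) -> float:
        vals = self.genome_fraction_by_level[level]
        return sum(vals) / len(vals)

    def monotone_non_decreasing(self) -> bool:
        means = [self.mean_fraction(lv) for lv in self.levels]
        return all(b >= a for a, b in zip(means, means[1:]))

    def ablation_change_pct(self) -> Optional[float]:
        """Percent change in binned eukaryote bases, ablated vs full DB."""
        if self.ablation_metrics is None:
            return None
        full = self.top_metrics["euk_bases_binned_pct"] * self.top_metrics["euk_contig_bases"]
        ablated = (
            self.ablation_metrics["euk_bases_binned_pct"]
            * self.ablation_metrics["euk_contig_bases"]
        )
        if full == 0:
            return None
        return 100.0 * (ablated - full) / full


def run_desk_titration(
    seed: int = 1234,
    spec: Optional[MockCommunitySpec] = None,
    include_ablation: bool = True,
    keep_runs: bool = False,
) -> TitrationSummary:
    """Simulate the default community set and run the pipeline on every
    level × replicate; optionally re-run the top level with the eukaryote
    removed from the database."""
    if spec is None:
        spec = MockCommunitySpec(seed=seed)
    refs = generate_genomes(spec)
    db = build_kmer_index(refs.ref_entries())
    background, bg_truth = simulate_background(refs, spec)
    pool, pool_truth = simulate_euk_pool(refs, spec)
    logger.info("classifying %d background and %d pool reads", 2 * len(background), 2 * len(pool))
    bg_hits = classify_batch([r for p in background for r in p], db)
    pool_hits = classify_batch([r for p in pool for r in p], db)
    hits_by_read: dict[str, list] = {}
    for h in bg_hits + pool_hits:
        hits_by_read.setdefault(h.query_id, []).append(h)

    communities = build_titration_series(
        background, bg_truth, pool, pool_truth,
        spec.euk_read_levels, spec.replicates, seed, refs=refs,
    )
    summary = TitrationSummary(
        levels=sorted(set(spec.euk_read_levels)),
        genome_fraction_by_level={lv: [] for lv in spec.euk_read_levels},
        top_metrics={},
    )
    top_level = max(spec.euk_read_levels)
    for community in communities:
        read_hits = [
            h for p in community.pairs for r in p for h in hits_by_read.get(r.id, ())
        ]
        run = run_community_short(community, refs, db, seed=seed, read_hits=read_hits)
        summary.genome_fraction_by_level[community.level].append(
            run.metrics.get("genome_fraction_nuclear_pct", 0.0)
        )
        if community.level == top_level and community.replicate == 0:
            summary.top_metrics = run.metrics
            top_community = community
        if keep_runs:
            summary.runs[(community.level, community.replicate)] = run
        logger.info(
            "level %d rep %d: %s", community.level, community.replicate,
            {k: round(v, 2) for k, v in run.metrics.items()},
        )

    if include_ablation:
        db_wo = build_kmer_index(
            refs.ref_entries(exclude_genomes=refs.euk_genome_ids())
        )
        bg_hits_wo = classify_batch([r for p in background for r in p], db_wo)
        euk_pairs = top_community.pairs[len(background):]
        euk_hits_wo = classify_batch([r for p in euk_pairs for r in p], db_wo)
        hits_wo: dict[str, list] = {}
        for h in bg_hits_wo + euk_hits_wo:
            hits_wo.setdefault(h.query_id, []).append(h)
        read_hits = [
            h for p in top_community.pairs for r in p for h in hits_wo.get(r.id, ())
        ]
        run_wo = run_community_short(top_community, refs, db_wo, seed=seed, read_hits=read_hits)
        summary.ablation_metrics = run_wo.metrics
        euk_contigs = [
            c.id for c in run_wo.contigs
            if run_wo.contig_truth[c.id].genome_id in refs.euk_genome_ids()
        ]
        unknown = [
            cid for cid in euk_contigs
            if run_wo.workflow.round2 is not None
            and run_wo.workflow.round2.categories.get(cid) is TaxCategory.UNKNOWN
        ]
        summary.ablation_unknown_contig_fraction = (
            len(unknown) / len(euk_contigs) if euk_contigs else 0.0
        )
        if keep_runs:
            summary.runs[("ablation", 0)] = run_wo
    return summary
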