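"""Supervised consensus binning of Eukaryote/Unknown contigs.

Three independent composition clusterings (4-mer, 5-mer, and concatenated
5+6-mer canonical frequency vectors) are combined with read-depth, rRNA/
mitochondrial marker, and nt-alignment evidence.  A contig reaches the final
eukaryotic bin(s) only if:

1. its depth of coverage does not exceed that of the SSU rRNA gene
   (strictly: "exceed" — equality is allowed);
2. its best nt hit is not a prokaryote or virus with >90% identity over an
   aligned length ≥ 1,000 bp;
3. contigs with a mitochondrial marker call AND a mitochondrial best hit are
   split into the mitochondrial bin (exempt from the depth cap — organellar
   genomes legitimately run much deeper than the nucleus);
4. it is eukaryotic by at least one evidence source, or carries no
   conflicting taxonomic evidence at all (evidence-free contigs ride along:
   this is what lets genomes absent from every database survive);
5. it appears in a flagged eukaryotic cluster in at least 2 of the 3
   clusterings.

The clusterer is a deterministic stand-in for MyCC: standardized features,
PCA to ≤ 10 components, and PAM k-medoids with the cluster count chosen by
silhouette.  Externally computed cluster assignments can be supplied
instead, so real MyCC output slots straight in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances, silhouette_score
from sklearn.preprocessing import StandardScaler

from . import _kmers
from .io_formats import AlignmentHit, DepthRecord, MarkerCall, SeqRecord
from .taxonomy import PROK_VIRUS, MiniRefDB, TaxCategory, build_kmer_index

logger = logging.getLogger(__name__)

KSETS: dict[str, tuple[int, ...]] = {"k4": (4,), "k5": (5,), "k56": (5, 6)}

REASONS = ("DEPTH_GT_SSU", "PROK_HIT", "CONSENSUS_LT2", "CONFLICTING_TAXONOMY")


@dataclass
class CompositionVector:
    contig_id: str
    kset: tuple[int, ...]
    values: np.ndarray


@dataclass
class ClusterAssignment:
    """Labels of one clustering plus per-cluster eukaryote flags."""

    clustering_id: str
    labels: dict[str, int]
    euk_flags: dict[int, bool] = field(default_factory=dict)

    def flagged_ids(self) -> set[str]:
        return {c for c, l in self.labels.items() if self.euk_flags.get(l, False)}


@dataclass
class ContigEvidence:
    """The per-contig evidence layers the inclusion criteria combine."""

    depth: Optional[DepthRecord] = None
    markers: list[MarkerCall] = field(default_factory=list)
    best_hit: Optional[AlignmentHit] = None
    best_hit_category: Optional[TaxCategory] = None
    best_hit_is_mito: bool = False
    routing_category: TaxCategory = TaxCategory.UNKNOWN

    def mean_depth(self) -> float:
        return self.depth.mean_depth if self.depth is not None else 0.0

    def has_marker(self, marker: str) -> bool:
        return any(m.marker == marker for m in self.markers)

    def has_euk_marker(self, marker: str) -> bool:
        return any(
            m.marker == marker and m.taxon_label.startswith("Eukaryota")
            for m in self.markers
        )


@dataclass
class BinResult:
    """Nuclear bins, the mitochondrial bin, and per-contig rejection reasons."""

    nuclear_bins: dict[str, set[str]]
    mito_bin: set[str]
    rejected: dict[str, str]

    def binned_ids(self) -> set[str]:
        out = set(self.mito_bin)
        for ids in self.nuclear_bins.values():
            out |= ids
        return out

    def check_partition(self, input_ids: Iterable[str]) -> None:
        binned = self.binned_ids()
        if binned & set(self.rejected):
            raise AssertionError("contig both binned and rejected")
        nuc_all: set[str] = set()
        for ids in self.nuclear_bins.values():
            if ids & nuc_all or ids & self.mito_bin:
                raise AssertionError("overlapping bins")
            nuc_all |= ids
        if binned | set(self.rejected) != set(input_ids):
            raise AssertionError("bins + rejections do not cover the input contigs")


# ---------------------------------------------------------------------------
# composition features
# ---------------------------------------------------------------------------

_CANON_CACHE: dict[int, tuple[np.ndarray, int]] = {}


def _canon(k: int) -> tuple[np.ndarray, int]:
    if k not in _CANON_CACHE:
        _CANON_CACHE[k] = _kmers.canonical_index(k)
    return _CANON_CACHE[k]


def composition_vector(contig: SeqRecord, kset: Sequence[int] = (4,)) -> CompositionVector:
    """Canonical k-mer frequency vector; one L1-normalized block per k."""
    kset = tuple(kset)
    if len(contig) < max(kset):
        raise ValueError(
            f"contig {contig.id!r} ({len(contig)} bp) shorter than max k {max(kset)}"
        )
    arr = _kmers.encode(contig.sequence)
    blocks = []
    for k in kset:
        lut, n_feat = _canon(k)
        codes, valid = _kmers.canonical_codes(arr, k)
        # canonical_codes returns min(fwd, rc) which is already the canonical
        # packed code; map it to its dense feature index
        counts = np.bincount(lut[codes[valid].astype(np.int64)], minlength=n_feat).astype(float)
        total = counts.sum()
        blocks.append(counts / total if total > 0 else counts)
    return CompositionVector(contig_id=contig.id, kset=kset, values=np.concatenate(blocks))


# ---------------------------------------------------------------------------
# clustering (MyCC stand-in)
# ---------------------------------------------------------------------------


def _pam_kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic PAM: greedy BUILD initialization + SWAP refinement."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    best_cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = [m for j, m in enumerate(medoids) if j != mi]
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = sorted(others + [cand])
                cost = D[:, trial].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    medoids, best_cost, improved = trial, cost, True
                    break
            if improved:
                break
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1)


def cluster_contigs(
    vectors: Sequence[CompositionVector],
    clustering_id: str = "k4",
    n_clusters: Optional[int] = None,
    seed: int = 1234,
) -> ClusterAssignment:
    """Cluster contigs by composition.

    Features are standardized, projected to ≤ 10 principal components, and
    clustered with PAM k-medoids; the cluster count is chosen over
    k ∈ [2, min(10, n−1)] by mean silhouette unless ``n_clusters`` is given.
    The PAM initialization is greedy and deterministic, so results do not
    depend on ``seed``; the parameter is kept for interface stability with
    stochastic clusterers.
    """
    ids = [v.contig_id for v in vectors]
    n = len(ids)
    if n < 2:
        return ClusterAssignment(clustering_id, {i: 0 for i in ids})
    X = np.vstack([v.values for v in vectors])
    if np.allclose(X, X[0]):
        warnings.warn("all composition vectors identical; single cluster")
        return ClusterAssignment(clustering_id, {i: 0 for i in ids})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance features are fine
        X = StandardScaler().fit_transform(X)
    n_comp = min(10, n, X.shape[1])
    X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    D = pairwise_distances(X)
    ks = [n_clusters] if n_clusters else list(range(2, min(10, n - 1) + 1))
    best: tuple[float, int, np.ndarray] | None = None
    for k in ks:
        labels = _pam_kmedoids(D, k)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed") if n_clusters is None else 1.0
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels)
    if best is None:  # n == 2 degenerate case: two singletons
        labels = np.arange(n)
    else:
        labels = best[2]
    return ClusterAssignment(clustering_id, dict(zip(ids, (int(l) for l in labels))))


def cluster_all_ksets(
    contigs: Sequence[SeqRecord], seed: int = 1234
) -> list[ClusterAssignment]:
    """The three composition clusterings (k4, k5, k5+6)."""
    out = []
    for cid, kset in KSETS.items():
        vectors = [composition_vector(c, kset) for c in contigs]
        out.append(cluster_contigs(vectors, clustering_id=cid, seed=seed))
    return out


# ---------------------------------------------------------------------------
# depth (read-mapping stand-in)
# ---------------------------------------------------------------------------


def estimate_depth(
    reads: Iterable[SeqRecord],
    contigs: Sequence[SeqRecord],
    k: int = 31,
) -> list[DepthRecord]:
    """Depth by unique best k-mer assignment of reads to contigs.

    Each read goes to the contig covering most of it with shared k-mers;
    ambiguous (tied) reads are dropped.  mean_depth = assigned read bases /
    contig length, matching the jgi depth-table definition.
    """
    from .taxonomy import _classify_one

    db = build_kmer_index([(c.id, 0, c) for c in contigs], k=k)
    assigned_bp = {c.id: 0 for c in contigs}
    for read in reads:
        results = _classify_one(read.sequence, db)
        if not results:
            continue
        if len(results) > 1 and results[0][1] == results[1][1]:
            continue  # ambiguous
        assigned_bp[db.refs[results[0][0]].ref_id] += len(read)
    return [
        DepthRecord(
            contig_id=c.id,
            contig_len=len(c),
            mean_depth=assigned_bp[c.id] / len(c),
            samples={"reads": (assigned_bp[c.id] / len(c), 0.0)},
        )
        for c in contigs
    ]


# ---------------------------------------------------------------------------
# marker filtering and template scanning (Metaxa2 stand-in)
# ---------------------------------------------------------------------------


def filter_marker_calls(raw: Iterable[MarkerCall]) -> list[MarkerCall]:
    """Keep calls with aligned length > 300 and identity > 90 (both strict)."""
    return [c for c in raw if c.aln_length > 300 and c.pident > 90.0]


def scan_marker_templates(
    contigs: Iterable[SeqRecord],
    templates: Mapping[str, str],
    taxon_label: str = "Eukaryota;synthetic-marker",
    k: int = 21,
) -> list[MarkerCall]:
    """Detect planted marker templates in contigs by exact k-mer anchoring.

    A stand-in for an HMM-based rRNA caller, usable only with the synthetic
    marker templates this package plants; reports the number of template
    bases covered by k-mers shared with the contig as the aligned length.
    """
    calls = []
    tmpl_kmers = {
        name: {seq[i : i + k]: i for i in range(len(seq) - k + 1)}
        for name, seq in templates.items()
    }
    for contig in contigs:
        contig_kmers = {
            contig.sequence[i : i + k] for i in range(len(contig.sequence) - k + 1)
        }
        rc = _kmers.revcomp(contig.sequence)
        contig_kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
        for name, kmap in tmpl_kmers.items():
            hit_pos = sorted(p for s, p in kmap.items() if s in contig_kmers)
            if not hit_pos:
                continue
            covered = _union_len([(p, p + k) for p in hit_pos])
            marker = name if name in ("SSU", "LSU", "MITO") else "SSU"
            calls.append(
                MarkerCall(
                    contig_id=contig.id,
                    marker=marker,
                    pident=100.0,
                    aln_length=covered,
                    taxon_label=taxon_label,
                )
            )
    return calls


def _union_len(intervals: Sequence[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def flag_euk_clusters(
    assignment: ClusterAssignment,
    evidence: Mapping[str, ContigEvidence],
) -> ClusterAssignment:
    """Flag clusters as potentially eukaryotic.

    A cluster is flagged iff a strict majority of its taxonomically labeled
    contigs (routing category Eukaryote vs Archaea/Bacteria/Virus; Unknown is
    uninformative) are Eukaryote, or it contains a eukaryotic marker call
    (SSU, LSU or MITO — organellar and rDNA contigs form their own
    composition clusters with no routed members, and the marker is then the
    only eukaryote-diagnostic signal).  Clusters with no labeled contigs and
    no markers stay unflagged.
    """
    members: dict[int, list[str]] = {}
    for cid, label in assignment.labels.items():
        members.setdefault(label, []).append(cid)
    flags = {}
    for label, cids in members.items():
        n_euk = n_labeled = 0
        has_euk_marker = False
        for cid in cids:
            ev = evidence.get(cid)
            if ev is None:
                continue
            if ev.routing_category is TaxCategory.EUKARYOTE:
                n_euk += 1
                n_labeled += 1
            elif ev.routing_category in PROK_VIRUS:
                n_labeled += 1
            if any(m.taxon_label.startswith("Eukaryota") for m in ev.markers):
                has_euk_marker = True
        flags[label] = (n_labeled > 0 and n_euk * 2 > n_labeled) or has_euk_marker
    return ClusterAssignment(assignment.clustering_id, dict(assignment.labels), flags)


def consensus_membership(assignments: Sequence[ClusterAssignment]) -> set[str]:
    """Contigs sitting in a flagged eukaryotic cluster in ≥ 2 of 3 clusterings."""
    if len(assignments) != 3:
        raise ValueError(f"expected exactly 3 clusterings, got {len(assignments)}")
    counts: dict[str, int] = {}
    for a in assignments:
        for cid in a.flagged_ids():
            counts[cid] = counts.get(cid, 0) + 1
    return {cid for cid, n in counts.items() if n >= 2}


def flag_mitochondrial(
    candidates: Iterable[str],
    evidence: Mapping[str, ContigEvidence],
) -> set[str]:
    """Contigs with a MITO marker call AND a mitochondrial best hit."""
    out = set()
    for cid in candidates:
        ev = evidence.get(cid)
        if ev is not None and ev.has_marker("MITO") and ev.best_hit_is_mito:
            out.add(cid)
    return out


def compute_ssu_cap(
    candidates: Iterable[str], evidence: Mapping[str, ContigEvidence]
) -> Optional[float]:
    """Max mean depth among SSU-marker contigs in the candidate set, or None."""
    depths = [
        evidence[cid].mean_depth()
        for cid in candidates
        if cid in evidence and evidence[cid].has_marker("SSU")
    ]
    return max(depths) if depths else None


def _is_eukaryotic_by_any(ev: ContigEvidence) -> bool:
    return (
        ev.routing_category is TaxCategory.EUKARYOTE
        or ev.best_hit_category is TaxCategory.EUKARYOTE
        or any(m.taxon_label.startswith("Eukaryota") for m in ev.markers)
    )


def _is_unlabeled(ev: ContigEvidence) -> bool:
    return (
        ev.routing_category is TaxCategory.UNKNOWN
        and ev.best_hit is None
        and not ev.markers
    )


def apply_inclusion_criteria(
    candidates: Iterable[str],
    evidence: Mapping[str, ContigEvidence],
    ssu_cap: Optional[float],
    assignments: Sequence[ClusterAssignment],
    all_ids: Optional[Iterable[str]] = None,
) -> BinResult:
    """Apply the five inclusion criteria to the consensus candidates.

    ``candidates`` is the output of :func:`consensus_membership`; contigs in
    ``all_ids`` but not in it are rejected CONSENSUS_LT2.  ``ssu_cap`` =
    None skips the depth criterion (no SSU contig to anchor it).  Retained
    contigs are grouped into nuclear bins by their first flagged cluster (k4
    before k5 before k5+6).
    """
    candidates = set(candidates)
    all_ids = set(all_ids) if all_ids is not None else set(candidates)
    if ssu_cap is None:
        warnings.warn("no SSU-marker contig among candidates; depth cap skipped")
    rejected: dict[str, str] = {cid: "CONSENSUS_LT2" for cid in all_ids - candidates}
    mito = flag_mitochondrial(candidates, evidence)
    nuclear: dict[str, set[str]] = {}
    for cid in sorted(candidates):
        ev = evidence.get(cid, ContigEvidence())
        if cid in mito:
            continue  # mitochondrial bin: exempt from the depth cap
        if ssu_cap is not None and ev.mean_depth() > ssu_cap:
            rejected[cid] = "DEPTH_GT_SSU"
            continue
        if (
            ev.best_hit is not None
            and ev.best_hit_category in PROK_VIRUS
            and ev.best_hit.pident > 90.0
            and ev.best_hit.aln_length >= 1000
        ):
            rejected[cid] = "PROK_HIT"
            continue
        if not (_is_eukaryotic_by_any(ev) or _is_unlabeled(ev)):
            rejected[cid] = "CONFLICTING_TAXONOMY"
            continue
        bin_id = _bin_key(cid, assignments)
        nuclear.setdefault(bin_id, set()).add(cid)
    result = BinResult(nuclear_bins=nuclear, mito_bin=mito, rejected=rejected)
    result.check_partition(all_ids)
    return result


def _bin_key(cid: str, assignments: Sequence[ClusterAssignment]) -> str:
    for a in assignments:
        label = a.labels.get(cid)
        if label is not None and a.euk_flags.get(label, False):
            return f"{a.clustering_id}_{label}"
    return "bin_unassigned"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_binning(
    contigs: Sequence[SeqRecord],
    evidence: Mapping[str, ContigEvidence],
    seed: int = 1234,
    assignments: Optional[Sequence[ClusterAssignment]] = None,
) -> tuple[BinResult, list[ClusterAssignment]]:
    """Full binning workflow: cluster ×3, flag, consensus, criteria.

    ``assignments`` (exactly three, e.g. parsed from external MyCC output)
    bypasses the built-in clusterer.
    """
    if not contigs:
        return BinResult({}, set(), {}), []
    if assignments is None:
        assignments = cluster_all_ksets(contigs, seed=seed)
    if len(assignments) != 3:
        raise ValueError("binning requires exactly three clusterings")
    flagged = [flag_euk_clusters(a, evidence) for a in assignments]
    candidates = consensus_membership(flagged)
    ssu_cap = compute_ssu_cap(candidates, evidence)
    result = apply_inclusion_criteria(
        candidates, evidence, ssu_cap, flagged, all_ids=[c.id for c in contigs]
    )
    logger.info(
        "binning: %d contigs -> %d nuclear bins (%d contigs), %d mito, %d rejected",
        len(contigs),
        len(result.nuclear_bins),
        sum(len(v) for v in result.nuclear_bins.values()),
        len(result.mito_bin),
        len(result.rejected),
    )
    return result, list(flagged)
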