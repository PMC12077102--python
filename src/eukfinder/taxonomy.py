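"""Taxid routing categories and the built-in mini k-mer reference classifier.

Every sequence is routed into one of five categories — Archaea, Bacteria,
Virus, Eukaryote, Unknown — by walking its taxid up the taxonomy to a
superkingdom node.  ``categorize_taxid`` is total: taxid 0 (the unclassified
sentinel), unknown taxids, and lineages that never reach a superkingdom all
map to UNKNOWN.

The mini classifier indexes reference sequences by canonical k-mers (default
k = 31) and reports, per query, the reference covering the most query bases
with matching k-mers.  Its output has Centrifuge semantics: ``hit_length``
is the number of query bases covered by at least one matching k-mer (union
of matched k-mer intervals), and equal-best ties are emitted as multiple
rows with ``num_matches`` = tie count.  It exists so the routing workflow is
testable end-to-end with no external databases; it is not an FM-index search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kmers
from .io_formats import ClassifierHit, SeqRecord, open_text


class TaxCategory(Enum):
    ARCHAEA = "Archaea"
    BACTERIA = "Bacteria"
    VIRUS = "Virus"
    EUKARYOTE = "Eukaryote"
    UNKNOWN = "Unknown"


_SUPERKINGDOMS = {
    "Archaea": TaxCategory.ARCHAEA,
    "Bacteria": TaxCategory.BACTERIA,
    "Viruses": TaxCategory.VIRUS,
    "Eukaryota": TaxCategory.EUKARYOTE,
}

PROK_VIRUS = frozenset({TaxCategory.ARCHAEA, TaxCategory.BACTERIA, TaxCategory.VIRUS})


class TaxonomyMap:
    """taxid -> (parent, rank, name), rooted at taxid 1, with memoized routing.

    Build from an NCBI-style nodes/names dump subset, a flat lineage TSV
    (taxid, parent, rank, name), or directly from a dict.
    """

    def __init__(self, nodes: dict[int, tuple[int, str, str]]):
        self.nodes = dict(nodes)
        self._cache: dict[int, TaxCategory] = {}
        self._validate()

    def _validate(self) -> None:
        for taxid in self.nodes:
            seen = set()
            t = taxid
            while t != 1:
                if t in seen:
                    raise ValueError(f"taxonomy cycle at taxid {t}")
                seen.add(t)
                if t not in self.nodes:
                    break  # dangling parent: tolerated, categorizes UNKNOWN
                parent = self.nodes[t][0]
                if parent == t:
                    break  # self-parent leaf: terminates the walk (UNKNOWN)
                t = parent

    @classmethod
    def from_lineage_tsv(cls, path) -> "TaxonomyMap":
        nodes = {}
        with open_text(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                taxid, parent, rank, name = line.rstrip("\n").split("\t")[:4]
                nodes[int(taxid)] = (int(parent), rank, name)
        return cls(nodes)

    def to_lineage_tsv(self, path) -> None:
        with open_text(path, "wt") as out:
            for taxid in sorted(self.nodes):
                parent, rank, name = self.nodes[taxid]
                out.write(f"{taxid}\t{parent}\t{rank}\t{name}\n")

    @classmethod
    def from_nodes_names(cls, nodes_path, names_path) -> "TaxonomyMap":
        """Parse NCBI taxdump-style nodes.dmp / names.dmp subsets."""
        parents: dict[int, tuple[int, str]] = {}
        with open_text(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.split("|")]
                if len(fields) >= 3 and fields[0]:
                    parents[int(fields[0])] = (int(fields[1]), fields[2])
        names: dict[int, str] = {}
        with open_text(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.split("|")]
                if len(fields) >= 4 and fields[0]:
                    if fields[3] == "scientific name" or int(fields[0]) not in names:
                        names[int(fields[0])] = fields[1]
        nodes = {
            t: (p, r, names.get(t, "")) for t, (p, r) in parents.items()
        }
        return cls(nodes)

    def category(self, taxid: int) -> TaxCategory:
        if taxid in self._cache:
            return self._cache[taxid]
        cat = _categorize_uncached(taxid, self.nodes)
        self._cache[taxid] = cat
        return cat


def _categorize_uncached(taxid: int, nodes: dict[int, tuple[int, str, str]]) -> TaxCategory:
    t = taxid
    for _ in range(1000):  # bounded walk; validated trees are far shallower
        if t == 0 or t not in nodes:
            return TaxCategory.UNKNOWN
        parent, rank, name = nodes[t]
        if name in _SUPERKINGDOMS:
            return _SUPERKINGDOMS[name]
        if t == parent or t == 1:
            return TaxCategory.UNKNOWN
        t = parent
    return TaxCategory.UNKNOWN


def categorize_taxid(taxid: int, taxmap: TaxonomyMap) -> TaxCategory:
    """Route a taxid to its five-way category (total function, memoized)."""
    return taxmap.category(taxid)


# ---------------------------------------------------------------------------
# mini reference database
# ---------------------------------------------------------------------------


@dataclass
class RefSeq:
    ref_id: str
    taxid: int
    record: SeqRecord


@dataclass
class MiniRefDB:
    """Canonical k-mer index over a small reference set.

    The index is stored as parallel sorted arrays (k-mer code, reference
    index); a k-mer shared by several references appears once per reference.
    """

    refs: list[RefSeq]
    k: int
    kmer_codes: np.ndarray = field(repr=False)  # uint64, sorted
    kmer_refs: np.ndarray = field(repr=False)  # int32, parallel to kmer_codes

    @property
    def ref_ids(self) -> list[str]:
        return [r.ref_id for r in self.refs]

    def lookup(self, kmer: str) -> set[str]:
        """Reference ids containing the canonical form of ``kmer``."""
        codes, valid = _kmers.canonical_codes(_kmers.encode(kmer), self.k)
        if codes.size != 1 or not valid[0]:
            return set()
        lo = np.searchsorted(self.kmer_codes, codes[0], side="left")
        hi = np.searchsorted(self.kmer_codes, codes[0], side="right")
        return {self.refs[i].ref_id for i in self.kmer_refs[lo:hi]}

    @property
    def n_kmers(self) -> int:
        return int(self.kmer_codes.size)

    def save(self, path) -> None:
        meta = [(r.ref_id, r.taxid, r.record.sequence) for r in self.refs]
        np.savez_compressed(
            path,
            k=self.k,
            kmer_codes=self.kmer_codes,
            kmer_refs=self.kmer_refs,
            refs=json.dumps(meta),
        )

    @classmethod
    def load(cls, path) -> "MiniRefDB":
        data = np.load(path, allow_pickle=False)
        refs = [
            RefSeq(ref_id, int(taxid), SeqRecord(id=ref_id, sequence=seq))
            for ref_id, taxid, seq in json.loads(str(data["refs"]))
        ]
        return cls(
            refs=refs,
            k=int(data["k"]),
            kmer_codes=data["kmer_codes"],
            kmer_refs=data["kmer_refs"],
        )


def build_kmer_index(
    refs: Sequence[tuple[str, int, SeqRecord]] | Sequence[RefSeq],
    k: int = 31,
) -> MiniRefDB:
    """Index every N-free canonical k-mer of every reference.

    ``k`` must be odd (so no k-mer is its own reverse complement) and in
    [11, 31].  Raises if no reference is at least ``k`` long.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    ref_objs = [r if isinstance(r, RefSeq) else RefSeq(*r) for r in refs]
    if not ref_objs:
        raise ValueError("no reference sequences supplied")
    ids = [r.ref_id for r in ref_objs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ref_ids in reference set")
    code_blocks, ref_blocks = [], []
    for i, ref in enumerate(ref_objs):
        codes, valid = _kmers.canonical_codes(_kmers.encode(ref.record.sequence), k)
        codes = np.unique(codes[valid])
        if codes.size:
            code_blocks.append(codes)
            ref_blocks.append(np.full(codes.size, i, dtype=np.int32))
    if not code_blocks:
        raise ValueError(f"all references shorter than k={k}: empty index")
    all_codes = np.concatenate(code_blocks)
    all_refs = np.concatenate(ref_blocks)
    order = np.argsort(all_codes, kind="stable")
    return MiniRefDB(refs=ref_objs, k=k, kmer_codes=all_codes[order], kmer_refs=all_refs[order])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _coverage(positions: np.ndarray, k: int) -> int:
    # union length of intervals [p, p+k) for sorted positions
    if positions.size == 0:
        return 0
    return int(np.minimum(np.diff(positions), k).sum()) + k


def _classify_one(seq: str, db: MiniRefDB) -> list[tuple[int, int]]:
    """Return [(ref_index, hit_length)] sorted best-first (ties by ref_id)."""
    codes, valid = _kmers.canonical_codes(_kmers.encode(seq), db.k)
    if codes.size == 0:
        return []
    lo = np.searchsorted(db.kmer_codes, codes, side="left")
    hi = np.searchsorted(db.kmer_codes, codes, side="right")
    counts = hi - lo
    matched = valid & (counts > 0)
    if not matched.any():
        return []
    pos_list, ref_list = [], []
    single = matched & (counts == 1)
    if single.any():
        pos_list.append(np.flatnonzero(single))
        ref_list.append(db.kmer_refs[lo[single]])
    multi = np.flatnonzero(matched & (counts > 1))
    for p in multi:
        for j in range(lo[p], hi[p]):
            pos_list.append(np.array([p]))
            ref_list.append(db.kmer_refs[j : j + 1])
    positions = np.concatenate(pos_list)
    refs = np.concatenate(ref_list)
    results = []
    for ref_idx in np.unique(refs):
        pos = np.sort(positions[refs == ref_idx])
        results.append((int(ref_idx), _coverage(pos, db.k)))
    results.sort(key=lambda t: (-t[1], db.refs[t[0]].ref_id))
    return results


def classify_with_index(seq: SeqRecord, db: MiniRefDB) -> ClassifierHit:
    """Best-hit classification of one sequence (ties broken by lowest ref_id)."""
    results = _classify_one(seq.sequence, db)
    if not results:
        return ClassifierHit(
            query_id=seq.id, ref_id="unclassified", taxid=0, score=0.0,
            hit_length=0, query_length=len(seq), num_matches=0,
        )
    best_len = results[0][1]
    ties = [r for r in results if r[1] == best_len]
    second = results[len(ties)][1] if len(results) > len(ties) else 0
    ref = db.refs[ties[0][0]]
    return ClassifierHit(
        query_id=seq.id, ref_id=ref.ref_id, taxid=ref.taxid, score=float(best_len),
        second_best_score=float(second), hit_length=best_len, query_length=len(seq),
        num_matches=len(ties),
    )


def classify_batch(
    seqs: Iterable[SeqRecord],
    db: MiniRefDB,
    expand_ties: bool = True,
) -> list[ClassifierHit]:
    """Classify many sequences; with ``expand_ties`` every equal-best
    reference yields its own row (Centrifuge convention)."""
    hits: list[ClassifierHit] = []
    for seq in seqs:
        results = _classify_one(seq.sequence, db)
        if not results:
            hits.append(
                ClassifierHit(
                    query_id=seq.id, ref_id="unclassified", taxid=0, score=0.0,
                    hit_length=0, query_length=len(seq), num_matches=0,
                )
            )
            continue
        best_len = results[0][1]
        ties = [r for r in results if r[1] == best_len]
        second = results[len(ties)][1] if len(results) > len(ties) else 0
        emit = ties if expand_ties else ties[:1]
        for ref_idx, hl in emit:
            ref = db.refs[ref_idx]
            hits.append(
                ClassifierHit(
                    query_id=seq.id, ref_id=ref.ref_id, taxid=ref.taxid,
                    score=float(hl), second_best_score=float(second),
                    hit_length=hl, query_length=len(seq), num_matches=len(ties),
                )
            )
    return hits


def kmer_pseudo_align(
    seqs: Iterable[SeqRecord],
    db: MiniRefDB,
    min_fraction: float = 0.2,
) -> list:
    """Crude alignment-hit emulation from k-mer coverage.

    For each query, the best reference's k-mer-covered span is reported as an
    m8-style hit with pident 100 (the index stores exact k-mers).  Useful as
    a stand-in nt search for the binning evidence layer on synthetic data.
    """
    from .io_formats import AlignmentHit

    out = []
    for seq in seqs:
        results = _classify_one(seq.sequence, db)
        if not results:
            continue
        ref_idx, hl = results[0]
        if hl < min_fraction * len(seq):
            continue
        ref = db.refs[ref_idx]
        out.append(
            AlignmentHit(
                query_id=seq.id, subject_id=ref.ref_id, pident=100.0,
                aln_length=hl, evalue=1e-30, bitscore=2.0 * hl,
                q_start=0, q_end=hl, s_start=0, s_end=hl,
                subject_taxid=ref.taxid,
            )
        )
    return out
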