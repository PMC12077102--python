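"""Mock-community generator with full ground truth.

The benchmark design it reproduces: a staggered prokaryote background
(genome abundances log-spaced over several orders of magnitude) plus a
titration series of eukaryote reads sampled without replacement from a
fixed pool, several replicates per level.  Desk-scale defaults keep the
whole pipeline runnable in minutes on one CPU: 10 background genomes of
300 kb, one 200 kb eukaryote, a 200,000-read background, and levels
{2k, 5k, 10k, 20k} eukaryote reads × 2 replicates.  The eukaryote carries
two extra replicons mirroring the multi-copy elements real recovery relies
on: an rDNA cassette (SSU+LSU, ~5 kb) at 10× copy number — tandem rDNA
arrays collapse into one high-depth contig, which is what anchors the SSU
depth cap — and a 10 kb mitochondrial replicon at 4× copy number, the
separate high-depth organellar bin.  A paper-scale preset (51 background
genomes, 16.6 M background reads, 8 levels × 4 replicates = 32
communities) exists for completeness but is not a desk-scale default.

Genomes are drawn from genome-specific second-order Markov composition
models (distinct GC and dinucleotide bias per genome) so composition
clustering has signal to learn.  Eukaryote genomes carry planted SSU/LSU
rRNA, mitochondrial, and single-copy-gene segments copied from bundled
*synthetic* marker templates — tagged random sequences, not biological
rRNA; detection tests match by identity, not biology.

Everything is deterministic under a fixed seed (byte-identical outputs).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import _kmers, io_formats
from .io_formats import SeqRecord, open_text
from .taxonomy import TaxCategory, TaxonomyMap

_TEMPLATE_SEED = 20240915

EUK_TAXID = 9001
MITO_TAXID = 9002


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return _kmers.decode(rng.integers(0, 4, size=length).astype(np.uint8))


def marker_templates() -> dict[str, str]:
    """Bundled synthetic SSU/LSU/MITO marker templates (fixed sequences)."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    return {"SSU": _rand_seq(rng, 1500), "LSU": _rand_seq(rng, 800), "MITO": _rand_seq(rng, 900)}


def scg_templates(n: int = 5) -> dict[str, str]:
    """Bundled synthetic single-copy-gene templates (fixed sequences)."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    return {f"SCG{i + 1:02d}": _rand_seq(rng, 600) for i in range(n)}


# ---------------------------------------------------------------------------
# spec and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockCommunitySpec:
    """Parameters of the staggered mock community.

    ``euk_read_levels`` are total eukaryote *read* counts (a level of 2,000
    means 1,000 pairs); the background read budget is likewise in reads.
    """

    n_background: int = 10
    background_genome_size: int = 300_000
    euk_genome_size: int = 200_000
    mito_size: int = 10_000
    rdna_spacer: int = 1_000
    total_background_reads: int = 200_000
    euk_read_levels: tuple[int, ...] = (2_000, 5_000, 10_000, 20_000)
    replicates: int = 2
    read_length: int = 100
    error_rate: float = 0.005
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    abundance_decades: float = 3.0
    mito_copy_number: float = 4.0
    rdna_copy_number: float = 10.0
    seed: int = 1234

    def __post_init__(self):
        if list(self.euk_read_levels) != sorted(self.euk_read_levels):
            raise ValueError("euk_read_levels must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")

    @classmethod
    def paper_scale(cls) -> "MockCommunitySpec":
        """Full-scale design (51 isolates, 16.6M reads, 8 levels × 4 = 32
        communities). Hours of CPU; not a desk-scale default."""
        levels = tuple(
            int(x) for x in np.round(np.geomspace(300_000, 10_000_000, 8), -3)
        )
        return cls(
            n_background=51,
            background_genome_size=3_000_000,
            euk_genome_size=12_000_000,
            total_background_reads=16_600_000,
            euk_read_levels=levels,
            replicates=4,
        )


@dataclass
class TruthRow:
    seq_id: str
    genome_id: str
    replicon: str
    category: TaxCategory
    start: int
    end: int


@dataclass
class TruthTable:
    """Ground-truth origin of every emitted read and contig."""

    reads: dict[str, TruthRow] = field(default_factory=dict)
    contigs: dict[str, TruthRow] = field(default_factory=dict)
    genomes: dict[tuple[str, str], tuple[int, int, TaxCategory]] = field(default_factory=dict)
    # (genome_id, replicon) -> (length, taxid, category)

    def genome_length(self, genome_id: str, replicon: Optional[str] = None) -> int:
        return sum(
            length
            for (g, r), (length, _, _) in self.genomes.items()
            if g == genome_id and (replicon is None or r == replicon)
        )

    def write_tsv(self, path) -> None:
        with open_text(path, "wt") as out:
            out.write("kind\tseq_id\tgenome_id\treplicon\tcategory\tstart\tend\n")
            for (g, r), (length, taxid, cat) in sorted(self.genomes.items()):
                out.write(f"genome\t{taxid}\t{g}\t{r}\t{cat.value}\t0\t{length}\n")
            for kind, rows in (("read", self.reads), ("contig", self.contigs)):
                for sid in sorted(rows):
                    t = rows[sid]
                    out.write(
                        f"{kind}\t{sid}\t{t.genome_id}\t{t.replicon}\t"
                        f"{t.category.value}\t{t.start}\t{t.end}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        table = cls()
        with open_text(path) as fh:
            header = fh.readline()
            if not header.startswith("kind\t"):
                raise io_formats.FormatError(f"{path}: bad truth header")
            for line in fh:
                kind, sid, g, r, cat, start, end = line.rstrip("\n").split("\t")
                category = TaxCategory(cat)
                if kind == "genome":
                    table.genomes[(g, r)] = (int(end), int(sid), category)
                else:
                    row = TruthRow(sid, g, r, category, int(start), int(end))
                    (table.reads if kind == "read" else table.contigs)[sid] = row
        return table


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass
class Replicon:
    name: str
    sequence: str
    features: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class GenomeRef:
    genome_id: str
    taxid: int
    category: TaxCategory
    replicons: dict[str, Replicon]

    def length(self) -> int:
        return sum(len(r.sequence) for r in self.replicons.values())


@dataclass
class CommunityReferences:
    genomes: list[GenomeRef]
    taxmap: TaxonomyMap

    def ref_entries(self, exclude_genomes: Iterable[str] = ()) -> list[tuple[str, int, SeqRecord]]:
        """(ref_id, taxid, record) per replicon, for the mini-DB builder."""
        excluded = set(exclude_genomes)
        entries = []
        for g in self.genomes:
            if g.genome_id in excluded:
                continue
            for rep in g.replicons.values():
                taxid = MITO_TAXID if (g.category is TaxCategory.EUKARYOTE and rep.name == "mito") else g.taxid
                rid = f"{g.genome_id}.{rep.name}"
                entries.append((rid, taxid, SeqRecord(id=rid, sequence=rep.sequence)))
        return entries

    def mito_ref_ids(self) -> set[str]:
        return {
            f"{g.genome_id}.{rep.name}"
            for g in self.genomes
            for rep in g.replicons.values()
            if g.category is TaxCategory.EUKARYOTE and rep.name == "mito"
        }

    def euk_genome_ids(self) -> set[str]:
        return {g.genome_id for g in self.genomes if g.category is TaxCategory.EUKARYOTE}


def _markov_sequence(rng: np.random.Generator, length: int, gc: float, dinuc_sd: float = 0.35) -> str:
    """Second-order Markov DNA with target GC and random dinucleotide bias.

    The random context bias shifts the chain's stationary base composition,
    so the transition matrix is iteratively rebalanced until its stationary
    marginal matches the target GC (the bias pattern is preserved).
    """
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    P = np.empty((16, 4))
    for ctx in range(16):
        w = p_base * np.exp(rng.normal(0.0, dinuc_sd, 4))
        P[ctx] = w / w.sum()
    for _ in range(50):
        pi = _stationary_base_freq(P)
        err = np.abs(pi - p_base).max()
        if err < 1e-4:
            break
        P *= (p_base / np.maximum(pi, 1e-12))[None, :]
        P /= P.sum(axis=1, keepdims=True)
    cum = [list(np.cumsum(row)) for row in P]
    cum0 = list(np.cumsum(p_base))
    u = rng.random(length)
    out = bytearray(length)
    chars = b"ACGT"

    def pick(row, x):
        if x < row[0]:
            return 0
        if x < row[1]:
            return 1
        if x < row[2]:
            return 2
        return 3

    a = pick(cum0, u[0])
    b = pick(cum0, u[1]) if length > 1 else 0
    out[0] = chars[a]
    if length > 1:
        out[1] = chars[b]
    for i in range(2, length):
        c = pick(cum[a * 4 + b], u[i])
        out[i] = chars[c]
        a, b = b, c
    return out.decode("ascii")


def _stationary_base_freq(P: np.ndarray) -> np.ndarray:
    """Stationary single-base marginal of the order-2 chain over (prev2, prev1)."""
    T = np.zeros((16, 16))
    for ctx in range(16):
        b = ctx % 4
        for c in range(4):
            T[ctx, b * 4 + c] = P[ctx, c]
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi16 = np.abs(np.real(vecs[:, i]))
    pi16 /= pi16.sum()
    return pi16.reshape(4, 4).sum(axis=0)


def _plant(sequence: str, insert: str, pos: int) -> str:
    return sequence[:pos] + insert + sequence[pos + len(insert) :]


def generate_genomes(spec: MockCommunitySpec, seed: Optional[int] = None) -> CommunityReferences:
    """Generate the background + eukaryote reference genomes and taxonomy.

    Background genomes get GC contents spread evenly over [0.30, 0.65];
    the eukaryote sits at GC 0.45 with SSU/LSU/SCG templates planted in the
    nuclear replicon and the MITO template in its mitochondrial replicon.
    """
    seed = spec.seed if seed is None else seed
    nodes: dict[int, tuple[int, str, str]] = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        2157: (1, "superkingdom", "Archaea"),
        10239: (1, "superkingdom", "Viruses"),
        2759: (1, "superkingdom", "Eukaryota"),
    }
    genomes: list[GenomeRef] = []
    gcs = np.linspace(0.30, 0.65, spec.n_background)
    for i in range(spec.n_background):
        rng = np.random.default_rng([seed, 100 + i])
        gid = f"bact{i + 1:02d}"
        taxid = 1001 + i
        nodes[taxid] = (2, "species", gid)
        seq = _markov_sequence(rng, spec.background_genome_size, float(gcs[i]))
        genomes.append(
            GenomeRef(gid, taxid, TaxCategory.BACTERIA, {"chrom": Replicon("chrom", seq)})
        )

    rng = np.random.default_rng([seed, 900])
    nodes[EUK_TAXID] = (2759, "species", "euk01")
    nodes[MITO_TAXID] = (EUK_TAXID, "no rank", "euk01-mitochondrion")
    chrom = _markov_sequence(rng, spec.euk_genome_size, 0.45)
    features: dict[str, tuple[int, int]] = {}
    templates = marker_templates()
    scgs = scg_templates()
    layout = [("SSU", templates["SSU"]), ("LSU", templates["LSU"])]
    layout += list(scgs.items())
    pos = int(0.2 * spec.euk_genome_size)
    gap = int(0.6 * spec.euk_genome_size / max(len(layout), 1))
    for name, tmpl in layout:
        chrom = _plant(chrom, tmpl, pos)
        features[name] = (pos, pos + len(tmpl))
        pos += gap
    # rDNA cassette: spacer + SSU + spacer + LSU + spacer (multi-copy replicon)
    sp = spec.rdna_spacer
    rdna_parts = [
        _markov_sequence(rng, sp, 0.45),
        templates["SSU"],
        _markov_sequence(rng, sp, 0.45),
        templates["LSU"],
        _markov_sequence(rng, sp, 0.45),
    ]
    rdna_seq = "".join(rdna_parts)
    ssu_start = sp
    lsu_start = 2 * sp + len(templates["SSU"])
    rdna_features = {
        "SSU": (ssu_start, ssu_start + len(templates["SSU"])),
        "LSU": (lsu_start, lsu_start + len(templates["LSU"])),
    }
    mito_seq = _markov_sequence(rng, spec.mito_size, 0.30)
    mito_pos = spec.mito_size // 4
    mito_seq = _plant(mito_seq, templates["MITO"], mito_pos)
    genomes.append(
        GenomeRef(
            "euk01",
            EUK_TAXID,
            TaxCategory.EUKARYOTE,
            {
                "chrom": Replicon("chrom", chrom, features),
                "rdna": Replicon("rdna", rdna_seq, rdna_features),
                "mito": Replicon(
                    "mito", mito_seq, {"MITO": (mito_pos, mito_pos + len(templates["MITO"]))}
                ),
            },
        )
    )
    return CommunityReferences(genomes=genomes, taxmap=TaxonomyMap(nodes))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

Pair = tuple[SeqRecord, SeqRecord]


def _mutate(mat: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    if error_rate <= 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    return np.where(mask, (mat + shift) % 4, mat)


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    chars = _kmers._CHARS[mat]
    return [row.tobytes().decode("ascii") for row in chars]


def simulate_read_pool(
    sources: Sequence[tuple[str, str, str, TaxCategory]],
    weights: Sequence[float],
    n_pairs: int,
    spec: MockCommunitySpec,
    seed: int,
    id_prefix: str,
) -> tuple[list[Pair], dict[str, TruthRow]]:
    """Draw ``n_pairs`` paired reads from weighted (genome, replicon, seq,
    category) sources.

    Pair counts per source are multinomial in the molar weights × source
    length; inserts are normal (truncated to [read_length, source length]);
    fragments come from either strand; substitution errors at
    ``spec.error_rate``; qualities constant Q30.  Raises if a source is
    shorter than the read length or the mean insert.
    """
    rng = np.random.default_rng([seed, 7])
    rl = spec.read_length
    w = np.asarray(weights, dtype=float) * np.array([len(s[2]) for s in sources], dtype=float)
    counts = rng.multinomial(n_pairs, w / w.sum())
    pairs: list[Pair] = []
    truth: dict[str, TruthRow] = {}
    qual = [30] * rl
    serial = 0
    for (gid, rep, seq, category), n in zip(sources, counts):
        if n == 0:
            continue
        L = len(seq)
        if L < rl or L < spec.insert_mean:
            raise ValueError(
                f"source {gid}.{rep} ({L} bp) shorter than the insert size "
                f"({spec.insert_mean:.0f} bp); cannot simulate pairs"
            )
        arr = _kmers.encode(seq)
        ins = np.clip(
            np.round(rng.normal(spec.insert_mean, spec.insert_sd, n)).astype(int), rl, L
        )
        starts = rng.integers(0, L - ins + 1)
        fwd_idx = starts[:, None] + np.arange(rl)
        rev_idx = (starts + ins - rl)[:, None] + np.arange(rl)
        m1 = _mutate(arr[fwd_idx], rng, spec.error_rate)
        m2 = _mutate((3 - arr[rev_idx])[:, ::-1], rng, spec.error_rate)
        minus = rng.random(n) < 0.5
        s1 = _rows_to_strings(m1)
        s2 = _rows_to_strings(m2)
        for j in range(n):
            pid = f"{id_prefix}{serial}"
            serial += 1
            seq1, seq2 = (s2[j], s1[j]) if minus[j] else (s1[j], s2[j])
            r1 = SeqRecord(f"{pid}/1", seq1, qualities=qual, mate=1, pair_id=pid)
            r2 = SeqRecord(f"{pid}/2", seq2, qualities=qual, mate=2, pair_id=pid)
            pairs.append((r1, r2))
            a, b = int(starts[j]), int(starts[j] + ins[j])
            iv1, iv2 = (a, a + rl), (b - rl, b)
            if minus[j]:
                iv1, iv2 = iv2, iv1
            truth[r1.id] = TruthRow(r1.id, gid, rep, category, *iv1)
            truth[r2.id] = TruthRow(r2.id, gid, rep, category, *iv2)
    return pairs, truth


def staggered_weights(n: int, decades: float) -> np.ndarray:
    """Log-spaced relative molar amounts spanning ``decades`` orders of magnitude."""
    if n == 1:
        return np.ones(1)
    return np.power(10.0, -decades * np.arange(n) / (n - 1))


def simulate_background(
    refs: CommunityReferences, spec: MockCommunitySpec, seed: Optional[int] = None
) -> tuple[list[Pair], dict[str, TruthRow]]:
    """The staggered prokaryote background (``total_background_reads`` reads)."""
    seed = spec.seed if seed is None else seed
    bg = [g for g in refs.genomes if g.category is not TaxCategory.EUKARYOTE]
    sources = [
        (g.genome_id, rep.name, rep.sequence, g.category)
        for g in bg
        for rep in g.replicons.values()
    ]
    weights = staggered_weights(len(bg), spec.abundance_decades)
    return simulate_read_pool(
        sources, list(weights), spec.total_background_reads // 2, spec, seed + 1, "bg"
    )


def simulate_euk_pool(
    refs: CommunityReferences,
    spec: MockCommunitySpec,
    n_reads: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[list[Pair], dict[str, TruthRow]]:
    """The eukaryote read pool titrations are sampled from.

    Defaults to 2× the largest titration level; the mitochondrial and rDNA
    replicons are weighted by their copy numbers.
    """
    seed = spec.seed if seed is None else seed
    n_reads = n_reads if n_reads is not None else 2 * max(spec.euk_read_levels)
    copy_number = {"mito": spec.mito_copy_number, "rdna": spec.rdna_copy_number}
    euks = [g for g in refs.genomes if g.category is TaxCategory.EUKARYOTE]
    sources, weights = [], []
    for g in euks:
        for rep in g.replicons.values():
            sources.append((g.genome_id, rep.name, rep.sequence, g.category))
            weights.append(copy_number.get(rep.name, 1.0))
    return simulate_read_pool(sources, weights, n_reads // 2, spec, seed + 2, "euk")


@dataclass
class Community:
    """One titration community: full background + sampled eukaryote pairs."""

    level: int
    replicate: int
    pairs: list[Pair]
    truth: TruthTable
    euk_pair_indices: np.ndarray


def build_titration_series(
    background: Sequence[Pair],
    background_truth: Mapping[str, TruthRow],
    euk_pool: Sequence[Pair],
    euk_truth: Mapping[str, TruthRow],
    levels: Sequence[int],
    replicates: int,
    seed: int,
    refs: Optional[CommunityReferences] = None,
) -> list[Community]:
    """levels × replicates communities, each = background + a without-
    replacement sample of ``level`` eukaryote reads from the pool."""
    genome_rows = _genome_rows(refs) if refs is not None else {}
    out = []
    for level in levels:
        n_pairs = level // 2
        if n_pairs > len(euk_pool):
            raise ValueError(
                f"titration level {level} reads exceeds the eukaryote pool "
                f"({2 * len(euk_pool)} reads)"
            )
        for rep in range(replicates):
            rng = np.random.default_rng([seed, 5, int(level), rep])
            idx = np.sort(rng.choice(len(euk_pool), size=n_pairs, replace=False))
            pairs = list(background) + [euk_pool[i] for i in idx]
            truth = TruthTable(genomes=dict(genome_rows))
            truth.reads.update(background_truth)
            for i in idx:
                r1, r2 = euk_pool[i]
                truth.reads[r1.id] = euk_truth[r1.id]
                truth.reads[r2.id] = euk_truth[r2.id]
            out.append(Community(int(level), rep, pairs, truth, idx))
    return out


def _genome_rows(refs: CommunityReferences) -> dict[tuple[str, str], tuple[int, int, TaxCategory]]:
    rows = {}
    for g in refs.genomes:
        for rep in g.replicons.values():
            rows[(g.genome_id, rep.name)] = (len(rep.sequence), g.taxid, g.category)
    return rows


# ---------------------------------------------------------------------------
# perfect assembly and evidence fixtures
# ---------------------------------------------------------------------------


def perfect_assembly_fixture(
    read_truth: Mapping[str, TruthRow],
    refs: CommunityReferences,
    read_ids: Optional[Iterable[str]] = None,
    min_len: int = 1000,
    id_prefix: str = "ctg",
) -> tuple[list[SeqRecord], dict[str, TruthRow]]:
    """Assembler stand-in: emit each genome's read-covered intervals as contigs.

    Intervals of the selected reads are merged per replicon and each merged
    interval ≥ ``min_len`` becomes one contig (an exact substring of the
    source genome).  Returns (contigs, contig truth rows).
    """
    selected = set(read_ids) if read_ids is not None else set(read_truth)
    by_replicon: dict[tuple[str, str], list[tuple[int, int]]] = {}
    cat_by_genome: dict[str, TaxCategory] = {}
    for rid in selected:
        t = read_truth[rid]
        by_replicon.setdefault((t.genome_id, t.replicon), []).append((t.start, t.end))
        cat_by_genome[t.genome_id] = t.category
    seqs = {
        (g.genome_id, rep.name): rep.sequence
        for g in refs.genomes
        for rep in g.replicons.values()
    }
    contigs: list[SeqRecord] = []
    contig_truth: dict[str, TruthRow] = {}
    for (gid, rep), intervals in sorted(by_replicon.items()):
        merged = _merge_intervals(intervals)
        src = seqs[(gid, rep)]
        for j, (s, e) in enumerate(merged):
            if e - s < min_len:
                continue
            cid = f"{id_prefix}_{gid}_{rep}_{j}"
            contigs.append(SeqRecord(cid, src[s:e]))
            contig_truth[cid] = TruthRow(cid, gid, rep, cat_by_genome[gid], s, e)
    return contigs, contig_truth


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def emit_evidence_fixtures(
    contig_truth: Mapping[str, TruthRow],
    refs: CommunityReferences,
    out_dir,
    depths: Optional[Mapping[str, float]] = None,
    label_noise: float = 0.0,
    missingness: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Write format-valid evidence tables consistent with contig truth.

    Emits classifier TSV, m8, jgi depth TSV and marker TSV into ``out_dir``.
    ``label_noise`` flips a contig's taxid to a random other genome;
    ``missingness`` drops a contig from every evidence table.  Returns the
    file paths.
    """
    rng = np.random.default_rng([seed, 11])
    os.makedirs(out_dir, exist_ok=True)
    by_genome = {g.genome_id: g for g in refs.genomes}
    taxids = sorted({g.taxid for g in refs.genomes})
    classifier_rows, m8_rows, depth_rows, marker_rows = [], [], [], []
    for cid in sorted(contig_truth):
        t = contig_truth[cid]
        if rng.random() < missingness:
            continue
        length = t.end - t.start
        genome = by_genome[t.genome_id]
        taxid = MITO_TAXID if (genome.category is TaxCategory.EUKARYOTE and t.replicon == "mito") else genome.taxid
        if rng.random() < label_noise:
            taxid = int(rng.choice([x for x in taxids if x != taxid]))
        ref_id = f"{t.genome_id}.{t.replicon}"
        classifier_rows.append(
            io_formats.ClassifierHit(
                query_id=cid, ref_id=ref_id, taxid=taxid, score=float(length),
                hit_length=length, query_length=length, num_matches=1,
            )
        )
        m8_rows.append(
            io_formats.AlignmentHit(
                query_id=cid, subject_id=ref_id, pident=100.0, aln_length=length,
                evalue=1e-50, bitscore=2.0 * length, q_start=0, q_end=length,
                s_start=t.start, s_end=t.end, subject_taxid=taxid,
            )
        )
        depth = depths.get(cid, 10.0) if depths is not None else 10.0
        depth_rows.append(
            io_formats.DepthRecord(
                contig_id=cid, contig_len=length, mean_depth=depth,
                samples={"sim": (depth, 0.0)},
            )
        )
        for name, (fs, fe) in by_genome[t.genome_id].replicons[t.replicon].features.items():
            overlap = min(fe, t.end) - max(fs, t.start)
            if overlap > 300 and name in ("SSU", "LSU", "MITO"):
                marker_rows.append(
                    io_formats.MarkerCall(
                        contig_id=cid, marker=name, pident=99.0,
                        aln_length=overlap, taxon_label="Eukaryota;euk01",
                    )
                )
    paths = {
        "classifier": os.path.join(out_dir, "classifier.tsv"),
        "m8": os.path.join(out_dir, "hits.m8"),
        "depth": os.path.join(out_dir, "depth.tsv"),
        "markers": os.path.join(out_dir, "markers.tsv"),
    }
    io_formats.write_hits(classifier_rows, paths["classifier"], "classifier")
    io_formats.write_hits(m8_rows, paths["m8"], "m8")
    io_formats.write_depth_table(depth_rows, paths["depth"])
    io_formats.write_marker_table(marker_rows, paths["markers"])
    return paths
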