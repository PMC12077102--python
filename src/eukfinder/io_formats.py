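"""Readers and writers for every on-disk format the pipeline touches.

Supported formats
-----------------
* FASTA and FASTQ (Phred+33 only; other encodings are rejected, not guessed)
* Centrifuge-style classification TSV
  (readID/seqID/taxID/score/2ndBestScore/hitLength/queryLength/numMatches)
* BLAST/PLAST tabular "m8" (12 headerless columns, optional 13th = subject
  taxid)
* MetaBAT2 ``jgi_summarize_bam_contig_depths`` depth TSV
* Metaxa2-style rRNA/mitochondrial marker call TSV
* bin-membership TSV (contig_id, bin_id, reason)

Coordinates in m8 files follow the BLAST convention (1-based inclusive);
conversion to internal 0-based half-open coordinates happens here and only
here.  Gzip-compressed inputs are auto-detected by magic bytes.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, os.PathLike]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class PairingError(ValueError):
    """Two paired FASTQ files are out of sync."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A read or contig: uppercase ACGTN sequence, optional Phred qualities.

    ``mate`` (1 or 2) and ``pair_id`` are set together for paired-end reads.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    mate: Optional[int] = None
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")
        if (self.mate is None) != (self.pair_id is None):
            raise ValueError(f"record {self.id!r}: mate and pair_id must be set together")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClassifierHit:
    """One row of k-mer-classifier evidence (Centrifuge semantics).

    ``hit_length`` counts query bases covered by matching k-mers; ``taxid`` 0
    means unclassified.  Ties are emitted as multiple rows sharing a
    ``query_id``, each carrying ``num_matches`` = tie count.
    """

    query_id: str
    ref_id: str
    taxid: int
    score: float
    hit_length: int
    query_length: int
    num_matches: int
    second_best_score: float = 0.0

    def __post_init__(self) -> None:
        if self.taxid < 0:
            raise ValueError("taxid must be non-negative")
        if not 0 <= self.hit_length <= self.query_length:
            raise ValueError(
                f"hit {self.query_id!r}: hit_length {self.hit_length} outside "
                f"[0, query_length={self.query_length}]"
            )
        if self.taxid == 0 and self.num_matches != 0:
            raise ValueError("unclassified hit (taxid 0) must have num_matches 0")


@dataclass
class AlignmentHit:
    """One m8 alignment row; coordinates stored 0-based half-open."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    mismatch: int = 0
    gapopen: int = 0
    subject_taxid: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError("pident outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.q_start > self.q_end:
            self.q_start, self.q_end = self.q_end, self.q_start


@dataclass
class DepthRecord:
    """Per-contig read coverage depth (jgi depth table semantics)."""

    contig_id: str
    contig_len: int
    mean_depth: float
    depth_var: float = 0.0
    samples: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.contig_len < 1:
            raise ValueError("contig_len must be >= 1")
        if self.mean_depth < 0 or self.depth_var < 0:
            raise ValueError("depth statistics must be non-negative")


MARKERS = ("SSU", "LSU", "MITO")


@dataclass
class MarkerCall:
    """An rRNA/mitochondrial marker detection on a contig (Metaxa2 semantics)."""

    contig_id: str
    marker: str
    pident: float
    aln_length: int
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError("pident outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def open_text(path: PathLike, mode: str = "rt") -> TextIO:
    """Open a text file, transparently decompressing gzip (magic-byte sniff)."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt")
        return open(path, "rt")
    if str(path).endswith(".gz"):
        return gzip.open(path, mode if "t" in mode else mode + "t")
    return open(path, mode)


_VALID = set("ACGTN")


def _clean_seq(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def _strip_mate_suffix(read_id: str) -> tuple[str, Optional[int]]:
    if read_id.endswith("/1"):
        return read_id[:-2], 1
    if read_id.endswith("/2"):
        return read_id[:-2], 2
    return read_id, None


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: PathLike) -> Iterator[SeqRecord]:
    """Yield records from a (possibly gzipped) Phred+33 FASTQ file.

    Truncated or malformed records raise :class:`FormatError` naming the
    0-based index of the offending record.
    """
    handle = open_text(path)
    parser = SeqIO.parse(handle, "fastq")
    idx = 0
    try:
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"{path}: malformed FASTQ record #{idx}: {exc}") from exc
            yield SeqRecord(
                id=rec.id,
                sequence=_clean_seq(str(rec.seq)),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
            idx += 1
    finally:
        handle.close()


def read_fastq_pairs(path1: PathLike, path2: PathLike) -> Iterator[tuple[SeqRecord, SeqRecord]]:
    """Yield synchronized mate pairs from two FASTQ files.

    Pair identity is the read id with any ``/1``–``/2`` suffix stripped; a
    mismatch at any position raises :class:`PairingError`.
    """
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for i, (r1, r2) in enumerate(_zip_strict(it1, it2, path1, path2)):
        p1, _ = _strip_mate_suffix(r1.id)
        p2, _ = _strip_mate_suffix(r2.id)
        if p1 != p2:
            raise PairingError(
                f"desynchronized pairs at record #{i}: {r1.id!r} vs {r2.id!r}"
            )
        r1.pair_id, r1.mate = p1, 1
        r2.pair_id, r2.mate = p2, 2
        yield r1, r2


def _zip_strict(it1, it2, path1, path2):
    while True:
        a = next(it1, None)
        b = next(it2, None)
        if a is None and b is None:
            return
        if a is None or b is None:
            longer = path2 if a is None else path1
            raise PairingError(f"paired FASTQ files differ in length ({longer} is longer)")
        yield a, b


def write_fastq(records: Iterable[SeqRecord], path: PathLike) -> int:
    """Write Phred+33 FASTQ; records must carry qualities. Returns count."""
    n = 0
    with open_text(path, "wt") as out:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: PathLike) -> Iterator[SeqRecord]:
    """Yield records from a (possibly gzipped) FASTA file."""
    with open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SeqRecord(id=rec.id, sequence=_clean_seq(str(rec.seq)))


def write_fasta(records: Iterable[SeqRecord], path: PathLike, width: int = 80) -> int:
    n = 0
    with open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# tabular hit files
# ---------------------------------------------------------------------------

CLASSIFIER_COLUMNS = [
    "readID",
    "seqID",
    "taxID",
    "score",
    "2ndBestScore",
    "hitLength",
    "queryLength",
    "numMatches",
]


def read_tabular_hits(
    path: PathLike,
    dialect: str,
    rejects: Optional[list] = None,
) -> list:
    """Parse a hit table.

    ``dialect`` is ``"classifier"`` (headered, Centrifuge columns) or ``"m8"``
    (12+ headerless BLAST/PLAST columns, optional 13th column = subject
    taxid).  Rows that fail numeric conversion are rejected; pass a list as
    ``rejects`` to collect ``(line_number, reason)`` tuples (1-based line
    numbers).  A row with the wrong column count raises :class:`FormatError`.
    """
    if dialect not in ("classifier", "m8"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list = []
    with open_text(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if dialect == "classifier":
        if not lines:
            return hits
        header = lines[0].split("\t")
        if header != CLASSIFIER_COLUMNS:
            raise FormatError(f"{path}: bad classifier header {header!r}")
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            if dialect == "classifier":
                if len(fields) != 8:
                    raise FormatError(
                        f"{path}:{lineno}: expected 8 columns, got {len(fields)}"
                    )
                hits.append(
                    ClassifierHit(
                        query_id=fields[0],
                        ref_id=fields[1],
                        taxid=int(fields[2]),
                        score=float(fields[3]),
                        second_best_score=float(fields[4]),
                        hit_length=int(fields[5]),
                        query_length=int(fields[6]),
                        num_matches=int(fields[7]),
                    )
                )
            else:
                if len(fields) < 12:
                    raise FormatError(
                        f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                    )
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                taxid = None
                if len(fields) >= 13 and fields[12] not in ("", "N/A"):
                    taxid = int(fields[12])
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        # 1-based inclusive -> 0-based half-open
                        q_start=min(qs, qe) - 1,
                        q_end=max(qs, qe),
                        s_start=min(ss, se) - 1,
                        s_end=max(ss, se),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        subject_taxid=taxid,
                    )
                )
        except FormatError:
            raise
        except (ValueError, TypeError) as exc:
            if rejects is not None:
                rejects.append((lineno, str(exc)))
    return hits


def write_hits(hits: Sequence, path: PathLike, dialect: str) -> int:
    """Inverse of :func:`read_tabular_hits` (m8 coords back to 1-based)."""
    with open_text(path, "wt") as out:
        if dialect == "classifier":
            out.write("\t".join(CLASSIFIER_COLUMNS) + "\n")
            for h in hits:
                out.write(
                    f"{h.query_id}\t{h.ref_id}\t{h.taxid}\t{h.score:g}\t"
                    f"{h.second_best_score:g}\t{h.hit_length}\t{h.query_length}\t"
                    f"{h.num_matches}\n"
                )
        elif dialect == "m8":
            for h in hits:
                cols = [
                    h.query_id,
                    h.subject_id,
                    f"{h.pident:.2f}",
                    str(h.aln_length),
                    str(h.mismatch),
                    str(h.gapopen),
                    str(h.q_start + 1),
                    str(h.q_end),
                    str(h.s_start + 1),
                    str(h.s_end),
                    repr(h.evalue),  # shortest exact representation
                    repr(h.bitscore),
                ]
                if h.subject_taxid is not None:
                    cols.append(str(h.subject_taxid))
                out.write("\t".join(cols) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return len(hits)


# ---------------------------------------------------------------------------
# depth tables (jgi_summarize_bam_contig_depths dialect)
# ---------------------------------------------------------------------------

_DEPTH_REQUIRED = ["contigName", "contigLen", "totalAvgDepth"]


def read_depth_table(path: PathLike) -> list[DepthRecord]:
    """Parse a MetaBAT2 jgi depth TSV.

    ``mean_depth`` comes from totalAvgDepth; per-sample depth/var column
    pairs after it are preserved on ``DepthRecord.samples`` for round-trip.
    """
    df = pd.read_csv(open_text(path), sep="\t")
    for col in _DEPTH_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _DEPTH_REQUIRED and not c.endswith("-var")]
    records = []
    for _, row in df.iterrows():
        samples = {}
        for sc in sample_cols:
            var_col = sc + "-var"
            samples[sc] = (
                float(row[sc]),
                float(row[var_col]) if var_col in df.columns else 0.0,
            )
        depth_var = next(iter(samples.values()))[1] if samples else 0.0
        records.append(
            DepthRecord(
                contig_id=str(row["contigName"]),
                contig_len=int(row["contigLen"]),
                mean_depth=float(row["totalAvgDepth"]),
                depth_var=depth_var,
                samples=samples,
            )
        )
    return records


def write_depth_table(records: Sequence[DepthRecord], path: PathLike) -> int:
    sample_names: list[str] = []
    for rec in records:
        for name in rec.samples:
            if name not in sample_names:
                sample_names.append(name)
    header = list(_DEPTH_REQUIRED)
    for name in sample_names:
        header += [name, name + "-var"]
    with open_text(path, "wt") as out:
        out.write("\t".join(header) + "\n")
        for rec in records:
            cols = [rec.contig_id, str(rec.contig_len), f"{rec.mean_depth:g}"]
            for name in sample_names:
                d, v = rec.samples.get(name, (0.0, 0.0))
                cols += [f"{d:g}", f"{v:g}"]
            out.write("\t".join(cols) + "\n")
    return len(records)


# ---------------------------------------------------------------------------
# marker call tables (Metaxa2 dialect) and bin membership
# ---------------------------------------------------------------------------

_MARKER_HEADER = ["contig_id", "marker", "pident", "aln_length", "taxon_label"]


def read_marker_table(path: PathLike) -> list[MarkerCall]:
    with open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    if lines[0].split("\t") != _MARKER_HEADER:
        raise FormatError(f"{path}: bad marker table header")
    calls = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        calls.append(
            MarkerCall(
                contig_id=fields[0],
                marker=fields[1],
                pident=float(fields[2]),
                aln_length=int(fields[3]),
                taxon_label=fields[4],
            )
        )
    return calls


def write_marker_table(calls: Sequence[MarkerCall], path: PathLike) -> int:
    with open_text(path, "wt") as out:
        out.write("\t".join(_MARKER_HEADER) + "\n")
        for c in calls:
            out.write(
                f"{c.contig_id}\t{c.marker}\t{c.pident:g}\t{c.aln_length}\t{c.taxon_label}\n"
            )
    return len(calls)


def write_bin_membership(rows: Sequence[tuple[str, str, str]], path: PathLike) -> int:
    """Write (contig_id, bin_id, reason) rows; reason empty for binned contigs."""
    with open_text(path, "wt") as out:
        out.write("contig_id\tbin_id\treason\n")
        for contig_id, bin_id, reason in rows:
            out.write(f"{contig_id}\t{bin_id}\t{reason}\n")
    return len(rows)


def read_bin_membership(path: PathLike) -> list[tuple[str, str, str]]:
    with open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["contig_id", "bin_id", "reason"]:
        raise FormatError(f"{path}: bad bin membership header")
    rows = []
    for line in lines[1:]:
        if line.strip():
            f = line.split("\t")
            if len(f) != 3:
                raise FormatError(f"{path}: expected 3 columns")
            rows.append((f[0], f[1], f[2]))
    return rows
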