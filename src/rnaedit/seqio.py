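"""Sequence and annotation I/O plus the shared coordinate model.

All coordinates are 0-based half-open internally.  Report-facing writers
render positions 1-based, matching the ``chr1:20124223`` style used in the
editing-site literature.  Supported formats: FASTA (via Biopython), FASTQ
(Biopython's fast string iterator), a SAM subset (via pysam), and BED4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# anything outside the nucleotide alphabet collapses to N
_SANITIZE = {c: c if c in "ACGTN" else "N" for c in map(chr, range(128))}
_SANITIZE_TABLE = str.maketrans(_SANITIZE)

#: precedence when feature intervals overlap; repeat membership is orthogonal
FEATURE_PRECEDENCE = ("CDS", "3'-UTR", "5'-UTR", "intron")
INTERGENIC = "intergenic"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def to_report_pos(pos: int) -> int:
    """Internal 0-based position -> 1-based report position."""
    return pos + 1


def from_report_pos(pos: int) -> int:
    """1-based report position -> internal 0-based position."""
    return pos - 1


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single genomic position with the strand of the assayed transcript."""

    contig: str
    pos: int  # 0-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    def report(self) -> str:
        return f"{self.contig}:{to_report_pos(self.pos)}"


@dataclass
class ReferenceGenome:
    """Uppercase A/C/G/T/N reference sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"interval [{start},{end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)


def load_reference(path: str | Path) -> ReferenceGenome:
    """Read a FASTA file into a :class:`ReferenceGenome`.

    Lowercase (soft-masked) bases are uppercased; characters outside
    A/C/G/T/N are mapped to N.  Duplicate contig names and empty files are
    hard errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper().translate(_SANITIZE_TABLE)
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality_string)`` from a FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for rid, seq, qual in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# CIGAR operators supported by the SAM subset (pysam numeric codes)
_CIGAR_OPS = "MIDNSHP=X"
_SUPPORTED_OPS = frozenset("MIDS=X")
_READ_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MD=X")


@dataclass
class AlignedRead:
    """A mapped read with per-base qualities and run-length alignment ops."""

    read_id: str
    contig: str
    pos: int  # leftmost 0-based reference position
    strand: str
    sequence: str
    qualities: np.ndarray  # Phred scores, uint8, same length as sequence
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        consumed = sum(n for op, n in self.cigar if op in _READ_CONSUMING)
        if consumed != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {consumed} bases on the "
                f"read side but sequence has {len(self.sequence)}"
            )

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def end(self) -> int:
        """One past the last reference position covered."""
        return self.pos + self.reference_span

    def is_gapless(self) -> bool:
        return len(self.cigar) == 1 and self.cigar[0][0] in "M=X"


def load_alignments(
    path: str | Path, min_mapq: int = 20, sample_id: Optional[str] = None
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM file, excluding MAPQ < ``min_mapq``.

    Records with CIGAR operators outside M/I/D/S/=/X are skipped with a
    warning; unmapped records are dropped silently.  Malformed records are
    a hard error naming the offending record index.
    """
    skipped_ops = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        record_no = 0
        it = sam.fetch(until_eof=True)
        while True:
            record_no += 1
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:  # pragma: no cover - rare
                raise ValueError(
                    f"malformed SAM record #{record_no} in {path}: {exc}"
                ) from exc
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            cigar = tuple(
                (_CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or ())
            )
            if any(op not in _SUPPORTED_OPS for op, _ in cigar):
                skipped_ops += 1
                log.warning(
                    "skipping read %s: unsupported CIGAR operator in %s",
                    rec.query_name,
                    rec.cigarstring,
                )
                continue
            if rec.query_qualities is None:
                raise ValueError(
                    f"read {rec.query_name} in {path} has no base qualities"
                )
            yield AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                sequence=rec.query_sequence.upper(),
                qualities=np.array(rec.query_qualities, dtype=np.uint8),
                mapq=rec.mapping_quality,
                cigar=cigar,
                sample_id=sample_id,
            )
    if skipped_ops:
        log.info("skipped %d reads with unsupported CIGAR operators", skipped_ops)


def write_sam(
    reads: Iterable[AlignedRead],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> int:
    """Write reads as SAM text with an @SQ header per contig."""
    names = list(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": contig_lengths[n]} for n in names],
    }
    index = {n: i for i, n in enumerate(names)}
    n_written = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.flag = 16 if read.strand == "-" else 0
            seg.reference_id = index[read.contig]
            seg.reference_start = read.pos
            seg.mapping_quality = read.mapq
            seg.cigartuples = [
                (_CIGAR_OPS.index(op), ln) for op, ln in read.cigar
            ]
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.qualities)
            )
            out.write(seg)
            n_written += 1
    return n_written


@dataclass
class AnnotationSet:
    """Feature intervals (CDS/UTR/intron) and repeat-family intervals.

    Both tracks are half-open interval trees keyed by contig.  Feature
    queries resolve overlaps by ``FEATURE_PRECEDENCE``; repeat queries
    return the family of the earliest-starting overlapping element.
    """

    features: dict[str, IntervalTree] = field(default_factory=dict)
    repeats: dict[str, IntervalTree] = field(default_factory=dict)

    def category_at(self, contig: str, pos: int) -> str:
        tree = self.features.get(contig)
        if tree is None:
            return INTERGENIC
        labels = {iv.data[0] for iv in tree.at(pos)}
        if not labels:
            return INTERGENIC
        for label in FEATURE_PRECEDENCE:
            if label in labels:
                return label
        # unknown labels preserved verbatim, deterministic pick
        return sorted(labels)[0]

    def repeat_family_at(self, contig: str, pos: int) -> Optional[str]:
        tree = self.repeats.get(contig)
        if tree is None:
            return None
        hits = tree.at(pos)
        if not hits:
            return None
        return min(hits, key=lambda iv: (iv.begin, iv.data)).data

    def repeat_base_totals(self) -> dict[str, int]:
        """Bases occupied per repeat family (overlaps counted per element)."""
        totals: dict[str, int] = {}
        for tree in self.repeats.values():
            for iv in tree:
                totals[iv.data] = totals.get(iv.data, 0) + (iv.end - iv.begin)
        return totals

    def check_bounds(self, genome: ReferenceGenome) -> None:
        for track in (self.features, self.repeats):
            for contig, tree in track.items():
                if contig not in genome:
                    raise ValueError(f"annotation contig {contig!r} not in genome")
                limit = genome.length(contig)
                for iv in tree:
                    if iv.begin < 0 or iv.end > limit:
                        raise ValueError(
                            f"interval [{iv.begin},{iv.end}) out of bounds "
                            f"for contig {contig!r} (length {limit})"
                        )


def _parse_bed4(path: str | Path, with_strand: bool = False):
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 needs >=4 columns")
            contig, start, end, label = fields[:4]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if with_strand and len(fields) > 5 else "+"
            rows.append((contig, start, end, label, strand))
    return rows


def load_annotations(
    features_path: Optional[str | Path] = None,
    repeats_path: Optional[str | Path] = None,
) -> AnnotationSet:
    """Load feature and repeat BED4 tracks (either may be omitted)."""
    ann = AnnotationSet()
    if features_path is not None:
        for contig, start, end, label, strand in _parse_bed4(
            features_path, with_strand=True
        ):
            ann.features.setdefault(contig, IntervalTree()).addi(
                start, end, (label, strand)
            )
    if repeats_path is not None:
        for contig, start, end, label, _ in _parse_bed4(repeats_path):
            ann.repeats.setdefault(contig, IntervalTree()).addi(start, end, label)
    return ann


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write BED4 rows sorted by (contig, start, end, label)."""
    rows = sorted(intervals)
    with open(path, "w") as handle:
        for contig, start, end, label in rows:
            handle.write(f"{contig}\t{start}\t{end}\t{label}\n")
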