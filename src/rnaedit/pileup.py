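"""Per-position, quality-filtered allele counting over aligned reads.

Semantics follow samtools-style pileup: deletions reduce depth rather than
counting as a fifth allele, insertions are ignored for counting, N bases are
discarded, and each read contributes at most one base per column.  Read
pairs are not de-duplicated (single-end chemistry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

from .seqio import AlignedRead, GenomicSite, ReferenceGenome, to_report_pos

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class FilterThresholds:
    """Every quantitative cutoff used across the pipeline.

    The defaults reproduce the published analysis: bases and reads enter
    counts only at quality >= 20; hyperediting candidates need more than
    five edited reads and an editing level above 0.01; amplicon sites are
    retained at depth >= 400 in >= 75% of a genotype's samples with a mean
    level of at least 2%; off-target discovery needs >= 10 mismatch reads.
    Cluster geometry (100 bp window, >= 3 same-class sites) and the pooled
    gDNA alternate-allele ceiling (1%) are this package's own defaults.
    """

    min_base_qual: int = 20
    min_mapq: int = 20
    min_mismatch_reads: int = 10
    he_min_edited_reads: int = 6  # "more than five edited reads"
    he_min_level: float = 0.01  # exclusive
    amp_min_coverage: int = 400
    amp_min_level: float = 0.02
    amp_min_incidence: float = 0.75
    cluster_window_bp: int = 100
    cluster_min_sites: int = 3
    snp_max_gdna_alt: float = 0.01

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"{f.name} must be non-negative, got {value}")
        for name in ("he_min_level", "amp_min_level", "amp_min_incidence",
                     "snp_max_gdna_alt"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {value}")

    def with_overrides(self, **kwargs) -> "FilterThresholds":
        return replace(self, **kwargs)


@dataclass
class PileupColumn:
    """Quality-passing base counts at one position, with supporting reads."""

    site: GenomicSite
    ref: str
    counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES}
    )
    supporters: dict[str, list[str]] = field(
        default_factory=lambda: {b: [] for b in BASES}
    )

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class UndefinedLevelError(ValueError):
    """Editing level requested where no A or G evidence exists."""


def editing_level(n_ref: int, n_alt: int) -> float:
    """Edited fraction: alt / (ref + alt) among quality-passing bases.

    For A-to-I editing this is the fraction of G reads among A+G reads.
    Raises :class:`UndefinedLevelError` when both counts are zero, which is
    distinct from a true level of 0.
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("counts must be non-negative")
    total = n_ref + n_alt
    if total == 0:
        raise UndefinedLevelError("editing level undefined with zero coverage")
    return n_alt / total


def build_pileup(
    reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    contig: str,
    start: int,
    end: int,
    thresholds: FilterThresholds | None = None,
    strand: str = "+",
) -> list[PileupColumn]:
    """Count quality-passing bases per position over ``[start, end)``.

    Reads below ``min_mapq`` contribute nothing; bases below
    ``min_base_qual`` and N bases are excluded.  A read extending beyond
    the contig end is a hard error naming the read.
    """
    thresholds = thresholds or FilterThresholds()
    contig_len = reference.length(contig)
    columns: dict[int, PileupColumn] = {}

    for read in reads:
        if read.contig != contig:
            continue
        if read.mapq < thresholds.min_mapq:
            continue
        if read.end > contig_len or read.pos < 0:
            raise ValueError(
                f"read {read.read_id} spans [{read.pos},{read.end}) beyond "
                f"contig {contig!r} of length {contig_len}"
            )
        ref_pos = read.pos
        read_pos = 0
        for op, length in read.cigar:
            if op in "M=X":
                for i in range(length):
                    pos = ref_pos + i
                    if not start <= pos < end:
                        continue
                    base = read.sequence[read_pos + i]
                    if base == "N" or base not in "ACGT":
                        continue
                    if read.qualities[read_pos + i] < thresholds.min_base_qual:
                        continue
                    col = columns.get(pos)
                    if col is None:
                        col = PileupColumn(
                            site=GenomicSite(contig, pos, strand),
                            ref=reference.base(contig, pos),
                        )
                        columns[pos] = col
                    col.counts[base] += 1
                    col.supporters[base].append(read.read_id)
                ref_pos += length
                read_pos += length
            elif op == "I" or op == "S":
                read_pos += length
            elif op == "D":
                ref_pos += length
            else:  # pragma: no cover - load_alignments already filters
                raise ValueError(f"unsupported CIGAR op {op!r}")

    return [columns[pos] for pos in sorted(columns)]


def write_pileup_tsv(columns: Sequence[PileupColumn], path) -> None:
    """TSV report: contig, 1-based pos, ref, A, C, G, T, depth."""
    with open(path, "w") as handle:
        handle.write("contig\tpos\tref\tA\tC\tG\tT\tdepth\n")
        for col in columns:
            handle.write(
                "\t".join(
                    [
                        col.site.contig,
                        str(to_report_pos(col.site.pos)),
                        col.ref,
                        *(str(col.counts[b]) for b in BASES),
                        str(col.depth),
                    ]
                )
                + "\n"
            )
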