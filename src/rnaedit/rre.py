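"""FMRP RNA-recognition-element (RRE) motif scanning.

FMRP binds mRNA through two short degenerate elements, ACUK and WGGA
(IUPAC K = G/U, W = A/U).  This module scans nucleotide sequences for all
(overlapping) occurrences, optionally labels matches by genomic region,
and counts exact cross-species matches of flank-extended motif segments —
the homology criterion used to call conserved FMRP binding elements in a
target coding sequence.  DNA and RNA alphabets are unified on T
internally; reports may render U for RNA context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import AnnotationSet, revcomp

#: motif class -> allowed bases per position (on the T alphabet)
MOTIFS: dict[str, tuple[frozenset, ...]] = {
    "ACUK": tuple(map(frozenset, ("A", "C", "T", "GT"))),
    "WGGA": tuple(map(frozenset, ("AT", "G", "G", "A"))),
}

_U2T = str.maketrans("Uu", "Tt")


def _normalize(seq: str) -> str:
    return seq.upper().translate(_U2T)


@dataclass(frozen=True)
class RREMatch:
    sequence_id: str
    start: int  # 0-based
    motif: str  # ACUK or WGGA
    matched: str  # the 4-mer, T alphabet
    region: str = "other"  # CDS, 3'-UTR or other


def scan_rre(
    sequence: str,
    sequence_id: str = "seq",
    annotation: Optional[AnnotationSet] = None,
    contig: Optional[str] = None,
    motifs: Iterable[str] = ("ACUK", "WGGA"),
) -> list[RREMatch]:
    """All (overlapping) RRE motif matches, in ascending start order.

    T and U are treated identically.  With an annotation and contig name,
    each match is labeled CDS / 3'-UTR / other by its start position.
    Sequences shorter than 4 yield no matches.
    """
    seq = _normalize(sequence)
    matches: list[RREMatch] = []
    for start in range(len(seq) - 3):
        window = seq[start:start + 4]
        for name in motifs:
            pattern = MOTIFS[name]
            if all(base in allowed for base, allowed in zip(window, pattern)):
                if annotation is not None and contig is not None:
                    category = annotation.category_at(contig, start)
                    region = category if category in ("CDS", "3'-UTR") else "other"
                else:
                    region = "other"
                matches.append(
                    RREMatch(
                        sequence_id=sequence_id,
                        start=start,
                        motif=name,
                        matched=window,
                        region=region,
                    )
                )
    return matches


def extract_rre_segments(
    sequence: str, flank: int, motifs: Iterable[str] = ("ACUK", "WGGA")
) -> list[str]:
    """Unique flank-extended motif segments from one sequence.

    Each motif occurrence is extended by ``flank`` bases on both sides;
    occurrences too close to a sequence end for the full extension are
    dropped.  Duplicates collapse to one segment.
    """
    seq = _normalize(sequence)
    segments = []
    seen = set()
    for match in scan_rre(seq, motifs=motifs):
        lo = match.start - flank
        hi = match.start + 4 + flank
        if lo < 0 or hi > len(seq):
            continue
        segment = seq[lo:hi]
        if segment not in seen:
            seen.add(segment)
            segments.append(segment)
    return segments


def conserved_rre_matches(
    query_segments: Sequence[str],
    target: str,
    search_revcomp: bool = False,
) -> tuple[int, list[str]]:
    """Count query segments occurring verbatim in a target sequence.

    Each segment counts at most once regardless of how many times it
    occurs; returns ``(count, matched_segments)``.  Longer segments can
    only match less often, so counts are non-increasing in flank length.
    """
    tgt = _normalize(target)
    haystacks = [tgt, revcomp(tgt)] if search_revcomp else [tgt]
    matched = []
    for segment in dict.fromkeys(_normalize(s) for s in query_segments):
        if any(segment in hay for hay in haystacks):
            matched.append(segment)
    return len(matched), matched


def write_matches_tsv(matches: Sequence[RREMatch], path, rna: bool = False) -> None:
    """Match TSV; set ``rna`` to render the matched 4-mer with U."""
    with open(path, "w") as handle:
        handle.write("sequence_id\tstart\tmotif\tmatched\tregion\n")
        for m in matches:
            rendered = m.matched.replace("T", "U") if rna else m.matched
            handle.write(
                f"{m.sequence_id}\t{m.start + 1}\t{m.motif}\t{rendered}\t{m.region}\n"
            )
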