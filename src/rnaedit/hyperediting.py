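"""Hyperediting (HE) detection and descriptive analytics.

Candidate editing sites are DNA-RNA mismatches passing the edited-read and
editing-level floors; dense same-class runs of candidates form HE clusters.
Because a genomic SNP produces one isolated mismatch while Adar acts
processively on dsRNA, clustering separates editing from polymorphism even
without matched genomic DNA.  The analytics here profile the 12-class
mismatch spectrum, the +/-1 neighbor preference (Adar disfavors G at -1),
genomic-category fractions, and repeat-family enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .pileup import BASES, FilterThresholds, PileupColumn, editing_level
from .seqio import (
    AnnotationSet,
    GenomicSite,
    ReferenceGenome,
    complement,
    to_report_pos,
)

log = logging.getLogger(__name__)

#: the 12 ordered ref->alt substitutions, expressed on the transcript strand
MISMATCH_CLASSES = tuple(f"{a}>{b}" for a, b in permutations(BASES, 2))


@dataclass
class EditingSite:
    """A located DNA-RNA mismatch with counts and editing level."""

    site: GenomicSite
    mismatch: str  # e.g. "A>G", on the transcript strand
    n_ref: int
    n_alt: int
    level: float
    category: Optional[str] = None
    repeat_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mismatch not in MISMATCH_CLASSES:
            raise ValueError(f"invalid mismatch class {self.mismatch!r}")


@dataclass
class EditingCluster:
    """A maximal run of same-class sites with bounded inter-site gaps."""

    sites: list[EditingSite]

    @property
    def contig(self) -> str:
        return self.sites[0].site.contig

    @property
    def strand(self) -> str:
        return self.sites[0].site.strand

    @property
    def mismatch(self) -> str:
        return self.sites[0].mismatch

    @property
    def start(self) -> int:
        return self.sites[0].site.pos

    @property
    def end(self) -> int:
        """One past the last member position (half-open span)."""
        return self.sites[-1].site.pos + 1

    @property
    def size(self) -> int:
        return len(self.sites)


@dataclass
class NeighborProfile:
    """Base frequencies 1 bp upstream (-1) and downstream (+1) of sites."""

    upstream: dict[str, float]
    downstream: dict[str, float]
    n_sites: int
    n_skipped: int = 0


def call_candidate_sites(
    columns: Iterable[PileupColumn],
    thresholds: FilterThresholds | None = None,
    strand: str = "auto",
) -> list[EditingSite]:
    """Emit a site for every non-reference allele with enough edited reads.

    A site requires at least ``he_min_edited_reads`` (default 6, i.e. more
    than five) alternate reads and an editing level strictly above
    ``he_min_level``.  With ``strand`` '+' or '-', the mismatch class is
    re-oriented onto that transcript strand; 'auto' uses each column's own
    strand annotation.
    """
    thresholds = thresholds or FilterThresholds()
    if strand not in ("+", "-", "auto"):
        raise ValueError(f"strand must be +, - or auto, not {strand!r}")
    sites: list[EditingSite] = []
    for col in columns:
        if col.ref not in BASES:
            continue
        n_ref = col.counts[col.ref]
        for alt in BASES:
            if alt == col.ref:
                continue
            n_alt = col.counts[alt]
            if n_alt < thresholds.he_min_edited_reads:
                continue
            level = editing_level(n_ref, n_alt)
            if level <= thresholds.he_min_level:
                continue
            use_strand = col.site.strand if strand == "auto" else strand
            if use_strand == "-":
                mismatch = f"{complement(col.ref)}>{complement(alt)}"
            else:
                mismatch = f"{col.ref}>{alt}"
            sites.append(
                EditingSite(
                    site=GenomicSite(col.site.contig, col.site.pos, use_strand),
                    mismatch=mismatch,
                    n_ref=n_ref,
                    n_alt=n_alt,
                    level=level,
                )
            )
    return sites


def cluster_candidates(
    sites: Sequence[EditingSite],
    thresholds: FilterThresholds | None = None,
) -> list[EditingCluster]:
    """Group same-class sites into maximal runs with bounded gaps.

    Consecutive members must lie within ``cluster_window_bp`` of each
    other, and a run must contain at least ``cluster_min_sites`` members;
    sites in no qualifying run are dropped.
    """
    thresholds = thresholds or FilterThresholds()
    key = lambda s: (s.site.contig, s.site.strand, s.mismatch, s.site.pos)
    ordered = sorted(sites, key=key)
    clusters: list[EditingCluster] = []
    run: list[EditingSite] = []

    def flush() -> None:
        if len(run) >= thresholds.cluster_min_sites:
            clusters.append(EditingCluster(sites=list(run)))

    for site in ordered:
        if run and (
            site.site.contig != run[-1].site.contig
            or site.site.strand != run[-1].site.strand
            or site.mismatch != run[-1].mismatch
            or site.site.pos - run[-1].site.pos > thresholds.cluster_window_bp
        ):
            flush()
            run = []
        run.append(site)
    flush()
    return clusters


def mismatch_spectrum(sites: Sequence[EditingSite]) -> dict[str, float]:
    """Fraction of sites in each of the 12 substitution classes."""
    if not sites:
        raise ValueError("mismatch spectrum undefined for an empty site set")
    counts = {cls: 0 for cls in MISMATCH_CLASSES}
    for site in sites:
        counts[site.mismatch] += 1
    total = len(sites)
    return {cls: n / total for cls, n in counts.items()}


def neighbor_preference(
    sites: Sequence[EditingSite], reference: ReferenceGenome
) -> NeighborProfile:
    """Base frequencies at offsets -1/+1 on the transcript strand.

    For a minus-strand site the -1 neighbor is the reverse complement of
    the reference base one position to the right on the plus strand.
    Sites at contig ends are skipped (counted in ``n_skipped``).
    """
    up = {b: 0 for b in BASES}
    down = {b: 0 for b in BASES}
    used = skipped = 0
    for s in sites:
        contig, pos = s.site.contig, s.site.pos
        if pos == 0 or pos == reference.length(contig) - 1:
            skipped += 1
            continue
        left = reference.base(contig, pos - 1)
        right = reference.base(contig, pos + 1)
        if s.site.strand == "-":
            minus1, plus1 = complement(right), complement(left)
        else:
            minus1, plus1 = left, right
        if minus1 not in BASES or plus1 not in BASES:
            skipped += 1
            continue
        up[minus1] += 1
        down[plus1] += 1
        used += 1
    if skipped:
        log.info("neighbor_preference: skipped %d contig-end/N sites", skipped)
    if used == 0:
        raise ValueError("no sites with usable flanking context")
    return NeighborProfile(
        upstream={b: n / used for b, n in up.items()},
        downstream={b: n / used for b, n in down.items()},
        n_sites=used,
        n_skipped=skipped,
    )


def annotate_sites(
    sites: Sequence[EditingSite], annotation: AnnotationSet
) -> dict[str, float]:
    """Assign each site a genomic category (and repeat family) in place.

    Returns the category fractions, which sum to 1 over the assigned
    sites.  Overlapping features resolve by precedence
    CDS > 3'-UTR > 5'-UTR > intron > intergenic.
    """
    if not sites:
        raise ValueError("cannot annotate an empty site set")
    counts: dict[str, int] = {}
    for s in sites:
        s.category = annotation.category_at(s.site.contig, s.site.pos)
        s.repeat_family = annotation.repeat_family_at(s.site.contig, s.site.pos)
        counts[s.category] = counts.get(s.category, 0) + 1
    total = len(sites)
    return {cat: n / total for cat, n in sorted(counts.items())}


def repeat_enrichment(
    sites: Sequence[EditingSite], annotation: AnnotationSet
) -> pd.DataFrame:
    """Per-family fold enrichment of edited sites over genomic occupancy.

    ``genomic_fraction`` is the family's share of all repeat bases;
    ``edited_fraction`` is its share of repeat-resident sites; ``fold`` is
    their ratio (infinite when a family has edited sites but no bases).
    """
    base_totals = annotation.repeat_base_totals()
    if not base_totals:
        raise ValueError("repeat track is empty")
    total_bases = sum(base_totals.values())

    site_counts: dict[str, int] = {}
    for s in sites:
        family = s.repeat_family
        if family is None:
            family = annotation.repeat_family_at(s.site.contig, s.site.pos)
            s.repeat_family = family
        if family is not None:
            site_counts[family] = site_counts.get(family, 0) + 1
    total_sites = sum(site_counts.values())

    rows = []
    for family in sorted(set(base_totals) | set(site_counts)):
        genomic = base_totals.get(family, 0) / total_bases
        edited = (
            site_counts.get(family, 0) / total_sites if total_sites else 0.0
        )
        if genomic > 0:
            fold = edited / genomic
        else:
            fold = math.inf if edited > 0 else float("nan")
        rows.append(
            {
                "family": family,
                "genomic_fraction": genomic,
                "edited_fraction": edited,
                "fold": fold,
            }
        )
    return pd.DataFrame(rows)


def gene_he_enrichment(
    panel_genes: Iterable[str],
    he_genes: Iterable[str],
    genome_background_fraction: float,
) -> float:
    """Fold enrichment of HE-cluster genes in a target panel.

    ``(|panel & he| / |panel|) / background``.  With 7 of 12 panel genes
    HE-positive against a 2.9% genomic background this is ~20-fold.
    """
    panel = set(panel_genes)
    if not panel:
        raise ValueError("panel gene set is empty")
    if not 0 < genome_background_fraction <= 1:
        raise ValueError("background fraction must lie in (0,1]")
    observed = len(panel & set(he_genes)) / len(panel)
    return observed / genome_background_fraction


def write_site_table(sites: Sequence[EditingSite], path) -> None:
    """Site TSV: contig, 1-based pos, strand, class, counts, level, labels."""
    rows = [
        {
            "contig": s.site.contig,
            "pos": to_report_pos(s.site.pos),
            "strand": s.site.strand,
            "mismatch": s.mismatch,
            "n_ref": s.n_ref,
            "n_alt": s.n_alt,
            "level": s.level,
            "category": s.category or "",
            "repeat_family": s.repeat_family or "",
        }
        for s in sites
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "strand", "mismatch", "n_ref", "n_alt",
            "level", "category", "repeat_family",
        ],
    )
    df.sort_values(["contig", "pos", "strand", "mismatch"]).to_csv(
        path, sep="\t", index=False
    )


def write_cluster_bed(clusters: Sequence[EditingCluster], path) -> None:
    rows = [
        (c.contig, c.start, c.end, f"{c.mismatch}|n={c.size}|{c.strand}")
        for c in clusters
    ]
    from .seqio import write_bed

    write_bed(rows, path)
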