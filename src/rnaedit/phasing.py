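"""Read-backed phasing of adjacent editing sites into mRNA variants.

When several editing sites fall on one amplicon, each sequenced molecule
reports the joint allele tuple across all of them, so the relative
abundance of every edited/unedited transcript combination can be measured
directly rather than inferred from per-site marginals.  Tuples translate
to protein-variant labels through per-site codon maps (e.g. the
genomically encoded unedited form "LR", or the double-edited "AV").
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import stats
from .amplicon import Amplicon, SampleSheet, _AG_ON_PLUS, _stack_reads
from .pileup import FilterThresholds
from .seqio import AlignedRead, to_report_pos

log = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Per-sample counts of joint A/G tuples across clustered sites."""

    amplicon_id: str
    sites: tuple[int, ...]  # ordered genomic positions
    counts: dict[str, Counter] = field(default_factory=dict)  # sample -> tuple counts
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def arity(self) -> int:
        return len(self.sites)

    def total(self, sample: str) -> int:
        return sum(self.counts.get(sample, Counter()).values())

    def variants(self) -> list[tuple[str, ...]]:
        seen = set()
        for counter in self.counts.values():
            seen.update(counter)
        return sorted(seen)

    def abundances(self, sample: str) -> dict[tuple[str, ...], float]:
        """Relative abundance of each observed tuple; sums to 1."""
        counter = self.counts.get(sample, Counter())
        total = sum(counter.values())
        if total == 0:
            raise ValueError(f"no phased reads for sample {sample!r}")
        return {tup: n / total for tup, n in counter.items()}

    def marginal_level(self, sample: str, site_index: int) -> float:
        """G-fraction at one site computed from the tuple table."""
        counter = self.counts.get(sample, Counter())
        total = sum(counter.values())
        if total == 0:
            raise ValueError(f"no phased reads for sample {sample!r}")
        edited = sum(n for tup, n in counter.items() if tup[site_index] == "G")
        return edited / total


def extract_read_haplotypes(
    alignments_by_sample: dict[str, Sequence[AlignedRead]],
    amplicon: Amplicon,
    sites: Sequence[int],
    thresholds: FilterThresholds | None = None,
) -> HaplotypeTable:
    """Tally the joint transcript-strand A/G tuple per spanning read.

    A read contributes one tuple iff it spans every site with a base
    quality >= the floor and an A or G (transcript strand) at each one;
    reads failing any condition are excluded and counted.  All sites must
    lie on the given amplicon.
    """
    thresholds = thresholds or FilterThresholds()
    ordered = tuple(sorted(sites))
    if len(ordered) < 2:
        raise ValueError("phasing needs at least two sites")
    for pos in ordered:
        if not amplicon.start <= pos < amplicon.end:
            raise ValueError(
                f"site {pos} is not on amplicon {amplicon.amplicon_id}; "
                "clustered sites must share one amplicon"
            )
    a_plus, g_plus = _AG_ON_PLUS[amplicon.strand]
    cols = np.array([amplicon.column(p) for p in ordered])

    table = HaplotypeTable(amplicon_id=amplicon.amplicon_id, sites=ordered)
    for sample_id, reads in alignments_by_sample.items():
        spanning = [
            r
            for r in reads
            if r.contig == amplicon.contig
            and r.pos <= ordered[0]
            and r.end > ordered[-1]
            and r.mapq >= thresholds.min_mapq
        ]
        excluded = len(reads) - len(spanning)
        counter: Counter = Counter()
        if spanning:
            base, qual = _stack_reads(spanning, amplicon.start, amplicon.length)
            b = base[:, cols]
            q = qual[:, cols]
            is_a = b == ord(a_plus)
            is_g = b == ord(g_plus)
            ok = ((is_a | is_g) & (q >= thresholds.min_base_qual)).all(axis=1)
            excluded += int((~ok).sum())
            alleles = np.where(is_g, "G", "A")
            for row in np.flatnonzero(ok):
                counter[tuple(str(a) for a in alleles[row])] += 1
        table.counts[sample_id] = counter
        table.n_excluded[sample_id] = excluded
        if excluded:
            log.debug(
                "phasing %s sample %s: excluded %d reads",
                amplicon.amplicon_id, sample_id, excluded,
            )
    return table


def label_protein_variants(
    alleles: Sequence[str], codon_map: Sequence[tuple[str, int]]
) -> str:
    """Translate a joint allele tuple into an amino-acid label.

    ``codon_map`` gives, per site in tuple order, the coding-strand
    reference codon and the site's offset within it.  Each site's A or G
    is substituted at its offset and the codons are translated with the
    standard genetic code; labels concatenate in site order.
    """
    if len(alleles) != len(codon_map):
        raise ValueError("allele tuple and codon map lengths differ")
    label = []
    for allele, (codon, offset) in zip(alleles, codon_map):
        if not 0 <= offset <= 2 or len(codon) != 3:
            raise ValueError(f"invalid codon map entry ({codon!r}, {offset})")
        if codon[offset] != "A":
            raise ValueError(
                f"codon {codon!r} has {codon[offset]!r} at offset {offset}; "
                "an editable site must be an A on the coding strand"
            )
        if allele not in "AG":
            raise ValueError(f"allele must be A or G, got {allele!r}")
        edited = codon[:offset] + allele + codon[offset + 1:]
        label.append(str(Seq(edited).translate()))
    return "".join(label)


def differential_variant_abundance(
    table: HaplotypeTable,
    sheet: SampleSheet,
    codon_map: Optional[Sequence[tuple[str, int]]] = None,
) -> pd.DataFrame:
    """Welch-test per-variant relative abundances between genotypes.

    A variant absent from a sample counts as abundance 0 (not skipped);
    samples with no phased reads at all are dropped with a log message.
    """
    genotypes = sheet.genotypes("RNA")
    if len(genotypes) != 2:
        raise ValueError("variant comparison needs exactly 2 genotypes")
    g1, g2 = genotypes
    genotype_of = {s.sample_id: s.genotype for s in sheet.subset("RNA")}

    per_sample: dict[str, dict[tuple[str, ...], float]] = {}
    for sample_id in table.counts:
        if genotype_of.get(sample_id) is None:
            continue
        if table.total(sample_id) == 0:
            log.info("dropping sample %s with no phased reads", sample_id)
            continue
        per_sample[sample_id] = table.abundances(sample_id)

    rows = []
    for variant in table.variants():
        values = {g1: [], g2: []}
        for sample_id, abundances in per_sample.items():
            values[genotype_of[sample_id]].append(abundances.get(variant, 0.0))
        if len(values[g1]) < 2 or len(values[g2]) < 2:
            continue
        res = stats.welch_t_test(values[g1], values[g2])
        s1 = stats.GroupSummary.from_values(values[g1], g1)
        s2 = stats.GroupSummary.from_values(values[g2], g2)
        rows.append(
            {
                "variant": "".join(variant),
                "label": (
                    label_protein_variants(variant, codon_map)
                    if codon_map is not None
                    else ""
                ),
                f"mean_{g1}": s1.mean,
                f"sem_{g1}": s1.sem,
                f"mean_{g2}": s2.mean,
                f"sem_{g2}": s2.sem,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def write_haplotype_tsv(
    table: HaplotypeTable,
    path,
    codon_map: Optional[Sequence[tuple[str, int]]] = None,
) -> None:
    rows = []
    for sample_id in sorted(table.counts):
        total = table.total(sample_id)
        for variant in table.variants():
            count = table.counts[sample_id].get(variant, 0)
            rows.append(
                {
                    "amplicon_id": table.amplicon_id,
                    "sites": ",".join(
                        str(to_report_pos(p)) for p in table.sites
                    ),
                    "sample": sample_id,
                    "variant": "".join(variant),
                    "label": (
                        label_protein_variants(variant, codon_map)
                        if codon_map is not None
                        else ""
                    ),
                    "count": count,
                    "abundance": count / total if total else math.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
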