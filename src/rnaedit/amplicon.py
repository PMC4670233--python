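"""Targeted-amplicon (mmPCR-style) editing quantification.

The pipeline: exact-match barcode demultiplexing, gapless best-offset
alignment of reads to a small amplicon panel, per-sample/per-site A-vs-G
counting at quality >= 20, off-target site discovery, genomic-SNP masking
against matched gDNA, the three-criterion retention cascade (sample
incidence >= 75%, depth >= 400, mean level >= 2%), and Welch-test
differential editing between genotype groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .pileup import FilterThresholds, UndefinedLevelError, editing_level
from .seqio import AlignedRead, ReferenceGenome, revcomp, to_report_pos

log = logging.getLogger(__name__)

# transcript-strand A/G expressed on the reference plus strand
_AG_ON_PLUS = {"+": ("A", "G"), "-": ("T", "C")}


@dataclass
class Amplicon:
    """One PCR target region with primer spans and targeted site positions.

    ``codons`` optionally maps a targeted genomic position to its
    (coding-strand codon, offset-of-site-within-codon) pair for protein
    recoding labels.
    """

    amplicon_id: str
    gene: str
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    sequence: str  # plus-strand genomic slice
    fwd_primer: tuple[int, int]  # genomic half-open span at the 5' end
    rev_primer: tuple[int, int]
    target_sites: tuple[int, ...]  # genomic 0-based positions
    codons: Optional[dict[int, tuple[str, int]]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"amplicon {self.amplicon_id}: sequence length "
                f"{len(self.sequence)} != interval span {self.end - self.start}"
            )
        for pos in self.target_sites:
            if not self.start <= pos < self.end:
                raise ValueError(
                    f"amplicon {self.amplicon_id}: target site {pos} outside "
                    f"[{self.start},{self.end})"
                )
            for span in (self.fwd_primer, self.rev_primer):
                if span[0] <= pos < span[1]:
                    raise ValueError(
                        f"amplicon {self.amplicon_id}: target site {pos} "
                        f"inside primer span {span}"
                    )

    @property
    def length(self) -> int:
        return self.end - self.start

    def column(self, pos: int) -> int:
        return pos - self.start

    def insert_interval(self) -> tuple[int, int]:
        """Genomic interval between the primers."""
        return self.fwd_primer[1], self.rev_primer[0]


@dataclass
class AmpliconPanel:
    amplicons: list[Amplicon]

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate amplicon ids in panel")
        self._by_id = {a.amplicon_id: a for a in self.amplicons}

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    def validate_against(self, genome: ReferenceGenome) -> None:
        for amp in self.amplicons:
            if genome.fetch(amp.contig, amp.start, amp.end) != amp.sequence:
                raise ValueError(
                    f"amplicon {amp.amplicon_id}: sequence does not match "
                    f"the reference slice"
                )

    def amplicon_at(self, contig: str, pos: int) -> Optional[Amplicon]:
        for amp in self.amplicons:
            if amp.contig == contig and amp.start <= pos < amp.end:
                return amp
        return None


def _serialize_codons(codons: Optional[dict[int, tuple[str, int]]]) -> str:
    if not codons:
        return ""
    return ";".join(
        f"{pos}:{codon}:{offset}" for pos, (codon, offset) in sorted(codons.items())
    )


def _parse_codons(text: str) -> Optional[dict[int, tuple[str, int]]]:
    if not text:
        return None
    out: dict[int, tuple[str, int]] = {}
    for item in text.split(";"):
        pos, codon, offset = item.split(":")
        out[int(pos)] = (codon, int(offset))
    return out


def write_panel_tsv(panel: AmpliconPanel, path) -> None:
    rows = [
        {
            "amplicon_id": a.amplicon_id,
            "gene": a.gene,
            "contig": a.contig,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "fwd_primer_start": a.fwd_primer[0],
            "fwd_primer_end": a.fwd_primer[1],
            "rev_primer_start": a.rev_primer[0],
            "rev_primer_end": a.rev_primer[1],
            "target_sites": ",".join(map(str, a.target_sites)),
            "codons": _serialize_codons(a.codons),
            "sequence": a.sequence,
        }
        for a in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_panel_tsv(path, genome: Optional[ReferenceGenome] = None) -> AmpliconPanel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    amplicons = []
    for _, row in df.iterrows():
        sites = tuple(
            int(x) for x in str(row["target_sites"]).split(",") if x != ""
        )
        amplicons.append(
            Amplicon(
                amplicon_id=row["amplicon_id"],
                gene=row["gene"],
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                sequence=row["sequence"],
                fwd_primer=(int(row["fwd_primer_start"]), int(row["fwd_primer_end"])),
                rev_primer=(int(row["rev_primer_start"]), int(row["rev_primer_end"])),
                target_sites=sites,
                codons=_parse_codons(row.get("codons", "")),
            )
        )
    panel = AmpliconPanel(amplicons)
    if genome is not None:
        panel.validate_against(genome)
    return panel


@dataclass(frozen=True)
class Sample:
    sample_id: str
    barcode: str
    genotype: str
    material: str  # RNA or gDNA

    def __post_init__(self) -> None:
        if self.material not in ("RNA", "gDNA"):
            raise ValueError(f"material must be RNA or gDNA, got {self.material!r}")


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in sample sheet")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        if "unassigned" in ids:
            raise ValueError("'unassigned' is a reserved sample id")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    def subset(self, material: str) -> list[Sample]:
        return [s for s in self.samples if s.material == material]

    def genotypes(self, material: str = "RNA") -> list[str]:
        seen: list[str] = []
        for s in self.subset(material):
            if s.genotype not in seen:
                seen.append(s.genotype)
        return seen

    def genotype_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].genotype


def write_sheet_tsv(sheet: SampleSheet, path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "barcode": s.barcode,
                "genotype": s.genotype,
                "material": s.material,
            }
            for s in sheet
        ]
    ).to_csv(path, sep="\t", index=False)


def load_sheet_tsv(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(
        [
            Sample(
                sample_id=row["sample_id"],
                barcode=row["barcode"],
                genotype=row["genotype"],
                material=row["material"],
            )
            for _, row in df.iterrows()
        ]
    )


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    barcode_length: Optional[int] = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Assign reads to samples by exact 5' barcode match, trimming it.

    Returns a mapping sample-id -> reads plus an ``"unassigned"`` bin;
    every input read lands in exactly one bin.  No mismatch tolerance:
    exactness keeps the bins reproducible.
    """
    lengths = {len(s.barcode) for s in sheet}
    if barcode_length is None:
        if len(lengths) != 1:
            raise ValueError("mixed barcode lengths; pass barcode_length")
        barcode_length = lengths.pop()
    lookup = {s.barcode: s.sample_id for s in sheet}
    bins: dict[str, list[tuple[str, str, str]]] = {
        s.sample_id: [] for s in sheet
    }
    bins["unassigned"] = []
    for rid, seq, qual in reads:
        sample = lookup.get(seq[:barcode_length])
        if sample is None:
            bins["unassigned"].append((rid, seq, qual))
        else:
            bins[sample].append(
                (rid, seq[barcode_length:], qual[barcode_length:])
            )
    return bins


def _seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_amplicon_reads(
    reads: Sequence[tuple[str, str, str]],
    panel: AmpliconPanel,
    max_mismatch_frac: float = 0.1,
    sample_id: Optional[str] = None,
    mapq: int = 60,
) -> list[AlignedRead]:
    """Gapless best-offset assignment of reads to panel amplicons.

    Each read is compared, in both orientations and at every in-bounds
    offset, against every amplicon; the placement minimizing the mismatch
    count wins.  Reads whose best mismatch count exceeds
    ``max_mismatch_frac`` of their length, or whose best count is tied
    between two amplicons, are dropped (counts logged).  Output reads
    carry plus-strand sequences and a synthesized MAPQ.
    """
    if len(panel) == 0:
        raise ValueError("empty amplicon panel")

    amp_arrays = [
        (amp, _seq_to_bytes(amp.sequence), _seq_to_bytes(revcomp(amp.sequence)))
        for amp in panel
    ]

    # group reads by length so mismatch counting vectorizes over reads
    by_length: dict[int, list[int]] = {}
    for i, (_, seq, _) in enumerate(reads):
        by_length.setdefault(len(seq), []).append(i)

    aligned: list[AlignedRead] = []
    n_dropped_ceiling = n_dropped_tie = 0

    for length, indices in by_length.items():
        if length == 0:
            n_dropped_ceiling += len(indices)
            continue
        block = np.empty((len(indices), length), dtype=np.uint8)
        for row, i in enumerate(indices):
            block[row] = _seq_to_bytes(reads[i][1])

        # candidate placements: (amplicon index, orientation, offset)
        placements: list[tuple[int, str, int]] = []
        mm_cols: list[np.ndarray] = []
        for ai, (amp, fwd, rev) in enumerate(amp_arrays):
            if amp.length < length:
                continue
            for orient, arr in (("+", fwd), ("-", rev)):
                windows = np.lib.stride_tricks.sliding_window_view(arr, length)
                for offset in range(windows.shape[0]):
                    placements.append((ai, orient, offset))
                    mm_cols.append(
                        (block != windows[offset]).sum(axis=1)
                    )
        if not placements:
            n_dropped_ceiling += len(indices)
            continue
        mm = np.stack(mm_cols, axis=1)  # reads x placements
        amp_of = np.array([p[0] for p in placements])
        ceiling = max_mismatch_frac * length

        best_placement = mm.argmin(axis=1)
        best_mm = mm[np.arange(mm.shape[0]), best_placement]

        for row, i in enumerate(indices):
            if best_mm[row] > ceiling:
                n_dropped_ceiling += 1
                continue
            winners = np.flatnonzero(mm[row] == best_mm[row])
            if len(set(amp_of[w] for w in winners)) > 1:
                n_dropped_tie += 1
                continue
            ai, orient, offset = placements[winners[0]]
            amp = amp_arrays[ai][0]
            rid, seq, qual = reads[i]
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            if orient == "-":
                # store on the plus strand, SAM style: revcomp the read
                # (an offset on revcomp(amp) maps to the amplicon 3' end)
                seq = revcomp(seq)
                quals = quals[::-1]
                pos = amp.start + amp.length - length - offset
                strand = "-"
            else:
                pos = amp.start + offset
                strand = "+"
            aligned.append(
                AlignedRead(
                    read_id=rid,
                    contig=amp.contig,
                    pos=pos,
                    strand=strand,
                    sequence=seq,
                    qualities=quals,
                    mapq=mapq,
                    cigar=(("M", length),),
                    sample_id=sample_id,
                )
            )
    if n_dropped_ceiling or n_dropped_tie:
        log.info(
            "align_amplicon_reads: dropped %d reads over the mismatch "
            "ceiling and %d ambiguous reads",
            n_dropped_ceiling,
            n_dropped_tie,
        )
    return aligned


TABLE_COLUMNS = [
    "sample", "amplicon_id", "gene", "contig", "pos", "strand",
    "targeted", "n_A", "n_G", "depth", "level",
]


@dataclass
class SiteEditingTable:
    """samples x sites editing levels; one row per (sample, site).

    ``depth`` is n_A + n_G at the site (quality-passing, transcript
    strand); ``level`` is n_G / depth, NaN where depth is 0.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"site table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return sorted(
            {(r.contig, r.pos) for r in self.df.itertuples(index=False)}
        )

    def concat(self, other: "SiteEditingTable") -> "SiteEditingTable":
        return SiteEditingTable(
            pd.concat([self.df, other.df], ignore_index=True)
        )

    def restrict(self, sites: Iterable[tuple[str, int]]) -> "SiteEditingTable":
        keep = set(sites)
        mask = [
            (r.contig, r.pos) in keep for r in self.df.itertuples(index=False)
        ]
        return SiteEditingTable(self.df[mask].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["pos"] = out["pos"].map(to_report_pos)
        out.sort_values(["contig", "pos", "sample"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def _stack_reads(
    reads: Sequence[AlignedRead], start: int, span: int
) -> tuple[np.ndarray, np.ndarray]:
    """Place reads into (N x span) base/quality matrices on region coords.

    Positions not covered by a read hold base 0.  Gapless reads place via
    slicing; reads with indels walk their CIGAR.
    """
    base = np.zeros((len(reads), span), dtype=np.uint8)
    qual = np.zeros((len(reads), span), dtype=np.uint8)
    for row, read in enumerate(reads):
        if read.is_gapless():
            lo = read.pos - start
            hi = lo + len(read.sequence)
            src_lo = max(0, -lo)
            src_hi = len(read.sequence) - max(0, hi - span)
            if src_lo >= src_hi:
                continue
            dst_lo, dst_hi = lo + src_lo, lo + src_hi
            base[row, dst_lo:dst_hi] = _seq_to_bytes(read.sequence)[src_lo:src_hi]
            qual[row, dst_lo:dst_hi] = read.qualities[src_lo:src_hi]
        else:
            ref_pos, read_pos = read.pos, 0
            for op, length in read.cigar:
                if op in "M=X":
                    for k in range(length):
                        col = ref_pos + k - start
                        if 0 <= col < span:
                            base[row, col] = ord(read.sequence[read_pos + k])
                            qual[row, col] = read.qualities[read_pos + k]
                    ref_pos += length
                    read_pos += length
                elif op in "IS":
                    read_pos += length
                elif op == "D":
                    ref_pos += length
    return base, qual


def _count_ag(
    base: np.ndarray, qual: np.ndarray, col: int, strand: str, min_qual: int
) -> tuple[int, int]:
    """Quality-passing transcript-strand A and G counts at one column."""
    a_plus, g_plus = _AG_ON_PLUS[strand]
    ok = qual[:, col] >= min_qual
    b = base[:, col]
    n_a = int(((b == ord(a_plus)) & ok).sum())
    n_g = int(((b == ord(g_plus)) & ok).sum())
    return n_a, n_g


def quantify_sites(
    alignments_by_sample: dict[str, Sequence[AlignedRead]],
    panel: AmpliconPanel,
    thresholds: FilterThresholds | None = None,
    positions: Optional[dict[str, Sequence[int]]] = None,
    targeted: bool = True,
) -> SiteEditingTable:
    """Count A/G on the transcript strand at each targeted site per sample.

    A site outside the covered region yields a row with depth 0.  Pass
    ``positions`` (amplicon-id -> genomic positions) to quantify a custom
    position set, e.g. discovered off-target sites.
    """
    thresholds = thresholds or FilterThresholds()
    rows = []
    for sample_id, reads in alignments_by_sample.items():
        for amp in panel:
            sites = (
                positions.get(amp.amplicon_id, ())
                if positions is not None
                else amp.target_sites
            )
            if not sites:
                continue
            amp_reads = [
                r
                for r in reads
                if r.contig == amp.contig
                and r.pos < amp.end
                and r.end > amp.start
                and r.mapq >= thresholds.min_mapq
            ]
            if amp_reads:
                base, qual = _stack_reads(amp_reads, amp.start, amp.length)
            for pos in sites:
                if amp_reads:
                    n_a, n_g = _count_ag(
                        base, qual, amp.column(pos), amp.strand,
                        thresholds.min_base_qual,
                    )
                else:
                    n_a = n_g = 0
                depth = n_a + n_g
                rows.append(
                    {
                        "sample": sample_id,
                        "amplicon_id": amp.amplicon_id,
                        "gene": amp.gene,
                        "contig": amp.contig,
                        "pos": pos,
                        "strand": amp.strand,
                        "targeted": targeted,
                        "n_A": n_a,
                        "n_G": n_g,
                        "depth": depth,
                        "level": (n_g / depth) if depth else math.nan,
                    }
                )
    return SiteEditingTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


def discover_offtarget_sites(
    alignments_by_sample: dict[str, Sequence[AlignedRead]],
    panel: AmpliconPanel,
    thresholds: FilterThresholds | None = None,
) -> SiteEditingTable:
    """Find untargeted A>G positions supported by enough mismatch reads.

    Every transcript-strand A position inside an amplicon insert (between
    the primers), not in the targeted list, with at least
    ``min_mismatch_reads`` quality-passing G reads in some sample is
    quantified across all samples and flagged off-target.
    """
    thresholds = thresholds or FilterThresholds()
    discovered: dict[str, set[int]] = {}
    for amp in panel:
        a_plus, _ = _AG_ON_PLUS[amp.strand]
        ins_lo, ins_hi = amp.insert_interval()
        candidate_cols = [
            amp.column(pos)
            for pos in range(ins_lo, ins_hi)
            if amp.sequence[amp.column(pos)] == a_plus
            and pos not in amp.target_sites
        ]
        if not candidate_cols:
            continue
        for sample_id, reads in alignments_by_sample.items():
            amp_reads = [
                r
                for r in reads
                if r.contig == amp.contig
                and r.pos < amp.end
                and r.end > amp.start
                and r.mapq >= thresholds.min_mapq
            ]
            if not amp_reads:
                continue
            base, qual = _stack_reads(amp_reads, amp.start, amp.length)
            for col in candidate_cols:
                _, n_g = _count_ag(
                    base, qual, col, amp.strand, thresholds.min_base_qual
                )
                if n_g >= thresholds.min_mismatch_reads:
                    discovered.setdefault(amp.amplicon_id, set()).add(
                        amp.start + col
                    )
    positions = {aid: sorted(cols) for aid, cols in discovered.items()}
    if not positions:
        return SiteEditingTable(pd.DataFrame(columns=TABLE_COLUMNS))
    return quantify_sites(
        alignments_by_sample, panel, thresholds,
        positions=positions, targeted=False,
    )


def mask_genomic_variants(
    rna_table: SiteEditingTable,
    gdna_table: SiteEditingTable,
    known_snps: Optional[Iterable[tuple[str, int]]] = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[SiteEditingTable, pd.DataFrame]:
    """Drop sites that look edited in matched genomic DNA.

    A site is excluded when its pooled gDNA G-fraction exceeds
    ``snp_max_gdna_alt``, when it appears in ``known_snps``, or when no
    gDNA evidence exists at all (conservative).  Returns the filtered
    table and an exclusion log.
    """
    thresholds = thresholds or FilterThresholds()
    known = set(known_snps or ())
    pooled = (
        gdna_table.df.groupby(["contig", "pos"])[["n_A", "n_G"]]
        .sum()
        .to_dict("index")
    )
    exclusions = []
    keep = []
    for contig, pos in rna_table.sites:
        if (contig, pos) in known:
            exclusions.append(
                {"contig": contig, "pos": pos, "reason": "known SNP",
                 "gdna_alt_frac": math.nan}
            )
            continue
        counts = pooled.get((contig, pos))
        depth = (counts["n_A"] + counts["n_G"]) if counts else 0
        if depth == 0:
            exclusions.append(
                {"contig": contig, "pos": pos, "reason": "no gDNA evidence",
                 "gdna_alt_frac": math.nan}
            )
            continue
        frac = counts["n_G"] / depth
        if frac > thresholds.snp_max_gdna_alt:
            exclusions.append(
                {"contig": contig, "pos": pos,
                 "reason": "gDNA alternate allele", "gdna_alt_frac": frac}
            )
            continue
        keep.append((contig, pos))
    exclusion_log = pd.DataFrame(
        exclusions, columns=["contig", "pos", "reason", "gdna_alt_frac"]
    )
    return rna_table.restrict(keep), exclusion_log


def apply_selection_criteria(
    table: SiteEditingTable,
    sheet: SampleSheet,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """The three-criterion retention cascade, per genotype.

    A sample-site cell is "captured" iff its depth meets
    ``amp_min_coverage`` (criterion ii).  A site passes for a genotype iff
    captured in at least ``amp_min_incidence`` of that genotype's samples
    (criterion i) and the genotype's mean level over captured samples
    meets ``amp_min_level`` (criterion iii).  A site is retained overall
    when it passes in every genotype.  The audit attributes each per-
    genotype failure to the first failing criterion: coverage when no
    sample is captured, incidence when too few are, level otherwise.
    """
    thresholds = thresholds or FilterThresholds()
    genotypes = sheet.genotypes("RNA")
    samples_by_genotype = {
        g: [s.sample_id for s in sheet.subset("RNA") if s.genotype == g]
        for g in genotypes
    }
    df = table.df.set_index(["contig", "pos", "sample"])

    audit_rows = []
    retained: list[tuple[str, int]] = []
    for contig, pos in table.sites:
        passes_all = True
        for genotype in genotypes:
            sample_ids = samples_by_genotype[genotype]
            depths, levels = [], []
            for sid in sample_ids:
                try:
                    row = df.loc[(contig, pos, sid)]
                except KeyError:
                    depths.append(0)
                    continue
                depths.append(int(row["depth"]))
                levels.append((int(row["depth"]), float(row["level"])))
            captured = [d for d in depths if d >= thresholds.amp_min_coverage]
            incidence = len(captured) / len(sample_ids) if sample_ids else 0.0
            captured_levels = [
                lv for d, lv in levels
                if d >= thresholds.amp_min_coverage and not math.isnan(lv)
            ]
            mean_level = (
                float(np.mean(captured_levels)) if captured_levels else math.nan
            )
            if not captured:
                status = "fail_coverage"
            elif incidence < thresholds.amp_min_incidence:
                status = "fail_incidence"
            elif mean_level < thresholds.amp_min_level:
                status = "fail_level"
            else:
                status = "pass"
            audit_rows.append(
                {
                    "contig": contig,
                    "pos": pos,
                    "genotype": genotype,
                    "incidence": incidence,
                    "mean_level": mean_level,
                    "status": status,
                }
            )
            if status != "pass":
                passes_all = False
        if passes_all:
            retained.append((contig, pos))
    audit = pd.DataFrame(
        audit_rows,
        columns=["contig", "pos", "genotype", "incidence", "mean_level", "status"],
    )
    return retained, audit


def differential_editing(
    table: SiteEditingTable,
    sheet: SampleSheet,
    sites: Optional[Iterable[tuple[str, int]]] = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Welch-test editing levels between two genotype groups per site.

    Uses each sample's level where depth > 0; a site is skipped (with a
    log message) when either genotype has fewer than two defined values.
    Raw two-sided p-values are reported; a Benjamini-Hochberg column is
    added only when ``fdr`` is set.
    """
    genotypes = sheet.genotypes("RNA")
    if len(genotypes) != 2:
        raise ValueError(
            f"differential editing needs exactly 2 genotypes, got {genotypes}"
        )
    g1, g2 = genotypes
    genotype_of = {s.sample_id: s.genotype for s in sheet.subset("RNA")}
    df = table.df[table.df["depth"] > 0]
    target_sites = list(sites) if sites is not None else table.sites

    rows = []
    for contig, pos in target_sites:
        sub = df[(df["contig"] == contig) & (df["pos"] == pos)]
        values = {g1: [], g2: []}
        meta = None
        for r in sub.itertuples(index=False):
            genotype = genotype_of.get(r.sample)
            if genotype in values:
                values[genotype].append(r.level)
            meta = r
        if len(values[g1]) < 2 or len(values[g2]) < 2:
            log.info(
                "differential_editing: skipping %s:%d with <2 defined "
                "levels in a genotype", contig, to_report_pos(pos),
            )
            continue
        res = stats.welch_t_test(values[g1], values[g2])
        s1 = stats.GroupSummary.from_values(values[g1], g1)
        s2 = stats.GroupSummary.from_values(values[g2], g2)
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "gene": meta.gene if meta else "",
                "targeted": bool(meta.targeted) if meta else True,
                f"mean_{g1}": s1.mean,
                f"sem_{g1}": s1.sem,
                f"n_{g1}": s1.n,
                f"mean_{g2}": s2.mean,
                f"sem_{g2}": s2.sem,
                f"n_{g2}": s2.n,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["q_bh"] = stats.benjamini_hochberg(out["p"].to_numpy())
    return out


def depth_correlation(
    table: SiteEditingTable, sheet: SampleSheet
) -> tuple[float, float]:
    """Pearson r across amplicons of per-genotype mean site depths.

    A high r indicates that capture efficiency, not genotype, drives
    coverage differences between groups.
    """
    genotypes = sheet.genotypes("RNA")
    if len(genotypes) != 2:
        raise ValueError("depth correlation needs exactly 2 genotypes")
    genotype_of = {s.sample_id: s.genotype for s in sheet.subset("RNA")}
    df = table.df.copy()
    df["genotype"] = df["sample"].map(genotype_of)
    df = df.dropna(subset=["genotype"])
    means = (
        df.groupby(["amplicon_id", "genotype"])["depth"].mean().unstack()
    )
    if means.shape[0] < 2:
        raise ValueError("depth correlation needs at least 2 amplicons")
    return stats.pearson_r(
        means[genotypes[0]].to_numpy(), means[genotypes[1]].to_numpy()
    )
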