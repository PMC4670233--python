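"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes:
per-site binomial editing at planted levels, joint haplotype distributions
over clustered sites (marginals equal per-site levels by construction),
genotype-dependent editing shifts, heterozygous/homozygous gDNA SNPs that
masquerade as editing in RNA, Phred-scored uniform substitution error, and
hyperediting clusters planted inside inverted-repeat elements of labeled
repeat families.  Everything is deterministic under a fixed master seed;
per-stage generators draw from seeds spawned off it.

Default study conditions mirror the targeted-resequencing design being
modeled: two genotypes, 10 RNA samples each, ~2,000x amplicon coverage,
76 bp transcriptome reads, and editing levels in the 5-45% range with
small (a few percent) genotype shifts at a subset of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .amplicon import Amplicon, AmpliconPanel, Sample, SampleSheet
from .pileup import BASES, PileupColumn
from .hyperediting import MISMATCH_CLASSES
from .seqio import (
    AlignedRead,
    AnnotationSet,
    GenomicSite,
    ReferenceGenome,
    revcomp,
)
from intervaltree import IntervalTree

_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BYTE_TO_INDEX[ord(_b)] = _i
_INDEX_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    # reference + transcriptome
    contig_length: int = 50_000
    read_length: int = 76
    transcriptome_depth: int = 30
    he_cluster_count: int = 8
    he_cluster_size: int = 5
    he_cluster_span: int = 80
    he_level: float = 0.30
    ag_fraction: float = 1.0  # planted clusters that are A>G vs another class
    error_rate: float = 1e-3
    base_quality: int = 30
    # repeat layout: (family, element count, element length); one family
    # additionally carries an exact inverted-repeat pair (dsRNA substrate)
    repeat_layout: tuple[tuple[str, int, int], ...] = (
        ("hAT-ANGEL", 6, 400),
        ("hAT-TDR19", 4, 300),
        ("DNA-TcMar", 10, 500),
        ("LTR-Gypsy", 8, 350),
    )
    inverted_family: str = "hAT-ANGEL"
    inverted_arm: int = 400
    inverted_spacer: int = 200
    # amplicon study
    amplicon_count: int = 12
    amplicon_length: int = 120
    primer_length: int = 20
    barcode_length: int = 8
    samples_per_genotype: int = 10
    gdna_samples_per_genotype: int = 3
    amplicon_depth: int = 2000
    gdna_depth: int = 800
    genotype_labels: tuple[str, str] = ("WT", "MUT")
    effect_size: float = 0.04
    n_shifted_sites: int = 4
    amplicon_error_rate: float = 1e-3
    snp_on_target: bool = True  # plant one het SNP at a targeted position
    # two-site amplicon parameterization: unedited-tuple abundance per
    # genotype on the first, double-edited abundance on the second
    unedited_abundance: tuple[float, float] = (0.432, 0.406)
    double_edited_abundance: tuple[float, float] = (0.098, 0.113)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contig_length <= 0 or self.amplicon_count <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0 <= self.he_level <= 1 or not 0 <= self.ag_fraction <= 1:
            raise ValueError("levels must lie in [0,1]")
        if self.effect_size + 0.45 > 1:
            raise ValueError("effect size pushes editing levels above 1")


@dataclass
class SyntheticTruth:
    """Every planted quantity; the oracle for recovery tests."""

    seed: int
    error_rate: float = 0.0
    # transcriptome truth
    he_sites: list[tuple[str, int, str, str, float]] = field(default_factory=list)
    clusters: list[list[int]] = field(default_factory=list)  # indices into he_sites
    repeat_elements: list[tuple[str, int, int, str]] = field(default_factory=list)
    inverted_pair: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    # amplicon truth
    site_levels: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    haplotype_probs: dict[tuple[str, str], dict[tuple[str, ...], float]] = field(
        default_factory=dict
    )
    snps: dict[tuple[str, int], dict] = field(default_factory=dict)
    shifted_sites: list[tuple[str, int]] = field(default_factory=list)
    read_depth: dict[str, int] = field(default_factory=dict)

    def site_index(self) -> dict[tuple[str, int], tuple[str, float]]:
        return {
            (contig, pos): (mismatch, level)
            for contig, pos, _, mismatch, level in self.he_sites
        }


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _INDEX_TO_BYTE[rng.integers(0, 4, size=length)]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReferenceGenome, AnnotationSet, SyntheticTruth]:
    """Random contig with repeat/feature tracks and planted HE clusters.

    Repeat elements are placed without overlap; the configured inverted
    family carries one exact inverted-repeat pair (arm2 is the reverse
    complement of arm1).  Each HE cluster lives inside one repeat element
    (inverted arms are used first), with same-class sites whose reference
    base is forced to match the class.  Gene features (5'-UTR, CDS,
    intron, 3'-UTR) tile the contig independently of repeats.
    """
    rng = _rng(config.seed if rng is None else rng)
    contig = "chrS"
    n = config.contig_length
    seq = _random_seq(rng, n)
    truth = SyntheticTruth(seed=config.seed, error_rate=config.error_rate)

    # --- repeats, non-overlapping by rejection sampling ------------------
    occupied = IntervalTree()
    placements: list[tuple[int, int, str]] = []

    def place(length: int) -> int:
        for _ in range(10_000):
            start = int(rng.integers(0, n - length))
            if not occupied.overlap(start, start + length):
                occupied.addi(start, start + length)
                return start
        raise RuntimeError("could not place repeat element; contig too full")

    arm = config.inverted_arm
    if 2 * arm + config.inverted_spacer > n:
        raise ValueError("inverted-repeat arms longer than the contig")
    # the inverted pair: arm1 + spacer + revcomp(arm1), placed as one block
    block = 2 * arm + config.inverted_spacer
    b0 = place(block)
    arm1 = seq[b0:b0 + arm].copy()
    seq[b0 + arm + config.inverted_spacer:b0 + block] = np.frombuffer(
        revcomp(bytes(arm1).decode()).encode(), dtype=np.uint8
    )
    inverted_spans = [(b0, b0 + arm), (b0 + arm + config.inverted_spacer, b0 + block)]
    for span in inverted_spans:
        placements.append((*span, config.inverted_family))
    truth.inverted_pair = (inverted_spans[0], inverted_spans[1])

    for family, count, length in config.repeat_layout:
        n_needed = count - (2 if family == config.inverted_family else 0)
        for _ in range(max(0, n_needed)):
            start = place(length)
            placements.append((start, start + length, family))

    # --- gene features tiling the contig ---------------------------------
    features: list[tuple[int, int, str]] = []
    cursor, stride = 0, 2_200
    while cursor + 1_700 < n:
        features.append((cursor, cursor + 200, "5'-UTR"))
        features.append((cursor + 200, cursor + 600, "CDS"))
        features.append((cursor + 600, cursor + 900, "intron"))
        features.append((cursor + 900, cursor + 1_300, "CDS"))
        features.append((cursor + 1_300, cursor + 1_700, "3'-UTR"))
        cursor += stride

    # --- planted HE clusters inside repeat elements -----------------------
    # the second inverted arm never hosts sites directly: it receives the
    # mirrored complement of arm-1 bases, keeping the palindrome exact
    hosts = sorted(
        (p for p in placements if (p[0], p[1]) != inverted_spans[1]),
        key=lambda p: (p[2] != config.inverted_family, p[0]),
    )
    other_classes = [c for c in MISMATCH_CLASSES if c != "A>G"]
    for k in range(config.he_cluster_count):
        host = hosts[k % len(hosts)]
        if rng.random() < config.ag_fraction:
            mismatch = "A>G"
        else:
            mismatch = other_classes[int(rng.integers(0, len(other_classes)))]
        ref_base = mismatch[0]
        span = min(config.he_cluster_span, host[1] - host[0] - 2)
        base0 = int(rng.integers(host[0], host[1] - span))
        positions = sorted(
            rng.choice(span, size=config.he_cluster_size, replace=False)
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        (i1s, i1e), (i2s, i2e) = inverted_spans

        def mirror(pos: int) -> None:
            # keep the inverted-repeat pair an exact palindrome when a
            # planted base lands inside one of its arms
            if i1s <= pos < i1e:
                partner = i2e - 1 - (pos - i1s)
            elif i2s <= pos < i2e:
                partner = i1e - 1 - (pos - i2s)
            else:
                return
            seq[partner] = ord(comp[chr(seq[pos])])

        members = []
        for offset in positions:
            pos = base0 + int(offset)
            seq[pos] = ord(ref_base)
            mirror(pos)
            members.append(len(truth.he_sites))
            truth.he_sites.append(
                (contig, pos, "+", mismatch, config.he_level)
            )
        truth.clusters.append(members)

    truth.repeat_elements = [
        (contig, start, end, family) for start, end, family in placements
    ]

    genome = ReferenceGenome({contig: bytes(seq).decode()})
    annotation = AnnotationSet()
    ftree = IntervalTree()
    for start, end, label in features:
        ftree.addi(start, end, (label, "+"))
    annotation.features[contig] = ftree
    rtree = IntervalTree()
    for start, end, family in placements:
        rtree.addi(start, end, family)
    annotation.repeats[contig] = rtree
    return genome, annotation, truth


def simulate_transcriptome_reads(
    reference: ReferenceGenome,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[AlignedRead]:
    """Gapless reads with per-molecule Bernoulli editing at planted sites.

    Each read covering a planted site shows the edited base with the
    site's level, independently per molecule; uniform substitution error
    is applied at ``error_rate``; qualities are constant ``base_quality``.
    Alignments are emitted directly so the pipeline runs without an
    external aligner.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    reads: list[AlignedRead] = []
    length = config.read_length
    site_map: dict[str, list[tuple[int, str, float]]] = {}
    for contig, pos, _, mismatch, level in truth.he_sites:
        site_map.setdefault(contig, []).append((pos, mismatch[2], level))
    for contig in site_map:
        site_map[contig].sort()

    for contig, seq in reference.contigs.items():
        n = len(seq)
        if n < length:
            continue
        n_reads = int(round(config.transcriptome_depth * n / length))
        if n_reads == 0:
            continue
        starts = rng.integers(0, n - length + 1, size=n_reads)
        positions = np.array([p for p, _, _ in site_map.get(contig, ())])
        alts = [a for _, a, _ in site_map.get(contig, ())]
        levels = np.array([lv for _, _, lv in site_map.get(contig, ())])
        seq_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i, start in enumerate(starts):
            start = int(start)
            read = seq_bytes[start:start + length].copy()
            if len(positions):
                lo = np.searchsorted(positions, start, side="left")
                hi = np.searchsorted(positions, start + length, side="left")
                for j in range(lo, hi):
                    if rng.random() < levels[j]:
                        read[positions[j] - start] = ord(alts[j])
            if config.error_rate > 0:
                hits = np.flatnonzero(rng.random(length) < config.error_rate)
                if len(hits):
                    idx = _BYTE_TO_INDEX[read[hits]]
                    shift = rng.integers(1, 4, size=len(hits)).astype(np.uint8)
                    read[hits] = _INDEX_TO_BYTE[(idx + shift) % 4]
            reads.append(
                AlignedRead(
                    read_id=f"sim:{contig}:{i}",
                    contig=contig,
                    pos=start,
                    strand="+",
                    sequence=bytes(read).decode(),
                    qualities=np.full(length, config.base_quality, dtype=np.uint8),
                    mapq=60,
                    cigar=(("M", length),),
                )
            )
    return reads


def simulate_site_columns(
    n_sites: int,
    depth: int,
    level: float,
    ag_fraction: float,
    rng,
    contig: str = "chrS",
    spacing: int = 500,
) -> tuple[list[PileupColumn], list[tuple[str, int, str, str, float]]]:
    """Planted pileup columns for spectrum studies, bypassing read I/O.

    Each site draws its mismatch class (A>G with probability
    ``ag_fraction``, else uniform over the other 11) and a binomial
    alternate count at the planted level.  Supporter lists are left empty;
    these columns feed the candidate caller and spectrum analytics only.
    """
    rng = _rng(rng)
    other = [c for c in MISMATCH_CLASSES if c != "A>G"]
    columns, truth_sites = [], []
    for i in range(n_sites):
        if rng.random() < ag_fraction:
            mismatch = "A>G"
        else:
            mismatch = other[int(rng.integers(0, len(other)))]
        ref, alt = mismatch[0], mismatch[2]
        n_alt = int(rng.binomial(depth, level))
        col = PileupColumn(
            site=GenomicSite(contig, i * spacing, "+"), ref=ref
        )
        col.counts[ref] = depth - n_alt
        col.counts[alt] += n_alt
        columns.append(col)
        truth_sites.append((contig, i * spacing, "+", mismatch, level))
    return columns, truth_sites


def _barcodes(count: int, length: int) -> list[str]:
    """Deterministic distinct barcodes, spread over the k-mer space."""
    total = 4**length
    step = max(1, total // (count + 1))
    codes = []
    for i in range(count):
        x = (i + 1) * step
        code = "".join("ACGT"[(x >> (2 * k)) & 3] for k in range(length))
        codes.append(code)
    assert len(set(codes)) == count
    return codes


def _two_site_joint(
    anchor: float, anchor_tuple: tuple[str, str], weights: dict[tuple[str, str], float]
) -> dict[tuple[str, str], float]:
    """Joint A/G distribution fixing one tuple's mass, splitting the rest."""
    rest = 1.0 - anchor
    total_w = sum(weights.values())
    joint = {t: rest * w / total_w for t, w in weights.items()}
    joint[anchor_tuple] = anchor
    assert abs(sum(joint.values()) - 1.0) < 1e-9
    return joint


def _joint_marginals(joint: dict[tuple[str, ...], float]) -> list[float]:
    arity = len(next(iter(joint)))
    return [
        sum(p for t, p in joint.items() if t[i] == "G") for i in range(arity)
    ]


@dataclass
class SimulatedStudy:
    """The complete synthetic mmPCR experiment."""

    genome: ReferenceGenome
    panel: AmpliconPanel
    sheet: SampleSheet
    truth: SyntheticTruth
    reads: list[tuple[str, str, str]]  # pooled, barcoded (id, seq, qual)


def simulate_amplicon_panel(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedStudy:
    """Full synthetic targeted-resequencing study with barcoded reads.

    The panel holds two two-site amplicons with codon maps (one
    parameterized by the unedited-tuple abundance, translating to "LR"
    unedited; one by the double-edited abundance, translating to "AV"
    when fully edited), one minus-strand amplicon, and single-site
    amplicons, a subset of which carry a genotype shift of
    ``effect_size``.  One heterozygous SNP sits on a targeted site and one
    homozygous SNP at an untargeted position (an off-target decoy); both
    appear in RNA and gDNA alike and must be masked by the gDNA
    comparison.  RNA reads sample a haplotype tuple from the genotype's
    joint distribution and then per-base error; half the reads are
    reverse-complemented; barcodes are prepended per the sample sheet.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    truth = SyntheticTruth(seed=config.seed, error_rate=config.amplicon_error_rate)
    contig = "ampref"
    gap = 50
    m = config.amplicon_length
    pl = config.primer_length
    wt, mut = config.genotype_labels

    # --- build amplicon sequences and the backing contig ------------------
    pieces: list[np.ndarray] = []
    specs: list[dict] = []
    cursor = 0
    site_levels: dict[tuple[str, int], dict[str, float]] = {}
    single_site_candidates: list[tuple[str, int]] = []

    for i in range(config.amplicon_count):
        arr = _random_seq(rng, m)
        start = cursor
        strand = "-" if i == 2 else "+"
        aid = f"amp{i:02d}"
        gene = f"gene{i:02d}"
        codons = None
        if i == 0:
            gene = "gria2a_like"
            # codon boundary pair: TTA|AGA -> L R unedited; sites are the
            # last base of the Leu codon and the first of the Arg codon
            c0 = m // 2 - (m // 2) % 3  # keep frame 0 within the amplicon
            arr[c0:c0 + 6] = np.frombuffer(b"TTAAGA", dtype=np.uint8)
            sites = (start + c0 + 2, start + c0 + 3)
            codons = {sites[0]: ("TTA", 2), sites[1]: ("AGA", 0)}
        elif i == 1:
            gene = "gria3a_like"
            c0 = m // 2 - (m // 2) % 3
            arr[c0:c0 + 6] = np.frombuffer(b"ACAATT", dtype=np.uint8)
            sites = (start + c0, start + c0 + 3)
            codons = {sites[0]: ("ACA", 0), sites[1]: ("ATT", 0)}
        else:
            col = m // 2
            arr[col] = ord("T") if strand == "-" else ord("A")
            sites = (start + col,)
            single_site_candidates.append((aid, sites[0]))
        specs.append(
            dict(
                amplicon_id=aid, gene=gene, start=start, strand=strand,
                target_sites=sites, codons=codons,
            )
        )
        pieces.append(arr)
        pieces.append(_random_seq(rng, gap))
        cursor += m + gap

    # --- SNPs: one het on a targeted site, one hom off-target decoy -------
    snp_specs: list[tuple[int, float, str, bool]] = []  # pos, alt frac, zygosity
    if config.snp_on_target and len(single_site_candidates) >= 2:
        _, pos = single_site_candidates[-1]
        snp_specs.append((pos, 0.5, "het", True))
    decoy_col = m // 2 + 17
    pieces[2 * 3][decoy_col] = ord("A")  # force an untargeted A in amp03
    snp_specs.append((specs[3]["start"] + decoy_col, 1.0, "hom", False))
    for pos, frac, zygosity, on_target in snp_specs:
        truth.snps[(contig, pos)] = {
            "zygosity": zygosity,
            "gdna_alt_frac": frac,
            "on_target": on_target,
        }

    contig_seq = bytes(np.concatenate(pieces)).decode()
    genome = ReferenceGenome({contig: contig_seq})
    amplicons = [
        Amplicon(
            amplicon_id=s["amplicon_id"],
            gene=s["gene"],
            contig=contig,
            start=s["start"],
            end=s["start"] + m,
            strand=s["strand"],
            sequence=genome.fetch(contig, s["start"], s["start"] + m),
            fwd_primer=(s["start"], s["start"] + pl),
            rev_primer=(s["start"] + m - pl, s["start"] + m),
            target_sites=s["target_sites"],
            codons=s["codons"],
        )
        for s in specs
    ]
    panel = AmpliconPanel(amplicons)
    panel.validate_against(genome)

    # --- planted editing levels and joint distributions -------------------
    snp_positions = {pos for pos, *_ in snp_specs}
    shiftable = [
        (aid, pos) for aid, pos in single_site_candidates
        if pos not in snp_positions
    ]
    shifted = [
        (contig, pos)
        for _, pos in [
            shiftable[int(k)]
            for k in rng.choice(
                len(shiftable),
                size=min(config.n_shifted_sites, len(shiftable)),
                replace=False,
            )
        ]
    ]
    truth.shifted_sites = shifted

    for aid, pos in single_site_candidates:
        if pos in snp_positions:
            site_levels[(contig, pos)] = {wt: 0.0, mut: 0.0}
            continue
        base_level = float(rng.uniform(0.05, 0.45))
        delta = config.effect_size if (contig, pos) in shifted else 0.0
        site_levels[(contig, pos)] = {wt: base_level, mut: base_level + delta}

    u_wt, u_mut = config.unedited_abundance
    d_wt, d_mut = config.double_edited_abundance
    joints: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    joints[("amp00", wt)] = _two_site_joint(
        u_wt, ("A", "A"),
        {("A", "G"): 0.75, ("G", "A"): 0.10, ("G", "G"): 0.15},
    )
    joints[("amp00", mut)] = _two_site_joint(
        u_mut, ("A", "A"),
        {("A", "G"): 0.75, ("G", "A"): 0.10, ("G", "G"): 0.15},
    )
    joints[("amp01", wt)] = _two_site_joint(
        d_wt, ("G", "G"),
        {("A", "A"): 0.70, ("A", "G"): 0.18, ("G", "A"): 0.12},
    )
    joints[("amp01", mut)] = _two_site_joint(
        d_mut, ("G", "G"),
        {("A", "A"): 0.70, ("A", "G"): 0.18, ("G", "A"): 0.12},
    )
    truth.haplotype_probs = joints
    for (aid, genotype), joint in joints.items():
        amp = panel[aid]
        for site_pos, marginal in zip(amp.target_sites, _joint_marginals(joint)):
            site_levels.setdefault((contig, site_pos), {})[genotype] = marginal
    truth.site_levels = site_levels

    # --- sample sheet ------------------------------------------------------
    n_rna = config.samples_per_genotype
    n_gdna = config.gdna_samples_per_genotype
    total = 2 * (n_rna + n_gdna)
    codes = _barcodes(total, config.barcode_length)
    samples: list[Sample] = []
    ci = 0
    for genotype in (wt, mut):
        for k in range(n_rna):
            samples.append(Sample(f"{genotype}_R{k + 1}", codes[ci], genotype, "RNA"))
            ci += 1
    for genotype in (wt, mut):
        for k in range(n_gdna):
            samples.append(Sample(f"{genotype}_D{k + 1}", codes[ci], genotype, "gDNA"))
            ci += 1
    sheet = SampleSheet(samples)

    # --- reads -------------------------------------------------------------
    efficiency = np.exp(rng.normal(0.0, 0.25, size=config.amplicon_count))
    qual_char = chr(33 + config.base_quality)
    all_reads: list[tuple[str, str, str]] = []

    for sample in sheet:
        is_rna = sample.material == "RNA"
        base_depth = config.amplicon_depth if is_rna else config.gdna_depth
        sample_factor = float(np.exp(rng.normal(0.0, 0.08)))
        for ai, amp in enumerate(panel):
            n_reads = max(1, int(round(base_depth * efficiency[ai] * sample_factor)))
            truth.read_depth[f"{sample.sample_id}:{amp.amplicon_id}"] = n_reads
            mat = np.tile(
                np.frombuffer(amp.sequence.encode(), dtype=np.uint8),
                (n_reads, 1),
            )
            edited_plus = "C" if amp.strand == "-" else "G"
            if is_rna:
                key = (amp.amplicon_id, sample.genotype)
                if key in joints:
                    joint = joints[key]
                    tuples = list(joint)
                    probs = np.array([joint[t] for t in tuples])
                    choice = rng.choice(len(tuples), size=n_reads, p=probs)
                    for si, pos in enumerate(amp.target_sites):
                        col = amp.column(pos)
                        g_rows = np.array(
                            [tuples[c][si] == "G" for c in choice]
                        )
                        mat[g_rows, col] = ord(edited_plus)
                else:
                    for pos in amp.target_sites:
                        if (contig, pos) in truth.snps:
                            continue
                        level = site_levels[(contig, pos)][sample.genotype]
                        col = amp.column(pos)
                        mask = rng.random(n_reads) < level
                        mat[mask, col] = ord(edited_plus)
            # SNP alleles appear in RNA and gDNA alike
            for pos, frac, _, _ in snp_specs:
                host = panel.amplicon_at(contig, pos)
                if host is None or host.amplicon_id != amp.amplicon_id:
                    continue
                col = amp.column(pos)
                alt = "C" if amp.strand == "-" else "G"
                mask = rng.random(n_reads) < frac
                mat[mask, col] = ord(alt)
            if config.amplicon_error_rate > 0:
                hits = rng.random(mat.shape) < config.amplicon_error_rate
                if hits.any():
                    idx = _BYTE_TO_INDEX[mat[hits]]
                    shift = rng.integers(1, 4, size=hits.sum()).astype(np.uint8)
                    mat[hits] = _INDEX_TO_BYTE[(idx + shift) % 4]
            flip = rng.random(n_reads) < 0.5
            qual = qual_char * m
            for r in range(n_reads):
                seq = bytes(mat[r]).decode()
                if flip[r]:
                    seq = revcomp(seq)
                all_reads.append(
                    (
                        f"{sample.sample_id}:{amp.amplicon_id}:{r}",
                        sample.barcode + seq,
                        "I" * config.barcode_length + qual,
                    )
                )

    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[int(i)] for i in order]
    return SimulatedStudy(
        genome=genome, panel=panel, sheet=sheet, truth=truth, reads=all_reads
    )
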