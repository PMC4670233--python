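import math

import numpy as np
import pandas as pd
import pytest

from rnaedit.amplicon import (
    Amplicon,
    AmpliconPanel,
    Sample,
    SampleSheet,
    SiteEditingTable,
    TABLE_COLUMNS,
    align_amplicon_reads,
    apply_selection_criteria,
    demultiplex,
    depth_correlation,
    differential_editing,
    discover_offtarget_sites,
    mask_genomic_variants,
    quantify_sites,
)
from rnaedit.pileup import FilterThresholds, build_pileup, editing_level
from rnaedit.seqio import ReferenceGenome, revcomp
from rnaedit.stats import welch_t_test

from conftest import make_read


def _amplicon(seq, start=0, aid="a1", strand="+", sites=(), contig="c1"):
    return Amplicon(
        amplicon_id=aid,
        gene=f"gene_{aid}",
        contig=contig,
        start=start,
        end=start + len(seq),
        strand=strand,
        sequence=seq,
        fwd_primer=(start, start + 5),
        rev_primer=(start + len(seq) - 5, start + len(seq)),
        target_sites=tuple(sites),
    )


@pytest.fixture
def small_panel(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
    amps = []
    cursor = 0
    for i, seq in enumerate(seqs):
        seq = seq[:20] + "A" + seq[21:]
        amps.append(
            _amplicon(seq, start=cursor, aid=f"a{i}", sites=(cursor + 20,))
        )
        cursor += 50
    return AmpliconPanel(amps)


def _reads_for(amp, n, edit_cols=(), qual=30, prefix="r"):
    reads = []
    for i in range(n):
        seq = list(amp.sequence)
        for col in edit_cols:
            seq[col] = "G" if amp.strand == "+" else "C"
        reads.append((f"{prefix}{i}", "".join(seq), chr(33 + qual) * len(seq)))
    return reads


class TestPanel:
    def test_site_inside_primer_rejected(self):
        with pytest.raises(ValueError, match="primer"):
            _amplicon("A" * 40, sites=(2,))

    def test_sequence_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            Amplicon(
                amplicon_id="x", gene="g", contig="c", start=0, end=50,
                strand="+", sequence="ACGT", fwd_primer=(0, 2),
                rev_primer=(48, 50), target_sites=(),
            )

    def test_validate_against_genome(self, small_panel):
        contig = "".join(
            a.sequence.ljust(50, "T") for a in small_panel
        )
        genome = ReferenceGenome({"c1": contig})
        small_panel.validate_against(genome)
        bad = ReferenceGenome({"c1": "T" * len(contig)})
        with pytest.raises(ValueError, match="does not match"):
            small_panel.validate_against(bad)


class TestSampleSheet:
    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError, match="barcode"):
            SampleSheet(
                [
                    Sample("s1", "ACGTACGT", "WT", "RNA"),
                    Sample("s2", "ACGTACGT", "MUT", "RNA"),
                ]
            )

    def test_material_validated(self):
        with pytest.raises(ValueError):
            Sample("s1", "ACGT", "WT", "protein")


class TestDemultiplex:
    @pytest.fixture
    def sheet(self):
        return SampleSheet(
            [
                Sample("s1", "AAAA", "WT", "RNA"),
                Sample("s2", "CCCC", "WT", "RNA"),
                Sample("s3", "GGGG", "MUT", "RNA"),
            ]
        )

    def test_exact_match_assigns_and_trims(self, sheet):
        bins = demultiplex([("r1", "GGGGACGTACGT", "I" * 12)], sheet)
        assert len(bins["s3"]) == 1
        rid, seq, qual = bins["s3"][0]
        assert seq == "ACGTACGT" and len(qual) == 8

    def test_one_mismatch_goes_unassigned(self, sheet):
        bins = demultiplex([("r1", "GGGTACGTACGT", "I" * 12)], sheet)
        assert len(bins["unassigned"]) == 1
        assert all(not bins[s] for s in ("s1", "s2", "s3"))

    def test_read_conservation(self, sheet, rng):
        reads = [
            (f"r{i}", "".join(rng.choice(list("ACGT"), size=12)), "I" * 12)
            for i in range(500)
        ]
        bins = demultiplex(reads, sheet)
        assert sum(len(v) for v in bins.values()) == len(reads)


class TestAlignment:
    def test_identical_read_zero_mismatches(self, small_panel):
        amp = small_panel["a1"]
        (aligned,) = align_amplicon_reads(
            [("r1", amp.sequence, "I" * 40)], small_panel
        )
        assert aligned.contig == "c1"
        assert aligned.pos == amp.start
        assert aligned.strand == "+"
        assert aligned.sequence == amp.sequence

    def test_revcomp_read_mapped_to_forward_coordinates(self, small_panel):
        amp = small_panel["a2"]
        seq = list(amp.sequence)
        seq[7] = "A" if seq[7] != "A" else "C"
        seq[30] = "T" if seq[30] != "T" else "G"
        mutated = "".join(seq)
        (aligned,) = align_amplicon_reads(
            [("r1", revcomp(mutated), "I" * 40)], small_panel
        )
        assert aligned.strand == "-"
        assert aligned.pos == amp.start
        assert aligned.sequence == mutated  # stored plus-strand

    def test_tie_between_amplicons_dropped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        panel = AmpliconPanel(
            [_amplicon(seq, 0, "a1"), _amplicon(seq, 40, "a2")]
        )
        assert align_amplicon_reads([("r1", seq, "I" * 30)], panel) == []

    def test_mismatch_ceiling_drops_read(self, small_panel):
        amp = small_panel["a0"]
        garbled = "".join(
            "T" if b != "T" else "A" for b in amp.sequence[:20]
        ) + amp.sequence[20:]
        assert align_amplicon_reads(
            [("r1", garbled, "I" * 40)], small_panel
        ) == []

    def test_shorter_read_placed_at_best_offset(self, small_panel):
        amp = small_panel["a1"]
        fragment = amp.sequence[12:32]
        (aligned,) = align_amplicon_reads(
            [("r1", fragment, "I" * 20)], small_panel
        )
        assert aligned.pos == amp.start + 12

    def test_empty_panel_is_error(self):
        with pytest.raises(ValueError):
            align_amplicon_reads([("r", "ACGT", "IIII")], AmpliconPanel([]))

    def test_matches_exhaustive_oracle(self, rng):
        """Random reads vs an all-offsets/all-amplicons brute-force scan."""
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(3)]
        panel = AmpliconPanel(
            [_amplicon(s, 40 * i, f"a{i}") for i, s in enumerate(seqs)]
        )
        for trial in range(100):
            src = int(rng.integers(0, 3))
            lo = int(rng.integers(0, 10))
            read = list(seqs[src][lo:lo + 20])
            for _ in range(int(rng.integers(0, 3))):
                j = int(rng.integers(0, 20))
                read[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.random() < 0.5:
                query = revcomp(read)
            else:
                query = read
            # oracle
            best = []
            for ai, seq in enumerate(seqs):
                for orient, hay in ((1, seq), (-1, revcomp(seq))):
                    for off in range(len(seq) - 20 + 1):
                        mm = sum(
                            1 for x, y in zip(query, hay[off:off + 20]) if x != y
                        )
                        best.append((mm, ai, orient, off))
            best.sort()
            mm0 = best[0][0]
            winners = {b[1] for b in best if b[0] == mm0}
            got = align_amplicon_reads([("q", query, "I" * 20)], panel)
            if mm0 > 2 or len(winners) > 1:
                assert got == []
            else:
                assert len(got) == 1
                assert got[0].contig == "c1"
                amp = panel[f"a{best[0][1]}"]
                assert amp.start <= got[0].pos < amp.end


class TestQuantify:
    def test_unedited_reads(self, small_panel):
        amp = small_panel["a0"]
        aligned = align_amplicon_reads(
            _reads_for(amp, 400), small_panel, sample_id="s1"
        )
        table = quantify_sites({"s1": aligned}, small_panel)
        row = table.df[
            (table.df["sample"] == "s1") & (table.df["pos"] == amp.target_sites[0])
        ].iloc[0]
        assert row["n_A"] == 400 and row["n_G"] == 0 and row["level"] == 0.0

    def test_planted_level_within_binomial_bound(self, small_panel, rng):
        amp = small_panel["a1"]
        level, depth = 0.30, 1000
        col = amp.column(amp.target_sites[0])
        reads = []
        for i in range(depth):
            seq = list(amp.sequence)
            if rng.random() < level:
                seq[col] = "G"
            reads.append((f"r{i}", "".join(seq), "I" * 40))
        aligned = align_amplicon_reads(reads, small_panel, sample_id="s")
        table = quantify_sites({"s": aligned}, small_panel)
        row = table.df[table.df["pos"] == amp.target_sites[0]].iloc[0]
        bound = 3 * math.sqrt(0.3 * 0.7 / depth)
        assert abs(row["level"] - level) < bound

    def test_low_quality_bases_excluded(self, small_panel):
        amp = small_panel["a0"]
        col = amp.column(amp.target_sites[0])
        qual = ["I"] * 40  # Q40
        qual[col] = chr(33 + 19)  # Q19 at the site
        reads = [("lo", amp.sequence, "".join(qual)), ("hi", amp.sequence, "I" * 40)]
        aligned = align_amplicon_reads(reads, small_panel, sample_id="s")
        table = quantify_sites({"s": aligned}, small_panel)
        row = table.df[table.df["pos"] == amp.target_sites[0]].iloc[0]
        assert row["depth"] == 1  # only the Q40 read counts

    def test_uncovered_site_has_zero_depth_row(self, small_panel):
        table = quantify_sites({"s1": []}, small_panel)
        assert len(table.df) == 3
        assert (table.df["depth"] == 0).all()
        assert table.df["level"].isna().all()

    def test_consistent_with_pileup_editing_level(self, small_panel, rng):
        """Cross-module: quantify_sites equals editing_level on pileup counts."""
        amp = small_panel["a2"]
        col = amp.column(amp.target_sites[0])
        reads = []
        for i in range(200):
            seq = list(amp.sequence)
            if rng.random() < 0.2:
                seq[col] = "G"
            reads.append((f"r{i}", "".join(seq), "I" * 40))
        aligned = align_amplicon_reads(reads, small_panel, sample_id="s")
        table = quantify_sites({"s": aligned}, small_panel)
        row = table.df[table.df["pos"] == amp.target_sites[0]].iloc[0]

        contig = "T" * amp.start + amp.sequence
        genome = ReferenceGenome({"c1": contig})
        columns = build_pileup(aligned, genome, "c1", amp.start, amp.end)
        pcol = next(c for c in columns if c.site.pos == amp.target_sites[0])
        assert row["level"] == pytest.approx(
            editing_level(pcol.counts["A"], pcol.counts["G"])
        )


class TestOffTarget:
    def _panel_with_offtarget_a(self, rng, off_col=25):
        seq = list("".join(rng.choice(list("ACGT"), size=40)))
        seq[20] = "A"
        seq[off_col] = "A"
        return AmpliconPanel([_amplicon("".join(seq), 0, "a0", sites=(20,))]), off_col

    def test_nine_mismatch_reads_not_called_ten_called(self, rng):
        panel, off_col = self._panel_with_offtarget_a(rng)
        amp = panel["a0"]
        for n_g, expect in ((9, 0), (10, 1)):
            reads = _reads_for(amp, n_g, edit_cols=(off_col,)) + _reads_for(
                amp, 300, prefix="u"
            )
            aligned = align_amplicon_reads(reads, panel, sample_id="s")
            off = discover_offtarget_sites({"s": aligned}, panel)
            n_sites = len(off.sites) if len(off.df) else 0
            assert n_sites == expect

    def test_all_reference_amplicon_yields_none(self, rng):
        panel, _ = self._panel_with_offtarget_a(rng)
        aligned = align_amplicon_reads(
            _reads_for(panel["a0"], 500), panel, sample_id="s"
        )
        off = discover_offtarget_sites({"s": aligned}, panel)
        assert len(off.df) == 0

    def test_planted_offtarget_recovered(self, rng):
        panel, off_col = self._panel_with_offtarget_a(rng)
        amp = panel["a0"]
        reads = []
        for i in range(500):
            seq = list(amp.sequence)
            if rng.random() < 0.10:
                seq[off_col] = "G"
            reads.append((f"r{i}", "".join(seq), "I" * 40))
        aligned = align_amplicon_reads(reads, panel, sample_id="s")
        off = discover_offtarget_sites({"s": aligned}, panel)
        assert off.sites == [("c1", off_col)]
        assert (~off.df["targeted"]).all()


def _table(rows):
    df = pd.DataFrame(rows)
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = {
                "amplicon_id": "a0", "gene": "g", "contig": "c1",
                "strand": "+", "targeted": True,
            }.get(col, 0)
    df["level"] = df.apply(
        lambda r: (r["n_G"] / r["depth"]) if r["depth"] else math.nan, axis=1
    )
    return SiteEditingTable(df[TABLE_COLUMNS])


def _row(sample, pos, n_a, n_g):
    return {
        "sample": sample, "pos": pos, "n_A": n_a, "n_G": n_g,
        "depth": n_a + n_g,
    }


class TestSnpMasking:
    @pytest.fixture
    def sheet(self):
        return SampleSheet(
            [
                Sample("r1", "AAAA", "WT", "RNA"),
                Sample("d1", "CCCC", "WT", "gDNA"),
            ]
        )

    def test_heterozygote_excluded(self):
        rna = _table([_row("r1", 10, 500, 500)])
        gdna = _table([_row("d1", 10, 260, 240)])
        masked, log = mask_genomic_variants(rna, gdna)
        assert masked.sites == []
        assert log.iloc[0]["reason"] == "gDNA alternate allele"
        assert log.iloc[0]["gdna_alt_frac"] == pytest.approx(0.48)

    def test_clean_gdna_retained(self):
        rna = _table([_row("r1", 10, 900, 100)])
        gdna = _table([_row("d1", 10, 500, 0)])
        masked, log = mask_genomic_variants(rna, gdna)
        assert masked.sites == [("c1", 10)]
        assert len(log) == 0

    def test_known_snp_list_takes_precedence(self):
        rna = _table([_row("r1", 10, 900, 100)])
        gdna = _table([_row("d1", 10, 500, 0)])
        masked, log = mask_genomic_variants(rna, gdna, known_snps=[("c1", 10)])
        assert masked.sites == []
        assert log.iloc[0]["reason"] == "known SNP"

    def test_zero_gdna_depth_excluded_conservatively(self):
        rna = _table([_row("r1", 10, 900, 100)])
        gdna = _table([_row("d1", 10, 0, 0)])
        masked, log = mask_genomic_variants(rna, gdna)
        assert masked.sites == []
        assert log.iloc[0]["reason"] == "no gDNA evidence"


def _sheet_n(n_per_genotype):
    samples = []
    codes = iter(
        "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(4)) for i in range(256)
    )
    for g in ("WT", "MUT"):
        for i in range(n_per_genotype):
            samples.append(Sample(f"{g}{i}", next(codes), g, "RNA"))
    return SampleSheet(samples)


class TestSelectionCriteria:
    def test_depth_399_fails_coverage(self):
        sheet = _sheet_n(4)
        rows = [
            _row(s.sample_id, 10, 380, 19) for s in sheet
        ]  # depth 399 everywhere
        retained, audit = apply_selection_criteria(_table(rows), sheet)
        assert retained == []
        assert set(audit["status"]) == {"fail_coverage"}

    def test_incidence_boundary_75_percent(self):
        sheet = _sheet_n(4)  # 3/4 = 75% exactly
        def rows(n_captured):
            out = []
            for g in ("WT", "MUT"):
                for i in range(4):
                    depth_ok = i < n_captured
                    out.append(
                        _row(f"{g}{i}", 10, 380 if depth_ok else 100,
                             120 if depth_ok else 10)
                    )
            return out
        retained, _ = apply_selection_criteria(_table(rows(3)), sheet)
        assert retained == [("c1", 10)]
        retained, audit = apply_selection_criteria(_table(rows(2)), sheet)
        assert retained == []
        assert set(audit["status"]) == {"fail_incidence"}

    def test_level_boundary_two_percent(self):
        sheet = _sheet_n(2)
        def rows(n_g):
            return [_row(s.sample_id, 10, 1000 - n_g, n_g) for s in sheet]
        retained, _ = apply_selection_criteria(_table(rows(20)), sheet)  # 2%
        assert retained == [("c1", 10)]
        retained, audit = apply_selection_criteria(_table(rows(19)), sheet)
        assert retained == []
        assert set(audit["status"]) == {"fail_level"}

    def test_matches_brute_force_cascade(self, rng):
        sheet = _sheet_n(5)
        thr = FilterThresholds(amp_min_coverage=100)
        rows = []
        for pos in range(0, 200, 10):
            for s in sheet:
                depth = int(rng.integers(0, 300))
                n_g = int(rng.integers(0, depth + 1)) if depth else 0
                rows.append(_row(s.sample_id, pos, depth - n_g, n_g))
        table = _table(rows)
        retained, _ = apply_selection_criteria(table, sheet, thr)
        # oracle: triple filter recomputed naively
        expected = []
        for pos in range(0, 200, 10):
            ok = True
            for g in ("WT", "MUT"):
                cells = [
                    r for r in rows
                    if r["pos"] == pos and r["sample"].startswith(g)
                ]
                captured = [c for c in cells if c["depth"] >= 100]
                if len(captured) / len(cells) < 0.75:
                    ok = False
                    break
                mean_level = np.mean(
                    [c["n_G"] / c["depth"] for c in captured]
                )
                if mean_level < 0.02:
                    ok = False
                    break
            if ok:
                expected.append(("c1", pos))
        assert retained == expected

    def test_monotone_in_each_threshold(self, rng):
        sheet = _sheet_n(4)
        rows = []
        for pos in range(0, 100, 10):
            for s in sheet:
                depth = int(rng.integers(200, 600))
                n_g = int(rng.integers(0, depth // 10))
                rows.append(_row(s.sample_id, pos, depth - n_g, n_g))
        table = _table(rows)
        base, _ = apply_selection_criteria(table, sheet)
        for tighter in (
            FilterThresholds(amp_min_coverage=500),
            FilterThresholds(amp_min_level=0.05),
            FilterThresholds(amp_min_incidence=1.0),
        ):
            subset, _ = apply_selection_criteria(table, sheet, tighter)
            assert set(subset) <= set(base)


class TestDifferential:
    def test_identical_levels_give_p_one(self):
        sheet = _sheet_n(3)
        rows = [_row(s.sample_id, 10, 900, 100) for s in sheet]
        result = differential_editing(_table(rows), sheet)
        assert result.iloc[0]["t"] == 0.0 and result.iloc[0]["p"] == 1.0

    def test_matches_welch_closed_form(self):
        sheet = _sheet_n(3)
        wt_levels = [0.10, 0.12, 0.11]
        mut_levels = [0.20, 0.22, 0.21]
        rows = []
        for s, lv in zip(sheet.subset("RNA"), wt_levels + mut_levels):
            n_g = round(1000 * lv)
            rows.append(_row(s.sample_id, 10, 1000 - n_g, n_g))
        result = differential_editing(_table(rows), sheet)
        ref = welch_t_test(wt_levels, mut_levels)
        assert result.iloc[0]["t"] == pytest.approx(ref.t, rel=1e-9)
        assert result.iloc[0]["p"] == pytest.approx(ref.p, rel=1e-9)
        assert result.iloc[0]["df"] == pytest.approx(ref.df, rel=1e-9)

    def test_site_with_insufficient_group_skipped(self):
        sheet = _sheet_n(2)
        rows = [
            _row("WT0", 10, 900, 100),
            _row("WT1", 10, 900, 100),
            _row("MUT0", 10, 900, 100),
            _row("MUT1", 10, 0, 0),  # undefined level
        ]
        result = differential_editing(_table(rows), sheet)
        assert len(result) == 0

    def test_fdr_column_optional(self):
        sheet = _sheet_n(3)
        rows = [_row(s.sample_id, 10, 900, 100 + i) for i, s in enumerate(sheet)]
        plain = differential_editing(_table(rows), sheet)
        assert "q_bh" not in plain.columns
        with_q = differential_editing(_table(rows), sheet, fdr=True)
        assert "q_bh" in with_q.columns


class TestDepthCorrelation:
    def _table_with_amplicons(self, depths_by_amp):
        sheet = _sheet_n(2)
        rows = []
        for aid, (wt_depth, mut_depth) in depths_by_amp.items():
            for s in sheet:
                d = wt_depth if s.genotype == "WT" else mut_depth
                rows.append(
                    dict(_row(s.sample_id, int(aid[1:]) * 10, d, 0),
                         amplicon_id=aid)
                )
        df = pd.DataFrame(rows)
        for col in TABLE_COLUMNS:
            if col not in df.columns:
                df[col] = {"gene": "g", "contig": "c1", "strand": "+",
                           "targeted": True}.get(col, 0)
        df["level"] = 0.0
        return SiteEditingTable(df[TABLE_COLUMNS]), sheet

    def test_identical_depths_give_r_one(self):
        table, sheet = self._table_with_amplicons(
            {"a0": (100, 100), "a1": (300, 300), "a2": (700, 700)}
        )
        r, r2 = depth_correlation(table, sheet)
        assert r == pytest.approx(1.0)

    def test_anti_ordered_depths_give_r_minus_one(self):
        table, sheet = self._table_with_amplicons(
            {"a0": (100, 300), "a1": (200, 200), "a2": (300, 100)}
        )
        r, _ = depth_correlation(table, sheet)
        assert r == pytest.approx(-1.0)

    def test_shared_efficiency_drives_high_correlation(self, rng):
        eff = rng.lognormal(0, 0.5, size=12)
        depths = {
            f"a{i}": (
                int(500 * e * rng.lognormal(0, 0.05)),
                int(500 * e * rng.lognormal(0, 0.05)),
            )
            for i, e in enumerate(eff)
        }
        table, sheet = self._table_with_amplicons(depths)
        r, _ = depth_correlation(table, sheet)
        assert r > 0.9
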