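"""PAS/UGUA scanning and the three-criteria candidate screen."""

import numpy as np
import pytest

from apascreen import (
    ScreenParams,
    SimConfig,
    UTRIsoformGroup,
    evaluate_gene,
    filter_expressed_candidates,
    generate_genome,
    run_screen,
    scan_pas,
    scan_ugua,
)
from apascreen.screen import PASHit, find_motif

from conftest import write_genome


def make_group(sequences, strand="+", utr_start=1000, gene_id="g1"):
    """Plus-strand group from sense sequences (nested prefixes not required)."""
    if strand == "+":
        ends = [utr_start + len(s) for s in sequences]
    else:
        ends = [utr_start - len(s) for s in sequences]
    return UTRIsoformGroup(
        gene_id=gene_id, chrom="chr1", strand=strand,
        utr_start=utr_start, ends=ends, sequences=list(sequences),
    )


def place(background_len, *motifs_at):
    """'C' background with motifs written at given positions (no accidents)."""
    seq = ["C"] * background_len
    for pos, motif in motifs_at:
        seq[pos : pos + len(motif)] = motif
    return "".join(seq)


class TestScanPas:
    def test_hit_inside_window_with_distance(self):
        # AATAAA 3' edge 30 nt upstream of the short end, none near long end
        short = place(100, (100 - 30 - 6, "AATAAA"))
        long = short + "C" * 80
        hits = scan_pas(make_group([short, long]), ScreenParams())
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.distance, h.is_proximal) == ("AATAAA", 30, True)
        assert h.end_supported == 1100

    @pytest.mark.parametrize("dist, expect", [(9, 0), (10, 1), (60, 1), (61, 0)])
    def test_inclusive_window_bounds(self, dist, expect):
        seq = place(100, (100 - dist - 6, "AATAAA"))
        hits = scan_pas(make_group([seq]), ScreenParams())
        assert len(hits) == expect

    def test_overlapping_motifs_two_hits(self):
        # AATAAATAAA holds AATAAA at two offsets; compare with brute force
        seq = place(60, (60 - 30 - 10, "AATAAATAAA"))
        hits = scan_pas(make_group([seq]), ScreenParams())
        brute = [
            p for p in range(len(seq) - 5)
            if seq[p : p + 6] == "AATAAA" and 10 <= len(seq) - p - 6 <= 60
        ]
        assert len(hits) == len(brute) == 2
        assert sorted(h.seq_start for h in hits) == brute

    def test_short_utr_no_hits(self):
        hits = scan_pas(make_group(["AATAAA"]), ScreenParams())
        assert hits == []

    def test_minus_strand_genomic_interval(self):
        seq = place(100, (64, "AATAAA"))
        g = make_group([seq], strand="-", utr_start=1000)
        (h,) = scan_pas(g, ScreenParams())
        # motif occupies sense positions [64,70) => genomic [930, 936)
        assert (h.start, h.end) == (930, 936)
        assert h.distance == 30


class TestScanUgua:
    def _anchor(self, seq_start):
        return PASHit("g1", "chr1", "+", 0, "AATAAA", 30, seq_start, 0, 6, True)

    def test_flanking_both_sides_true(self):
        seq = place(700, (300, "AATAAA"), (250, "TGTA"), (420, "TGTA"))
        c3, offsets = scan_ugua(make_group([seq]), self._anchor(300), ScreenParams())
        assert c3 and sorted(offsets) == [-50, 120]
        c3_any, _ = scan_ugua(
            make_group([seq]), self._anchor(300), ScreenParams(ugua_rule="any_two")
        )
        assert c3_any

    def test_one_sided_pair_fails_flanking_passes_any_two(self):
        seq = place(700, (300, "AATAAA"), (250, "TGTA"), (200, "TGTA"))
        c3, _ = scan_ugua(make_group([seq]), self._anchor(300), ScreenParams())
        assert not c3
        c3_any, _ = scan_ugua(
            make_group([seq]), self._anchor(300), ScreenParams(ugua_rule="any_two")
        )
        assert c3_any

    def test_radius_boundary_exclusive_beyond_200(self):
        seq = place(700, (300, "AATAAA"), (250, "TGTA"), (300 + 201, "TGTA"))
        c3, offsets = scan_ugua(make_group([seq]), self._anchor(300), ScreenParams())
        assert offsets == [-50]
        assert not c3
        # brute-force distance oracle
        brute = [
            p - 300 for p in range(len(seq) - 3)
            if seq[p : p + 4] == "TGTA" and abs(p - 300) <= 200
        ]
        assert offsets == brute


class TestEvaluateGene:
    def test_synthetic_positive_gene_all_true(self):
        short = place(250, (250 - 36, "AATAAA"), (250 - 36 - 80, "TGTA"))
        long = place(
            600, (250 - 36, "AATAAA"), (250 - 36 - 80, "TGTA"),
            (250 - 36 + 80, "TGTA"), (600 - 36, "AATAAA"),
        )
        v = evaluate_gene(make_group([short, long]), ScreenParams())
        assert (v.c1, v.c2, v.c3, v.candidate) == (True, True, True, True)

    def test_missing_ugua_decoy(self):
        short = place(250, (250 - 36, "AATAAA"))
        long = place(600, (250 - 36, "AATAAA"), (600 - 36, "AATAAA"))
        v = evaluate_gene(make_group([short, long]), ScreenParams())
        assert (v.c1, v.c2, v.c3) == (True, True, False)
        assert not v.candidate
        v_any = evaluate_gene(
            make_group([short, long]), ScreenParams(criteria_mode="any")
        )
        assert v_any.candidate

    def test_single_isoform_c1_false_c3_vacuous(self):
        seq = place(250, (250 - 36, "AATAAA"), (250 - 36 - 80, "TGTA"),
                    (250 - 36 + 80, "TGTA"))
        v = evaluate_gene(make_group([seq]), ScreenParams())
        assert (v.c1, v.c2, v.c3, v.candidate) == (False, True, False, False)

    def test_pas_at_any_end_relaxation(self):
        # PAS only at the proximal end: strict c2 false, relaxed c2 true
        short = place(250, (250 - 36, "AATAAA"), (250 - 36 - 80, "TGTA"))
        long = place(
            600, (250 - 36, "AATAAA"), (250 - 36 - 80, "TGTA"), (250 - 36 + 80, "TGTA")
        )
        strict = evaluate_gene(make_group([short, long]), ScreenParams())
        relaxed = evaluate_gene(
            make_group([short, long]), ScreenParams(pas_at_every_end=False)
        )
        assert not strict.c2 and relaxed.c2


class TestRunScreen:
    def test_candidate_count_matches_planted_truth(self, tmp_path):
        cfg = SimConfig(n_genes=200, frac_positive=0.2, seed=11)
        fasta, gtf, truth = generate_genome(cfg)
        gp, fp = write_genome(tmp_path, fasta, gtf)
        table, _ = run_screen(gp, fp)
        assert int(table["candidate"].sum()) == 40
        m = table.merge(truth, on="gene_id")
        assert (m["candidate"] == (m["class"] == "positive")).all()

    def test_expressed_gene_list_intersection(self, tmp_path):
        cfg = SimConfig(n_genes=200, frac_positive=0.2, seed=11)
        fasta, gtf, truth = generate_genome(cfg)
        gp, fp = write_genome(tmp_path, fasta, gtf)
        positives = truth.loc[truth["class"] == "positive", "gene_id"].tolist()
        half = set(positives[: len(positives) // 2])
        table, _ = run_screen(gp, fp, expressed_gene_list=half)
        assert "expressed" in table.columns
        sub = filter_expressed_candidates(table)
        assert len(sub) == 20
        assert set(sub["gene_id"]) == half

    def test_empty_annotation_empty_table(self, tmp_path):
        (tmp_path / "e.gtf").write_text("")
        (tmp_path / "g.fa").write_text(">chr1\nACGT\n")
        table, verdicts = run_screen(tmp_path / "e.gtf", tmp_path / "g.fa")
        assert len(table) == 0 and verdicts == []

    def test_missing_chromosome_named_in_error(self, tmp_path):
        cfg = SimConfig(n_genes=4, seed=1)
        fasta, gtf, _ = generate_genome(cfg)
        gp, _ = write_genome(tmp_path, fasta, gtf)
        (tmp_path / "other.fa").write_text(">chrX\nACGT\n")
        with pytest.raises(KeyError, match="chr1"):
            run_screen(gp, tmp_path / "other.fa")

    def test_bed_output_written(self, tmp_path):
        cfg = SimConfig(n_genes=10, seed=4)
        fasta, gtf, _ = generate_genome(cfg)
        gp, fp = write_genome(tmp_path, fasta, gtf)
        bed = tmp_path / "pas.bed"
        run_screen(gp, fp, bed_path=bed)
        lines = bed.read_text().splitlines()
        assert lines and all(len(l.split("\t")) == 6 for l in lines)


class TestProperties:
    def test_monotone_in_window_and_radius(self, tmp_path):
        cfg = SimConfig(n_genes=40, seed=13)
        fasta, gtf, _ = generate_genome(cfg)
        gp, fp = write_genome(tmp_path, fasta, gtf)
        narrow, _ = run_screen(gp, fp, ScreenParams())
        wide, _ = run_screen(
            gp, fp, ScreenParams(pas_window=(5, 120), ugua_radius=400)
        )
        before = set(narrow.loc[narrow["candidate"], "gene_id"])
        after = set(wide.loc[wide["candidate"], "gene_id"])
        assert before <= after

    def test_motif_find_matches_naive_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for motif in ("AATAAA", "TGTA"):
                naive = [
                    p for p in range(len(seq) - len(motif) + 1)
                    if seq[p : p + len(motif)] == motif
                ]
                assert find_motif(seq, motif) == naive
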