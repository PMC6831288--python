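"""Candidate screen for CFIm25/NUDT21-responsive APA genes.

A gene is a candidate when its 3'UTR isoform structure and motif content fit
the CFIm-regulated APA model:

  c1  the gene has >= 2 3'UTR isoforms sharing a 5' start with distinct
      cleavage ends (alternative polyadenylation within one UTR);
  c2  each retained cleavage end has a poly(A) signal (PAS) hexamer whose
      3' edge lies 10-60 nt upstream of that end (inclusive);
  c3  the proximal PAS is flanked by UGUA elements (CFIm binding sites)
      within 200 nt.

Motifs are stated in RNA (AAUAAA, UGUA) but matched on the sense-strand DNA
sequence as AATAAA/TGTA. The canonical PAS plus its strongest variant
(AATAAA, ATTAAA) is the default motif set; ``EXTENDED_PAS_MOTIFS`` adds the
ten further common hexamer variants for a looser notion of "similar
sequence".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import (
    UTRIsoformGroup,
    group_utr_isoforms,
    read_fasta,
    read_gtf,
    write_bed,
)

CANONICAL_PAS_MOTIFS = ("AATAAA", "ATTAAA")
# the common weaker hexamer variants, as catalogued for human poly(A) sites
EXTENDED_PAS_MOTIFS = CANONICAL_PAS_MOTIFS + (
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
)
UGUA_DNA = "TGTA"


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the screen.

    ``pas_window`` bounds (inclusive) the distance in nt from a PAS hexamer's
    3' edge to the cleavage end it supports. ``ugua_radius`` bounds |offset|
    of a UGUA from the proximal PAS. ``ugua_rule`` is ``flanking_both_sides``
    (>= 1 UGUA on each side; "surrounded") or ``any_two`` (>= 2 total).
    ``criteria_mode`` combines c1-c3 with AND (``all``) or OR (``any``).
    ``pas_at_every_end`` requires a PAS supporting each retained end for c2;
    when False a single supported end suffices.
    """

    pas_motifs: tuple[str, ...] = CANONICAL_PAS_MOTIFS
    pas_window: tuple[int, int] = (10, 60)
    ugua_radius: int = 200
    ugua_rule: str = "flanking_both_sides"
    criteria_mode: str = "all"
    pas_at_every_end: bool = True

    def __post_init__(self):
        w_min, w_max = self.pas_window
        if not (0 < w_min <= w_max):
            raise ValueError(f"invalid PAS window {self.pas_window}")
        if self.ugua_radius <= 0:
            raise ValueError("ugua_radius must be positive")
        if self.ugua_rule not in {"flanking_both_sides", "any_two"}:
            raise ValueError(f"unknown ugua_rule {self.ugua_rule!r}")
        if self.criteria_mode not in {"all", "any"}:
            raise ValueError(f"unknown criteria_mode {self.criteria_mode!r}")


@dataclass
class PASHit:
    """One PAS hexamer occurrence supporting a cleavage end.

    ``distance`` is measured from the motif's 3'-most base to the cleavage
    end (sense-strand transcript coordinates). ``seq_start`` is the motif
    start within the isoform's 3'UTR sequence; ``start``/``end`` the genomic
    interval (0-based half-open).
    """

    gene_id: str
    chrom: str
    strand: str
    end_supported: int
    motif: str
    distance: int
    seq_start: int
    start: int
    end: int
    is_proximal: bool


@dataclass
class CandidateVerdict:
    """Per-gene screen outcome with supporting motif evidence."""

    gene_id: str
    c1: bool
    c2: bool
    c3: bool
    candidate: bool
    pas_hits: list[PASHit] = field(default_factory=list)
    ugua_offsets: list[int] = field(default_factory=list)


def _genomic_interval(
    group: UTRIsoformGroup, seq_pos: int, length: int
) -> tuple[int, int]:
    """Map a position in the group's sense-strand sequence to genome coords."""
    if group.strand == "+":
        start = group.utr_start + seq_pos
        return start, start + length
    # minus strand: utr_start is the half-open 5' boundary (largest coord)
    end = group.utr_start - seq_pos
    return end - length, end


def find_motif(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start positions of ``motif`` in ``seq``."""
    positions = []
    i = seq.find(motif)
    while i != -1:
        positions.append(i)
        i = seq.find(motif, i + 1)
    return positions


def scan_pas(group: UTRIsoformGroup, params: ScreenParams) -> list[PASHit]:
    """Scan each isoform end for in-window PAS hexamers.

    For each cleavage end, every motif occurrence whose 3'-most base lies
    between w_min and w_max nt (inclusive) upstream of that end is reported.
    Hits supporting a non-distal end carry ``is_proximal=True``.
    """
    w_min, w_max = params.pas_window
    hits: list[PASHit] = []
    n = len(group.ends)
    for idx, (end, seq) in enumerate(zip(group.ends, group.sequences)):
        is_proximal = idx < n - 1
        for motif in params.pas_motifs:
            for p in find_motif(seq, motif):
                distance = len(seq) - (p + len(motif))
                if w_min <= distance <= w_max:
                    g_start, g_end = _genomic_interval(group, p, len(motif))
                    hits.append(
                        PASHit(
                            gene_id=group.gene_id,
                            chrom=group.chrom,
                            strand=group.strand,
                            end_supported=end,
                            motif=motif,
                            distance=distance,
                            seq_start=p,
                            start=g_start,
                            end=g_end,
                            is_proximal=is_proximal,
                        )
                    )
    hits.sort(key=lambda h: (h.seq_start, h.motif, h.end_supported))
    return hits


def scan_ugua(
    group: UTRIsoformGroup, proximal_pas: PASHit, params: ScreenParams
) -> tuple[bool, list[int]]:
    """Report UGUA (TGTA) occurrences near the proximal PAS and judge c3.

    Offsets are measured from the motif start to the PAS start on the distal
    (long-isoform) sequence so a downstream flank exists; occurrences with
    |offset| <= ugua_radius are kept, windows truncated at UTR bounds simply
    shrink. c3 is true iff the configured rule holds.
    """
    seq = group.distal_sequence
    pas_start = proximal_pas.seq_start
    offsets = [
        p - pas_start
        for p in find_motif(seq, UGUA_DNA)
        if abs(p - pas_start) <= params.ugua_radius
    ]
    if params.ugua_rule == "flanking_both_sides":
        c3 = any(o < 0 for o in offsets) and any(o > 0 for o in offsets)
    else:
        c3 = len(offsets) >= 2
    return c3, offsets


def _proximal_pas(hits: list[PASHit], group: UTRIsoformGroup) -> PASHit | None:
    """PAS anchoring c3: supports the 5'-most non-distal end; nearest wins ties."""
    proximal_hits = [h for h in hits if h.is_proximal]
    if not proximal_hits:
        return None
    first_end = group.ends[0]
    first = [h for h in proximal_hits if h.end_supported == first_end]
    pool = first or proximal_hits
    return min(pool, key=lambda h: (h.distance, h.seq_start))


def evaluate_gene(group: UTRIsoformGroup, params: ScreenParams) -> CandidateVerdict:
    """Apply all three criteria to one UTR isoform group."""
    c1 = group.is_multi
    hits = scan_pas(group, params)
    supported_ends = {h.end_supported for h in hits}
    if params.pas_at_every_end:
        c2 = all(e in supported_ends for e in group.ends)
    else:
        c2 = bool(supported_ends)
    anchor = _proximal_pas(hits, group)
    if anchor is None:
        c3, offsets = False, []
    else:
        c3, offsets = scan_ugua(group, anchor, params)
    flags = (c1, c2, c3)
    candidate = all(flags) if params.criteria_mode == "all" else any(flags)
    return CandidateVerdict(
        gene_id=group.gene_id,
        c1=c1,
        c2=c2,
        c3=c3,
        candidate=candidate,
        pas_hits=hits,
        ugua_offsets=offsets,
    )


def _best_verdict(verdicts: list[CandidateVerdict]) -> CandidateVerdict:
    """Gene-level verdict when a gene has several UTR start groups."""
    return max(
        verdicts,
        key=lambda v: (v.candidate, v.c1 + v.c2 + v.c3, len(v.pas_hits)),
    )


def screen_groups(
    groups: list[UTRIsoformGroup], params: ScreenParams
) -> list[CandidateVerdict]:
    """One verdict per gene; multi-group genes keep their best-scoring group."""
    by_gene: dict[str, list[CandidateVerdict]] = {}
    for g in groups:
        by_gene.setdefault(g.gene_id, []).append(evaluate_gene(g, params))
    return [_best_verdict(by_gene[g]) for g in sorted(by_gene)]


def verdicts_to_table(
    verdicts: list[CandidateVerdict],
    expressed_gene_list: set[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {
            "gene_id": v.gene_id,
            "c1_multi_utr": v.c1,
            "c2_pas_in_window": v.c2,
            "c3_ugua_flanking": v.c3,
            "candidate": v.candidate,
            "n_pas_hits": len(v.pas_hits),
            "n_ugua_near_pas": len(v.ugua_offsets),
        }
        if expressed_gene_list is not None:
            row["expressed"] = v.gene_id in expressed_gene_list
        rows.append(row)
    cols = [
        "gene_id",
        "c1_multi_utr",
        "c2_pas_in_window",
        "c3_ugua_flanking",
        "candidate",
        "n_pas_hits",
        "n_ugua_near_pas",
    ]
    if expressed_gene_list is not None:
        cols.append("expressed")
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values("gene_id", ignore_index=True)


def run_screen(
    annotation_path,
    genome_path,
    params: ScreenParams | None = None,
    expressed_gene_list: set[str] | None = None,
    bed_path=None,
):
    """Screen a genome+annotation; return (candidate table, verdict list).

    When ``expressed_gene_list`` is given, the table gains an ``expressed``
    column and the candidate sub-table returned by
    :func:`filter_expressed_candidates` is restricted to that list. PAS hits
    can optionally be written as BED6.
    """
    params = params or ScreenParams()
    genome = read_fasta(genome_path)
    models = read_gtf(annotation_path)
    for m in models:
        if m.chrom not in genome:
            raise KeyError(f"chromosome {m.chrom!r} missing from genome FASTA")
    groups = group_utr_isoforms(models, genome)
    verdicts = screen_groups(groups, params)
    table = verdicts_to_table(verdicts, expressed_gene_list)
    if bed_path is not None:
        all_hits = [h for v in verdicts for h in v.pas_hits]
        write_bed(all_hits, bed_path)
    return table, verdicts


def filter_expressed_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Candidates intersected with the user-supplied expressed-gene list."""
    if "expressed" not in table.columns:
        raise ValueError("table has no 'expressed' column; pass expressed_gene_list")
    return table[table["candidate"] & table["expressed"]].reset_index(drop=True)
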