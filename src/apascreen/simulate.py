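"""Seeded synthetic genomes, annotations and qPCR-style expression tables.

The generator builds toy loci that realize — or deliberately violate — each
inclusion criterion of the APA candidate screen, so the whole pipeline can be
exercised against exact ground truth:

* ``positive`` genes carry two 3'UTR isoforms sharing a 5' start, a PAS
  hexamer planted in the 10-60 nt window upstream of both cleavage ends, and
  UGUA elements flanking the proximal PAS within 200 nt;
* ``decoy_c1`` genes have a single 3'UTR isoform (criterion 1 fails; with no
  proximal end, the UGUA criterion has no anchor and is false as well);
* ``decoy_c2`` genes keep the two-isoform structure but the distal end's PAS
  sits outside the 10-60 nt window;
* ``decoy_c3`` genes lack UGUA elements near the proximal PAS;
* ``negative`` genes are single-isoform with no planted motifs at all.

Background sequence is i.i.d. uniform ACGT with every accidental PAS-like
hexamer (AATAAA/ATTAAA) or TGTA inside the scanned 3'UTR span rewritten, so
truth labels are exact rather than probabilistic. Expression tables emulate
replicated long/total amplicon qPCR under control, NUDT21-overexpression and
two knockdown conditions, with Ct values derived from latent abundances via
Ct = -log_b(abundance) (b = PCR efficiency, 2 by default) plus Gaussian
noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import revcomp, write_gtf_line

SCRUB_MOTIFS = ("AATAAA", "ATTAAA", "TGTA")
PLANT_PAS = "AATAAA"
PLANT_UGUA = "TGTA"
CLASSES = ("positive", "decoy_c1", "decoy_c2", "decoy_c3", "negative")
CONDITIONS = ("control", "OE", "KD1", "KD2")

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Lengths and offsets are in nucleotides. ``pas_offset`` is the distance
    from the planted PAS hexamer's 3' edge to the cleavage end; it must lie
    in the screen's 10-60 nt window, while ``decoy_pas_offset`` must lie
    outside it. ``ugua_offsets`` are signed positions of planted UGUA
    elements relative to the proximal PAS start (negative = upstream).
    ``decoy_mix`` gives per-class fractions of the total gene count; the
    remainder after positives and decoys is motif-free negatives.

    The expression block mirrors a triplicate qPCR design: a latent
    long/total ratio of ``baseline_ratio`` that moves to ``baseline_ratio *
    oe_fold`` under overexpression and ``baseline_ratio * kd_fold`` under
    each knockdown, read out as Ct values with noise ``ct_noise_sd``.
    """

    n_genes: int = 200
    frac_positive: float = 0.2
    decoy_mix: dict = field(
        default_factory=lambda: {
            "decoy_c1": 0.2,
            "decoy_c2": 0.2,
            "decoy_c3": 0.2,
        }
    )
    utr_short_len: int = 250
    utr_long_len: int = 600
    pas_offset: int = 30
    decoy_pas_offset: int = 5
    ugua_offsets: tuple[int, ...] = (-80, 80)
    strand_policy: str = "plus_only"
    cds_len: int = 300
    intergenic_spacing: int = 500
    seed: int = 0
    # expression block
    n_replicates: int = 3
    baseline_ratio: float = 0.5
    oe_fold: float = 1.5
    kd_fold: float = 0.5
    ct_noise_sd: float = 0.2
    pcr_efficiency: float = 2.0
    total_abundance: float = 1e-6

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.utr_long_len > self.utr_short_len > self.pas_offset + 6:
            raise ConfigError(
                "need utr_long_len > utr_short_len > pas_offset + 6, got "
                f"{self.utr_long_len}/{self.utr_short_len}/{self.pas_offset}"
            )
        if not 10 <= self.pas_offset <= 60:
            raise ConfigError(f"pas_offset {self.pas_offset} outside [10, 60]")
        if 10 <= self.decoy_pas_offset <= 60:
            raise ConfigError(
                f"decoy_pas_offset {self.decoy_pas_offset} must lie outside [10, 60]"
            )
        if not any(o < 0 for o in self.ugua_offsets) or not any(
            o > 0 for o in self.ugua_offsets
        ):
            raise ConfigError("ugua_offsets must flank the PAS (one <0 and one >0)")
        for o in self.ugua_offsets:
            if abs(o) > 200:
                raise ConfigError(f"UGUA offset {o} exceeds the 200 nt radius")
        if not 0 <= self.frac_positive <= 1:
            raise ConfigError("frac_positive must be in [0, 1]")
        mix_total = self.frac_positive + sum(self.decoy_mix.values())
        if mix_total > 1 + 1e-9:
            raise ConfigError("frac_positive + decoy_mix fractions exceed 1")
        if self.strand_policy not in {"plus_only", "random", "minus_only"}:
            raise ConfigError(f"unknown strand_policy {self.strand_policy!r}")
        if not 0 < self.baseline_ratio < 1:
            raise ConfigError("baseline_ratio must be in (0, 1)")
        if self.oe_fold < 1 or self.kd_fold > 1 or self.kd_fold <= 0:
            raise ConfigError("need oe_fold >= 1 and 0 < kd_fold <= 1")
        if self.baseline_ratio * self.oe_fold > 1:
            raise ConfigError(
                "oe_fold * baseline_ratio exceeds 1: the long/total ratio "
                "cannot exceed 1 when the long amplicon nests inside total"
            )
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be >= 0")
        if not 1 < self.pcr_efficiency <= 2:
            raise ConfigError("pcr_efficiency must be in (1, 2]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def _class_counts(config: SimConfig) -> dict[str, int]:
    counts = {"positive": int(round(config.frac_positive * config.n_genes))}
    for cls in ("decoy_c1", "decoy_c2", "decoy_c3"):
        counts[cls] = int(round(config.decoy_mix.get(cls, 0.0) * config.n_genes))
    assigned = sum(counts.values())
    if assigned > config.n_genes:
        raise ConfigError("class fractions round to more genes than n_genes")
    counts["negative"] = config.n_genes - assigned
    return counts


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _plant(codes: np.ndarray, pos: int, motif: str) -> None:
    idx = ["ACGT".index(c) for c in motif]
    codes[pos : pos + len(motif)] = idx


def _scrub(
    codes: np.ndarray,
    region: tuple[int, int],
    planted: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Rewrite accidental scan motifs inside ``region``, sparing planted spans."""
    lo, hi = region
    protected = np.zeros(len(codes), dtype=bool)
    for s, e in planted:
        protected[s:e] = True
    for _ in range(max_rounds):
        seq = "".join(_BASES[codes[lo:hi]])
        dirty = False
        for motif in SCRUB_MOTIFS:
            start = seq.find(motif)
            while start != -1:
                s, e = lo + start, lo + start + len(motif)
                planted_here = any(s >= ps and e <= pe for ps, pe in planted)
                if not planted_here:
                    mutable = [p for p in range(s, e) if not protected[p]]
                    if mutable:
                        p = mutable[len(mutable) // 2]
                        codes[p] = (codes[p] + int(rng.integers(1, 4))) % 4
                        dirty = True
                start = seq.find(motif, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motifs within the rewrite budget")


def _build_gene_sense_sequence(
    config: SimConfig, cls: str, rng: np.random.Generator
) -> str:
    """Sense-strand sequence of one locus (CDS + full long-UTR span)."""
    L = config.cds_len + config.utr_long_len
    codes = _random_seq(rng, L)
    u0 = config.cds_len  # UTR start in sense-local coords
    short_end = u0 + config.utr_short_len
    long_end = u0 + config.utr_long_len
    planted: list[tuple[int, int]] = []

    def plant(pos: int, motif: str) -> None:
        _plant(codes, pos, motif)
        planted.append((pos, pos + len(motif)))

    pas_prox = short_end - config.pas_offset - len(PLANT_PAS)
    if cls == "positive":
        plant(pas_prox, PLANT_PAS)
        plant(long_end - config.pas_offset - len(PLANT_PAS), PLANT_PAS)
        for off in config.ugua_offsets:
            plant(pas_prox + off, PLANT_UGUA)
    elif cls == "decoy_c1":
        # single isoform: in-window PAS at its only end, UGUAs around it
        plant(pas_prox, PLANT_PAS)
        for off in config.ugua_offsets:
            plant(pas_prox + off, PLANT_UGUA)
    elif cls == "decoy_c2":
        # distal PAS shifted out of the 10-60 nt window
        plant(pas_prox, PLANT_PAS)
        plant(long_end - config.decoy_pas_offset - len(PLANT_PAS), PLANT_PAS)
        for off in config.ugua_offsets:
            plant(pas_prox + off, PLANT_UGUA)
    elif cls == "decoy_c3":
        plant(pas_prox, PLANT_PAS)
        plant(long_end - config.pas_offset - len(PLANT_PAS), PLANT_PAS)
    elif cls == "negative":
        pass
    else:  # pragma: no cover
        raise ValueError(cls)

    # overlapping planted spans would corrupt each other
    for (s1, e1) in planted:
        for (s2, e2) in planted:
            if (s1, e1) < (s2, e2) and s2 < e1 and s1 < e2:
                raise ConfigError(
                    "planted motif spans overlap; adjust pas_offset/ugua_offsets"
                )
    _scrub(codes, (u0, long_end), planted, rng)
    return "".join(_BASES[codes])


_EXPECTED_FLAGS = {
    "positive": (True, True, True),
    "decoy_c1": (False, True, False),
    "decoy_c2": (True, False, True),
    "decoy_c3": (True, True, False),
    "negative": (False, False, False),
}


def generate_genome(config: SimConfig) -> tuple[str, str, pd.DataFrame]:
    """Build (FASTA text, GTF text, truth table) for one seeded dataset.

    The truth table has one row per gene: its class, the criteria flags the
    screen is expected to report, and whether its expression responds to
    NUDT21 perturbation (planted only for positives).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    classes: list[str] = []
    for cls in CLASSES:
        classes.extend([cls] * counts[cls])

    spacing = config.intergenic_spacing
    gene_len = config.cds_len + config.utr_long_len
    chrom_parts: list[str] = []
    gtf = io.StringIO()
    gtf.write(f"#!apascreen synthetic annotation\n#!seed {config.seed}\n")
    truth_rows = []
    cursor = 0
    chrom = "chr1"

    for i, cls in enumerate(classes):
        gene_id = f"g{i + 1:04d}"
        sense = _build_gene_sense_sequence(config, cls, rng)
        if config.strand_policy == "plus_only":
            strand = "+"
        elif config.strand_policy == "minus_only":
            strand = "-"
        else:
            strand = "+" if rng.integers(0, 2) == 0 else "-"
        pad = "".join(_BASES[_random_seq(rng, spacing)])
        chrom_parts.append(pad)
        cursor += spacing
        g0 = cursor
        chrom_parts.append(sense if strand == "+" else revcomp(sense))
        cursor += gene_len

        def gmap(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return g0 + a, g0 + b
            return g0 + gene_len - b, g0 + gene_len - a

        u0 = config.cds_len
        n_isoforms = 2 if cls in ("positive", "decoy_c2", "decoy_c3") else 1
        tx_ends = [u0 + config.utr_short_len]
        if n_isoforms == 2:
            tx_ends.append(u0 + config.utr_long_len)
        gene_span = gmap(0, max(tx_ends))
        attrs = f'gene_id "{gene_id}";'
        gtf.write(write_gtf_line(chrom, "sim", "gene", *gene_span, strand, attrs))
        for k, tend in enumerate(tx_ends, start=1):
            tid = f"{gene_id}.t{k}"
            tattrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
            for feat, (a, b) in (
                ("transcript", (0, tend)),
                ("exon", (0, tend)),
                ("CDS", (0, u0)),
                ("three_prime_utr", (u0, tend)),
            ):
                gtf.write(write_gtf_line(chrom, "sim", feat, *gmap(a, b), strand, tattrs))
        c1, c2, c3 = _EXPECTED_FLAGS[cls]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "c1": c1,
                "c2": c2,
                "c3": c3,
                "expected_responsive": cls == "positive",
            }
        )

    chrom_parts.append("".join(_BASES[_random_seq(rng, spacing)]))
    chrom_seq = "".join(chrom_parts)
    fasta = io.StringIO()
    fasta.write(f">{chrom} apascreen synthetic genome seed={config.seed}\n")
    for j in range(0, len(chrom_seq), 60):
        fasta.write(chrom_seq[j : j + 60] + "\n")
    truth = pd.DataFrame(truth_rows)
    return fasta.getvalue(), gtf.getvalue(), truth


def generate_expression(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Replicated long/total Ct measurements under control/OE/KD conditions.

    Responsive genes shift their latent long/total ratio by ``oe_fold`` under
    overexpression and ``kd_fold`` under each knockdown; non-responsive genes
    keep the baseline ratio everywhere. Ct = -log_b(abundance) + N(0, sd).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base = config.pcr_efficiency
    log_base = np.log(base)
    rows = []
    for _, g in truth.iterrows():
        responsive = bool(g["expected_responsive"])
        for cond in CONDITIONS:
            ratio = config.baseline_ratio
            if responsive and cond == "OE":
                ratio *= config.oe_fold
            elif responsive and cond.startswith("KD"):
                ratio *= config.kd_fold
            ab = {"total": config.total_abundance, "long": ratio * config.total_abundance}
            for rep in range(1, config.n_replicates + 1):
                for amplicon in ("long", "total"):
                    ct = -np.log(ab[amplicon]) / log_base
                    if config.ct_noise_sd > 0:
                        ct += rng.normal(0.0, config.ct_noise_sd)
                    rows.append(
                        {
                            "gene_id": g["gene_id"],
                            "condition": cond,
                            "replicate": rep,
                            "amplicon": amplicon,
                            "value_kind": "Ct",
                            "value": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


def write_dataset(config: SimConfig, out_dir) -> dict[str, str]:
    """Write genome.fa, annotation.gtf, truth.tsv and expression.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta, gtf, truth = generate_genome(config)
    expr = generate_expression(config, truth)
    paths = {
        "genome": str(out / "genome.fa"),
        "annotation": str(out / "annotation.gtf"),
        "truth": str(out / "truth.tsv"),
        "expression": str(out / "expression.tsv"),
    }
    (out / "genome.fa").write_text(fasta)
    (out / "annotation.gtf").write_text(gtf)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    return paths
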