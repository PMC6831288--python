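"""Reading genomes and annotations, and deriving strand-aware 3'UTR models.

All internal coordinates are 0-based half-open; GTF's 1-based inclusive
coordinates are converted at the I/O boundary. A transcript's *cleavage end*
is the genomic boundary of its 3' terminus in half-open convention: the
interval end for a plus-strand transcript, the interval start for a
minus-strand one. "Start" of a 3'UTR always means its 5' boundary in
transcription order, which is the only reading under which alternative
polyadenylation produces isoforms with the same start but different ends.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One annotated transcript with its derived 3'UTR.

    Intervals are 0-based half-open and sorted 5'->3' in transcription order
    (i.e. descending genomic coordinate on the minus strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def cleavage_end(self) -> int:
        """Genomic boundary of the transcript 3' terminus (half-open)."""
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return hi if self.strand == "+" else lo

    @property
    def utr3_length(self) -> int:
        return sum(e - s for s, e in self.utr3)


@dataclass
class UTRIsoformGroup:
    """Per-gene 3'UTR isoforms sharing a 5' start with distinct 3' ends.

    ``ends`` is ordered proximal -> distal in transcription order, so on the
    minus strand the proximal end is the numerically larger coordinate.
    ``sequences`` are sense-strand 3'UTR sequences, one per end, in the same
    order; each is a prefix of the next since all isoforms share the start.
    """

    gene_id: str
    chrom: str
    strand: str
    utr_start: int
    ends: list[int]
    sequences: list[str]

    @property
    def is_multi(self) -> bool:
        return len(self.ends) >= 2

    @property
    def distal_sequence(self) -> str:
        return self.sequences[-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence map.

    Names are truncated at the first whitespace. Duplicate names and empty
    records are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise ValueError(f"duplicate FASTA record name: {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {name!r}")
        seqs[name] = seq
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as 60-column-wrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _prevalidate_gtf_lines(lines: Iterable[str]) -> None:
    """Cheap line-numbered sanity pass so errors can cite the offending line."""
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise AnnotationError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        if fields[6] not in {"+", "-"}:
            raise AnnotationError(
                f"GTF line {lineno}: unknown strand symbol {fields[6]!r}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise AnnotationError(f"GTF line {lineno}: non-integer coordinates") from None
        if start < 1 or end < start:
            raise AnnotationError(
                f"GTF line {lineno}: invalid coordinate range {start}-{end}"
            )


def _iv(feature: gffutils.Feature) -> Interval:
    # GTF 1-based inclusive -> 0-based half-open
    return (feature.start - 1, feature.end)


def _transcription_sort(intervals: list[Interval], strand: str) -> list[Interval]:
    return sorted(intervals, reverse=(strand == "-"))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF2.2 annotation into transcript models with derived 3'UTRs.

    Transcripts carrying explicit ``three_prime_utr`` features use them;
    otherwise the 3'UTR is derived strand-aware as the exonic span between the
    CDS 3' boundary and the transcript 3' end. Transcripts with neither CDS
    nor explicit 3'UTR get an empty ``utr3`` (logged as a warning).
    """
    text = Path(path).read_text()
    _prevalidate_gtf_lines(text.splitlines())
    if not any(
        line.strip() and not line.startswith("#") for line in text.splitlines()
    ):
        return []  # empty annotation: no transcripts
    with tempfile.NamedTemporaryFile("w", suffix=".db", delete=True) as tmp:
        db = gffutils.create_db(
            text,
            tmp.name,
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        models = _models_from_db(db)
    return models


def _models_from_db(db: gffutils.FeatureDB) -> list[TranscriptModel]:
    models = []
    for tx in db.features_of_type("transcript", order_by="start"):
        strand = tx.strand
        exons = [_iv(f) for f in db.children(tx, featuretype="exon")]
        cds = [_iv(f) for f in db.children(tx, featuretype="CDS")]
        utr3 = [_iv(f) for f in db.children(tx, featuretype="three_prime_utr")]
        if not exons:
            # single-feature transcripts: treat the transcript span as one exon
            exons = [_iv(tx)]
        tx_lo = min(s for s, _ in exons)
        tx_hi = max(e for _, e in exons)
        for s, e in exons:
            if s < tx.start - 1 or e > tx.end:
                raise AnnotationError(
                    f"exon [{s},{e}) outside transcript bounds for {tx.id!r}"
                )
        if not utr3:
            utr3 = _derive_utr3(exons, cds, strand, tx_lo, tx_hi)
        model = TranscriptModel(
            transcript_id=tx.attributes["transcript_id"][0],
            gene_id=tx.attributes["gene_id"][0],
            chrom=tx.seqid,
            strand=strand,
            exons=_transcription_sort(exons, strand),
            cds=_transcription_sort(cds, strand),
            utr3=_transcription_sort(utr3, strand),
        )
        if not model.utr3:
            logger.warning(
                "transcript %s has neither CDS nor three_prime_utr; empty 3'UTR",
                model.transcript_id,
            )
        models.append(model)
    return models


def _derive_utr3(
    exons: list[Interval], cds: list[Interval], strand: str, tx_lo: int, tx_hi: int
) -> list[Interval]:
    """Exonic span between the CDS 3' boundary and the transcript 3' end."""
    if not cds:
        return []
    utr3 = []
    if strand == "+":
        cds_end = max(e for _, e in cds)
        for s, e in sorted(exons):
            s2 = max(s, cds_end)
            if s2 < e:
                utr3.append((s2, e))
    else:
        cds_start = min(s for s, _ in cds)
        for s, e in sorted(exons):
            e2 = min(e, cds_start)
            if s < e2:
                utr3.append((s, e2))
    return utr3


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def utr3_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Sense-strand 3'UTR sequence, exon slices concatenated 5'->3'."""
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} missing from genome FASTA")
    chrom_seq = genome[model.chrom]
    parts = []
    for s, e in model.utr3:
        piece = chrom_seq[s:e]
        if model.strand == "-":
            piece = revcomp(piece)
        parts.append(piece)
    return "".join(parts)


def _utr_start(model: TranscriptModel) -> int:
    """Genomic 5' boundary of the 3'UTR in transcription order (half-open)."""
    lo = min(s for s, _ in model.utr3)
    hi = max(e for _, e in model.utr3)
    return lo if model.strand == "+" else hi


def group_utr_isoforms(
    models: list[TranscriptModel], genome: dict[str, str]
) -> list[UTRIsoformGroup]:
    """Group per-gene 3'UTR isoforms by shared 5' start.

    One group per gene per distinct UTR start. Isoforms with identical
    (start, end) collapse to one. Ends are ordered proximal -> distal in
    transcription order; sequences are sense-strand. Genes spanning multiple
    chromosomes or strands are rejected.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if not m.utr3:
            continue
        by_gene.setdefault(m.gene_id, []).append(m)

    groups: list[UTRIsoformGroup] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chroms = {m.chrom for m in txs}
        strands = {m.strand for m in txs}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {gene_id!r} has transcripts on multiple chromosomes/strands"
            )
        strand = txs[0].strand
        by_start: dict[int, dict[int, TranscriptModel]] = {}
        for m in txs:
            by_start.setdefault(_utr_start(m), {})[m.cleavage_end] = m
        for start in sorted(by_start):
            end_map = by_start[start]
            # proximal -> distal: ascending on +, descending on -
            ends = sorted(end_map, reverse=(strand == "-"))
            seqs = [utr3_sequence(end_map[e], genome) for e in ends]
            groups.append(
                UTRIsoformGroup(
                    gene_id=gene_id,
                    chrom=txs[0].chrom,
                    strand=strand,
                    utr_start=start,
                    ends=ends,
                    sequences=seqs,
                )
            )
    return groups


def write_bed(hits, path: str | Path) -> None:
    """Write motif hits as BED6 (0-based half-open; name = gene_id:motif)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.gene_id}:{h.motif}\t0\t{h.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    """Read BED6 back into (chrom, start, end, name, score, strand) tuples."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        c, s, e, n, sc, st = line.split("\t")
        rows.append((c, int(s), int(e), n, int(sc), st))
    return rows


def write_gtf_line(
    chrom: str,
    source: str,
    feature: str,
    start0: int,
    end0: int,
    strand: str,
    attrs: str,
) -> str:
    """Format one GTF line from 0-based half-open coordinates."""
    return f"{chrom}\t{source}\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def make_fasta_record(name: str, seq: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=name, description=description)
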