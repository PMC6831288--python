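"""In-silico 3'RACE: predict amplicon sizes for proximal vs distal PAS usage.

3'RACE reverse-transcribes mRNA with an anchored oligo-dT primer (an adapter
followed by a T-run) and amplifies with a gene-specific forward primer plus
a universal reverse primer matching the adapter. Each 3'UTR isoform then
yields one band whose size is

    length = (forward-primer 5' start -> cleavage end) + polyA_len + adapter_len

so proximal vs distal poly(A)-site usage maps to a band-size difference
exactly equal to the distance between the two cleavage ends. Primer binding
is exact-match only; this is a validation-scale design tool, not a PCR
thermodynamics model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import UTRIsoformGroup, revcomp
from .screen import find_motif

# anchored oligo-dT RT primer and the matching universal reverse primer
DEFAULT_RT_PRIMER = "CCAGTGAGCAGAGTGACGAGGACTCGAGCTCAAGCTTTTTTTTTTTTTTTTT"
DEFAULT_UNIVERSAL_REVERSE = "CCAGTGAGCAGAGTGACG"


def adapter_of(rt_primer: str) -> str:
    """The RT primer minus its trailing oligo-dT run."""
    return re.sub(r"T+$", "", rt_primer)


def polya_run_of(rt_primer: str) -> int:
    m = re.search(r"T+$", rt_primer)
    return len(m.group(0)) if m else 0


@dataclass
class PrimerSet:
    """RT/universal primers plus per-gene forward primers.

    ``gene_forward`` maps gene_id -> {primer_id: sense-strand sequence}. The
    universal reverse primer must be a prefix of the RT primer's adapter
    portion; all primers must be 15-60 nt.
    """

    rt_primer: str = DEFAULT_RT_PRIMER
    universal_reverse: str = DEFAULT_UNIVERSAL_REVERSE
    gene_forward: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.rt_primer = self.rt_primer.upper()
        self.universal_reverse = self.universal_reverse.upper()
        adapter = adapter_of(self.rt_primer)
        if not adapter.startswith(self.universal_reverse):
            raise ValueError(
                "universal_reverse must be a prefix of the RT primer adapter"
            )
        for name, seq in [("rt_primer", self.rt_primer),
                          ("universal_reverse", self.universal_reverse)] + [
            (f"{g}:{pid}", s)
            for g, d in self.gene_forward.items()
            for pid, s in d.items()
        ]:
            if not 15 <= len(seq) <= 60:
                raise ValueError(f"primer {name} length {len(seq)} outside 15-60 nt")

    @property
    def adapter(self) -> str:
        return adapter_of(self.rt_primer)


@dataclass
class AmpliconPrediction:
    """One predicted RACE band."""

    gene_id: str
    end_used: int  # genomic cleavage-end coordinate
    is_distal: bool
    primer_id: str
    length: int
    sequence: str


def predict_amplicons(
    group: UTRIsoformGroup,
    primers: PrimerSet,
    polya_len: int | None = None,
) -> list[AmpliconPrediction]:
    """Predict RACE amplicons for every (forward primer, isoform end) pair.

    The cDNA 3' region is modeled as isoform sequence + A*polya_len +
    reverse-complemented adapter; ``polya_len`` defaults to the RT primer's
    oligo-dT run length. Each forward primer must match the distal isoform
    sequence exactly once (sense strand); ambiguous or absent binding is an
    error listing the match positions.
    """
    if polya_len is None:
        polya_len = polya_run_of(primers.rt_primer)
    adapter_rc = revcomp(primers.adapter)
    forward = primers.gene_forward.get(group.gene_id, {})
    predictions: list[AmpliconPrediction] = []
    template = group.distal_sequence
    n = len(group.ends)
    for primer_id in sorted(forward):
        fseq = forward[primer_id].upper()
        matches = find_motif(template, fseq)
        if len(matches) != 1:
            raise ValueError(
                f"forward primer {group.gene_id}:{primer_id} has "
                f"{len(matches)} exact matches at positions {matches}; need 1"
            )
        start = matches[0]
        for idx, (end, seq) in enumerate(zip(group.ends, group.sequences)):
            if start + len(fseq) > len(seq):
                continue  # primer site not 5' of this cleavage end
            amplicon = seq[start:] + "A" * polya_len + adapter_rc
            predictions.append(
                AmpliconPrediction(
                    gene_id=group.gene_id,
                    end_used=end,
                    is_distal=(idx == n - 1),
                    primer_id=primer_id,
                    length=len(amplicon),
                    sequence=amplicon,
                )
            )
    return predictions


def band_distinguishability(
    predictions: list[AmpliconPrediction], min_gap: int = 50
) -> dict[str, bool]:
    """True per gene iff all pairwise band-size gaps are >= min_gap.

    A single (or no) band is vacuously distinguishable. This is a coarse gel
    resolution heuristic for primer-design sanity checks.
    """
    by_gene: dict[str, list[int]] = {}
    for p in predictions:
        by_gene.setdefault(p.gene_id, []).append(p.length)
    out = {}
    for gene, lengths in by_gene.items():
        out[gene] = all(
            abs(x - y) >= min_gap
            for i, x in enumerate(lengths)
            for y in lengths[i + 1 :]
        )
    return out
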