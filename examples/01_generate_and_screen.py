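"""Generate a seeded synthetic genome and run the three-criteria APA screen.

The generator plants the exact motif geometry the screen looks for
(two 3'UTR isoforms sharing a start, a PAS hexamer 10-60 nt upstream of each
cleavage end, UGUA elements flanking the proximal PAS within 200 nt) in
"positive" genes, and breaks exactly one criterion in each decoy class.
"""

import tempfile
from pathlib import Path

from apascreen import SimConfig, generate_genome, run_screen

cfg = SimConfig(n_genes=50, frac_positive=0.2, seed=7, strand_policy="random")
fasta, gtf, truth = generate_genome(cfg)

with tempfile.TemporaryDirectory() as d:
    (Path(d) / "genome.fa").write_text(fasta)
    (Path(d) / "annotation.gtf").write_text(gtf)
    table, verdicts = run_screen(Path(d) / "annotation.gtf", Path(d) / "genome.fa")

merged = table.merge(truth, on="gene_id")
print(merged[["gene_id", "class", "c1_multi_utr", "c2_pas_in_window",
              "c3_ugua_flanking", "candidate"]].head(12).to_string(index=False))
print(f"\ncandidates: {int(table.candidate.sum())} "
      f"(planted positives: {(truth['class'] == 'positive').sum()})")
agree = (
    (merged.c1_multi_utr == merged.c1)
    & (merged.c2_pas_in_window == merged.c2)
    & (merged.c3_ugua_flanking == merged.c3)
).mean()
print(f"criteria flags matching planted truth: {agree:.0%}")
# Every candidate should be a planted positive and every flag should match
# the generator's ground truth -- the screen reads the motif geometry back
# exactly, on either strand.
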