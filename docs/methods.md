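# Methods

## The screening model

CFIm25/NUDT21 binds UGUA elements in pre-mRNA and, as part of the CFIm
complex, biases poly(A)-site choice toward distal sites; losing it shifts
usage toward proximal sites and shortens 3′UTRs. The screen encodes the
sequence geometry this model predicts for a regulable gene:

* **c1 — isoform structure.** The gene must produce ≥ 2 3′UTR isoforms with
  the same 5′ start and different 3′ ends. "Start" is the 5′ boundary of the
  3′UTR in transcription order: APA changes where the UTR *ends*, not where
  it begins, so isoforms from alternative last exons (different starts) are
  grouped separately and do not satisfy c1 on their own.
* **c2 — poly(A) signal placement.** Each retained cleavage end needs a PAS
  hexamer whose 3′-most base lies 10–60 nt (inclusive) upstream of that
  end. The distance is anchored on the cleavage end, not on the UTR start,
  because PAS hexamers function upstream of cleavage sites. The default
  motif set is {AATAAA, ATTAAA} (canonical signal plus its strongest
  variant, written as sense-strand DNA); `EXTENDED_PAS_MOTIFS` adds the ten
  further common human variants for a looser reading of "similar sequence".
  By default a PAS is required at *every* end (both sites must be genuine
  poly(A) sites); `pas_at_every_end=False` relaxes this to any end.
* **c3 — CFIm binding geometry.** The proximal PAS must be "surrounded" by
  UGUA (DNA: TGTA) elements: by default ≥ 1 within 200 nt on each side
  (`flanking_both_sides`), with `any_two` (≥ 2 within 200 nt regardless of
  side) as the alternate reading. Offsets are measured motif-start to
  PAS-start on the *distal* isoform sequence so a downstream flank exists;
  windows clipped by UTR boundaries shrink rather than error. The anchoring
  proximal PAS is the one supporting the 5′-most non-distal cleavage end,
  ties broken by smallest distance-to-end — deterministic and unique.
  A single-isoform gene has no proximal end, so c3 is vacuously false.

Criteria combine conjunctively by default (`criteria_mode="all"`): the
biological model is a multi-ended UTR whose proximal site carries CFIm
geometry, and each criterion alone is far too weak a filter. `"any"` is
available for the disjunctive reading.

Coordinates are 0-based half-open internally; GTF's 1-based inclusive
coordinates are converted at the I/O boundary, and a transcript's cleavage
end is its 3′ boundary in half-open convention (interval end on +, interval
start on −). Motifs stated in RNA are matched on the sense strand of the
DNA, so minus-strand UTRs are reverse-complemented before scanning; the
screen is therefore strand-symmetric by construction, and tested to be.

## Quantification and the responsiveness rule

qPCR Ct values convert to relative abundances as `base**(-Ct)` with base =
PCR efficiency (2 for a perfectly efficient reaction — the 2^−ΔΔCT
convention). The long/total ratio R divides the long-isoform-specific
amplicon's abundance by that of an amplicon common to all isoforms; because
both amplicons share one template, no reference-gene normalization is
applied to R by default (it cancels), though `ddct_relative` supports the
full four-Ct form with a reference and calibrator.

A gene is *responsive* when its mean ratio strictly rises under
overexpression and strictly falls under knockdown, with a fold margin:
R_OE > R_ctrl, R_OE ≥ min_fold·R_ctrl, and for every (default) or any
knockdown R_KD < R_ctrl, R_KD ≤ R_ctrl/min_fold. The direction test is
strict so that a perfectly flat profile is never called responsive even at
min_fold = 1; the margin (default 1.2) is this package's parameterization of
"increased/decreased" — the underlying rule is directional and states no
magnitude — and guards against replicate noise. All knockdowns must agree by
default because a responsive call should be reproducible across independent
shRNAs. Mann–Whitney p-values (two-sided) are reported for each
condition-vs-control comparison when both groups have ≥ 3 replicates, but do
not gate the call: the classification is directional, and with triplicates
the smallest attainable two-sided exact p is 0.1, so a significance gate
would empty the screen. p-values are reported raw, without multiple-testing
correction across genes.

`rank_test` enumerates all C(n₁+n₂, n₁) assignments exactly (tie-tolerant,
two-sided by distance from the null center U = n₁n₂/2) when the combined
sample is ≤ 12, and uses the tie-corrected normal approximation (scipy)
above that. Completely tied data returns p = 1.

## 3′RACE prediction

Reverse transcription with an anchored oligo-dT primer (a 35 nt adapter
followed by 17 T's; the universal reverse primer is the adapter's first
18 nt) produces cDNA modeled as isoform sequence + A×poly(A) +
reverse-complemented adapter. Each gene-specific forward primer must match
the distal isoform sequence exactly once (exact matching only — this is a
validation-scale design aid, not a thermodynamic PCR model); one amplicon is
predicted per isoform end the primer lies 5′ of, with

    length = (primer 5′ start → cleavage end) + polyA_len + adapter_len.

The poly(A) and adapter terms are constant per primer set, so the band-size
gap between proximal and distal products equals the cleavage-end distance
exactly. `band_distinguishability` flags genes whose pairwise band gaps all
exceed a gel-resolution floor (default 50 nt — a conservative figure for
resolving bands on a 1% agarose gel).

## The synthetic-data generator

`SimConfig` defaults define the simulated study: 200 genes, 20% positives,
per-criterion decoy classes at 20% each (remainder motif-free negatives);
3′UTR isoforms of 250/600 nt; PAS planted 30 nt upstream of each cleavage
end (mid-window); UGUA elements at ±80 nt around the proximal PAS;
single-exon transcripts with a 300 nt CDS and ≥ 500 nt intergenic spacing so
scan windows never cross genes. Expression defaults mirror a small qPCR
study: 3 replicates, baseline ratio 0.5, overexpression fold 1.5, knockdown
fold 0.5 (one control, one overexpression, two knockdown conditions),
Ct noise SD 0.2 cycles, efficiency base 2. Larger runs in the acceptance
checks use 6 replicates and 500 genes, sizes at which the stochastic
recovery and false-positive rates are stable to within about one percentage
point across seeds.

Background sequence is i.i.d. uniform ACGT, then every accidental AATAAA,
ATTAAA or TGTA inside the scanned UTR span that is not a planted motif is
rewritten (one base mutated, bounded retries), making truth labels exact
rather than probabilistic. Consequences and non-goals: the generator does
not emulate realistic base composition, introns inside 3′UTRs, > 2 isoforms
per gene, PAS-strength heterogeneity, or biological variation in expression
beyond lognormal Ct noise. Passing the planted-truth tests therefore
demonstrates that the *logic* of the screen and classifier is exact under
the stated geometry — not that the criteria themselves are sensitive or
specific on real genomes, where motif context is far noisier.

Decoy expectations follow the screen's own semantics: a `decoy_c1` gene
(single isoform) is recorded as (c1 F, c2 T, c3 F) because c3 has no
proximal-PAS anchor without a second end; `decoy_c2` breaks the PAS window
at the distal end only, so its proximal anchor — and hence c3 — survives,
giving (T, F, T); `decoy_c3` is (T, T, F). Only positives are planted as
expression-responsive.

Determinism: one numpy `Generator` seeded from `SimConfig.seed` drives the
genome build in a fixed iteration order; expression uses a child stream of
the same seed. Same seed ⇒ byte-identical FASTA/GTF/tables, and the seed is
recorded in the FASTA and GTF headers.

## Numerical and degenerate-input choices

* PAS window bounds are inclusive on both sides (a hexamer ending exactly
  10 or 60 nt upstream counts); UGUA radius is |offset| ≤ 200.
* A UTR shorter than w_min + 6 yields no PAS hits (warning, not an error).
* A replicate with zero total abundance has an undefined ratio and is
  dropped with a warning; a missing amplicon likewise drops the replicate.
* Genes with several UTR-start groups get the best-scoring group's verdict
  (candidate first, then number of satisfied criteria, then evidence count).
* The IHC proportion bins overlap at exactly 80% as published; the "80% or
  more" bin wins there. Tumor volume warns (but computes) when W > L;
  wound closure clips negative closures to 0% with a warning.

## Known limitations

* Intronless 3′UTRs are assumed in v1 (the generator guarantees this);
  multi-exon UTRs are concatenated in transcription order if encountered,
  but positional windows then mix transcript and genomic distance.
* The screen's criteria are sequence-geometric only: no PAS strength
  scoring, conservation, or expression weighting.
* Exact-match primer binding means a single SNP in a template defeats the
  RACE predictor; that is intentional for a deterministic validation tool.
* Headline gene counts from any real database depend on the annotation
  version supplied by the user and are not targets of this package.
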