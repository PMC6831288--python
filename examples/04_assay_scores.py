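"""Score IHC staining, xenograft volumes and wound closure.

Small deterministic rubrics used when relating NUDT21 levels to tumor
phenotype: composite IHC score = intensity (0-3) x proportion bin (0-4),
with 0-3 low / 4-12 high; caliper tumor volume (L x W^2)/2; percent
wound-gap closure.
"""

from apascreen import ihc_score, proportion_bin, tumor_volume, wound_closure

for intensity, pct in [(1, 60), (2, 30), (3, 85), (1, 100)]:
    bin_ = proportion_bin(pct)
    s = ihc_score(intensity, bin_)
    print(f"intensity {intensity}, {pct:3.0f}% positive cells -> "
          f"proportion bin {bin_}, final {s.final:2d} -> {s.level}")

print(f"\ntumor volume L=12.3 mm, W=7.1 mm: {tumor_volume(12.3, 7.1):.4f} mm^3")
print(f"wound closure 100 -> 40 area units: {wound_closure(100, 40):.0f}%")
# The low/high boundary sits between final scores 3 and 4, so intensity 1
# with 51-80% positive cells (1 x 3 = 3) is still "low" expression.
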