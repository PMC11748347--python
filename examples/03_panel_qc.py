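"""Coverage QC: fold-80 base penalty, coverage thresholds, and the
commonly-uncovered-exon rule on a hand-built batch."""

from panelprio.qc import (
    DepthTrack,
    coverage_fractions,
    find_common_uncovered_exons,
    fold80_base_penalty,
)
from panelprio.types import GenomicInterval

# a deliberately non-uniform track: 80 bases at 10x, 20 bases at 90x
depths = [10] * 80 + [90] * 20
print(f"fold-80 base penalty: {fold80_base_penalty(depths):.2f} "
      "(1.0 would be perfectly uniform)")
print(f"fold-80 on constant coverage: {fold80_base_penalty([100] * 100):.2f}")
frac = coverage_fractions(depths, [20, 30])
print(f"bases at >=20x: {frac[20]:.0%}   >=30x: {frac[30]:.0%}")

# an exon covered <50% in 19 of 20 samples is systematically uncovered
exon = GenomicInterval("1", 101, 200, "EX_HARD")
tracks = {}
for i in range(20):
    covered = 40 if i < 19 else 90  # bases of the exon at good depth
    tracks[f"S{i:02d}"] = DepthTrack(
        [("1", 100, 100 + covered, 100), ("1", 100 + covered, 200, 5)]
    )
(summary,) = find_common_uncovered_exons([exon], tracks)
print(
    f"exon {exon.label}: below-50%-covered in {summary.n_samples_below}/20 "
    f"samples -> flagged={summary.flag_common_uncovered}"
)
print(
    "Flagged exons are candidates for probe redesign or Sanger fill-in;\n"
    "the rule needs at least 95% of batch samples under 50% coverage."
)
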