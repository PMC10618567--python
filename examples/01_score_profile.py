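"""Score a single tumor segment profile.

Builds a small allele-specific copy-number profile by hand — one
interstitial copy-loss LOH region on 1p and one telomeric gain on 2p over
a diploid background — and counts the scar events it contains.
"""

from hrdscar import ScoreParams, Segment, SegmentProfile, load_reference, score_gi

MB = 1_000_000
genome = load_reference("hg19")

segments = {}
for chrom in genome.autosome_names():
    length = genome.chromosome(chrom).length
    if chrom == "1":
        # 20 Mb deletion LOH (one retained copy) at 30-50 Mb
        segments[chrom] = [
            Segment(0, 30 * MB, 2, 1),
            Segment(30 * MB, 50 * MB, 1, 0),
            Segment(50 * MB, length, 2, 1),
        ]
    elif chrom == "2":
        # 12 Mb single-copy gain anchored at the p telomere
        segments[chrom] = [Segment(0, 12 * MB, 3, 1), Segment(12 * MB, length, 2, 1)]
    else:
        segments[chrom] = [Segment(0, length, 2, 1)]

profile = SegmentProfile(sample="TUMOR-1", segments=segments)
result = score_gi(profile, genome, ScoreParams())

print(f"sample {result.sample}: LOH={result.loh} TAI={result.tai} LST={result.lst} "
      f"GI/HRD score={result.gi_score}")
for ev in result.events:
    print(f"  {ev.kind} on {ev.chrom}{ev.arm} [{ev.start/MB:.1f}, {ev.end/MB:.1f}] Mb")

# The 20 Mb minor-copy-zero region counts as one LOH event and its two
# breakpoints as large-scale transitions; the telomeric gain is one TAI and
# one further transition.  The GI/HRD score is the plain sum of the three.
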