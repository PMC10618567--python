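import numpy as np
import pytest

from hrdscar.genome import load_reference
from hrdscar.scoring import Segment, SegmentProfile

MB = 1_000_000


@pytest.fixture(scope="session")
def genome():
    return load_reference("hg19")


def build_profile(genome, lesions, sample="T", background=(2, 1)):
    """Full-coverage profile: diploid background with (chrom, start_bp, end_bp,
    total, minor) lesions overlaid.  Lesions must be non-overlapping."""
    by_chrom = {}
    for chrom, start, end, total, minor in lesions:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), total, minor))
    segments = {}
    for chrom in genome.autosome_names():
        cm = genome.chromosome(chrom)
        segs = []
        pos = 0
        for start, end, total, minor in sorted(by_chrom.get(chrom, [])):
            if pos < start:
                segs.append(Segment(pos, start, *background))
            segs.append(Segment(start, end, total, minor))
            pos = end
        if pos < cm.length:
            segs.append(Segment(pos, cm.length, *background))
        segments[chrom] = segs
    return SegmentProfile(sample=sample, segments=segments)


@pytest.fixture(scope="session")
def make_profile(genome):
    def _make(lesions, sample="T"):
        return build_profile(genome, lesions, sample=sample)

    return _make


def random_lesion_plan(rng):
    """Lesion-count draw matching the cohort generator's study conditions."""
    from hrdscar.simulate import LesionPlan

    intensity = rng.exponential(1.0)
    return LesionPlan(
        n_interstitial_loh=int(rng.poisson(1.5 * intensity)),
        n_telomeric_ai=int(rng.poisson(1.2 * intensity)),
        n_staircase=int(rng.poisson(1.0 * intensity)),
        whole_chrom_loh=bool(rng.random() < 0.05),
        tp53_loh=bool(rng.random() < 0.15),
    )


@pytest.fixture(scope="session")
def small_cohort(genome, tmp_path_factory):
    """One shared 40-sample synthetic cohort written to disk."""
    from hrdscar.simulate import SimConfig, simulate_cohort, write_cohort

    cohort = simulate_cohort(SimConfig(seed=11, n_samples=40), genome)
    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(cohort, outdir)
    return cohort, paths
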