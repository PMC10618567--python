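"""Reference coordinate model: hg19 autosomes, arms, centromeres, gene loci.

Coordinates are 0-based half-open internally.  The packaged hg19 model
stores chromosome lengths and centromere (acen) bounds rounded to 100-kb
resolution: scar scoring operates at megabase scale, and a uniform 100-kb
grid keeps arm/length arithmetic exact across the scoring engine and the
bin-rasterizing oracle.  Gene loci keep their exact extents.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = [
    "ChromosomeModel",
    "GeneLocus",
    "GenomeBuild",
    "load_reference",
    "arm_of",
    "crosses_centromere",
    "reaches_telomere",
    "normalize_chrom",
]

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMS = ("X", "Y")


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix; ``chr17`` and ``17`` are the same chromosome."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class ChromosomeModel:
    """One chromosome with its centromere interval.

    The p arm is ``[0, cen_start)``, the q arm ``[cen_end, length)``; the
    two arms plus the centromere partition the chromosome.
    """

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise ValueError(
                f"chromosome {self.name}: require 0 < cen_start < cen_end < length, "
                f"got ({self.cen_start}, {self.cen_end}, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (0, self.cen_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.cen_end, self.length)


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start must be < end")


@dataclass(frozen=True)
class GenomeBuild:
    """A build label plus chromosome models and gene loci, keyed by name."""

    label: str
    chromosomes: dict[str, ChromosomeModel]
    genes: dict[str, GeneLocus]

    def chromosome(self, name: str) -> ChromosomeModel:
        key = normalize_chrom(name)
        try:
            return self.chromosomes[key]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r} in build {self.label}") from None

    def autosome_names(self) -> tuple[str, ...]:
        return tuple(c for c in AUTOSOMES if c in self.chromosomes)

    def scoring_chromosomes(self, include_sex: bool = False) -> tuple[str, ...]:
        """Chromosomes that contribute to scar scores (autosomes by default)."""
        names = list(self.autosome_names())
        if include_sex:
            names += [c for c in SEX_CHROMS if c in self.chromosomes]
        return tuple(names)


def _read_packaged_tsv(filename: str) -> list[dict[str, str]]:
    text = resources.files("hrdscar.data").joinpath(filename).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_reference(build_label: str = "hg19") -> GenomeBuild:
    """Load a packaged reference build ("hg19"): 22 autosomes + X/Y, arm
    intervals, and gene loci (TP53 on 17p).  No network access."""
    if build_label != "hg19":
        raise ValueError(f"unknown build {build_label!r}; packaged builds: 'hg19'")
    chroms: dict[str, ChromosomeModel] = {}
    for row in _read_packaged_tsv("hg19_chromosomes.tsv"):
        chroms[row["chrom"]] = ChromosomeModel(
            name=row["chrom"],
            length=int(row["length"]),
            cen_start=int(row["cen_start"]),
            cen_end=int(row["cen_end"]),
        )
    genes: dict[str, GeneLocus] = {}
    for row in _read_packaged_tsv("hg19_genes.tsv"):
        # gene table is 1-based inclusive on disk
        genes[row["gene"]] = GeneLocus(
            gene=row["gene"],
            chrom=normalize_chrom(row["chrom"]),
            start=int(row["start"]) - 1,
            end=int(row["end"]),
        )
    for g in genes.values():
        if g.chrom not in chroms:
            raise ValueError(f"gene {g.gene} on unmodeled chromosome {g.chrom}")
    return GenomeBuild(label=build_label, chromosomes=chroms, genes=genes)


def arm_of(build: GenomeBuild, chrom: str, pos: int) -> str:
    """Arm label at a position: ``"p"``, ``"q"`` or ``"cen"``."""
    cm = build.chromosome(chrom)
    if not (0 <= pos < cm.length):
        raise ValueError(f"position {pos} out of range for chromosome {cm.name} (length {cm.length})")
    if pos < cm.cen_start:
        return "p"
    if pos >= cm.cen_end:
        return "q"
    return "cen"


def crosses_centromere(build: GenomeBuild, chrom: str, start: int, end: int) -> bool:
    """True iff the interval overlaps both the p arm and the q arm.

    A segment ending inside the centromere touches only one arm and does
    not cross.
    """
    cm = build.chromosome(chrom)
    return start < cm.cen_start and end > cm.cen_end


def reaches_telomere(build: GenomeBuild, chrom: str, start: int, end: int, tol_bp: int = 0) -> bool:
    """True iff the interval comes within ``tol_bp`` of either chromosome end."""
    if tol_bp < 0:
        raise ValueError("tol_bp must be >= 0")
    cm = build.chromosome(chrom)
    return start <= tol_bp or end >= cm.length - tol_bp
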