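"""Chromosome-arm model of the D. melanogaster genome used throughout the package.

Arms are the units of physical coordinates and of the recombination model;
arms of the same Muller chromosome (2L+2R, 3L+3R) are linked during
transmission: a gamete picks one parental haplotype per *chromosome* and
crossovers within either arm toggle the phase, which carries across the
centromere.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Arm:
    """A chromosome arm with a physical and genetic length.

    genetic_length is the female map length in Morgans: the mean number of
    crossovers per female meiosis on this arm (Poisson, no interference).
    Males are achiasmate by default.
    """

    name: str
    length_bp: int
    genetic_length: float
    chromosome: str

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"arm {self.name}: length_bp must be positive")
        if self.genetic_length < 0:
            raise ValueError(f"arm {self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class Genome:
    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate arm names")

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for a in self.arms:
            if a.chromosome not in out:
                out.append(a.chromosome)
        return out

    def chromosome_arms(self, chrom: str) -> list[Arm]:
        return [a for a in self.arms if a.chromosome == chrom]

    def chromosome_of(self, arm_name: str) -> str:
        return self.arm(arm_name).chromosome

    @property
    def total_length(self) -> int:
        return sum(a.length_bp for a in self.arms)


# Default five-arm genome: physical lengths approximate the major arms of the
# reference assembly; genetic lengths are Drosophila-scale female map lengths
# (~0.55 M per major autosome arm, 0.70 M for X), uniform within arm.
DEFAULT_GENOME = Genome(
    arms=(
        Arm("2L", 23_000_000, 0.55, "2"),
        Arm("2R", 21_000_000, 0.55, "2"),
        Arm("3L", 24_500_000, 0.55, "3"),
        Arm("3R", 28_000_000, 0.55, "3"),
        Arm("X", 22_400_000, 0.70, "X"),
    )
)

AUTOSOME_ARMS = ("2L", "2R", "3L", "3R")
NUCLEAR_ARMS = ("2L", "2R", "3L", "3R", "X")


def autosomes_only(genome: Genome = DEFAULT_GENOME) -> Genome:
    return Genome(arms=tuple(a for a in genome.arms if a.chromosome != "X"))
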