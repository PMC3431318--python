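"""Genotypes, X-linked inheritance, and allele-frequency accounting.

The locus of interest is a biallelic X-linked site carrying either the
sexually antagonistic allele (SAA) or the control allele.  Because males
are hemizygous for the X there are exactly five legal (sex, genotype)
states: two male hemizygote classes and three female diploid classes.
Each state corresponds to one eye-colour phenotype (the SAA carries a
partial ``white`` rescue): SAA hemizygote males and SAA homozygote
females are red-eyed, heterozygous females orange-eyed, and all control
genotypes white-eyed.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SexGenotype",
    "MALE_GENOTYPES",
    "FEMALE_GENOTYPES",
    "GENOTYPE_LABELS",
    "PopulationState",
    "InvalidCrossError",
    "UndefinedFrequencyError",
    "phenotype_of",
    "offspring_distribution",
    "offspring_distribution_vector",
    "x_allele_frequency",
    "x_frequency_from_counts",
]


class InvalidCrossError(ValueError):
    """Raised when a cross does not pair one male with one female."""


class UndefinedFrequencyError(ValueError):
    """Raised when an allele frequency is requested for an empty population."""


class SexGenotype(enum.Enum):
    """The five legal (sex, genotype) states at the X-linked locus.

    The ``value`` of each member is its canonical serialization label,
    used verbatim in all CSV/JSON artifacts.
    """

    M_SAA = "M_SAA"
    M_CTRL = "M_CTRL"
    F_SAA_SAA = "F_SAA_SAA"
    F_SAA_CTRL = "F_SAA_CTRL"
    F_CTRL_CTRL = "F_CTRL_CTRL"

    @property
    def sex(self) -> str:
        return "male" if self.name.startswith("M_") else "female"

    @property
    def n_saa_alleles(self) -> int:
        """Copies of the SAA allele carried (0-1 for males, 0-2 for females)."""
        return self.name.count("SAA")

    @property
    def n_x(self) -> int:
        """X chromosomes carried: one in males, two in females."""
        return 1 if self.sex == "male" else 2


MALE_GENOTYPES = (SexGenotype.M_SAA, SexGenotype.M_CTRL)
FEMALE_GENOTYPES = (
    SexGenotype.F_SAA_SAA,
    SexGenotype.F_SAA_CTRL,
    SexGenotype.F_CTRL_CTRL,
)
#: Canonical class ordering for all vectorized state representations.
ALL_GENOTYPES = MALE_GENOTYPES + FEMALE_GENOTYPES
GENOTYPE_LABELS = tuple(g.value for g in ALL_GENOTYPES)

_PHENOTYPES = {
    SexGenotype.M_SAA: "red",
    SexGenotype.M_CTRL: "white",
    SexGenotype.F_SAA_SAA: "red",
    SexGenotype.F_SAA_CTRL: "orange",
    SexGenotype.F_CTRL_CTRL: "white",
}


def phenotype_of(g: SexGenotype) -> str:
    """Eye colour of a genotype: ``red``, ``orange`` or ``white``.

    Within each sex the mapping is invertible: female genotypes map
    bijectively onto the three colours, and male red/white distinguishes
    the two hemizygote classes (orange males are impossible).
    """
    return _PHENOTYPES[g]


def _maternal_saa_prob(mother: SexGenotype) -> float:
    # probability that a maternal gamete carries the SAA allele
    return mother.n_saa_alleles / 2.0


def offspring_distribution(
    father: SexGenotype, mother: SexGenotype
) -> dict[SexGenotype, float]:
    """Mendelian offspring distribution of a single cross.

    Sons receive one maternal X; daughters receive the paternal X plus
    one maternal X.  Sexes are equally likely (1:1 at birth) and there
    is no recombination between the allele and its eye-colour marker.

    Returns a dict over all five states summing to 1.

    Raises
    ------
    InvalidCrossError
        If ``father`` is not male or ``mother`` is not female.
    """
    if father.sex != "male" or mother.sex != "female":
        raise InvalidCrossError(
            f"cross requires a male father and a female mother, "
            f"got {father.value} x {mother.value}"
        )
    p_mat = _maternal_saa_prob(mother)
    pat_saa = float(father.n_saa_alleles)

    dist = dict.fromkeys(ALL_GENOTYPES, 0.0)
    # sons: maternal allele only
    dist[SexGenotype.M_SAA] = 0.5 * p_mat
    dist[SexGenotype.M_CTRL] = 0.5 * (1.0 - p_mat)
    # daughters: paternal x maternal
    dist[SexGenotype.F_SAA_SAA] = 0.5 * pat_saa * p_mat
    dist[SexGenotype.F_SAA_CTRL] = 0.5 * (
        pat_saa * (1.0 - p_mat) + (1.0 - pat_saa) * p_mat
    )
    dist[SexGenotype.F_CTRL_CTRL] = 0.5 * (1.0 - pat_saa) * (1.0 - p_mat)
    return dist


@functools.lru_cache(maxsize=None)
def _offspring_vector_cached(father: SexGenotype, mother: SexGenotype) -> np.ndarray:
    d = offspring_distribution(father, mother)
    v = np.array([d[g] for g in ALL_GENOTYPES])
    v.setflags(write=False)
    return v


def offspring_distribution_vector(
    father: SexGenotype, mother: SexGenotype
) -> np.ndarray:
    """:func:`offspring_distribution` as a length-5 vector in canonical order."""
    return _offspring_vector_cached(father, mother)


@dataclass
class PopulationState:
    """Per-sex genotype frequencies of one discrete generation.

    ``male_freqs`` is ordered (SAA hemizygote, control); ``female_freqs``
    is (SAA homozygote, heterozygote, control homozygote).  ``n_males``
    and ``n_females`` are the adult census sizes used to weight the two
    sexes in X-chromosome allele-frequency accounting; they need not be
    equal (founding cages may deliberately be male-light).
    """

    male_freqs: np.ndarray
    female_freqs: np.ndarray
    generation: int = 1
    n_males: int = 100
    n_females: int = 100
    counts: dict[SexGenotype, int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.male_freqs = np.asarray(self.male_freqs, dtype=float)
        self.female_freqs = np.asarray(self.female_freqs, dtype=float)
        if self.generation < 0:
            raise ValueError("generation must be non-negative")
        if self.male_freqs.shape != (2,) or self.female_freqs.shape != (3,):
            raise ValueError("male_freqs must have length 2, female_freqs length 3")
        if (self.male_freqs < -1e-12).any() or (self.female_freqs < -1e-12).any():
            raise ValueError("genotype frequencies must be non-negative")
        for name, v, n in (
            ("male", self.male_freqs, self.n_males),
            ("female", self.female_freqs, self.n_females),
        ):
            if n > 0 and abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} frequencies must sum to 1, got {v.sum()!r}")

    @property
    def sex_extinct(self) -> bool:
        return self.n_males == 0 or self.n_females == 0

    def freq_vector(self) -> np.ndarray:
        """Concatenated (male, female) frequency vector in canonical order."""
        return np.concatenate([self.male_freqs, self.female_freqs])

    @classmethod
    def from_counts(
        cls, counts: dict[SexGenotype, int], generation: int = 1
    ) -> "PopulationState":
        """Build a state from integer class counts.

        Census sizes are the realized per-sex totals.
        """
        nm = sum(int(counts.get(g, 0)) for g in MALE_GENOTYPES)
        nf = sum(int(counts.get(g, 0)) for g in FEMALE_GENOTYPES)
        if nm == 0 and nf == 0:
            raise UndefinedFrequencyError("empty population")
        mf = (
            np.array([counts.get(g, 0) for g in MALE_GENOTYPES], float) / nm
            if nm
            else np.array([0.0, 1.0])
        )
        ff = (
            np.array([counts.get(g, 0) for g in FEMALE_GENOTYPES], float) / nf
            if nf
            else np.array([0.0, 0.0, 1.0])
        )
        return cls(
            male_freqs=mf,
            female_freqs=ff,
            generation=generation,
            n_males=nm,
            n_females=nf,
            counts=dict(counts),
        )


def x_allele_frequency(state: PopulationState) -> float:
    """SAA frequency among X chromosomes, weighting adults by census size.

    Males carry one X and females two, so with per-sex census sizes
    ``N_m`` and ``N_f``::

        q = (m_SAA * N_m + (2 f_SS + f_het) * N_f) / (N_m + 2 N_f)

    Raises
    ------
    UndefinedFrequencyError
        If both sexes are extinct.
    """
    nm, nf = state.n_males, state.n_females
    if nm == 0 and nf == 0:
        raise UndefinedFrequencyError("both sexes extinct: allele frequency undefined")
    m_saa = state.male_freqs[0]
    f_allele = 2.0 * state.female_freqs[0] + state.female_freqs[1]
    return float((m_saa * nm + f_allele * nf) / (nm + 2.0 * nf))


def x_frequency_from_counts(
    counts: dict[SexGenotype, int],
    n_males: int | None = None,
    n_females: int | None = None,
) -> float:
    """SAA X-chromosome frequency of integer class counts.

    ``n_males``/``n_females`` override the census denominators; by
    default the realized per-sex totals are used.  Overriding matters
    when per-class rounding has shaved an individual off a sex (a cage
    nominally founded at 100 females may hold 99 after rounding, and
    the conventional percentage is quoted against the design census).
    """
    saa = sum(counts.get(g, 0) * g.n_saa_alleles for g in ALL_GENOTYPES)
    nm = sum(counts.get(g, 0) for g in MALE_GENOTYPES)
    nf = sum(counts.get(g, 0) for g in FEMALE_GENOTYPES)
    nm = nm if n_males is None else n_males
    nf = nf if n_females is None else n_females
    total_x = nm + 2 * nf
    if total_x == 0:
        raise UndefinedFrequencyError("no X chromosomes in population")
    return float(saa) / total_x
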