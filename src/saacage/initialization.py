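"""Founding cage compositions at Hardy-Weinberg-with-selection proportions.

A cage is founded from a target pre-selection SAA allele frequency
``q``: genotype classes are formed at Hardy-Weinberg proportions,
weighted by rudimentary per-genotype fitness estimates, renormalized
within each sex, scaled to the per-sex census and rounded per class to
the nearest integer.  Because rounding is applied per class with no
reconciliation, the realized sex totals can miss the census by one —
a quirk deliberately preserved, because the high-frequency published
cage compositions show exactly such 99-female totals.

The low-frequency cages (3% SAA) were founded directly as 9 SAA males,
81 control males and 100 control females rather than from ``q``; that
composition ships as a named preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    ALL_GENOTYPES,
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    SexGenotype,
    UndefinedFrequencyError,
    x_frequency_from_counts,
)

__all__ = [
    "FitnessEstimates",
    "CompositionSpec",
    "hw_selection_composition",
    "composition_percent",
    "FOUNDING_PRESETS",
]


@dataclass(frozen=True)
class FitnessEstimates:
    """Relative fitness weights per genotype class.

    Defaults are the rudimentary empirical estimates used to seed the
    high-frequency cages: SAA males 1 vs control males 0.55 (the SAA
    photophase mating advantage), and females 0.388 (SAA homozygote,
    the recessive fecundity cost), 0.9 (heterozygote), 1 (control).
    """

    male_saa: float = 1.0
    male_ctrl: float = 0.55
    female_saa: float = 0.388
    female_het: float = 0.9
    female_ctrl: float = 1.0

    def __post_init__(self) -> None:
        for name in ("male_saa", "male_ctrl", "female_saa", "female_het", "female_ctrl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fitness weight {name} must be positive")

    @property
    def male_weights(self) -> np.ndarray:
        return np.array([self.male_saa, self.male_ctrl])

    @property
    def female_weights(self) -> np.ndarray:
        return np.array([self.female_saa, self.female_het, self.female_ctrl])


@dataclass(frozen=True)
class CompositionSpec:
    """A founding composition request: frequency, census and fitness."""

    q: float
    n_per_sex: int = 100
    fitness: FitnessEstimates = field(default_factory=FitnessEstimates)

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be at least 1")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Nearest-integer rounding, halves away from zero (not banker's)."""
    return np.floor(x + 0.5).astype(int)


def hw_selection_composition(spec: CompositionSpec) -> dict[SexGenotype, int]:
    """Integer class counts at Hardy-Weinberg-with-selection proportions.

    Male classes are proportional to ``(q * w_m_SAA, (1-q) * w_m_CTRL)``
    and female classes to ``(q^2 w_SS, 2q(1-q) w_het, (1-q)^2 w_CC)``,
    each sex normalized independently, scaled to ``n_per_sex`` and
    rounded per class to the nearest integer (no total reconciliation,
    so a sex may total ``n_per_sex`` +/- 1).
    """
    q = spec.q
    w = spec.fitness
    male_raw = np.array([q, 1.0 - q]) * w.male_weights
    female_raw = np.array([q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2]) * w.female_weights
    male = _round_half_away(male_raw / male_raw.sum() * spec.n_per_sex)
    female = _round_half_away(female_raw / female_raw.sum() * spec.n_per_sex)
    counts = dict(zip(MALE_GENOTYPES, male.tolist()))
    counts.update(zip(FEMALE_GENOTYPES, female.tolist()))
    return counts


def composition_percent(
    counts: dict[SexGenotype, int],
    n_males: int | None = None,
    n_females: int | None = None,
) -> int:
    """SAA X-chromosome percentage of a composition, rounded to integer.

    By default the X-chromosome denominator uses the realized per-sex
    totals; ``n_males``/``n_females`` override them.  Compositions
    produced by :func:`hw_selection_composition` are conventionally
    quoted against their nominal ``n_per_sex`` even when per-class
    rounding leaves a sex one individual short, so pass the design
    census explicitly when reproducing quoted percentages (e.g. the
    P6 composition is 48% against 100 nominal females but 49% against
    its realized 99).
    """
    if sum(counts.values()) == 0:
        raise UndefinedFrequencyError("empty composition")
    freq = x_frequency_from_counts(counts, n_males=n_males, n_females=n_females)
    return int(np.floor(100.0 * freq + 0.5))


def _counts(m_saa, m_ctrl, f_ss, f_het, f_cc) -> dict[SexGenotype, int]:
    return dict(zip(ALL_GENOTYPES, (m_saa, m_ctrl, f_ss, f_het, f_cc)))


#: Founding compositions of the eight experimental cage populations.
#: P1-P4 (3% SAA, males only) were constructed directly from crosses;
#: P5-P8 follow the Hardy-Weinberg-with-selection ladder at nominal
#: pre-selection frequencies 0.30 / 0.50 / 0.70 / 0.90.  The P5-P8
#: entries are the compositions as published; at q = 0.90 the published
#: SAA-homozygote female count (64) is one below what the stated
#: procedure yields (65, from an unrounded 64.63), so the preset and
#: the procedure intentionally disagree in that single cell.
FOUNDING_PRESETS: dict[str, dict[SexGenotype, int]] = {
    "P1": _counts(9, 81, 0, 0, 100),
    "P2": _counts(9, 81, 0, 0, 100),
    "P3": _counts(9, 81, 0, 0, 100),
    "P4": _counts(9, 81, 0, 0, 100),
    "P5": _counts(44, 56, 4, 42, 54),
    "P6": _counts(65, 35, 12, 56, 31),
    "P7": _counts(81, 19, 29, 57, 14),
    "P8": _counts(94, 6, 64, 33, 2),
}

#: Nominal pre-selection allele frequencies behind the P5-P8 ladder.
PRESET_Q = {"P5": 0.30, "P6": 0.50, "P7": 0.70, "P8": 0.90}
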