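"""Synthetic cage-experiment datasets.

Emulates the observable record of an experimental-evolution cage study:
per line and generation, the eye-colour-scored offspring sample (the
300 larvae drawn from the pool), the adult census reconstituted from
those proportions (100 males + 100 females, rounded), and photophase
spot-check mating observations.  Each line evolves by the stochastic
model step under a per-generation light schedule, so regime switches
(e.g. moving a line to permanent dark) are first-class.

Scoring is error-free by default; an optional misclassification rate
swaps scored genotype classes within sex for robustness exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetics import (
    ALL_GENOTYPES,
    FEMALE_GENOTYPES,
    GENOTYPE_LABELS,
    MALE_GENOTYPES,
    PopulationState,
    SexGenotype,
    x_allele_frequency,
    x_frequency_from_counts,
)
from .dynamics import ModelParams, stochastic_step
from .initialization import FOUNDING_PRESETS

__all__ = [
    "ExperimentDesign",
    "CageDataset",
    "generate_experiment",
    "genotype_counts_from_phenotypes",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic cage experiment.

    ``light_schedule`` is either a single light-hours value applied to
    every generation or a sequence of per-generation values of length
    ``n_generations``.  ``founding`` is a preset name ("P1".."P8") or a
    dict of integer counts per genotype.  Defaults mirror the original
    cage design: 4 replicate lines founded at 3% SAA, 16 generations on
    a 12:12 cycle, 300 scored offspring, and ~6 photophase spot checks
    per generation (62 observations were spread over 10 generations in
    the original study).
    """

    params: ModelParams
    n_lines: int = 4
    n_generations: int = 16
    founding: str | dict[SexGenotype, int] = "P1"
    light_schedule: float | tuple[float, ...] | None = None
    spot_checks_per_gen: int = 6
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_generations < 1:
            raise ValueError("n_lines and n_generations must be at least 1")
        if not 0.0 <= self.misclassification_rate < 1.0:
            raise ValueError("misclassification_rate must lie in [0, 1)")
        if self.spot_checks_per_gen < 0:
            raise ValueError("spot_checks_per_gen must be non-negative")
        sched = self.resolved_schedule()
        if len(sched) != self.n_generations:
            raise ValueError(
                f"light schedule length {len(sched)} != n_generations "
                f"{self.n_generations}"
            )
        if any(not 0.0 <= h <= 24.0 for h in sched):
            raise ValueError("light hours must lie in [0, 24]")

    def resolved_schedule(self) -> tuple[float, ...]:
        sched = self.light_schedule
        if sched is None:
            sched = self.params.mating.light_hours
        if np.isscalar(sched):
            return (float(sched),) * self.n_generations
        return tuple(float(h) for h in sched)

    def founding_counts(self) -> dict[SexGenotype, int]:
        if isinstance(self.founding, str):
            try:
                return dict(FOUNDING_PRESETS[self.founding])
            except KeyError:
                raise ValueError(f"unknown founding preset {self.founding!r}") from None
        return dict(self.founding)


@dataclass
class CageDataset:
    """Observable record of a (synthetic) cage experiment.

    ``offspring``: one row per line and generation with the scored
    offspring counts per genotype class (columns named by the canonical
    labels), summing to the sample size.  ``adults``: the reconstituted
    adult census per line and generation.  ``matings``: one row per
    spot-check observation (line, generation, winner).  ``truth``: the
    generator's underlying per-generation SAA X-frequencies and
    parameters, kept for parameter-recovery tests and never an input to
    analysis code.
    """

    offspring: pd.DataFrame
    adults: pd.DataFrame
    matings: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return dict(self.truth)


def _round_census(freqs: np.ndarray, n: int) -> np.ndarray:
    """Nearest-integer per class, then largest-remainder fix-up to sum to n."""
    raw = freqs * n
    base = np.floor(raw + 0.5).astype(int)
    diff = n - base.sum()
    if diff != 0:
        # push the correction onto the classes with the largest absolute
        # rounding residue, one unit at a time
        resid = raw - base
        order = np.argsort(-np.sign(diff) * resid)
        for k in range(abs(diff)):
            base[order[k % len(base)]] += int(np.sign(diff))
    return base


def _misclassify_within_sex(
    counts: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Reassign each scored individual to a uniform wrong class w.p. ``rate``."""
    k = len(counts)
    out = np.zeros(k, dtype=int)
    for i, c in enumerate(counts):
        stay = rng.binomial(c, 1.0 - rate)
        out[i] += stay
        moved = c - stay
        if moved > 0:
            others = [j for j in range(k) if j != i]
            out[others] += rng.multinomial(moved, [1.0 / (k - 1)] * (k - 1))
    return out


def generate_experiment(design: ExperimentDesign) -> CageDataset:
    """Run the generative model of the cage protocol.

    Each line iterates the stochastic model step under its light
    schedule; the multinomial draw of each step *is* the scored
    offspring sample.  The adult census is rebuilt from the drawn
    proportions with per-sex largest-remainder rounding so each sex
    sums exactly to the configured census.  Spot-check matings are
    independent photophase events where the SAA male wins with
    probability ``w_photo * m_SAA / (w_photo * m_SAA + m_CTRL)``.
    """
    params = design.params
    schedule = design.resolved_schedule()
    founding = design.founding_counts()
    master = np.random.SeedSequence(design.seed)
    line_seeds = master.spawn(design.n_lines)

    off_rows, adult_rows, mating_rows = [], [], []
    true_freqs: dict[str, list[float]] = {}

    for li, line_seed in enumerate(line_seeds):
        line = f"L{li + 1}"
        rng = np.random.default_rng(line_seed)
        state = PopulationState.from_counts(founding, generation=1)
        # founding adults are recorded as given, not re-rounded
        adult_rows.append(
            {"line": line, "generation": 1}
            | {g.value: founding.get(g, 0) for g in ALL_GENOTYPES}
        )
        freqs = [x_allele_frequency(state)]
        for gen_idx in range(design.n_generations):
            light = schedule[gen_idx]
            p_gen = replace(
                params,
                mating=replace(params.mating, light_hours=light),
                n_males=state.n_males,
                n_females=state.n_females,
            )
            # spot-check matings among the current adults (photophase only)
            if design.spot_checks_per_gen > 0 and light > 0:
                m_saa, m_ctrl = state.male_freqs
                w = params.mating.w_photo
                p_win = w * m_saa / (w * m_saa + m_ctrl)
                wins = rng.random(design.spot_checks_per_gen) < p_win
                for win in wins:
                    mating_rows.append(
                        {
                            "line": line,
                            "generation": state.generation,
                            "winner": "M_SAA" if win else "M_CTRL",
                        }
                    )
            nxt, ok = stochastic_step(state, p_gen, rng)
            if not ok:
                break
            scored = np.array([nxt.counts[g] for g in ALL_GENOTYPES])
            if design.misclassification_rate > 0:
                males = _misclassify_within_sex(
                    scored[:2], design.misclassification_rate, rng
                )
                females = _misclassify_within_sex(
                    scored[2:], design.misclassification_rate, rng
                )
                scored = np.concatenate([males, females])
            off_rows.append(
                {"line": line, "generation": nxt.generation}
                | dict(zip(GENOTYPE_LABELS, scored.tolist()))
            )
            male_census = _round_census(nxt.male_freqs, params.n_males)
            female_census = _round_census(nxt.female_freqs, params.n_females)
            adult_rows.append(
                {"line": line, "generation": nxt.generation}
                | dict(
                    zip(
                        GENOTYPE_LABELS,
                        np.concatenate([male_census, female_census]).tolist(),
                    )
                )
            )
            state = nxt
            # the observable truth: SAA X-frequency of the drawn offspring
            # sample, weighted by the realized per-sex totals of the draw
            freqs.append(x_frequency_from_counts(state.counts))
        true_freqs[line] = [float(f) for f in freqs]

    offspring = pd.DataFrame(off_rows, columns=["line", "generation", *GENOTYPE_LABELS])
    adults = pd.DataFrame(adult_rows, columns=["line", "generation", *GENOTYPE_LABELS])
    matings = pd.DataFrame(mating_rows, columns=["line", "generation", "winner"])
    truth = {
        "seed": design.seed,
        "n_lines": design.n_lines,
        "n_generations": design.n_generations,
        "light_schedule": list(schedule),
        "w_photo": params.mating.w_photo,
        "light_dark_propensity": list(params.mating.light_dark_propensity),
        "brood_size": params.brood_size,
        "female_fecundity": list(params.female_fecundity),
        "sample_size": params.sample_size,
        "founding": {g.value: int(v) for g, v in founding.items()},
        "true_frequencies": true_freqs,
    }
    return CageDataset(offspring=offspring, adults=adults, matings=matings, truth=truth)


_FEMALE_BY_COLOUR = {
    "red": SexGenotype.F_SAA_SAA,
    "orange": SexGenotype.F_SAA_CTRL,
    "white": SexGenotype.F_CTRL_CTRL,
}
_MALE_BY_COLOUR = {"red": SexGenotype.M_SAA, "white": SexGenotype.M_CTRL}


def genotype_counts_from_phenotypes(
    scored: dict[tuple[str, str], int],
) -> dict[SexGenotype, int]:
    """Invert eye-colour scoring to genotype counts.

    ``scored`` maps (sex, colour) pairs — e.g. ``("female", "orange")``
    — to counts.  Within each sex the colour map is invertible, so
    totals are preserved exactly.  Orange males are genetically
    impossible (males are hemizygous) and raise ``ValueError``.
    """
    out = dict.fromkeys(ALL_GENOTYPES, 0)
    for (sex, colour), n in scored.items():
        if n < 0:
            raise ValueError("negative phenotype count")
        if n == 0:
            continue
        if sex == "male":
            if colour not in _MALE_BY_COLOUR:
                raise ValueError(
                    f"impossible phenotype: {colour} males cannot occur at an "
                    "X-linked locus (males are hemizygous)"
                )
            out[_MALE_BY_COLOUR[colour]] += int(n)
        elif sex == "female":
            if colour not in _FEMALE_BY_COLOUR:
                raise ValueError(f"unknown eye colour {colour!r}")
            out[_FEMALE_BY_COLOUR[colour]] += int(n)
        else:
            raise ValueError(f"unknown sex {sex!r}")
    return out
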