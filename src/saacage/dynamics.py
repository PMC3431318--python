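"""Genotype-frequency recursion for the X-linked SAA and its stochastic variant.

Deterministic model
-------------------
Each discrete generation: (1) matings between male and female genotype
classes occur in proportions given by :func:`saacage.mating.cross_frequencies`
(every female mates once; males compete with the cycle-averaged SAA
weight ``w_eff``); (2) each cross contributes offspring in proportion
to its mean surviving brood (baseline brood size times the mother's
relative fecundity by default), split over offspring genotypes by
X-linked Mendelian segregation; (3) the pooled offspring expectation is
renormalized within each sex to give next-generation frequencies.

Stochastic variant
------------------
The cage protocol scores a fixed number of offspring (300 by default)
drawn at random from the full pool of a few thousand.  The stochastic
step draws that sample as a single multinomial over the five (sex,
genotype) classes with the deterministic pool proportions, and the
next generation's frequencies are the drawn counts renormalized per
sex.  An optional exact-pool mode realizes the pool as rounded integer
counts and samples without replacement (multivariate hypergeometric);
with pools of 2500-5400 the variance correction is at most a few
percent, so the multinomial is the default.

Ensembles of seeded runs supply per-generation means, standard
deviations and percentile 95% bands, mirroring how replicate cage
trajectories spread around the deterministic prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    ALL_GENOTYPES,
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    PopulationState,
    offspring_distribution_vector,
    x_allele_frequency,
)
from .mating import MatingParams, cross_frequencies, effective_male_weight

__all__ = [
    "ModelParams",
    "Trajectory",
    "Ensemble",
    "EquilibriumResult",
    "PopulationCollapseError",
    "deterministic_step",
    "run_deterministic",
    "find_equilibrium",
    "stochastic_step",
    "run_stochastic",
    "run_ensemble",
    "state_at_hw",
    "expected_pool_size",
    "calibrate_w_photo",
]

#: Default relative fecundity of (SAA homozygote, heterozygote, control) mothers.
DEFAULT_FEMALE_FECUNDITY = (0.388, 0.9, 1.0)

#: Default baseline surviving brood per mated control female.  Chosen so
#: that a 100-female cage generates an offspring pool in the few-thousand
#: range typical of the cage protocol (100 x 30 = 3000 at low SAA
#: frequency, shrinking as low-fecundity SAA mothers become common).
DEFAULT_BROOD_SIZE = 30.0


class PopulationCollapseError(RuntimeError):
    """Raised when the expected offspring pool is empty."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population collapsed at generation {generation}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the recursion.

    ``cross_fecundity`` maps each (father class, mother class) cross to
    its mean number of surviving offspring; when ``None`` it defaults to
    ``brood_size`` times the mother's relative fecundity, identical for
    both father genotypes (sperm competition between SAA and control
    males is neutral, so siring shares follow mating shares).
    """

    mating: MatingParams
    brood_size: float = DEFAULT_BROOD_SIZE
    female_fecundity: tuple[float, float, float] = DEFAULT_FEMALE_FECUNDITY
    cross_fecundity: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    sample_size: int = 300
    n_runs: int = 100
    max_generations: int = 1000
    n_males: int = 100
    n_females: int = 100
    exact_pool: bool = False

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be at least 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if any(f < 0 for f in self.female_fecundity):
            raise ValueError("fecundities must be non-negative")
        if self.cross_fecundity is not None:
            arr = np.asarray(self.cross_fecundity, float)
            if arr.shape != (2, 3):
                raise ValueError("cross_fecundity must be a 2x3 table")
            if (arr < 0).any():
                raise ValueError("fecundities must be non-negative")

    def fecundity_table(self) -> np.ndarray:
        """2x3 array of mean surviving offspring per (father, mother) cross."""
        if self.cross_fecundity is not None:
            return np.asarray(self.cross_fecundity, float)
        row = self.brood_size * np.asarray(self.female_fecundity)
        return np.vstack([row, row])

    def w_eff(self) -> float:
        return effective_male_weight(self.mating)


@dataclass
class Trajectory:
    """A single generation-indexed run of the model."""

    states: list[PopulationState]
    freqs: np.ndarray
    converged: bool = False
    extinct: bool = False
    fixed: bool = False
    failed: bool = False

    def __post_init__(self) -> None:
        if self.extinct and self.fixed:
            raise ValueError("extinct and fixed are mutually exclusive")

    @property
    def generations(self) -> np.ndarray:
        return np.array([s.generation for s in self.states])

    @property
    def final_freq(self) -> float:
        return float(self.freqs[-1])


@dataclass
class Ensemble:
    """Per-generation summary over replicate stochastic runs."""

    freqs: np.ndarray  # (n_runs, n_gen)
    generations: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_failed: int = 0

    @property
    def n_runs(self) -> int:
        return self.freqs.shape[0]


@dataclass
class EquilibriumResult:
    equilibrium: float
    freq_at_700: float | None
    generations_run: int
    converged: bool


def _offspring_pool(state: PopulationState, params: ModelParams) -> np.ndarray:
    """Expected offspring counts per class (unnormalized), one female = one mating."""
    w_eff = params.w_eff()
    crosses = cross_frequencies(state, w_eff)
    fec = params.fecundity_table()
    pool = np.zeros(5)
    for i, father in enumerate(MALE_GENOTYPES):
        for j, mother in enumerate(FEMALE_GENOTYPES):
            c = crosses[i, j]
            if c == 0.0:
                continue
            pool += c * fec[i, j] * offspring_distribution_vector(father, mother)
    return pool


def _pool_to_state(pool: np.ndarray, generation: int, params: ModelParams) -> PopulationState:
    males, females = pool[:2], pool[2:]
    ms, fs = males.sum(), females.sum()
    if ms <= 0 or fs <= 0:
        raise PopulationCollapseError(generation)
    return PopulationState(
        male_freqs=males / ms,
        female_freqs=females / fs,
        generation=generation,
        n_males=params.n_males,
        n_females=params.n_females,
    )


def deterministic_step(state: PopulationState, params: ModelParams) -> PopulationState:
    """One generation of the deterministic recursion."""
    pool = _offspring_pool(state, params)
    if pool.sum() <= 0:
        raise PopulationCollapseError(state.generation + 1)
    return _pool_to_state(pool, state.generation + 1, params)


_CONV_TOL = 1e-10
_CONV_STREAK = 10


def run_deterministic(
    params: ModelParams, initial: PopulationState, n_gen: int
) -> Trajectory:
    """Iterate :func:`deterministic_step` for ``n_gen`` generations.

    Records the SAA X-frequency at every generation (including the
    initial one); ``converged`` is set when |dq| stayed below 1e-10 for
    10 consecutive generations at any point in the run.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be at least 1")
    states = [initial]
    freqs = [x_allele_frequency(initial)]
    streak = 0
    converged = False
    for _ in range(n_gen):
        nxt = deterministic_step(states[-1], params)
        states.append(nxt)
        freqs.append(x_allele_frequency(nxt))
        if abs(freqs[-1] - freqs[-2]) < _CONV_TOL:
            streak += 1
            if streak >= _CONV_STREAK:
                converged = True
        else:
            streak = 0
    freqs_arr = np.array(freqs)
    return Trajectory(
        states=states,
        freqs=freqs_arr,
        converged=converged,
        extinct=bool(freqs_arr[-1] < 1e-12),
        fixed=bool(freqs_arr[-1] > 1.0 - 1e-12),
    )


def find_equilibrium(params: ModelParams, initial: PopulationState) -> EquilibriumResult:
    """Long-run SAA frequency after ``params.max_generations`` generations.

    Also reports the frequency at generation 700 when the run extends
    that far, since long-run equilibria are conventionally quoted at
    that horizon for this system.
    """
    traj = run_deterministic(params, initial, params.max_generations)
    gen0 = initial.generation
    idx_700 = 700 - gen0
    freq_700 = float(traj.freqs[idx_700]) if 0 <= idx_700 < len(traj.freqs) else None
    return EquilibriumResult(
        equilibrium=traj.final_freq,
        freq_at_700=freq_700,
        generations_run=params.max_generations,
        converged=traj.converged,
    )


def stochastic_step(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> tuple[PopulationState, bool]:
    """One generation with random selection of ``sample_size`` offspring.

    Returns ``(next_state, ok)``; ``ok`` is False when the draw left a
    sex with zero individuals (a failed line — terminal, not an
    exception, so ensembles can carry on).
    """
    pool = _offspring_pool(state, params)
    total = pool.sum()
    if total <= 0:
        raise PopulationCollapseError(state.generation + 1)
    if params.exact_pool:
        # realize the pool at its true scale (one brood per female) and
        # sample without replacement
        pool_counts = np.floor(pool * state.n_females + 0.5).astype(int)
        deficit = params.sample_size - pool_counts.sum()
        if deficit > 0:  # integerized pool must still cover the sample
            pool_counts[int(np.argmax(pool))] += deficit
        draw = rng.multivariate_hypergeometric(pool_counts, params.sample_size)
    else:
        draw = rng.multinomial(params.sample_size, pool / total)
    males, females = draw[:2], draw[2:]
    if males.sum() == 0 or females.sum() == 0:
        return state, False
    nxt = PopulationState(
        male_freqs=males / males.sum(),
        female_freqs=females / females.sum(),
        generation=state.generation + 1,
        n_males=params.n_males,
        n_females=params.n_females,
        counts=dict(zip(ALL_GENOTYPES, draw.tolist())),
    )
    return nxt, True


def run_stochastic(
    params: ModelParams,
    initial: PopulationState,
    n_gen: int,
    rng: np.random.Generator,
) -> Trajectory:
    """A single stochastic trajectory of ``n_gen`` generations."""
    states = [initial]
    freqs = [x_allele_frequency(initial)]
    failed = False
    for _ in range(n_gen):
        if failed:
            # a failed line holds its last defined frequency
            freqs.append(freqs[-1])
            continue
        nxt, ok = stochastic_step(states[-1], params, rng)
        if not ok:
            failed = True
            freqs.append(freqs[-1])
            continue
        states.append(nxt)
        freqs.append(x_allele_frequency(nxt))
    freqs_arr = np.array(freqs)
    return Trajectory(
        states=states,
        freqs=freqs_arr,
        extinct=bool(freqs_arr[-1] < 1e-12),
        fixed=bool(freqs_arr[-1] > 1.0 - 1e-12),
        failed=failed,
    )


def run_ensemble(
    params: ModelParams,
    initial: PopulationState,
    n_gen: int,
    seed: int,
) -> Ensemble:
    """``params.n_runs`` seeded stochastic runs with per-generation summaries.

    Per-run generators are spawned deterministically from the master
    seed, so a fixed seed reproduces the ensemble exactly.  Runs that
    lose or fix the allele stay at the absorbed frequency and remain in
    the averages; the 95% band is the 2.5/97.5 percentile across runs.
    """
    if params.n_runs < 2:
        raise ValueError("an ensemble needs at least 2 runs")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(params.n_runs)
    freqs = np.empty((params.n_runs, n_gen + 1))
    n_failed = 0
    for i, child in enumerate(children):
        traj = run_stochastic(params, initial, n_gen, np.random.default_rng(child))
        freqs[i] = traj.freqs
        n_failed += int(traj.failed)
    generations = initial.generation + np.arange(n_gen + 1)
    return Ensemble(
        freqs=freqs,
        generations=generations,
        mean=freqs.mean(axis=0),
        sd=freqs.std(axis=0, ddof=1),
        lo95=np.percentile(freqs, 2.5, axis=0),
        hi95=np.percentile(freqs, 97.5, axis=0),
        n_failed=n_failed,
    )


def expected_pool_size(state: PopulationState, params: ModelParams) -> float:
    """Expected total offspring generated, scaled to the female census.

    Every female mates once, so the pool is ``n_females`` times the
    mean brood over the cross distribution.  Useful to sanity-check a
    fecundity configuration against the few-thousand offspring pools
    the cage protocol produces.
    """
    if state.n_females == 0:
        return 0.0
    w_eff = params.w_eff()
    crosses = cross_frequencies(state, w_eff)
    return float(state.n_females * (crosses * params.fecundity_table()).sum())


def calibrate_w_photo(
    target_equilibrium: float,
    params: ModelParams,
    initial: PopulationState,
    bracket: tuple[float, float] = (1.05, 30.0),
    xtol: float = 1e-10,
) -> float:
    """Photophase weight whose long-run equilibrium hits a target frequency.

    Solves ``equilibrium(w_photo) = target_equilibrium`` by Brent's
    method over ``bracket``, holding every other parameter fixed.  The
    long-run equilibrium is monotone non-decreasing in ``w_photo``, so
    the root is unique once bracketed.
    """
    from scipy.optimize import brentq

    def objective(w_photo: float) -> float:
        p = replace(params, mating=replace(params.mating, w_photo=w_photo))
        return find_equilibrium(p, initial).equilibrium - target_equilibrium

    lo, hi = bracket
    if objective(lo) > 0 or objective(hi) < 0:
        raise ValueError(
            f"target equilibrium {target_equilibrium} not bracketed by "
            f"w_photo in {bracket}"
        )
    return float(brentq(objective, lo, hi, xtol=xtol))


def state_at_hw(q: float, generation: int = 1, n_males: int = 100, n_females: int = 100) -> PopulationState:
    """Population at unselected Hardy-Weinberg proportions for frequency ``q``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return PopulationState(
        male_freqs=np.array([q, 1.0 - q]),
        female_freqs=np.array([q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2]),
        generation=generation,
        n_males=n_males,
        n_females=n_females,
    )
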