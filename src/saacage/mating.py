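"""Male mating-advantage machinery.

The SAA male mating advantage is expressed only in photophase (the
light portion of the day); in the dark, SAA and control males mate
equally.  Two distinct parameters are therefore kept apart and must
never be conflated:

* ``w_photo`` — the relative mating weight of SAA males *during light*,
  measurable directly from paired one-on-one mating trials;
* the *effective* (cycle-averaged) weight, obtained by mixing
  ``w_photo`` with the neutral dark weight 1 according to the fraction
  of matings expected to occur in light.  That fraction combines the
  hours of light in the 24 h cycle with the empirical light:dark mating
  propensities (default 0.402:0.598 at 12:12, reflecting the slight
  preference of Drosophila for mating in the dark).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import PopulationState

__all__ = [
    "MatingParams",
    "effective_male_weight",
    "photophase_mating_fraction",
    "cross_frequencies",
    "estimate_weight_paired",
    "binomial_tail",
    "MatingOpportunitySummary",
    "mating_opportunity_summary",
]

#: Default light:dark mating propensity at a 12:12 cycle.
DEFAULT_LIGHT_DARK_PROPENSITY = (0.402, 0.598)


@dataclass(frozen=True)
class MatingParams:
    """Parameters of the photoperiod-dependent male mating advantage.

    ``w_photo`` is the photophase-only relative weight of SAA males
    (control male weight fixed at 1); ``light_hours`` is the hours of
    light per 24 h cycle.
    """

    w_photo: float
    light_hours: float = 12.0
    light_dark_propensity: tuple[float, float] = DEFAULT_LIGHT_DARK_PROPENSITY

    def __post_init__(self) -> None:
        if self.w_photo <= 0:
            raise ValueError("w_photo must be positive")
        if not 0.0 <= self.light_hours <= 24.0:
            raise ValueError("light_hours must lie in [0, 24]")
        pl, pd_ = self.light_dark_propensity
        if pl <= 0 or pd_ <= 0 or abs(pl + pd_ - 1.0) > 1e-9:
            raise ValueError("light_dark_propensity must be positive and sum to 1")


def photophase_mating_fraction(
    light_hours: float,
    propensity: tuple[float, float] = DEFAULT_LIGHT_DARK_PROPENSITY,
) -> float:
    """Fraction of matings expected to occur in the light.

    The light and dark propensities are quoted for a 12:12 cycle; they
    are scaled linearly by the actual hours of light and dark and
    renormalized, so p_L(12) equals the light propensity, p_L(0) = 0
    (permanent dark) and p_L(24) = 1 (permanent light).
    """
    if not 0.0 <= light_hours <= 24.0:
        raise ValueError("light_hours must lie in [0, 24]")
    pl, pdk = propensity
    light = pl * (light_hours / 12.0)
    dark = pdk * ((24.0 - light_hours) / 12.0)
    return light / (light + dark)


def effective_male_weight(p: MatingParams) -> float:
    """Cycle-averaged SAA male mating weight.

    ``p_L * w_photo + (1 - p_L) * 1`` where ``p_L`` is the photophase
    mating fraction.  Equals 1 whenever ``w_photo`` is 1 (no photophase
    advantage) or the cage is in permanent dark.
    """
    p_l = photophase_mating_fraction(p.light_hours, p.light_dark_propensity)
    return p_l * p.w_photo + (1.0 - p_l)


def cross_frequencies(state: PopulationState, w_eff: float) -> np.ndarray:
    """2x3 matrix of mating proportions between male and female classes.

    Every female mates exactly once; males compete for each mating with
    weights ``(w_eff, 1)`` for (SAA, control).  Entry ``(i, j)`` is the
    proportion of all matings that pair male class ``i`` with female
    class ``j``; entries sum to 1 and the column sums recover the female
    genotype frequencies exactly.
    """
    if w_eff <= 0:
        raise ValueError("w_eff must be positive")
    if state.n_males == 0 or state.n_females == 0:
        raise ValueError("no matings possible: one sex is absent")
    weights = np.array([w_eff, 1.0]) * state.male_freqs
    total = weights.sum()
    if total <= 0:
        raise ValueError("no matings possible: male frequencies are all zero")
    male_share = weights / total
    return np.outer(male_share, state.female_freqs)


def estimate_weight_paired(k_wins: int, n_trials: int) -> float:
    """Mating-weight estimate from paired one-on-one competition trials.

    In a trial one SAA and one control male compete for a single female;
    if the SAA male wins with probability ``w / (w + 1)`` then the odds
    ``k / (n - k)`` estimate ``w``.  Degenerate outcomes (all wins or
    all losses) give an unbounded estimate and are rejected.
    """
    if not 0 <= k_wins <= n_trials:
        raise ValueError("k_wins must lie in [0, n_trials]")
    if k_wins == 0 or k_wins == n_trials:
        raise ValueError(
            "degenerate trial outcome (0 or all wins): weight estimate is 0 or "
            "infinite; collect more trials or handle separately"
        )
    return k_wins / (n_trials - k_wins)


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    # sf gives P(X > k - 1) = P(X >= k)
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class MatingOpportunitySummary:
    """Observed vs expected mating counts for SAA and control males.

    ``expected`` is the proportional-mating expectation: per generation,
    the SAA male frequency times the number of observations made that
    generation, summed over generations.  ``chi2``/``p_value`` compare
    the observed split to the expectation with a 1-df chi-square test.
    """

    observed_saa: int
    observed_ctrl: int
    expected_saa: float
    expected_ctrl: float
    n_observations: int
    chi2: float
    p_value: float


def mating_opportunity_summary(
    observations: pd.DataFrame, availability: pd.DataFrame
) -> MatingOpportunitySummary:
    """Aggregate spot-check mating observations against male availability.

    Parameters
    ----------
    observations:
        One row per observed mating with columns ``generation`` and
        ``winner`` ("M_SAA" or "M_CTRL"); a ``line`` column is allowed
        and ignored for the aggregate.
    availability:
        Per-generation SAA male frequency, columns ``generation`` and
        ``saa_male_freq`` (optionally ``line``; (line, generation) keys
        are used when present in both tables).

    Raises
    ------
    KeyError
        If an observation's generation (or line-generation) has no
        availability entry.
    """
    obs = observations.copy()
    keys = ["generation"]
    if "line" in obs.columns and "line" in availability.columns:
        keys = ["line", "generation"]
    avail = availability.set_index(keys)["saa_male_freq"]
    grouped = obs.groupby(keys)
    expected_saa = 0.0
    n_total = 0
    for key, grp in grouped:
        key = key if len(keys) > 1 else key
        try:
            freq = float(avail.loc[key])
        except KeyError as err:
            raise KeyError(
                f"no SAA male availability recorded for generation {key!r}"
            ) from err
        expected_saa += freq * len(grp)
        n_total += len(grp)
    observed_saa = int((obs["winner"] == "M_SAA").sum())
    observed_ctrl = n_total - observed_saa
    expected_ctrl = n_total - expected_saa
    chi2, p = stats.chisquare(
        [observed_saa, observed_ctrl], [expected_saa, expected_ctrl]
    )
    return MatingOpportunitySummary(
        observed_saa=observed_saa,
        observed_ctrl=observed_ctrl,
        expected_saa=expected_saa,
        expected_ctrl=expected_ctrl,
        n_observations=n_total,
        chi2=float(chi2),
        p_value=float(p),
    )
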