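"""Frequency trajectories and summaries from observed cage data.

Turns the scored-offspring record of a cage experiment (real or
synthetic) into per-line SAA X-frequency series and simple descriptive
summaries: a terminal-window equilibrium estimate and per-phase
frequency deltas between chosen breakpoint generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import GENOTYPE_LABELS, SexGenotype, x_frequency_from_counts
from .synth import CageDataset

__all__ = [
    "FrequencySeries",
    "frequency_trajectory",
    "equilibrium_estimate",
    "phase_deltas",
    "trajectory_frame",
]


@dataclass
class FrequencySeries:
    """Per-generation SAA X-frequency of one replicate line."""

    line: str
    generations: np.ndarray
    freqs: np.ndarray
    counts: pd.DataFrame  # backing genotype counts, one row per generation

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.generations) != len(self.freqs):
            raise ValueError("generations and freqs must have equal length")
        if (np.diff(self.generations) <= 0).any():
            raise ValueError("generations must be strictly increasing")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")


def _series_from_frame(df: pd.DataFrame) -> list[FrequencySeries]:
    missing = [c for c in ("line", "generation", *GENOTYPE_LABELS) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in cage data: {missing}")
    unknown = [
        c for c in df.columns if c not in ("line", "generation", *GENOTYPE_LABELS)
    ]
    if unknown:
        raise ValueError(f"unknown genotype columns in cage data: {unknown}")
    out = []
    for line, grp in df.groupby("line", sort=True):
        grp = grp.sort_values("generation")
        freqs = [
            x_frequency_from_counts(
                {SexGenotype(lbl): int(row[lbl]) for lbl in GENOTYPE_LABELS}
            )
            for _, row in grp.iterrows()
        ]
        out.append(
            FrequencySeries(
                line=str(line),
                generations=grp["generation"].to_numpy(),
                freqs=np.array(freqs),
                counts=grp.reset_index(drop=True),
            )
        )
    return out


def frequency_trajectory(
    dataset: CageDataset, source: str = "offspring"
) -> list[FrequencySeries]:
    """Per-line SAA X-frequency series from a cage dataset.

    ``source`` selects the observable: ``"offspring"`` (default) uses
    the scored offspring sample of each generation — the quantity the
    protocol actually records — while ``"adults"`` uses the
    reconstituted adult census.  Both have the same expectation; the
    offspring series carries the sampling noise of the scored draw,
    the adult series adds census rounding.  Frequencies weight the
    sexes by their realized counts in the chosen table.
    """
    if source not in ("offspring", "adults"):
        raise ValueError("source must be 'offspring' or 'adults'")
    frame = dataset.offspring if source == "offspring" else dataset.adults
    return _series_from_frame(frame)


def trajectory_frame(series: list[FrequencySeries]) -> pd.DataFrame:
    """Tidy (line, generation, saa_x_freq) frame from frequency series."""
    rows = [
        {"line": s.line, "generation": int(g), "saa_x_freq": float(f)}
        for s in series
        for g, f in zip(s.generations, s.freqs)
    ]
    return pd.DataFrame(rows, columns=["line", "generation", "saa_x_freq"])


def equilibrium_estimate(
    series: FrequencySeries, window: int
) -> dict[str, float]:
    """Mean SAA frequency over the final ``window`` generations.

    Returns the mean together with the window's min and max, a simple
    plateau summary for a trajectory that has stopped trending.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    if window > len(series.freqs):
        raise ValueError("window exceeds series length")
    tail = series.freqs[-window:]
    return {
        "mean": float(tail.mean()),
        "min": float(tail.min()),
        "max": float(tail.max()),
        "window": int(window),
    }


def phase_deltas(
    series: FrequencySeries, breakpoints: list[int]
) -> list[dict[str, float]]:
    """End-minus-start frequency change over segments between breakpoints.

    ``breakpoints`` are generation numbers (present in the series)
    splitting it into consecutive segments; each segment reports its
    start/end generations, the frequency delta and its sign.  A
    descriptive substitute for segmented-regression phase analysis.
    """
    gens = series.generations
    for b in breakpoints:
        if b not in gens:
            raise ValueError(f"breakpoint generation {b} not in series")
    if list(breakpoints) != sorted(set(breakpoints)):
        raise ValueError("breakpoints must be strictly increasing")
    edges = [int(gens[0]), *[int(b) for b in breakpoints], int(gens[-1])]
    if len(set(edges)) != len(edges):
        raise ValueError("breakpoints must be interior generations")
    out = []
    idx = {int(g): i for i, g in enumerate(gens)}
    for start, end in zip(edges[:-1], edges[1:]):
        delta = float(series.freqs[idx[end]] - series.freqs[idx[start]])
        out.append(
            {
                "start": start,
                "end": end,
                "delta": delta,
                "sign": float(np.sign(delta)),
            }
        )
    return out
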