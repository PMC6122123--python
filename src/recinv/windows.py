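"""Sliding-window recombination rates with bootstrap confidence intervals.

Chromosomes are tiled with 1 Mb windows advancing in 100 kb steps by default;
the final window of each chromosome is truncated at the chromosome end rather
than dropped.  Each crossover contributes fractional "mass" to every window
it overlaps, pro-rated by the fraction of its localization interval inside
the window, so total mass over a non-overlapping tiling conserves the
crossover count exactly.  Confidence intervals resample offspring (not
crossovers) with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .linkage import CrossoverInterval

__all__ = [
    "GenomeWindow",
    "tile_windows",
    "window_rate",
    "crossover_mass_matrix",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class GenomeWindow:
    chrom: str
    start_bp: int
    end_bp: int
    index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError("window requires 0 <= start_bp < end_bp")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def tile_windows(
    genome: Sequence, size_bp: int = 1_000_000, step_bp: int = 100_000
) -> list[GenomeWindow]:
    """Sliding windows over a genome of ChromosomeSpec.

    Starts at 0, step, 2*step, ...; every full window whose end fits on the
    chromosome is emitted, plus one final truncated window when the chromosome
    length is not reached exactly.  A chromosome shorter than one window
    yields a single window covering it.
    """
    if step_bp <= 0 or size_bp <= 0 or step_bp > size_bp:
        raise ValueError("require 0 < step_bp <= size_bp")
    out: list[GenomeWindow] = []
    idx = 0
    for chrom in genome:
        L = chrom.length_bp
        if L <= size_bp:
            out.append(GenomeWindow(chrom.name, 0, L, idx))
            idx += 1
            continue
        n_full = (L - size_bp) // step_bp + 1
        for i in range(n_full):
            s = i * step_bp
            out.append(GenomeWindow(chrom.name, s, s + size_bp, idx))
            idx += 1
        if (L - size_bp) % step_bp:
            s = n_full * step_bp
            out.append(GenomeWindow(chrom.name, s, L, idx))
            idx += 1
    return out


def _window_arrays(windows: Sequence[GenomeWindow]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {w.chrom for w in windows}:
        ws = [w for w in windows if w.chrom == chrom]
        by_chrom[chrom] = (
            np.array([w.start_bp for w in ws]),
            np.array([w.end_bp for w in ws]),
            np.array([w.index for w in ws]),
        )
    return by_chrom


def crossover_mass_matrix(
    crossovers: Iterable[CrossoverInterval],
    windows: Sequence[GenomeWindow],
    offspring_ids: Sequence[str],
) -> np.ndarray:
    """Per-offspring per-window crossover mass (n_offspring x n_windows).

    Mass of one crossover in one window = overlap of its localization
    interval with the window, divided by the interval length; masses of a
    crossover sum to 1 over any non-overlapping tiling covering it.
    """
    row = {o: i for i, o in enumerate(offspring_ids)}
    arrays = _window_arrays(windows)
    M = np.zeros((len(offspring_ids), len(windows)))
    for x in crossovers:
        if x.chrom not in arrays:
            raise ValueError(f"crossover on chromosome {x.chrom!r} outside the tiling")
        if x.offspring_id not in row:
            raise ValueError(f"unknown offspring {x.offspring_id!r}")
        starts, ends, idxs = arrays[x.chrom]
        ov = np.minimum(ends, x.right_bp) - np.maximum(starts, x.left_bp)
        hit = ov > 0
        M[row[x.offspring_id], idxs[hit]] += ov[hit] / x.length_bp
    return M


def window_rate(
    crossovers: Iterable[CrossoverInterval],
    windows: Sequence[GenomeWindow],
    n_offspring: int,
    group: str = "",
) -> pd.DataFrame:
    """Windowed map length and recombination rate.

    Window cM = 100 x mass / n_offspring; rate = cM / (window span in Mb),
    using the actual span for truncated windows.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    xs = list(crossovers)
    ids = sorted({x.offspring_id for x in xs})
    mass = (
        crossover_mass_matrix(xs, windows, ids).sum(axis=0)
        if ids
        else np.zeros(len(windows))
    )
    cM = 100.0 * mass / n_offspring
    span_mb = np.array([w.span_bp for w in windows]) / 1e6
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "group": group,
            "mass": mass,
            "cM": cM,
            "rate_cM_per_Mb": cM / span_mb,
        }
    )


def bootstrap_ci(
    crossovers: Iterable[CrossoverInterval],
    windows: Sequence[GenomeWindow],
    offspring_ids: Sequence[str],
    n_boot: int = 10_000,
    seed: int = 0,
    quantiles: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Bootstrap 95% CIs for windowed cM and rate, resampling offspring.

    ``offspring_ids`` must list every offspring in the group (including those
    without crossovers) so resampling weights are correct.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(offspring_ids)
    if n < 1:
        raise ValueError("offspring_ids must be non-empty")
    M = crossover_mass_matrix(crossovers, windows, offspring_ids)
    rng = np.random.default_rng(seed)
    # resampling offspring uniformly with replacement == multinomial weights
    w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    reps_cM = 100.0 * (w @ M) / n
    lo, hi = np.percentile(reps_cM, quantiles, axis=0)
    span_mb = np.array([wd.span_bp for wd in windows]) / 1e6
    out = window_rate(crossovers, windows, n)
    out["ci_low_cM"] = lo
    out["ci_high_cM"] = hi
    out["ci_low_rate"] = lo / span_mb
    out["ci_high_rate"] = hi / span_mb
    return out
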