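"""Crossover detection from ordered parental-phase genotypes and genetic-map estimation.

Because female meiosis is achiasmatic in this system, maternal markers are
constant and every informative phase switch along an offspring's ordered
paternal markers is a candidate paternal crossover.  Maps are estimated from
the recombination fraction alone (cM increment = 100 x crossovers / offspring
per marker interval); the maps are fine-scale enough that no mapping function
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "CrossoverInterval",
    "GeneticMap",
    "detect_crossovers_sequence",
    "detect_crossovers",
    "estimate_map",
    "estimate_maps",
    "map_statistics",
    "mean_crossovers_per_offspring",
]


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos_bp: int
    cM: float = float("nan")


@dataclass(frozen=True)
class CrossoverInterval:
    """One crossover in one offspring, localized to a half-open bp interval.

    The interval runs from the last informative marker of the old phase to the
    first informative marker of the new phase; missing calls in between simply
    widen it.
    """

    offspring_id: str
    chrom: str
    left_bp: int
    right_bp: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.left_bp < self.right_bp:
            raise ValueError("crossover interval requires left_bp < right_bp")

    @property
    def length_bp(self) -> int:
        return self.right_bp - self.left_bp


@dataclass
class GeneticMap:
    """Ordered markers on one chromosome with cumulative cM positions."""

    chrom: str
    positions_bp: np.ndarray
    cM: np.ndarray
    n_offspring: int

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.cM = np.asarray(self.cM, dtype=float)
        if self.positions_bp.ndim != 1 or self.positions_bp.size != self.cM.size:
            raise ValueError("positions_bp and cM must be 1-d and equal length")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if np.any(np.diff(self.cM) < -1e-9):
            raise ValueError("cM must be non-decreasing with position")

    @property
    def total_cM(self) -> float:
        return float(self.cM[-1] - self.cM[0]) if self.cM.size else 0.0

    @property
    def gaps_bp(self) -> np.ndarray:
        return np.diff(self.positions_bp)

    @property
    def markers(self) -> list[Marker]:
        return [
            Marker(self.chrom, int(p), float(c))
            for p, c in zip(self.positions_bp, self.cM)
        ]


# ---------------------------------------------------------------------------
# crossover detection
# ---------------------------------------------------------------------------


def detect_crossovers_sequence(
    calls: Sequence[str], positions: Sequence[int], min_support: int = 2
) -> list[tuple[int, int]]:
    """Phase switches in one offspring's ordered calls on one chromosome.

    A switch is called only when the new phase is corroborated by at least
    ``min_support`` consecutive informative markers; shorter runs are treated
    as genotyping error and skipped.  The initial phase is that of the first
    informative marker (only the new phase of a switch needs support).
    Returns half-open (left_bp, right_bp) localization intervals.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    if positions.ndim != 1 or len(calls) != positions.size:
        raise ValueError("calls and positions must be 1-d and equal length")
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("marker positions must be strictly increasing")

    idx = [i for i, c in enumerate(calls) if c in ("A", "B")]
    if not idx:
        return []
    phases = [calls[i] for i in idx]

    # run-length encode the informative calls
    runs: list[tuple[str, int, int]] = []  # (phase, first informative idx, run length)
    j = 0
    while j < len(phases):
        k = j
        while k < len(phases) and phases[k] == phases[j]:
            k += 1
        runs.append((phases[j], j, k - j))
        j = k

    out: list[tuple[int, int]] = []
    current: str | None = None
    last_good = -1  # index (into idx) of the last marker of the current phase
    for phase, start, length in runs:
        if current is None:
            current = phase
            last_good = start + length - 1
            continue
        if phase == current:
            last_good = start + length - 1
            continue
        if length >= min_support:
            left = int(positions[idx[last_good]])
            right = int(positions[idx[start]])
            out.append((left, right))
            current = phase
            last_good = start + length - 1
        # else: short run of the other phase -> genotyping error, stay in phase
    return out


def detect_crossovers(
    dataset, min_support: int = 2, which: str = "paternal"
) -> list[CrossoverInterval]:
    """Detect crossovers for every offspring and chromosome of a CrossDataset."""
    geno = dataset.genotypes if which == "paternal" else dataset.maternal_genotypes
    out: list[CrossoverInterval] = []
    for chrom, calls in geno.items():
        pos = dataset.markers[chrom]
        for i, oid in enumerate(dataset.offspring_ids):
            for left, right in detect_crossovers_sequence(calls[i], pos, min_support):
                out.append(
                    CrossoverInterval(
                        offspring_id=oid,
                        chrom=chrom,
                        left_bp=left,
                        right_bp=right,
                        group_label=dataset.group_labels[i],
                    )
                )
    return out


# ---------------------------------------------------------------------------
# map estimation
# ---------------------------------------------------------------------------


def estimate_map(
    crossovers: Iterable[CrossoverInterval],
    positions_bp: Sequence[int],
    n_offspring: int,
    chrom: str | None = None,
) -> GeneticMap:
    """Genetic map for one chromosome from localized crossovers.

    The cM increment of each adjacent marker interval is 100 x (crossover
    mass localized to the interval) / n_offspring, with a crossover whose
    localization interval spans several marker intervals pro-rated by
    overlap so the total map length conserves the crossover count exactly.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    pos = np.asarray(positions_bp, dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    xs = list(crossovers)
    chroms = {x.chrom for x in xs}
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError("crossovers span multiple chromosomes; pass chrom")
        chrom = next(iter(chroms)) if chroms else "unknown"
    elif not chroms <= {chrom}:
        raise ValueError("crossovers from a different chromosome")

    marker_set = set(int(p) for p in pos)
    increments = np.zeros(max(pos.size - 1, 0))
    for x in xs:
        if x.left_bp not in marker_set or x.right_bp not in marker_set:
            raise ValueError(
                f"crossover endpoints ({x.left_bp}, {x.right_bp}) are not marker positions"
            )
        i = int(np.searchsorted(pos, x.left_bp))
        j = int(np.searchsorted(pos, x.right_bp))
        span = float(x.right_bp - x.left_bp)
        for k in range(i, j):
            increments[k] += (pos[k + 1] - pos[k]) / span
    cM = np.concatenate([[0.0], np.cumsum(100.0 * increments / n_offspring)])
    return GeneticMap(chrom=chrom, positions_bp=pos, cM=cM, n_offspring=n_offspring)


def estimate_maps(
    crossovers: Iterable[CrossoverInterval],
    markers: Mapping[str, Sequence[int]],
    n_offspring: int,
) -> dict[str, GeneticMap]:
    """Per-chromosome maps for a whole genome."""
    by_chrom: dict[str, list[CrossoverInterval]] = {c: [] for c in markers}
    for x in crossovers:
        if x.chrom not in by_chrom:
            raise ValueError(f"crossover on unknown chromosome {x.chrom!r}")
        by_chrom[x.chrom].append(x)
    return {
        c: estimate_map(by_chrom[c], markers[c], n_offspring, chrom=c) for c in markers
    }


def map_statistics(gmap: GeneticMap, chrom_length_bp: int) -> dict[str, float]:
    """Summary of one map: total cM, cM/Mb rate (2 dp) and marker-gap stats."""
    if gmap.positions_bp.size == 0:
        raise ValueError("empty map")
    if chrom_length_bp <= 0:
        raise ValueError("chrom_length_bp must be > 0")
    gaps = gmap.gaps_bp
    return {
        "total_cM": gmap.total_cM,
        "rate_cM_per_Mb": round(gmap.total_cM / (chrom_length_bp / 1e6), 2),
        "n_markers": int(gmap.positions_bp.size),
        "mean_gap_bp": float(gaps.mean()) if gaps.size else float("nan"),
        "median_gap_bp": float(np.median(gaps)) if gaps.size else float("nan"),
        "max_gap_bp": float(gaps.max()) if gaps.size else float("nan"),
    }


def mean_crossovers_per_offspring(
    crossovers: Iterable[CrossoverInterval] | Sequence[float],
    n_offspring: int,
    offspring_ids: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Mean and SD of per-offspring crossover counts (zeros included).

    The mean equals the total map length in Morgans by construction.  Accepts
    either CrossoverInterval records or a precomputed per-offspring count
    vector.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    xs = list(crossovers)
    if not xs:
        return 0.0, 0.0
    if isinstance(xs[0], CrossoverInterval):
        counts_by_id: dict[str, int] = {}
        for x in xs:
            counts_by_id[x.offspring_id] = counts_by_id.get(x.offspring_id, 0) + 1
        if offspring_ids is not None:
            counts = np.array([counts_by_id.get(o, 0) for o in offspring_ids], dtype=float)
            if counts.size != n_offspring:
                raise ValueError("offspring_ids length must equal n_offspring")
        else:
            counts = np.zeros(n_offspring)
            vals = list(counts_by_id.values())
            counts[: len(vals)] = vals
    else:
        counts = np.asarray(xs, dtype=float)
        if counts.size != n_offspring:
            raise ValueError("count vector length must equal n_offspring")
    mean = float(counts.sum() / n_offspring)
    sd = float(counts.std(ddof=1)) if n_offspring > 1 else 0.0
    return mean, sd
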