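"""Power to detect inversions of a given size from linkage maps alone.

A linkage map can only reveal an inverted segment if flipping the segment
would visibly reorder the map, which requires the segment to contain at
least two markers the map can order.  Random inversions of each candidate
size are placed uniformly across the genome and scored against this
criterion, giving a detection-power curve as a function of inversion size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import GeneticMap

__all__ = ["PowerCurve", "is_detectable", "power_curve"]

CRITERIA = ("two_informative", "two_markers")


@dataclass
class PowerCurve:
    size_bp: list[int]
    power: list[float]
    n_sim: int
    criterion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_bp": self.size_bp,
                "power": self.power,
                "n_sim": self.n_sim,
                "criterion": self.criterion,
            }
        )


def is_detectable(
    start_bp: int,
    end_bp: int,
    gmap: GeneticMap,
    criterion: str = "two_informative",
    chrom_length_bp: int | None = None,
) -> bool:
    """Would an inversion of [start_bp, end_bp) reorder this map?

    ``two_informative`` (default): the interval must contain >= 2 markers at
    distinct genetic (cM) positions — markers at identical cM are unordered by
    the map, so flipping them changes nothing.  ``two_markers``: >= 2 markers
    regardless of cM.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if start_bp < 0 or start_bp >= end_bp:
        raise ValueError("require 0 <= start_bp < end_bp")
    if chrom_length_bp is not None and end_bp > chrom_length_bp:
        raise ValueError("interval extends beyond the chromosome")
    pos = gmap.positions_bp
    i = int(np.searchsorted(pos, start_bp, side="left"))
    j = int(np.searchsorted(pos, end_bp, side="left"))
    if j - i < 2:
        return False
    if criterion == "two_markers":
        return True
    return np.unique(gmap.cM[i:j]).size >= 2


def power_curve(
    maps: Mapping[str, GeneticMap] | Sequence[Mapping[str, GeneticMap]],
    chrom_lengths: Mapping[str, int],
    sizes_bp: Sequence[int],
    n_sim: int = 10_000,
    seed: int = 0,
    criterion: str = "two_informative",
) -> PowerCurve:
    """Detection power for random inversions of each size.

    Placements pick a chromosome with probability proportional to its length
    and a uniform start, rejecting placements that cross a chromosome end.  A
    placement counts as detected if it is detectable in at least one of the
    supplied maps (pass one mapping for a single map, a sequence for a map
    set, e.g. both species).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if any(s <= 0 for s in sizes_bp):
        raise ValueError("sizes must be positive")
    map_sets = [maps] if isinstance(maps, Mapping) else list(maps)
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    rng = np.random.default_rng(seed)

    powers: list[float] = []
    for size in sizes_bp:
        if size > lens.max():
            raise ValueError(f"size {size} exceeds every chromosome length")
        # length-proportional chromosome choice with uniform start and
        # rejection of placements crossing the end is equivalent to weighting
        # each chromosome by its number of valid starts
        n_starts = np.maximum(lens - size + 1, 0)
        probs = n_starts / n_starts.sum()
        hits = 0
        for _ in range(n_sim):
            ci = int(rng.choice(len(names), p=probs))
            start = int(rng.integers(0, n_starts[ci]))
            chrom = names[ci]
            detected = any(
                chrom in ms
                and is_detectable(start, start + size, ms[chrom], criterion)
                for ms in map_sets
            )
            hits += detected
        powers.append(hits / n_sim)
    return PowerCurve(
        size_bp=[int(s) for s in sizes_bp],
        power=powers,
        n_sim=n_sim,
        criterion=criterion,
    )
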