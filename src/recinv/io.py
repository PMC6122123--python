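"""Plain-text readers and writers for every table the pipeline exchanges.

All files are TSV; coordinates are 0-based half-open throughout (positions in
the site-frequency table are 1-based single sites, as in VCF).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import CrossoverInterval, GeneticMap
from .sieve import ContigLayout, SplitReadCandidate, TrioScaffoldAlignment

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_crossovers",
    "read_crossovers",
    "write_map",
    "read_map",
    "write_candidates",
    "read_candidates",
    "write_alignments",
    "read_alignments",
    "write_contig_layout",
    "read_contig_layout",
    "write_site_frequencies",
    "read_site_frequencies",
]


# --- marker/genotype table: chrom, pos_bp, one column per offspring (A/B/N) --


def write_genotypes(dataset, path: str | Path) -> None:
    frames = []
    for chrom, calls in dataset.genotypes.items():
        df = pd.DataFrame(
            calls.T, columns=dataset.offspring_ids
        )
        df.insert(0, "pos_bp", dataset.markers[chrom])
        df.insert(0, "chrom", chrom)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path):
    """Returns (markers: dict chrom -> positions, genotypes: dict chrom -> matrix, offspring_ids)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    offspring = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    markers: dict[str, np.ndarray] = {}
    geno: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        pos = sub["pos_bp"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"duplicate or unordered marker positions on {chrom}")
        markers[chrom] = pos
        geno[chrom] = sub[offspring].to_numpy(dtype="U1").T
    return markers, geno, offspring


# --- crossover BED: chrom, left_bp, right_bp, offspring_id, group_label -----


def write_crossovers(crossovers: Iterable[CrossoverInterval], path: str | Path) -> None:
    pd.DataFrame(
        [
            (x.chrom, x.left_bp, x.right_bp, x.offspring_id, x.group_label)
            for x in crossovers
        ],
        columns=["chrom", "left_bp", "right_bp", "offspring_id", "group_label"],
    ).to_csv(path, sep="\t", index=False)


def read_crossovers(path: str | Path) -> list[CrossoverInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return [
        CrossoverInterval(
            offspring_id=str(r.offspring_id),
            chrom=str(r.chrom),
            left_bp=int(r.left_bp),
            right_bp=int(r.right_bp),
            group_label=str(r.group_label),
        )
        for r in df.itertuples()
    ]


# --- per-chromosome map TSV: chrom, pos_bp, cM ------------------------------


def write_map(maps: Mapping[str, GeneticMap], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"chrom": c, "pos_bp": m.positions_bp, "cM": m.cM})
        for c, m in maps.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_map(path: str | Path, n_offspring: int = 1) -> dict[str, GeneticMap]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        out[chrom] = GeneticMap(
            chrom=chrom,
            positions_bp=sub["pos_bp"].to_numpy(dtype=np.int64),
            cM=sub["cM"].to_numpy(dtype=float),
            n_offspring=n_offspring,
        )
    return out


# --- split-read candidates --------------------------------------------------

_CAND_COLS = ["chrom", "start_bp", "end_bp", "species", "sex", "support_reads", "support_tier"]


def write_candidates(candidates: Iterable[SplitReadCandidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.chrom, c.start_bp, c.end_bp, c.species, c.sex, c.support_reads, c.support_tier)
            for c in candidates
        ],
        columns=_CAND_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[SplitReadCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SplitReadCandidate(
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            species=str(r.species),
            sex=str(r.sex),
            support_reads=int(r.support_reads),
            support_tier=str(r.support_tier),
        )
        for r in df.itertuples()
    ]


# --- coords-style trio-scaffold alignments ----------------------------------

_ALN_COLS = [
    "scaffold", "species", "sex", "chrom",
    "ref_start_bp", "ref_end_bp", "orientation", "identity",
]


def write_alignments(alignments: Iterable[TrioScaffoldAlignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            (a.scaffold, a.species, a.sex, a.chrom, a.ref_start_bp, a.ref_end_bp, a.orientation, a.identity)
            for a in alignments
        ],
        columns=_ALN_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[TrioScaffoldAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        TrioScaffoldAlignment(
            scaffold=str(r.scaffold),
            species=str(r.species),
            sex=str(r.sex),
            chrom=str(r.chrom),
            ref_start_bp=int(r.ref_start_bp),
            ref_end_bp=int(r.ref_end_bp),
            orientation=str(r.orientation),
            identity=float(r.identity),
        )
        for r in df.itertuples()
    ]


# --- contig layout ----------------------------------------------------------


def write_contig_layout(layouts: Iterable[ContigLayout], path: str | Path) -> None:
    rows = [(cl.chrom, b) for cl in layouts for b in cl.boundaries_bp]
    pd.DataFrame(rows, columns=["chrom", "boundary_bp"]).to_csv(path, sep="\t", index=False)


def read_contig_layout(path: str | Path) -> list[ContigLayout]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ContigLayout(chrom=str(chrom), boundaries_bp=tuple(sub["boundary_bp"].astype(int)))
        for chrom, sub in df.groupby("chrom", sort=False)
    ]


# --- 4-population site frequencies ------------------------------------------


def write_site_frequencies(freqs: pd.DataFrame, path: str | Path) -> None:
    freqs.to_csv(path, sep="\t", index=False)


def read_site_frequencies(path: str | Path) -> pd.DataFrame:
    from .popgen import FREQ_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(FREQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site-frequency table missing columns: {sorted(missing)}")
    return df
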