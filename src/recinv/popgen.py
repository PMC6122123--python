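"""FST, dXY, D and fd in equal-sized windows around candidate inversions.

A candidate inversion acting as a barrier to gene flow should show elevated
FST (and possibly dXY) inside the inversion relative to its flanks; one that
carried an adaptive cassette between species should show elevated fd.  For
each candidate, up to 11 contiguous windows of the candidate's own length are
laid out (five upstream, the candidate, five downstream; windows falling off
the chromosome are dropped, not truncated) and the statistics are computed
per window from per-site derived-allele frequencies of four populations:
P1 and P2 (the focal pair for FST/dXY, with P2 the potential introgression
recipient), P3 (the donor) and an outgroup O.

Estimator choices: FST is the Hudson-type ratio of averages with the
(n-1) sample-size correction in the numerator; dXY is the mean per-site
pairwise difference p_a(1-p_b) + p_b(1-p_a); D and fd follow the standard
ABBA-BABA construction with fd's denominator replacing both p2 and p3 by
pD = max(p2, p3) site-wise.  fd is reported only for windows with D >= 0 —
it is not meaningful elsewhere — and is never clamped.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .windows import GenomeWindow

__all__ = [
    "layout_flanking_windows",
    "fst_window",
    "dxy_window",
    "fd_window",
    "candidate_window_stats",
]

FREQ_COLUMNS = ["chrom", "pos", "p1", "p2", "p3", "pO", "n1", "n2", "n3", "nO"]


def _sites_in(freqs: pd.DataFrame, window: GenomeWindow) -> pd.DataFrame:
    m = (
        (freqs["chrom"] == window.chrom)
        & (freqs["pos"] >= window.start_bp)
        & (freqs["pos"] < window.end_bp)
    )
    return freqs.loc[m]


def layout_flanking_windows(
    start_bp: int,
    end_bp: int,
    chrom: str,
    chrom_length_bp: int,
    n_flank: int = 5,
) -> list[GenomeWindow]:
    """Up to ``2*n_flank + 1`` contiguous windows of the candidate's length.

    Window index 0 is the candidate itself; negative indices are upstream,
    positive downstream.  Windows extending beyond either chromosome end are
    dropped entirely so all returned windows are equal-sized.
    """
    if not 0 <= start_bp < end_bp <= chrom_length_bp:
        raise ValueError("candidate must lie within the chromosome")
    size = end_bp - start_bp
    out = []
    for k in range(-n_flank, n_flank + 1):
        s = start_bp + k * size
        e = end_bp + k * size
        if s < 0 or e > chrom_length_bp:
            continue
        out.append(GenomeWindow(chrom, s, e, index=k))
    return out


def fst_window(
    freqs: pd.DataFrame,
    window: GenomeWindow | None = None,
    pops: tuple[str, str] = ("p1", "p2"),
) -> float:
    """Hudson-type FST between two populations, as a ratio of averages.

    Per-site numerator: (p_a - p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1);
    per-site denominator: p_a(1-p_b) + p_b(1-p_a).  Window FST is the sum of
    numerators over the sum of denominators; NaN when the window has no
    variation (zero total denominator) or no sites.
    """
    sites = _sites_in(freqs, window) if window is not None else freqs
    if len(sites) == 0:
        return float("nan")
    a, b = pops
    pa = sites[a].to_numpy(dtype=float)
    pb = sites[b].to_numpy(dtype=float)
    na = sites["n" + a[1:]].to_numpy(dtype=float)
    nb = sites["n" + b[1:]].to_numpy(dtype=float)
    if np.any(na < 2) or np.any(nb < 2):
        raise ValueError("haplotype counts must be >= 2 for the variance correction")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    tot = den.sum()
    if tot == 0:
        return float("nan")
    return float(num.sum() / tot)


def dxy_window(
    freqs: pd.DataFrame,
    window: GenomeWindow | None = None,
    pops: tuple[str, str] = ("p1", "p2"),
    n_total_sites: int | None = None,
) -> float:
    """Mean per-site divergence p_a(1-p_b) + p_b(1-p_a) between two populations.

    When ``n_total_sites`` gives the number of accessible sites in the window
    (monomorphic included), the per-site scaling uses it; otherwise the value
    is scaled over the variant sites present in the table only.
    """
    sites = _sites_in(freqs, window) if window is not None else freqs
    if len(sites) == 0:
        return float("nan")
    a, b = pops
    pa = sites[a].to_numpy(dtype=float)
    pb = sites[b].to_numpy(dtype=float)
    d = pa * (1 - pb) + pb * (1 - pa)
    denom = n_total_sites if n_total_sites is not None else len(sites)
    return float(d.sum() / denom)


def fd_window(
    freqs: pd.DataFrame, window: GenomeWindow | None = None
) -> tuple[float, float]:
    """ABBA-BABA D statistic and the fd admixture-proportion estimate.

    Per site, ABBA = (1-p1) p2 p3 (1-pO) and BABA = p1 (1-p2) p3 (1-pO);
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA).  fd shares D's
    numerator; its denominator recomputes ABBA-BABA with pD = max(p2, p3)
    substituted for both p2 and p3 (a complete-introgression donor).  fd is
    NaN when D < 0 or the denominator is zero.
    """
    sites = _sites_in(freqs, window) if window is not None else freqs
    if len(sites) == 0:
        return float("nan"), float("nan")
    p1 = sites["p1"].to_numpy(dtype=float)
    p2 = sites["p2"].to_numpy(dtype=float)
    p3 = sites["p3"].to_numpy(dtype=float)
    pO = sites["pO"].to_numpy(dtype=float)

    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    num = abba.sum() - baba.sum()
    tot = abba.sum() + baba.sum()
    d_stat = float(num / tot) if tot > 0 else 0.0  # no ABBA/BABA mass: no skew

    pD = np.maximum(p2, p3)
    abba_d = (1 - p1) * pD * pD * (1 - pO)
    baba_d = p1 * (1 - pD) * pD * (1 - pO)
    den = abba_d.sum() - baba_d.sum()

    if not math.isfinite(d_stat) or d_stat < 0 or den == 0:
        return d_stat, float("nan")
    return d_stat, float(num / den)


def candidate_window_stats(
    freqs: pd.DataFrame,
    candidates: Sequence[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_flank: int = 5,
) -> pd.DataFrame:
    """Windowed FST/dXY/D/fd around each candidate interval.

    ``candidates`` are (chrom, start_bp, end_bp) tuples; one row is produced
    per candidate per laid-out window, indexed -n_flank..+n_flank with 0 the
    candidate itself.
    """
    rows = []
    for ci, (chrom, start, end) in enumerate(candidates):
        wins = layout_flanking_windows(start, end, chrom, chrom_lengths[chrom], n_flank)
        for w in wins:
            sites = _sites_in(freqs, w)
            d_stat, fd = fd_window(freqs, w)
            rows.append(
                {
                    "candidate": ci,
                    "chrom": chrom,
                    "window_index": w.index,
                    "start_bp": w.start_bp,
                    "end_bp": w.end_bp,
                    "n_sites": len(sites),
                    "fst": fst_window(freqs, w),
                    "dxy": dxy_window(freqs, w),
                    "d_stat": d_stat,
                    "fd": fd,
                }
            )
    return pd.DataFrame(rows)
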