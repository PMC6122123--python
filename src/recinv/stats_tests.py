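"""Group comparisons of recombination: bootstrapped KS, window permutation tests, FDR.

Chromosome-scale comparisons use per-offspring per-chromosome crossover
counts, which are discrete with many ties, so significance of the one-sided
Kolmogorov-Smirnov statistic is calibrated by bootstrap resampling from the
pooled sample rather than by the asymptotic KS distribution.  Fine-scale
comparisons permute offspring group labels globally (each offspring carries
all its crossovers) and compare windowed map lengths.  Multiple testing is
controlled with Benjamini-Hochberg at a stated false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .linkage import CrossoverInterval
from .windows import GenomeWindow, crossover_mass_matrix

__all__ = [
    "TestResult",
    "ks_boot_one_tailed",
    "permutation_window_test",
    "bh_fdr",
]


@dataclass
class TestResult:
    unit: str
    comparison: tuple[str, str]
    statistic: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


# ---------------------------------------------------------------------------
# bootstrapped one-tailed KS on discrete counts
# ---------------------------------------------------------------------------


def _dplus(counts_a: np.ndarray, counts_b: np.ndarray, support: int) -> float:
    """One-sided KS statistic D+ = max_x [ECDF_b(x) - ECDF_a(x)]."""
    fa = np.cumsum(np.bincount(counts_a, minlength=support)) / counts_a.size
    fb = np.cumsum(np.bincount(counts_b, minlength=support)) / counts_b.size
    return float(np.max(fb - fa))


def ks_boot_one_tailed(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    n_boot: int = 10_000,
    seed: int = 0,
    unit: str = "",
    comparison: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Bootstrapped one-tailed KS test that sample b is stochastically smaller.

    The statistic is D+ = max_x [ECDF_b(x) - ECDF_a(x)]; its null distribution
    is built by redrawing both samples, at their original sizes, with
    replacement from the pooled sample ``n_boot`` times.  The p-value carries
    a +1 continuity correction so it is never exactly zero.  Suitable for
    discrete data with ties, such as per-offspring crossover counts.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative integers")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    support = int(max(a.max(), b.max())) + 1
    d_obs = _dplus(a, b, support)

    pooled = np.bincount(np.concatenate([a, b]), minlength=support)
    probs = pooled / pooled.sum()
    rng = np.random.default_rng(seed)
    # iid draws from the pooled ECDF == multinomial counts over its support
    ca = rng.multinomial(a.size, probs, size=n_boot)
    cb = rng.multinomial(b.size, probs, size=n_boot)
    fa = np.cumsum(ca, axis=1) / a.size
    fb = np.cumsum(cb, axis=1) / b.size
    d_null = np.max(fb - fa, axis=1)

    p = (1.0 + np.sum(d_null >= d_obs - 1e-12)) / (n_boot + 1.0)
    return TestResult(unit=unit, comparison=comparison, statistic=d_obs, p_value=float(p))


# ---------------------------------------------------------------------------
# window-scale permutation test
# ---------------------------------------------------------------------------


def permutation_window_test(
    crossovers: Iterable[CrossoverInterval],
    windows: Sequence[GenomeWindow],
    offspring_by_group: Mapping[str, Sequence[str]],
    n_perm: int = 270_000,
    seed: int = 0,
    tail: str = "two_sided",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Permutation test for per-window map-length differences between two groups.

    The observed statistic in each window is the difference in window cM
    (group b minus group a).  The null distribution shuffles offspring group
    labels globally, each offspring carrying all of its crossovers.  Per-window
    p = (1 + #{permuted statistic as or more extreme}) / (n_perm + 1);
    ``tail='less'`` tests for a reduction in group b, ``'two_sided'`` for any
    difference.  Benjamini-Hochberg q-values are computed across windows.
    """
    if tail not in ("two_sided", "less"):
        raise ValueError("tail must be 'two_sided' or 'less'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = list(offspring_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    ga, gb = groups
    ids_a = list(offspring_by_group[ga])
    ids_b = list(offspring_by_group[gb])
    all_ids = ids_a + ids_b
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("offspring ids must be unique across groups")
    na, nb = len(ids_a), len(ids_b)

    M = crossover_mass_matrix(list(crossovers), windows, all_ids)
    total = M.sum(axis=0)

    def stat_from_sa(sa: np.ndarray) -> np.ndarray:
        return 100.0 * ((total - sa) / nb - sa / na)

    obs = stat_from_sa(M[:na].sum(axis=0))

    rng = np.random.default_rng(seed)
    n_tot = na + nb
    exceed = np.zeros(len(windows), dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.permutation(n_tot)[:na]
        s = stat_from_sa(M[idx].sum(axis=0))
        if tail == "two_sided":
            exceed += np.abs(s) >= np.abs(obs) - 1e-12
        else:
            exceed += s <= obs + 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)

    q, sig = bh_fdr(p, alpha=alpha)
    return [
        TestResult(
            unit=f"{w.chrom}:{w.start_bp}-{w.end_bp}",
            comparison=(ga, gb),
            statistic=float(obs[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            significant=bool(sig[i]),
        )
        for i, w in enumerate(windows)
    ]


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, significance flags at alpha)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sig, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, sig


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "comparison": [f"{r.comparison[0]}_vs_{r.comparison[1]}" for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
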