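"""Synthetic crosses, inversions, split-read candidates, trio alignments and site frequencies.

This module generates every input the pipeline consumes, with known ground
truth, so that crossover detection, map estimation, rate testing, the
inversion-candidate sieve and the introgression statistics can all be exercised
end-to-end under controlled conditions.

The simulated biology follows the Heliconius-style study system:

* 21 chromosomes with realistic physical lengths (defaults come from the
  ordered Hmel2 assembly, ~272.6 Mb total);
* achiasmatic female meiosis — mothers transmit whole non-recombinant
  haplotypes, so every crossover observed in offspring is paternal;
* an obligate single male crossover per chromosome per meiosis, with the
  recombinant chromatid inherited half the time, giving ~50 cM per chromosome;
* within-species F1 crosses and hybrid backcrosses (F1 male x parental female)
  with roughly 300 offspring per group;
* species-specific inversions that suppress crossovers in heterozygous
  (hybrid) fathers, implemented by rejection sampling of crossover position;
* a split-read candidate process emulating a long-read SV caller, including
  spurious calls; trio-assembly scaffolds aligned back to the reference, with
  reverse-orientation segments inside carrier-species inversions;
* four-population derived-allele frequencies (P1, P2, P3, outgroup) under a
  simple drift model with a tunable fraction of P2 ancestry drawn from P3.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sieve import SplitReadCandidate, TrioScaffoldAlignment

__all__ = [
    "ChromosomeSpec",
    "CrossConfig",
    "TruthInversion",
    "CrossDataset",
    "simulate_cross",
    "simulate_split_read_candidates",
    "simulate_trio_alignments",
    "simulate_popgen_sites",
]

SPECIES_LABELS = ("melpomene", "cydno")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome with a name and physical length in bp."""

    name: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")


@dataclass
class CrossConfig:
    """Parameters of one simulated cross design.

    design
        ``within_species_F1`` (father homozygous for his species' inversions)
        or ``hybrid_backcross`` (F1 father heterozygous for every
        species-specific inversion, so crossover suppression applies).
    n_offspring, n_crosses
        offspring total and number of families they are split across.
    marker_gap_mean_bp
        mean of the exponential inter-marker gap distribution (defaults to the
        ~115 kb mean marker spacing of the real paternal maps).
    genotype_error_rate, missing_rate
        independent per-call phase-flip and missing-data probabilities.
    male_crossover_model
        ``obligate_single``: each offspring chromosome carries 0 or 1 paternal
        crossover with probability 1/2 each (one obligate chiasma, recombinant
        chromatid inherited half the time). ``poisson``: Poisson(0.5)
        crossovers per chromosome, same 50 cM expectation.
    """

    design: str = "within_species_F1"
    n_offspring: int = 300
    n_crosses: int = 1
    marker_gap_mean_bp: float = 115_000.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    male_crossover_model: str = "obligate_single"
    species: str = "melpomene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("within_species_F1", "hybrid_backcross"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.male_crossover_model not in ("obligate_single", "poisson"):
            raise ValueError(f"unknown crossover model {self.male_crossover_model!r}")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.n_crosses < 1:
            raise ValueError("n_crosses must be >= 1")
        if self.marker_gap_mean_bp <= 0:
            raise ValueError("marker_gap_mean_bp must be > 0")
        for name in ("genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def group_label(self) -> str:
        return "hybrid" if self.design == "hybrid_backcross" else self.species


@dataclass(frozen=True)
class TruthInversion:
    """A planted inversion: ground truth for the detection pipeline.

    ``suppression`` is the probability that a crossover falling inside the
    inverted interval is rejected (and redrawn) in a heterozygous father.
    """

    chrom: str
    start_bp: int
    end_bp: int
    carrier_species: str
    suppression: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError("inversion requires 0 <= start_bp < end_bp")
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression must be in [0, 1]")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class CrossDataset:
    """A simulated cross with ground truth.

    ``genotypes`` holds the paternal-phase call matrix (offspring x marker,
    values ``A``/``B``/``N``) per chromosome; ``maternal_genotypes`` the
    maternal-phase calls, which are constant along each chromosome because
    female meiosis is achiasmatic.  ``truth_crossovers`` records the exact
    paternal crossover positions before any genotyping noise;
    ``truth_maternal_crossovers`` exists only to make the achiasmy guarantee
    explicit and is always empty.
    """

    chromosomes: list[ChromosomeSpec]
    markers: dict[str, np.ndarray]
    offspring_ids: list[str]
    offspring_sex: list[str]
    group_labels: list[str]
    cross_ids: list[str]
    genotypes: dict[str, np.ndarray]
    maternal_genotypes: dict[str, np.ndarray]
    truth_crossovers: pd.DataFrame  # columns: offspring_id, chrom, pos_bp
    truth_maternal_crossovers: pd.DataFrame
    config: CrossConfig = None

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)

    def chrom_length(self, chrom: str) -> int:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.length_bp
        raise KeyError(chrom)


# ---------------------------------------------------------------------------
# cross simulation
# ---------------------------------------------------------------------------


def _check_genome(genome: Sequence[ChromosomeSpec]) -> dict[str, int]:
    lengths = {c.name: c.length_bp for c in genome}
    if len(lengths) != len(genome):
        raise ValueError("chromosome names must be unique")
    return lengths


def _check_inversions(
    inversions: Iterable[TruthInversion], lengths: dict[str, int]
) -> list[TruthInversion]:
    out = list(inversions)
    for inv in out:
        if inv.chrom not in lengths:
            raise ValueError(f"inversion on unknown chromosome {inv.chrom!r}")
        if inv.end_bp > lengths[inv.chrom]:
            raise ValueError(
                f"inversion [{inv.start_bp}, {inv.end_bp}) outside {inv.chrom}"
            )
    return out


def _draw_marker_positions(
    rng: np.random.Generator, length_bp: int, mean_gap_bp: float
) -> np.ndarray:
    """Exponential inter-marker gaps along [0, length_bp); at least 2 markers."""
    n_expect = max(4, int(length_bp / mean_gap_bp * 2))
    pos: list[int] = []
    x = rng.exponential(mean_gap_bp)
    while x < length_bp:
        pos.append(int(x))
        x += rng.exponential(mean_gap_bp)
        if len(pos) > n_expect * 4:  # safety for tiny mean gaps
            break
    arr = np.unique(np.asarray(pos, dtype=np.int64))
    if arr.size < 2:  # degenerate short chromosome: anchor both ends
        arr = np.unique(
            np.array([length_bp // 3, (2 * length_bp) // 3], dtype=np.int64)
        )
        if arr.size < 2:
            arr = np.array([0, max(1, length_bp - 1)], dtype=np.int64)
    return arr


def _draw_crossover_positions(
    rng: np.random.Generator,
    n: int,
    length_bp: int,
    suppressed: list[tuple[int, int, float]],
) -> np.ndarray:
    """Uniform crossover positions with rejection inside suppressed intervals."""
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        for _ in range(10_000):
            p = int(rng.integers(0, length_bp))
            hit = next((s for s in suppressed if s[0] <= p < s[1]), None)
            if hit is None or rng.random() >= hit[2]:
                out[i] = p
                break
        else:  # pragma: no cover - only reachable with pathological configs
            raise RuntimeError("crossover rejection sampling did not converge")
    return out


def simulate_cross(
    config: CrossConfig,
    genome: Sequence[ChromosomeSpec] | None = None,
    inversions: Iterable[TruthInversion] = (),
) -> CrossDataset:
    """Simulate one cross design on a genome with optional planted inversions.

    Paternal meiosis follows the configured crossover model; crossover
    positions are uniform on physical length, redrawn when they land inside a
    suppressed inversion interval in a heterozygous (hybrid-backcross) father.
    Maternal meiosis is achiasmatic and contributes no crossovers.  Genotypes
    are derived from the true phases and then perturbed by independent
    flip/missing noise.  Deterministic for a fixed config (including seed).
    """
    if genome is None:
        from .tables import hmel2_genome

        genome = hmel2_genome()
    lengths = _check_genome(genome)
    inversions = _check_inversions(inversions, lengths)

    rng = np.random.default_rng(config.seed)
    n = config.n_offspring

    offspring_ids = [f"{config.group_label}_o{i:04d}" for i in range(n)]
    offspring_sex = list(rng.choice(["female", "male"], size=n))
    cross_ids = [f"{config.group_label}_cross{(i % config.n_crosses) + 1}" for i in range(n)]
    group_labels = [config.group_label] * n

    # inversions suppress crossovers only in heterozygous fathers (hybrids)
    heterozygous = config.design == "hybrid_backcross"

    markers: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    maternal: dict[str, np.ndarray] = {}
    xo_rows: list[tuple[str, str, int]] = []

    for chrom in genome:
        pos = _draw_marker_positions(rng, chrom.length_bp, config.marker_gap_mean_bp)
        markers[chrom.name] = pos
        m = pos.size

        suppressed = [
            (inv.start_bp, inv.end_bp, inv.suppression)
            for inv in inversions
            if heterozygous and inv.chrom == chrom.name and inv.suppression > 0
        ]

        if config.male_crossover_model == "obligate_single":
            n_xo = (rng.random(n) < 0.5).astype(np.int64)
        else:
            n_xo = rng.poisson(0.5, size=n)

        start_phase = rng.integers(0, 2, size=n)  # 0 -> A, 1 -> B
        phase = np.broadcast_to(start_phase[:, None], (n, m)).copy()
        for i in range(n):
            if n_xo[i] == 0:
                continue
            xo_pos = _draw_crossover_positions(rng, int(n_xo[i]), chrom.length_bp, suppressed)
            for p in np.sort(xo_pos):
                xo_rows.append((offspring_ids[i], chrom.name, int(p)))
                phase[i, pos >= p] ^= 1

        calls = np.where(phase == 0, "A", "B").astype("U1")
        calls = _apply_noise(rng, calls, config.genotype_error_rate, config.missing_rate)
        genotypes[chrom.name] = calls

        # maternal haplotype: whole-chromosome transmission, no recombination
        mat_phase = rng.integers(0, 2, size=n)
        mat_calls = np.where(
            np.broadcast_to(mat_phase[:, None], (n, m)) == 0, "A", "B"
        ).astype("U1")
        mat_calls = _apply_noise(rng, mat_calls, config.genotype_error_rate, config.missing_rate)
        maternal[chrom.name] = mat_calls

    truth = pd.DataFrame(xo_rows, columns=["offspring_id", "chrom", "pos_bp"])
    truth_maternal = pd.DataFrame(columns=["offspring_id", "chrom", "pos_bp"])

    return CrossDataset(
        chromosomes=list(genome),
        markers=markers,
        offspring_ids=offspring_ids,
        offspring_sex=offspring_sex,
        group_labels=group_labels,
        cross_ids=cross_ids,
        genotypes=genotypes,
        maternal_genotypes=maternal,
        truth_crossovers=truth,
        truth_maternal_crossovers=truth_maternal,
        config=config,
    )


def _apply_noise(
    rng: np.random.Generator, calls: np.ndarray, error_rate: float, missing_rate: float
) -> np.ndarray:
    out = calls.copy()
    if error_rate > 0:
        flip = rng.random(out.shape) < error_rate
        out[flip & (out == "A")] = "b"  # temp to avoid double flip
        out[flip & (out == "B")] = "A"
        out[out == "b"] = "B"
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = "N"
    return out


# ---------------------------------------------------------------------------
# split-read candidates
# ---------------------------------------------------------------------------


def simulate_split_read_candidates(
    truth: Sequence[TruthInversion],
    fp_count: int,
    genome: Sequence[ChromosomeSpec],
    seed: int = 0,
    fp_mean_length_bp: float = 20_000.0,
    species_labels: Sequence[str] = SPECIES_LABELS,
) -> list[SplitReadCandidate]:
    """Emulate a split-read SV caller's inversion candidates.

    Every true inversion yields a default-tier candidate in both sexes of the
    carrier species.  ``fp_count`` spurious candidates are placed uniformly on
    the genome (chromosome chosen proportional to length) with exponential
    lengths, random species/sex and a mix of default/tentative support tiers —
    emulating the caller's substantial false-positive process.
    """
    if fp_count < 0:
        raise ValueError("fp_count must be >= 0")
    lengths = _check_genome(genome)
    _check_inversions(truth, lengths)
    rng = np.random.default_rng(seed)

    out: list[SplitReadCandidate] = []
    for inv in truth:
        for sex in ("female", "male"):
            out.append(
                SplitReadCandidate(
                    chrom=inv.chrom,
                    start_bp=inv.start_bp,
                    end_bp=inv.end_bp,
                    species=inv.carrier_species,
                    sex=sex,
                    support_reads=int(rng.integers(3, 13)),
                    support_tier="default",
                )
            )

    names = list(lengths)
    probs = np.array([lengths[c] for c in names], dtype=float)
    probs /= probs.sum()
    for _ in range(fp_count):
        chrom = names[int(rng.choice(len(names), p=probs))]
        L = lengths[chrom]
        length = max(200, int(rng.exponential(fp_mean_length_bp)))
        length = min(length, L - 1)
        start = int(rng.integers(0, L - length))
        tier = "default" if rng.random() < 0.5 else "tentative"
        out.append(
            SplitReadCandidate(
                chrom=chrom,
                start_bp=start,
                end_bp=start + length,
                species=str(rng.choice(list(species_labels))),
                sex=str(rng.choice(["female", "male"])),
                support_reads=int(rng.integers(2, 4)) if tier == "tentative" else int(rng.integers(3, 13)),
                support_tier=tier,
            )
        )
    return out


# ---------------------------------------------------------------------------
# trio-scaffold alignments
# ---------------------------------------------------------------------------


def simulate_trio_alignments(
    truth: Sequence[TruthInversion],
    genome: Sequence[ChromosomeSpec],
    scaffold_n50_bp: int = 25_000,
    seed: int = 0,
    species_labels: Sequence[str] = SPECIES_LABELS,
) -> list[TrioScaffoldAlignment]:
    """Emulate coords-style alignments of haplotypic trio-assembly scaffolds.

    Each species/sex haplotype is tiled with scaffolds whose lengths are
    exponential with the requested N50 (for an exponential length distribution
    the length-weighted median is ~1.678x the mean).  Scaffolds of the carrier
    species crossing an inversion produce reverse-orientation segments inside
    the inverted interval flanked by forward segments; non-carrier scaffolds
    align collinearly across the same interval.
    """
    if scaffold_n50_bp <= 0:
        raise ValueError("scaffold_n50_bp must be > 0")
    lengths = _check_genome(genome)
    _check_inversions(truth, lengths)
    rng = np.random.default_rng(seed)
    mean_len = scaffold_n50_bp / 1.678

    out: list[TrioScaffoldAlignment] = []
    for species in species_labels:
        carried = [inv for inv in truth if inv.carrier_species == species]
        for sex in ("female", "male"):
            for chrom, L in lengths.items():
                inv_here = sorted(
                    ((inv.start_bp, inv.end_bp) for inv in carried if inv.chrom == chrom)
                )
                start = 0
                k = 0
                while start < L:
                    length = max(1_000, int(rng.exponential(mean_len)))
                    end = min(L, start + length)
                    name = f"{species}_{sex}_{chrom}_s{k:05d}"
                    # split the scaffold's alignment at inversion boundaries
                    cuts = [start]
                    for a, b in inv_here:
                        if a < end and b > start:
                            cuts.extend([max(start, a), min(end, b)])
                    cuts.append(end)
                    cuts = sorted(set(cuts))
                    for a, b in zip(cuts[:-1], cuts[1:]):
                        inside = any(ia <= a and b <= ib for ia, ib in inv_here)
                        out.append(
                            TrioScaffoldAlignment(
                                scaffold=name,
                                species=species,
                                sex=sex,
                                chrom=chrom,
                                ref_start_bp=a,
                                ref_end_bp=b,
                                orientation="reverse" if inside else "forward",
                                identity=float(np.round(99.0 + rng.random(), 2)),
                            )
                        )
                    start = end
                    k += 1
    return out


# ---------------------------------------------------------------------------
# four-population site frequencies
# ---------------------------------------------------------------------------


def simulate_popgen_sites(
    n_sites: int,
    gamma: float,
    n_hap: int = 20,
    seed: int = 0,
    chrom: str = "chr1",
    spacing_bp: int = 100,
    drift_sd: float = 0.2,
    outgroup_poly_rate: float = 0.05,
) -> pd.DataFrame:
    """Derived-allele frequencies for P1, P2, P3 and an outgroup O.

    A shared ancestral frequency drifts independently into the (P1, P2)
    lineage and the P3 lineage; P1 and P2 then drift from their common
    lineage.  At a fraction ``gamma`` of sites, P2's ancestry is drawn from
    the P3 lineage instead (site-level introgression), producing an ABBA
    excess roughly proportional to gamma.  The outgroup is fixed ancestral at
    most sites.  Observed frequencies are binomial samples of ``n_hap``
    haplotypes per population.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    rng = np.random.default_rng(seed)

    def drift(p: np.ndarray, sd: float) -> np.ndarray:
        return np.clip(p + rng.normal(0.0, sd, size=p.shape), 0.0, 1.0)

    p_root = rng.beta(0.5, 0.5, size=n_sites)
    p3 = drift(p_root, drift_sd)
    p12 = drift(p_root, drift_sd)
    p1 = drift(p12, drift_sd / 2)
    p2 = drift(p12, drift_sd / 2)
    introgressed = rng.random(n_sites) < gamma
    p2 = np.where(introgressed, drift(p3, drift_sd / 2), p2)
    pO = np.where(
        rng.random(n_sites) < outgroup_poly_rate,
        rng.beta(0.5, 5.0, size=n_sites),
        0.0,
    )

    cols = {}
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3), ("pO", pO)):
        counts = rng.binomial(n_hap, p)
        cols[name] = counts / n_hap
        cols["n" + name[1:]] = np.full(n_sites, n_hap, dtype=np.int64)

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp,
            "p1": cols["p1"],
            "p2": cols["p2"],
            "p3": cols["p3"],
            "pO": cols["pO"],
            "n1": cols["n1"],
            "n2": cols["n2"],
            "n3": cols["n3"],
            "nO": cols["nO"],
        }
    )
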