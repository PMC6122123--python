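"""Multi-filter sieve for split-read inversion candidates, with evidence classification.

Raw split-read candidates from a long-read SV caller have a high false-positive
rate, so they are filtered against independent evidence before being taken
seriously:

1. linkage maps — a candidate is rejected if a crossover of the same species
   is localized entirely inside it (an inversion heterozygous or fixed between
   the species should not recombine internally in that species' map);
2. trio-assembly scaffolds — a candidate is rejected when a single collinear
   (forward) same-species alignment spans it, extending more than half the
   candidate length beyond both breakpoints;
3. length — candidates shorter than 1 kb are rejected, since linkage
   disequilibrium at that scale is above background anyway;
4. tentative-tier candidates (from low-coverage samples, called with relaxed
   read support) are rescued only where they overlap a default-tier candidate
   from a different sample.

Survivors are merged into groups by interval overlap, and each group is
classified by the joint split-read / trio-assembly evidence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SplitReadCandidate",
    "TrioScaffoldAlignment",
    "ContigLayout",
    "CandidateGroup",
    "filter_by_recombination",
    "filter_by_trio_span",
    "filter_by_length",
    "rescue_tentative",
    "merge_groups",
    "classify_groups",
    "run_sieve",
]

SUPPORT_TIERS = ("default", "tentative")
CLASSIFICATIONS = ("split_and_trio", "split_only", "split_one_trio_both")


@dataclass(frozen=True)
class SplitReadCandidate:
    """A putative inversion interval called from split long reads."""

    chrom: str
    start_bp: int
    end_bp: int
    species: str
    sex: str
    support_reads: int = 3
    support_tier: str = "default"

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError("candidate requires start_bp < end_bp")
        if self.support_reads < 1:
            raise ValueError("support_reads must be >= 1")
        if self.support_tier not in SUPPORT_TIERS:
            raise ValueError(f"support_tier must be one of {SUPPORT_TIERS}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def sample(self) -> tuple[str, str]:
        return (self.species, self.sex)


@dataclass(frozen=True)
class TrioScaffoldAlignment:
    """One aligned segment of a haplotypic trio-assembly scaffold."""

    scaffold: str
    species: str
    sex: str
    chrom: str
    ref_start_bp: int
    ref_end_bp: int
    orientation: str
    identity: float = 99.0

    def __post_init__(self) -> None:
        if not self.ref_start_bp < self.ref_end_bp:
            raise ValueError("alignment requires ref_start_bp < ref_end_bp")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")


@dataclass(frozen=True)
class ContigLayout:
    """Contig boundary positions along one chromosome."""

    chrom: str
    boundaries_bp: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries_bp", tuple(sorted(self.boundaries_bp)))


@dataclass
class CandidateGroup:
    chrom: str
    start_bp: int
    end_bp: int
    members: list[SplitReadCandidate]
    classification: str = ""
    species_set: frozenset = frozenset()
    near_contig_boundary: bool = False

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


# ---------------------------------------------------------------------------
# filters (each a pure predicate on one candidate; order-independent)
# ---------------------------------------------------------------------------


def filter_by_recombination(
    candidates: Iterable[SplitReadCandidate],
    crossovers: Iterable,
    crossover_species=None,
) -> tuple[list[SplitReadCandidate], list[SplitReadCandidate]]:
    """Reject candidates containing a same-species crossover interval.

    A crossover rejects a candidate only when its localization interval is
    entirely contained within the candidate (partial overlap means the
    crossover may have occurred outside).  ``crossovers`` are
    CrossoverInterval records whose ``group_label`` names the species, unless
    ``crossover_species`` supplies the species per crossover.
    """
    xs = list(crossovers)
    species = (
        list(crossover_species)
        if crossover_species is not None
        else [x.group_label for x in xs]
    )
    kept, rejected = [], []
    for c in candidates:
        contained = any(
            sp == c.species
            and x.chrom == c.chrom
            and c.start_bp <= x.left_bp
            and x.right_bp <= c.end_bp
            for x, sp in zip(xs, species)
        )
        (rejected if contained else kept).append(c)
    return kept, rejected


def filter_by_trio_span(
    candidates: Iterable[SplitReadCandidate],
    alignments: Iterable[TrioScaffoldAlignment],
    span_mode: str = "both",
) -> tuple[list[SplitReadCandidate], list[SplitReadCandidate]]:
    """Reject candidates spanned collinearly by a same-species trio scaffold.

    A single forward-orientation alignment of the candidate's own species must
    cover the whole candidate and extend more than half the candidate length
    beyond the breakpoints — beyond both under ``span_mode='both'`` (default),
    beyond at least one under ``'either'``.  Reverse alignments never reject
    (an inverted hit supports, rather than refutes, an inversion).
    """
    if span_mode not in ("both", "either"):
        raise ValueError("span_mode must be 'both' or 'either'")
    alns = [a for a in alignments if a.orientation == "forward"]
    kept, rejected = [], []
    for c in candidates:
        half = c.length_bp / 2.0
        spanned = False
        for a in alns:
            if a.species != c.species or a.chrom != c.chrom:
                continue
            left_ext = c.start_bp - a.ref_start_bp
            right_ext = a.ref_end_bp - c.end_bp
            if left_ext < 0 or right_ext < 0:  # must cover the candidate
                continue
            if span_mode == "both":
                spanned = left_ext > half and right_ext > half
            else:
                spanned = left_ext > half or right_ext > half
            if spanned:
                break
        (rejected if spanned else kept).append(c)
    return kept, rejected


def filter_by_length(
    candidates: Iterable[SplitReadCandidate], min_bp: int = 1_000
) -> tuple[list[SplitReadCandidate], list[SplitReadCandidate]]:
    """Reject candidates strictly shorter than ``min_bp`` (default 1 kb)."""
    if min_bp <= 0:
        raise ValueError("min_bp must be > 0")
    kept, rejected = [], []
    for c in candidates:
        (kept if c.length_bp >= min_bp else rejected).append(c)
    return kept, rejected


def rescue_tentative(
    candidates_default: Sequence[SplitReadCandidate],
    candidates_tentative: Sequence[SplitReadCandidate],
) -> list[SplitReadCandidate]:
    """Keep tentative candidates only where corroborated by another sample.

    A tentative candidate survives iff it overlaps at least one default-tier
    candidate from a different sample (species/sex combination).  All default
    candidates are retained unconditionally.
    """
    out = list(candidates_default)
    for t in candidates_tentative:
        if any(
            d.sample != t.sample
            and d.chrom == t.chrom
            and _overlaps(t.start_bp, t.end_bp, d.start_bp, d.end_bp)
            for d in candidates_default
        ):
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# grouping and classification
# ---------------------------------------------------------------------------


def merge_groups(candidates: Iterable[SplitReadCandidate]) -> list[CandidateGroup]:
    """Connected components of the interval-overlap graph (>= 1 bp, same chromosome)."""
    by_chrom: dict[str, list[SplitReadCandidate]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    groups: list[CandidateGroup] = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.start_bp, c.end_bp))
        cur: list[SplitReadCandidate] = []
        cur_end = -1
        for c in cs:
            if cur and c.start_bp < cur_end:  # overlap (half-open intervals)
                cur.append(c)
                cur_end = max(cur_end, c.end_bp)
            else:
                if cur:
                    groups.append(
                        CandidateGroup(
                            chrom,
                            min(m.start_bp for m in cur),
                            cur_end,
                            cur,
                            species_set=frozenset(m.species for m in cur),
                        )
                    )
                cur = [c]
                cur_end = c.end_bp
        if cur:
            groups.append(
                CandidateGroup(
                    chrom,
                    min(m.start_bp for m in cur),
                    cur_end,
                    cur,
                    species_set=frozenset(m.species for m in cur),
                )
            )
    return groups


def _trio_inversion_evidence(
    group: CandidateGroup, alignments: Sequence[TrioScaffoldAlignment]
) -> set[str]:
    """Species whose trio scaffolds show forward+reverse alignments across a breakpoint.

    Evidence requires a single scaffold with at least one reverse-orientation
    alignment overlapping the group interval and at least one forward
    alignment extending outside it — i.e. segments in both orientations on
    either side of an inversion breakpoint.
    """
    by_scaffold: dict[str, list[TrioScaffoldAlignment]] = {}
    for a in alignments:
        if a.chrom == group.chrom:
            by_scaffold.setdefault(a.scaffold, []).append(a)
    species: set[str] = set()
    for alns in by_scaffold.values():
        rev_in = any(
            a.orientation == "reverse"
            and _overlaps(a.ref_start_bp, a.ref_end_bp, group.start_bp, group.end_bp)
            for a in alns
        )
        fwd_out = any(
            a.orientation == "forward"
            and (a.ref_start_bp < group.start_bp or a.ref_end_bp > group.end_bp)
            for a in alns
        )
        if rev_in and fwd_out:
            species.add(alns[0].species)
    return species


def classify_groups(
    groups: Sequence[CandidateGroup],
    alignments: Sequence[TrioScaffoldAlignment],
    contigs: Sequence[ContigLayout] = (),
    near_bp: int = 5_000,
    all_species: Sequence[str] | None = None,
) -> list[CandidateGroup]:
    """Assign an evidence class and contig-boundary flag to each group.

    * ``split_one_trio_both`` — split reads in only one species, but inverted
      trio scaffolds in both;
    * ``split_and_trio`` — some species has both split-read and inverted
      trio-scaffold evidence;
    * ``split_only`` — split reads with no inverted trio scaffolds.

    ``near_contig_boundary`` flags groups with a breakpoint within ``near_bp``
    of a contig boundary (misassembly-prone regions).
    """
    if near_bp < 0:
        raise ValueError("near_bp must be >= 0")
    boundaries = {cl.chrom: cl.boundaries_bp for cl in contigs}
    if all_species is None:
        all_species = sorted(
            {c.species for g in groups for c in g.members}
            | {a.species for a in alignments}
        )
    for g in groups:
        if not g.members:
            raise ValueError("cannot classify an empty group")
        split_species = frozenset(c.species for c in g.members)
        trio_species = _trio_inversion_evidence(g, alignments)
        if (
            len(split_species) == 1
            and len(all_species) > 1
            and set(all_species) <= trio_species
        ):
            g.classification = "split_one_trio_both"
            g.species_set = frozenset(all_species)
        elif split_species & trio_species:
            g.classification = "split_and_trio"
            g.species_set = split_species
        else:
            g.classification = "split_only"
            g.species_set = split_species
        bs = boundaries.get(g.chrom, ())
        g.near_contig_boundary = any(
            abs(bp - b) <= near_bp for bp in (g.start_bp, g.end_bp) for b in bs
        )
    return list(groups)


# ---------------------------------------------------------------------------
# full sieve
# ---------------------------------------------------------------------------


def run_sieve(
    candidates: Sequence[SplitReadCandidate],
    crossovers: Iterable = (),
    alignments: Sequence[TrioScaffoldAlignment] = (),
    contigs: Sequence[ContigLayout] = (),
    min_bp: int = 1_000,
    span_mode: str = "both",
    near_bp: int = 5_000,
) -> tuple[list[CandidateGroup], pd.DataFrame]:
    """Run every filter, rescue, merge and classify; return groups and a report.

    Default-tier candidates pass through the recombination, trio-span and
    length filters; surviving tentative-tier candidates are then rescued where
    they overlap surviving default candidates from another sample.  The report
    records one row per input candidate with its decision and the first rule
    it failed (the filters are pure per-candidate predicates, so the rejection
    reasons partition the rejected set regardless of evaluation order).
    """
    reasons: dict[SplitReadCandidate, str] = {}

    def apply(cands, name, fn):
        kept, rejected = fn(cands)
        for c in rejected:
            reasons.setdefault(c, name)
        return kept

    default = [c for c in candidates if c.support_tier == "default"]
    tentative = [c for c in candidates if c.support_tier == "tentative"]

    def sieve_one_tier(cands):
        cands = apply(cands, "recombination", lambda cs: filter_by_recombination(cs, crossovers))
        cands = apply(cands, "trio_span", lambda cs: filter_by_trio_span(cs, alignments, span_mode))
        cands = apply(cands, "length", lambda cs: filter_by_length(cs, min_bp))
        return cands

    default_kept = sieve_one_tier(default)
    tentative_kept = sieve_one_tier(tentative)
    survivors = rescue_tentative(default_kept, tentative_kept)
    for c in tentative_kept:
        if c not in survivors:
            reasons.setdefault(c, "unrescued_tentative")

    groups = merge_groups(survivors)
    classify_groups(groups, alignments, contigs, near_bp)

    surviving = set(id(c) for c in survivors)
    report = pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "start_bp": [c.start_bp for c in candidates],
            "end_bp": [c.end_bp for c in candidates],
            "species": [c.species for c in candidates],
            "sex": [c.sex for c in candidates],
            "support_tier": [c.support_tier for c in candidates],
            "decision": ["kept" if id(c) in surviving else "rejected" for c in candidates],
            "reason": [
                "" if id(c) in surviving else reasons.get(c, "") for c in candidates
            ],
        }
    )
    return groups, report
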