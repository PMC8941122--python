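"""Chromosome-level organization of a gene family.

Gene families that expand by tandem duplication, as DUF26 receptor
kinases do, pile up on a few chromosomes, sit in tight physical clusters,
and tend toward the telomeric ends of chromosome arms.  This module
quantifies those three observations: per-chromosome counts, tandem-cluster
detection under an explicit distance / intervening-gene criterion, and the
fraction of family members whose midpoint falls on a terminal arm.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import GeneLocus

__all__ = [
    "ClusterPolicy",
    "TandemCluster",
    "chromosome_counts",
    "detect_tandem_clusters",
    "terminal_arm_fraction",
]

_UNPLACED = re.compile(r"^(scaffold|contig|tig|un\b|chrun)", re.IGNORECASE)


@dataclass(frozen=True)
class ClusterPolicy:
    """Criterion joining two consecutive family members into one cluster.

    ``max_gap_bp`` bounds the distance between nearest gene boundaries;
    ``max_intervening`` bounds the number of non-family genes between them
    (only applied when the full gene set is supplied; −1 disables it);
    ``arm_fraction`` is the fraction of chromosome length counted as each
    terminal arm.
    """

    max_gap_bp: int = 250_000
    max_intervening: int = 8
    arm_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.max_gap_bp > 0:
            raise ValueError("max_gap_bp must be positive")
        if not (0 < self.arm_fraction < 0.5):
            raise ValueError("arm_fraction must lie in (0, 0.5)")


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]
    span_start: int
    span_end: int

    @property
    def member_count(self) -> int:
        return len(self.members)


def chromosome_counts(loci: Iterable[GeneLocus]) -> dict[tuple[str, str], int]:
    """Count family genes per (species, chromosome).

    Unplaced scaffolds and contigs are pooled under ``"unplaced"`` so that
    density comparisons only involve assembled chromosomes.
    """
    counts: dict[tuple[str, str], int] = {}
    for locus in loci:
        chrom = locus.chromosome
        if _UNPLACED.match(chrom):
            chrom = "unplaced"
        key = (locus.species, chrom)
        counts[key] = counts.get(key, 0) + 1
    return counts


def detect_tandem_clusters(
    family_loci: Sequence[GeneLocus],
    all_loci: Optional[Sequence[GeneLocus]] = None,
    policy: Optional[ClusterPolicy] = None,
) -> list[TandemCluster]:
    """Find tandem clusters (runs of ≥2 family members) per chromosome.

    Two consecutive family members chain into one cluster iff the distance
    between their nearest boundaries is at most ``max_gap_bp`` and, when
    the full gene set is given and ``max_intervening ≥ 0``, no more than
    ``max_intervening`` non-family genes start between them.  Clusters are
    the transitive closure of that relation; singletons are not reported.
    """
    policy = policy or ClusterPolicy()
    family_ids = {l.gene_id for l in family_loci}
    use_intervening = all_loci is not None and policy.max_intervening >= 0
    if all_loci is not None:
        present = {l.gene_id for l in all_loci}
        missing = sorted(family_ids - present)
        if missing:
            raise ValueError(f"full gene set is missing family genes: {missing}")

    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in family_loci:
        by_chrom.setdefault((locus.species, locus.chromosome), []).append(locus)

    others_by_chrom: dict[tuple[str, str], list[int]] = {}
    if use_intervening:
        for locus in all_loci:  # type: ignore[union-attr]
            if locus.gene_id in family_ids:
                continue
            others_by_chrom.setdefault(
                (locus.species, locus.chromosome), []
            ).append(locus.start)
        for starts in others_by_chrom.values():
            starts.sort()

    clusters: list[TandemCluster] = []
    for key in sorted(by_chrom):
        members = sorted(by_chrom[key], key=lambda l: (l.start, l.end))
        other_starts = others_by_chrom.get(key, [])
        run: list[GeneLocus] = [members[0]]
        for prev, cur in zip(members, members[1:]):
            gap = max(0, cur.start - prev.end - 1)
            joined = gap <= policy.max_gap_bp
            if joined and use_intervening:
                n_between = bisect.bisect_left(
                    other_starts, cur.start
                ) - bisect.bisect_right(other_starts, prev.start)
                joined = n_between <= policy.max_intervening
            if joined:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(key[1], run))
                run = [cur]
        if len(run) >= 2:
            clusters.append(_make_cluster(key[1], run))
    return clusters


def _make_cluster(chromosome: str, run: Sequence[GeneLocus]) -> TandemCluster:
    return TandemCluster(
        chromosome=chromosome,
        members=tuple(l.gene_id for l in run),
        span_start=min(l.start for l in run),
        span_end=max(l.end for l in run),
    )


def terminal_arm_fraction(
    family_loci: Sequence[GeneLocus],
    chromosome_lengths: dict[str, int],
    policy: Optional[ClusterPolicy] = None,
) -> tuple[float, dict[str, tuple[int, int]]]:
    """Fraction of family genes lying on a terminal chromosome arm.

    A gene is terminal iff its midpoint lies within ``arm_fraction`` of the
    chromosome length from either end.  Returns the overall fraction and a
    per-chromosome ``(terminal, total)`` breakdown.
    """
    policy = policy or ClusterPolicy()
    terminal = 0
    breakdown: dict[str, tuple[int, int]] = {}
    for locus in family_loci:
        if locus.chromosome not in chromosome_lengths:
            raise ValueError(f"no length known for chromosome {locus.chromosome!r}")
        length = chromosome_lengths[locus.chromosome]
        mid = locus.midpoint
        is_terminal = mid <= policy.arm_fraction * length or mid >= (
            1 - policy.arm_fraction
        ) * length
        t, n = breakdown.get(locus.chromosome, (0, 0))
        breakdown[locus.chromosome] = (t + int(is_terminal), n + 1)
        terminal += int(is_terminal)
    total = len(family_loci)
    return (terminal / total if total else 0.0), breakdown
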