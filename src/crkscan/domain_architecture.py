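"""From raw domain hits to one clean, ordered architecture per protein.

A protein enters the CRK family when it carries at least one confident
DUF26 (``Stress-antifungal``) hit; InterPro evidence (IPR038408 /
IPR002902) can be required as cross-validation.  Scanner output is then
tidied: near-duplicate overlapping hits are reduced to the single best hit,
split fragments of one domain are merged, and the surviving hits, read
N-terminal to C-terminal, form the protein's domain architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .io_formats import DomainHit

logger = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "Architecture",
    "filter_crk_candidates",
    "resolve_overlaps",
    "merge_fragmented",
    "build_architecture",
    "architectures_from_hits",
]

#: The DUF26 / Gnk2 ectodomain label that defines CRK family membership.
DUF26 = "Stress-antifungal"


@dataclass(frozen=True)
class FilterPolicy:
    """Criteria a DUF26 hit must meet for its protein to become a candidate.

    When the scanner reports a curated significance flag (Pfam gathering
    threshold) that flag is trusted; hits without one fall back to the
    E-value cutoff.  ``interpro_mode`` controls cross-validation against
    the accepted InterPro accessions: ``"off"`` skips it, ``"either"``
    requires at least one accepted accession on the protein, ``"both"``
    requires all of them.
    """

    e_value_max: float = 1e-3
    require_significant: bool = True
    interpro_accessions: frozenset[str] = frozenset({"IPR038408", "IPR002902"})
    interpro_mode: str = "either"

    def __post_init__(self) -> None:
        if not self.e_value_max > 0:
            raise ValueError("e_value_max must be positive")
        if self.interpro_mode not in ("off", "either", "both"):
            raise ValueError(f"unknown interpro_mode {self.interpro_mode!r}")

    def hit_passes(self, hit: DomainHit) -> bool:
        if hit.significant is not None and self.require_significant:
            return hit.significant
        if hit.e_value is None:
            return True
        return hit.e_value <= self.e_value_max


@dataclass(frozen=True)
class Architecture:
    """Ordered, overlap-free domain-label sequence of one protein."""

    protein_id: str
    elements: tuple[tuple[str, int, int], ...]
    protein_length: Optional[int] = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.elements)

    def signature(self, sep: str = "__") -> str:
        return sep.join(self.labels)

    def count(self, label: str) -> int:
        return sum(1 for name in self.labels if name == label)


def filter_crk_candidates(
    hits: Iterable[DomainHit],
    policy: Optional[FilterPolicy] = None,
    interpro_hits: Optional[Iterable[DomainHit]] = None,
) -> set[str]:
    """Return ids of proteins admitted to the CRK family.

    A protein qualifies iff it carries at least one DUF26 hit passing the
    policy.  When ``interpro_mode != "off"`` and InterPro hits are supplied,
    the protein must additionally carry an accepted InterPro accession
    (either/both of them, per the mode).
    """
    policy = policy or FilterPolicy()
    candidates = {
        h.protein_id for h in hits if h.domain_name == DUF26 and policy.hit_passes(h)
    }
    if policy.interpro_mode != "off" and interpro_hits is not None:
        seen: dict[str, set[str]] = {}
        for h in interpro_hits:
            if h.domain_accession in policy.interpro_accessions:
                seen.setdefault(h.protein_id, set()).add(h.domain_accession)
        if policy.interpro_mode == "either":
            validated = set(seen)
        else:
            validated = {
                pid
                for pid, accs in seen.items()
                if accs >= policy.interpro_accessions
            }
        candidates &= validated
    return candidates


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def _reciprocal_conflict(a: DomainHit, b: DomainHit, fraction: float) -> bool:
    ov = _overlap(a, b)
    if ov <= 0:
        return False
    return ov / a.length > fraction and ov / b.length > fraction


def _priority(h: DomainHit):
    # highest bit_score wins; ties: lowest e_value, leftmost, name
    ev = h.e_value if h.e_value is not None else float("inf")
    return (-h.bit_score, ev, h.start, h.domain_name)


def resolve_overlaps(hits: Sequence[DomainHit], overlap_fraction: float = 0.3) -> list[DomainHit]:
    """Reduce overlapping hits on one protein to a non-overlapping set.

    Hits overlapping reciprocally by more than *overlap_fraction* of both
    intervals compete, and only the best survives (bit score, then E-value,
    then leftmost start, then domain name — a total order, so the result is
    deterministic).  Residual small boundary overlaps between survivors are
    trimmed from the lower-priority hit so that output intervals are
    strictly disjoint.  The operation is idempotent.
    """
    hits = list(hits)
    if not hits:
        return []
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"resolve_overlaps expects one protein, got {sorted(ids)}")

    survivors: list[DomainHit] = []
    for h in sorted(hits, key=_priority):
        if not any(_reciprocal_conflict(h, kept, overlap_fraction) for kept in survivors):
            survivors.append(h)

    # trim residual boundary jitter: the weaker hit yields the contested span
    survivors_by_rank = sorted(survivors, key=_priority)
    trimmed: list[DomainHit] = []
    for h in survivors_by_rank:
        start, end = h.start, h.end
        for kept in trimmed:
            if end < kept.start or start > kept.end:
                continue
            if start < kept.start:
                end = min(end, kept.start - 1)
            else:
                start = max(start, kept.end + 1)
        if start > end:
            logger.debug(
                "hit %s:%s %d-%d fully shadowed after trimming; dropped",
                h.protein_id, h.domain_name, h.start, h.end,
            )
            continue
        if (start, end) != (h.start, h.end):
            h = replace(h, start=start, end=end)
        trimmed.append(h)
    return sorted(trimmed, key=lambda h: (h.start, h.end))


def merge_fragmented(hits: Sequence[DomainHit], max_gap: int = 30) -> list[DomainHit]:
    """Merge consecutive same-domain hits separated by at most *max_gap* residues.

    HMM scans frequently split one long domain into adjacent fragments;
    merging keeps the better bit score and the smaller E-value of the pair.
    ``max_gap = 0`` disables merging.  Input must be non-overlapping and
    sorted by start.
    """
    if max_gap == 0 or not hits:
        return list(hits)
    merged: list[DomainHit] = [hits[0]]
    for h in hits[1:]:
        prev = merged[-1]
        gap = h.start - prev.end - 1
        if h.domain_name == prev.domain_name and gap <= max_gap:
            evs = [e for e in (prev.e_value, h.e_value) if e is not None]
            merged[-1] = replace(
                prev,
                end=h.end,
                bit_score=max(prev.bit_score, h.bit_score),
                e_value=min(evs) if evs else None,
                significant=(prev.significant or h.significant)
                if (prev.significant is not None or h.significant is not None)
                else None,
            )
        else:
            merged.append(h)
    return merged


def build_architecture(
    hits: Sequence[DomainHit], length: Optional[int] = None
) -> Architecture:
    """Assemble the overlap-resolved hits of one protein into an Architecture."""
    if not hits:
        raise ValueError("cannot build an architecture from zero hits")
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    protein_id = ids.pop()
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    if length is not None:
        for h in ordered:
            if h.end > length:
                raise ValueError(
                    f"hit {h.domain_name}@{h.start}-{h.end} exceeds declared length "
                    f"{length} of protein {protein_id}"
                )
    return Architecture(
        protein_id=protein_id,
        elements=tuple((h.domain_name, h.start, h.end) for h in ordered),
        protein_length=length,
    )


def architectures_from_hits(
    hits: Iterable[DomainHit],
    candidates: Optional[set[str]] = None,
    policy: Optional[FilterPolicy] = None,
    overlap_fraction: float = 0.3,
    max_gap: int = 30,
    lengths: Optional[dict[str, int]] = None,
) -> dict[str, Architecture]:
    """Run the per-protein cleanup over a whole hit table.

    Insignificant hits (per *policy*) are removed before overlap resolution
    so that sub-threshold noise cannot displace genuine domains.  When
    *candidates* is given, only those proteins are processed.
    """
    policy = policy or FilterPolicy()
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        if candidates is not None and h.protein_id not in candidates:
            continue
        if not policy.hit_passes(h):
            continue
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, Architecture] = {}
    for pid, protein_hits in by_protein.items():
        resolved = resolve_overlaps(protein_hits, overlap_fraction)
        merged = merge_fragmented(resolved, max_gap)
        length = lengths.get(pid) if lengths else None
        out[pid] = build_architecture(merged, length)
    return out
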