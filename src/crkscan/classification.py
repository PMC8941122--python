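"""Three-way classification of CRK domain architectures.

Scheme 1 (major classes) keys on which domain types occur and in what
order, collapsing consecutive repeats — so ``DUF26, DUF26, kinase`` and
``DUF26, kinase`` fall into different classes only when a non-adjacent
repeat distinguishes them.  Scheme 2 (subclasses) keeps every repeat,
distinguishing e.g. single- from double-DUF26 receptors.  Scheme 3 renders
the literature nomenclature: a repeat-count prefix (sd/dd/td/qd for 1–4
DUF26 domains), a core telling secreted proteins (CRRSP) from kinases
(CRK, or CRdK when a divergent fungal-type kinase domain is also present),
and one-letter suffixes for known decoy domains (D = DUF3403, F = FYVE,
P = PRIMA1, S = sugar transporter, dS = doubled sugar transporter).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .domain_architecture import DUF26, Architecture

__all__ = [
    "MAJOR_SEP",
    "SUBCLASS_SEP",
    "NomenclatureGrammar",
    "ClassAssignment",
    "classify_major",
    "classify_subclass",
    "classify_nomenclature",
    "parse_nomenclature",
    "assign_all",
]

#: Separator used in scheme-1 signatures (as printed in family surveys).
MAJOR_SEP = "–"  # en dash
#: Separator used in scheme-2 signatures.
SUBCLASS_SEP = "__"

#: Labels that never contribute to any scheme (membrane-topology evidence).
_TOPOLOGY_LABELS = frozenset({"SignalPeptide", "Transmembrane"})


@dataclass(frozen=True)
class NomenclatureGrammar:
    """Alphabet of the scheme-3 naming grammar."""

    prefixes: tuple[tuple[int, str], ...] = ((1, "sd"), (2, "dd"), (3, "td"), (4, "qd"))
    kinase_labels: frozenset[str] = frozenset({"Pkinase-tyr", "Pkinase"})
    fungal_kinase_label: str = "Pkinase_fungal"
    decoy_suffixes: tuple[tuple[str, str], ...] = (
        ("DUF3403", "D"),
        ("FYVE", "F"),
        ("PRIMA1", "P"),
        ("SugarTransporter", "S"),
    )
    double_sugar_suffix: str = "dS"

    def __post_init__(self) -> None:
        if len({p for _, p in self.prefixes}) != len(self.prefixes):
            raise ValueError("prefix map must be injective")
        if len({s for _, s in self.decoy_suffixes}) != len(self.decoy_suffixes):
            raise ValueError("suffix map must be injective")

    @property
    def prefix_map(self) -> dict[int, str]:
        return dict(self.prefixes)

    @property
    def suffix_map(self) -> dict[str, str]:
        return dict(self.decoy_suffixes)

    def prefix(self, duf26_count: int) -> tuple[str, bool]:
        """Prefix for a repeat count; flags counts beyond the standard table."""
        table = self.prefix_map
        if duf26_count in table:
            return table[duf26_count], False
        return f"{duf26_count}d", True


@dataclass(frozen=True)
class ClassAssignment:
    """The three class labels of one protein plus derived metadata.

    ``decoys`` lists each non-DUF26, non-kinase domain with the side it
    occupies relative to the first DUF26 element (``N`` or ``C``), in
    N→C order.
    """

    protein_id: str
    major_signature: str
    major_class_id: int
    subclass_signature: str
    nomenclature: str
    duf26_count: int
    has_kinase: bool
    decoys: tuple[tuple[str, str], ...] = ()
    species: str = ""
    extended_prefix: bool = False


def _scheme_labels(arch: Architecture) -> tuple[str, ...]:
    labels = tuple(l for l in arch.labels if l not in _TOPOLOGY_LABELS)
    if DUF26 not in labels:
        raise ValueError(
            f"protein {arch.protein_id} has no {DUF26} domain: not a CRK architecture"
        )
    return labels


def classify_major(arch: Architecture) -> str:
    """Scheme-1 signature: consecutive same-label runs collapsed, order kept.

    Non-adjacent repeats survive, so alternating patterns such as
    kinase–DUF26–kinase remain distinct from DUF26–kinase.
    """
    labels = _scheme_labels(arch)
    collapsed: list[str] = []
    for label in labels:
        if not collapsed or collapsed[-1] != label:
            collapsed.append(label)
    return MAJOR_SEP.join(collapsed)


def classify_subclass(arch: Architecture) -> str:
    """Scheme-2 signature: the full ordered label sequence, repeats retained."""
    return SUBCLASS_SEP.join(_scheme_labels(arch))


def _decoy_sides(labels: Sequence[str], arch: Architecture, grammar: NomenclatureGrammar):
    """Non-DUF26, non-kinase labels with their side relative to the first DUF26."""
    non_decoy = {DUF26, grammar.fungal_kinase_label} | set(grammar.kinase_labels)
    first_duf = labels.index(DUF26)
    out = []
    for i, label in enumerate(labels):
        if label in non_decoy:
            continue
        out.append((label, "N" if i < first_duf else "C"))
    return tuple(out)


def classify_nomenclature(
    arch: Architecture, grammar: Optional[NomenclatureGrammar] = None
) -> str:
    """Scheme-3 name: repeat-count prefix + CRRSP/CRK/CRdK core + decoy suffixes.

    Suffixes follow the N→C order of each decoy's first occurrence; a
    doubled sugar-transporter domain contributes ``dS`` instead of ``S``.
    Decoy side (N- vs C-terminal) is recorded in the assignment metadata
    but does not alter the name.
    """
    grammar = grammar or NomenclatureGrammar()
    labels = _scheme_labels(arch)
    prefix, _ = grammar.prefix(labels.count(DUF26))
    has_kinase = any(l in grammar.kinase_labels for l in labels)
    has_fungal = grammar.fungal_kinase_label in labels
    if not has_kinase:
        core = "CRRSP"
    elif has_fungal:
        core = "CRdK"
    else:
        core = "CRK"
    suffix_map = grammar.suffix_map
    suffixes: list[str] = []
    seen: set[str] = set()
    for label in labels:
        if label in suffix_map and label not in seen:
            seen.add(label)
            if label == "SugarTransporter" and labels.count(label) >= 2:
                suffixes.append(grammar.double_sugar_suffix)
            else:
                suffixes.append(suffix_map[label])
    return prefix + core + "".join(suffixes)


def parse_nomenclature(
    name: str, grammar: Optional[NomenclatureGrammar] = None
) -> tuple[int, str, tuple[str, ...]]:
    """Inverse of :func:`classify_nomenclature` on its image.

    Returns ``(duf26_count, core, suffixes)``.  An unparseable name raises
    a ``ValueError`` reporting the longest valid prefix of the name.
    """
    grammar = grammar or NomenclatureGrammar()
    rest, parsed = name, ""

    count = None
    for n, prefix in grammar.prefixes:
        if rest.startswith(prefix):
            count, rest, parsed = n, rest[len(prefix):], prefix
            break
    if count is None:
        m = re.match(r"^(\d+)d", rest)
        if m:
            count = int(m.group(1))
            parsed = m.group(0)
            rest = rest[len(parsed):]
        else:
            raise ValueError(f"cannot parse {name!r}: longest valid prefix is ''")

    core = None
    for candidate in ("CRRSP", "CRdK", "CRK"):
        if rest.startswith(candidate):
            core = candidate
            rest = rest[len(candidate):]
            parsed += candidate
            break
    if core is None:
        raise ValueError(f"cannot parse {name!r}: longest valid prefix is {parsed!r}")

    suffix_tokens = sorted(
        [grammar.double_sugar_suffix] + [s for _, s in grammar.decoy_suffixes],
        key=len,
        reverse=True,
    )
    suffixes: list[str] = []
    while rest:
        for token in suffix_tokens:
            if rest.startswith(token):
                suffixes.append(token)
                rest = rest[len(token):]
                parsed += token
                break
        else:
            raise ValueError(f"cannot parse {name!r}: longest valid prefix is {parsed!r}")
    return count, core, tuple(suffixes)


def assign_all(
    architectures: Iterable[Architecture],
    grammar: Optional[NomenclatureGrammar] = None,
    species: Optional[dict[str, str]] = None,
) -> list[ClassAssignment]:
    """Assign all three class labels to every architecture.

    ``major_class_id`` numbers distinct scheme-1 signatures by first
    appearance, so a fixed input order yields stable ids.  *species* maps
    protein ids to species tags for downstream cross-species summaries.
    """
    grammar = grammar or NomenclatureGrammar()
    major_ids: dict[str, int] = {}
    out: list[ClassAssignment] = []
    for arch in architectures:
        try:
            labels = _scheme_labels(arch)
            major = classify_major(arch)
            sub = classify_subclass(arch)
            name = classify_nomenclature(arch, grammar)
        except ValueError as exc:
            raise ValueError(f"classification failed for {arch.protein_id}: {exc}") from exc
        if major not in major_ids:
            major_ids[major] = len(major_ids) + 1
        duf26_count = labels.count(DUF26)
        _, extended = grammar.prefix(duf26_count)
        out.append(
            ClassAssignment(
                protein_id=arch.protein_id,
                major_signature=major,
                major_class_id=major_ids[major],
                subclass_signature=sub,
                nomenclature=name,
                duf26_count=duf26_count,
                has_kinase=any(l in grammar.kinase_labels for l in labels),
                decoys=_decoy_sides(labels, arch, grammar),
                species=(species or {}).get(arch.protein_id, ""),
                extended_prefix=extended,
            )
        )
    return out
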