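"""Cross-species aggregation of class assignments.

Builds the class × species count matrix a comparative gene-family survey
reports, identifies classes shared by all species or restricted to one,
and reproduces the derived arithmetic (largest class, percentage of genes
assigned to orthogroups).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .classification import ClassAssignment

__all__ = [
    "FamilySummary",
    "summarize",
    "largest_class_total",
    "assignment_percentage",
]

Scheme = Literal["major", "subclass", "nomenclature"]

_SCHEME_FIELD = {
    "major": "major_signature",
    "subclass": "subclass_signature",
    "nomenclature": "nomenclature",
}


@dataclass(frozen=True)
class FamilySummary:
    """Class × species count matrix with derived totals.

    ``counts`` rows are class labels ordered by descending grand total
    (ties lexicographic); columns are species in sorted order.
    """

    counts: pd.DataFrame

    @property
    def per_species_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def per_class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def shared_classes(self) -> list[str]:
        """Classes present (count > 0) in every species."""
        if self.counts.empty:
            return []
        return sorted(self.counts.index[(self.counts > 0).all(axis=1)])

    @property
    def species_specific_classes(self) -> list[str]:
        """Classes present in exactly one species."""
        if self.counts.empty:
            return []
        return sorted(self.counts.index[(self.counts > 0).sum(axis=1) == 1])

    def to_long(self) -> pd.DataFrame:
        long = self.counts.reset_index(names="class_label").melt(
            id_vars="class_label", var_name="species", value_name="count"
        )
        return long


def summarize(
    assignments: Sequence[ClassAssignment], scheme: Scheme = "major"
) -> FamilySummary:
    """Count assignments per (class label, species) under the chosen scheme."""
    field = _SCHEME_FIELD[scheme]
    for a in assignments:
        if not a.species:
            raise ValueError(f"assignment for {a.protein_id} has no species tag")
    if not assignments:
        return FamilySummary(counts=pd.DataFrame(dtype=int))
    df = pd.DataFrame(
        {
            "class_label": [getattr(a, field) for a in assignments],
            "species": [a.species for a in assignments],
        }
    )
    counts = (
        df.groupby(["class_label", "species"], sort=True)
        .size()
        .unstack(fill_value=0)
        .astype(int)
    )
    counts.columns = list(counts.columns)
    order = counts.sum(axis=1).sort_values(ascending=False, kind="stable")
    # descending total, ties broken lexicographically by label
    ordered_index = sorted(counts.index, key=lambda c: (-order[c], c))
    counts = counts.loc[ordered_index]
    return FamilySummary(counts=counts)


def largest_class_total(summary: FamilySummary) -> tuple[str, int, bool]:
    """Class with the maximal grand total, its total, and a tie flag."""
    if summary.counts.empty:
        raise ValueError("empty summary has no largest class")
    totals = summary.per_class_totals
    best_total = int(totals.max())
    tied = sorted(totals.index[totals == best_total])
    return tied[0], best_total, len(tied) > 1


def assignment_percentage(total_genes: int, unassigned: int) -> float:
    """Percentage of genes assigned (100·(total−unassigned)/total), rounded
    half-up to one decimal — the convention used in orthogroup summaries."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if not (0 <= unassigned <= total_genes):
        raise ValueError("unassigned must lie in [0, total_genes]")
    pct = Decimal(100) * (Decimal(total_genes) - Decimal(unassigned)) / Decimal(total_genes)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def plot_class_counts(summary: FamilySummary, path: str) -> None:
    """Grouped bar chart of per-class counts by species (optional export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = summary.counts.plot.bar(figsize=(10, 5))
    ax.set_ylabel("genes")
    ax.set_xlabel("class")
    plt.tight_layout()
    plt.savefig(path)
    plt.close()
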