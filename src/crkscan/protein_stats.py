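"""Per-protein physicochemical statistics.

Computes the quantities gene-family surveys tabulate for each protein:
length, molecular weight (average isotopic, kDa), net charge at a chosen
pH, isoelectric point, and GRAVY (grand average of hydropathy,
Kyte–Doolittle).  Charge follows the Henderson–Hasselbalch model with an
EMBOSS-style pKa set; because every term is strictly decreasing in pH, the
isoelectric point is the unique zero crossing and is found by bisection.

The constants live in editable two-column data files under ``data/`` so a
different hydropathy scale or pKa set can be swapped in without code
changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

__all__ = ["PhysChemTables", "ProteinStats", "compute_stats", "stats_table", "net_charge"]

WATER_MASS = 18.01528  # Da, average

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def _load_two_column(name: str) -> dict[str, float]:
    text = resources.files("crkscan.data").joinpath(name).read_text()
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        out[cols[0]] = float(cols[1])
    return out


def _load_pka() -> dict[str, tuple[float, int]]:
    text = resources.files("crkscan.data").joinpath("pka.tsv").read_text()
    out: dict[str, tuple[float, int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, pka, sign = line.split("\t")
        out[key] = (float(pka), +1 if sign == "+" else -1)
    return out


@dataclass(frozen=True)
class PhysChemTables:
    """Residue masses (Da, free amino acids), hydropathy scale, and pKa set."""

    masses: Mapping[str, float]
    hydropathy: Mapping[str, float]
    pka: Mapping[str, tuple[float, int]]

    @classmethod
    def default(cls) -> "PhysChemTables":
        tables = cls(
            masses=_load_two_column("residue_masses.tsv"),
            hydropathy=_load_two_column("hydropathy.tsv"),
            pka=_load_pka(),
        )
        missing = _STANDARD_RESIDUES - set(tables.masses) | _STANDARD_RESIDUES - set(
            tables.hydropathy
        )
        if missing:
            raise ValueError(f"constant tables incomplete, missing {sorted(missing)}")
        return tables


@dataclass(frozen=True)
class ProteinStats:
    protein_id: str
    length: int
    molecular_weight: float  # kDa
    charge: float  # elementary charges at the stated pH
    isoelectric_point: float  # pH units
    gravy: float


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    for i, letter in enumerate(sequence, start=1):
        if letter not in _STANDARD_RESIDUES and letter != "X":
            raise ValueError(f"unknown residue {letter!r} at position {i}")
    return sequence


def net_charge(sequence: str, ph: float, tables: Optional[PhysChemTables] = None) -> float:
    """Net charge at *ph*: sum of Henderson–Hasselbalch terms over the two
    termini and the ionizable side chains (D, E, C, Y, H, K, R)."""
    tables = tables or PhysChemTables.default()
    sequence = _validate(sequence)
    groups: list[str] = ["Nterm", "Cterm"]
    groups.extend(letter for letter in sequence if letter in tables.pka)
    charge = 0.0
    for group in groups:
        pka, sign = tables.pka[group]
        if sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def _isoelectric_point(sequence: str, tables: PhysChemTables) -> float:
    lo, hi = 0.0, 14.0
    # charge is strictly decreasing in pH; bisect the zero crossing
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, tables) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_stats(
    sequence: str, tables: Optional[PhysChemTables] = None, ph: float = 7.0,
    protein_id: str = "",
) -> ProteinStats:
    """Compute all physicochemical statistics for one sequence.

    ``X`` (ambiguous residue) is tolerated: it is excluded from the mass
    and GRAVY averages with a warning and carries no ionizable group.
    """
    tables = tables or PhysChemTables.default()
    sequence = _validate(sequence)
    counted = [letter for letter in sequence if letter != "X"]
    if len(counted) < len(sequence):
        logger.warning(
            "%s: %d ambiguous X residue(s) excluded from mass/GRAVY",
            protein_id or "sequence", len(sequence) - len(counted),
        )
    if not counted:
        raise ValueError("sequence contains no standard residues")
    mass_da = sum(tables.masses[letter] for letter in counted) - (
        len(counted) - 1
    ) * WATER_MASS
    gravy = sum(tables.hydropathy[letter] for letter in counted) / len(counted)
    return ProteinStats(
        protein_id=protein_id,
        length=len(sequence),
        molecular_weight=mass_da / 1000.0,
        charge=net_charge(sequence, ph, tables),
        isoelectric_point=_isoelectric_point(sequence, tables),
        gravy=gravy,
    )


_SUMMARY_FIELDS = ("length", "molecular_weight", "charge", "isoelectric_point", "gravy")


def stats_table(
    sequences: Mapping[str, str],
    tables: Optional[PhysChemTables] = None,
    ph: float = 7.0,
) -> tuple[list[ProteinStats], dict[str, tuple[float, float]]]:
    """Compute stats for every sequence plus a min/max range summary.

    Sequences that fail validation are excluded from the summary and their
    count is logged, mirroring how family surveys report feature ranges
    over the proteins that could be scored.
    """
    tables = tables or PhysChemTables.default()
    rows: list[ProteinStats] = []
    failures = 0
    for pid, seq in sequences.items():
        try:
            rows.append(compute_stats(seq, tables, ph, protein_id=pid))
        except ValueError as exc:
            failures += 1
            logger.warning("skipping %s: %s", pid, exc)
    if failures:
        logger.warning("%d sequence(s) excluded from the range summary", failures)
    summary = {
        name: (
            min(getattr(r, name) for r in rows),
            max(getattr(r, name) for r in rows),
        )
        for name in _SUMMARY_FIELDS
    } if rows else {}
    return rows, summary
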