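"""Readers and writers for the external file formats the pipeline consumes.

Everything on disk stays in the convention of its source format; internally
every coordinate is 1-based inclusive (the GFF3 / Pfam-Scan convention).
Domain labels from scanners are spelled inconsistently in the wild
("DUF 26", "DUF26", "Gnk2", "Stress-antifungal" all denote PF01657), so every
hit passes through an :class:`AliasTable` that maps raw names and accessions
onto one canonical vocabulary.  Unknown labels are kept as ``Other`` and
logged, never dropped.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_DOMAINS",
    "AliasTable",
    "DomainHit",
    "GeneLocus",
    "FastaMapping",
    "read_fasta",
    "read_pfamscan",
    "read_interproscan",
    "read_gff",
    "read_chromosome_lengths",
    "write_hits_tsv",
    "read_hits_tsv",
]

#: Canonical domain vocabulary used throughout the pipeline.
CANONICAL_DOMAINS = frozenset(
    {
        "Stress-antifungal",
        "Pkinase-tyr",
        "Pkinase",
        "Pkinase_fungal",
        "DUF3403",
        "FYVE",
        "ALMT",
        "FUSC_2",
        "FUSC",
        "Cript",
        "TauE",
        "PRIMA1",
        "SugarTransporter",
        "SignalPeptide",
        "Transmembrane",
        "Other",
    }
)

_DEFAULT_ALIASES = {
    # DUF26 / Gnk2 / Stress-antifungal ectodomain (PF01657)
    "PF01657": "Stress-antifungal",
    "Stress-antifung": "Stress-antifungal",
    "Stress-antifungal": "Stress-antifungal",
    "Gnk2": "Stress-antifungal",
    "Gnk2-homologous": "Stress-antifungal",
    "DUF26": "Stress-antifungal",
    "DUF 26": "Stress-antifungal",
    "IPR002902": "Stress-antifungal",
    "IPR038408": "Stress-antifungal",
    # kinase domains
    "PF07714": "Pkinase-tyr",
    "Pkinase_Tyr": "Pkinase-tyr",
    "Pkinase-tyr": "Pkinase-tyr",
    "PK_Tyr_Ser-Thr": "Pkinase-tyr",
    "PF00069": "Pkinase",
    "Pkinase": "Pkinase",
    "Pkinase_fungal": "Pkinase_fungal",
    "PF17667": "Pkinase_fungal",
    # decoy domains seen fused into CRK architectures
    "PF11883": "DUF3403",
    "DUF3403": "DUF3403",
    "PF01363": "FYVE",
    "FYVE": "FYVE",
    "PF11744": "ALMT",
    "ALMT": "ALMT",
    "FUSC_2": "FUSC_2",
    "FUSC": "FUSC",
    "PF04632": "FUSC",
    "Cript": "Cript",
    "CRIPT": "Cript",
    "PF10235": "Cript",
    "TauE": "TauE",
    "PF01925": "TauE",
    "PRIMA1": "PRIMA1",
    "PF16101": "PRIMA1",
    "Sugar_tr": "SugarTransporter",
    "SugarTransporter": "SugarTransporter",
    "Sugar_transporter": "SugarTransporter",
    "PF00083": "SugarTransporter",
    # topology annotations (ignored by the classification schemes)
    "SignalP": "SignalPeptide",
    "SignalPeptide": "SignalPeptide",
    "signal_peptide": "SignalPeptide",
    "TMhelix": "Transmembrane",
    "Transmembrane": "Transmembrane",
    "Other": "Other",
}

_ACC_VERSION = re.compile(r"^(PF\d{5})\.\d+$")


class AliasTable:
    """Total mapping from raw scanner labels/accessions to canonical labels.

    Lookups try the raw name first, then the accession (with any ``.N``
    version suffix stripped).  A label that matches neither maps to
    ``Other`` and is counted in :attr:`fallbacks`.
    """

    def __init__(self, mapping: Optional[dict[str, str]] = None):
        self.mapping = dict(_DEFAULT_ALIASES)
        if mapping:
            for raw, canonical in mapping.items():
                if canonical not in CANONICAL_DOMAINS:
                    raise ValueError(
                        f"alias target {canonical!r} is not a canonical domain label"
                    )
                self.mapping[raw] = canonical
        self.fallbacks: dict[str, int] = {}

    def normalize(self, name: str, accession: Optional[str] = None) -> str:
        if name in self.mapping:
            return self.mapping[name]
        if accession:
            acc = accession
            m = _ACC_VERSION.match(acc)
            if m:
                acc = m.group(1)
            if acc in self.mapping:
                return self.mapping[acc]
        self.fallbacks[name] = self.fallbacks.get(name, 0) + 1
        logger.warning("unknown domain label %r: keeping as Other", name)
        return "Other"


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    e_value: Optional[float] = None
    bit_score: float = 0.0
    significant: Optional[bool] = None
    domain_accession: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}-{self.end} on {self.protein_id}"
            )
        if self.e_value is not None and not self.e_value >= 0:
            raise ValueError(f"negative e_value {self.e_value} on {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal placement of one gene (1-based inclusive, as in GFF3)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    species: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for gene {self.gene_id}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class FastaMapping(dict):
    """``protein_id -> sequence`` mapping carrying the FASTA descriptions."""

    def __init__(self) -> None:
        super().__init__()
        self.descriptions: dict[str, str] = {}


def read_fasta(path: str | Path) -> FastaMapping:
    """Read a FASTA file into an id → uppercased-sequence mapping.

    The description (text after the first whitespace of the header) is kept
    in ``result.descriptions``.  A duplicated identifier is an error; an
    empty file yields an empty mapping with a warning.
    """
    out = FastaMapping()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.descriptions[rec.id] = desc
    if not out:
        logger.warning("FASTA file %s contained no records", path)
    return out


_PFAMSCAN_NCOLS = 15


def read_pfamscan(path: str | Path, aliases: Optional[AliasTable] = None) -> list[DomainHit]:
    """Parse Pfam-Scan tabular output into normalized :class:`DomainHit` rows.

    Expected columns (whitespace-separated, ``#`` comments skipped)::

        seq_id aln_start aln_end env_start env_end hmm_acc hmm_name type
        hmm_start hmm_end hmm_len bit_score e_value significance clan

    Alignment (not envelope) coordinates become the hit interval.
    """
    aliases = aliases or AliasTable()
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != _PFAMSCAN_NCOLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_PFAMSCAN_NCOLS} whitespace-separated "
                    f"Pfam-Scan columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                bit_score = float(cols[11])
                e_value = float(cols[12])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            name = aliases.normalize(cols[6], cols[5])
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    domain_name=name,
                    start=start,
                    end=end,
                    e_value=e_value,
                    bit_score=bit_score,
                    significant=cols[13] == "1",
                    domain_accession=cols[5],
                )
            )
    return hits


_IPRSCAN_MIN_COLS = 11


def read_interproscan(path: str | Path, aliases: Optional[AliasTable] = None) -> list[DomainHit]:
    """Parse InterProScan TSV output.

    Column 12 (the InterPro accession, e.g. ``IPR002902``) is stored as the
    hit's accession when present so that candidate filtering can
    cross-validate against accepted InterPro entries; otherwise the member
    database signature accession is kept.
    """
    aliases = aliases or AliasTable()
    hits: list[DomainHit] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            cols = line.split("\t")
            if len(cols) < _IPRSCAN_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {_IPRSCAN_MIN_COLS} "
                    f"tab-separated InterProScan columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[6]), int(cols[7])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            score = cols[8]
            e_value = None if score in ("-", "") else float(score)
            ipr_acc = cols[11] if len(cols) > 11 and cols[11] not in ("-", "") else None
            accession = ipr_acc or cols[4]
            name = aliases.normalize(cols[5], accession) if cols[5] else aliases.normalize(
                cols[4], accession
            )
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    domain_name=name,
                    start=start,
                    end=end,
                    e_value=e_value,
                    bit_score=0.0,
                    significant=None,
                    domain_accession=accession,
                )
            )
    if n_rows == 0:
        logger.warning("InterProScan file %s contained no data rows", path)
    return hits


def read_gff(path: str | Path, feature_type: str = "gene", species: str = "") -> list[GeneLocus]:
    """Read gene loci from a GFF3 file, keeping 1-based inclusive coordinates.

    Only rows whose third column equals *feature_type* are returned, in file
    order.  ``gene_id`` is taken from the ``ID`` attribute; a selected row
    without one is an error.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] != feature_type:
                continue
            attrs = {}
            for part in cols[8].split(";"):
                part = part.strip()
                if "=" in part:
                    key, _, value = part.partition("=")
                    attrs[key] = value
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: {feature_type} row lacks an ID attribute")
            strand = cols[6] if cols[6] in ("+", "-") else "unknown"
            loci.append(
                GeneLocus(
                    gene_id=attrs["ID"],
                    chromosome=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=strand,
                    species=species,
                )
            )
    return loci


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chromosome<TAB>length_bp`` table (optional header)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and not cols[1].isdigit():
                continue  # header row
            lengths[cols[0]] = int(cols[1])
    return lengths


_HIT_COLUMNS = [
    "protein_id",
    "domain_name",
    "domain_accession",
    "start",
    "end",
    "e_value",
    "bit_score",
    "significant",
]


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits to the canonical internal TSV (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HIT_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.protein_id,
                    h.domain_name,
                    h.domain_accession or "",
                    h.start,
                    h.end,
                    "" if h.e_value is None else repr(h.e_value),
                    repr(h.bit_score),
                    "" if h.significant is None else int(h.significant),
                ]
            )


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Read the canonical internal hit TSV written by :func:`write_hits_tsv`."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HIT_COLUMNS:
            raise ValueError(f"{path}: not a canonical hit table (header {header})")
        for row in reader:
            if not row:
                continue
            hits.append(
                DomainHit(
                    protein_id=row[0],
                    domain_name=row[1],
                    domain_accession=row[2] or None,
                    start=int(row[3]),
                    end=int(row[4]),
                    e_value=float(row[5]) if row[5] else None,
                    bit_score=float(row[6]),
                    significant=bool(int(row[7])) if row[7] else None,
                )
            )
    return hits
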