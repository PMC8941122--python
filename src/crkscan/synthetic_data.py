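"""Synthetic multi-species proteome generator with planted ground truth.

Emulates the structure of the cotton-proteome inputs the pipeline targets:
several species, each with a multi-chromosome gene set, proteins carrying
planted ordered domain architectures drawn from configurable class
frequencies, tandem clusters placed at chosen spacings, and realistic
scanner noise (overlapping duplicate hits, sub-threshold DUF26 hits on
non-family decoy proteins).  Every generated dataset carries a truth table
whose expected class labels are computed by a deliberately independent
rule copy — not by the classification module — so that end-to-end recovery
is a genuine cross-validation.

Protein sequences are uniform-random residues: the pipeline consumes scan
output, so domain content lives in the hit table, not in sequence motifs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import DomainHit, GeneLocus, write_hits_tsv

__all__ = [
    "COTTON_MAJOR_ARCHITECTURES",
    "LAND_PLANT_CLASS_ARCHITECTURES",
    "ClusterSpec",
    "SimConfig",
    "SyntheticDataset",
    "generate_dataset",
    "inject_noise",
    "end_to_end_recovery",
]

SA = "Stress-antifungal"
PK = "Pkinase-tyr"

#: The 11 major-class architectures observed in the cotton CRK family.
COTTON_MAJOR_ARCHITECTURES: dict[str, tuple[str, ...]] = {
    "ALMT-fusion": ("ALMT", "FUSC_2", "FUSC", SA),
    "Cript-fusion": ("Cript", SA, PK),
    "kinase-flanked": (PK, SA, PK),
    "ectodomain-only": (SA,),
    "DUF3403-secreted": (SA, "DUF3403"),
    "canonical-kinase": (SA, PK),
    "kinase-DUF3403": (SA, PK, "DUF3403"),
    "kinase-FYVE": (SA, PK, "FYVE"),
    "double-kinase": (SA, PK, "Pkinase_fungal"),
    "tandem-repeat": (SA, PK, SA, PK),
    "kinase-TauE": (SA, PK, "TauE"),
}

#: The 19 land-plant nomenclature classes, keyed by their grammar name.
LAND_PLANT_CLASS_ARCHITECTURES: dict[str, tuple[str, ...]] = {
    "sdCRRSP": (SA,),
    "sdCRRSPD": ("DUF3403", SA),
    "sdCRRSPdS": ("SugarTransporter", "SugarTransporter", SA),
    "ddCRRSP": (SA, SA),
    "ddCRRSPD": ("DUF3403", SA, SA),
    "ddCRRSPP": ("PRIMA1", SA, SA),
    "tdCRRSP": (SA, SA, SA),
    "sdCRK": (SA, PK),
    "sdCRKD": ("DUF3403", SA, PK),
    "ddCRK": (SA, SA, PK),
    "ddCRKD": (SA, SA, PK, "DUF3403"),
    "ddCRKF": ("FYVE", SA, SA, PK),
    "ddCRKP": ("PRIMA1", SA, SA, PK),
    "ddCRKS": ("SugarTransporter", SA, SA, PK),
    "ddCRdK": (SA, SA, PK, "Pkinase_fungal"),
    "tdCRK": (SA, SA, SA, PK),
    "tdCRdK": (SA, SA, SA, PK, "Pkinase_fungal"),
    "qdCRK": (SA, SA, SA, SA, PK),
    "qdCRKD": (SA, SA, SA, SA, PK, "DUF3403"),
}

#: Per-species CRK counts of the five cotton proteomes the generator emulates.
DEFAULT_SPECIES: dict[str, int] = {
    "Gar": 60,
    "Gra": 74,
    "Gher": 65,
    "Ghir": 118,
    "Gbar": 120,
}

#: Major-class gene totals in the cotton family, used as default frequencies.
_COTTON_CLASS_TOTALS: dict[str, int] = {
    "ALMT-fusion": 2,
    "Cript-fusion": 1,
    "kinase-flanked": 1,
    "ectodomain-only": 169,
    "DUF3403-secreted": 1,
    "canonical-kinase": 2,
    "kinase-DUF3403": 243,
    "kinase-FYVE": 13,
    "double-kinase": 2,
    "tandem-repeat": 2,
    "kinase-TauE": 1,
}


def _default_frequencies() -> dict[str, float]:
    total = sum(_COTTON_CLASS_TOTALS.values())
    return {name: n / total for name, n in _COTTON_CLASS_TOTALS.items()}


_DEFAULT_DOMAIN_LENGTHS: dict[str, tuple[int, int]] = {
    SA: (90, 110),
    PK: (250, 290),
    "Pkinase": (250, 290),
    "Pkinase_fungal": (250, 290),
}
_DEFAULT_DECOY_LENGTH = (60, 120)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ClusterSpec:
    """A tandem cluster to plant: *n_members* consecutive family genes on one
    chromosome (0-based index within the species) at *spacing_bp* gaps."""

    species: str
    chromosome_index: int
    n_members: int
    spacing_bp: int = 10_000


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; a fixed seed yields byte-identical files."""

    seed: int = 0
    species: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    templates: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(COTTON_MAJOR_ARCHITECTURES)
    )
    class_frequencies: dict[str, float] = field(default_factory=_default_frequencies)
    chromosomes_per_species: int = 13
    chromosome_length: int = 60_000_000
    planted_clusters: tuple[ClusterSpec, ...] = ()
    duplicate_noise_rate: float = 0.0
    subthreshold_noise_rate: float = 0.0
    decoy_protein_rate: float = 0.0
    domain_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DOMAIN_LENGTHS)
    )
    linker_range: tuple[int, int] = (35, 80)
    max_protein_length: int = 2000
    background_spacing_bp: int = 1_000_000

    def __post_init__(self) -> None:
        freq_sum = sum(self.class_frequencies.values())
        if abs(freq_sum - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {freq_sum}, not 1")
        unknown = set(self.class_frequencies) - set(self.templates)
        if unknown:
            raise ValueError(f"frequencies reference unknown templates: {sorted(unknown)}")
        if any(n < 0 for n in self.species.values()):
            raise ValueError("species gene counts must be non-negative")


# ---------------------------------------------------------------------------
# Independent truth-label rules.  These re-derive the expected class labels
# from the planted label sequence with deliberately different code from the
# classification module, so agreement between the two is a real check.

_TRUTH_KINASES = (PK, "Pkinase")
_TRUTH_SUFFIX = {"DUF3403": "D", "FYVE": "F", "PRIMA1": "P", "SugarTransporter": "S"}
_TRUTH_PREFIX = {1: "sd", 2: "dd", 3: "td", 4: "qd"}


def _truth_major(labels: Sequence[str]) -> str:
    return "–".join(key for key, _ in itertools.groupby(labels))


def _truth_subclass(labels: Sequence[str]) -> str:
    return "__".join(labels)


def _truth_nomenclature(labels: Sequence[str]) -> str:
    n_duf = sum(1 for l in labels if l == SA)
    prefix = _TRUTH_PREFIX.get(n_duf, f"{n_duf}d")
    kinase = any(l in _TRUTH_KINASES for l in labels)
    fungal = "Pkinase_fungal" in labels
    core = {(False, False): "CRRSP", (False, True): "CRRSP",
            (True, False): "CRK", (True, True): "CRdK"}[(kinase, fungal)]
    suffix = ""
    done = set()
    for l in labels:
        if l in _TRUTH_SUFFIX and l not in done:
            done.add(l)
            if l == "SugarTransporter" and labels.count(l) >= 2:
                suffix += "dS"
            else:
                suffix += _TRUTH_SUFFIX[l]
    return prefix + core + suffix


# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory dataset plus writers for the standard on-disk formats."""

    sequences: dict[str, str]
    descriptions: dict[str, str]
    loci: list[GeneLocus]
    hits: list[DomainHit]
    hit_origins: list[str]  # "planted" | "duplicate" | "subthreshold"
    chromosome_lengths: dict[str, int]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "gff": outdir / "genes.gff3",
            "hits": outdir / "hits.tsv",
            "chromosomes": outdir / "chromosome_lengths.tsv",
            "truth": outdir / "truth.tsv",
            "hit_origins": outdir / "hit_origins.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for pid, seq in self.sequences.items():
                fh.write(f">{pid} {self.descriptions[pid]}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for l in self.loci:
                strand = l.strand if l.strand in "+-" else "."
                fh.write(
                    f"{l.chromosome}\tcrkscan-sim\tgene\t{l.start}\t{l.end}\t.\t"
                    f"{strand}\t.\tID={l.gene_id};species={l.species}\n"
                )
        write_hits_tsv(self.hits, paths["hits"])
        with open(paths["chromosomes"], "w") as fh:
            fh.write("chromosome\tlength_bp\n")
            for chrom, length in self.chromosome_lengths.items():
                fh.write(f"{chrom}\t{length}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["hit_origins"], "w") as fh:
            fh.write("protein_id\tdomain_name\tstart\tend\torigin\n")
            for h, origin in zip(self.hits, self.hit_origins):
                fh.write(f"{h.protein_id}\t{h.domain_name}\t{h.start}\t{h.end}\t{origin}\n")
        return paths


def _plant_protein(
    pid: str,
    labels: Sequence[str],
    rng: np.random.Generator,
    config: SimConfig,
    template: str,
) -> tuple[str, list[DomainHit]]:
    """Lay the template's domains onto a random sequence, N→C with linkers."""
    cursor = int(rng.integers(*config.linker_range, endpoint=True))
    hits = []
    for label in labels:
        lo, hi = config.domain_length_ranges.get(label, _DEFAULT_DECOY_LENGTH)
        dlen = int(rng.integers(lo, hi, endpoint=True))
        start = cursor + 1
        end = start + dlen - 1
        hits.append(
            DomainHit(
                protein_id=pid,
                domain_name=label,
                start=start,
                end=end,
                e_value=float(10.0 ** -rng.uniform(10, 40)),
                bit_score=float(np.round(rng.uniform(50, 300), 1)),
                significant=True,
            )
        )
        cursor = end + int(rng.integers(*config.linker_range, endpoint=True))
    length = cursor
    if length > config.max_protein_length:
        raise ValueError(
            f"template {template!r} needs {length} residues, exceeding the "
            f"configured maximum protein length {config.max_protein_length}"
        )
    seq = "".join(rng.choice(_RESIDUES, size=length))
    return seq, hits


def generate_dataset(config: Optional[SimConfig] = None) -> SyntheticDataset:
    """Generate the full synthetic dataset described by *config*."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    template_names = sorted(config.class_frequencies)
    probs = np.array([config.class_frequencies[t] for t in template_names])

    sequences: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    hits: list[DomainHit] = []
    origins: list[str] = []
    truth_rows: list[dict] = []
    loci: list[GeneLocus] = []
    chromosome_lengths: dict[str, int] = {}

    decoy_ids: list[str] = []
    per_species_genes: dict[str, list[str]] = {}

    for sp, n_genes in config.species.items():
        chroms = [f"{sp}_Chr{i + 1:02d}" for i in range(config.chromosomes_per_species)]
        for c in chroms:
            chromosome_lengths[c] = config.chromosome_length
        gene_ids = []
        choices = rng.choice(len(template_names), size=n_genes, p=probs)
        for i in range(n_genes):
            pid = f"{sp}CRK{i + 1:03d}"
            template = template_names[choices[i]]
            labels = config.templates[template]
            seq, planted = _plant_protein(pid, labels, rng, config, template)
            sequences[pid] = seq
            descriptions[pid] = f"synthetic CRK family member, template {template}"
            hits.extend(planted)
            origins.extend(["planted"] * len(planted))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "species": sp,
                    "is_family": True,
                    "template": template,
                    "architecture": "__".join(labels),
                    "expected_major": _truth_major(labels),
                    "expected_subclass": _truth_subclass(labels),
                    "expected_nomenclature": _truth_nomenclature(labels),
                    "cluster_id": "",
                }
            )
            gene_ids.append(pid)
        # decoy non-family proteins: kinase only, no DUF26
        n_decoys = int(round(config.decoy_protein_rate * n_genes))
        for i in range(n_decoys):
            pid = f"{sp}DEC{i + 1:03d}"
            seq, planted = _plant_protein(pid, ("Pkinase",), rng, config, "decoy")
            sequences[pid] = seq
            descriptions[pid] = "synthetic non-family decoy protein"
            hits.extend(planted)
            origins.extend(["planted"] * len(planted))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "species": sp,
                    "is_family": False,
                    "template": "decoy",
                    "architecture": "Pkinase",
                    "expected_major": "",
                    "expected_subclass": "",
                    "expected_nomenclature": "",
                    "cluster_id": "",
                }
            )
            decoy_ids.append(pid)
            gene_ids.append(pid)
        per_species_genes[sp] = gene_ids

    truth = pd.DataFrame(truth_rows)

    # --- chromosome placement -------------------------------------------
    cursors: dict[str, int] = {c: 400_000 for c in chromosome_lengths}
    placed: dict[str, GeneLocus] = {}
    cluster_counter = 0
    for spec in config.planted_clusters:
        if spec.species not in per_species_genes:
            raise ValueError(f"cluster spec names unknown species {spec.species!r}")
        chrom = f"{spec.species}_Chr{spec.chromosome_index + 1:02d}"
        family = [
            g
            for g in per_species_genes[spec.species]
            if g not in placed and not g.startswith(f"{spec.species}DEC")
        ]
        if len(family) < spec.n_members:
            raise ValueError(
                f"cluster spec needs {spec.n_members} genes but only "
                f"{len(family)} unplaced family genes remain in {spec.species}"
            )
        cluster_counter += 1
        cid = f"cluster{cluster_counter:02d}"
        for g in family[: spec.n_members]:
            glen = 3 * len(sequences[g]) + 200
            start = cursors[chrom]
            placed[g] = GeneLocus(
                gene_id=g,
                chromosome=chrom,
                start=start,
                end=start + glen - 1,
                strand="+" if rng.random() < 0.5 else "-",
                species=spec.species,
            )
            cursors[chrom] = start + glen + spec.spacing_bp
            truth.loc[truth.protein_id == g, "cluster_id"] = cid
        # push the cursor far enough that background genes cannot chain on
        cursors[chrom] += config.background_spacing_bp

    for sp, gene_ids in per_species_genes.items():
        chroms = [f"{sp}_Chr{i + 1:02d}" for i in range(config.chromosomes_per_species)]
        k = 0
        for g in gene_ids:
            if g in placed:
                continue
            chrom = chroms[k % len(chroms)]
            k += 1
            glen = 3 * len(sequences[g]) + 200
            start = cursors[chrom]
            placed[g] = GeneLocus(
                gene_id=g,
                chromosome=chrom,
                start=start,
                end=start + glen - 1,
                strand="+" if rng.random() < 0.5 else "-",
                species=sp,
            )
            cursors[chrom] = start + glen + config.background_spacing_bp
    overflow = [c for c, cur in cursors.items() if cur > chromosome_lengths[c]]
    if overflow:
        raise ValueError(f"chromosome(s) too short for the gene load: {overflow}")
    loci = [placed[g] for sp in per_species_genes for g in per_species_genes[sp]]
    truth["chromosome"] = [placed[p].chromosome for p in truth.protein_id]

    hits, origins = inject_noise(hits, config, rng, decoy_ids, origins)
    return SyntheticDataset(
        sequences=sequences,
        descriptions=descriptions,
        loci=loci,
        hits=hits,
        hit_origins=origins,
        chromosome_lengths=chromosome_lengths,
        truth=truth,
    )


def inject_noise(
    hits: list[DomainHit],
    config: SimConfig,
    rng_or_seed: np.random.Generator | int,
    decoy_ids: Sequence[str] = (),
    origins: Optional[list[str]] = None,
) -> tuple[list[DomainHit], list[str]]:
    """Add scanner-noise rows to a clean hit table.

    Two noise kinds: (a) overlapping near-duplicates of planted hits with
    strictly lower bit score — overlap resolution must remove them; and
    (b) sub-threshold DUF26 hits (insignificant, high E-value) on decoy
    proteins — the candidate filter must reject them.  Returns the
    augmented table and per-row origin flags.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    out = list(hits)
    flags = list(origins) if origins is not None else ["planted"] * len(hits)
    if config.duplicate_noise_rate > 0:
        by_protein: dict[str, list[DomainHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for pid in sorted(by_protein):
            if rng.random() >= config.duplicate_noise_rate:
                continue
            victim = by_protein[pid][int(rng.integers(len(by_protein[pid])))]
            shift = int(rng.integers(1, 10))
            dup = replace(
                victim,
                start=victim.start + shift,
                end=victim.end + shift,
                bit_score=float(np.round(victim.bit_score * rng.uniform(0.4, 0.9), 1)),
                e_value=(victim.e_value or 1e-10) * 10.0,
            )
            out.append(dup)
            flags.append("duplicate")
    if config.subthreshold_noise_rate > 0:
        for pid in decoy_ids:
            if rng.random() >= config.subthreshold_noise_rate:
                continue
            start = int(rng.integers(1, 40))
            out.append(
                DomainHit(
                    protein_id=pid,
                    domain_name=SA,
                    start=start,
                    end=start + 60,
                    e_value=float(rng.uniform(0.05, 5.0)),
                    bit_score=float(np.round(rng.uniform(5, 15), 1)),
                    significant=False,
                )
            )
            flags.append("subthreshold")
    return out, flags


def end_to_end_recovery(config: Optional[SimConfig] = None) -> dict:
    """Run generate → filter → resolve → build → classify → summarize and
    score the result against the planted truth.

    Returns a report with candidate counts, per-scheme label agreement
    fractions over the planted family proteins, the number of non-family
    decoys wrongly admitted, and tandem-cluster recovery (fraction of
    planted clusters recovered with identical membership).
    """
    from .classification import assign_all
    from .domain_architecture import FilterPolicy, architectures_from_hits, filter_crk_candidates
    from .genome_distribution import detect_tandem_clusters

    config = config or SimConfig()
    ds = generate_dataset(config)
    policy = FilterPolicy()
    candidates = filter_crk_candidates(ds.hits, policy)
    lengths = {pid: len(seq) for pid, seq in ds.sequences.items()}
    archs = architectures_from_hits(
        ds.hits, candidates=candidates, policy=policy, lengths=lengths
    )
    truth = ds.truth.set_index("protein_id")
    species_map = truth["species"].to_dict()
    ordered = [archs[pid] for pid in truth.index if pid in archs]
    assignments = assign_all(ordered, species=species_map)

    family = truth[truth.is_family]
    agree = {"major": 0, "subclass": 0, "nomenclature": 0}
    assigned = {a.protein_id: a for a in assignments}
    for pid, row in family.iterrows():
        a = assigned.get(pid)
        if a is None:
            continue
        agree["major"] += a.major_signature == row.expected_major
        agree["subclass"] += a.subclass_signature == row.expected_subclass
        agree["nomenclature"] += a.nomenclature == row.expected_nomenclature
    n_family = len(family)

    family_loci = [l for l in ds.loci if l.gene_id in set(family.index)]
    found = detect_tandem_clusters(family_loci)
    found_sets = {frozenset(c.members) for c in found}
    planted = {
        cid: frozenset(group.index)
        for cid, group in family.groupby("cluster_id")
        if cid
    }
    recovered = sum(1 for members in planted.values() if members in found_sets)

    return {
        "n_proteins": len(ds.sequences),
        "n_family": n_family,
        "n_candidates": len(candidates),
        "false_candidates": len(candidates - set(family.index)),
        "major_agreement": agree["major"] / n_family if n_family else 1.0,
        "subclass_agreement": agree["subclass"] / n_family if n_family else 1.0,
        "nomenclature_agreement": agree["nomenclature"] / n_family if n_family else 1.0,
        "clusters_planted": len(planted),
        "clusters_recovered": recovered,
        "cluster_recovery": recovered / len(planted) if planted else 1.0,
    }
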