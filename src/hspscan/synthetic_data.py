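"""Miniature annotated genome generator with machine-readable ground truth.

The generator emulates the input bundle of a genome-wide chaperone-family
survey: a multi-chromosome genome (FASTA) with GFF3 annotation, matching
proteome and CDS FASTA, a TPM expression matrix over named sample groups,
a divergent progenitor CDS set with a chromosome-correspondence map, a
promoter motif catalogue, a reference set of known family proteins for
the homology stream, and a truth table recording every planted feature.

Planted structure, all seed-deterministic:

* family proteins carry their sub-family signature domains, sampled from
  the bundled consensus with per-site substitution at ``domain_divergence``;
  decoys are background-composition proteins with no domain;
* tandem arrays (one per entry of ``tandem_array_sizes``) are same-strand
  runs of near-identical copies separated by 0-2 decoy genes; the first
  two members of each array are byte-identical proteins (planted identical
  duplicates); isolated family genes are laid out so that no spurious
  pair can satisfy the tandem rule (alternating unit strands, >= 2 decoys
  between units, hence >= 5 genes between any two same-strand family
  genes of different units);
* a ``pseudogene_fraction`` of family genes get TPM rows summing < 1,
  all others sum >= 1 by construction;
* promoters of family genes receive planted motif occurrences per
  sub-family; the truth table stores the post-planting count from an
  independent naive scan (planting into a random background can create
  or absorb incidental occurrences);
* every family gene has a progenitor CDS diverged at
  ``progenitor_divergence``, placed on the corresponding progenitor
  chromosome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats as io
from .domain_models import DOMAIN_CONSENSUS, SUBFAMILY_DOMAINS
from .expression_profiling import ExpressionMatrix
from .io_formats import GeneModel, SequenceRecord, reverse_complement
from .sequence_properties import (DEFAULT_CARE_MOTIFS, IUPAC, CareMotif,
                                  reverse_complement_iupac, write_care_motifs)

AA = io.AMINO_ACIDS
NT = "ACGT"

#: fixed reverse-translation codon per amino acid (codon realism is a non-goal)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

SUBFAMILIES = ("SHSP", "HSP40", "HSP60", "HSP70", "HSP90", "HSP100")

#: expression atlas layout: (sample id, group label)
SAMPLE_CATALOGUE: tuple[tuple[str, str], ...] = (
    ("grain_z71", "grain"), ("grain_z75", "grain"), ("grain_z85", "grain"),
    ("leaf_z10", "leaf"), ("leaf_z71", "leaf"),
    ("root_z10", "root"), ("root_z39", "root"), ("spike_z39", "spike"),
    ("control", "control"),
    ("heat_1h", "abiotic"), ("heat_6h", "abiotic"), ("drought_1h", "abiotic"),
    ("heat_drought_6h", "abiotic"),
    ("septoria_24h", "biotic"), ("blumeria_24h", "biotic"),
)

#: condition-specific induction multipliers per sub-family
DEFAULT_INDUCTION: dict[str, dict[str, float]] = {
    "SHSP": {"grain": 10.0, "abiotic": 3.0},
    "HSP40": {"biotic": 4.0},
    "HSP60": {"biotic": 3.0},
    "HSP70": {"spike": 4.0, "abiotic": 4.0},
    "HSP90": {"abiotic": 3.0},
    "HSP100": {"abiotic": 4.0},
}

DEFAULT_SUBFAMILY_MIX: dict[str, float] = {
    "SHSP": 0.30, "HSP40": 0.25, "HSP60": 0.10,
    "HSP70": 0.15, "HSP90": 0.05, "HSP100": 0.15,
}

DEFAULT_MOTIF_PLANTS: dict[str, dict[str, int]] = {
    "SHSP": {"HSE": 3, "ABRE": 2, "TATA-box": 1},
    "HSP40": {"W-box": 2, "TATA-box": 1},
    "HSP60": {"bZIP-Gbox": 2, "TATA-box": 1},
    "HSP70": {"HSE": 2, "STRE": 2, "TATA-box": 1},
    "HSP90": {"HSE": 1, "GARE": 1, "TATA-box": 1},
    "HSP100": {"DRE-CRT": 2, "TATA-box": 1},
}


class LayoutError(ValueError):
    """Requested gene complement cannot be placed on the genome."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions."""

    n_chromosomes: int = 6
    chromosome_length: int = 1_000_000
    n_family_genes: int = 60
    n_decoy_genes: int = 140
    subfamily_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBFAMILY_MIX))
    domain_divergence: float = 0.2
    tandem_array_sizes: list[int] = field(default_factory=lambda: [2, 5, 7])
    pseudogene_fraction: float = 0.2
    n_samples: int = 15
    motif_plant_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_MOTIF_PLANTS.items()})
    progenitor_divergence: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if not math.isclose(sum(self.subfamily_mix.values()), 1.0,
                            abs_tol=1e-6):
            raise ValueError("subfamily_mix must sum to 1")
        if any(p < 0 for p in self.subfamily_mix.values()):
            raise ValueError("subfamily_mix proportions must be >= 0")
        if not 0.0 <= self.domain_divergence <= 0.5:
            raise ValueError("domain_divergence must be in [0, 0.5]")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("pseudogene_fraction must be in [0, 1]")
        if not 0.0 <= self.progenitor_divergence <= 1.0:
            raise ValueError("progenitor_divergence must be in [0, 1]")
        if any(not 2 <= s <= 7 for s in self.tandem_array_sizes):
            raise ValueError("tandem array sizes must be in {2..7}")
        if sum(self.tandem_array_sizes) > self.n_family_genes:
            raise ValueError("tandem arrays exceed family gene count")
        if self.n_samples < 2:
            raise ValueError("need at least two expression samples")


@dataclass
class TruthRecord:
    """Ground truth for one emitted gene."""

    gene_id: str
    is_family_member: bool
    subfamily: str = ""
    planted_domains: list[str] = field(default_factory=list)
    tandem_array_id: str = ""
    is_pseudogene: bool = False
    planted_motif_counts: dict[str, int] = field(default_factory=dict)
    progenitor_ortholog_id: str = ""
    expression_params: dict[str, float] = field(default_factory=dict)


@dataclass
class TruthTable:
    records: dict[str, TruthRecord]

    def family_ids(self) -> list[str]:
        return sorted(g for g, r in self.records.items() if r.is_family_member)

    def pseudogene_ids(self) -> list[str]:
        return sorted(g for g, r in self.records.items() if r.is_pseudogene)

    def arrays(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, r in self.records.items():
            if r.tandem_array_id:
                out.setdefault(r.tandem_array_id, []).append(g)
        for members in out.values():
            members.sort()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records.values():
            rows.append({
                "gene_id": r.gene_id,
                "is_family_member": int(r.is_family_member),
                "subfamily": r.subfamily,
                "planted_domains": ",".join(r.planted_domains),
                "tandem_array_id": r.tandem_array_id,
                "is_pseudogene": int(r.is_pseudogene),
                "planted_motif_counts": json.dumps(r.planted_motif_counts,
                                                   sort_keys=True),
                "progenitor_ortholog_id": r.progenitor_ortholog_id,
                "expression_params": json.dumps(r.expression_params,
                                                sort_keys=True),
            })
        rows.sort(key=lambda d: d["gene_id"])
        return pd.DataFrame(rows)


@dataclass
class DatasetBundle:
    """In-memory dataset plus (optionally) the directory it was written to."""

    config: SyntheticConfig
    genome: dict[str, str]
    models: list[GeneModel]
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    tpm: ExpressionMatrix
    progenitor_cds: list[SequenceRecord]
    progenitor_chromosomes: dict[str, str]
    chromosome_map: dict[str, str]
    reference_proteins: list[SequenceRecord]
    truth: TruthTable
    outdir: Path | None = None


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def mutate_sequence(seq: str, rate: float, alphabet: str = AA,
                    rng: np.random.Generator | int | None = None) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted position always changes to a *different* symbol of the
    alphabet, so ``rate=1`` leaves no position intact and ``rate=0`` is
    the identity. Length is preserved; an empty sequence stays empty.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not seq:
        return ""
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        options = alphabet.replace(chars[i], "")
        chars[i] = options[rng.integers(len(options))]
    return "".join(chars)


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = AA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _reverse_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein) + "TAA"


def _largest_remainder(total: int, mix: Mapping[str, float]) -> dict[str, int]:
    raw = {k: total * v for k, v in mix.items()}
    counts = {k: int(math.floor(x)) for k, x in raw.items()}
    short = total - sum(counts.values())
    order = sorted(mix, key=lambda k: -(raw[k] - counts[k]))
    for k in order[:short]:
        counts[k] += 1
    return counts


def naive_motif_count(seq: str, motif: CareMotif, both_strands: bool = True
                      ) -> int:
    """Position-by-position IUPAC occurrence count (generator-side truth).

    Independent of the pipeline's regex-based scanner; same conventions:
    overlaps counted, both strands, palindromes once per position.
    """
    def count(pattern: str) -> int:
        k, n = len(pattern), 0
        allowed = [set(IUPAC[c]) for c in pattern.upper()]
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in allowed[j] for j in range(k)):
                n += 1
        return n

    total = count(motif.pattern)
    if both_strands and motif.pattern.upper() != reverse_complement_iupac(
            motif.pattern):
        total += count(reverse_complement_iupac(motif.pattern))
    return total


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _family_protein(rng: np.random.Generator, subfamily: str,
                    divergence: float) -> tuple[str, list[str]]:
    """Protein with the sub-family's signature domains in random flanks."""
    domains = SUBFAMILY_DOMAINS[subfamily]
    parts = [_random_seq(rng, int(rng.integers(40, 91)))]
    for k, dom in enumerate(domains):
        planted = mutate_sequence(DOMAIN_CONSENSUS[dom], divergence, AA, rng)
        parts.append(planted)
        if k < len(domains) - 1:
            parts.append(_random_seq(rng, int(rng.integers(10, 21))))
    parts.append(_random_seq(rng, int(rng.integers(40, 91))))
    return "".join(parts), list(domains)


def _exon_layout(rng: np.random.Generator, cds_len: int, subfamily: str | None
                 ) -> tuple[list[int], list[int]]:
    """(exon chunk lengths, intron lengths) for one gene."""
    if subfamily == "SHSP":
        n_exons = int(rng.choice([1, 1, 1, 2, 3]))      # at most two introns
    elif subfamily in ("HSP60", "HSP90"):
        n_exons = int(rng.integers(4, 9))               # never intronless
    elif subfamily is not None:
        n_exons = int(rng.choice([1, 2, 3, 4]))
    else:
        n_exons = int(rng.choice([1, 2, 3]))
    n_exons = min(n_exons, max(1, cds_len // 30))
    if n_exons == 1:
        return [cds_len], []
    cuts = sorted(rng.choice(np.arange(3, cds_len - 3, 3), size=n_exons - 1,
                             replace=False).tolist())
    bounds = [0, *cuts, cds_len]
    chunks = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(60, 301)) for _ in range(n_exons - 1)]
    return chunks, introns


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _chromosome_names(n: int) -> list[str]:
    return [f"{i // 3 + 1}{'ABD'[i % 3]}" for i in range(n)]


def generate_dataset(config: SyntheticConfig | None = None,
                     outdir: str | Path | None = None) -> DatasetBundle:
    """Generate the full dataset bundle; optionally write it to ``outdir``.

    All randomness flows from ``config.seed``; two runs with the same
    config produce byte-identical bundles. The layout is assembled and
    validated entirely in memory before any file is written, so an
    impossible layout fails without partial output.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = _chromosome_names(config.n_chromosomes)

    # --- sub-family quotas and tandem arrays -------------------------------
    quotas = _largest_remainder(config.n_family_genes, config.subfamily_mix)
    array_subfamilies: list[str] = []
    preference = ["HSP40", "SHSP", "HSP70", "HSP100", "HSP60", "HSP90"]
    remaining = dict(quotas)
    for size in sorted(config.tandem_array_sizes, reverse=True):
        for sf in preference:
            if remaining.get(sf, 0) >= size:
                array_subfamilies.append(sf)
                remaining[sf] -= size
                break
        else:
            raise LayoutError(f"no sub-family can host an array of {size}")
    sizes_sorted = sorted(config.tandem_array_sizes, reverse=True)

    # units: (kind, subfamily, n_members)
    units: list[tuple[str, str, int]] = [
        ("array", sf, size) for sf, size in zip(array_subfamilies, sizes_sorted)]
    for sf in SUBFAMILIES:
        units.extend(("lone", sf, 1) for _ in range(remaining.get(sf, 0)))
    rng.shuffle(units)

    # assign units round-robin; between-unit gaps get >= 2 decoys
    per_chrom_units: dict[str, list[tuple[str, str, int]]] = {
        c: [] for c in chrom_names}
    for i, unit in enumerate(units):
        per_chrom_units[chrom_names[i % len(chrom_names)]].append(unit)

    decoys_needed = sum(max(0, len(u) - 1) * 2
                        for u in per_chrom_units.values())
    intra_gaps: dict[int, list[int]] = {}
    for idx, (kind, _sf, size) in enumerate(units):
        if kind == "array":
            gaps = [int(rng.integers(0, 3)) for _ in range(size - 1)]
            intra_gaps[idx] = gaps
            decoys_needed += sum(gaps)
    if decoys_needed > config.n_decoy_genes:
        raise LayoutError(
            f"layout needs {decoys_needed} decoys, have {config.n_decoy_genes}")
    spare = config.n_decoy_genes - decoys_needed

    # --- build gene plans per chromosome ------------------------------------
    @dataclass
    class _Plan:
        gene_id: str
        chromosome: str
        strand: str
        is_family: bool
        subfamily: str = ""
        array_id: str = ""
        protein: str = ""
        domains: list[str] = field(default_factory=list)

    plans_by_chrom: dict[str, list[_Plan]] = {c: [] for c in chrom_names}
    unit_index = {id(u): i for i, u in enumerate(units)}
    n_arrays = 0
    gene_counter = 0
    decoy_counter = 0

    def new_decoy(chrom: str) -> _Plan:
        nonlocal decoy_counter
        decoy_counter += 1
        return _Plan(gene_id=f"g{chrom}d{decoy_counter:03d}", chromosome=chrom,
                     strand="+-"[int(rng.integers(2))], is_family=False)

    array_records: dict[str, list[str]] = {}
    for chrom in chrom_names:
        strand = "+-"[int(rng.integers(2))]
        chrom_units = per_chrom_units[chrom]
        for u_i, unit in enumerate(chrom_units):
            kind, sf, size = unit
            if u_i > 0:
                for _ in range(2):
                    plans_by_chrom[chrom].append(new_decoy(chrom))
            if kind == "lone":
                gene_counter += 1
                prot, doms = _family_protein(rng, sf, config.domain_divergence)
                plans_by_chrom[chrom].append(_Plan(
                    gene_id=f"g{chrom}f{gene_counter:03d}", chromosome=chrom,
                    strand=strand, is_family=True, subfamily=sf,
                    protein=prot, domains=doms))
            else:
                n_arrays += 1
                array_id = f"truth_array_{n_arrays}"
                gaps = intra_gaps[unit_index[id(unit)]]
                prot, doms = _family_protein(rng, sf, config.domain_divergence)
                members = []
                for m in range(size):
                    gene_counter += 1
                    if m == 1:
                        member_prot = prot       # planted identical duplicate
                    elif m > 1:
                        member_prot = mutate_sequence(prot, 0.03, AA, rng)
                        prot = member_prot
                    else:
                        member_prot = prot
                    gid = f"g{chrom}f{gene_counter:03d}"
                    members.append(gid)
                    plans_by_chrom[chrom].append(_Plan(
                        gene_id=gid, chromosome=chrom, strand=strand,
                        is_family=True, subfamily=sf, array_id=array_id,
                        protein=member_prot, domains=list(doms)))
                    if m < size - 1:
                        for _ in range(gaps[m]):
                            plans_by_chrom[chrom].append(new_decoy(chrom))
                array_records[array_id] = members
            strand = "-" if strand == "+" else "+"
        # spare decoys at the chromosome end
        n_extra = spare // len(chrom_names) + (
            1 if chrom_names.index(chrom) < spare % len(chrom_names) else 0)
        for _ in range(n_extra):
            plans_by_chrom[chrom].append(new_decoy(chrom))

    # decoy proteins
    for chrom in chrom_names:
        for plan in plans_by_chrom[chrom]:
            if not plan.is_family:
                plan.protein = _random_seq(rng, int(rng.integers(120, 281)))

    # --- physical layout -----------------------------------------------------
    genomes: dict[str, np.ndarray] = {}
    models: list[GeneModel] = []
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    truth: dict[str, TruthRecord] = {}
    nt_codes = np.frombuffer(b"ACGT", dtype=np.uint8)

    placements: dict[str, _Plan] = {}
    for chrom in chrom_names:
        genome = nt_codes[rng.integers(0, 4, config.chromosome_length)].copy()
        cursor = 3000 + int(rng.integers(0, 500))
        for plan in plans_by_chrom[chrom]:
            cds = _reverse_translate(plan.protein)
            chunks, introns = _exon_layout(
                rng, len(cds), plan.subfamily if plan.is_family else None)
            g_parts, e_offsets, off, pos = [], [], 0, 0
            for i, ch in enumerate(chunks):
                g_parts.append(cds[pos:pos + ch])
                e_offsets.append((off, off + ch))
                pos += ch
                off += ch
                if i < len(introns):
                    g_parts.append(_random_seq(rng, introns[i], NT))
                    off += introns[i]
            g_seq = "".join(g_parts)
            start = cursor
            end = start + len(g_seq) - 1
            if end + 3500 > config.chromosome_length:
                raise LayoutError(
                    f"chromosome {chrom} too short at gene {plan.gene_id}")
            if plan.strand == "+":
                placed = g_seq
                exons = [(start + a, start + b - 1) for a, b in e_offsets]
            else:
                placed = reverse_complement(g_seq)
                L = len(g_seq)
                exons = sorted((start + L - b, start + L - a - 1)
                               for a, b in e_offsets)
            genome[start - 1:end] = np.frombuffer(placed.encode(),
                                                  dtype=np.uint8)
            models.append(GeneModel(plan.gene_id, chrom, start, end,
                                    plan.strand, exons))
            proteins.append(SequenceRecord(plan.gene_id, plan.protein, "aa"))
            cds_records.append(SequenceRecord(plan.gene_id, cds, "nt"))
            placements[plan.gene_id] = plan
            truth[plan.gene_id] = TruthRecord(
                gene_id=plan.gene_id, is_family_member=plan.is_family,
                subfamily=plan.subfamily, planted_domains=list(plan.domains),
                tandem_array_id=plan.array_id)
            cursor = end + 1 + int(rng.integers(3300, 4800))
        genomes[chrom] = genome

    # --- promoter motif planting --------------------------------------------
    motifs = {m.name: m for m in DEFAULT_CARE_MOTIFS}
    for model in models:
        plan = placements[model.gene_id]
        if not plan.is_family:
            continue
        plant_spec = config.motif_plant_counts.get(plan.subfamily, {})
        genome = genomes[model.chromosome]
        # coding-strand promoter slice of the genome (0-based [lo, hi))
        if model.strand == "+":
            lo, hi = max(0, model.start - 1501), model.start - 1
        else:
            lo, hi = model.end, min(len(genome), model.end + 1500)
        promoter = bytes(genome[lo:hi]).decode()
        if model.strand == "-":
            promoter = reverse_complement(promoter)
        prom = list(promoter)
        used: list[tuple[int, int]] = []
        for name in sorted(plant_spec):
            motif = motifs[name]
            for _ in range(plant_spec[name]):
                instance = "".join(
                    IUPAC[c][rng.integers(len(IUPAC[c]))]
                    for c in motif.pattern.upper())
                for _attempt in range(60):
                    p = int(rng.integers(0, len(prom) - len(instance) + 1))
                    if all(p + len(instance) <= a or p >= b for a, b in used):
                        prom[p:p + len(instance)] = list(instance)
                        used.append((p, p + len(instance)))
                        break
        planted = "".join(prom)
        back = planted if model.strand == "+" else reverse_complement(planted)
        genome[lo:hi] = np.frombuffer(back.encode(), dtype=np.uint8)
        truth[model.gene_id].planted_motif_counts = {
            m.name: naive_motif_count(planted, m) for m in DEFAULT_CARE_MOTIFS}

    genome_seqs = {c: bytes(g).decode() for c, g in genomes.items()}

    # --- expression matrix ---------------------------------------------------
    samples = list(SAMPLE_CATALOGUE)
    while len(samples) < config.n_samples:
        k = len(samples) - len(SAMPLE_CATALOGUE) + 2
        base = SAMPLE_CATALOGUE[(len(samples) - len(SAMPLE_CATALOGUE))
                                % len(SAMPLE_CATALOGUE)]
        samples.append((f"{base[0]}_r{k}", base[1]))
    samples = samples[:config.n_samples]
    sample_ids = [s for s, _ in samples]
    groups = {s: g for s, g in samples}

    family_ids = [m.gene_id for m in models
                  if placements[m.gene_id].is_family]
    n_pseudo = int(round(config.pseudogene_fraction * len(family_ids)))
    pseudo_ids = set(rng.choice(family_ids, size=n_pseudo, replace=False)
                     .tolist()) if n_pseudo else set()

    values = np.zeros((len(models), config.n_samples))
    for gi, model in enumerate(models):
        plan = placements[model.gene_id]
        if model.gene_id in pseudo_ids:
            values[gi] = rng.uniform(0, 0.9 / config.n_samples,
                                     config.n_samples)
            truth[model.gene_id].is_pseudogene = True
            continue
        induction = (DEFAULT_INDUCTION.get(plan.subfamily, {})
                     if plan.is_family else {})
        base = float(np.exp(rng.normal(1.0, 0.8)))
        row = np.array([
            base * induction.get(groups[s], 1.0)
            * float(np.exp(rng.normal(0.0, 0.25)))
            for s in sample_ids])
        if row.sum() < 1.0:
            row *= 1.5 / row.sum()
        values[gi] = row
        if plan.is_family:
            truth[model.gene_id].expression_params = {
                f"induction_{g}": m for g, m in induction.items()}
    tpm = ExpressionMatrix([m.gene_id for m in models], sample_ids, values,
                           dict(groups))

    # --- progenitor CDS ------------------------------------------------------
    # tandem arrays model lineage-specific expansion: the progenitor carries
    # one ortholog per array (its first member), so planted top-hit orthology
    # stays unambiguous among near-identical array copies
    progenitor: list[SequenceRecord] = []
    prog_chrom: dict[str, str] = {}
    chromosome_map = {c: c[:-1] for c in chrom_names}
    cds_by_id = {r.id: r for r in cds_records}
    later_members = {g for members in array_records.values()
                     for g in members[1:]}
    for gid in (g for g in family_ids if g not in later_members):
        pid = f"prg_{gid}"
        seq = mutate_sequence(cds_by_id[gid].sequence,
                              config.progenitor_divergence, NT, rng)
        progenitor.append(SequenceRecord(pid, seq, "nt"))
        wheat_chrom = next(m.chromosome for m in models if m.gene_id == gid)
        prog_chrom[pid] = chromosome_map[wheat_chrom]
        truth[gid].progenitor_ortholog_id = pid

    reference = reference_hsp_set()

    bundle = DatasetBundle(
        config=config, genome=genome_seqs, models=models, proteins=proteins,
        cds=cds_records, tpm=tpm, progenitor_cds=progenitor,
        progenitor_chromosomes=prog_chrom, chromosome_map=chromosome_map,
        reference_proteins=reference, truth=TruthTable(truth))
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def reference_hsp_set() -> list[SequenceRecord]:
    """Fixed 'known family member' reference proteins (homology stream).

    Two per sub-family: signature domains at 5% divergence from consensus
    inside fixed flanks. Seeded independently of the dataset config, as a
    stand-in for an external curated database; synthetic by construction.
    """
    rng = np.random.default_rng(988)
    out = []
    for sf in SUBFAMILIES:
        for k in (1, 2):
            parts = [_random_seq(rng, 50)]
            for dom in SUBFAMILY_DOMAINS[sf]:
                parts.append(mutate_sequence(DOMAIN_CONSENSUS[dom], 0.05,
                                             AA, rng))
                parts.append(_random_seq(rng, 12))
            out.append(SequenceRecord(f"ref_{sf}_{k}", "".join(parts), "aa"))
    return out


def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> Path:
    """Write every bundle file (FASTA / GFF3 / TSV) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta([SequenceRecord(c, s, "nt")
                    for c, s in sorted(bundle.genome.items())],
                   outdir / "genome.fasta")
    io.write_gff3(bundle.models, outdir / "annotation.gff3")
    io.write_fasta(bundle.proteins, outdir / "proteome.fasta")
    io.write_fasta(bundle.cds, outdir / "cds.fasta")
    io.write_fasta(bundle.progenitor_cds, outdir / "progenitor_cds.fasta")
    io.write_fasta(bundle.reference_proteins, outdir / "reference_hsp.fasta")
    io.write_tpm_matrix(bundle.tpm, outdir / "tpm_matrix.tsv")
    io.write_tsv(pd.DataFrame(
        [{"sample_id": s, "group": g}
         for s, g in bundle.tpm.sample_groups.items()]),
        outdir / "sample_groups.tsv")
    io.write_tsv(pd.DataFrame(
        [(p, c) for p, c in sorted(bundle.progenitor_chromosomes.items())],
        columns=["progenitor_gene_id", "chromosome"]),
        outdir / "progenitor_map.tsv")
    io.write_tsv(pd.DataFrame(
        [{"chromosome": a, "progenitor_chromosome": b}
         for a, b in sorted(bundle.chromosome_map.items())]),
        outdir / "chromosome_map.tsv")
    write_care_motifs(DEFAULT_CARE_MOTIFS, outdir / "care_motifs.tsv")
    io.write_tsv(bundle.truth.to_frame(), outdir / "truth_table.tsv")
    bundle.outdir = outdir
    return outdir


def read_truth_table(path: str | Path) -> TruthTable:
    df = io.read_tsv(path, dtype={"subfamily": str, "tandem_array_id": str,
                                  "planted_domains": str,
                                  "progenitor_ortholog_id": str},
                     keep_default_na=False)
    records = {}
    for _, row in df.iterrows():
        records[row["gene_id"]] = TruthRecord(
            gene_id=row["gene_id"],
            is_family_member=bool(int(row["is_family_member"])),
            subfamily=row["subfamily"],
            planted_domains=[d for d in row["planted_domains"].split(",") if d],
            tandem_array_id=row["tandem_array_id"],
            is_pseudogene=bool(int(row["is_pseudogene"])),
            planted_motif_counts=json.loads(row["planted_motif_counts"] or "{}"),
            progenitor_ortholog_id=row["progenitor_ortholog_id"],
            expression_params=json.loads(row["expression_params"] or "{}"))
    return TruthTable(records)
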