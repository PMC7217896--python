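"""Candidate merging, sub-family classification, naming and gene structure.

The family survey combines two evidence streams: domain hits from profile
scanning and homology hits against known family members. Candidates from
either stream are only confirmed if a required sub-family domain is
present (the confirmation re-scan). Confirmed members are classified into
the six chaperone sub-families by signature-domain content:

    SHSP    alpha-crystallin domain (pfam00011)
    HSP40   DnaJ J-domain (pfam00226)
    HSP60   Cpn60_TCP1 (pfam00118)
    HSP70   HSP70 domain (pfam00012)
    HSP90   HSP90 domain (pfam00183), HATPase_c (pfam02518) expected
    HSP100  any >=2 of Clp_N (pfam02861), ClpB_D2-small (pfam10431),
            AAA variants (pfam07724, pfam07728)

Names follow the positional scheme TaSHSP<n> / Ta<subfamily>.<n>: within a
sub-family, genes are numbered by chromosome (natural order 1A, 1B, 1D,
..., 7D) and ascending start coordinate, the annotation origin standing in
for the short-arm telomere; unplaced genes are numbered last. Isoforms of
one gene share its number with a .k suffix.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, chromosome_sort_key, logger
from .sequence_search import AlignmentResult, DomainHit

SUBFAMILIES = ("SHSP", "HSP40", "HSP60", "HSP70", "HSP90", "HSP100")


@dataclass(frozen=True)
class SubfamilyRule:
    """Signature-domain rule for one sub-family.

    ``required_domains`` is an any-of set; ``min_required`` distinct
    required domains must be present (>1 only for the multi-domain
    disaggregase family). ``auxiliary_domains`` are expected but their
    absence is recorded, not disqualifying.
    """

    subfamily: str
    required_domains: frozenset[str]
    auxiliary_domains: frozenset[str] = frozenset()
    min_required: int = 1

    def __post_init__(self) -> None:
        if not self.required_domains:
            raise ValueError("required_domains must be non-empty")


DEFAULT_RULES: tuple[SubfamilyRule, ...] = (
    SubfamilyRule("SHSP", frozenset({"pfam00011"})),
    SubfamilyRule("HSP40", frozenset({"pfam00226"})),
    SubfamilyRule("HSP60", frozenset({"pfam00118"})),
    SubfamilyRule("HSP70", frozenset({"pfam00012"})),
    SubfamilyRule("HSP90", frozenset({"pfam00183"}),
                  auxiliary_domains=frozenset({"pfam02518"})),
    SubfamilyRule("HSP100",
                  frozenset({"pfam02861", "pfam10431", "pfam07724", "pfam07728"}),
                  min_required=2),
)

ALL_REQUIRED_DOMAINS = frozenset().union(*(r.required_domains for r in DEFAULT_RULES))


@dataclass
class SubfamilyRecord:
    """A confirmed family member with its evidence and assigned name."""

    gene_id: str
    subfamily: str
    evidence_domains: list[DomainHit] = field(default_factory=list)
    evidence_homology: list[AlignmentResult] = field(default_factory=list)
    assigned_name: str = ""
    isoform_names: list[str] = field(default_factory=list)
    auxiliary_missing: list[str] = field(default_factory=list)


@dataclass
class GeneStructureStats:
    """Exon/intron statistics of one gene model."""

    gene_id: str
    gene_length: int
    exon_count: int
    intron_count: int
    intron_lengths: list[int]
    intronless: bool
    strand: str


# ---------------------------------------------------------------------------
# Evidence merging and classification
# ---------------------------------------------------------------------------

def merge_candidates(domain_hits: Sequence[DomainHit],
                     homology_hits: Sequence[AlignmentResult],
                     rules: Sequence[SubfamilyRule] = DEFAULT_RULES,
                     domain_e_max: float = 1e-4) -> list[str]:
    """Union of the two evidence streams, confirmed by required domains.

    A candidate arriving from either stream is kept only if it carries at
    least one required domain of some sub-family at ``domain_e_max``; the
    rest are dropped (homology resemblance without a signature domain is
    not family membership).
    """
    required = frozenset().union(*(r.required_domains for r in rules))
    by_gene: dict[str, list[DomainHit]] = defaultdict(list)
    for h in domain_hits:
        by_gene[h.protein_id].append(h)
    candidates = set(by_gene) | {h.query_id for h in homology_hits}
    confirmed = []
    for gene in candidates:
        ok = any(h.domain_id in required and h.e_value <= domain_e_max
                 for h in by_gene.get(gene, ()))
        if ok:
            confirmed.append(gene)
        else:
            logger.debug("candidate %s dropped: no confirmed required domain", gene)
    return sorted(confirmed)


def assign_subfamily(hits: Sequence[DomainHit],
                     rules: Sequence[SubfamilyRule] = DEFAULT_RULES,
                     domain_e_max: float = 1e-4) -> tuple[str, list[str]]:
    """Sub-family label for one protein's domain hits.

    Returns ``(label, missing_auxiliary_domains)``; label is
    ``"unclassified"`` when no rule matches. When the required domains of
    several rules are present (chimeric domain content), the rule backed
    by the highest-scoring required-domain hit wins and the conflict is
    logged.
    """
    good = [h for h in hits if h.e_value <= domain_e_max]
    present = {h.domain_id for h in good}
    best_bit = {d: max(h.bit_score for h in good if h.domain_id == d)
                for d in present}
    matches = []
    for rule in rules:
        found = rule.required_domains & present
        if len(found) >= rule.min_required:
            matches.append((max(best_bit[d] for d in found), rule))
    if not matches:
        return "unclassified", []
    if len(matches) > 1:
        names = [r.subfamily for _, r in matches]
        logger.warning("protein matches multiple sub-families %s; "
                       "assigning by best domain bit score", names)
    matches.sort(key=lambda t: -t[0])
    rule = matches[0][1]
    missing = sorted(rule.auxiliary_domains - present)
    return rule.subfamily, missing


def classify_candidates(candidates: Iterable[str],
                        domain_hits: Sequence[DomainHit],
                        homology_hits: Sequence[AlignmentResult] = (),
                        rules: Sequence[SubfamilyRule] = DEFAULT_RULES,
                        domain_e_max: float = 1e-4) -> list[SubfamilyRecord]:
    """Build SubfamilyRecords for confirmed candidates (one per gene)."""
    dom_by_gene: dict[str, list[DomainHit]] = defaultdict(list)
    for h in domain_hits:
        dom_by_gene[h.protein_id].append(h)
    hom_by_gene: dict[str, list[AlignmentResult]] = defaultdict(list)
    for h in homology_hits:
        hom_by_gene[h.query_id].append(h)
    records = []
    for gene in sorted(candidates):
        label, missing = assign_subfamily(dom_by_gene.get(gene, ()), rules,
                                          domain_e_max)
        if label == "unclassified":
            logger.info("gene %s confirmed but unclassified", gene)
            continue
        records.append(SubfamilyRecord(
            gene_id=gene, subfamily=label,
            evidence_domains=sorted(dom_by_gene.get(gene, ()),
                                    key=lambda h: -h.bit_score),
            evidence_homology=hom_by_gene.get(gene, []),
            auxiliary_missing=missing))
    return records


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def subfamily_prefix(subfamily: str) -> str:
    return "TaSHSP" if subfamily == "SHSP" else f"Ta{subfamily}"


def assign_names(records: Sequence[SubfamilyRecord],
                 models: Mapping[str, GeneModel] | Sequence[GeneModel]
                 ) -> list[SubfamilyRecord]:
    """Assign positional names within each sub-family (in place).

    Genes are ordered by chromosome (natural order), then start
    coordinate; unplaced genes (chromosome ``Un``) come last, ordered by
    gene id. The small-chaperone family is named ``TaSHSP<n>``, all others
    ``Ta<subfamily>.<n>``; a gene with several annotated isoforms also
    receives ``<name>.<k>`` isoform names in annotation order.
    """
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        dup = [g for g, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate gene ids: {dup}")

    def sort_key(rec: SubfamilyRecord):
        model = models.get(rec.gene_id)
        if model is None or model.unplaced:
            return (1, (0, 0, ""), 0, rec.gene_id)
        return (0, chromosome_sort_key(model.chromosome), model.start,
                rec.gene_id)

    by_subfamily: dict[str, list[SubfamilyRecord]] = defaultdict(list)
    for rec in records:
        by_subfamily[rec.subfamily].append(rec)
    for subfamily, recs in by_subfamily.items():
        recs.sort(key=sort_key)
        prefix = subfamily_prefix(subfamily)
        for n, rec in enumerate(recs, 1):
            base = f"{prefix}{n}" if subfamily == "SHSP" else f"{prefix}.{n}"
            rec.assigned_name = base
            model = models.get(rec.gene_id)
            n_iso = model.n_isoforms if model is not None else 1
            rec.isoform_names = ([f"{base}.{k}" for k in range(1, n_iso + 1)]
                                 if n_iso > 1 else [base])
    return list(records)


# ---------------------------------------------------------------------------
# Gene structure and distribution
# ---------------------------------------------------------------------------

def structure_stats(model: GeneModel) -> GeneStructureStats:
    """Intron/exon statistics from the gene's exon union."""
    exons = model.exons
    introns = [(exons[i][1] + 1, exons[i + 1][0] - 1)
               for i in range(len(exons) - 1)]
    lengths = [e - s + 1 for s, e in introns]
    return GeneStructureStats(
        gene_id=model.gene_id, gene_length=model.length,
        exon_count=len(exons), intron_count=len(introns),
        intron_lengths=lengths, intronless=not introns, strand=model.strand)


@dataclass
class DistributionSummary:
    per_chromosome: dict[str, int]
    per_subgenome: dict[str, int]
    per_subfamily: dict[str, int]
    per_subfamily_chromosome: dict[tuple[str, str], int]
    unplaced: int


def distribution_summary(records: Sequence[SubfamilyRecord],
                         models: Mapping[str, GeneModel] | Sequence[GeneModel]
                         ) -> DistributionSummary:
    """Per-chromosome / sub-genome / sub-family member counts."""
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}
    per_chrom: Counter = Counter()
    per_sub: Counter = Counter()
    per_fam: Counter = Counter()
    per_fam_chrom: Counter = Counter()
    unplaced = 0
    for rec in records:
        per_fam[rec.subfamily] += 1
        model = models.get(rec.gene_id)
        if model is None or model.unplaced:
            unplaced += 1
            continue
        per_chrom[model.chromosome] += 1
        per_fam_chrom[(rec.subfamily, model.chromosome)] += 1
        if model.subgenome:
            per_sub[model.subgenome] += 1
    return DistributionSummary(dict(per_chrom), dict(per_sub), dict(per_fam),
                               dict(per_fam_chrom), unplaced)


def family_table(records: Sequence[SubfamilyRecord],
                 models: Mapping[str, GeneModel]) -> pd.DataFrame:
    """Master family table (one row per member), mirroring a survey's
    supplementary gene list."""
    rows = []
    for rec in records:
        m = models.get(rec.gene_id)
        rows.append({
            "gene_id": rec.gene_id,
            "name": rec.assigned_name,
            "subfamily": rec.subfamily,
            "chromosome": m.chromosome if m else "Un",
            "start": m.start if m else 0,
            "end": m.end if m else 0,
            "strand": m.strand if m else ".",
            "domains": ",".join(sorted({h.domain_id
                                        for h in rec.evidence_domains})),
            "auxiliary_missing": ",".join(rec.auxiliary_missing),
            "evidence": ("domain+homology" if rec.evidence_homology
                         else "domain"),
        })
    columns = ["gene_id", "name", "subfamily", "chromosome", "start", "end",
               "strand", "domains", "auxiliary_missing", "evidence"]
    return pd.DataFrame(rows, columns=columns)
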