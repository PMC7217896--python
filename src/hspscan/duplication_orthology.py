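"""Tandem duplication, identical duplicates, orthology and synteny.

The tandem rule: a pair of family genes is a tandem duplication event iff
both lie on the same chromosome and strand, their protein identity is
strictly greater than 40%, and strictly fewer than five annotated genes
(of any kind, not only family members) lie between them. Qualifying pairs
are chained transitively into arrays (connected components of the
qualifying-pair graph).

Orthologs are top hits of family CDS against a progenitor CDS set, kept
only at e-value <= 1e-10 and bit score >= 150; an ortholog is syntenic
when it lies on the chromosome corresponding to its wheat gene's
chromosome (e.g. 7A and chromosome 7 of the A-genome progenitor).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import InitVar, dataclass, field
from typing import Callable, Mapping, Sequence

from .io_formats import GeneModel, SequenceRecord, logger
from .sequence_search import AlignmentResult, smith_waterman


@dataclass
class TandemPair:
    """One qualifying tandem-duplication gene pair."""

    gene_a: str
    gene_b: str
    chromosome: str
    strand: str
    identity_pct: float
    intervening_genes: int


@dataclass
class TandemArray:
    """A transitively chained cluster of tandem-duplicated genes."""

    array_id: str
    chromosome: str
    strand: str
    member_gene_ids: list[str]
    pairwise_identities: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("array needs at least two members")


def _intervening_counts(all_models: Sequence[GeneModel]
                        ) -> dict[str, dict[str, int]]:
    """Per chromosome, each gene's rank in the start-sorted gene order."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in all_models:
        by_chrom[m.chromosome].append(m)
    ranks: dict[str, dict[str, int]] = {}
    for chrom, models in by_chrom.items():
        models.sort(key=lambda m: (m.start, m.gene_id))
        ranks[chrom] = {m.gene_id: i for i, m in enumerate(models)}
    return ranks


def find_tandem_duplications(
        family_models: Sequence[GeneModel],
        all_models: Sequence[GeneModel],
        proteins: Mapping[str, SequenceRecord],
        identity_fn: Callable[[SequenceRecord, SequenceRecord], float] | None = None,
        min_identity: float = 40.0,
        max_intervening: int = 5,
) -> tuple[list[TandemPair], list[TandemArray]]:
    """Detect tandem-duplication pairs and chain them into arrays.

    ``identity_fn`` defaults to local-alignment percent identity
    (BLAST-style); pass a global-identity function to switch conventions.
    Positional screening (chromosome, strand, intervening count) runs
    before any alignment, so only nearby same-strand pairs are aligned.
    """
    for m in family_models:
        if m.gene_id not in proteins:
            raise KeyError(f"no protein sequence for family gene {m.gene_id}")
    if identity_fn is None:
        def identity_fn(a: SequenceRecord, b: SequenceRecord) -> float:
            return smith_waterman(a, b).identity_pct

    ranks = _intervening_counts(all_models)
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in family_models:
        if not m.unplaced:
            by_chrom[m.chromosome].append(m)

    pairs: list[TandemPair] = []
    for chrom, models in sorted(by_chrom.items()):
        models.sort(key=lambda m: (m.start, m.gene_id))
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                a, b = models[i], models[j]
                if a.strand != b.strand:
                    continue
                between = abs(ranks[chrom][b.gene_id]
                              - ranks[chrom][a.gene_id]) - 1
                if between >= max_intervening:
                    continue
                ident = identity_fn(proteins[a.gene_id], proteins[b.gene_id])
                if ident > min_identity:
                    pairs.append(TandemPair(a.gene_id, b.gene_id, chrom,
                                            a.strand, ident, between))
    return pairs, chain_arrays(pairs, family_models)


def chain_arrays(pairs: Sequence[TandemPair],
                 family_models: Sequence[GeneModel]) -> list[TandemArray]:
    """Connected components of the qualifying-pair graph, ordered by
    coordinate."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        parent.setdefault(p.gene_a, p.gene_a)
        parent.setdefault(p.gene_b, p.gene_b)
        ra, rb = find(p.gene_a), find(p.gene_b)
        if ra != rb:
            parent[ra] = rb

    comps: dict[str, list[str]] = defaultdict(list)
    for g in parent:
        comps[find(g)].append(g)
    models = {m.gene_id: m for m in family_models}
    arrays = []
    ordered = sorted(comps.values(),
                     key=lambda ms: (models[ms[0]].chromosome,
                                     min(models[g].start for g in ms)))
    for k, member_ids in enumerate(ordered, 1):
        member_ids.sort(key=lambda g: models[g].start)
        first = models[member_ids[0]]
        idents = {(p.gene_a, p.gene_b): p.identity_pct for p in pairs
                  if p.gene_a in member_ids and p.gene_b in member_ids}
        arrays.append(TandemArray(
            array_id=f"array_{k}", chromosome=first.chromosome,
            strand=first.strand, member_gene_ids=member_ids,
            pairwise_identities=idents))
    return arrays


def find_identical_duplicates(proteins_by_subfamily:
                              Mapping[str, Sequence[SequenceRecord]]
                              ) -> dict[str, list[tuple[str, str]]]:
    """Character-identical protein pairs within each sub-family."""
    out: dict[str, list[tuple[str, str]]] = {}
    for subfamily, records in proteins_by_subfamily.items():
        groups: dict[str, list[str]] = defaultdict(list)
        for r in records:
            groups[r.sequence].append(r.id)
        pairs = []
        for ids in groups.values():
            ids.sort()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((ids[i], ids[j]))
        if pairs:
            out[subfamily] = sorted(pairs)
    return out


# ---------------------------------------------------------------------------
# Orthology and synteny
# ---------------------------------------------------------------------------

@dataclass
class OrthologPair:
    """Top-hit ortholog of one family gene in a progenitor CDS set.

    Construction enforces the reporting thresholds (protocol defaults
    e <= 1e-10 and bit >= 150; pass ``e_max``/``bit_min`` to relax).
    """

    query_gene: str
    subject_gene: str
    subject_species: str
    identity_pct: float
    bit_score: float
    e_value: float
    query_chromosome: str | None = None
    subject_chromosome: str | None = None
    syntenic: bool = False
    e_max: InitVar[float] = 1e-10
    bit_min: InitVar[float] = 150.0

    def __post_init__(self, e_max: float, bit_min: float) -> None:
        if self.e_value > e_max or self.bit_score < bit_min:
            raise ValueError(
                f"ortholog pair must pass e<={e_max:g}, bit>={bit_min:g}")


def find_orthologs(query_cds: Sequence[SequenceRecord],
                   subject_cds: Sequence[SequenceRecord],
                   e_max: float = 1e-10, bit_min: float = 150.0,
                   subject_species: str = "progenitor",
                   query_chromosomes: Mapping[str, str] | None = None,
                   subject_chromosomes: Mapping[str, str] | None = None,
                   ) -> list[OrthologPair]:
    """Per query, the best-bit-score subject passing both thresholds.

    Ties on bit score break by lower e-value, then lexical subject id.
    Queries whose best hit misses either threshold get no ortholog.
    """
    db_len = sum(len(s) for s in subject_cds)
    out: list[OrthologPair] = []
    for q in query_cds:
        best: AlignmentResult | None = None
        for s in subject_cds:
            aln = smith_waterman(q, s, search_space=len(q) * db_len)
            if (best is None
                    or (aln.bit_score, -aln.e_value, s.id)
                    > (best.bit_score, -best.e_value, best.subject_id)):
                best = aln
        if best is None or best.e_value > e_max or best.bit_score < bit_min:
            continue
        out.append(OrthologPair(
            query_gene=q.id, subject_gene=best.subject_id,
            subject_species=subject_species,
            identity_pct=best.identity_pct, bit_score=best.bit_score,
            e_value=best.e_value,
            query_chromosome=(query_chromosomes or {}).get(q.id),
            subject_chromosome=(subject_chromosomes or {}).get(best.subject_id),
            e_max=e_max, bit_min=bit_min))
    return out


def synteny_fraction(pairs: Sequence[OrthologPair],
                     chromosome_map: Mapping[str, str],
                     family_chromosomes: Mapping[str, str]
                     ) -> dict[str, float]:
    """Fraction of each chromosome's family genes with a syntenic ortholog.

    ``chromosome_map`` maps a family chromosome to its corresponding
    progenitor chromosome (e.g. ``7A -> 7``); chromosomes missing from
    the map count as non-syntenic (logged). The flag is also written back
    onto the pairs.
    """
    totals: dict[str, int] = defaultdict(int)
    for chrom in family_chromosomes.values():
        totals[chrom] += 1
    syntenic: dict[str, int] = defaultdict(int)
    for p in pairs:
        qchrom = p.query_chromosome or family_chromosomes.get(p.query_gene)
        if qchrom is None:
            continue
        expected = chromosome_map.get(qchrom)
        if expected is None:
            logger.warning("chromosome %s absent from correspondence map; "
                           "ortholog of %s counted non-syntenic",
                           qchrom, p.query_gene)
            p.syntenic = False
            continue
        p.syntenic = (p.subject_chromosome == expected)
        if p.syntenic:
            syntenic[qchrom] += 1
    return {chrom: syntenic[chrom] / n
            for chrom, n in sorted(totals.items()) if n > 0}


def find_homeologs(cds_by_subgenome: Mapping[str, Sequence[SequenceRecord]],
                   e_max: float = 1e-10, bit_min: float = 150.0
                   ) -> list[OrthologPair]:
    """Exploratory cross-sub-genome copy detection via the ortholog
    machinery: top hits of each sub-genome's CDS against the others."""
    out: list[OrthologPair] = []
    for sg, queries in sorted(cds_by_subgenome.items()):
        subjects = [r for other, recs in sorted(cds_by_subgenome.items())
                    if other != sg for r in recs]
        if subjects:
            out.extend(find_orthologs(queries, subjects, e_max, bit_min,
                                      subject_species=f"subgenome-not-{sg}"))
    return out
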