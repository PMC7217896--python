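"""Tandem rule strictness, array chaining, orthology and synteny."""

import numpy as np
import pytest

from hspscan.duplication_orthology import (OrthologPair, TandemPair,
                                           chain_arrays,
                                           find_identical_duplicates,
                                           find_orthologs,
                                           find_tandem_duplications,
                                           synteny_fraction)
from hspscan.io_formats import AMINO_ACIDS, GeneModel, SequenceRecord


def _models_on_chrom(spec):
    """spec: list of (gene_id, strand, is_family). Genes every 5 kb."""
    models = []
    for i, (gid, strand, _fam) in enumerate(spec):
        start = 1000 + i * 5000
        models.append(GeneModel(gid, "1A", start, start + 2000, strand))
    family = [m for m, (_g, _s, fam) in zip(models, spec) if fam]
    return family, models


def test_adjacent_similar_pair_detected():
    family, models = _models_on_chrom(
        [("f1", "+", True), ("f2", "+", True)])
    proteins = {"f1": SequenceRecord("f1", "MKVLHEWDNATQRCMKVLHEWDNATQRC"),
                "f2": SequenceRecord("f2", "MKVLHEWDNATQRCMKVLHEWDNATQRC")}
    pairs, arrays = find_tandem_duplications(family, models, proteins)
    assert len(pairs) == 1 and pairs[0].intervening_genes == 0
    assert arrays[0].member_gene_ids == ["f1", "f2"]


def test_identity_exactly_40_percent_excluded():
    family, models = _models_on_chrom([("f1", "+", True), ("f2", "+", True)])
    proteins = {"f1": SequenceRecord("f1", "X"), "f2": SequenceRecord("f2", "X")}
    pairs, _ = find_tandem_duplications(
        family, models, proteins, identity_fn=lambda a, b: 40.0)
    assert pairs == []
    pairs, _ = find_tandem_duplications(
        family, models, proteins, identity_fn=lambda a, b: 40.0001)
    assert len(pairs) == 1


def test_exactly_five_intervening_genes_excluded():
    # f1, five decoys, f2: 5 intervening genes -> excluded (strict)
    spec = [("f1", "+", True)] + [(f"d{i}", "+", False) for i in range(5)] \
        + [("f2", "+", True)]
    family, models = _models_on_chrom(spec)
    proteins = {g: SequenceRecord(g, "MKVLHEWDNATQRC") for g in ("f1", "f2")}
    pairs, _ = find_tandem_duplications(family, models, proteins,
                                        identity_fn=lambda a, b: 99.0)
    assert pairs == []
    # four intervening genes -> detected
    spec = [("f1", "+", True)] + [(f"d{i}", "+", False) for i in range(4)] \
        + [("f2", "+", True)]
    family, models = _models_on_chrom(spec)
    pairs, _ = find_tandem_duplications(family, models, proteins,
                                        identity_fn=lambda a, b: 99.0)
    assert len(pairs) == 1 and pairs[0].intervening_genes == 4


def test_opposite_strand_pair_excluded():
    family, models = _models_on_chrom([("f1", "+", True), ("f2", "-", True)])
    proteins = {g: SequenceRecord(g, "MKVLHEWDNATQRC") for g in ("f1", "f2")}
    pairs, _ = find_tandem_duplications(family, models, proteins,
                                        identity_fn=lambda a, b: 99.0)
    assert pairs == []


def test_missing_protein_raises():
    family, models = _models_on_chrom([("f1", "+", True), ("f2", "+", True)])
    with pytest.raises(KeyError, match="f2"):
        find_tandem_duplications(family, models,
                                 {"f1": SequenceRecord("f1", "MKV")})


def test_array_chaining_is_connected_components():
    models = [GeneModel(g, "1A", 100 * i + 1, 100 * i + 50, "+")
              for i, g in enumerate(["a", "b", "c", "x", "y"])]
    pairs = [TandemPair("a", "b", "1A", "+", 90.0, 0),
             TandemPair("b", "c", "1A", "+", 88.0, 1),
             TandemPair("x", "y", "1A", "+", 70.0, 0)]
    arrays = chain_arrays(pairs, models)
    members = sorted(tuple(a.member_gene_ids) for a in arrays)
    assert members == [("a", "b", "c"), ("x", "y")]


def test_identical_duplicates_exact_equality_only():
    rng = np.random.default_rng(4)
    seq = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 500))
    near = "A" + seq[1:] if seq[0] != "A" else "C" + seq[1:]
    groups = {"SHSP": [SequenceRecord("a", seq), SequenceRecord("b", seq),
                       SequenceRecord("c", near)]}
    found = find_identical_duplicates(groups)
    assert found == {"SHSP": [("a", "b")]}


def test_identical_duplicates_independent_of_position():
    """Identical copies far apart are identical duplicates but not tandem."""
    spec = [("f1", "+", True)] + [(f"d{i}", "+", False) for i in range(8)] \
        + [("f2", "+", True)]
    family, models = _models_on_chrom(spec)
    seq = "MKVLHEWDNATQRCMKVLHEWDNATQRC"
    proteins = {g: SequenceRecord(g, seq) for g in ("f1", "f2")}
    pairs, _ = find_tandem_duplications(family, models, proteins)
    assert pairs == []                             # 8 intervening genes
    dup = find_identical_duplicates(
        {"SHSP": [proteins["f1"], proteins["f2"]]})
    assert dup["SHSP"] == [("f1", "f2")]


def test_planted_identical_duplicates_recovered(small_bundle):
    truth_arrays = small_bundle.truth.arrays()
    prot = {p.id: p for p in small_bundle.proteins}
    by_sf = {}
    for g, r in small_bundle.truth.records.items():
        if r.is_family_member:
            by_sf.setdefault(r.subfamily, []).append(prot[g])
    found = find_identical_duplicates(by_sf)
    found_pairs = {p for pairs in found.values() for p in pairs}
    # the first two members of every planted array are byte-identical
    for members in truth_arrays.values():
        models = {m.gene_id: m for m in small_bundle.models}
        ordered = sorted(members, key=lambda g: models[g].start)
        pair = tuple(sorted(ordered[:2]))
        assert pair in found_pairs


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------

def _nt(rng, n):
    return "".join("ACGT"[k] for k in rng.integers(0, 4, n))


def test_identical_cds_is_top_hit_with_full_identity():
    rng = np.random.default_rng(6)
    seqs = [SequenceRecord(f"s{i}", _nt(rng, 400), "nt") for i in range(3)]
    query = SequenceRecord("q", seqs[1].sequence, "nt")
    pairs = find_orthologs([query], seqs)
    assert len(pairs) == 1
    assert pairs[0].subject_gene == "s1"
    assert pairs[0].identity_pct == 100.0


def test_sub_threshold_hits_rejected():
    rng = np.random.default_rng(7)
    # short identical CDS: passes e-value scale but cannot reach bit 150
    short = _nt(rng, 60)
    query = SequenceRecord("q", short, "nt")
    subject = SequenceRecord("s", short, "nt")
    assert find_orthologs([query], [subject], bit_min=150.0) in ([],)
    assert len(find_orthologs([query], [subject], bit_min=50.0)) == 1


def test_ortholog_pair_invariant_enforced():
    with pytest.raises(ValueError):
        OrthologPair("q", "s", "sp", 99.0, bit_score=149.0, e_value=1e-20)
    with pytest.raises(ValueError):
        OrthologPair("q", "s", "sp", 99.0, bit_score=200.0, e_value=1e-5)


def test_synteny_translocation_fixture():
    """10 genes on 3A; orthologs of 2 lie on progenitor chromosome 5."""
    fam_chrom = {f"g{i}": "3A" for i in range(10)}
    pairs = []
    for i in range(10):
        subject_chrom = "5" if i < 2 else "3"
        pairs.append(OrthologPair(
            f"g{i}", f"p{i}", "progenitor", 95.0, 500.0, 1e-50,
            query_chromosome="3A", subject_chromosome=subject_chrom))
    fractions = synteny_fraction(pairs, {"3A": "3"}, fam_chrom)
    assert fractions == {"3A": 0.8}


def test_synteny_all_or_nothing():
    fam_chrom = {"a": "1A", "b": "1A", "c": "2A"}
    mk = lambda g, qc, sc: OrthologPair(g, "p_" + g, "x", 99.0, 300.0, 1e-40,
                                        query_chromosome=qc,
                                        subject_chromosome=sc)
    pairs = [mk("a", "1A", "1"), mk("b", "1A", "1")]
    fr = synteny_fraction(pairs, {"1A": "1", "2A": "2"}, fam_chrom)
    assert fr["1A"] == 1.0 and fr["2A"] == 0.0


def test_unmapped_chromosome_counts_non_syntenic():
    fam_chrom = {"a": "9Z"}
    pair = OrthologPair("a", "p", "x", 99.0, 300.0, 1e-40,
                        query_chromosome="9Z", subject_chromosome="9")
    fr = synteny_fraction([pair], {"1A": "1"}, fam_chrom)
    assert fr == {"9Z": 0.0} and pair.syntenic is False
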