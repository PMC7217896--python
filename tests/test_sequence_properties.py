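"""Molecular weight, isoelectric point and promoter motif scanning."""

import numpy as np
import pytest

from oracles import grid_pi, naive_motif_count

from hspscan.io_formats import AMINO_ACIDS, SequenceRecord, reverse_complement
from hspscan.sequence_properties import (DEFAULT_CARE_MOTIFS, PKA_TABLES,
                                         CareMotif, isoelectric_point,
                                         molecular_weight, net_charge,
                                         scan_cares, summarize_cares)


def _random_peptide(rng, n):
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, n))


# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

def test_molecular_weight_glycine_examples():
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)
    assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)


def test_molecular_weight_additivity_and_permutation():
    a, b = "MKVLH", "EWDNA"
    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - 18.0153, abs=1e-6)
    assert molecular_weight("KVMHL") == pytest.approx(molecular_weight(a))
    with pytest.raises(ValueError):
        molecular_weight("")


def test_molecular_weight_matches_biopython():
    from Bio.SeqUtils import molecular_weight as bp_mw
    rng = np.random.default_rng(41)
    for _ in range(25):
        pep = _random_peptide(rng, int(rng.integers(5, 120)))
        # Biopython derives masses from a slightly different atomic table;
        # agreement is to ~1e-5 relative
        assert molecular_weight(pep) == pytest.approx(
            bp_mw(pep, seq_type="protein", monoisotopic=False), rel=1e-4)


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table", ["ipc", "emboss"])
def test_gg_two_group_closed_form(table):
    pka = PKA_TABLES[table]
    expected = (pka["Nterm"] + pka["Cterm"]) / 2.0
    assert isoelectric_point("GG", table) == pytest.approx(expected, abs=1e-3)


def test_charge_shifts_monotone():
    base = "MKVLHEWDNA"
    assert isoelectric_point(base + "K") > isoelectric_point(base)
    assert isoelectric_point(base + "D") < isoelectric_point(base)


def test_charge_strictly_decreasing_in_ph():
    rng = np.random.default_rng(43)
    for _ in range(10):
        pep = _random_peptide(rng, 30)
        charges = [net_charge(pep, ph) for ph in np.linspace(0, 14, 60)]
        assert all(a > b for a, b in zip(charges, charges[1:]))


def test_bisection_matches_grid_oracle_and_charge_vanishes():
    rng = np.random.default_rng(47)
    worst = 0.0
    for _ in range(200):
        pep = _random_peptide(rng, int(rng.integers(5, 60)))
        pi = isoelectric_point(pep)
        assert abs(net_charge(pep, pi)) < 1e-4
        worst = max(worst, abs(pi - grid_pi(pep)))
    assert worst <= 0.01


# ---------------------------------------------------------------------------
# CARE scanning
# ---------------------------------------------------------------------------

def test_iupac_expansion_single_hit():
    motif = CareMotif("MYC", "CANNTG", "TF-binding")
    assert scan_cares("ACAGGTGA", [motif])["MYC"] == 1


def test_overlapping_occurrences_counted():
    motif = CareMotif("t", "TATA", "other")
    assert scan_cares("TATATA", [motif], both_strands=False)["t"] == 2


def test_illegal_iupac_symbol_rejected_at_load():
    with pytest.raises(ValueError, match="illegal"):
        CareMotif("bad", "ACGJ", "other")
    with pytest.raises(ValueError, match="category"):
        CareMotif("bad", "ACGT", "nonsense")


def test_counts_match_naive_oracle_both_strands():
    rng = np.random.default_rng(51)
    for _ in range(10):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 600))
        counts = scan_cares(seq, DEFAULT_CARE_MOTIFS)
        for motif in DEFAULT_CARE_MOTIFS:
            assert counts[motif.name] == naive_motif_count(seq, motif.pattern)


def test_strand_consistency():
    rng = np.random.default_rng(53)
    seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 800))
    a = scan_cares(seq, DEFAULT_CARE_MOTIFS)
    b = scan_cares(reverse_complement(seq), DEFAULT_CARE_MOTIFS)
    assert a == b


def test_summary_set_identities():
    per_gene = {"g1": {"HSE": 2, "MYC": 0, "TATA-box": 1},
                "g2": {"HSE": 0, "MYC": 3, "TATA-box": 0},
                "g3": {"HSE": 0, "MYC": 0, "TATA-box": 0}}
    fams = {"g1": "SHSP", "g2": "HSP70", "g3": "HSP70"}
    summary = summarize_cares(per_gene, fams)
    assert summary.unique_motif_count == {"SHSP": 2, "HSP70": 1}
    # union over sub-families equals the family-wide unique count
    union = (summary.counts > 0).any(axis=0).sum()
    assert summary.family_unique_count == union == 3
    # motif present in no promoter is excluded everywhere
    assert "GT1" not in summary.counts.columns or \
        summary.counts["GT1"].sum() == 0


def test_missing_promoter_scan_rejected():
    with pytest.raises(KeyError, match="g2"):
        summarize_cares({"g1": {"HSE": 1}}, {"g1": "SHSP", "g2": "SHSP"})
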