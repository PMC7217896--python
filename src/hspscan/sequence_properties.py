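"""Physico-chemical characterization and promoter cis-element scanning.

Molecular weight is the sum of average-isotopic residue masses plus one
water. The isoelectric point is the unique root of the
Henderson-Hasselbalch net-charge curve on pH 0-14, found by bisection;
the pKa set is explicit configuration (an IPC-style protein table by
default, EMBOSS values as the alternative) because web pI calculators are
not bit-reproducible.

CARE (cis-acting regulatory element) scanning counts every, possibly
overlapping, occurrence of an IUPAC-degenerate motif on the promoter,
by default on both strands; self-reverse-complementary (palindromic)
patterns are counted once per position.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import SequenceRecord, logger

# average isotopic residue masses (Da); free water added once per chain
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
#: mass contributed by an X (unknown) residue: the unweighted average
X_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: IPC-style protein pKa set (default) and EMBOSS values (alternative)
PKA_TABLES: dict[str, dict[str, float]] = {
    "ipc": {"Nterm": 9.094, "Cterm": 2.869, "C": 7.555, "D": 3.872,
            "E": 4.412, "H": 5.637, "K": 9.052, "R": 11.84, "Y": 10.85},
    "emboss": {"Nterm": 8.6, "Cterm": 3.6, "C": 8.5, "D": 3.9,
               "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1},
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


@dataclass
class PhyschemRecord:
    gene_id: str
    molecular_weight: float
    isoelectric_point: float
    length: int

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if not 0 < self.isoelectric_point < 14:
            raise ValueError("pI must lie in (0, 14)")


def molecular_weight(seq: str, x_mass: float = X_MASS) -> float:
    """Average-isotopic molecular weight of a peptide in Da."""
    if not seq:
        raise ValueError("cannot compute mass of an empty sequence")
    total = WATER_MASS
    for ch in seq.upper():
        if ch == "X":
            total += x_mass
        elif ch in RESIDUE_MASS:
            total += RESIDUE_MASS[ch]
        elif ch == "*":
            continue
        else:
            raise ValueError(f"unknown residue {ch!r}")
    return total


def net_charge(seq: str, pH: float,
               pka_table: Mapping[str, float] | str = "ipc",
               include_termini: bool = True) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Positive groups (N-terminus, H, K, R) contribute
    ``1 / (1 + 10^(pH - pKa))``; negative groups (C-terminus, D, E, C, Y)
    contribute ``-1 / (1 + 10^(pKa - pH))``. Strictly decreasing in pH.
    """
    if isinstance(pka_table, str):
        pka_table = PKA_TABLES[pka_table]
    seq = seq.upper()
    charge = 0.0
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka_table["Nterm"]))
        charge -= 1.0 / (1.0 + 10.0 ** (pka_table["Cterm"] - pH))
    pos = {"H", "K", "R"}
    neg = {"D", "E", "C", "Y"}
    counted = include_termini
    for ch in set(seq):
        n = seq.count(ch)
        if ch in pos and ch in pka_table:
            charge += n / (1.0 + 10.0 ** (pH - pka_table[ch]))
            counted = True
        elif ch in neg and ch in pka_table:
            charge -= n / (1.0 + 10.0 ** (pka_table[ch] - pH))
            counted = True
    if not counted:
        raise ValueError("sequence has no ionizable groups under this model")
    return charge


def isoelectric_point(seq: str,
                      pka_table: Mapping[str, float] | str = "ipc",
                      include_termini: bool = True,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge curve is strictly decreasing, so the root is unique.
    Bisection narrows the bracket below 1e-6 pH units (the curve can be
    nearly flat around neutral peptides, so converging the charge alone
    would not localise the root); the returned pH satisfies
    ``|charge| < tol``.
    """
    if not seq:
        raise ValueError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pka_table, include_termini)
    c_hi = net_charge(seq, hi, pka_table, include_termini)
    if c_lo < 0:
        return lo
    if c_hi > 0:
        return hi
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_table, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2.0
    if abs(net_charge(seq, mid, pka_table, include_termini)) >= tol:
        raise ArithmeticError("charge did not vanish at the bisection root")
    return mid


def physchem_table(proteins: Sequence[SequenceRecord],
                   pka_table: Mapping[str, float] | str = "ipc"
                   ) -> list[PhyschemRecord]:
    return [PhyschemRecord(p.id, molecular_weight(p.sequence),
                           isoelectric_point(p.sequence, pka_table),
                           len(p.sequence)) for p in proteins]


# ---------------------------------------------------------------------------
# CARE motifs
# ---------------------------------------------------------------------------

CARE_CATEGORIES = ("stress", "TF-binding", "light", "hormone",
                   "tissue-specific", "polyadenylation", "other")


@dataclass(frozen=True)
class CareMotif:
    """A named IUPAC promoter motif with a functional category."""

    name: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {self.name}: illegal IUPAC symbol {bad}")
        if self.category not in CARE_CATEGORIES:
            raise ValueError(f"motif {self.name}: unknown category "
                             f"{self.category!r}")

    @property
    def regex(self) -> re.Pattern:
        expanded = "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c]
                           for c in self.pattern.upper())
        return re.compile(f"(?=({expanded}))")

    @property
    def is_palindromic(self) -> bool:
        return self.pattern.upper() == reverse_complement_iupac(self.pattern)


def reverse_complement_iupac(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


#: Bundled PLACE-style motif catalogue (classical plant promoter elements).
DEFAULT_CARE_MOTIFS: tuple[CareMotif, ...] = (
    CareMotif("HSE", "NGAANNTTCN", "stress"),
    CareMotif("W-box", "TTGACC", "stress"),
    CareMotif("STRE", "AGGGG", "stress"),
    CareMotif("DRE-CRT", "RCCGAC", "stress"),
    CareMotif("LTRE", "CCGAAA", "stress"),
    CareMotif("MYB", "WAACCA", "TF-binding"),
    CareMotif("MYC", "CANNTG", "TF-binding"),
    CareMotif("bZIP-Gbox", "CACGTG", "TF-binding"),
    CareMotif("GT1", "GRWAAW", "light"),
    CareMotif("I-box", "GATAAG", "light"),
    CareMotif("circadian", "CAANNNNATC", "light"),
    CareMotif("ABRE", "ACGTGKC", "hormone"),
    CareMotif("GARE", "TAACAAR", "hormone"),
    CareMotif("ERE", "AWTTCAAA", "hormone"),
    CareMotif("SKn-1", "GTCAT", "tissue-specific"),
    CareMotif("RY-seed", "CATGCA", "tissue-specific"),
    CareMotif("root-OSE", "AAAGAT", "tissue-specific"),
    CareMotif("polyA-signal", "AATAAA", "polyadenylation"),
    CareMotif("TATA-box", "TATAAA", "other"),
    CareMotif("CAAT-box", "CCAAT", "other"),
)


def load_care_motifs(path) -> list[CareMotif]:
    """Read a motif catalogue TSV (name, pattern, category)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [CareMotif(str(r["name"]), str(r["pattern"]), str(r["category"]))
            for _, r in df.iterrows()]


def write_care_motifs(motifs: Sequence[CareMotif], path) -> None:
    pd.DataFrame([{"name": m.name, "pattern": m.pattern,
                   "category": m.category} for m in motifs]
                 ).to_csv(path, sep="\t", index=False)


def scan_cares(promoter: SequenceRecord | str,
               motifs: Sequence[CareMotif] = DEFAULT_CARE_MOTIFS,
               both_strands: bool = True) -> dict[str, int]:
    """Count overlapping occurrences of each motif on a promoter.

    Reverse-strand occurrences are found by matching the motif's IUPAC
    reverse complement on the forward sequence, which preserves genomic
    positions; palindromic motifs are scanned forward only so each
    position is counted once.
    """
    seq = promoter.sequence if isinstance(promoter, SequenceRecord) else promoter
    seq = seq.upper()
    counts: dict[str, int] = {}
    for motif in motifs:
        n = len(motif.regex.findall(seq))
        if both_strands and not motif.is_palindromic:
            rc = CareMotif(motif.name, reverse_complement_iupac(motif.pattern),
                           motif.category)
            n += len(rc.regex.findall(seq))
        counts[motif.name] = n
    return counts


@dataclass
class CareHitSummary:
    """Per-sub-family motif occurrence totals and unique-motif counts."""

    counts: pd.DataFrame            # subfamily x motif occurrence totals
    unique_motif_count: dict[str, int]
    family_unique_count: int
    top_motifs: pd.DataFrame        # per category, most frequent motifs


def summarize_cares(per_gene_counts: Mapping[str, Mapping[str, int]],
                    gene_subfamilies: Mapping[str, str],
                    motifs: Sequence[CareMotif] = DEFAULT_CARE_MOTIFS,
                    top_k: int = 5) -> CareHitSummary:
    """Aggregate per-promoter motif counts into the sub-family summary."""
    missing = [g for g in gene_subfamilies if g not in per_gene_counts]
    if missing:
        raise KeyError(f"family genes without a promoter scan: {missing}")
    totals: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for gene, counts in per_gene_counts.items():
        subfamily = gene_subfamilies.get(gene)
        if subfamily is None:
            continue
        for motif, n in counts.items():
            totals[subfamily][motif] += n
    names = [m.name for m in motifs]
    table = pd.DataFrame(
        {m: {sf: totals[sf].get(m, 0) for sf in sorted(totals)} for m in names}
    ).fillna(0).astype(int)
    unique = {sf: int((table.loc[sf] > 0).sum()) for sf in table.index}
    family_unique = int((table.sum(axis=0) > 0).sum())
    cat = {m.name: m.category for m in motifs}
    rows = []
    grand = table.sum(axis=0)
    for category in CARE_CATEGORIES:
        members = [n for n in names if cat[n] == category]
        ranked = sorted(members, key=lambda n: (-grand.get(n, 0), n))[:top_k]
        for n in ranked:
            if grand.get(n, 0) > 0:
                rows.append({"category": category, "motif": n,
                             "total_occurrences": int(grand[n])})
    return CareHitSummary(counts=table, unique_motif_count=unique,
                          family_unique_count=family_unique,
                          top_motifs=pd.DataFrame(rows))
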