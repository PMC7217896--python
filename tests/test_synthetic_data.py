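"""Generator determinism, planted-feature guarantees and primitives."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hspscan.domain_models import DOMAIN_CONSENSUS
from hspscan.sequence_search import build_pssm, scan_profile
from hspscan.domain_models import DOMAIN_ALIGNMENTS
from hspscan.io_formats import SequenceRecord
from hspscan.synthetic_data import (AA, NT, LayoutError, SyntheticConfig,
                                    generate_dataset, mutate_sequence)

TINY = dict(n_chromosomes=2, chromosome_length=250_000, n_family_genes=12,
            n_decoy_genes=30, tandem_array_sizes=[2], seed=5)


def _dir_hash(path):
    out = {}
    for p in sorted(path.iterdir()):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_dataset(SyntheticConfig(**TINY), a)
    generate_dataset(SyntheticConfig(**TINY), b)
    assert _dir_hash(a) == _dir_hash(b)


def test_truth_gff_and_fasta_agree(tmp_path):
    bundle = generate_dataset(SyntheticConfig(**TINY))
    genes = set(bundle.truth.records)
    assert {m.gene_id for m in bundle.models} == genes
    assert {p.id for p in bundle.proteins} == genes
    assert {c.id for c in bundle.cds} == genes
    assert set(bundle.tpm.gene_ids) == genes


def test_zero_pseudogene_fraction_forces_expressed_rows():
    cfg = SyntheticConfig(**{**TINY, "pseudogene_fraction": 0.0})
    bundle = generate_dataset(cfg)
    assert bundle.truth.pseudogene_ids() == []
    assert (bundle.tpm.values.sum(axis=1) >= 1.0).all()


def test_pseudogene_rows_sum_below_one():
    bundle = generate_dataset(SyntheticConfig(**TINY, ))
    sums = dict(zip(bundle.tpm.gene_ids, bundle.tpm.values.sum(axis=1)))
    for g, r in bundle.truth.records.items():
        if r.is_pseudogene:
            assert sums[g] < 1.0
        else:
            assert sums[g] >= 1.0


def test_planted_domains_match_subfamily():
    bundle = generate_dataset(SyntheticConfig(**TINY))
    from hspscan.domain_models import SUBFAMILY_DOMAINS
    for r in bundle.truth.records.values():
        if r.is_family_member:
            assert r.planted_domains == SUBFAMILY_DOMAINS[r.subfamily]
        else:
            assert r.planted_domains == []


def test_impossible_layout_fails_cleanly(tmp_path):
    cfg = SyntheticConfig(**{**TINY, "chromosome_length": 20_000})
    outdir = tmp_path / "never"
    with pytest.raises(LayoutError):
        generate_dataset(cfg, outdir)
    assert not outdir.exists()                     # no partial files


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticConfig(subfamily_mix={"SHSP": 0.5}).validate()
    with pytest.raises(ValueError, match="2..7"):
        SyntheticConfig(tandem_array_sizes=[8]).validate()
    with pytest.raises(ValueError, match="domain_divergence"):
        SyntheticConfig(domain_divergence=0.9).validate()


def test_zero_divergence_domain_attains_profile_maximum():
    cfg = SyntheticConfig(**{**TINY, "domain_divergence": 0.0})
    bundle = generate_dataset(cfg)
    profiles = {d: build_pssm(rows, domain_id=d)
                for d, rows in DOMAIN_ALIGNMENTS.items()}
    proteins = {p.id: p for p in bundle.proteins}
    checked = 0
    for r in bundle.truth.records.values():
        if not r.is_family_member or len(r.planted_domains) != 1:
            continue
        prof = profiles[r.planted_domains[0]]
        hits = scan_profile(proteins[r.gene_id], prof)
        assert hits and hits[0].raw_score == pytest.approx(prof.max_score())
        checked += 1
    assert checked > 0


# ---------------------------------------------------------------------------
# mutate_sequence
# ---------------------------------------------------------------------------

def test_mutate_rate_zero_and_one():
    seq = "MKVLHEWDNATQRC" * 3
    assert mutate_sequence(seq, 0.0, AA, 1) == seq
    mutated = mutate_sequence(seq, 1.0, AA, 1)
    assert len(mutated) == len(seq)
    assert all(a != b for a, b in zip(seq, mutated))
    assert mutate_sequence("", 0.5, AA, 1) == ""


def test_mutate_observed_fraction_binomial_bound():
    rng = np.random.default_rng(2)
    seq = "".join(NT[k] for k in rng.integers(0, 4, 10_000))
    mutated = mutate_sequence(seq, 0.3, NT, rng)
    frac = sum(a != b for a, b in zip(seq, mutated)) / len(seq)
    sd = (0.3 * 0.7 / len(seq)) ** 0.5
    assert abs(frac - 0.3) < 3 * sd


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet=NT, min_size=0, max_size=200),
       st.floats(min_value=0.0, max_value=1.0),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_mutate_preserves_length_and_alphabet(seq, rate, seed):
    out = mutate_sequence(seq, rate, NT, seed)
    assert len(out) == len(seq)
    assert set(out) <= set(NT)


def test_progenitor_divergence_respected():
    bundle = generate_dataset(SyntheticConfig(**TINY))
    cds = {c.id: c.sequence for c in bundle.cds}
    checked = 0
    for g, r in bundle.truth.records.items():
        if not r.progenitor_ortholog_id:
            continue
        prog = next(p.sequence for p in bundle.progenitor_cds
                    if p.id == r.progenitor_ortholog_id)
        assert len(prog) == len(cds[g])
        frac = sum(a != b for a, b in zip(prog, cds[g])) / len(prog)
        sd = (0.05 * 0.95 / len(prog)) ** 0.5
        assert abs(frac - 0.05) < 4 * sd
        checked += 1
    assert checked > 0
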