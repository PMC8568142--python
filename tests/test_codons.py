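"""Codon extraction, terminal classification, counts, RSCU and presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoprofile as mp
from mitoprofile import datasets
from mitoprofile.utils import round_half_up


def test_extract_codons_and_remnant():
    assert mp.extract_codons("ATGAAATAA") == (["ATG", "AAA", "TAA"], "")
    assert mp.extract_codons("ATGAAAT") == (["ATG", "AAA"], "T")
    with pytest.raises(ValueError):
        mp.extract_codons("AT")


@pytest.mark.parametrize(
    "cds, start, start_class, stop, complete",
    [
        ("ATGAAATAA", "ATG", "ATN", "TAA", True),
        ("TTGAAAAAATAG", "TTG", "nonstandard", "TAG", True),
        ("GTGAAAAAAT", "GTG", "nonstandard", "T", False),
        ("ATTAAAAAATA", "ATT", "ATN", "TA", False),
        ("ATGAAACCC", "ATG", "ATN", "none", False),
    ],
)
def test_classify_terminals(cds, start, start_class, stop, complete):
    rep = mp.classify_terminals("g", cds)
    assert (rep.start_codon, rep.start_class, rep.stop_codon,
            rep.stop_complete) == (start, start_class, stop, complete)


def test_count_codons_example_and_concatenation_invariance():
    counts = mp.counts_as_dict(mp.count_codons(["ATGATGTAA"]))
    assert counts["AUG"] == 2 and counts["UAA"] == 1
    assert sum(counts.values()) == 3
    genes = ["ATGAAATTTTAA", "ATGCCCGGGT", "TTGAAATAG"]
    batch = mp.count_codons(genes)
    summed = sum(mp.count_codons([g]) for g in genes)
    assert (batch == summed).all()


def test_count_codons_matches_naive_triplet_tally(default_genome):
    record, _ = default_genome
    cds_list = [record.extract(f) for f in record.features_of("PCG")]
    counts = mp.counts_as_dict(mp.count_codons(cds_list))
    naive: dict[str, int] = {c: 0 for c in mp.CODONS}
    for cds in cds_list:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            naive[cds[i : i + 3].replace("T", "U")] += 1
    assert counts == naive


counts_vectors = st.lists(st.integers(0, 500), min_size=64, max_size=64)


@given(counts=counts_vectors)
@settings(deadline=None, max_examples=60)
def test_rscu_family_sums_and_means(counts):
    """Within every nonzero family, RSCU sums to the family size (mean 1)."""
    for preset in ("invertebrate-mito", "table3-compat"):
        table = mp.get_table(preset)
        values = mp.rscu(counts, table)
        arr = np.asarray(counts)
        for codons in table.families.values():
            idx = [mp.CODONS.index(c) for c in codons]
            if arr[idx].sum() > 0:
                assert values[idx].sum() == pytest.approx(len(codons))
            else:
                assert (values[idx] == 0).all()


@given(counts=counts_vectors, factor=st.integers(2, 9))
@settings(deadline=None, max_examples=40)
def test_rscu_invariant_under_count_scaling(counts, factor):
    base = mp.rscu(counts, "invertebrate-mito")
    scaled = mp.rscu([c * factor for c in counts], "invertebrate-mito")
    assert np.allclose(base, scaled)


def test_uniform_family_counts_give_rscu_one():
    counts = np.ones(64, dtype=int)
    assert np.allclose(mp.rscu(counts, "table3-compat"), 1.0)


def test_presets_differ_in_family_structure():
    t5 = mp.get_table("invertebrate-mito")
    std = mp.get_table("table3-compat")
    assert t5.amino_acid["UGA"] == "W" and std.amino_acid["UGA"] == "*"
    assert t5.amino_acid["AGA"] == "S" and std.amino_acid["AGA"] == "R"
    assert len(std.families["*"]) == 3 and len(t5.families["*"]) == 2
    for table in (t5, std):
        assert sorted(c for f in table.families.values() for c in f) == sorted(
            mp.CODONS)


def test_published_rscu_reproduced_under_table3_compat_preset():
    """All 64 published RSCU values are recovered to 2 dp from the
    published counts under standard-code families with pooled stops."""
    published = {
        "UUU": 1.68, "UUC": 0.32, "UUA": 3.13, "UUG": 0.35,
        "CUU": 1.45, "CUC": 0.36, "CUA": 0.65, "CUG": 0.06,
        "AUU": 1.60, "AUC": 0.25, "AUA": 1.15, "AUG": 1.00,
        "GUU": 1.82, "GUC": 0.15, "GUA": 1.67, "GUG": 0.36,
        "UCU": 2.46, "UCC": 0.55, "UCA": 1.76, "UCG": 0.23,
        "CCU": 2.71, "CCC": 0.38, "CCA": 0.75, "CCG": 0.16,
        "ACU": 1.95, "ACC": 0.53, "ACA": 1.40, "ACG": 0.11,
        "GCU": 2.14, "GCC": 0.57, "GCA": 1.15, "GCG": 0.14,
        "UAU": 1.57, "UAC": 0.43, "UAA": 0.29, "UAG": 0.03,
        "CAU": 1.47, "CAC": 0.53, "CAA": 1.62, "CAG": 0.38,
        "AAU": 1.65, "AAC": 0.35, "AAA": 1.77, "AAG": 0.23,
        "GAU": 1.51, "GAC": 0.49, "GAA": 1.35, "GAG": 0.65,
        "UGU": 1.56, "UGC": 0.44, "UGA": 2.68, "UGG": 1.00,
        "CGU": 0.40, "CGC": 0.07, "CGA": 1.26, "CGG": 0.36,
        "AGU": 0.86, "AGC": 0.13, "AGA": 3.08, "AGG": 0.83,
        "GGU": 1.06, "GGC": 0.35, "GGA": 1.84, "GGG": 0.75,
    }
    counts = mp.counts_from_dict(datasets.lvittata_codon_counts())
    values = dict(zip(mp.CODONS, mp.rscu(counts, "table3-compat")))
    mismatches = {
        c: (round_half_up(values[c]), published[c])
        for c in published
        if round_half_up(values[c]) != published[c]
    }
    assert mismatches == {}


def test_published_amino_acid_totals():
    counts = mp.counts_from_dict(datasets.lvittata_codon_counts())
    totals = mp.aa_totals(counts, "table3-compat")
    assert totals["I"] == 499
    assert totals["F"] == 357
    assert totals["C"] == 41
    assert totals["M"] == 24
    split = mp.aa_totals(counts, "table3-compat", split_sixfold=True)
    assert split["L2"] == 315  # UUR leucine
    assert split["L1"] + split["L2"] == totals["L"]
    assert mp.aa_totals([0] * 64, "table3-compat") == {
        k: 0 for k in totals
    }


def test_aa_totals_exclude_stop_codons():
    counts = mp.counts_from_dict({"UAA": 5, "AUG": 3})
    totals = mp.aa_totals(counts, "table3-compat")
    assert "*" not in totals
    assert sum(totals.values()) == 3


def test_codon_usage_report_recovers_generator_profile(default_genome):
    record, truth = default_genome
    usage = mp.codon_usage_report(record)
    expect = {c: 0 for c in mp.CODONS} | truth.codon_counts
    assert mp.counts_as_dict(usage.counts) == expect
    assert usage.n_stop_incomplete == 2  # nad4 and nad5 end in bare T
    assert usage.n_stop_complete == 11
    # joint and per-gene total bookkeeping
    total_len = sum(f.length for f in record.features_of("PCG"))
    assert usage.n_codons_joint == total_len // 3
    assert usage.n_codons_total == sum(
        f.length // 3 for f in record.features_of("PCG"))


def test_rscu_unchanged_when_every_gene_is_duplicated(default_genome):
    record, _ = default_genome
    cds_list = [record.extract(f) for f in record.features_of("PCG")]
    once = mp.rscu(mp.count_codons(cds_list), "invertebrate-mito")
    twice = mp.rscu(mp.count_codons(cds_list * 2), "invertebrate-mito")
    assert np.allclose(once, twice)


def test_pcg_matrix_export_trims_stops(tmp_path, default_genome):
    record, _ = default_genome
    nt, aa = tmp_path / "nt.fasta", tmp_path / "aa.fasta"
    mp.export_pcg_matrices(record, nt, aa)
    nt_seq = nt.read_text().splitlines()[1]
    aa_seq = aa.read_text().splitlines()[1]
    assert len(nt_seq) == 3 * len(aa_seq)
    assert "*" not in aa_seq
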