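"""Synthetic-genome generator: determinism, truth recovery, feasibility."""

import math

import numpy as np
import pytest

import mitoprofile as mp
from mitoprofile import datasets
from mitoprofile.synthetic import DEFAULT_PCG_LENGTHS


def test_same_seed_gives_byte_identical_output():
    a, _ = mp.generate(mp.SyntheticSpec(seed=1))
    b, _ = mp.generate(mp.SyntheticSpec(seed=1))
    assert a.sequence == b.sequence
    assert [f.spans for f in a.features] == [f.spans for f in b.features]
    c, _ = mp.generate(mp.SyntheticSpec(seed=2))
    assert c.sequence != a.sequence


def test_default_genome_matches_emulated_conditions(default_genome):
    record, truth = default_genome
    assert len(record.features) == 37
    assert len(record.features_of("PCG")) == 13
    assert len(record.features_of("tRNA")) == 22
    assert len(record.features_of("rRNA")) == 2
    for gene, length in DEFAULT_PCG_LENGTHS.items():
        assert record.feature_by_name(gene).length == length
    strands = {f.name: f.strand for f in record.features}
    assert sum(1 for s in strands.values() if s == "F") == 23
    assert strands["nad5"] == "R" and strands["cox1"] == "F"


def test_exact_internal_codons_recovered_by_count_codons():
    capacity = sum(
        length // 3 - 1 - (1 if gene not in ("nad4", "nad5") else 0)
        for gene, length in DEFAULT_PCG_LENGTHS.items()
    )
    profile = {"AUU": capacity - 100, "GGA": 60, "UUU": 40}
    spec = mp.SyntheticSpec(seed=3, exact_internal_codons=profile)
    record, truth = mp.generate(spec)
    usage = mp.codon_usage_report(record)
    counts = mp.counts_as_dict(usage.counts)
    starts = {}
    for gene, codon in spec.start_codons.items():
        rna = codon.replace("T", "U")
        starts[rna] = starts.get(rna, 0) + 1
    assert counts["GGA"] == 60 + starts.get("GGA", 0)
    assert counts["UUU"] == 40 + starts.get("UUU", 0)
    assert counts["UAA"] == 10  # complete TAA stops
    assert counts["UAG"] == 1   # cox1
    assert counts == {c: 0 for c in mp.CODONS} | truth.codon_counts


def test_realized_at_content_within_analytic_99pct_interval(default_genome):
    """Oracle: the genome is a mixture of independent base draws — filler and
    tRNA/rRNA from the base pool, CRs from their own AT bias, PCG codons from
    the codon profile — so AT count is a sum of independent Bernoullis with
    known mean and variance; the realized AT content must sit inside the
    normal-approximation 99% interval."""
    record, truth = default_genome
    spec = truth.spec
    p_pool = spec.base_freq[0] + spec.base_freq[1]

    n_random = sum(
        f.length for f in record.features if f.category in ("tRNA", "rRNA"))
    n_random += sum(n for _, _, n in truth.spacers)
    n_random -= sum(  # overlap bases were emitted once, by the upstream gene
        k for _, _, k in truth.overlaps)
    mean = n_random * p_pool
    var = n_random * p_pool * (1 - p_pool)
    for cr in truth.cr_regions:
        mean += cr["length_bp"] * cr["at_bias"]
        var += cr["length_bp"] * cr["at_bias"] * (1 - cr["at_bias"])
    # PCG codons: expected AT per codon under the sampling profile
    from mitoprofile.synthetic import _default_codon_profile

    profile = _default_codon_profile(mp.get_table(spec.codon_table))
    at_per_codon = np.array(
        [c.count("U") + c.count("A") for c in mp.CODONS], dtype=float)
    mu_c = float(profile @ at_per_codon)
    var_c = float(profile @ (at_per_codon - mu_c) ** 2)
    n_internal = sum(
        truth.codon_counts.values()) - 13 - 11  # minus starts and stops
    mean += n_internal * mu_c + sum(
        (c.replace("T", "U").count("U") + c.count("A"))
        for c in list(spec.start_codons.values())
        + [s for s in spec.stop_codons.values() if len(s) == 3]
    )
    mean += sum(len(s) for s in spec.stop_codons.values() if len(s) < 3)
    var += n_internal * var_c

    observed = record.sequence.count("A") + record.sequence.count("T")
    z = (observed - mean) / math.sqrt(var)
    assert abs(z) < 2.58


def test_full_pipeline_truth_recovery(default_genome):
    record, truth = default_genome
    assert mp.counts_as_dict(
        mp.codon_usage_report(record).counts
    ) == {c: 0 for c in mp.CODONS} | truth.codon_counts
    assert mp.linearize_gene_order(record, "cox1").genes == truth.gene_order.genes
    crs = mp.detect_control_regions(record, 200)
    assert [(c["start"], c["end"]) for c in crs] == [
        (c["start"], c["end"]) for c in truth.cr_regions]
    for gene, info in truth.terminals.items():
        rep = mp.classify_terminals(gene, record.extract(
            record.feature_by_name(gene)))
        assert rep.start_codon == info["start_codon"]
        assert rep.stop_codon == info["stop_codon"]
        assert rep.stop_complete == info["stop_complete"]


def test_infeasible_plans_rejected_before_sampling():
    with pytest.raises(mp.InfeasiblePlan, match="PCG"):
        mp.generate(mp.SyntheticSpec(
            seed=0, overlap_plan=(("trnD", "atp8", 4),)))
    with pytest.raises(mp.InfeasiblePlan, match="not adjacent"):
        mp.generate(mp.SyntheticSpec(
            seed=0, overlap_plan=(("cox1", "trnK", 2),)))
    with pytest.raises(mp.InfeasiblePlan, match="length target"):
        mp.generate(mp.SyntheticSpec(seed=0, length_target=5000))
    with pytest.raises(mp.InfeasiblePlan, match="inconsistent with stop"):
        mp.generate(mp.SyntheticSpec(
            seed=0, pcg_lengths={**DEFAULT_PCG_LENGTHS, "atp6": 676}))
    with pytest.raises(mp.InfeasiblePlan, match="stop"):
        mp.generate(mp.SyntheticSpec(seed=0, codon_profile={"UAA": 1.0}))


def test_length_target_pads_genome():
    spec = mp.SyntheticSpec(seed=4, length_target=25000)
    record, truth = mp.generate(spec)
    assert record.length == 25000


def test_perturb_zero_moves_identity():
    ref = datasets.ancestral_gene_order()
    assert mp.perturb_order(ref, []).genes == ref.genes


def test_perturb_single_move_detected_exactly():
    ref = datasets.ancestral_gene_order()
    qry = mp.perturb_order(ref, [("trnA", "cob")])
    rep = mp.compare_gene_orders(qry, ref)
    assert rep.moved_genes == frozenset({"trnA"})


def test_perturb_absent_token_error():
    ref = datasets.ancestral_gene_order()
    with pytest.raises(ValueError, match="absent"):
        mp.perturb_order(ref, [("nope", "cob")])


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_three_sampled_noninteracting_moves_detected_exactly(seed):
    """Brute-force non-interaction check: applying the three sampled moves in
    every order yields the same arrangement, and the comparison then reports
    exactly those three genes as moved."""
    import itertools

    ref = datasets.ancestral_gene_order().rotated_to("cox1")
    moves = mp.sample_moves(ref, k=3, seed=seed)
    results = {
        str(mp.perturb_order(ref, list(perm)))
        for perm in itertools.permutations(moves)
    }
    assert len(results) == 1  # moves do not interact
    qry = mp.perturb_order(ref, moves)
    rep = mp.compare_gene_orders(qry, ref)
    assert rep.moved_genes == frozenset(m[0] for m in moves)


def test_truth_json_export(tmp_path, default_genome):
    import json

    _, truth = default_genome
    path = tmp_path / "truth.json"
    truth.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["length"] == truth.length
    assert payload["codon_counts"] == truth.codon_counts
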