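"""Deterministic generator of annotated circular mitogenomes with known truth.

Every pipeline stage is testable without downloads: the generator emits a
:class:`~mitoprofile.records.MitogenomeRecord` together with a
:class:`TruthSet` holding the exact gene order, codon counts, terminal
codons, overlap/spacer/control-region coordinates and the sampling
parameters, so recomputed statistics can be checked against ground truth.

Defaults emulate a shrimp-like mitogenome at the ~20-22 kb scale: 13 PCGs
with the published *L. vittata* gene lengths, start codons and (incomplete)
stop codons, 22 tRNAs and 2 rRNAs on two strands in the ancestral
pancrustacean order, an AT-rich base pool (71.5% A+T), internal codons drawn
from the published codon-usage profile, four gene overlaps (longest 23 bp),
small intergenic spacers, and three AT-rich unannotated control regions of
650 / 3821 / 888 bp.

All randomness flows from the single seed in the spec; the same seed yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .architecture import GeneOrderSignature
from .codons import CODONS, CodonTable, get_table
from .records import Feature, MitogenomeRecord, reverse_complement


def _default_order() -> tuple[tuple[str, str], ...]:
    from .datasets import ancestral_gene_order

    return ancestral_gene_order().genes


DEFAULT_PCG_LENGTHS: dict[str, int] = {
    "atp6": 675, "atp8": 165, "cob": 1137, "cox1": 1614, "cox2": 693,
    "cox3": 756, "nad1": 927, "nad2": 1005, "nad3": 354, "nad4": 1336,
    "nad4l": 246, "nad5": 1732, "nad6": 504,
}
DEFAULT_START_CODONS: dict[str, str] = {
    "atp6": "ATG", "atp8": "ATG", "cob": "ATG", "nad2": "ATG", "nad3": "ATG",
    "nad4": "ATG", "nad5": "ATG", "cox2": "ATT", "nad1": "ATT", "nad6": "ATC",
    "cox1": "TTG", "nad4l": "TTG", "cox3": "GTG",
}
DEFAULT_STOP_CODONS: dict[str, str] = {
    **{g: "TAA" for g in DEFAULT_PCG_LENGTHS},
    "cox1": "TAG", "nad4": "T", "nad5": "T",
}
DEFAULT_TRNA_LENGTHS: dict[str, int] = {"trnA": 60, "trnN": 77}
DEFAULT_RRNA_LENGTHS: dict[str, int] = {"rrnL": 1494, "rrnS": 821}
#: whole-genome base fractions (A, T, G, C) of the emulated genome
DEFAULT_BASE_FREQ: tuple[float, float, float, float] = (0.3435, 0.3715, 0.1180, 0.1669)
DEFAULT_OVERLAP_PLAN: tuple[tuple[str, str, int], ...] = (
    ("trnL1", "rrnL", 23), ("trnE", "trnF", 2), ("trnW", "trnC", 2),
    ("rrnL", "trnV", 1),
)
DEFAULT_CR_PLAN: tuple[tuple[str, int, float], ...] = (
    ("rrnS", 650, 0.8046), ("cox1", 3821, 0.7223), ("trnL2", 888, 0.7725),
)
DEFAULT_SPACER_PLAN: dict[str, int] = {
    "cox2": 2, "trnK": 4, "trnD": 3, "atp6": 8, "cox3": 2, "nad3": 5,
    "trnA": 2, "trnR": 3, "trnN": 6, "trnS1": 2, "trnF": 15, "trnH": 4,
    "nad4l": 7, "trnT": 2, "trnP": 9, "nad6": 2, "cob": 11, "trnS2": 20,
    "nad1": 3, "trnV": 2, "trnI": 2, "trnQ": 28, "trnM": 2, "nad2": 5,
    "trnC": 3, "trnY": 30,
}


def _default_codon_profile(table: CodonTable) -> np.ndarray:
    """Internal-codon sampling profile from the published codon counts,
    with the genetic code's stop codons zeroed (stops only occur terminally)."""
    from .datasets import lvittata_codon_counts

    counts = lvittata_codon_counts()
    profile = np.array([float(counts[c]) for c in CODONS])
    for i, codon in enumerate(CODONS):
        if table.amino_acid[codon] == "*":
            profile[i] = 0.0
    return profile / profile.sum()


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mitogenome; defaults are the emulated genome."""

    seed: int = 0
    gene_order: tuple[tuple[str, str], ...] = field(default_factory=_default_order)
    pcg_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    stop_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOP_CODONS))
    trna_length: int = 68
    trna_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRNA_LENGTHS))
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS))
    base_freq: tuple[float, float, float, float] = DEFAULT_BASE_FREQ
    codon_profile: dict[str, float] | None = None  # None -> published profile
    exact_internal_codons: dict[str, int] | None = None
    overlap_plan: tuple[tuple[str, str, int], ...] = DEFAULT_OVERLAP_PLAN
    cr_plan: tuple[tuple[str, int, float], ...] = DEFAULT_CR_PLAN
    spacer_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_PLAN))
    length_target: int | None = None
    codon_table: str = "invertebrate-mito"

    def category_of(self, token: str) -> str:
        if token in self.pcg_lengths:
            return "PCG"
        if token.startswith("rrn"):
            return "rRNA"
        if token.startswith("trn"):
            return "tRNA"
        return "other"

    def feature_length(self, token: str) -> int:
        cat = self.category_of(token)
        if cat == "PCG":
            return self.pcg_lengths[token]
        if cat == "rRNA":
            return self.rrna_lengths[token]
        if cat == "tRNA":
            return self.trna_lengths.get(token, self.trna_length)
        raise ValueError(f"no length rule for {token!r}")


@dataclass
class TruthSet:
    """Generator ground truth for one realized record."""

    spec: SyntheticSpec
    gene_order: GeneOrderSignature
    codon_counts: dict[str, int]
    terminals: dict[str, dict]
    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    cr_regions: list[dict]
    length: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.spec.seed,
            "length": self.length,
            "gene_order": str(self.gene_order),
            "codon_counts": self.codon_counts,
            "terminals": self.terminals,
            "overlaps": [list(o) for o in self.overlaps],
            "spacers": [list(s) for s in self.spacers],
            "cr_regions": self.cr_regions,
            "spec": {k: v for k, v in asdict(self.spec).items()
                     if k != "gene_order"},
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=list))


class InfeasiblePlan(ValueError):
    """The spec's plans cannot be realized (raised before any sampling)."""


def _validate(spec: SyntheticSpec) -> None:
    tokens = [t for t, _ in spec.gene_order]
    if len(tokens) != len(set(tokens)):
        raise InfeasiblePlan("duplicate tokens in gene order")
    token_set = set(tokens)
    succ = {tokens[i]: tokens[(i + 1) % len(tokens)] for i in range(len(tokens))}
    total = sum(abs(x) for x in [
        *(spec.feature_length(t) for t in tokens),
    ])
    for up, down, k in spec.overlap_plan:
        if up not in token_set or down not in token_set:
            raise InfeasiblePlan(f"overlap pair ({up}, {down}) not in gene order")
        if succ[up] != down:
            raise InfeasiblePlan(
                f"overlap pair ({up}, {down}) not adjacent in gene order")
        if spec.category_of(down) == "PCG":
            raise InfeasiblePlan(
                f"overlap into PCG {down!r}: would corrupt its planned codons")
        if k < 1 or k >= min(spec.feature_length(up), spec.feature_length(down)):
            raise InfeasiblePlan(f"overlap length {k} infeasible for ({up}, {down})")
        if up in spec.spacer_plan or any(c[0] == up for c in spec.cr_plan):
            raise InfeasiblePlan(
                f"{up!r} has both an overlap and a spacer/CR after it")
        total -= k
    for after, length, at in spec.cr_plan:
        if after not in token_set:
            raise InfeasiblePlan(f"CR anchor {after!r} not in gene order")
        if length < 1 or not 0 < at < 1:
            raise InfeasiblePlan("CR plan needs positive length and AT in (0,1)")
        total += length
    for after, length in spec.spacer_plan.items():
        if after in token_set and length >= 1:
            total += length
    freq = np.asarray(spec.base_freq, dtype=float)
    if freq.min() < 0 or abs(freq.sum() - 1) > 0.01:
        raise InfeasiblePlan("base frequencies must be non-negative and sum to 1")
    for g in (t for t in tokens if spec.category_of(t) == "PCG"):
        stop = spec.stop_codons[g]
        want_mod = {"TAA": 0, "TAG": 0, "T": 1, "TA": 2}[stop]
        if spec.pcg_lengths[g] % 3 != want_mod:
            raise InfeasiblePlan(
                f"{g}: length {spec.pcg_lengths[g]} inconsistent with stop {stop!r}")
        if spec.pcg_lengths[g] // 3 < 2:
            raise InfeasiblePlan(f"{g}: too short for start plus a codon")
    if spec.length_target is not None and total > spec.length_target:
        raise InfeasiblePlan(
            f"planned features total {total} bp > length target {spec.length_target}")


def _sample_bases(rng: np.random.Generator, n: int, freq) -> str:
    freq = np.asarray(freq, dtype=float)
    freq = freq / freq.sum()
    return "".join(rng.choice(list("ATGC"), size=n, p=freq)) if n else ""


def _internal_codon_pools(
    spec: SyntheticSpec, rng: np.random.Generator, table: CodonTable
) -> dict[str, list[str]]:
    """Per-gene internal codon lists (between start and stop), DNA alphabet."""
    pcgs = [t for t, _ in spec.gene_order if spec.category_of(t) == "PCG"]
    capacity = {}
    for g in pcgs:
        n_codons = spec.pcg_lengths[g] // 3
        complete_stop = len(spec.stop_codons[g]) == 3
        capacity[g] = n_codons - 1 - (1 if complete_stop else 0)
    if spec.exact_internal_codons is not None:
        pool: list[str] = []
        for codon, count in spec.exact_internal_codons.items():
            pool.extend([codon.replace("U", "T")] * int(count))
        if len(pool) != sum(capacity.values()):
            raise InfeasiblePlan(
                f"exact internal codons total {len(pool)} != capacity "
                f"{sum(capacity.values())}")
        rng.shuffle(pool)
        out, i = {}, 0
        for g in pcgs:
            out[g] = pool[i : i + capacity[g]]
            i += capacity[g]
        return out
    if spec.codon_profile is None:
        profile = _default_codon_profile(table)
    else:
        profile = np.array([spec.codon_profile.get(c, 0.0) for c in CODONS])
        for i, codon in enumerate(CODONS):
            if table.amino_acid[codon] == "*" and profile[i] > 0:
                raise InfeasiblePlan(f"codon profile assigns mass to stop {codon}")
        profile = profile / profile.sum()
    dna = [c.replace("U", "T") for c in CODONS]
    return {
        g: list(rng.choice(dna, size=capacity[g], p=profile)) for g in pcgs
    }


def generate(spec: SyntheticSpec) -> tuple[MitogenomeRecord, TruthSet]:
    """Realize a spec into an annotated circular record plus its TruthSet."""
    _validate(spec)
    table = get_table(spec.codon_table)
    rng = np.random.default_rng(spec.seed)
    pools = _internal_codon_pools(spec, rng, table)

    overlap_by_down = {down: (up, k) for up, down, k in spec.overlap_plan}
    cr_by_anchor = {after: (length, at) for after, length, at in spec.cr_plan}

    parts: list[str] = []
    cursor = 0  # 0-based length so far
    features: list[Feature] = []
    codon_counts: dict[str, int] = {}
    terminals: dict[str, dict] = {}
    spacers: list[tuple[str, str, int]] = []
    cr_regions: list[dict] = []
    overlaps: list[tuple[str, str, int]] = []

    order = list(spec.gene_order)
    for idx, (token, sign) in enumerate(order):
        cat = spec.category_of(token)
        if cat == "PCG":
            start = spec.start_codons[token]
            stop = spec.stop_codons[token]
            codons = [start] + pools[token] + ([stop] if len(stop) == 3 else [])
            for c in codons:
                rna = c.replace("T", "U")
                codon_counts[rna] = codon_counts.get(rna, 0) + 1
            cds = "".join(codons) + (stop if len(stop) < 3 else "")
            gene_seq = reverse_complement(cds) if sign == "-" else cds
            terminals[token] = {
                "start_codon": start, "stop_codon": stop,
                "stop_complete": len(stop) == 3,
            }
        else:
            gene_seq = _sample_bases(rng, spec.feature_length(token), spec.base_freq)

        k = 0
        if token in overlap_by_down:
            up, k = overlap_by_down[token]
            overlaps.append((up, token, k))
            # the overlapping bases are the upstream gene's tail, already emitted
            gene_seq = gene_seq[k:]
        start_pos = cursor - k  # 0-based
        parts.append(gene_seq)
        cursor += len(gene_seq)
        features.append(
            Feature(
                name=token,
                category=cat if cat != "other" else "other",
                strand="F" if sign == "+" else "R",
                spans=((start_pos + 1, cursor),),
            )
        )

        nxt = order[(idx + 1) % len(order)][0]
        if token in spec.spacer_plan and spec.spacer_plan[token] >= 1:
            n = spec.spacer_plan[token]
            parts.append(_sample_bases(rng, n, spec.base_freq))
            spacers.append((token, nxt, n))
            cursor += n
        if token in cr_by_anchor:
            length, at = cr_by_anchor[token]
            cr_freq = (at / 2, at / 2, (1 - at) / 2, (1 - at) / 2)
            parts.append(_sample_bases(rng, length, cr_freq))
            cr_regions.append(
                {"start": cursor + 1, "end": cursor + length,
                 "length_bp": length, "at_bias": at}
            )
            cursor += length

    if spec.length_target is not None and cursor < spec.length_target:
        parts.append(
            _sample_bases(rng, spec.length_target - cursor, spec.base_freq))
        cursor = spec.length_target

    record = MitogenomeRecord(
        id=f"synthetic-{spec.seed}", sequence="".join(parts), circular=True,
        features=features,
    )
    cr_regions.sort(key=lambda d: d["start"])
    for i, cr in enumerate(cr_regions, start=1):
        cr["label"] = f"CR{i}"
    anchor = order[0][0]
    truth = TruthSet(
        spec=spec,
        gene_order=GeneOrderSignature(
            genes=tuple(spec.gene_order), circular=True
        ).rotated_to(anchor),
        codon_counts=codon_counts,
        terminals=terminals,
        overlaps=overlaps,
        spacers=spacers,
        cr_regions=cr_regions,
        length=record.length,
    )
    return record, truth


def perturb_order(
    reference: GeneOrderSignature,
    moves: list[tuple[str, str | None]],
    seed: int | None = None,
) -> GeneOrderSignature:
    """Apply single-gene translocations: each ``(token, after)`` removes the
    token and reinserts it immediately after ``after`` (or at the front when
    ``after`` is None).  Moving an absent token is an error."""
    genes = list(reference.genes)
    for token, after in moves:
        tokens = [g for g, _ in genes]
        if token not in tokens:
            raise ValueError(f"cannot move absent gene {token!r}")
        entry = genes.pop(tokens.index(token))
        tokens = [g for g, _ in genes]
        if after is None:
            genes.insert(0, entry)
        else:
            if after not in tokens:
                raise ValueError(f"insertion anchor {after!r} absent")
            genes.insert(tokens.index(after) + 1, entry)
    sig = GeneOrderSignature(genes=tuple(genes), circular=reference.circular)
    if reference.anchor and reference.anchor in sig.tokens:
        sig = sig.rotated_to(reference.anchor)
    return sig


def sample_moves(
    reference: GeneOrderSignature, k: int, seed: int,
    forbidden: set[str] = frozenset(),
) -> list[tuple[str, str]]:
    """Draw ``k`` non-interacting single-gene translocations.

    Non-interacting means moved genes and insertion anchors are pairwise
    non-adjacent in the reference and mutually distinct, so each move changes
    an independent neighborhood and the moved-gene set has size exactly k.
    """
    rng = np.random.default_rng(seed)
    tokens = list(reference.tokens)
    n = len(tokens)
    for _ in range(10_000):
        chosen = list(rng.choice(n, size=2 * k, replace=False))
        movers, anchors = chosen[:k], chosen[k:]
        idx_set = set(chosen)
        anchor_tok = tokens[0] if reference.anchor is None else reference.anchor
        pairs = [(i, j) for i in idx_set for j in idx_set if i != j]
        if any((i + 1) % n == j for i, j in pairs):
            continue
        if any(tokens[i] in forbidden for i in chosen):
            continue
        if any(tokens[i] == anchor_tok for i in movers):
            continue
        moves = [(tokens[m], tokens[a]) for m, a in zip(movers, anchors)]
        return moves
    raise RuntimeError("could not sample non-interacting moves")
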