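"""Codon extraction, terminal-codon classification, codon counts and RSCU.

Relative synonymous codon usage of codon *c* in its synonymous family *f* is

    RSCU(c) = count(c) * |f| / sum of counts over f

i.e. the observed count divided by the count expected if all synonyms were
used equally; 1 means no bias, values above 1 mark preferred codons.  The
family partition comes from a :class:`CodonTable` preset:

``invertebrate-mito``
    NCBI translation table 5 families — the biologically correct code for
    invertebrate mitochondria (UGA = Trp, AGA/AGG = Ser, AUA = Met).
``table3-compat``
    Standard-code (table 1) families with the three standard stop codons
    pooled as one family.  Codon-usage software frequently reports RSCU under
    this grouping even for mitochondrial genes, so published mitogenome RSCU
    tables are often reproducible only with it; the preset makes that
    convention explicit and selectable rather than silently assumed.

Counts are kept in RNA-alphabet codon order (UUU, UUC, ... GGG).  Complete
stop codons are counted (published tables list them); 1-2 base incomplete
terminal remnants — stops completed by polyadenylation of the transcript —
are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from .records import MitogenomeRecord
from .utils import round_half_up

#: The 64 RNA codons in lexicographic U, C, A, G order (standard table order).
_ORDER = "UCAG"
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _ORDER for b in _ORDER for c in _ORDER
)
_CODON_INDEX = {codon: i for i, codon in enumerate(CODONS)}

STOP_LABEL = "*"


def _dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class CodonTable:
    """A genetic code plus a partition of the 64 codons into synonymous families.

    ``amino_acid`` maps every RNA codon to its amino-acid label (``*`` for
    stops); ``families`` maps a family label to the tuple of codons it
    contains and must partition the 64 codons exactly.
    """

    name: str
    code_id: int
    amino_acid: Mapping[str, str]
    start_codons: frozenset[str]
    families: Mapping[str, tuple[str, ...]]
    family_of: Mapping[str, str] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, codons in self.families.items():
            if not codons:
                raise ValueError(f"family {label!r} is empty")
            for codon in codons:
                if codon in seen:
                    raise ValueError(f"codon {codon} in two families")
                seen[codon] = label
        if set(seen) != set(CODONS):
            missing = set(CODONS) - set(seen)
            raise ValueError(f"families do not partition the 64 codons: {missing}")
        object.__setattr__(self, "family_of", seen)

    def is_stop(self, codon: str) -> bool:
        return self.amino_acid[_dna_to_rna(codon)] == STOP_LABEL


def _families_from_code(
    code_id: int, pool_stops: bool
) -> tuple[dict[str, str], frozenset[str], dict[str, tuple[str, ...]]]:
    bio = _BioCodonTable.unambiguous_rna_by_id[code_id]
    amino_acid = {codon: aa for codon, aa in bio.forward_table.items()
                  if len(codon) == 3 and set(codon) <= set("ACGU")}
    for codon in bio.stop_codons:
        amino_acid[codon] = STOP_LABEL
    families: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = amino_acid[codon]
        families.setdefault(aa, []).append(codon)
    if not pool_stops:
        # keep stops one family anyway; callers may exclude them downstream
        pass
    return (
        amino_acid,
        frozenset(_dna_to_rna(c) for c in bio.start_codons),
        {label: tuple(codons) for label, codons in families.items()},
    )


def _make_preset(name: str, code_id: int) -> CodonTable:
    amino_acid, starts, families = _families_from_code(code_id, pool_stops=True)
    return CodonTable(
        name=name, code_id=code_id, amino_acid=amino_acid,
        start_codons=starts, families=families,
    )


#: Registered family presets, addressable by name from reports and the CLI.
PRESETS: dict[str, CodonTable] = {
    "invertebrate-mito": _make_preset("invertebrate-mito", 5),
    "table3-compat": _make_preset("table3-compat", 1),
}


def get_table(preset: str | CodonTable) -> CodonTable:
    if isinstance(preset, CodonTable):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown codon-table preset {preset!r}; known: {sorted(PRESETS)}"
        ) from None


def extract_codons(cds_sequence: str) -> tuple[list[str], str]:
    """Split a coding-strand CDS into frame-0 codons plus a 0-2 base remnant.

    The remnant (an incomplete terminal codon, typically a truncated stop)
    is returned separately and never enters codon counts.
    """
    seq = cds_sequence.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    n_codons = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
    return codons, seq[3 * n_codons :]


@dataclass(frozen=True)
class TerminalCodonReport:
    """Start/stop classification of one protein-coding gene."""

    gene: str
    start_codon: str
    start_class: str  # "ATN" or "nonstandard"
    stop_codon: str   # TAA / TAG / TA / T / "none"
    stop_complete: bool


def classify_terminals(
    gene: str, cds_sequence: str, table: str | CodonTable = "invertebrate-mito"
) -> TerminalCodonReport:
    """Classify the initiation and termination codons of one CDS.

    The start codon is the first triplet, classed ``ATN`` when it matches
    that pattern, else ``nonstandard`` (nonstandard starts such as TTG and
    GTG are routine in invertebrate mitochondria).  The stop is the trailing
    complete codon when that codon is a stop under the genetic code;
    otherwise the 1-2 base remnant is reported as an incomplete stop.  A gene
    with neither ends with stop ``"none"`` (flagged, not an error).
    """
    tab = get_table(table)
    codons, remnant = extract_codons(cds_sequence)
    start = codons[0]
    start_class = "ATN" if start.startswith("AT") else "nonstandard"
    if remnant:
        stop, complete = remnant, False
    elif tab.is_stop(codons[-1]):
        stop, complete = codons[-1], True
    else:
        stop, complete = "none", False
    return TerminalCodonReport(
        gene=gene, start_codon=start, start_class=start_class,
        stop_codon=stop, stop_complete=complete,
    )


def count_codons(cds_list: Iterable[str]) -> np.ndarray:
    """Sum of per-gene codon count vectors (64 ints, RNA codon order).

    Complete terminal stop codons are included; incomplete remnants and any
    codon containing an ambiguous base are excluded.
    """
    counts = np.zeros(len(CODONS), dtype=np.int64)
    for cds in cds_list:
        codons, _ = extract_codons(cds)
        for codon in codons:
            idx = _CODON_INDEX.get(_dna_to_rna(codon))
            if idx is not None:
                counts[idx] += 1
    return counts


def counts_as_dict(counts: Sequence[int]) -> dict[str, int]:
    return {codon: int(n) for codon, n in zip(CODONS, counts)}


def counts_from_dict(mapping: Mapping[str, int]) -> np.ndarray:
    counts = np.zeros(len(CODONS), dtype=np.int64)
    for codon, n in mapping.items():
        counts[_CODON_INDEX[_dna_to_rna(codon)]] = n
    return counts


def rscu(
    counts: Sequence[int], table: str | CodonTable = "invertebrate-mito"
) -> np.ndarray:
    """RSCU of all 64 codons under the table's synonymous-family partition.

    A family with total count 0 gets RSCU 0 for all its codons; a singleton
    family's codon has RSCU 1 whenever its count is positive.
    """
    tab = get_table(table)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (64,):
        raise ValueError("counts must be a 64-vector in RNA codon order")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.zeros(64)
    for codons in tab.families.values():
        idx = [_CODON_INDEX[c] for c in codons]
        total = counts[idx].sum()
        if total > 0:
            out[idx] = counts[idx] * len(idx) / total
    return out


def aa_totals(
    counts: Sequence[int],
    table: str | CodonTable = "invertebrate-mito",
    split_sixfold: bool = False,
) -> dict[str, int]:
    """Per-amino-acid codon totals (stop codons excluded).

    With ``split_sixfold=True`` the six-fold leucine and serine families are
    reported as Leu1/Leu2 and Ser1/Ser2 (CUN vs UUR; UCN vs AGN) in the style
    of mitogenome codon-usage summaries.
    """
    tab = get_table(table)
    counts = np.asarray(counts)
    totals: dict[str, int] = {}
    for label, codons in tab.families.items():
        if label == STOP_LABEL:
            continue
        if split_sixfold and label in ("L", "S") and len(codons) == 6:
            sub: dict[str, int] = {}
            for codon in codons:
                key = f"{label}1" if codon[0] == ("C" if label == "L" else "U") \
                    else f"{label}2"
                sub[key] = sub.get(key, 0) + int(counts[_CODON_INDEX[codon]])
            totals.update(sub)
        else:
            totals[label] = int(sum(counts[_CODON_INDEX[c]] for c in codons))
    return totals


@dataclass(frozen=True)
class CodonUsage:
    """End-to-end codon-usage summary of a record's protein-coding genes."""

    preset: str
    counts: tuple[int, ...]
    rscu: tuple[float, ...]
    aa_totals: dict[str, int]
    n_codons_total: int        # per-gene flooring: sum of floor(len_g / 3)
    n_codons_joint: int        # joint flooring: floor(sum len_g / 3)
    n_stop_complete: int
    n_stop_incomplete: int
    terminals: tuple[TerminalCodonReport, ...]

    def to_frame(self, digits: int = 2) -> pd.DataFrame:
        """Table in the published layout: codon, amino acid, count, RSCU."""
        tab = get_table(self.preset)
        return pd.DataFrame(
            {
                "codon": CODONS,
                "aa": [tab.amino_acid[c] for c in CODONS],
                "count": self.counts,
                "rscu": [round_half_up(v, digits) for v in self.rscu],
            }
        )


def codon_usage_report(
    record: MitogenomeRecord, table: str | CodonTable = "invertebrate-mito"
) -> CodonUsage:
    """Extract every PCG on its coding strand, count codons, and compute RSCU."""
    tab = get_table(table)
    pcgs = record.features_of("PCG")
    if not pcgs:
        raise ValueError("record has no protein-coding genes")
    cds_list = [record.extract(f) for f in pcgs]
    counts = count_codons(cds_list)
    terminals = tuple(
        classify_terminals(f.name, cds, tab) for f, cds in zip(pcgs, cds_list)
    )
    total_len = sum(len(c) for c in cds_list)
    return CodonUsage(
        preset=tab.name,
        counts=tuple(int(n) for n in counts),
        rscu=tuple(rscu(counts, tab)),
        aa_totals=aa_totals(counts, tab),
        n_codons_total=sum(len(c) // 3 for c in cds_list),
        n_codons_joint=total_len // 3,
        n_stop_complete=sum(1 for t in terminals if t.stop_complete),
        n_stop_incomplete=sum(
            1 for t in terminals if not t.stop_complete and t.stop_codon != "none"
        ),
        terminals=terminals,
    )


def export_pcg_matrices(
    record: MitogenomeRecord,
    nt_path,
    aa_path,
    table: str | CodonTable = "invertebrate-mito",
) -> None:
    """Write concatenated 13-PCG nucleotide and amino-acid FASTA matrices.

    These are the inputs external alignment/phylogenetics tools expect;
    terminal stop codons and incomplete remnants are trimmed before
    concatenation and translation.
    """
    from Bio.Seq import Seq

    tab = get_table(table)
    nt_parts, aa_parts = [], []
    for feat in record.features_of("PCG"):
        cds = record.extract(feat)
        codons, _ = extract_codons(cds)
        while codons and tab.is_stop(codons[-1]):
            codons.pop()
        trimmed = "".join(codons)
        nt_parts.append(trimmed)
        aa_parts.append(str(Seq(trimmed).translate(table=tab.code_id)))
    from pathlib import Path

    Path(nt_path).write_text(f">{record.id}_13pcg_nt\n{''.join(nt_parts)}\n")
    Path(aa_path).write_text(f">{record.id}_13pcg_aa\n{''.join(aa_parts)}\n")
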