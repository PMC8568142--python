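"""Packaged reference data.

Published summary statistics for the *Lysmata vittata* mitogenome (GenBank
MT478132) — per-codon counts of the 13 protein-coding genes and the
composition/skew table — plus the ancestral pancrustacean gene order used as
the rearrangement reference and a *synthetic reconstruction* of the
L. vittata gene order (see the data files' headers for provenance caveats).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .architecture import GeneOrderSignature

_DATA = resources.files("mitoprofile") / "data"


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def _read_order(name: str) -> GeneOrderSignature:
    text = (_DATA / name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneOrderSignature.from_string(lines[0])


def lvittata_codon_counts() -> dict[str, int]:
    """Published per-codon counts (RNA alphabet) of the 13 PCGs."""
    df = _read_tsv("lvittata_codon_counts.tsv")
    return dict(zip(df["codon"], df["count"].astype(int)))


def lvittata_composition() -> pd.DataFrame:
    """Published composition/skew table, indexed by region label."""
    return _read_tsv("lvittata_composition.tsv").set_index("region")


def ancestral_gene_order() -> GeneOrderSignature:
    """The ancestral pancrustacean / Decapoda mitochondrial gene order."""
    return _read_order("ancestral_pancrustacea_order.txt")


def lvittata_gene_order() -> GeneOrderSignature:
    """Synthetic reconstruction of the L. vittata gene order (see file header)."""
    return _read_order("lvittata_gene_order.synthetic.txt")


def lvittata_pcg_lengths() -> dict[str, int]:
    """Published PCG lengths in bp, from the composition table."""
    df = lvittata_composition()
    pcgs = [
        "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    ]
    return {g: int(df.loc[g, "size_bp"]) for g in pcgs}
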