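"""Normalization of mitochondrial gene names to canonical lowercase tokens.

The 37 canonical metazoan mitochondrial genes are addressed by the tokens
``atp6 atp8 cob cox1-3 nad1-6 nad4l`` (13 protein-coding genes), ``trnX`` /
``trnL1 trnL2 trnS1 trnS2`` (22 tRNAs), ``rrnL rrnS`` (2 rRNAs), plus ``CRn``
for control regions.  Aliases cover the common GenBank spellings (``COX1``,
``COI``, ``ND4L``, ``CYTB``, ``12S``, ``tRNA-Leu`` ...).  Leucine and serine
tRNA copies are disambiguated by anticodon when one is given; an ambiguous
``trnL``/``trnS`` without an anticodon or explicit suffix is flagged rather
than guessed.
"""

from __future__ import annotations

import re

PCG_TOKENS = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
TRNA_TOKENS = tuple(
    f"trn{aa}" for aa in (
        "A", "C", "D", "E", "F", "G", "H", "I", "K", "M", "N",
        "P", "Q", "R", "T", "V", "W", "Y",
    )
) + ("trnL1", "trnL2", "trnS1", "trnS2")
RRNA_TOKENS = ("rrnL", "rrnS")
CANONICAL_TOKENS = PCG_TOKENS + TRNA_TOKENS + RRNA_TOKENS

_THREE_TO_ONE = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Copy assignment by anticodon for the duplicated leucine/serine tRNAs.
# Both the true anticodon spelling and the codon-family spelling seen in the
# literature are accepted (e.g. trnL1 is the CUN-codon leucine tRNA with
# anticodon UAG; some tables print the codon "CUA" instead).
_LS_BY_ANTICODON = {
    ("L", "UAG"): "trnL1", ("L", "TAG"): "trnL1",
    ("L", "CUA"): "trnL1", ("L", "CTA"): "trnL1", ("L", "CUN"): "trnL1",
    ("L", "UAA"): "trnL2", ("L", "TAA"): "trnL2",
    ("L", "UUA"): "trnL2", ("L", "TTA"): "trnL2", ("L", "UUR"): "trnL2",
    ("S", "UCU"): "trnS1", ("S", "TCT"): "trnS1",
    ("S", "AGA"): "trnS1", ("S", "AGN"): "trnS1", ("S", "GCU"): "trnS1",
    ("S", "UGA"): "trnS2", ("S", "TGA"): "trnS2",
    ("S", "UCA"): "trnS2", ("S", "TCA"): "trnS2", ("S", "UCN"): "trnS2",
}

_PCG_ALIASES = {
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "cob": "cob", "cytb": "cob", "ctyb": "cob", "cob1": "cob",
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l", "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
}
_RRNA_ALIASES = {
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "lsu": "rrnL", "rrn16": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    "ssu": "rrnS", "rrn12": "rrnS",
}

_CATEGORY_BY_TOKEN = (
    {tok: "PCG" for tok in PCG_TOKENS}
    | {tok: "tRNA" for tok in TRNA_TOKENS}
    | {tok: "rRNA" for tok in RRNA_TOKENS}
)

_CR_RE = re.compile(r"^(?:cr|d-?loop|control[ _-]?region)[ _-]?(\d*)$")
_TRN_RE = re.compile(r"^trn([a-z])(\d?)$")
_TRNA_LONG_RE = re.compile(r"^trna[-_ ]?([a-z]{3})(\d?)\(?([acgtun]{3})?\)?$")


class AmbiguousGeneName(ValueError):
    """A leucine/serine tRNA that cannot be assigned to copy 1 or 2."""


def normalize_gene_name(
    name: str, anticodon: str | None = None
) -> tuple[str, str]:
    """Map an annotation label to ``(canonical token, category)``.

    Unrecognized names pass through unchanged with category ``other``.
    Raises :class:`AmbiguousGeneName` for a leucine/serine tRNA with neither
    a copy suffix nor an anticodon.
    """
    raw = name.strip()
    key = re.sub(r"[\s_]+", "", raw.lower())
    key = key.replace("*", "")

    if key in _PCG_ALIASES:
        return _PCG_ALIASES[key], "PCG"
    if key in _RRNA_ALIASES:
        return _RRNA_ALIASES[key], "rRNA"

    m = _CR_RE.match(key.replace("(", "").replace(")", ""))
    if m:
        suffix = m.group(1) or "1"
        return f"CR{suffix}", "CR"

    token = _match_trna(key, anticodon)
    if token is not None:
        return token, "tRNA"

    return raw, "other"


def _match_trna(key: str, anticodon: str | None) -> str | None:
    m = _TRN_RE.match(key)
    aa = suffix = None
    ac_from_name = None
    if m:
        aa, suffix = m.group(1).upper(), m.group(2)
    else:
        m = _TRNA_LONG_RE.match(key)
        if m and m.group(1) in _THREE_TO_ONE:
            aa = _THREE_TO_ONE[m.group(1)]
            suffix = m.group(2)
            ac_from_name = m.group(3)
        else:
            # compact forms like "trnl1(cua)" / "trns(uga)"
            m = re.match(r"^trn([a-z])(\d?)\(([acgtun]{3})\)$", key)
            if m:
                aa, suffix, ac_from_name = m.group(1).upper(), m.group(2), m.group(3)
    if aa is None or aa not in _THREE_TO_ONE.values():
        return None

    if aa not in ("L", "S"):
        return f"trn{aa}"

    if suffix in ("1", "2"):
        return f"trn{aa}{suffix}"
    ac = (anticodon or ac_from_name or "").upper()
    if ac:
        tok = _LS_BY_ANTICODON.get((aa, ac)) or _LS_BY_ANTICODON.get(
            (aa, ac.replace("T", "U"))
        )
        if tok:
            return tok
    raise AmbiguousGeneName(
        f"cannot assign trn{aa} to copy 1 or 2: no suffix and no known anticodon"
    )


def category_of(token: str) -> str:
    """Category of a canonical token (``other`` for pass-through names)."""
    if token in _CATEGORY_BY_TOKEN:
        return _CATEGORY_BY_TOKEN[token]
    if re.match(r"^CR\d+$", token):
        return "CR"
    return "other"
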