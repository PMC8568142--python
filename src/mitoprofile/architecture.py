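"""Genome architecture on the circle: overlaps, spacers, control regions,
and circular gene-order rearrangement comparison.

Gene orders are compared as strand-signed circular sequences canonicalized
by rotation to a shared anchor gene.  Conserved blocks are maximal runs of a
longest common subsequence (strand-sensitive: a gene on the opposite strand
counts as moved even in the same position); the breakpoint count is the
number of signed adjacencies of the reference, circular closure included,
that are absent from the query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .composition import base_composition
from .records import Feature, MitogenomeRecord


@dataclass(frozen=True)
class ArchitectureReport:
    """Overlaps, intergenic spacers, and control-region candidates."""

    overlaps: tuple[tuple[str, str, int], ...]
    spacers: tuple[tuple[str, str, int], ...]
    cr_candidates: tuple[dict, ...] = ()

    @property
    def longest_overlap(self) -> tuple[str, str, int] | None:
        return max(self.overlaps, key=lambda o: o[2], default=None)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "overlaps": pd.DataFrame(
                self.overlaps, columns=["gene_a", "gene_b", "length_bp"]
            ),
            "spacers": pd.DataFrame(
                self.spacers, columns=["upstream", "downstream", "length_bp"]
            ),
            "control_regions": pd.DataFrame(list(self.cr_candidates)),
        }


def _sorted_features(record: MitogenomeRecord) -> list[Feature]:
    feats = [f for f in record.features if f.category != "CR"]
    return sorted(feats, key=lambda f: (f.start, f.end))


def find_overlaps_and_spacers(record: MitogenomeRecord) -> ArchitectureReport:
    """Classify every adjacent-in-coordinate-order gene pair on the molecule.

    A positive gap between consecutive features is a spacer of that length, a
    negative gap an overlap of its magnitude; abutting genes (gap 0) appear in
    neither list.  On a circular record the closure pair (last feature back
    to the first across the origin) is included.
    """
    feats = _sorted_features(record)
    if len(feats) < 2:
        raise ValueError("need at least two located features")
    seen_spans = set()
    for f in feats:
        if f.spans in seen_spans:
            raise ValueError(f"two features share identical spans {f.spans}")
        seen_spans.add(f.spans)
    overlaps, spacers = [], []
    n = record.length

    def classify(a: Feature, b: Feature, gap: int) -> None:
        if gap > 0:
            spacers.append((a.name, b.name, gap))
        elif gap < 0:
            overlaps.append((a.name, b.name, -gap))

    for prev, nxt in zip(feats, feats[1:]):
        classify(prev, nxt, nxt.start - prev.end - 1)
    if record.circular:
        last, first = feats[-1], feats[0]
        end = last.end if not last.wraps_origin else last.spans[1][1]
        if last.wraps_origin:
            gap = first.start - end - 1
        else:
            gap = first.start + n - end - 1
        classify(last, first, gap)
    return ArchitectureReport(overlaps=tuple(overlaps), spacers=tuple(spacers))


def detect_control_regions(
    record: MitogenomeRecord, min_len: int = 200
) -> list[dict]:
    """Unannotated stretches of at least ``min_len`` bp, labeled CR1..CRk.

    Control regions in mitogenomes are the large AT-rich gaps left over once
    all genes are annotated; candidates are reported in coordinate order with
    1-based inclusive coordinates, length, and AT content.  The threshold is
    closed: a gap of exactly ``min_len`` is included.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = record.length
    covered = bytearray(n)
    for feat in record.features:
        if feat.category == "CR":
            continue
        for pos in feat.positions(n):
            covered[pos] = 1
    runs: list[tuple[int, int]] = []  # 0-based [start, end) of uncovered runs
    start = None
    for i in range(n):
        if not covered[i] and start is None:
            start = i
        elif covered[i] and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, n))
    # merge across the origin on circular records
    if record.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1] + n)
    out = []
    doubled = record.sequence + record.sequence
    for start, end in runs:
        length = end - start
        if length < min_len:
            continue
        seq = doubled[start:end]
        out.append(
            {
                "start": start % n + 1,
                "end": (end - 1) % n + 1,
                "length_bp": length,
                "at_content": round(base_composition(seq).at_content, 2),
            }
        )
    out.sort(key=lambda d: d["start"])
    for i, cr in enumerate(out, start=1):
        cr["label"] = f"CR{i}"
    return out


def annotate_control_regions(
    record: MitogenomeRecord, min_len: int = 200
) -> MitogenomeRecord:
    """Return the record with detected CR candidates added as CR features."""
    for cr in detect_control_regions(record, min_len):
        if cr["end"] >= cr["start"]:
            spans: tuple[tuple[int, int], ...] = ((cr["start"], cr["end"]),)
        else:
            spans = ((cr["start"], record.length), (1, cr["end"]))
        record.add_feature(
            Feature(name=cr["label"], category="CR", strand="F", spans=spans)
        )
    return record


@dataclass(frozen=True)
class GeneOrderSignature:
    """Strand-signed circular gene order, rotated so the anchor gene is first."""

    genes: tuple[tuple[str, str], ...]  # (token, "+" | "-")
    circular: bool = True
    anchor: str | None = None

    def __post_init__(self) -> None:
        tokens = [g for g, _ in self.genes]
        if len(tokens) != len(set(tokens)):
            dupes = sorted({t for t in tokens if tokens.count(t) > 1})
            raise ValueError(f"duplicate gene tokens in order: {dupes}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __str__(self) -> str:
        return " ".join(f"{s}{g}" for g, s in self.genes)

    @classmethod
    def from_string(cls, text: str, circular: bool = True) -> "GeneOrderSignature":
        """Parse the one-line sign-prefixed token format (``+cox1 -trnQ ...``)."""
        genes = []
        for tok in text.split():
            if tok[0] in "+-":
                genes.append((tok[1:], tok[0]))
            else:
                genes.append((tok, "+"))
        return cls(genes=tuple(genes), circular=circular)

    def rotated_to(self, anchor: str) -> "GeneOrderSignature":
        tokens = self.tokens
        if anchor not in tokens:
            raise ValueError(f"anchor gene {anchor!r} absent from order")
        i = tokens.index(anchor)
        return GeneOrderSignature(
            genes=self.genes[i:] + self.genes[:i],
            circular=self.circular, anchor=anchor,
        )


def linearize_gene_order(
    record: MitogenomeRecord, anchor: str = "cox1", include_cr: bool = False
) -> GeneOrderSignature:
    """Gene order of a record as a signature rotated to ``anchor``.

    Features are taken in coordinate order around the circle; control-region
    features are dropped unless ``include_cr`` is set.
    """
    feats = sorted(record.features, key=lambda f: (f.start, f.end))
    genes = tuple(
        (f.name, "+" if f.strand == "F" else "-")
        for f in feats
        if include_cr or f.category != "CR"
    )
    sig = GeneOrderSignature(genes=genes, circular=record.circular)
    return sig.rotated_to(anchor)


@dataclass(frozen=True)
class RearrangementReport:
    """Outcome of comparing a query gene order against a reference."""

    n_breakpoints: int
    conserved_blocks: tuple[tuple[str, ...], ...]
    moved_genes: frozenset[str]
    moved_blocks: tuple[tuple[str, ...], ...]
    private_query: frozenset[str] = frozenset()
    private_reference: frozenset[str] = frozenset()
    tie_occurred: bool = False


def _lcs_keep(
    ref: tuple[tuple[str, str], ...], qry: tuple[tuple[str, str], ...]
) -> tuple[list[tuple[str, str]], bool]:
    """Longest common subsequence of two signed orders.

    At equal-length DP branches the branch continuing the current conserved
    run is preferred, then the lexicographically smaller token is kept; a
    flag reports that such a tie occurred at all.
    """
    n, m = len(ref), len(qry)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            if ref[i] == qry[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    out: list[tuple[str, str]] = []
    tie = False
    i = j = 0
    while i < n and j < m:
        if ref[i] == qry[j]:
            out.append(ref[i])
            i += 1
            j += 1
        elif dp[i + 1][j] > dp[i][j + 1]:
            i += 1
        elif dp[i + 1][j] < dp[i][j + 1]:
            j += 1
        else:
            tie = True
            # prefer to skip the side whose current element breaks a run:
            # if the reference element matches further ahead in the query in
            # adjacency with the last kept gene, advance the query, else by
            # lexicographic token order
            if ref[i][0] <= qry[j][0]:
                j += 1
            else:
                i += 1
    return out, tie


def compare_gene_orders(
    query: GeneOrderSignature, reference: GeneOrderSignature
) -> RearrangementReport:
    """Rearrangement summary of ``query`` relative to ``reference``.

    Genes private to either order are dropped (and reported) before
    comparison; both orders are then rotated to a shared anchor.  Moved genes
    are those outside the retained longest common subsequence; breakpoints
    are reference adjacencies (including the circular closure) not preserved
    in the query, counting a signed adjacency as preserved also in its
    inverted form.
    """
    q_tokens, r_tokens = set(query.tokens), set(reference.tokens)
    common = q_tokens & r_tokens
    if not common:
        raise ValueError("gene orders share no genes")
    qry = tuple(g for g in query.genes if g[0] in common)
    ref = tuple(g for g in reference.genes if g[0] in common)

    anchor = reference.anchor or query.anchor
    if anchor not in common:
        anchor = ref[0][0]
    qry_sig = GeneOrderSignature(qry, query.circular).rotated_to(anchor)
    ref_sig = GeneOrderSignature(ref, reference.circular).rotated_to(anchor)
    qry, ref = qry_sig.genes, ref_sig.genes

    kept, tie = _lcs_keep(ref, qry)
    kept_tokens = {g for g, _ in kept}
    moved = frozenset(t for t, _ in ref if t not in kept_tokens)

    # conserved blocks: maximal runs of the kept subsequence that are
    # contiguous in BOTH orders
    ref_pos = {g: i for i, g in enumerate(ref)}
    qry_pos = {g: i for i, g in enumerate(qry)}
    blocks: list[list[str]] = []
    prev: tuple[str, str] | None = None
    for gene in kept:
        if (
            prev is not None
            and ref_pos[gene] == ref_pos[prev] + 1
            and qry_pos[gene] == qry_pos[prev] + 1
        ):
            blocks[-1].append(gene[0])
        else:
            blocks.append([gene[0]])
        prev = gene

    # moved blocks: maximal runs of moved genes contiguous in the query
    moved_blocks: list[list[str]] = []
    prev_idx = None
    for gene in qry:
        if gene[0] in moved:
            idx = qry_pos[gene]
            if prev_idx is not None and idx == prev_idx + 1:
                moved_blocks[-1].append(gene[0])
            else:
                moved_blocks.append([gene[0]])
            prev_idx = idx
        else:
            prev_idx = None

    n_breakpoints = _count_breakpoints(ref, qry)
    if tie:
        warnings.warn(
            "ambiguous longest common subsequence; moved-gene attribution "
            "used the documented tie-break", stacklevel=2,
        )
    return RearrangementReport(
        n_breakpoints=n_breakpoints,
        conserved_blocks=tuple(tuple(b) for b in blocks),
        moved_genes=moved,
        moved_blocks=tuple(tuple(b) for b in moved_blocks),
        private_query=frozenset(q_tokens - common),
        private_reference=frozenset(r_tokens - common),
        tie_occurred=tie,
    )


def _count_breakpoints(
    ref: tuple[tuple[str, str], ...], qry: tuple[tuple[str, str], ...]
) -> int:
    def adjacencies(order):
        pairs = set()
        seq = list(order) + ([order[0]] if len(order) > 1 else [])
        for a, b in zip(seq, seq[1:]):
            pairs.add((a, b))
        return pairs

    def inverted(pair):
        (ga, sa), (gb, sb) = pair
        flip = {"+": "-", "-": "+"}
        return ((gb, flip[sb]), (ga, flip[sa]))

    q_adj = adjacencies(qry)
    count = 0
    for pair in adjacencies(ref):
        if pair not in q_adj and inverted(pair) not in q_adj:
            count += 1
    return count
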