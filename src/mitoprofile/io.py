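"""Reading and writing annotated mitogenomes.

Supported inputs: GenBank flat files (via Biopython) and FASTA plus a tab-
separated feature table with columns ``name  category  strand  start  end
[anticodon]`` (1-based inclusive coordinates; ``end < start`` on a circular
record denotes a wrap-around feature).  Outputs: a normalized feature table,
FASTA per-region export, and a minimal GenBank writer for fixtures.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .names import AmbiguousGeneName, normalize_gene_name
from .records import Feature, MitogenomeRecord

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ("name", "category", "strand", "start", "end", "anticodon")

_GENBANK_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    Gene names are normalized through the alias table; the circular flag is
    taken from the LOCUS topology (default linear when absent).  Features
    whose locations cannot be interpreted are skipped with a logged warning;
    a file without sequence is a hard error.
    """
    seqrec = SeqIO.read(str(path), "genbank")
    if len(seqrec.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no sequence")
    circular = seqrec.annotations.get("topology", "linear") == "circular"
    record = MitogenomeRecord(
        id=seqrec.id or seqrec.name or Path(path).stem,
        sequence=str(seqrec.seq),
        circular=circular,
    )
    length = record.length
    for sf in seqrec.features:
        if sf.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop", "gene"):
            continue
        if sf.type == "gene" and _has_specific_sibling(seqrec.features, sf):
            continue
        label = _feature_label(sf)
        if label is None:
            logger.warning("skipping unnamed %s feature at %s", sf.type, sf.location)
            continue
        anticodon = _qualifier(sf, "anticodon")
        try:
            name, category = normalize_gene_name(label, anticodon)
        except AmbiguousGeneName as exc:
            logger.warning("feature %r: %s; kept as category 'other'", label, exc)
            name, category = label, "other"
        if category == "other" and sf.type in _GENBANK_CATEGORY:
            category = _GENBANK_CATEGORY[sf.type]
        try:
            spans, strand = _spans_from_location(sf, length)
        except ValueError as exc:
            logger.warning("skipping feature %r: unparseable location (%s)", label, exc)
            continue
        feature = Feature(
            name=name, category=category, strand=strand, spans=spans,
            anticodon=anticodon,
        )
        if any(f.name == feature.name and f.spans == feature.spans
               for f in record.features):
            continue  # gene + CDS pair annotating the same interval
        record.add_feature(feature)
    return record


def _has_specific_sibling(features, gene_feature) -> bool:
    for other in features:
        if other is gene_feature:
            continue
        if other.type in _GENBANK_CATEGORY and _overlaps(other, gene_feature):
            return True
    return False


def _overlaps(a, b) -> bool:
    return int(a.location.start) < int(b.location.end) and int(
        b.location.start
    ) < int(a.location.end)


def _feature_label(sf: SeqFeature) -> str | None:
    for key in ("gene", "product", "label", "note"):
        val = _qualifier(sf, key)
        if val:
            return val
    return None


def _qualifier(sf: SeqFeature, key: str) -> str | None:
    vals = sf.qualifiers.get(key)
    if not vals:
        return None
    val = vals[0]
    # anticodon qualifiers often look like "(pos:..,aa:Leu,seq:uag)"
    if key == "anticodon" and "seq:" in val:
        val = val.split("seq:")[1].strip(") ")
    return val.strip()


def _spans_from_location(sf: SeqFeature, length: int):
    loc = sf.location
    if loc is None:
        raise ValueError("no location")
    strand = "R" if loc.strand == -1 else "F"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    spans = [(int(p.start) + 1, int(p.end)) for p in parts]
    spans.sort(key=lambda s: s[0])
    if len(spans) == 2 and spans[1][1] == length and spans[0][0] == 1:
        spans = [spans[1], spans[0]]  # wrap-around: (.., length) first
    elif len(spans) > 1:
        raise ValueError(f"unsupported multi-part location {loc}")
    return tuple(spans), strand


def read_feature_table(
    fasta: str | Path, table: str | Path, record_id: str | None = None,
    circular: bool = True,
) -> MitogenomeRecord:
    """Build a record from a single-sequence FASTA and a TSV feature table.

    Table rows with ``end < start`` on a circular record become wrap-around
    features; an out-of-range coordinate is a hard error naming the row.
    """
    seqs = list(SeqIO.parse(str(fasta), "fasta"))
    if len(seqs) != 1:
        raise ValueError(f"{fasta}: expected exactly one sequence, found {len(seqs)}")
    record = MitogenomeRecord(
        id=record_id or seqs[0].id, sequence=str(seqs[0].seq), circular=circular
    )
    for feature in _parse_table_rows(Path(table).read_text().splitlines(), record):
        record.add_feature(feature)
    return record


def _parse_table_rows(lines: Iterable[str], record: MitogenomeRecord):
    length = record.length
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            if cells[0].strip().lower() == "name":
                header = [c.strip().lower() for c in cells]
                continue
            header = list(TABLE_COLUMNS[: len(cells)])
        row = dict(zip(header, (c.strip() for c in cells)))
        try:
            start, end = int(row["start"]), int(row["end"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"feature table row {lineno}: bad coordinates ({exc})")
        if not (1 <= start <= length) or not (1 <= end <= length):
            raise ValueError(
                f"feature table row {lineno} ({row.get('name')!r}): coordinate "
                f"outside [1, {length}]"
            )
        anticodon = row.get("anticodon") or None
        name, category = normalize_gene_name(row["name"], anticodon)
        if row.get("category"):
            category = row["category"]
        if end >= start:
            spans: tuple[tuple[int, int], ...] = ((start, end),)
        else:
            if not record.circular:
                raise ValueError(
                    f"feature table row {lineno}: end < start on a linear record"
                )
            spans = ((start, length), (1, end))
        yield Feature(
            name=name, category=category, strand=row.get("strand", "F"),
            spans=spans, anticodon=anticodon,
        )


def extract_region(record: MitogenomeRecord, feature: Feature) -> str:
    """Coding-strand sequence of ``feature`` (R-strand reverse-complemented)."""
    return record.extract(feature)


def write_feature_table(record: MitogenomeRecord, path: str | Path | TextIO) -> None:
    """Write the normalized TSV feature table (wrap-around rows as end < start)."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for feat in record.features:
        start = feat.spans[0][0]
        end = feat.spans[-1][1]
        lines.append(
            "\t".join(
                [feat.name, feat.category, feat.strand, str(start), str(end),
                 feat.anticodon or ""]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(
        SeqRecord(Seq(record.sequence), id=record.id, description=""),
        str(path), "fasta",
    )


def write_region_fasta(
    record: MitogenomeRecord, features: Iterable[Feature], path: str | Path
) -> None:
    """Per-region FASTA export on each feature's own coding strand."""
    recs = [
        SeqRecord(Seq(record.extract(f)), id=f.name, description=f.category)
        for f in features
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Minimal GenBank writer for fixtures and round-trip tests."""
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature",
               "other": "misc_feature"}
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA",
                           "topology": "circular" if record.circular else "linear",
                       })
    for feat in record.features:
        strand = -1 if feat.strand == "R" else 1
        locs = [SimpleLocation(start - 1, end, strand) for start, end in feat.spans]
        loc = CompoundLocation(locs) if len(locs) > 1 else locs[0]
        qualifiers = {"gene": [feat.name]}
        if feat.anticodon:
            qualifiers["anticodon"] = [feat.anticodon]
        seqrec.features.append(
            SeqFeature(loc, type=type_of[feat.category], qualifiers=qualifiers)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # BiopythonWarning on long locus names
        SeqIO.write(seqrec, str(path), "genbank")
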