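"""Core domain model: circular mitogenome records and their annotated features.

Coordinates are 1-based inclusive at this public boundary (the GenBank and
feature-table convention); all internal arithmetic converts to 0-based
half-open slices at the point of use.  A feature that crosses the origin of a
circular record carries exactly two spans, the first ending at the record
length and the second starting at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = set("ACGTN")
CATEGORIES = ("PCG", "tRNA", "rRNA", "CR", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated gene or region on a mitogenome.

    ``strand`` is ``"F"`` (majority / clockwise) or ``"R"`` (minority /
    counterclockwise).  ``spans`` is a tuple of 1-based inclusive
    ``(start, end)`` pairs in reading order on the F strand; a wrap-around
    feature on a circular record has two spans.
    """

    name: str
    category: str
    strand: str
    spans: tuple[tuple[int, int], ...]
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.strand not in ("F", "R"):
            raise ValueError(f"strand must be 'F' or 'R', got {self.strand!r}")
        if not self.spans:
            raise ValueError(f"feature {self.name!r} has no spans")
        for start, end in self.spans:
            if start < 1:
                raise ValueError(f"feature {self.name!r}: span start {start} < 1")
            if end < start:
                raise ValueError(
                    f"feature {self.name!r}: span ({start}, {end}) has end < start"
                )

    @property
    def start(self) -> int:
        """1-based start of the first span (coordinate-order anchor)."""
        return self.spans[0][0]

    @property
    def end(self) -> int:
        """1-based end of the last span."""
        return self.spans[-1][1]

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.spans)

    @property
    def wraps_origin(self) -> bool:
        return len(self.spans) == 2 and self.spans[1][0] == 1

    def positions(self, record_length: int) -> list[int]:
        """All 0-based positions covered, in reading order on the F strand."""
        out: list[int] = []
        for start, end in self.spans:
            out.extend(range(start - 1, end))
        if any(p >= record_length for p in out):
            raise ValueError(
                f"feature {self.name!r} exceeds record length {record_length}"
            )
        return out


@dataclass
class MitogenomeRecord:
    """A mitochondrial genome sequence plus its ordered feature annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty sequence")
        self._check_features()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _check_features(self) -> None:
        seen: set[tuple[str, tuple[tuple[int, int], ...]]] = set()
        for feat in self.features:
            if feat.end > self.length and not feat.wraps_origin:
                raise ValueError(
                    f"feature {feat.name!r} span {feat.spans} outside [1, {self.length}]"
                )
            if feat.wraps_origin:
                if not self.circular:
                    raise ValueError(
                        f"wrap-around feature {feat.name!r} on a linear record"
                    )
                if feat.spans[0][1] != self.length:
                    raise ValueError(
                        f"wrap-around feature {feat.name!r}: first span must end "
                        f"at record length {self.length}"
                    )
            key = (feat.name, feat.spans)
            if key in seen:
                raise ValueError(
                    f"duplicate feature (name, coordinates): {feat.name!r} {feat.spans}"
                )
            seen.add(key)
            if feat.category == "PCG" and feat.length < 3:
                raise ValueError(f"PCG {feat.name!r} shorter than one codon")

    def add_feature(self, feature: Feature) -> None:
        self.features.append(feature)
        try:
            self._check_features()
        except ValueError:
            self.features.pop()
            raise

    def feature_by_name(self, name: str) -> Feature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise KeyError(name)

    def extract(self, feature: Feature) -> str:
        """Sequence of a feature on its own coding strand.

        Spans are concatenated in F-strand reading order, then
        reverse-complemented for R-strand features.
        """
        parts = []
        for start, end in feature.spans:
            if end > self.length:
                raise ValueError(
                    f"feature {feature.name!r} span ({start}, {end}) exceeds "
                    f"record length {self.length}"
                )
            parts.append(self.sequence[start - 1 : end])
        seq = "".join(parts)
        return reverse_complement(seq) if feature.strand == "R" else seq

    def features_of(self, *categories: str) -> list[Feature]:
        return [f for f in self.features if f.category in categories]

    def reverse_complemented(self) -> "MitogenomeRecord":
        """The same molecule read from the opposite strand.

        Feature coordinates are mirrored and strands flipped, so that
        ``extract`` of the flipped feature returns the identical sequence.
        """
        n = self.length
        feats = []
        for feat in self.features:
            # mirror each span then reverse span order: keeps ascending
            # coordinates for plain features and the (.., L), (1, ..) shape
            # for wrap-around ones
            new_spans = tuple(
                (n - end + 1, n - start + 1) for start, end in reversed(feat.spans)
            )
            feats.append(
                Feature(
                    name=feat.name,
                    category=feat.category,
                    strand="R" if feat.strand == "F" else "F",
                    spans=new_spans,
                    anticodon=feat.anticodon,
                )
            )
        return MitogenomeRecord(
            id=self.id,
            sequence=reverse_complement(self.sequence),
            circular=self.circular,
            features=feats,
        )
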