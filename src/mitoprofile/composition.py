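"""Base composition, AT content, and strand-skew statistics.

Strand asymmetry is summarized by the two skew statistics

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed over unambiguous bases; ``N`` bases are preserved in sequences but
excluded from every denominator, so the four percentages always total 100.
A zero denominator (no A/T or no G/C at all) yields skew 0 with a warning
rather than NaN, keeping report tables total while remaining auditable.

Per-gene rows are computed on each gene's own coding strand by default, so a
minority-strand gene's skews flip sign relative to the majority strand —
mirroring how published mitogenome composition tables behave.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .records import Feature, MitogenomeRecord, reverse_complement


@dataclass(frozen=True)
class CompositionStats:
    """Base counts, percentages, AT content and skews of one region."""

    a: int
    t: int
    g: int
    c: int
    n_excluded: int

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def pct_a(self) -> float:
        return 100.0 * self.a / self.total

    @property
    def pct_t(self) -> float:
        return 100.0 * self.t / self.total

    @property
    def pct_g(self) -> float:
        return 100.0 * self.g / self.total

    @property
    def pct_c(self) -> float:
        return 100.0 * self.c / self.total

    @property
    def at_content(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def at_skew(self) -> float:
        return skew_from_fractions(self.a, self.t, warn=False)

    @property
    def gc_skew(self) -> float:
        return skew_from_fractions(self.g, self.c, warn=False)

    def as_row(self, digits: int = 2) -> dict[str, float | int]:
        """Table row in the published layout: size, T, C, A, G, A+T, skews."""
        return {
            "size_bp": self.total + self.n_excluded,
            "pct_T": round(self.pct_t, digits),
            "pct_C": round(self.pct_c, digits),
            "pct_A": round(self.pct_a, digits),
            "pct_G": round(self.pct_g, digits),
            "at_content": round(self.at_content, digits),
            "at_skew": round(self.at_skew, digits),
            "gc_skew": round(self.gc_skew, digits),
        }


def skew_from_fractions(x: float, y: float, warn: bool = True) -> float:
    """Skew ``(x - y) / (x + y)`` of two non-negative abundances.

    Works equally on raw counts and on printed percentages, which lets
    published table rows be checked directly from their percentage columns.
    ``x + y == 0`` returns 0 (with a warning by default) so that report
    tables stay total on degenerate regions.
    """
    if x < 0 or y < 0:
        raise ValueError("skew inputs must be non-negative")
    if x + y == 0:
        if warn:
            warnings.warn("skew denominator is zero; returning 0", stacklevel=2)
        return 0.0
    return (x - y) / (x + y)


def base_composition(sequence: str) -> CompositionStats:
    """Composition statistics of one sequence over {A,C,G,T,N}, case-insensitive."""
    seq = sequence.upper()
    a, t, g, c = seq.count("A"), seq.count("T"), seq.count("G"), seq.count("C")
    informative = a + t + g + c
    if informative == 0:
        raise ValueError("no informative bases (sequence empty or all ambiguous)")
    return CompositionStats(a=a, t=t, g=g, c=c, n_excluded=len(seq) - informative)


def region_composition_report(
    record: MitogenomeRecord,
    grouping: Mapping[str, Sequence[Feature]] | None = None,
    strand: str = "coding",
) -> pd.DataFrame:
    """Composition table with one row per named region group.

    ``grouping`` maps row label to the features concatenated for that row;
    when omitted, :func:`standard_grouping` reproduces the published layout
    (whole genome, each PCG, concatenated PCGs/tRNAs/rRNAs, each control
    region).  ``strand="coding"`` measures every gene on its own coding
    strand; ``strand="F"`` measures everything on the majority strand.
    Empty groups are omitted with a warning.
    """
    if strand not in ("coding", "F"):
        raise ValueError("strand must be 'coding' or 'F'")
    if grouping is None:
        grouping = standard_grouping(record)
    rows = {}
    for label, feats in grouping.items():
        if label == "whole genome":
            seq = record.sequence
        else:
            parts = []
            for feat in feats:
                seq_f = record.extract(feat)
                if strand == "F" and feat.strand == "R":
                    seq_f = reverse_complement(seq_f)
                parts.append(seq_f)
            seq = "".join(parts)
        if not seq or not set(seq) - {"N"}:
            warnings.warn(f"group {label!r} is empty; omitted", stacklevel=2)
            continue
        rows[label] = base_composition(seq).as_row()
    return pd.DataFrame.from_dict(rows, orient="index")


def standard_grouping(
    record: MitogenomeRecord,
) -> dict[str, list[Feature]]:
    """The published table layout: genome, per-PCG, pooled classes, per-CR."""
    pcgs = record.features_of("PCG")
    grouping: dict[str, list[Feature]] = {"whole genome": []}
    for feat in sorted(pcgs, key=lambda f: f.name):
        grouping[feat.name] = [feat]
    grouping["PCGs"] = pcgs
    grouping["tRNAs"] = record.features_of("tRNA")
    grouping["rRNAs"] = record.features_of("rRNA")
    for feat in record.features_of("CR"):
        grouping[feat.name] = [feat]
    return grouping


@dataclass(frozen=True)
class SkewProfile:
    """Sliding-window GC content / GC skew series around a (circular) record."""

    window: int
    step: int
    circular: bool
    midpoints: tuple[int, ...]
    gc_content: tuple[float, ...]
    gc_skew: tuple[float, ...]
    at_skew: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "midpoint": self.midpoints,
                "gc_content": self.gc_content,
                "gc_skew": self.gc_skew,
                "at_skew": self.at_skew,
            }
        )


def sliding_window_profile(
    record: MitogenomeRecord, window: int, step: int
) -> SkewProfile:
    """Windowed GC content and skews; windows wrap the origin on circular records.

    Produces ``ceil(length / step)`` windows on a circular record (every base
    is a window start modulo the step) and the non-wrapping windows only on a
    linear one.  Each point equals :func:`base_composition` of its window.
    """
    n = record.length
    if not 0 < step <= window:
        raise ValueError("need 0 < step <= window")
    if window > n:
        raise ValueError(f"window {window} exceeds record length {n}")
    starts = (
        range(0, n, step) if record.circular else range(0, n - window + 1, step)
    )
    mids, gc_content, gc_skew, at_skew = [], [], [], []
    doubled = record.sequence + record.sequence
    for start in starts:
        win = doubled[start : start + window]
        stats = base_composition(win)
        mids.append((start + window // 2) % n + 1)
        gc_content.append(100.0 - stats.at_content)
        gc_skew.append(stats.gc_skew)
        at_skew.append(stats.at_skew)
    assert not record.circular or len(mids) == math.ceil(n / step)
    return SkewProfile(
        window=window, step=step, circular=record.circular,
        midpoints=tuple(mids), gc_content=tuple(gc_content),
        gc_skew=tuple(gc_skew), at_skew=tuple(at_skew),
    )
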