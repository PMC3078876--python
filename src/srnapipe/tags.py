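"""Tag collapsing, length distribution and two-library overlap summary.

A *tag* is a unique 18-30 nt small-RNA sequence with one occurrence count
per library. Collapsing millions of raw reads to tags is the first step of
every small-RNA profiling analysis; all downstream statistics (annotation
shares, the exact test, the overlap table) operate on tags.

The overlap summary mirrors the classic three-way partition of a
two-library experiment: tags seen in both libraries ("common"), and tags
specific to either one, each reported with unique counts, read totals,
their percentage of the pooled library, and the mean frequency
(reads per unique tag).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from srnapipe.seqio import ParseError, canonical, is_valid_nt

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


class EmptyLibraryError(ValueError):
    """Raised when a library contains no (usable) reads."""


@dataclass(frozen=True)
class Tag:
    """A unique small-RNA sequence with per-library counts."""

    sequence: str
    count_fp: int = 0
    count_sp: int = 0

    @property
    def total(self) -> int:
        return self.count_fp + self.count_sp


@dataclass(frozen=True)
class LibraryStats:
    """Per-library totals after length filtering."""

    total_clean_reads: int
    unique_tags: int


@dataclass(frozen=True)
class FilterReport:
    """Reads discarded by the 18-30 nt length filter."""

    n_input: int
    n_kept: int
    n_too_short: int
    n_too_long: int


@dataclass
class OverlapSummary:
    """Library-overlap table: common / FP-specific / SP-specific classes.

    ``table`` has one row per class plus a pooled total row, with columns
    ``unique``, ``unique_pct``, ``total``, ``total_pct``, ``mean_frequency``.
    Percentages are relative to the pooled unique-tag and read totals;
    mean frequency is reads per unique tag, rendered to 2 decimals.
    """

    table: pd.DataFrame = field(repr=False)

    CLASSES = ("common", "fp_specific", "sp_specific")

    @classmethod
    def from_class_counts(cls, class_counts: dict[str, tuple[int, int]]) -> "OverlapSummary":
        """Build the summary from per-class ``(unique, total)`` counts.

        This is the arithmetic core: it is also usable to re-derive the
        percentage and mean-frequency columns of a published overlap table
        from its printed counts.
        """
        missing = set(cls.CLASSES) - set(class_counts)
        if missing:
            raise ValueError(f"missing overlap classes: {sorted(missing)}")
        pooled_unique = sum(u for u, _ in class_counts.values())
        pooled_total = sum(t for _, t in class_counts.values())
        if pooled_unique == 0 or pooled_total == 0:
            raise ValueError("zero pooled totals: overlap percentages undefined")
        rows = []
        for name in cls.CLASSES:
            u, t = class_counts[name]
            rows.append(
                {
                    "class": name,
                    "unique": u,
                    "unique_pct": round(100.0 * u / pooled_unique, 2),
                    "total": t,
                    "total_pct": round(100.0 * t / pooled_total, 2),
                    "mean_frequency": round(t / u, 2) if u else 0.0,
                }
            )
        rows.append(
            {
                "class": "total",
                "unique": pooled_unique,
                "unique_pct": 100.0,
                "total": pooled_total,
                "total_pct": 100.0,
                "mean_frequency": round(pooled_total / pooled_unique, 2),
            }
        )
        return cls(pd.DataFrame(rows).set_index("class"))

    def __getitem__(self, cls_name: str):
        # namespace access avoids Series method-name collisions (".unique")
        from types import SimpleNamespace

        return SimpleNamespace(**self.table.loc[cls_name].to_dict())


def _collapse_one(reads: Iterable[str | tuple[str, int]], label: str) -> tuple[Counter, FilterReport]:
    counts: Counter = Counter()
    n_input = n_kept = n_short = n_long = 0
    for lineno, item in enumerate(reads, start=1):
        seq, mult = item if isinstance(item, tuple) else (item, 1)
        seq = canonical(seq)
        if not seq or not is_valid_nt(seq):
            raise ParseError(f"{label}: non-nucleotide character in read {lineno}: {seq!r}")
        n_input += mult
        if len(seq) < MIN_TAG_LEN:
            n_short += mult
        elif len(seq) > MAX_TAG_LEN:
            n_long += mult
        else:
            counts[seq] += mult
            n_kept += mult
    if n_input == 0:
        raise EmptyLibraryError(f"{label}: empty library")
    return counts, FilterReport(n_input, n_kept, n_short, n_long)


def collapse_reads(
    fp_reads: Iterable[str | tuple[str, int]],
    sp_reads: Iterable[str | tuple[str, int]],
) -> tuple[list[Tag], dict[str, LibraryStats], dict[str, FilterReport]]:
    """Collapse two read collections to unique tags with per-library counts.

    Accepts plain sequence strings or ``(sequence, count)`` pairs (the
    collapsed-FASTA convention), so the function is idempotent on already
    collapsed input. Reads outside 18-30 nt are discarded and tallied in
    the filter reports; a non-nucleotide character raises
    :class:`~srnapipe.seqio.ParseError` naming the read number.
    """
    fp_counts, fp_report = _collapse_one(fp_reads, "FP")
    sp_counts, sp_report = _collapse_one(sp_reads, "SP")
    tags = [
        Tag(seq, fp_counts.get(seq, 0), sp_counts.get(seq, 0))
        for seq in sorted(set(fp_counts) | set(sp_counts))
    ]
    stats = {
        "FP": LibraryStats(sum(fp_counts.values()), len(fp_counts)),
        "SP": LibraryStats(sum(sp_counts.values()), len(sp_counts)),
    }
    return tags, stats, {"FP": fp_report, "SP": sp_report}


def length_distribution(tags: list[Tag]) -> pd.DataFrame:
    """Per-length read counts and fractions for each library.

    Returns a frame indexed by length 18-30 with columns ``count_fp``,
    ``count_sp``, ``fraction_fp``, ``fraction_sp``; the modal length per
    library is stored in ``df.attrs["mode"]``. Fractions sum to 1 per
    library (an all-zero library yields zero fractions).
    """
    idx = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    df = pd.DataFrame(0, index=pd.Index(idx, name="length"), columns=["count_fp", "count_sp"])
    for tag in tags:
        df.loc[len(tag.sequence), "count_fp"] += tag.count_fp
        df.loc[len(tag.sequence), "count_sp"] += tag.count_sp
    for lib in ("fp", "sp"):
        total = df[f"count_{lib}"].sum()
        df[f"fraction_{lib}"] = df[f"count_{lib}"] / total if total else 0.0
    df.attrs["mode"] = {
        lib.upper(): int(df[f"count_{lib}"].idxmax()) for lib in ("fp", "sp")
    }
    return df


def overlap_summary(tags: list[Tag], stats: dict[str, LibraryStats] | None = None) -> OverlapSummary:
    """Classify tags as common / FP-specific / SP-specific and summarize.

    A tag is *common* iff it has at least one read in both libraries.
    ``stats`` is accepted for interface symmetry and consistency checking:
    when given, per-library read totals must agree with the tag counts.
    """
    acc = {name: [0, 0] for name in OverlapSummary.CLASSES}
    for tag in tags:
        if tag.count_fp >= 1 and tag.count_sp >= 1:
            key = "common"
        elif tag.count_fp >= 1:
            key = "fp_specific"
        else:
            key = "sp_specific"
        acc[key][0] += 1
        acc[key][1] += tag.total
    if stats is not None:
        fp_total = sum(t.count_fp for t in tags)
        sp_total = sum(t.count_sp for t in tags)
        if fp_total != stats["FP"].total_clean_reads or sp_total != stats["SP"].total_clean_reads:
            raise ValueError("tag counts do not conserve the library read totals")
    return OverlapSummary.from_class_counts({k: (u, t) for k, (u, t) in acc.items()})
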