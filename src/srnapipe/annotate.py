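"""Prioritized annotation waterfall for small-RNA tags.

Tags are assigned to exactly one category in strict priority order:

1. structural ncRNA (rRNA / tRNA / snRNA / snoRNA) — exact substring match
   against the ncRNA reference set,
2. known miRNA — full-length alignment of the tag within a mature
   reference allowing a bounded number of substitutions (no indels),
3. genome-matched — exact full-length match to either genome strand,
4. other — everything else.

A tag is tested at a tier only if it was left unassigned by every higher
tier, so the waterfall is a partition. Deterministic matching (substring /
bounded Hamming) replaces database BLAST searches: for 18-30 nt queries
this is both reproducible and database-version free.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from srnapipe.seqio import RefRecord, revcomp
from srnapipe.tags import LibraryStats, Tag

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = NCRNA_CATEGORIES + ("known_miRNA", "genome_matched", "other")

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AnnotationRecord:
    """One tag's category assignment."""

    sequence: str
    category: str
    ref_id: str | None = None
    family: str | None = None
    mismatches: int | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _substring_index(refs: list[RefRecord], lengths: set[int]) -> dict[str, RefRecord]:
    """Map every substring of the reference set (at tag lengths) to the
    first reference containing it; first-come order makes ties deterministic."""
    index: dict[str, RefRecord] = {}
    for ref in refs:
        for k in sorted(lengths):
            for i in range(len(ref.seq) - k + 1):
                index.setdefault(ref.seq[i : i + k], ref)
    return index


class _MirnaMatcher:
    """Vectorized bounded-Hamming matcher of tags against mature references.

    For every tag length L, all length-L windows of every reference are
    stacked into one matrix; a tag is compared against all windows at once.
    The best hit is the window with the fewest mismatches; ties are broken
    by (family, reference id, offset) order, which is how the window list
    is sorted.
    """

    def __init__(self, refs: list[RefRecord], max_mismatches: int = 2):
        self.max_mismatches = max_mismatches
        self._by_len: dict[int, tuple[np.ndarray, list[RefRecord]]] = {}
        self._refs = sorted(refs, key=lambda r: (r.family, r.id))

    def _windows(self, k: int) -> tuple[np.ndarray, list[RefRecord]]:
        if k not in self._by_len:
            mats, owners = [], []
            for ref in self._refs:
                enc = _encode(ref.seq)
                for i in range(len(ref.seq) - k + 1):
                    mats.append(enc[i : i + k])
                    owners.append(ref)
            mat = np.vstack(mats) if mats else np.empty((0, k), dtype=np.uint8)
            self._by_len[k] = (mat, owners)
        return self._by_len[k]

    def best_hit(self, seq: str) -> tuple[RefRecord, int] | None:
        mat, owners = self._windows(len(seq))
        if mat.shape[0] == 0:
            return None
        mm = (mat != _encode(seq)).sum(axis=1)
        j = int(np.argmin(mm))  # argmin returns the first minimum: tie-break order
        if mm[j] > self.max_mismatches:
            return None
        return owners[j], int(mm[j])


def annotate_waterfall(
    tags: list[Tag],
    ncrna_refs: list[RefRecord],
    mirna_refs: list[RefRecord],
    genome: list[tuple[str, str]],
    max_mismatches: int = 2,
) -> list[AnnotationRecord]:
    """Assign every tag exactly one category via the priority waterfall.

    ``genome`` is a list of ``(record_id, sequence)`` pairs; the genome
    tier requires an exact full-length match on either strand (the minus
    strand is searched via the reverse complement).
    """
    if not ncrna_refs:
        raise IOError("ncRNA tier: no reference records supplied")
    if not mirna_refs:
        raise IOError("known-miRNA tier: no reference records supplied")
    if not genome:
        raise IOError("genome tier: no genome records supplied")

    lengths = {len(t.sequence) for t in tags}
    nc_index = _substring_index(ncrna_refs, lengths)
    matcher = _MirnaMatcher(mirna_refs, max_mismatches)
    genome_index: dict[str, str] = {}
    for gid, gseq in genome:
        for strand_seq in (gseq, revcomp(gseq)):
            for k in sorted(lengths):
                for i in range(len(strand_seq) - k + 1):
                    genome_index.setdefault(strand_seq[i : i + k], gid)

    records = []
    for tag in tags:
        seq = tag.sequence
        nc = nc_index.get(seq)
        if nc is not None:
            records.append(AnnotationRecord(seq, nc.category, nc.id))
            continue
        hit = matcher.best_hit(seq)
        if hit is not None:
            ref, mm = hit
            records.append(AnnotationRecord(seq, "known_miRNA", ref.id, ref.family, mm))
            continue
        gid = genome_index.get(seq)
        if gid is not None:
            records.append(AnnotationRecord(seq, "genome_matched", gid))
            continue
        records.append(AnnotationRecord(seq, "other"))
    return records


def mean_frequency(total: int, unique: int) -> float:
    """Reads per unique tag, 2 decimals; 0 for an empty category."""
    return round(total / unique, 2) if unique else 0.0


def category_share(count: int, library_total: int) -> float:
    """A category's percentage of its library, 2 decimals."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return round(100.0 * count / library_total, 2)


def summarize_annotation(
    records: list[AnnotationRecord],
    tags: list[Tag],
    stats: dict[str, LibraryStats],
) -> pd.DataFrame:
    """Per-category unique/total counts, library shares and mean frequency.

    One row per waterfall category plus an ``ncRNA`` subtotal and a
    ``total`` row; shares are percentages of each library's unique-tag and
    clean-read totals, rendered to 2 decimals.
    """
    counts = {t.sequence: t for t in tags}
    acc: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(4, dtype=np.int64))
    for rec in records:
        tag = counts[rec.sequence]
        acc[rec.category] += np.array(
            [tag.count_fp > 0, tag.count_sp > 0, tag.count_fp, tag.count_sp]
        )
    acc["ncRNA"] = sum((acc[c] for c in NCRNA_CATEGORIES), np.zeros(4, dtype=np.int64))
    lib_unique = {
        "FP": sum(1 for t in tags if t.count_fp > 0),
        "SP": sum(1 for t in tags if t.count_sp > 0),
    }
    rows = []
    order = list(NCRNA_CATEGORIES) + ["ncRNA", "known_miRNA", "genome_matched", "other"]
    for cat in order:
        ufp, usp, tfp, tsp = acc[cat]
        rows.append(
            {
                "category": cat,
                "unique_fp": int(ufp),
                "unique_sp": int(usp),
                "unique_fp_pct": round(100.0 * ufp / lib_unique["FP"], 2) if lib_unique["FP"] else 0.0,
                "unique_sp_pct": round(100.0 * usp / lib_unique["SP"], 2) if lib_unique["SP"] else 0.0,
                "total_fp": int(tfp),
                "total_sp": int(tsp),
                "total_fp_pct": round(100.0 * tfp / stats["FP"].total_clean_reads, 2),
                "total_sp_pct": round(100.0 * tsp / stats["SP"].total_clean_reads, 2),
                "mean_freq_fp": mean_frequency(int(tfp), int(ufp)),
                "mean_freq_sp": mean_frequency(int(tsp), int(usp)),
            }
        )
    total_fp = stats["FP"].total_clean_reads
    total_sp = stats["SP"].total_clean_reads
    rows.append(
        {
            "category": "total",
            "unique_fp": lib_unique["FP"],
            "unique_sp": lib_unique["SP"],
            "unique_fp_pct": 100.0,
            "unique_sp_pct": 100.0,
            "total_fp": total_fp,
            "total_sp": total_sp,
            "total_fp_pct": 100.0,
            "total_sp_pct": 100.0,
            "mean_freq_fp": mean_frequency(total_fp, lib_unique["FP"]),
            "mean_freq_sp": mean_frequency(total_sp, lib_unique["SP"]),
        }
    )
    return pd.DataFrame(rows).set_index("category")


def family_assign(
    records: list[AnnotationRecord],
    tags: list[Tag],
) -> pd.DataFrame:
    """Aggregate known-miRNA tag counts per family.

    Family membership follows the best (fewest-mismatch) reference hit made
    during annotation; ties were already broken lexicographically there.
    Returns per-family read counts and each family's share of the
    conserved-miRNA read pool in each library.
    """
    counts = {t.sequence: t for t in tags}
    acc: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(3, dtype=np.int64))
    for rec in records:
        if rec.category != "known_miRNA":
            continue
        tag = counts[rec.sequence]
        acc[rec.family] += np.array([1, tag.count_fp, tag.count_sp])
    if not acc:
        return pd.DataFrame(
            columns=["unique_tags", "count_fp", "count_sp", "share_fp", "share_sp"]
        ).rename_axis("family")
    df = pd.DataFrame(
        {fam: dict(zip(["unique_tags", "count_fp", "count_sp"], v)) for fam, v in acc.items()}
    ).T.rename_axis("family").sort_index()
    for lib in ("fp", "sp"):
        pool = df[f"count_{lib}"].sum()
        df[f"share_{lib}"] = df[f"count_{lib}"] / pool if pool else 0.0
    return df
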