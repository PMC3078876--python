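"""Sequence I/O and nucleotide utilities.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the
conventions the pipeline relies on:

* canonical internal alphabet {A, C, G, T} (U is folded into T on input),
* collapsed-FASTA headers ``>tag<n>_x<count>`` carrying read counts,
* reference headers ``>id|category|family`` for annotation tiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


class ParseError(ValueError):
    """Raised for malformed sequence input; carries the offending position."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGT]+$")
_COUNT_SUFFIX = re.compile(r"_x(\d+)$")


def canonical(seq: str) -> str:
    """Uppercase and fold RNA U into DNA T (mixed conventions are common
    across miRNA FASTA sources)."""
    return seq.upper().replace("U", "T")


def is_valid_nt(seq: str) -> bool:
    return bool(_VALID.match(seq))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RefRecord:
    """One reference sequence with the ``id|category|family`` header parsed."""

    id: str
    category: str
    family: str
    seq: str


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, canonical_sequence), ...]``."""
    return [(rec.id, canonical(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def read_reference_fasta(path: str | Path) -> list[RefRecord]:
    """Read a reference FASTA whose headers follow ``id|category|family``.

    Missing fields default to the empty string so plain headers are still
    usable (category/family then have to be supplied by the caller).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        rid = parts[0]
        category = parts[1] if len(parts) > 1 else ""
        family = parts[2] if len(parts) > 2 else ""
        out.append(RefRecord(rid, category, family, canonical(str(rec.seq))))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_collapsed_fasta(counts: dict[str, int], path: str | Path, prefix: str = "tag") -> None:
    """Write unique sequences with ``>tag<n>_x<count>`` headers.

    Sequences are emitted in descending count order (ties broken by
    sequence) so output is deterministic.
    """
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(ordered, start=1):
            fh.write(f">{prefix}{i}_x{n}\n{seq}\n")


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    """Write plain 4-line FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def iter_reads(path: str | Path) -> Iterator[tuple[str, int]]:
    """Yield ``(sequence, count)`` pairs from FASTQ or (collapsed) FASTA.

    FASTQ reads count 1 each; FASTA headers ending in ``_x<count>`` carry
    their multiplicity, other FASTA records count 1. Sequences are returned
    raw (not validated) so the collapser can report parse errors with read
    numbers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        count = 1
        if fmt == "fasta":
            m = _COUNT_SUFFIX.search(rec.id)
            if m:
                count = int(m.group(1))
        yield str(rec.seq), count
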