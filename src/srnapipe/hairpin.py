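"""Novel-miRNA hairpin screening.

Plant miRNA precursors are recognizable by their ability to fold into a
stem-loop in which the mature sequence sits on one arm and pairs almost
completely with the opposite arm. This module screens genome-matched,
otherwise unannotated tags by folding candidate precursor windows around
each genomic hit and applying strict geometric and stability criteria.

Folding is a weighted base-pair-maximization dynamic program (GC=3, AU=2,
GU=1, minimum loop 3, nested structures only) with a deterministic
traceback. It is not a thermodynamic model: the criteria only need the
stem-loop geometry plus a stability proxy, and the backend is pluggable
(``fold_backend`` argument) so a true MFE folder such as ViennaRNA can be
substituted where available.

The stability criterion compares the weighted pair sum of the candidate
against the mean over dinucleotide-shuffled versions of itself; the
shuffle preserves dinucleotide counts exactly (Euler-walk shuffle), which
is the accepted way to control for composition and local stacking bias.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from srnapipe.seqio import ParseError, canonical, is_valid_nt, revcomp
from srnapipe.tags import Tag

#: pair weights on encoded bases A=0, C=1, G=2, T=3
PAIR_WEIGHTS = np.zeros((4, 4), dtype=np.int64)
PAIR_WEIGHTS[2, 1] = PAIR_WEIGHTS[1, 2] = 3  # G:C
PAIR_WEIGHTS[0, 3] = PAIR_WEIGHTS[3, 0] = 2  # A:U
PAIR_WEIGHTS[2, 3] = PAIR_WEIGHTS[3, 2] = 1  # G:U wobble

MIN_LOOP = 3

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


@dataclass
class FoldResult:
    """Secondary structure from the weighted pair-maximization fold."""

    structure: str
    pairs: np.ndarray  # partner index per position, -1 if unpaired
    pair_count: int
    score: int  # weighted pair sum (the stability proxy)


@dataclass
class Window:
    """A candidate precursor window extracted around a genomic hit."""

    seq: str
    mature_start: int  # mature position within the window, 0-based
    mature_end: int  # inclusive
    genome_id: str
    genome_start: int
    strand: str


@dataclass
class HairpinCandidate:
    """A folded precursor window with per-criterion pass/fail flags."""

    locus_id: str
    precursor: str
    structure: str
    pairing_score: int  # number of base pairs
    stability: float  # weighted pair sum
    mature_start: int
    mature_end: int  # inclusive
    arm: str  # "5p" | "3p" | ""
    mature_in_one_arm: bool = False
    duplex_pairing_ok: bool = False
    loop_ok: bool = False
    stability_ok: bool = False
    shuffle_ratio: float = float("nan")
    count_fp: int = 0
    count_sp: int = 0
    low_abundance: bool = False
    window: Window | None = field(default=None, repr=False)

    @property
    def passes(self) -> bool:
        return (
            self.mature_in_one_arm
            and self.duplex_pairing_ok
            and self.loop_ok
            and self.stability_ok
        )


@njit(cache=True)
def _nussinov(codes, weights, min_loop):  # pragma: no cover - exercised via fold_rna
    n = codes.shape[0]
    S = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = S[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = weights[codes[i], codes[k]]
                if w > 0:
                    v = w
                    if i + 1 <= k - 1:
                        v += S[i + 1, k - 1]
                    if k + 1 <= j:
                        v += S[k + 1, j]
                    if v > best:
                        best = v
            S[i, j] = best
    return S


@njit(cache=True)
def _traceback(S, codes, weights, min_loop):  # pragma: no cover
    n = codes.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or j - i <= min_loop:
            continue
        target = S[i, j]
        # prefer pairing i with the outermost partner achieving the optimum;
        # fall back to leaving i unpaired (deterministic tie-break)
        found = False
        for k in range(j, i + min_loop, -1):
            w = weights[codes[i], codes[k]]
            if w > 0:
                v = w
                if i + 1 <= k - 1:
                    v += S[i + 1, k - 1]
                if k + 1 <= j:
                    v += S[k + 1, j]
                if v == target:
                    pairs[i] = k
                    pairs[k] = i
                    if i + 1 <= k - 1:
                        stack_i[top] = i + 1
                        stack_j[top] = k - 1
                        top += 1
                    if k + 1 <= j:
                        stack_i[top] = k + 1
                        stack_j[top] = j
                        top += 1
                    found = True
                    break
        if not found:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
    return pairs


def _encode(seq: str) -> np.ndarray:
    seq = canonical(seq)
    if not seq or not is_valid_nt(seq):
        raise ParseError(f"non-nucleotide character in sequence {seq!r}")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return codes.astype(np.int64)


def fold_score(seq: str, min_loop: int = MIN_LOOP) -> int:
    """Weighted pair sum of the optimal nested structure (score only)."""
    codes = _encode(seq)
    if len(codes) <= min_loop:
        return 0
    return int(_nussinov(codes, PAIR_WEIGHTS, min_loop)[0, -1])


def fold_rna(seq: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold a sequence by weighted base-pair maximization.

    Maximizes the weighted pair sum (GC=3, AU=2, GU=1) over pseudoknot-free
    structures with at least ``min_loop`` unpaired bases in every hairpin
    loop; the traceback prefers outermost pairings, so it is deterministic.
    """
    codes = _encode(seq)
    n = len(codes)
    if n <= min_loop:
        return FoldResult("." * n, np.full(n, -1, dtype=np.int64), 0, 0)
    S = _nussinov(codes, PAIR_WEIGHTS, min_loop)
    pairs = _traceback(S, codes, PAIR_WEIGHTS, min_loop)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    return FoldResult(structure, pairs, int((pairs >= 0).sum()) // 2, int(S[0, -1]))


def vienna_fold_backend(scale: float = 10.0) -> Callable[[str], FoldResult]:
    """Adapter turning ViennaRNA's MFE fold into a :class:`FoldResult`.

    Requires the ``RNA`` Python bindings. The stability proxy is the
    negated free energy times ``scale`` (criteria only use score ratios,
    so the unit is immaterial). Drop the result into ``fold_backend`` of
    :func:`apply_criteria` to screen with a thermodynamic model instead of
    the pair-maximization default.
    """
    import RNA  # deferred: optional backend

    def _fold(seq: str) -> FoldResult:
        structure, mfe = RNA.fold(seq.replace("T", "U"))
        pairs = np.full(len(seq), -1, dtype=np.int64)
        stack: list[int] = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pairs[i], pairs[j] = j, i
        score = max(0, int(round(-mfe * scale)))
        return FoldResult(structure, pairs, int((pairs >= 0).sum()) // 2, score)

    return _fold


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts exactly.

    Euler-walk shuffle: adjacent-pair edges are permuted per source
    nucleotide and the walk is accepted only if it consumes every edge
    (rejection sampling keeps the implementation simple and exact).
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    n_edges = len(seq) - 1
    while True:
        pools = {v: [lst[i] for i in rng.permutation(len(lst))] for v, lst in edges.items()}
        out = [seq[0]]
        cur = seq[0]
        for _ in range(n_edges):
            pool = pools.get(cur)
            if not pool:
                break
            cur = pool.pop()
            out.append(cur)
        if len(out) == len(seq):
            return "".join(out)


def extract_windows(
    hit_start: int,
    hit_end: int,
    genome_seq: str,
    flank: int,
    genome_id: str = "genome",
    strand: str = "+",
) -> list[Window]:
    """Candidate precursor windows around a genomic hit.

    Emits the left-extended window ``[hit-flank, hit_end]``, the
    right-extended window ``[hit, hit_end+flank]`` and the symmetric window
    ``[hit-flank, hit_end+flank]``, clipped to the genome bounds.
    ``hit_end`` is exclusive. Minus-strand hits are reverse-complemented so
    the mature always appears in sense orientation within the window.
    """
    if hit_start < 0 or hit_end > len(genome_seq) or hit_start >= hit_end:
        raise ValueError("genomic hit absent or out of bounds")
    mat_len = hit_end - hit_start
    spans = [
        (max(0, hit_start - flank), hit_end),
        (hit_start, min(len(genome_seq), hit_end + flank)),
        (max(0, hit_start - flank), min(len(genome_seq), hit_end + flank)),
    ]
    windows = []
    seen = set()
    for ws, we in spans:
        if (ws, we) in seen:
            continue
        seen.add((ws, we))
        seq = genome_seq[ws:we]
        m0 = hit_start - ws
        m1 = m0 + mat_len - 1
        if strand == "-":
            seq = revcomp(seq)
            m0, m1 = len(seq) - 1 - m1, len(seq) - 1 - m0
        windows.append(Window(seq, m0, m1, genome_id, ws, strand))
    return windows


def _mature_geometry(fold: FoldResult, m0: int, m1: int) -> tuple[bool, bool, str]:
    """Evaluate arm placement and duplex pairing of the mature interval.

    Returns (mature_in_one_arm, duplex_pairing_ok, arm). The mature is on
    one arm iff none of its bases pairs with another mature base (which
    would mean the mature straddles the terminal loop) and all partners lie
    on the same side of the interval.
    """
    partners = fold.pairs[m0 : m1 + 1]
    mat_len = m1 - m0 + 1
    paired = partners >= 0
    n_paired = int(paired.sum())
    self_paired = bool(((partners >= m0) & (partners <= m1)).any())
    outside = partners[paired]
    left = (outside < m0).sum()
    right = (outside > m1).sum()
    one_side = n_paired > 0 and (left == 0 or right == 0) and not self_paired
    arm = ""
    if one_side:
        arm = "5p" if right > 0 else "3p"
    # duplex pairing: >= 75% of mature bases paired, <= 4 unpaired, and no
    # internal unpaired run (bulge) longer than 2 nt
    n_unpaired = mat_len - n_paired
    runs = []
    run = 0
    seen_paired = False
    for p in paired:
        if not p:
            run += 1
        else:
            if run and seen_paired:  # runs at either end are ends, not bulges
                runs.append(run)
            run = 0
            seen_paired = True
    max_internal_bulge = max(runs) if runs else 0
    duplex_ok = (
        n_paired / mat_len >= 0.75 and n_unpaired <= 4 and max_internal_bulge <= 2
    )
    return one_side, duplex_ok, arm


def apply_criteria(
    precursor: str,
    mature_start: int,
    mature_end: int,
    locus_id: str = "candidate",
    *,
    min_len: int = 60,
    max_len: int = 300,
    n_shuffles: int = 100,
    shuffle_margin: float = 0.15,
    shuffle_seed: int = 0,
    skip_stability: bool = False,
    fold_backend: Callable[[str], FoldResult] = fold_rna,
) -> HairpinCandidate:
    """Fold a candidate precursor and apply the stem-loop criteria.

    A candidate passes iff (a) the mature lies entirely on one arm, (b) at
    least 75% of its bases pair to the opposite arm with at most 4 unpaired
    bases and no internal bulge longer than 2 nt, (c) the precursor length
    is within [min_len, max_len], and (d) the weighted pair sum is at least
    ``1 + shuffle_margin`` times the mean over ``n_shuffles`` dinucleotide
    shuffles of the precursor. ``mature_end`` is inclusive, 0-based within
    the precursor. ``skip_stability`` short-circuits the (expensive) shuffle
    test when the geometric flags already fail.
    """
    precursor = canonical(precursor)
    if not (0 <= mature_start <= mature_end < len(precursor)):
        raise ValueError("mature interval not found inside the precursor")
    fold = fold_backend(precursor)
    one_arm, duplex_ok, arm = _mature_geometry(fold, mature_start, mature_end)
    length_ok = min_len <= len(precursor) <= max_len
    cand = HairpinCandidate(
        locus_id=locus_id,
        precursor=precursor,
        structure=fold.structure,
        pairing_score=fold.pair_count,
        stability=float(fold.score),
        mature_start=mature_start,
        mature_end=mature_end,
        arm=arm,
        mature_in_one_arm=one_arm,
        duplex_pairing_ok=duplex_ok,
        loop_ok=length_ok,
    )
    if skip_stability and not (one_arm and duplex_ok and length_ok):
        return cand
    rng = np.random.default_rng([shuffle_seed, len(precursor)])
    shuffled = [
        fold_backend(dinucleotide_shuffle(precursor, rng)).score for _ in range(n_shuffles)
    ]
    mean_shuffled = float(np.mean(shuffled)) if shuffled else 0.0
    cand.shuffle_ratio = fold.score / mean_shuffled if mean_shuffled > 0 else float("inf")
    cand.stability_ok = fold.score >= (1.0 + shuffle_margin) * mean_shuffled
    return cand


def _find_hits(tag_seq: str, genome: list[tuple[str, str]]) -> list[tuple[str, int, int, str]]:
    hits = []
    for gid, gseq in genome:
        for strand, query in (("+", tag_seq), ("-", revcomp(tag_seq))):
            start = gseq.find(query)
            while start != -1:
                hits.append((gid, start, start + len(query), strand))
                start = gseq.find(query, start + 1)
    return hits


def screen_novel(
    tags: list[Tag],
    genome: list[tuple[str, str]],
    records,
    *,
    flanks: Sequence[int] = (25, 50, 100, 150),
    low_abundance_threshold: int = 40,
    **criteria_kwargs,
) -> list[HairpinCandidate]:
    """Screen genome-matched tags for novel miRNA hairpin loci.

    Only tags categorized ``genome_matched`` by the annotation waterfall are
    considered. For every genomic hit, candidate precursor windows are
    extracted at several flank extents (precursor boundaries are unknown a
    priori, so a grid of extents is tried, mimicking how precursor-folding
    screens probe the flanking sequence); a tag is reported if any window
    passes :func:`apply_criteria`, with the best-passing window (highest
    shuffle ratio) retained. Results are sorted by total read count
    descending; candidates below ``low_abundance_threshold`` total reads
    are flagged, since low-frequency candidates warrant experimental
    confirmation.
    """
    eligible = {r.sequence for r in records if r.category == "genome_matched"}
    genome_dict = dict(genome)
    min_len = criteria_kwargs.get("min_len", 60)
    max_len = criteria_kwargs.get("max_len", 300)
    out = []
    for tag in sorted(tags, key=lambda t: (-t.total, t.sequence)):
        if tag.sequence not in eligible:
            continue
        best: HairpinCandidate | None = None
        for gid, hs, he, strand in _find_hits(tag.sequence, genome):
            for flank in flanks:
                for win in extract_windows(hs, he, genome_dict[gid], flank, gid, strand):
                    if not (min_len <= len(win.seq) <= max_len):
                        continue
                    cand = apply_criteria(
                        win.seq,
                        win.mature_start,
                        win.mature_end,
                        locus_id=f"{gid}:{win.genome_start}:{strand}",
                        skip_stability=True,
                        **criteria_kwargs,
                    )
                    cand.window = win
                    if cand.passes and (
                        best is None or cand.shuffle_ratio > best.shuffle_ratio
                    ):
                        best = cand
        if best is not None:
            best.count_fp = tag.count_fp
            best.count_sp = tag.count_sp
            best.low_abundance = tag.total < low_abundance_threshold
            out.append(best)
    return out
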