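"""Plant miRNA target prediction by complementarity expectation scoring.

Plant miRNAs typically bind a single, near-perfectly complementary site in
the coding region of their target. Candidate sites are scored with an
expectation penalty in the style of the Allen et al. / psRNATarget
scheme: each mismatch costs 1, each G:U wobble 0.5 and each gap 2, with
penalties doubled within the seed region (miRNA positions 2-13, numbered
from the 5' end); lower expectation means better complementarity and only
sites at or below a configurable maximum expectation are reported.

The regulation mode is inferred from the central region: any non-match
(mismatch, G:U or gap) at miRNA positions 9-11 — the slicing site —
suggests translational inhibition rather than cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from srnapipe.seqio import canonical

MATCH, MISMATCH, GU, GAP = "match", "mismatch", "G:U", "gap"

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ScoringParams:
    """Expectation-scoring parameters (all penalties >= 0).

    ``seed_start``/``seed_end`` delimit the seed interval on the miRNA in
    1-based 5'->3' coordinates; penalties inside it are multiplied by
    ``seed_multiplier``. ``max_expectation`` is the reporting cutoff
    (sensible values lie in 1-5; 3.0 is a mid-stringency default) and
    ``max_gu_seed`` caps the number of G:U wobbles tolerated in the seed.
    """

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_start: int = 2
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_expectation: float = 3.0
    max_gu_seed: int = 2

    def __post_init__(self):
        if min(self.mismatch_penalty, self.gu_penalty, self.gap_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        if not (1.0 <= self.max_expectation <= 5.0):
            raise ValueError("max_expectation outside the sensible 1-5 range")


@dataclass
class TargetAlignment:
    """One miRNA-transcript complementarity hit.

    ``states`` holds one state per miRNA position (1-based index i maps to
    ``states[i-1]``); a target-bulge gap is recorded as an extra ``gap``
    entry at the position it interrupts. Transcript coordinates are 1-based
    inclusive.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    states: list[str] = field(repr=False)
    expectation: float = 0.0
    mode: str = "cleavage"
    mirna_seq: str = field(default="", repr=False)
    site_seq: str = field(default="", repr=False)

    def render(self) -> str:
        """Three-line text alignment: target 5'->3', pairing, miRNA 3'->5'."""
        sym = {MATCH: "|", GU: "o", MISMATCH: " ", GAP: "-"}
        pairing = "".join(sym[s] for s in reversed(self.states))
        return (
            f"target 5' {self.site_seq} 3'\n"
            f"          {pairing}\n"
            f"miRNA  3' {self.mirna_seq[::-1]} 5'"
        )


def _pair_state(m_base: str, t_base: str) -> str:
    if _COMP[m_base] == t_base:
        return MATCH
    if (m_base == "G" and t_base == "T") or (m_base == "T" and t_base == "G"):
        return GU
    return MISMATCH


def _position_multiplier(i: int, params: ScoringParams) -> float:
    return params.seed_multiplier if params.seed_start <= i <= params.seed_end else 1.0


def score_site(mirna: str, site: str, params: ScoringParams) -> tuple[float, list[str]] | None:
    """Score a gapless antiparallel duplex of a miRNA against a target site.

    ``site`` is the transcript subsequence 5'->3' with ``len(site) ==
    len(mirna)``; miRNA position i (1-based from its 5' end) faces site
    position ``len - i`` (0-based). Returns ``(expectation, states)`` or
    None once the running penalty exceeds ``max_expectation`` (early exit)
    or the seed G:U allowance is exhausted.
    """
    L = len(mirna)
    states = [MATCH] * L
    expectation = 0.0
    gu_seed = 0
    for i in range(1, L + 1):
        state = _pair_state(mirna[i - 1], site[L - i])
        states[i - 1] = state
        if state is MATCH:
            continue
        penalty = params.gu_penalty if state is GU else params.mismatch_penalty
        expectation += penalty * _position_multiplier(i, params)
        if state is GU and params.seed_start <= i <= params.seed_end:
            gu_seed += 1
            if gu_seed > params.max_gu_seed:
                return None
        if expectation > params.max_expectation:
            return None
    return expectation, states


def _score_gapped(
    mirna: str, window: str, params: ScoringParams
) -> tuple[float, list[str]] | None:
    """Best single-gap alignment of the miRNA against a window.

    Two variants are tried at every internal position: a miRNA bulge (one
    miRNA base unpaired; ``len(window) == len(mirna) - 1``) and a target
    bulge (one transcript base unpaired; ``len(window) == len(mirna) + 1``).
    The gap penalty takes the seed multiplier of the miRNA position it
    interrupts.
    """
    L = len(mirna)
    best: tuple[float, list[str]] | None = None
    if len(window) == L - 1:
        kind = "mirna"
    elif len(window) == L + 1:
        kind = "target"
    else:
        return None
    for g in range(2, L):  # 1-based miRNA position carrying the gap
        expectation = _position_multiplier(g, params) * params.gap_penalty
        if expectation > params.max_expectation:
            continue
        states: list[str] = [MATCH] * L
        gu_seed = 0
        ok = True
        t_idx = len(window)  # next site index to consume, walking target 3'->5'
        for i in range(1, L + 1):
            if kind == "mirna" and i == g:
                states[g - 1] = GAP  # miRNA base bulged out, no target base
                continue
            if kind == "target" and i == g:
                t_idx -= 1  # bulged target base skipped, charged to position g
            t_idx -= 1
            if t_idx < 0:
                ok = False
                break
            state = _pair_state(mirna[i - 1], window[t_idx])
            states[i - 1] = state
            if state is MATCH:
                continue
            penalty = params.gu_penalty if state is GU else params.mismatch_penalty
            expectation += penalty * _position_multiplier(i, params)
            if state is GU and params.seed_start <= i <= params.seed_end:
                gu_seed += 1
                if gu_seed > params.max_gu_seed:
                    ok = False
                    break
            if expectation > params.max_expectation:
                ok = False
                break
        if kind == "target" and ok and states[g - 1] == MATCH:
            states[g - 1] = GAP  # the bulge disrupts pairing at this position
        if ok and t_idx == 0 and (best is None or expectation < best[0]):
            best = (expectation, states)
    return best


def classify_mode(states: list[str], central: tuple[int, int] = (9, 11)) -> str:
    """Cleavage vs translational inhibition from the central region.

    Any non-match state at miRNA positions 9-11 (the slicing site) implies
    translational inhibition; perfect central pairing implies cleavage.
    """
    lo, hi = central
    for i in range(lo, hi + 1):
        if i - 1 < len(states) and states[i - 1] != MATCH:
            return "translational_inhibition"
    return "cleavage"


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: list[tuple[str, str]],
    params: ScoringParams | None = None,
    allow_gaps: bool = True,
) -> list[TargetAlignment]:
    """Scan a transcript set for complementarity sites of one miRNA.

    Every site with expectation <= ``params.max_expectation`` is reported;
    overlapping hits on the same transcript are reduced to the best
    (lowest-expectation) one. Single-gap alignments extend the gapless scan
    when ``allow_gaps`` is set.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    params = params or ScoringParams()
    mirna = canonical(mirna_seq)
    if not (18 <= len(mirna) <= 26):
        raise ValueError("miRNA length outside 18-26 nt")
    L = len(mirna)
    raw_hits: list[TargetAlignment] = []
    for tid, tseq in transcripts:
        tseq = canonical(tseq)
        for start in range(0, len(tseq) - L + 1):
            site = tseq[start : start + L]
            scored = score_site(mirna, site, params)
            if scored is not None:
                exp, states = scored
                raw_hits.append(
                    TargetAlignment(
                        mirna_id, tid, start + 1, start + L, states, exp,
                        classify_mode(states), mirna, site,
                    )
                )
        if allow_gaps:
            for w_len in (L - 1, L + 1):
                for start in range(0, len(tseq) - w_len + 1):
                    window = tseq[start : start + w_len]
                    scored = _score_gapped(mirna, window, params)
                    if scored is not None:
                        exp, states = scored
                        raw_hits.append(
                            TargetAlignment(
                                mirna_id, tid, start + 1, start + w_len, states, exp,
                                classify_mode(states), mirna, window,
                            )
                        )
    return _dedupe_overlaps(raw_hits)


def _dedupe_overlaps(hits: list[TargetAlignment]) -> list[TargetAlignment]:
    """Keep the best hit among mutually overlapping sites per transcript.

    Sorting by (expectation, gap count, start) and keeping greedily makes
    the reduction deterministic; a perfect gapless site therefore shadows
    its gapped near-duplicates.
    """
    hits = sorted(
        hits,
        key=lambda h: (h.expectation, sum(s == GAP for s in h.states), h.transcript_id, h.start),
    )
    kept: list[TargetAlignment] = []
    for h in hits:
        clash = any(
            k.transcript_id == h.transcript_id and not (h.end < k.start or h.start > k.end)
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.expectation, h.transcript_id, h.start))
    return kept


def summarize_targets(
    alignments: list[TargetAlignment], max_per_mirna: int | None = None
) -> pd.DataFrame:
    """Per-miRNA target table sorted by ascending expectation.

    Ties are ordered by transcript id; ``max_per_mirna`` truncates each
    miRNA's hit list. The ``n_targets`` column carries the number of
    distinct target transcripts per miRNA.
    """
    rows = [
        {
            "mirna": a.mirna_id,
            "transcript": a.transcript_id,
            "start": a.start,
            "end": a.end,
            "expectation": a.expectation,
            "mode": a.mode,
        }
        for a in alignments
    ]
    df = pd.DataFrame(
        rows, columns=["mirna", "transcript", "start", "end", "expectation", "mode"]
    )
    if df.empty:
        df["n_targets"] = pd.Series(dtype=int)
        return df
    df = df.sort_values(["mirna", "expectation", "transcript", "start"]).reset_index(drop=True)
    if max_per_mirna is not None:
        df = df.groupby("mirna", group_keys=False).head(max_per_mirna).reset_index(drop=True)
    df["n_targets"] = df.groupby("mirna")["transcript"].transform("nunique")
    return df
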