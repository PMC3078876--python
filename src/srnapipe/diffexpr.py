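"""Two-library differential expression of miRNA counts.

One pooled sequencing library per condition means no replicate-based
dispersion estimate is available; the appropriate test is the
Audic-Claverie exact test for digital expression profiles. Conditional on
the pooled count n = x + y of a miRNA, the second-library count y is
Binomial(n, q) with q = N2/(N1+N2) under the null hypothesis of equal
relative abundance, where N1 and N2 are the library clean-read totals.
The two-sided p-value doubles the smaller tail and is capped at 1.

Counts are reported as reads per million (RPM); a zero count is floored at
0.01 RPM so that log2 fold-changes stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

RPM_FLOOR = 0.01


@dataclass(frozen=True)
class DiffExprRecord:
    """One miRNA's counts, normalized values, fold-change and test result."""

    mirna: str
    count_fp: int
    count_sp: int
    rpm_fp: float
    rpm_sp: float
    log2fc: float
    p_value: float
    significance: str  # "" | "*" | "**"
    de_call: bool


def rpm_normalize(count: int, library_total: int, floor: float = RPM_FLOOR) -> float:
    """Reads-per-million normalization with a zero-count floor.

    Returns ``count / library_total * 1e6``; a zero count returns ``floor``
    (default 0.01) so downstream ratios are finite.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return floor
    return count / library_total * 1e6


def log2_fold_change(x: int, y: int, n1: int, n2: int, floor: float = RPM_FLOOR) -> float:
    """log2(SP/FP) of the floored, unrounded normalized values."""
    return math.log2(rpm_normalize(y, n2, floor) / rpm_normalize(x, n1, floor))


def poisson_exact_test(x: int, y: int, n1: int, n2: int) -> float:
    """Audic-Claverie two-library exact test.

    Conditional on n = x + y, y ~ Binomial(n, q) with q = N2/(N1+N2) under
    the null. Returns the two-sided p-value
    ``min(1, 2 * min(P(Y <= y), P(Y >= y)))``, computed in log space via
    the log-gamma based binomial tails so counts of order 1e5 do not
    underflow intermediate terms.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    n = x + y
    if n == 0:
        return 1.0
    q = n2 / (n1 + n2)
    log_lower = binom.logcdf(y, n, q)  # P(Y <= y)
    log_upper = binom.logsf(y - 1, n, q)  # P(Y >= y)
    log_p = math.log(2.0) + min(log_lower, log_upper)
    return min(1.0, float(np.exp(log_p)))


def build_diff_table(
    counts: dict[str, tuple[int, int]] | list[tuple[str, tuple[int, int]]],
    n1: int,
    n2: int,
    *,
    floor: float = RPM_FLOOR,
    alpha_star: float = 0.05,
    alpha_double_star: float = 0.01,
    fold_threshold: float = 1.0,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Differential-expression table, one row per miRNA.

    ``counts`` maps miRNA id to its (FP, SP) raw counts. Significance marks
    follow the usual convention: ``**`` for p < 0.01, ``*`` for
    0.01 <= p < 0.05. A differential-expression call (``de_call``)
    additionally requires ``|log2fc| >= fold_threshold``, i.e. at least a
    two-fold change by default. ``bh_column`` adds Benjamini-Hochberg
    adjusted p-values as an optional extra column.
    """
    items = list(counts.items()) if hasattr(counts, "items") else list(counts)
    ids = [mid for mid, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate miRNA ids")
    rows = []
    for mid, (x, y) in items:
        p = poisson_exact_test(x, y, n1, n2)
        lfc = log2_fold_change(x, y, n1, n2, floor)
        mark = "**" if p < alpha_double_star else ("*" if p < alpha_star else "")
        rows.append(
            {
                "mirna": mid,
                "count_fp": x,
                "count_sp": y,
                "rpm_fp": rpm_normalize(x, n1, floor),
                "rpm_sp": rpm_normalize(y, n2, floor),
                "log2fc": lfc,
                "p_value": p,
                "significance": mark,
                "de_call": p < alpha_double_star and abs(lfc) >= fold_threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "count_fp",
            "count_sp",
            "rpm_fp",
            "rpm_sp",
            "log2fc",
            "p_value",
            "significance",
            "de_call",
        ],
    ).set_index("mirna")
    if bh_column and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
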