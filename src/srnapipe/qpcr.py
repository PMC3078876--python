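"""Relative qRT-PCR quantification by the 2^-ddCt method.

Threshold cycles (CT) are normalized against a reference gene within each
sample (dCt = CT_target - CT_reference) and the treated sample is compared
to the control (ddCt = dCt_treated - dCt_control); the relative expression
is 2^-ddCt. Replicate CTs are averaged arithmetically before dCt.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ["sample", "gene", "replicate", "ct"]
DEFAULT_REFERENCE = "18S_rRNA"


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Load a TSV of CT values with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return df


def _mean_ct(ct: pd.DataFrame, sample: str, gene: str) -> float:
    rows = ct[(ct["sample"] == sample) & (ct["gene"] == gene)]
    if rows.empty:
        raise ValueError(f"no CT values for gene {gene!r} in sample {sample!r}")
    return float(rows["ct"].mean())


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    treated: str,
    control: str,
    reference_gene: str = DEFAULT_REFERENCE,
) -> float:
    """2^-ddCt relative expression of ``target_gene`` in treated vs control.

    Raises a ValueError naming the sample if the reference gene is missing
    from it. Adding a constant to every CT leaves the result unchanged
    (only CT differences enter).
    """
    for sample in (treated, control):
        if ct[(ct["sample"] == sample) & (ct["gene"] == reference_gene)].empty:
            raise ValueError(f"reference gene {reference_gene!r} missing in sample {sample!r}")
    d_treated = _mean_ct(ct, treated, target_gene) - _mean_ct(ct, treated, reference_gene)
    d_control = _mean_ct(ct, control, target_gene) - _mean_ct(ct, control, reference_gene)
    return 2.0 ** -(d_treated - d_control)
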