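"""Gene Ontology tabulation for predicted miRNA targets.

The mapping is a user-supplied (or synthetic) 3-column TSV
``gene<TAB>ontology<TAB>term`` with ontology restricted to the three GO
hierarchies; no live database retrieval is performed, which keeps results
reproducible across database releases.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd

ONTOLOGIES = ("biological_process", "molecular_function", "cellular_component")


def load_go_mapping(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Parse the 3-column mapping file into gene -> [(ontology, term)].

    An unknown ontology string raises a ValueError carrying the line
    number.
    """
    mapping: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
            gene, ontology, term = parts
            if ontology not in ONTOLOGIES:
                raise ValueError(f"line {lineno}: unknown ontology {ontology!r}")
            mapping.setdefault(gene, []).append((ontology, term))
    return mapping


def go_tabulate(
    genes: list[str], mapping: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Count genes per GO term within each hierarchy.

    Returns a frame with columns ``ontology``, ``term``, ``count`` sorted
    by descending count (ties by term) within each hierarchy. Genes with no
    mapping at all are tallied in a single ``unannotated`` row.
    """
    counts: Counter = Counter()
    n_unannotated = 0
    for gene in genes:
        assigned = mapping.get(gene, [])
        if not assigned:
            n_unannotated += 1
            continue
        for ontology, term in assigned:
            counts[(ontology, term)] += 1
    rows = [
        {"ontology": o, "term": t, "count": c} for (o, t), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["ontology", "term", "count"])
    if not df.empty:
        df["ontology"] = pd.Categorical(df["ontology"], categories=ONTOLOGIES, ordered=True)
        df = df.sort_values(
            ["ontology", "count", "term"], ascending=[True, False, True]
        ).reset_index(drop=True)
        df["ontology"] = df["ontology"].astype(str)
    if n_unannotated:
        df = pd.concat(
            [df, pd.DataFrame([{"ontology": "unannotated", "term": "unannotated", "count": n_unannotated}])],
            ignore_index=True,
        )
    return df
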