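"""Report rendering: TSV tables plus a reproducibility manifest.

The manifest records the package version, the run seed, a hash of the
configuration and the checksum of every written table, so identical runs
are verifiably identical and any config change is visible as a manifest
change.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from srnapipe import __version__ as _version


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config) -> str:
    """Stable hash of a configuration mapping/dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def render_report(
    outdir: str | Path,
    *,
    overlap=None,
    annotation_summary: pd.DataFrame | None = None,
    diff_table: pd.DataFrame | None = None,
    length_hist: pd.DataFrame | None = None,
    novel_candidates=None,
    target_table: pd.DataFrame | None = None,
    go_counts: pd.DataFrame | None = None,
    config=None,
    seed: int | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Write every provided stage output as TSV and a JSON manifest.

    At least one stage output must be given. Numeric rendering follows the
    conventional table precision: percentages, mean frequencies, RPM and
    log2 fold-changes to 2 decimals, p-values in scientific notation.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if overlap is not None:
        table = overlap.table if hasattr(overlap, "table") else overlap
        path = outdir / "table1_overlap.tsv"
        table.to_csv(path, sep="\t", float_format="%.2f")
        written["overlap"] = path
    if annotation_summary is not None:
        path = outdir / "table2_annotation.tsv"
        annotation_summary.to_csv(path, sep="\t", float_format="%.2f")
        written["annotation_summary"] = path
    if diff_table is not None:
        path = outdir / "table3_diffexpr.tsv"
        df = diff_table.copy()
        for col in ("rpm_fp", "rpm_sp", "log2fc"):
            if col in df:
                df[col] = df[col].map(lambda v: f"{v:.2f}")
        if "p_value" in df:
            df["p_value"] = df["p_value"].map(lambda v: f"{v:.2E}")
        df.to_csv(path, sep="\t")
        written["diff_table"] = path
    if length_hist is not None:
        path = outdir / "length_distribution.tsv"
        length_hist.to_csv(path, sep="\t", float_format="%.4f")
        written["length_hist"] = path
    if novel_candidates is not None:
        path = outdir / "novel_candidates.tsv"
        rows = [
            {
                "locus_id": c.locus_id,
                "count_fp": c.count_fp,
                "count_sp": c.count_sp,
                "low_abundance": c.low_abundance,
                "arm": c.arm,
                "pairing_score": c.pairing_score,
                "stability": c.stability,
                "shuffle_ratio": round(c.shuffle_ratio, 3),
                "precursor": c.precursor,
                "structure": c.structure,
            }
            for c in novel_candidates
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["novel_candidates"] = path
        vienna = outdir / "novel_candidates.str"
        with open(vienna, "w") as fh:
            for c in novel_candidates:
                fh.write(f">{c.locus_id}\n{c.precursor}\n{c.structure}\n")
        written["novel_structures"] = vienna
    if target_table is not None:
        path = outdir / "target_predictions.tsv"
        target_table.to_csv(path, sep="\t", index=False, float_format="%.1f")
        written["target_table"] = path
    if go_counts is not None:
        path = outdir / "go_counts.tsv"
        go_counts.to_csv(path, sep="\t", index=False)
        written["go_counts"] = path

    if not written:
        raise ValueError("no stage output provided to render")

    manifest = {
        "tool": "srnapipe",
        "version": _version,
        "seed": seed,
        "config_sha256": config_hash(config) if config is not None else None,
        "tables": {k: {"path": p.name, "sha256": _sha256_file(p)} for k, p in written.items()},
        "inputs": {
            k: {"path": str(p), "sha256": _sha256_file(Path(p))}
            for k, p in (input_paths or {}).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def plot_length_distribution(length_hist: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of the per-library size distribution (18-30 nt)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = length_hist[["fraction_fp", "fraction_sp"]].plot.bar(figsize=(7, 4))
    ax.set_xlabel("tag length (nt)")
    ax.set_ylabel("fraction of clean reads")
    ax.legend(["FP", "SP"])
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
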