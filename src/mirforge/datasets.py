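"""Bundled example datasets.

``smi_degradome_targets`` is the curated table of degradome-validated
miRNA target transcripts in *Salvia miltiorrhiza* with plant-homologous
annotations: one row per (miRNA variant, target EST), with the transcript
length and the homology-based functional annotation.  The miRNA column uses
the end-offset variant naming convention and exercises its parser on real
published names.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["smi_degradome_targets", "summarize_targets"]


def smi_degradome_targets() -> pd.DataFrame:
    """The curated *S. miltiorrhiza* degradome target table."""
    ref = resources.files("mirforge").joinpath("data/smi_degradome_targets.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_targets(sites: pd.DataFrame) -> dict:
    """Headline counts of a target table: distinct target transcripts,
    distinct miRNAs, and (when present) the per-category histogram."""
    out = {
        "n_targets": int(sites["transcript"].nunique()),
        "n_mirnas": int(sites["mirna"].nunique()),
    }
    if "category" in sites.columns:
        per_cat = (
            sites.drop_duplicates(["mirna", "transcript"])
            .groupby("category")["transcript"]
            .count()
        )
        out["category_counts"] = {int(k): int(v) for k, v in per_cat.items()}
    return out
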