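"""Expression-level analyses: normalization, tissue partitioning,
differential tests with Z-value calls, and comparative-Ct qPCR.

Counts are normalized to counts per million of clean reads per library.
Differential expression of a miRNA across libraries without replicates is
tested by a chi-squared goodness-of-fit of its counts against expectations
proportional to the library totals; with replicate columns per tissue a
one-way ANOVA on log2(CPM + 1) is used instead.  A per-library Z-value (the
row-standardized normalized count) supports up/down calls at p <= 0.01 and
|Z| > 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize",
    "tissue_partition",
    "diff_test",
    "z_values",
    "make_calls",
    "differential_expression",
    "delta_delta_ct",
]


def normalize(
    counts: pd.DataFrame, library_totals: pd.Series | None = None, scale: float = 1e6
) -> pd.DataFrame:
    """Counts-per-million normalization (rows: miRNAs, columns: libraries).

    ``library_totals`` defaults to the column sums of ``counts``; pass the
    clean-read totals of the libraries when the matrix is a subset.
    """
    totals = library_totals if library_totals is not None else counts.sum(axis=0)
    totals = pd.Series(totals, index=counts.columns, dtype=float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"library total must be > 0, offending: {bad}")
    return counts * scale / totals


def tissue_partition(
    counts: pd.DataFrame, presence_threshold: int = 1
) -> pd.Series:
    """Assign each miRNA to the exact set of tissues where it is present.

    Presence is raw count >= ``presence_threshold``.  The label is a
    ``&``-joined tissue-set string in column order (e.g. ``root`` for
    root-exclusive, ``stem&leaf``); miRNAs below threshold everywhere get
    ``absent``.
    """
    if presence_threshold < 1:
        raise ValueError("presence_threshold must be >= 1")
    present = counts >= presence_threshold

    def label(row) -> str:
        tissues = [c for c in counts.columns if row[c]]
        return "&".join(tissues) if tissues else "absent"

    return present.apply(label, axis=1)


def diff_test(row: np.ndarray, library_totals: np.ndarray) -> float:
    """Chi-squared goodness-of-fit p-value for one miRNA's counts.

    Expected counts are the row total split proportionally to the library
    totals.  Returns NaN (with a warning) when any expected count is zero.
    """
    obs = np.asarray(row, dtype=float)
    totals = np.asarray(library_totals, dtype=float)
    if obs.size < 2:
        raise ValueError("need counts from at least two libraries")
    exp = obs.sum() * totals / totals.sum()
    if np.any(exp == 0):
        warnings.warn("zero expected count; chi-squared test skipped")
        return float("nan")
    if obs.sum() == 0:
        return 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=obs.size - 1))


def z_values(normalized_row: np.ndarray) -> np.ndarray:
    """Row-standardized expression: Z_i = (x_i - mean) / sd (ddof=1).

    A constant row (sd = 0) yields all-zero Z.
    """
    x = np.asarray(normalized_row, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def make_calls(z: np.ndarray, p: float, alpha: float = 0.01, z_threshold: float = 1.0):
    """Per-library up/down/ns calls: up iff p <= alpha and Z > z_threshold,
    down iff p <= alpha and Z < -z_threshold."""
    calls = []
    for zi in np.asarray(z, dtype=float):
        if not np.isnan(p) and p <= alpha and zi > z_threshold:
            calls.append("up")
        elif not np.isnan(p) and p <= alpha and zi < -z_threshold:
            calls.append("down")
        else:
            calls.append("ns")
    return calls


def differential_expression(
    counts: pd.DataFrame,
    library_totals: pd.Series | None = None,
    replicate_groups: dict[str, list[str]] | None = None,
    alpha: float = 0.01,
    z_threshold: float = 1.0,
    scale: float = 1e6,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full differential-expression table for a count matrix.

    Without ``replicate_groups`` each column is one library and the
    chi-squared test is applied per row.  With replicate groups (tissue ->
    list of replicate columns) a one-way ANOVA on log2(CPM + 1) is applied
    and Z-values are computed on the per-tissue mean CPM.
    """
    totals = (
        library_totals if library_totals is not None else counts.sum(axis=0)
    )
    totals = pd.Series(totals, index=counts.columns, dtype=float)
    norm = normalize(counts, totals, scale)

    if replicate_groups:
        tissues = list(replicate_groups)
        logn = np.log2(norm + 1)
        pvals = []
        for _, row in logn.iterrows():
            groups = [row[cols].to_numpy() for cols in replicate_groups.values()]
            pvals.append(float(stats.f_oneway(*groups).pvalue))
        zmat = np.vstack(
            [
                z_values(
                    np.array(
                        [norm.loc[i, cols].mean() for cols in replicate_groups.values()]
                    )
                )
                for i in norm.index
            ]
        )
        zcols = tissues
    else:
        pvals = [
            diff_test(counts.loc[i].to_numpy(), totals.to_numpy())
            for i in counts.index
        ]
        zmat = np.vstack([z_values(norm.loc[i].to_numpy()) for i in norm.index])
        zcols = list(counts.columns)

    pvals = np.asarray(pvals, dtype=float)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(pvals)
        adj = pvals.copy()
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        pvals_use = adj
    else:
        pvals_use = pvals

    out = pd.DataFrame(index=counts.index)
    out["p_value"] = pvals_use
    for k, c in enumerate(zcols):
        out[f"Z_{c}"] = zmat[:, k]
    for k, c in enumerate(zcols):
        out[f"call_{c}"] = [
            make_calls(zmat[r, :], pvals_use[r], alpha, z_threshold)[k]
            for r in range(len(out))
        ]
    return out


def delta_delta_ct(
    measurements: pd.DataFrame,
    calibrator: str,
    reference_gene: str = "actin7",
) -> pd.DataFrame:
    """Relative expression by the comparative-Ct (2^-ddCt) method.

    ``measurements`` columns: ``sample``, ``gene``, ``ct`` (one row per
    technical replicate).  Replicate Cts are averaged per (sample, gene),
    dCt = Ct_target - Ct_reference within each sample, ddCt is taken against
    the calibrator sample, and relative expression is 2^-ddCt (calibrator =
    1 by construction).
    """
    req = {"sample", "gene", "ct"}
    if not req.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(req)}")
    mean_ct = measurements.groupby(["sample", "gene"])["ct"].mean().unstack()
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} missing")
    missing_ref = mean_ct[reference_gene].isna()
    if missing_ref.any():
        bad = list(mean_ct.index[missing_ref])
        raise ValueError(f"missing reference-gene Ct for samples: {bad}")
    genes = [g for g in mean_ct.columns if g != reference_gene]
    rows = []
    for gene in genes:
        dct = mean_ct[gene] - mean_ct[reference_gene]
        ddct = dct - dct.loc[calibrator]
        rel = 2.0 ** (-ddct)
        for sample in mean_ct.index:
            if np.isnan(mean_ct.loc[sample, gene]):
                continue
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "delta_ct": dct.loc[sample],
                    "delta_delta_ct": ddct.loc[sample],
                    "relative_expression": rel.loc[sample],
                }
            )
    return pd.DataFrame(rows)
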