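"""Clonal expansion, dominance and cross-subset sharing.

The clonal expansion index of a clone is the case:control frequency
ratio scaled by 100; a pseudocount (default one cell) rescues clones
absent from one condition so the ratio stays finite.  Dominance per
sample is summarised by the Berger-Parker index, the frequency of the
single most abundant clone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_BIN_EDGES = (1, 2, 3, 6, 11)  # {1, 2, 3-5, 6-10, >10}
DEFAULT_EXPANDED_THRESHOLD = 2


def expansion_index(
    n_case: int,
    total_case: int,
    n_control: int,
    total_control: int,
    pseudo: float = 1.0,
) -> float:
    """Case:control clone-frequency ratio × 100.

    The pseudocount is applied only to a zero cell count, so clones
    observed in both conditions are compared on their raw frequencies and
    the index stays exactly 100 for equal frequencies regardless of
    ``pseudo``.
    """
    if total_case <= 0 or total_control <= 0:
        raise ValueError("condition totals must be positive")
    f_case = (n_case if n_case > 0 else pseudo) / total_case
    f_control = (n_control if n_control > 0 else pseudo) / total_control
    if f_control == 0:
        return float("inf") if f_case > 0 else float("nan")
    return 100.0 * f_case / f_control


def copy_number_bin(n: int, edges=DEFAULT_BIN_EDGES) -> str:
    """Ordinal label for a cell count given ascending bin edges."""
    if n < 1:
        raise ValueError("cell count must be ≥1")
    edges = tuple(edges)
    for lo, hi in zip(edges, edges[1:]):
        if lo <= n < hi:
            return str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}"
    return f">{edges[-1] - 1}"


def expansion_table(
    rep,
    case_label: str,
    control_label: str,
    chain: str = "TRB",
    pseudo: float = 1.0,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-clone expansion record for one chain.

    Columns: chain, cdr3_aa, n_case, n_control, freq_case, freq_control,
    expansion_index (pseudocounted), expansion_index_raw (NaN when the
    clone is absent from the control), copy_number_bin (binned case cell
    count; clones absent from the case fall in no bin).
    """
    totals = rep.condition_totals(chain)
    for label in (case_label, control_label):
        if label not in totals.index:
            raise ValueError(f"unknown condition label {label!r}")
    cc = rep.clone_condition_counts()
    cc = cc[cc["chain"] == chain]
    wide = (
        cc.pivot_table(
            index=["chain", "cdr3_aa"],
            columns="condition",
            values="n_cells",
            fill_value=0,
            aggfunc="sum",
        )
        .reset_index()
    )
    n_case = wide.get(case_label, pd.Series(0, index=wide.index)).astype(int)
    n_control = wide.get(control_label, pd.Series(0, index=wide.index)).astype(int)
    t_case, t_control = int(totals[case_label]), int(totals[control_label])
    out = pd.DataFrame(
        {
            "chain": wide["chain"],
            "cdr3_aa": wide["cdr3_aa"],
            "n_case": n_case,
            "n_control": n_control,
            "freq_case": n_case / t_case,
            "freq_control": n_control / t_control,
        }
    )
    out = out[(out["n_case"] > 0) | (out["n_control"] > 0)].copy()
    out["expansion_index"] = [
        expansion_index(a, t_case, b, t_control, pseudo)
        for a, b in zip(out["n_case"], out["n_control"])
    ]
    out["expansion_index_raw"] = np.where(
        out["n_control"] > 0,
        100.0 * out["freq_case"] / out["freq_control"].replace(0, np.nan),
        np.nan,
    )
    out["copy_number_bin"] = [
        copy_number_bin(n, bin_edges) if n >= 1 else ""
        for n in out["n_case"]
    ]
    return out.sort_values(
        ["expansion_index", "cdr3_aa"], ascending=[False, True]
    ).reset_index(drop=True)


def berger_parker(counts) -> float:
    """Dominance index max(counts)/sum(counts) ∈ (0, 1]."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or (arr <= 0).all():
        raise ValueError("berger_parker requires at least one positive count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(arr.max() / arr.sum())


def berger_parker_by_sample(rep, chain: str = "TRB") -> pd.DataFrame:
    """Berger-Parker dominance per sample, with its condition label."""
    recs = rep.records
    recs = recs[recs["chain"] == chain]
    rows = []
    for (sample, condition), sub in recs.groupby(["sample_id", "condition"]):
        counts = sub.groupby("cdr3_aa").size()
        rows.append(
            {
                "sample_id": sample,
                "condition": condition,
                "chain": chain,
                "n_cells": int(counts.sum()),
                "n_clones": int(len(counts)),
                "berger_parker": berger_parker(counts),
            }
        )
    return pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)


def hydro_vs_expansion(
    metrics: pd.DataFrame,
    expansion: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
):
    """Mid-region hydrophobicity as a function of clonal copy number.

    Joins clone metrics to the expansion table on (chain, cdr3_aa),
    summarises mean hydro_mid per copy-number bin, and computes the
    Spearman correlation between case copy number and hydro_mid with a
    two-tailed p and a Fisher-z 95% CI.  Returns ``(per_bin, stats)``;
    with fewer than 3 joinable clones rho is undefined and flagged.
    """
    merged = expansion.merge(
        metrics[["chain", "cdr3_aa", "hydro_mid", "mid_length"]],
        on=["chain", "cdr3_aa"],
        how="inner",
    ).dropna(subset=["hydro_mid"])
    merged = merged[merged["n_case"] >= 1]
    per_bin = (
        merged.groupby("copy_number_bin")
        .agg(
            n_clones=("cdr3_aa", "size"),
            mean_hydro_mid=("hydro_mid", "mean"),
            sem_hydro_mid=("hydro_mid", "sem"),
        )
        .reset_index()
    )
    order = {copy_number_bin(e, bin_edges): i for i, e in enumerate(bin_edges)}
    per_bin["order"] = per_bin["copy_number_bin"].map(
        lambda b: order.get(b, len(order))
    )
    per_bin = per_bin.sort_values("order").drop(columns="order").reset_index(
        drop=True
    )

    if len(merged) < 3 or merged["n_case"].nunique() < 2:
        stats = {
            "spearman_rho": None, "p_value": None,
            "ci95": (None, None), "n": int(len(merged)),
            "defined": False,
        }
    else:
        rho, p = sps.spearmanr(merged["n_case"], merged["hydro_mid"])
        n = len(merged)
        if n > 3 and abs(rho) < 1:
            z = np.arctanh(rho)
            se = 1.0 / np.sqrt(n - 3)
            ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
        else:
            ci = (None, None)
        stats = {
            "spearman_rho": float(rho), "p_value": float(p),
            "ci95": ci, "n": int(n), "defined": True,
        }
    return per_bin, stats


def _lineage(subset_label: str) -> str:
    """CD4/CD8 lineage prefix of a phenotypic subset label ('' if neither)."""
    token = subset_label.split()[0] if subset_label else ""
    return token if token in ("CD4", "CD8") else ""


def sharing_matrix(rep, group_by: str = "subset", chain: str = "TRB"):
    """Clone × group cell-count matrix with sharing flags.

    ``group_by`` is the records column holding the grouping label
    (phenotypic ``subset`` by default, or e.g. a dataset column).  A
    clone is *shared* when present in ≥2 groups, and *cross-lineage*
    when its subset labels span both CD4- and CD8-prefixed groups.
    Returns ``(matrix, summary)``; matrix row sums equal clone totals.
    """
    recs = rep.records
    recs = recs[recs["chain"] == chain]
    if group_by not in recs.columns:
        raise ValueError(f"records have no column {group_by!r}")
    matrix = (
        recs.groupby(["cdr3_aa", group_by])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    shared = (matrix > 0).sum(axis=1) >= 2
    matrix = matrix.copy()
    out = matrix.assign(shared=shared)
    if group_by == "subset":
        lineages = {col: _lineage(col) for col in matrix.columns}
        cd4_cols = [c for c, l in lineages.items() if l == "CD4"]
        cd8_cols = [c for c, l in lineages.items() if l == "CD8"]
        cross = (matrix[cd4_cols].sum(axis=1) > 0) & (
            matrix[cd8_cols].sum(axis=1) > 0
        )
        out["cross_lineage"] = cross
    summary = {
        "n_clones": int(len(matrix)),
        "n_shared": int(shared.sum()),
        "n_cross_lineage": int(out["cross_lineage"].sum())
        if "cross_lineage" in out
        else None,
    }
    return out, summary
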