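"""Codon-redundancy (convergent recombination) analysis.

Because the genetic code is degenerate, distinct CDR3 nucleotide
rearrangements can encode the same amino-acid sequence.  A clone (cells
sharing one CDR3 amino-acid sequence on one chain) backed by k distinct
nucleotide variants is called a codon-redundancy event of order k:
CrE-1 (no convergence), CrE-2 (two variants), CrE-3 (three or more).
Converging clones are CrE-2 ∪ CrE-3.

This module classifies clones by convergence order, relates convergence
to hydrophobicity and V-gene usage, and tabulates α–β chain pairing of
expanded clones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .physchem import hydrophobicity, mid_region

CRE_LABELS = ("CrE-1", "CrE-2", "CrE-3")


def translate(nt: str) -> str:
    """Translate an in-frame, stop-free CDR3 nucleotide sequence.

    Raises ValueError for a length not divisible by 3, a non-ACGT
    letter, or a stop codon anywhere (productive CDR3s are stop-free).
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not divisible by 3")
    bad = set(nt) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT letters {sorted(bad)} in {nt!r}")
    aa = str(Seq(nt).translate())
    if "*" in aa:
        raise ValueError(f"internal stop codon in {nt!r}")
    return aa


def cre_class(n_nt_variants: int, max_class: int = 3) -> str:
    """Map a variant count to its CrE label; the top bin is open-ended."""
    if n_nt_variants < 1:
        raise ValueError("a clone has at least one nucleotide variant")
    return f"CrE-{min(n_nt_variants, max_class)}"


def classify_convergence(rep, scope: str = "condition", max_class: int = 3):
    """Classify every clone by its number of nucleotide variants.

    ``scope='condition'`` counts variants within each condition
    separately (one row per clone × condition); ``scope='pooled'`` pools
    all cells of a chain, matching an all-CD3+ analysis.

    Returns ``(records, percentages)``: a clone-level table with
    ``n_nt_variants`` and ``cre_class``, and a summary with both
    clone-weighted and cell-weighted percentage of each class per
    condition (per chain).  Percentages sum to 100 within each
    (condition, chain, weighting) group.
    """
    if scope not in ("condition", "pooled"):
        raise ValueError("scope must be 'condition' or 'pooled'")
    recs = rep.records
    keys = ["chain", "cdr3_aa"]
    if scope == "condition":
        keys = ["condition"] + keys
    grouped = (
        recs.groupby(keys)
        .agg(
            n_nt_variants=("cdr3_nt", "nunique"),
            n_cells=("barcode", "size"),
            v_genes=("v_gene", lambda s: tuple(sorted(set(s)))),
        )
        .reset_index()
    )
    grouped["cre_class"] = grouped["n_nt_variants"].map(
        lambda k: cre_class(k, max_class)
    )
    grouped["converging"] = grouped["n_nt_variants"] >= 2

    pct_keys = ["condition", "chain"] if scope == "condition" else ["chain"]
    rows = []
    for name, sub in grouped.groupby(pct_keys):
        if not isinstance(name, tuple):
            name = (name,)
        n_clones = len(sub)
        n_cells = sub["n_cells"].sum()
        for cls in [f"CrE-{k}" for k in range(1, max_class + 1)]:
            mask = sub["cre_class"] == cls
            rows.append(
                dict(zip(pct_keys, name))
                | {
                    "cre_class": cls,
                    "pct_clones": 100.0 * mask.sum() / n_clones,
                    "pct_cells": 100.0 * sub.loc[mask, "n_cells"].sum() / n_cells,
                }
            )
    percentages = pd.DataFrame(rows)
    return grouped, percentages


def convergence_vs_physchem(conv: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean mid-region hydrophobicity by CrE class × mid-length stratum.

    Joins the convergence table to clone metrics on (chain, cdr3_aa) and,
    within each mid-length stratum, compares hydro_mid across CrE classes
    with a Kruskal-Wallis test.  Strata with fewer than two classes are
    flagged (``tested=False``) rather than tested.
    """
    merged = conv.merge(
        metrics[["chain", "cdr3_aa", "mid_length", "hydro_mid"]],
        on=["chain", "cdr3_aa"],
        how="inner",
    ).dropna(subset=["hydro_mid"])
    rows = []
    for mlen, sub in merged.groupby("mid_length"):
        groups = {
            cls: g["hydro_mid"].to_numpy() for cls, g in sub.groupby("cre_class")
        }
        testable = (
            len(groups) >= 2 and all(len(v) >= 1 for v in groups.values())
        )
        if testable:
            try:
                h, p = sps.kruskal(*groups.values())
            except ValueError:  # all values identical
                h, p = np.nan, np.nan
                testable = False
        else:
            h, p = np.nan, np.nan
        for cls, vals in sorted(groups.items()):
            rows.append(
                {
                    "mid_length": mlen,
                    "cre_class": cls,
                    "n_clones": len(vals),
                    "mean_hydro_mid": float(np.mean(vals)),
                    "kruskal_h": h,
                    "p_value": p,
                    "tested": testable,
                }
            )
    return pd.DataFrame(rows)


def v_gene_convergence(rep, scope: str = "condition") -> pd.DataFrame:
    """Converging clones whose nucleotide variants use ≥2 distinct V genes.

    One row per qualifying clone (× condition if scoped), with the V-gene
    set and per-V-gene variant and cell counts, demonstrating that
    different V segments can recombine onto one amino-acid CDR3.
    """
    recs = rep.records
    keys = ["chain", "cdr3_aa"]
    if scope == "condition":
        keys = ["condition"] + keys
    per_v = (
        recs.groupby(keys + ["v_gene"])
        .agg(n_variants=("cdr3_nt", "nunique"), n_cells=("barcode", "size"))
        .reset_index()
    )
    nv = per_v.groupby(keys)["v_gene"].nunique().rename("n_v_genes")
    tot_var = (
        recs.groupby(keys)["cdr3_nt"].nunique().rename("n_nt_variants")
    )
    out = per_v.join(nv, on=keys).join(tot_var, on=keys)
    out = out[(out["n_v_genes"] >= 2) & (out["n_nt_variants"] >= 2)]
    return out.sort_values(keys + ["v_gene"]).reset_index(drop=True)


def alpha_beta_pairing(
    records: pd.DataFrame,
    expanded_threshold: int = 2,
    trim_n: int = 3,
    trim_c: int = 3,
    scale: str = "kyte_doolittle",
):
    """α-chain partners of expanded β clones, per cell.

    Cells contribute when their barcode carries both a TRB and a TRA
    record (after per-barcode dedup); chain-orphan cells are excluded and
    counted.  A β clone is "expanded" when at least ``expanded_threshold``
    cells carry it.  Returns ``(pairs, summary)``:

    * ``pairs`` — one row per (β clone, α partner) with cell counts,
      β/α mid lengths and β mid-region hydrophobicity;
    * ``summary`` — number of paired cells, number of excluded
      chain-orphan cells, Spearman rho/p between β and α mid lengths over
      paired cells of expanded clones, and mean β hydrophobicity by
      α-partner multiplicity.
    """
    trb = records[records["chain"] == "TRB"]
    tra = records[records["chain"] == "TRA"]
    paired = trb.merge(
        tra[["barcode", "cdr3_aa"]].rename(columns={"cdr3_aa": "alpha_cdr3_aa"}),
        on="barcode",
        how="inner",
    )
    n_orphan = (
        trb["barcode"].nunique()
        + tra["barcode"].nunique()
        - 2 * paired["barcode"].nunique()
    )
    clone_sizes = trb.groupby("cdr3_aa")["barcode"].size()
    expanded = clone_sizes[clone_sizes >= expanded_threshold].index
    paired_exp = paired[paired["cdr3_aa"].isin(expanded)].copy()

    pairs = (
        paired_exp.groupby(["cdr3_aa", "alpha_cdr3_aa"])
        .size()
        .rename("n_cells")
        .reset_index()
        .rename(columns={"cdr3_aa": "beta_cdr3_aa"})
    )
    pairs["beta_mid_length"] = pairs["beta_cdr3_aa"].map(
        lambda s: len(mid_region(s, trim_n, trim_c))
    )
    pairs["alpha_mid_length"] = pairs["alpha_cdr3_aa"].map(
        lambda s: len(mid_region(s, trim_n, trim_c))
    )
    pairs["beta_hydro_mid"] = pairs["beta_cdr3_aa"].map(
        lambda s: hydrophobicity(mid_region(s, trim_n, trim_c), scale)
    )

    # Cell-level length association (each paired cell of an expanded clone
    # contributes one point).
    bl = paired_exp["cdr3_aa"].str.len() - trim_n - trim_c
    al = paired_exp["alpha_cdr3_aa"].str.len() - trim_n - trim_c
    if len(paired_exp) >= 3 and bl.nunique() > 1 and al.nunique() > 1:
        rho, p = sps.spearmanr(bl, al)
    else:
        rho, p = np.nan, np.nan

    multiplicity = pairs.groupby("beta_cdr3_aa")["alpha_cdr3_aa"].nunique()
    hydro_by_mult = (
        pairs.groupby("beta_cdr3_aa")["beta_hydro_mid"]
        .first()
        .to_frame()
        .join(multiplicity.rename("n_alpha_partners"))
        .groupby("n_alpha_partners")["beta_hydro_mid"]
        .mean()
        .reset_index()
    )
    summary = {
        "n_paired_cells": int(len(paired)),
        "n_chain_orphan_cells": int(n_orphan),
        "n_expanded_beta_clones": int(len(expanded)),
        "length_spearman_rho": float(rho) if rho == rho else None,
        "length_spearman_p": float(p) if p == p else None,
        "beta_hydro_by_alpha_multiplicity": hydro_by_mult,
    }
    return pairs.sort_values(["beta_cdr3_aa", "alpha_cdr3_aa"]).reset_index(
        drop=True
    ), summary
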