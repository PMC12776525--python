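"""Condition-level statistical comparisons and single-score ROC.

Two-sample comparisons use the two-sided Kolmogorov-Smirnov test or the
Mann-Whitney U test (U reported for the first sample; U1 convention, so
[1,2,3] vs [4,5,6] gives U = 0).  Single-feature ROC is computed directly
on the scores — with one predictor, ranking by a fitted logistic
regression is identical to ranking by the score itself — and the p-value
against AUROC = 0.5 comes from the tie-corrected normal approximation to
the Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ComparisonResult:
    test: str            # "ks" or "mann_whitney"
    statistic_name: str  # "KS-D" or "Mann-Whitney-U"
    value: float
    p_two_tailed: float
    n_a: int
    n_b: int
    direction: str       # which group has the larger median ("a", "b", "tie")


@dataclass(frozen=True)
class RocResult:
    auroc: float
    p_value: float       # vs AUROC 0.5, normal approximation to U
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def compare_groups(values_a, values_b, test: str = "ks") -> ComparisonResult:
    """Two-sided two-sample comparison (KS or Mann-Whitney)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    med_a, med_b = np.median(a), np.median(b)
    direction = "a" if med_a > med_b else ("b" if med_b > med_a else "tie")
    if test == "ks":
        res = sps.ks_2samp(a, b, alternative="two-sided")
        return ComparisonResult(
            "ks", "KS-D", float(res.statistic), float(res.pvalue),
            a.size, b.size, direction,
        )
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(
            "mann_whitney", "Mann-Whitney-U", float(res.statistic),
            float(res.pvalue), a.size, b.size, direction,
        )
    raise ValueError(f"unknown test {test!r}")


def roc_from_scores(labels, scores) -> RocResult:
    """ROC of a single continuous score against binary labels.

    AUROC is the rank statistic (probability a random positive outscores
    a random negative, ties counted half); it equals the Mann-Whitney U
    of positives vs negatives divided by n_pos·n_neg.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(y, s))
    if np.all(s == s[0]):
        p = 1.0
    else:
        p = float(
            sps.mannwhitneyu(
                s[y == 1], s[y == 0], alternative="two-sided",
                method="asymptotic",
            ).pvalue
        )
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(auroc, p, n_pos, n_neg, fpr, tpr, thr)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (an extension over the raw
    per-comparison p-values; clearly labelled as such in reports)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float))


def expanded_hydro_shift(
    metrics,
    rep,
    case_label: str,
    control_label: str,
    chain: str = "TRB",
    expanded_threshold: int = 2,
    test: str = "ks",
):
    """Case-vs-control comparison of expanded-clone mid hydrophobicity.

    The headline repertoire comparison: per-clone mid-region
    hydrophobicity of clones with ≥ ``expanded_threshold`` cells in a
    condition, compared between conditions.  Each clone contributes one
    value per condition in which it is expanded, so the samples are
    clone-level (not cell-duplicated).  Returns ``(result, case_values,
    control_values)``.
    """
    cc = rep.clone_condition_counts()
    cc = cc[(cc["chain"] == chain) & (cc["n_cells"] >= expanded_threshold)]
    m = metrics[metrics["chain"] == chain][
        ["chain", "cdr3_aa", "hydro_mid"]
    ].dropna(subset=["hydro_mid"])
    merged = cc.merge(m, on=["chain", "cdr3_aa"], how="inner")
    case_vals = merged.loc[merged["condition"] == case_label, "hydro_mid"]
    control_vals = merged.loc[merged["condition"] == control_label, "hydro_mid"]
    result = compare_groups(case_vals, control_vals, test=test)
    return result, case_vals.to_numpy(), control_vals.to_numpy()
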