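"""Truth-based validation measures for simulated experiments.

These helpers score a pipeline run against the generator's planted truth:
dye-bias removal (mean absolute residual intensity-dependent trend before
and after normalization), planted-class recovery of the interaction groups,
and exact-recovery checks for noiseless runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .interaction import InteractionGroups
from .preprocess import compute_ma, loess_normalize, residual_trend_magnitude
from .simulate import HybridizationArray

#: Class mix for noiseless validation runs: a null majority (global LOESS
#: normalization presumes most genes unchanged, as on real arrays) with
#: every planted class at >= 50 genes once n_genes >= 1250.
NOISELESS_VALIDATION_PROPORTIONS = {
    "null": 0.65,
    "naa_only": 0.07,
    "nf_only": 0.04,
    "additive": 0.06,
    "syn_group1": 0.05,
    "syn_group2_enhanced": 0.04,
    "syn_group2_antagonized": 0.04,
    "syn_group3": 0.05,
}

_CONDITION_COLUMN = {
    "CT": None,
    "NAA": "true_lfc_naa",
    "NF": "true_lfc_nf",
    "NFNAA": "true_lfc_nfnaa",
}


def true_contrast_delta(truth: pd.DataFrame, contrast_id: str) -> pd.Series:
    """Per-gene true log2 ratio of one contrast (numerator - denominator)."""
    num, den = contrast_id.split("_vs_")
    t = truth.set_index("gene_id")
    zero = pd.Series(0.0, index=t.index)
    num_lfc = t[_CONDITION_COLUMN[num]] if _CONDITION_COLUMN[num] else zero
    den_lfc = t[_CONDITION_COLUMN[den]] if _CONDITION_COLUMN[den] else zero
    return num_lfc - den_lfc


def dye_bias_reduction(
    arrays: list[HybridizationArray],
    truth: pd.DataFrame,
    span: float = 0.4,
    iterations: int = 3,
) -> tuple[float, float]:
    """Mean absolute residual dye-bias trend before and after LOESS.

    For each array the known gene-effect component (the true contrast delta,
    sign-flipped on swapped arrays) is subtracted from M; the LOESS trend of
    the remainder against A measures systematic intensity-dependent bias.
    Returns (mean before normalization, mean after) across arrays.
    """
    before, after = [], []
    for arr in arrays:
        delta = true_contrast_delta(truth, arr.contrast_id)
        sign = -1.0 if arr.dye_orientation == "swapped" else 1.0
        expected = sign * delta.loc[arr.spots["gene_id"]].to_numpy()
        ma = compute_ma(arr)
        before.append(residual_trend_magnitude(ma, expected, span=span))
        normed = loess_normalize(ma, span=span, iterations=iterations)
        after.append(residual_trend_magnitude(normed, expected, span=span))
    return float(np.mean(before)), float(np.mean(after))


def planted_gene_sets(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Gene sets planted per response class."""
    return {
        cls: set(sub["gene_id"])
        for cls, sub in truth.groupby("response_class")
    }


def recall_precision(called: set[str], planted: set[str]) -> tuple[float, float]:
    tp = len(called & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else float("nan")
    return recall, precision


def group_recovery(
    groups: InteractionGroups, truth: pd.DataFrame
) -> pd.DataFrame:
    """Recall and precision of each called group against the planted truth."""
    planted = planted_gene_sets(truth)
    g2 = groups.group2
    called = {
        "syn_group1": set(groups.group1),
        "syn_group2_enhanced": set(g2.index[g2["sublabel"] == "enhanced"]),
        "syn_group2_antagonized": set(g2.index[g2["sublabel"] == "antagonized"]),
        "syn_group3": set(groups.group3),
    }
    rows = []
    for cls, genes in called.items():
        r, p = recall_precision(genes, planted.get(cls, set()))
        rows.append((cls, len(genes), len(planted.get(cls, set())), r, p))
    return pd.DataFrame(
        rows, columns=["class", "n_called", "n_planted", "recall", "precision"]
    ).set_index("class")


def exact_recovery(groups: InteractionGroups, truth: pd.DataFrame) -> bool:
    """True iff every planted interaction label is recovered exactly,
    including the group-1 direction and the group-2 sub-labels."""
    planted = planted_gene_sets(truth)
    t = truth.set_index("gene_id")
    g1_up_true = {
        g for g in planted.get("syn_group1", set())
        if t.at[g, "true_lfc_nfnaa"] > 0
    }
    g2 = groups.group2
    return (
        set(groups.group1_up) == g1_up_true
        and set(groups.group1_down) == planted.get("syn_group1", set()) - g1_up_true
        and set(g2.index[g2["sublabel"] == "enhanced"])
        == planted.get("syn_group2_enhanced", set())
        and set(g2.index[g2["sublabel"] == "antagonized"])
        == planted.get("syn_group2_antagonized", set())
        and set(groups.group3) == planted.get("syn_group3", set())
    )
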