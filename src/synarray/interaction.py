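"""Set-logic classification of Nod-factor x auxin interaction gene groups.

From the four contrasts' DEG calls the genes fall into three synergistic
groups: group 1 responds only to the combined NF+NAA treatment; group 2 is
auxin-responsive with a combined response that differs from the NAA response
(split into enhanced and antagonized by the y=x geometry of the two LFCs);
group 3 is NF-responsive with a combined response attenuated or amplified by
at least 30% relative to the NF response (on the linear fold-change scale by
default). The three groups are pairwise disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

NF_VS_CT = "NF_vs_CT"
NAA_VS_CT = "NAA_vs_CT"
NFNAA_VS_CT = "NFNAA_vs_CT"
NFNAA_VS_NAA = "NFNAA_vs_NAA"
REQUIRED_CONTRASTS = (NF_VS_CT, NAA_VS_CT, NFNAA_VS_CT, NFNAA_VS_NAA)
VS_CONTROL = (NF_VS_CT, NAA_VS_CT, NFNAA_VS_CT)


def deg_set(de: pd.DataFrame) -> set[str]:
    """Genes passing the combined DEG call (both thresholds) in one table."""
    return set(de.index[de["call"] != "ns"])


def _check_contrasts(de_tables: dict[str, pd.DataFrame], keys=REQUIRED_CONTRASTS):
    missing = [k for k in keys if k not in de_tables]
    if missing:
        raise ValueError(f"missing DE tables for contrasts: {missing}")


def venn_counts(de_tables: dict[str, pd.DataFrame]) -> dict[str, int]:
    """Seven-region Venn counts over the three vs-control DEG sets."""
    _check_contrasts(de_tables, VS_CONTROL)
    nf = deg_set(de_tables[NF_VS_CT])
    naa = deg_set(de_tables[NAA_VS_CT])
    both = deg_set(de_tables[NFNAA_VS_CT])
    return {
        "NF_only": len(nf - naa - both),
        "NAA_only": len(naa - nf - both),
        "NFNAA_only": len(both - nf - naa),
        "NF_and_NAA": len((nf & naa) - both),
        "NF_and_NFNAA": len((nf & both) - naa),
        "NAA_and_NFNAA": len((naa & both) - nf),
        "all_three": len(nf & naa & both),
        "total_NF": len(nf),
        "total_NAA": len(naa),
        "total_NFNAA": len(both),
        "union": len(nf | naa | both),
    }


def classify_group1(
    de_tables: dict[str, pd.DataFrame],
) -> tuple[list[str], list[str]]:
    """Genes DE only in the combined NF+NAA contrast, split up/down.

    group1 = DEG(NFNAA_vs_CT) \\ (DEG(NAA_vs_CT) | DEG(NF_vs_CT)); the
    direction is taken from the NFNAA_vs_CT call.
    """
    _check_contrasts(de_tables, VS_CONTROL)
    nfnaa = de_tables[NFNAA_VS_CT]
    excluded = deg_set(de_tables[NAA_VS_CT]) | deg_set(de_tables[NF_VS_CT])
    members = deg_set(nfnaa) - excluded
    calls = nfnaa.loc[sorted(members), "call"]
    up = sorted(calls.index[calls == "up"])
    down = sorted(calls.index[calls == "down"])
    return up, down


def classify_group2(
    de_tables: dict[str, pd.DataFrame],
    basis: str = "vs_control",
) -> pd.DataFrame:
    """Auxin-responsive genes whose combined response differs from NAA alone.

    Membership: DEG(NFNAA_vs_NAA) & DEG(NAA_vs_CT) & DEG(NFNAA_vs_CT) and
    not DEG(NF_vs_CT). The enhanced/antagonized sub-label compares the
    NFNAA_vs_CT and NAA_vs_CT log fold-changes (the axes of the y=x plot):
    enhanced iff the signs agree and |lfc_NFNAA| > |lfc_NAA|, else
    antagonized (sign reversals count as antagonism). With basis="vs_naa"
    the combined LFC is reconstructed as lfc_NAA + lfc(NFNAA_vs_NAA).
    """
    _check_contrasts(de_tables)
    if basis not in ("vs_control", "vs_naa"):
        raise ValueError(f"unknown sub-label basis {basis!r}")
    members = (
        deg_set(de_tables[NFNAA_VS_NAA])
        & deg_set(de_tables[NAA_VS_CT])
        & deg_set(de_tables[NFNAA_VS_CT])
    ) - deg_set(de_tables[NF_VS_CT])
    rows = []
    for gene in sorted(members):
        lfc_naa = de_tables[NAA_VS_CT].at[gene, "lfc"]
        if basis == "vs_control":
            lfc_nfnaa = de_tables[NFNAA_VS_CT].at[gene, "lfc"]
        else:
            lfc_nfnaa = lfc_naa + de_tables[NFNAA_VS_NAA].at[gene, "lfc"]
        if np.isnan(lfc_naa) or np.isnan(lfc_nfnaa):
            continue
        enhanced = (np.sign(lfc_nfnaa) == np.sign(lfc_naa)) and (
            abs(lfc_nfnaa) > abs(lfc_naa)
        )
        rows.append(
            (gene, lfc_naa, lfc_nfnaa, "enhanced" if enhanced else "antagonized")
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "lfc_naa", "lfc_nfnaa", "sublabel"]
    ).set_index("gene_id")


def classify_group3(
    de_tables: dict[str, pd.DataFrame],
    rel_threshold: float = 0.30,
    scale: str = "linear",
) -> tuple[list[str], list[str]]:
    """NF-responsive genes whose combined response differs by >= 30%.

    Candidates: DEG(NF_vs_CT) & DEG(NFNAA_vs_CT) and not DEG(NAA_vs_CT).
    The relative-difference rule is computed on linear fold-changes
    FC = 2**lfc by default (|FC_NFNAA - FC_NF| / |FC_NF| >= rel_threshold);
    scale="log" applies the same rule to the log2 fold-changes directly,
    excluding genes with lfc_NF = 0.
    """
    _check_contrasts(de_tables, VS_CONTROL)
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    candidates = sorted(
        (deg_set(de_tables[NF_VS_CT]) & deg_set(de_tables[NFNAA_VS_CT]))
        - deg_set(de_tables[NAA_VS_CT])
    )
    group3 = []
    for gene in candidates:
        lfc_nf = de_tables[NF_VS_CT].at[gene, "lfc"]
        lfc_nfnaa = de_tables[NFNAA_VS_CT].at[gene, "lfc"]
        if scale == "linear":
            fc_nf, fc_nfnaa = 2.0**lfc_nf, 2.0**lfc_nfnaa
            rel = abs(fc_nfnaa - fc_nf) / abs(fc_nf)
        else:
            if lfc_nf == 0:
                continue  # flagged: relative change undefined
            rel = abs(lfc_nfnaa - lfc_nf) / abs(lfc_nf)
        if rel >= rel_threshold:
            group3.append(gene)
    return candidates, group3


def cluster_group1(
    lfc_matrix: pd.DataFrame,
) -> tuple[list[str], np.ndarray | None]:
    """Hierarchical clustering of group-1 genes for heatmap display.

    Euclidean distance on the per-gene vectors of vs-control LFCs, average
    linkage; returns the leaf order (deterministic for fixed input) and the
    linkage matrix. A single gene yields the trivial ordering.
    """
    genes = list(lfc_matrix.index)
    if len(genes) < 2:
        return genes, None
    z = linkage(lfc_matrix.to_numpy(float), method="average", metric="euclidean")
    order = leaves_list(z)
    return [genes[i] for i in order], z


@dataclass
class InteractionGroups:
    """Partition of genes into the three synergistic groups."""

    group1_up: list[str]
    group1_down: list[str]
    group2: pd.DataFrame  # index gene_id; lfc_naa, lfc_nfnaa, sublabel
    group3_candidates: list[str]
    group3: list[str]
    venn: dict[str, int] = field(default_factory=dict)

    @property
    def group1(self) -> list[str]:
        return sorted(self.group1_up + self.group1_down)

    def summary(self) -> dict[str, int]:
        sub = self.group2["sublabel"]
        return {
            "group1": len(self.group1),
            "group1_up": len(self.group1_up),
            "group1_down": len(self.group1_down),
            "group2": len(self.group2),
            "group2_enhanced": int((sub == "enhanced").sum()),
            "group2_antagonized": int((sub == "antagonized").sum()),
            "group3_candidates": len(self.group3_candidates),
            "group3": len(self.group3),
        }


def classify_all(
    de_tables: dict[str, pd.DataFrame],
    rel_threshold: float = 0.30,
    group3_scale: str = "linear",
    group2_basis: str = "vs_control",
) -> InteractionGroups:
    """Run the full group classification and assert pairwise disjointness."""
    up, down = classify_group1(de_tables)
    g2 = classify_group2(de_tables, basis=group2_basis)
    candidates, g3 = classify_group3(
        de_tables, rel_threshold=rel_threshold, scale=group3_scale
    )
    groups = InteractionGroups(
        group1_up=up,
        group1_down=down,
        group2=g2,
        group3_candidates=candidates,
        group3=g3,
        venn=venn_counts(de_tables),
    )
    g1, g2s, g3s = set(groups.group1), set(g2.index), set(g3)
    assert not (g1 & g2s) and not (g1 & g3s) and not (g2s & g3s), (
        "interaction groups must be pairwise disjoint"
    )
    return groups
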