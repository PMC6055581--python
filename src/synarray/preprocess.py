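"""Spot intensities -> per-gene, per-biological-replicate log2 ratios.

The chain per array is: MA transform (M = log2 R/G, A = mean log2
intensity), intensity-dependent LOESS normalization of M on A to remove dye
bias, sign correction of dye-swapped arrays, then averaging over the
triplicated probes and over the technical (dye-swap) replicates, so that the
number of values per gene and contrast equals the number of biological
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import HybridizationArray

#: below this spot count LOESS is unreliable; fall back to median centering
MIN_SPOTS_FOR_LOESS = 50


def compute_ma(array: HybridizationArray) -> pd.DataFrame:
    """MA transform of one hybridization.

    Returns a frame with columns probe_id, gene_id, M, A where
    M = log2(red/green) and A = 0.5 * log2(red * green).
    """
    spots = array.spots
    red = spots["red"].to_numpy(float)
    green = spots["green"].to_numpy(float)
    bad = ~((red > 0) & (green > 0))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"nonpositive intensity at spot {spots['probe_id'].iloc[i]!r} "
            f"on array {array.array_id!r}"
        )
    return pd.DataFrame(
        {
            "probe_id": spots["probe_id"].to_numpy(),
            "gene_id": spots["gene_id"].to_numpy(),
            "M": np.log2(red) - np.log2(green),
            "A": 0.5 * (np.log2(red) + np.log2(green)),
        }
    )


def loess_normalize(
    ma: pd.DataFrame, span: float = 0.4, iterations: int = 3
) -> pd.DataFrame:
    """Subtract the LOESS trend of M on A (global dye-bias correction).

    Local-linear fit with `iterations` robustifying reweights (bisquare).
    With fewer than MIN_SPOTS_FOR_LOESS spots the trend is not identifiable
    and the M values are median-centered instead, with a warning.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    out = ma.copy()
    m = ma["M"].to_numpy(float)
    a = ma["A"].to_numpy(float)
    if len(ma) < MIN_SPOTS_FOR_LOESS:
        warnings.warn(
            f"only {len(ma)} spots; median-centering instead of LOESS",
            stacklevel=2,
        )
        out["M"] = m - np.median(m)
        return out
    delta = 0.01 * (a.max() - a.min())
    trend = lowess(
        m, a, frac=span, it=iterations, delta=delta, return_sorted=False
    )
    out["M"] = m - trend
    return out


def correct_dye(ma: pd.DataFrame, orientation: str) -> pd.DataFrame:
    """Negate M on swapped arrays so all arrays share the contrast's
    numerator/denominator convention."""
    if orientation == "forward":
        return ma.copy()
    if orientation == "swapped":
        out = ma.copy()
        out["M"] = -out["M"].to_numpy(float)
        return out
    raise ValueError(f"unknown dye orientation {orientation!r}")


def residual_trend_magnitude(
    ma: pd.DataFrame,
    expected_m: np.ndarray,
    span: float = 0.4,
) -> float:
    """Mean absolute intensity-dependent trend left in M after removing the
    expected per-spot signal — a QC measure of residual dye bias.

    `expected_m` is the known (or estimated) gene-effect component of each
    spot's M in the array's physical orientation; the LOESS trend of the
    remainder against A estimates systematic dye bias, and its mean absolute
    value summarizes how much remains.
    """
    a = ma["A"].to_numpy(float)
    r = ma["M"].to_numpy(float) - np.asarray(expected_m, dtype=float)
    delta = 0.01 * (a.max() - a.min())
    trend = lowess(r, a, frac=span, it=0, delta=delta, return_sorted=False)
    return float(np.mean(np.abs(trend)))


@dataclass
class NormalizedArray:
    """One hybridization after normalization and dye correction."""

    array_id: str
    contrast_id: str
    bio_rep: int
    ma: pd.DataFrame  # probe_id, gene_id, M, A


def normalize_array(
    array: HybridizationArray, span: float = 0.4, iterations: int = 3
) -> NormalizedArray:
    ma = compute_ma(array)
    ma = loess_normalize(ma, span=span, iterations=iterations)
    ma = correct_dye(ma, array.dye_orientation)
    return NormalizedArray(
        array_id=array.array_id,
        contrast_id=array.contrast_id,
        bio_rep=array.bio_rep,
        ma=ma,
    )


@dataclass
class ContrastMatrix:
    """Genes x biological replicates table of normalized log2 ratios."""

    contrast_id: str
    table: pd.DataFrame  # index gene_id, one column per bio rep ("rep_1", ...)


def summarize_gene(
    arrays: list[NormalizedArray],
    gene_universe: set[str] | None = None,
) -> ContrastMatrix:
    """Average probes within each array, then technical replicates within
    each biological replicate, for one contrast.

    A gene that lost all spots on every array of a biological replicate is
    reported as NaN (flagged missing) in that column.
    """
    if not arrays:
        raise ValueError("no arrays supplied")
    contrast = arrays[0].contrast_id
    if any(a.contrast_id != contrast for a in arrays):
        raise ValueError("summarize_gene expects arrays from a single contrast")
    if gene_universe is not None:
        for a in arrays:
            unknown = set(a.ma["gene_id"]) - gene_universe
            if unknown:
                raise ValueError(
                    f"array {a.array_id} maps probes to unknown genes: "
                    f"{sorted(unknown)[:5]}"
                )
    per_bio: dict[int, list[pd.Series]] = {}
    for a in arrays:
        gene_means = a.ma.groupby("gene_id", sort=True)["M"].mean()
        per_bio.setdefault(a.bio_rep, []).append(gene_means)
    cols = {}
    for b in sorted(per_bio):
        cols[f"rep_{b}"] = pd.concat(per_bio[b], axis=1).mean(axis=1)
    table = pd.DataFrame(cols).sort_index()
    table.index.name = "gene_id"
    return ContrastMatrix(contrast_id=contrast, table=table)


def preprocess_contrasts(
    arrays: list[HybridizationArray],
    span: float = 0.4,
    iterations: int = 3,
) -> dict[str, ContrastMatrix]:
    """Normalize every hybridization and summarize per contrast."""
    by_contrast: dict[str, list[NormalizedArray]] = {}
    for arr in arrays:
        by_contrast.setdefault(arr.contrast_id, []).append(
            normalize_array(arr, span=span, iterations=iterations)
        )
    return {cid: summarize_gene(group) for cid, group in by_contrast.items()}
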