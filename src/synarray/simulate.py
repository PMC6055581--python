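"""Ground-truthed synthetic factorial two-color microarray experiments.

Emulates a four-condition root treatment experiment (control CT, Nod factors
NF, the auxin analog NAA, and the combined NF+NAA treatment) hybridized
competitively as four contrasts, each with dye-swapped technical replicate
pairs over three biological replicates and triplicated probes per gene.
Every gene carries a planted response class (null, single-treatment,
additive, or one of the three synergistic interaction classes), so every
downstream stage of the pipeline can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONDITIONS = ("CT", "NF", "NAA", "NFNAA")

#: The four competitive hybridizations of the factorial design,
#: (numerator, denominator) on the log2-ratio scale.
DEFAULT_CONTRASTS = (
    ("NAA", "CT"),
    ("NF", "CT"),
    ("NFNAA", "CT"),
    ("NFNAA", "NAA"),
)

RESPONSE_CLASSES = (
    "null",
    "naa_only",
    "nf_only",
    "additive",
    "syn_group1",
    "syn_group2_enhanced",
    "syn_group2_antagonized",
    "syn_group3",
)

TRUTH_COLUMNS = (
    "gene_id",
    "response_class",
    "true_lfc_naa",
    "true_lfc_nf",
    "true_lfc_nfnaa",
)


def contrast_id(numerator: str, denominator: str) -> str:
    return f"{numerator}_vs_{denominator}"


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the factorial hybridization design."""

    n_genes: int
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    dye_swap: bool = True
    probes_per_gene: int = 3
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1 or self.probes_per_gene < 1:
            raise ValueError("replicate and probe counts must be >= 1")
        if self.dye_swap and self.n_tech_reps % 2 != 0:
            raise ValueError("n_tech_reps must be even when dye_swap is enabled")
        for num, den in self.contrasts:
            if num not in CONDITIONS or den not in CONDITIONS:
                raise ValueError(f"unknown condition in contrast {num} vs {den}")

    @property
    def contrast_ids(self) -> tuple[str, ...]:
        return tuple(contrast_id(n, d) for n, d in self.contrasts)

    @property
    def n_arrays(self) -> int:
        return len(self.contrasts) * self.n_bio_reps * self.n_tech_reps


def sigmoid_dye_bias(
    amplitude: float = 0.8, center: float = 10.0, width: float = 2.5
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth monotone dye bias bounded by ±amplitude log2 units.

    Intensity-dependent bias of this shape is what LOESS normalization is
    meant to remove; it is applied in the physical red/green frame, so it is
    not cancelled by sign-correcting a dye swap alone unless the two swap
    members share spot intensities.
    """

    def bias(a: np.ndarray) -> np.ndarray:
        return amplitude * np.tanh((np.asarray(a, dtype=float) - center) / width)

    return bias


def constant_dye_bias(offset: float) -> Callable[[np.ndarray], np.ndarray]:
    def bias(a: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(a, dtype=float), offset)

    return bias


def zero_dye_bias(a: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.asarray(a, dtype=float))


@dataclass
class NoiseSpec:
    """Noise model for the simulated hybridizations.

    bio_sd: per-gene, per-biological-replicate Gaussian shift of the true
        log2 ratio (shared by the dye-swap pair of a biological replicate).
    spot_sd: independent Gaussian noise per spot per array, log2 units.
    dye_bias_fn: deterministic log2 offset as a function of mean log
        intensity A, added in the physical red/green frame.
    baseline_mean/baseline_sd: per-probe mean log2 intensity distribution.
    intensity_floor: raw-scale floor; floored spots are flagged, not dropped.
    """

    bio_sd: float = 0.3
    spot_sd: float = 0.2
    dye_bias_fn: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=sigmoid_dye_bias
    )
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    intensity_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bio_sd < 0 or self.spot_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.intensity_floor <= 0:
            raise ValueError("intensity_floor must be positive")


@dataclass(frozen=True)
class EffectParams:
    """Planted log2 fold-change magnitudes per response class.

    lfc_mag may be a scalar or a (low, high) range; signs are random.
    The derived magnitudes must keep every class detectable at the DEG
    thresholds: group-2 antagonism, for instance, is only callable when both
    the attenuated response and the attenuation itself clear lfc_min, which
    forces the NAA response of antagonized genes above twice the cutoff.
    """

    lfc_mag: float | tuple[float, float] = 1.5
    lfc_min: float = 0.75
    group1_sub_frac: float = 0.25
    group2_enhance_factor: float = 1.8
    group2_antag_factor: float = 0.4
    group2_antag_base: float = 2.0
    group3_atten_factor: float = 0.6

    def mag_range(self) -> tuple[float, float]:
        if isinstance(self.lfc_mag, (int, float)):
            return (float(self.lfc_mag), float(self.lfc_mag))
        lo, hi = self.lfc_mag
        return (float(lo), float(hi))

    def validate(self, classes: Iterable[str]) -> None:
        lo, hi = self.mag_range()
        if lo <= 0 or hi < lo:
            raise ValueError("lfc_mag must be positive (low <= high)")
        if not 0 <= self.group1_sub_frac < 1:
            raise ValueError("group1_sub_frac must be in [0, 1)")
        classes = set(classes)
        if "syn_group1" in classes and lo < self.lfc_min:
            raise ValueError("syn_group1 requires lfc_mag >= lfc_min")
        if "syn_group2_enhanced" in classes:
            if self.group2_enhance_factor <= 1:
                raise ValueError("group2_enhance_factor must exceed 1")
            if lo * (self.group2_enhance_factor - 1) < self.lfc_min:
                raise ValueError(
                    "enhanced group-2 genes would not be detectable in the "
                    "NFNAA_vs_NAA contrast at these magnitudes"
                )
        if "syn_group2_antagonized" in classes:
            f, b = self.group2_antag_factor, self.group2_antag_base
            if not 0 < f < 1:
                raise ValueError("group2_antag_factor must be in (0, 1)")
            base = lo * b
            if base * f < self.lfc_min or base * (1 - f) < self.lfc_min:
                raise ValueError(
                    "antagonized group-2 genes need |lfc_naa| * antag_factor "
                    "and |lfc_naa| * (1 - antag_factor) both >= lfc_min"
                )
        if "syn_group3" in classes:
            g = self.group3_atten_factor
            if g <= 0 or g == 1:
                raise ValueError("group3_atten_factor must be positive and != 1")
            if abs(1 - g) < 0.30:
                raise ValueError(
                    "group3 attenuation must move the combined response by "
                    ">= 30% relative to the NF response"
                )
            if lo * g < self.lfc_min:
                raise ValueError("attenuated group3 response falls below lfc_min")


def largest_remainder_counts(
    proportions: Mapping[str, float], total: int
) -> dict[str, int]:
    """Apportion `total` items to classes by largest-remainder rounding.

    Ties on the fractional remainder are broken by the mapping's insertion
    order, so splits are exactly reproducible.
    """
    ssum = float(sum(proportions.values()))
    if not math.isclose(ssum, 1.0, abs_tol=1e-9):
        raise ValueError(f"class proportions must sum to 1 (got {ssum!r})")
    items = list(proportions.items())
    raw = [p * total for _, p in items]
    base = [int(math.floor(r)) for r in raw]
    remainder = total - sum(base)
    order = sorted(range(len(items)), key=lambda i: -(raw[i] - base[i]))
    for i in order[:remainder]:
        base[i] += 1
    return {name: c for (name, _), c in zip(items, base)}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_truth(
    design: DesignSpec,
    class_proportions: Mapping[str, float],
    effect_params: EffectParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene true log2 fold-changes for each planted response class.

    Returns one record per gene with columns ``gene_id``, ``response_class``
    and the true LFCs of the NAA, NF and NF+NAA conditions versus control.
    Class counts follow largest-remainder rounding of the proportions.
    """
    effect_params = effect_params or EffectParams()
    unknown = set(class_proportions) - set(RESPONSE_CLASSES)
    if unknown:
        raise ValueError(f"unknown response classes: {sorted(unknown)}")
    effect_params.validate(class_proportions)
    counts = largest_remainder_counts(class_proportions, design.n_genes)
    rng = np.random.default_rng(seed)
    lo, hi = effect_params.mag_range()

    records: list[tuple[str, str, float, float, float]] = []
    gene_ids = _gene_ids(design.n_genes)
    idx = 0
    for cls in RESPONSE_CLASSES:
        for _ in range(counts.get(cls, 0)):
            gid = gene_ids[idx]
            idx += 1
            mag = rng.uniform(lo, hi)
            sign = rng.choice((-1.0, 1.0))
            if cls == "null":
                naa = nf = nfnaa = 0.0
            elif cls == "naa_only":
                naa = sign * mag
                nf = 0.0
                nfnaa = naa
            elif cls == "nf_only":
                nf = sign * mag
                naa = 0.0
                nfnaa = nf
            elif cls == "additive":
                naa = sign * mag
                nf = rng.choice((-1.0, 1.0)) * rng.uniform(lo, hi)
                nfnaa = naa + nf
            elif cls == "syn_group1":
                sub = effect_params.group1_sub_frac * effect_params.lfc_min
                naa = rng.uniform(-sub, sub)
                nf = rng.uniform(-sub, sub)
                nfnaa = sign * mag
            elif cls == "syn_group2_enhanced":
                naa = sign * mag
                nf = 0.0
                nfnaa = naa * effect_params.group2_enhance_factor
            elif cls == "syn_group2_antagonized":
                naa = sign * mag * effect_params.group2_antag_base
                nf = 0.0
                nfnaa = naa * effect_params.group2_antag_factor
            elif cls == "syn_group3":
                nf = sign * mag
                naa = 0.0
                nfnaa = nf * effect_params.group3_atten_factor
            records.append((gid, cls, naa, nf, nfnaa))

    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    # restore gene-id order (classes were drawn in blocks)
    return truth.sort_values("gene_id", ignore_index=True)


@dataclass
class HybridizationArray:
    """Spot-level red/green intensities for one competitive hybridization."""

    array_id: str
    contrast_id: str
    bio_rep: int
    dye_orientation: str  # "forward" or "swapped"
    spots: pd.DataFrame  # probe_id, gene_id, red, green, floored

    def __post_init__(self) -> None:
        if self.dye_orientation not in ("forward", "swapped"):
            raise ValueError(f"unknown dye orientation {self.dye_orientation!r}")


def _condition_lfc(truth: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "CT": np.zeros(len(truth)),
        "NAA": truth["true_lfc_naa"].to_numpy(float),
        "NF": truth["true_lfc_nf"].to_numpy(float),
        "NFNAA": truth["true_lfc_nfnaa"].to_numpy(float),
    }


def simulate_experiment(
    truth: pd.DataFrame,
    design: DesignSpec,
    noise: NoiseSpec,
) -> list[HybridizationArray]:
    """Generate one hybridization per (contrast x bio rep x tech rep).

    The expected spot log-ratio of contrast X vs Y is
    ``true_lfc_X - true_lfc_Y`` plus the dye bias at the spot's mean log
    intensity A; on dye-swapped arrays the gene effect is sign-flipped while
    the dye bias keeps its physical sign. Biological noise is shared by the
    technical replicates of a biological replicate; spot noise is not.
    """
    if len(truth) != design.n_genes or truth["gene_id"].duplicated().any():
        raise ValueError(
            "truth table must contain exactly one record per design gene"
        )
    rng = np.random.default_rng(noise.seed)
    n_genes, ppg = design.n_genes, design.probes_per_gene
    genes = truth["gene_id"].to_numpy()
    lfc = _condition_lfc(truth)

    # probe identities and baseline intensities are fixed across arrays
    probe_gene = np.repeat(np.arange(n_genes), ppg)
    probe_ids = np.array(
        [f"{genes[g]}_p{k + 1}" for g in range(n_genes) for k in range(ppg)]
    )
    baseline = noise.baseline_mean + noise.baseline_sd * rng.standard_normal(
        n_genes * ppg
    )

    arrays: list[HybridizationArray] = []
    for num, den in design.contrasts:
        cid = contrast_id(num, den)
        delta = lfc[num] - lfc[den]
        for b in range(1, design.n_bio_reps + 1):
            bio = delta + noise.bio_sd * rng.standard_normal(n_genes)
            for t in range(design.n_tech_reps):
                swapped = design.dye_swap and (t % 2 == 1)
                orientation = "swapped" if swapped else "forward"
                signal = -bio if swapped else bio
                a = baseline
                m = (
                    signal[probe_gene]
                    + noise.spot_sd * rng.standard_normal(n_genes * ppg)
                    + np.asarray(noise.dye_bias_fn(a), dtype=float)
                )
                red = np.exp2(a + m / 2.0)
                green = np.exp2(a - m / 2.0)
                floored = (red < noise.intensity_floor) | (
                    green < noise.intensity_floor
                )
                red = np.maximum(red, noise.intensity_floor)
                green = np.maximum(green, noise.intensity_floor)
                arrays.append(
                    HybridizationArray(
                        array_id=f"{cid}_b{b}_t{t + 1}",
                        contrast_id=cid,
                        bio_rep=b,
                        dye_orientation=orientation,
                        spots=pd.DataFrame(
                            {
                                "probe_id": probe_ids,
                                "gene_id": genes[probe_gene],
                                "red": red,
                                "green": green,
                                "floored": floored,
                            }
                        ),
                    )
                )
    return arrays


# ---------------------------------------------------------------------------
# toy ontology + annotation generator

ASPECTS = ("molecular_function", "biological_process", "cellular_component")
_ASPECT_CODE = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


def simulate_annotation(
    gene_ids: Sequence[str],
    n_slim_per_aspect: int = 15,
    dag_depth: int = 3,
    leaves_per_slim: int = 3,
    annotation_rate: float = 0.9,
    terms_per_gene: int = 2,
    planted: Mapping[str, Iterable[str]] | None = None,
    min_planted_factor: float = 5.0,
    seed: int = 0,
) -> tuple[nx.MultiDiGraph, pd.DataFrame, list[str]]:
    """Build a toy GO-style DAG, a GAF-like annotation table and a slim list.

    Per aspect the DAG has a root, ``n_slim_per_aspect`` slim terms under the
    root, chains of depth ``dag_depth`` below each slim ending in
    ``leaves_per_slim`` leaves, one term with two parents under two distinct
    slims (exercising the multi-parent mapping rule) and one orphan term with
    no slim ancestor (exercising the catch-all). A fraction
    ``annotation_rate`` of genes is annotated per aspect; ``planted`` maps a
    slim term id to a gene subset that is annotated into that category so its
    true normed frequency exceeds ``min_planted_factor``.
    """
    if dag_depth < 2:
        raise ValueError("dag_depth must be >= 2 for nontrivial ancestry")
    if not 0 < annotation_rate <= 1:
        raise ValueError("annotation_rate must be in (0, 1]")
    gene_ids = list(gene_ids)
    gene_set = set(gene_ids)
    planted = {k: list(v) for k, v in (planted or {}).items()}
    for cat, subset in planted.items():
        if not set(subset) <= gene_set:
            raise ValueError(f"planted subset for {cat} is not within gene_ids")

    rng = np.random.default_rng(seed)
    graph = nx.MultiDiGraph()
    slim_terms: list[str] = []
    leaf_terms: dict[str, list[str]] = {}  # slim id -> leaf term ids
    counter = 0

    def new_term(name: str, aspect: str) -> str:
        nonlocal counter
        counter += 1
        tid = f"GO:{counter:07d}"
        graph.add_node(tid, name=name, namespace=aspect)
        return tid

    for ai, aspect in enumerate(ASPECTS):
        root = new_term(aspect.replace("_", " "), aspect)
        graph.nodes[root]["is_root"] = True
        aspect_slims = []
        for s in range(n_slim_per_aspect):
            slim = new_term(f"{aspect} slim {s + 1}", aspect)
            graph.add_edge(slim, root, key="is_a")
            aspect_slims.append(slim)
            slim_terms.append(slim)
            # a chain of intermediate terms, then leaves
            parent = slim
            for d in range(dag_depth - 2):
                mid = new_term(f"{aspect} s{s + 1} mid {d + 1}", aspect)
                graph.add_edge(mid, parent, key="is_a")
                parent = mid
            leaves = []
            for k in range(leaves_per_slim):
                leaf = new_term(f"{aspect} s{s + 1} leaf {k + 1}", aspect)
                graph.add_edge(leaf, parent, key="is_a")
                leaves.append(leaf)
            leaf_terms[slim] = leaves
        # one term with two parents under two distinct slim categories
        multi = new_term(f"{aspect} multiparent", aspect)
        graph.add_edge(multi, leaf_terms[aspect_slims[0]][0], key="is_a")
        graph.add_edge(multi, leaf_terms[aspect_slims[1]][0], key="part_of")
        leaf_terms.setdefault("_multi_" + aspect, []).append(multi)
        # one orphan term below the root only -> catch-all category
        orphan = new_term(f"other {aspect}", aspect)
        graph.add_edge(orphan, root, key="is_a")
        leaf_terms.setdefault("_orphan_" + aspect, []).append(orphan)

    # background annotation: each annotated gene gets `terms_per_gene`
    # random leaves per aspect
    rows: list[tuple[str, str, str]] = []  # gene, term, aspect code
    slims_by_aspect = {
        aspect: [s for s in slim_terms if graph.nodes[s]["namespace"] == aspect]
        for aspect in ASPECTS
    }
    planted_slims = set(planted)
    for aspect in ASPECTS:
        # leaves of planted slims are reserved for the planted subsets so the
        # planted categories stay rare in the background reference
        pool = [
            leaf
            for slim in slims_by_aspect[aspect]
            if slim not in planted_slims
            for leaf in leaf_terms[slim]
        ]
        pool = pool + leaf_terms["_multi_" + aspect] + leaf_terms["_orphan_" + aspect]
        annotated = rng.random(len(gene_ids)) < annotation_rate
        for gi, gid in enumerate(gene_ids):
            if not annotated[gi]:
                continue
            for term in rng.choice(pool, size=terms_per_gene, replace=False):
                rows.append((gid, term, _ASPECT_CODE[aspect]))

    # planting: annotate the subset into a leaf of the requested slim
    for cat, subset in planted.items():
        if cat not in leaf_terms:
            raise ValueError(f"planted category {cat!r} is not a slim term")
        aspect = graph.nodes[cat]["namespace"]
        leaf = leaf_terms[cat][0]
        for gid in subset:
            rows.append((gid, leaf, _ASPECT_CODE[aspect]))

    annotation = pd.DataFrame(rows, columns=["gene_id", "go_id", "aspect"])
    annotation = annotation.drop_duplicates(ignore_index=True)

    if planted:
        _check_planted_factor(annotation, graph, slim_terms, planted,
                              min_planted_factor, gene_ids)
    return graph, annotation, slim_terms


def _check_planted_factor(annotation, graph, slim_terms, planted, factor, genes):
    """Verify each planted subset's normed frequency exceeds `factor`."""
    from .enrich import AnnotationSet, OntologyDAG

    dag = OntologyDAG(graph, set(slim_terms))
    ann = AnnotationSet.from_table(annotation, dag, reference_genes=genes)
    for cat, subset in planted.items():
        row = ann.normed_frequency(subset, cat)
        if not row["normed_frequency"] > factor:
            raise ValueError(
                f"planted category {cat} reached normed frequency "
                f"{row['normed_frequency']:.2f} <= required factor {factor}"
            )
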