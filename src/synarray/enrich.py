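"""GO-Slim enrichment with normed frequencies, bootstrap SDs and
hypergeometric tests.

Detailed GO terms are mapped up the ontology DAG (is_a / part_of edges) to a
designated slim set; a term under multiple parents contributes every slim
ancestor it reaches, so one gene may raise several categories at once. The
per-category statistic is the normed frequency

    (n_in_class_input / n_classified_input)
    / (n_in_class_ref / n_classified_ref),

>1 meaning enrichment and <1 under-representation. Its error bar is the
standard deviation over bootstrap resamples of the input set (100 by
default), and significance comes from a hypergeometric tail test (over- or
under-representation chosen by comparing the observed count with its
expectation), flagged at p < 0.05 without multiplicity correction.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

ASPECTS = ("molecular_function", "biological_process", "cellular_component")
_ASPECT_FROM_CODE = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}
DEFAULT_RELATIONS = ("is_a", "part_of")


def catchall_category(aspect: str) -> str:
    """Category collecting terms with no slim ancestor in `aspect`."""
    return f"other:{aspect}"


def unknown_category(aspect: str) -> str:
    """Category for classified genes with no annotation in `aspect`."""
    return f"unknown:{aspect}"


class OntologyDAG:
    """GO-style DAG with a designated slim subset.

    Edges run child -> parent; only `relations` (is_a and part_of by
    default) are traversed when mapping terms to slim categories.
    """

    def __init__(
        self,
        graph: nx.MultiDiGraph,
        slim_terms: Iterable[str],
        relations: Sequence[str] = DEFAULT_RELATIONS,
    ):
        self.graph = graph
        self.slim_terms = set(slim_terms)
        self.relations = tuple(relations)
        missing = self.slim_terms - set(graph.nodes)
        if missing:
            raise ValueError(f"slim terms absent from ontology: {sorted(missing)[:5]}")
        sub = nx.DiGraph(
            (u, v)
            for u, v, k in graph.edges(keys=True)
            if k in self.relations
        )
        if not nx.is_directed_acyclic_graph(sub):
            raise ValueError("ontology contains a cycle over is_a/part_of edges")
        self._slim_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_obo(
        cls,
        obo_path: str,
        slim_terms: Iterable[str],
        relations: Sequence[str] = DEFAULT_RELATIONS,
    ) -> "OntologyDAG":
        import obonet

        return cls(obonet.read_obo(obo_path), slim_terms, relations)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def aspect_of(self, term: str) -> str:
        try:
            return self.graph.nodes[term]["namespace"]
        except KeyError:
            raise KeyError(f"term {term!r} not in ontology") from None

    def slim_ancestors(self, term: str) -> frozenset[str]:
        """All slim terms reachable upward from `term` (itself included)."""
        cached = self._slim_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        seen = {term}
        stack = [term]
        slims = set()
        while stack:
            t = stack.pop()
            if t in self.slim_terms:
                slims.add(t)
            for _, parent, key in self.graph.out_edges(t, keys=True):
                if key in self.relations and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        result = frozenset(slims)
        self._slim_cache[term] = result
        return result


def map_to_slim(term: str, dag: OntologyDAG) -> set[str]:
    """Slim categories for one term; the aspect catch-all if none reachable."""
    slims = dag.slim_ancestors(term)
    if slims:
        return set(slims)
    return {catchall_category(dag.aspect_of(term))}


class AnnotationSet:
    """Gene -> slim-category membership derived from a GO annotation table.

    Classified genes (per aspect) are the reference genes that appear in the
    annotation table at all; a classified gene with no term in an aspect
    falls in that aspect's "unknown" category, and terms without a slim
    ancestor fall in the "other" catch-all, so both participate in the
    statistic. Reference genes never annotated are unclassified and excluded
    from the counts. Terms absent from the ontology are recorded in
    `unmapped_terms`; their genes still count through their other terms.
    """

    def __init__(
        self,
        gene_categories: Mapping[str, dict[str, set[str]]],
        reference_genes: Sequence[str],
        unmapped_terms: set[str] | None = None,
        all_categories: Mapping[str, Sequence[str]] | None = None,
    ):
        # gene_categories: aspect -> gene -> set of category ids
        self.reference_genes = list(dict.fromkeys(reference_genes))
        self.unmapped_terms = unmapped_terms or set()
        annotated = sorted(
            set().union(*(gene_categories[a].keys() for a in ASPECTS))
        )
        self._gene_row = {g: i for i, g in enumerate(annotated)}
        self.classified_genes = annotated
        self.categories: dict[str, list[str]] = {}
        self._matrix: dict[str, np.ndarray] = {}
        for aspect in ASPECTS:
            derived = set().union(*gene_categories[aspect].values(), set())
            if all_categories is not None:
                cats = list(all_categories[aspect])
                extra = derived - set(cats)
                if extra:
                    raise ValueError(
                        f"genes annotated to categories outside the declared "
                        f"list: {sorted(extra)[:5]}"
                    )
            else:
                cats = sorted(derived)
            unk = unknown_category(aspect)
            if unk not in cats:
                cats.append(unk)
            col = {c: j for j, c in enumerate(cats)}
            mat = np.zeros((len(annotated), len(cats)), dtype=bool)
            for gene in annotated:
                gcats = gene_categories[aspect].get(gene)
                if gcats:
                    for c in gcats:
                        mat[self._gene_row[gene], col[c]] = True
                else:
                    mat[self._gene_row[gene], col[unk]] = True
            self.categories[aspect] = cats
            self._matrix[aspect] = mat

    @classmethod
    def from_table(
        cls,
        annotation: pd.DataFrame,
        dag: OntologyDAG,
        reference_genes: Sequence[str],
    ) -> "AnnotationSet":
        """Build from a table with columns gene_id, go_id, aspect (F/P/C)."""
        ref = set(reference_genes)
        gene_categories: dict[str, dict[str, set[str]]] = {
            a: {} for a in ASPECTS
        }
        unmapped: set[str] = set()
        for gene, term, code in annotation[
            ["gene_id", "go_id", "aspect"]
        ].itertuples(index=False):
            if gene not in ref:
                continue
            aspect = _ASPECT_FROM_CODE.get(code, code)
            if aspect not in ASPECTS:
                raise ValueError(f"unknown GO aspect {code!r}")
            try:
                cats = map_to_slim(term, dag)
            except KeyError:
                unmapped.add(term)
                # the gene is still classified (possibly "unknown") in
                # this aspect through the table row itself
                gene_categories[aspect].setdefault(gene, set())
                continue
            gene_categories[aspect].setdefault(gene, set()).update(cats)
        # a gene annotated in one aspect is classified in all three
        annotated = set().union(*(gene_categories[a] for a in ASPECTS))
        for aspect in ASPECTS:
            for gene in annotated:
                gene_categories[aspect].setdefault(gene, set())
        for aspect in ASPECTS:
            for gene in gene_categories[aspect]:
                if not gene_categories[aspect][gene]:
                    gene_categories[aspect][gene].add(unknown_category(aspect))
        all_categories = {
            aspect: sorted(
                t for t in dag.slim_terms if dag.aspect_of(t) == aspect
            )
            + [catchall_category(aspect), unknown_category(aspect)]
            for aspect in ASPECTS
        }
        return cls(gene_categories, list(reference_genes), unmapped, all_categories)

    # -- counting helpers ---------------------------------------------------

    def aspect_of_category(self, category: str) -> str:
        for aspect in ASPECTS:
            if category in self.categories[aspect]:
                return aspect
        raise KeyError(f"unknown category {category!r}")

    def _rows(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(
            [self._gene_row[g] for g in genes if g in self._gene_row], dtype=int
        )

    def reference_counts(self, aspect: str) -> tuple[np.ndarray, int]:
        """(per-category gene counts, number of classified genes) in the
        reference set."""
        mat = self._matrix[aspect]
        return mat.sum(axis=0), mat.shape[0]

    def input_counts(
        self, input_genes: Iterable[str], aspect: str
    ) -> tuple[np.ndarray, int]:
        rows = self._rows(set(input_genes))
        mat = self._matrix[aspect]
        if rows.size == 0:
            return np.zeros(mat.shape[1], dtype=int), 0
        return mat[rows].sum(axis=0), rows.size

    def normed_frequency(
        self, input_genes: Iterable[str], category: str
    ) -> dict[str, float]:
        """The SuperViewer statistic for one category."""
        input_genes = set(input_genes)
        if not input_genes <= set(self.reference_genes):
            raise ValueError("input genes must be a subset of the reference set")
        aspect = self.aspect_of_category(category)
        j = self.categories[aspect].index(category)
        k_ref, n_ref = self.reference_counts(aspect)
        k_in, n_in = self.input_counts(input_genes, aspect)
        row = {
            "n_in_class_input": int(k_in[j]),
            "n_classified_input": int(n_in),
            "n_in_class_ref": int(k_ref[j]),
            "n_classified_ref": int(n_ref),
        }
        if n_in == 0:
            raise ValueError("no classified genes in the input set")
        if k_ref[j] == 0:
            row["normed_frequency"] = float("nan")  # undefined, flagged
        else:
            row["normed_frequency"] = (k_in[j] / n_in) / (k_ref[j] / n_ref)
        return row


def bootstrap_sd(
    input_genes: Sequence[str],
    annotation: AnnotationSet,
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Per-category SD of the normed frequency over bootstrap resamples.

    Each replicate resamples |input| genes with replacement from the input
    set and recomputes the normed frequency of every category; replicates
    with no classified gene contribute nothing to a category's SD.
    """
    input_list = sorted(set(input_genes))
    if not input_list:
        raise ValueError("input set is empty")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.Series] = {}
    row_of = np.array(
        [annotation._gene_row.get(g, -1) for g in input_list], dtype=int
    )
    draws = rng.integers(0, len(input_list), size=(n_boot, len(input_list)))
    for aspect in ASPECTS:
        mat = annotation._matrix[aspect]
        k_ref, n_ref = annotation.reference_counts(aspect)
        with np.errstate(divide="ignore", invalid="ignore"):
            ref_rate = k_ref / n_ref
        reps = np.full((n_boot, mat.shape[1]), np.nan)
        for b in range(n_boot):
            rows = row_of[draws[b]]
            rows = rows[rows >= 0]
            if rows.size == 0:
                continue
            counts = mat[rows].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                reps[b] = (counts / rows.size) / ref_rate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(reps, axis=0, ddof=1)
        out[aspect] = pd.Series(sd, index=annotation.categories[aspect])
    return out


def hypergeom_test(
    input_genes: Iterable[str],
    annotation: AnnotationSet,
    category: str,
) -> tuple[float, str]:
    """One-tailed hypergeometric over/under-representation test.

    Population N = classified reference genes, successes K = reference genes
    in the category, draws n = classified input genes, observed k. The tail
    is chosen by comparing k with its expectation n*K/N; an exactly-expected
    k is tested for over-representation (deterministically).
    """
    aspect = annotation.aspect_of_category(category)
    j = annotation.categories[aspect].index(category)
    k_ref, n_ref = annotation.reference_counts(aspect)
    k_in, n_in = annotation.input_counts(set(input_genes), aspect)
    big_n, big_k = int(n_ref), int(k_ref[j])
    n, k = int(n_in), int(k_in[j])
    if n > big_n:
        raise ValueError("input set larger than classified reference set")
    expected = n * big_k / big_n if big_n else 0.0
    if k >= expected:
        return float(hypergeom.sf(k - 1, big_n, big_k, n)), "over"
    return float(hypergeom.cdf(k, big_n, big_k, n)), "under"


def enrichment_report(
    input_genes: Sequence[str],
    annotation: AnnotationSet,
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Full per-category enrichment table, ranked by normed frequency.

    One row per slim category (catch-alls and unknowns included), sorted by
    descending normed frequency within each aspect; `significant` flags
    hypergeometric p < alpha (raw by default; BH-adjusted across all
    categories when bh_adjust=True).
    """
    input_set = sorted(set(input_genes))
    if not input_set:
        warnings.warn("empty input set; returning empty report", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "aspect", "category", "n_in_class_input", "n_classified_input",
                "n_in_class_ref", "n_classified_ref", "normed_frequency",
                "bootstrap_sd", "p_hyper", "direction", "significant",
            ]
        )
    sds = bootstrap_sd(input_set, annotation, n_boot=n_boot, seed=seed)
    rows = []
    for aspect in ASPECTS:
        for category in annotation.categories[aspect]:
            nf = annotation.normed_frequency(input_set, category)
            p, direction = hypergeom_test(input_set, annotation, category)
            rows.append(
                {
                    "aspect": aspect,
                    "category": category,
                    **nf,
                    "bootstrap_sd": float(sds[aspect][category]),
                    "p_hyper": p,
                    "direction": direction,
                }
            )
    report = pd.DataFrame(rows)
    pcol = report["p_hyper"].to_numpy()
    if bh_adjust:
        from .diffexpr import adjust_bh

        pcol = adjust_bh(pcol)
        report["p_adj"] = pcol
    report["significant"] = pcol < alpha
    report = report.sort_values(
        ["aspect", "normed_frequency"],
        ascending=[True, False],
        na_position="last",
        kind="mergesort",
        ignore_index=True,
    )
    return report


def plot_enrichment(report: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of normed frequencies with bootstrap error bars,
    one panel per aspect; significant categories drawn in bold color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    aspects = report["aspect"].unique()
    fig, axes = plt.subplots(
        1, len(aspects), figsize=(5 * len(aspects), 0.25 * len(report) + 2),
        squeeze=False,
    )
    for ax, aspect in zip(axes[0], aspects):
        sub = report[report["aspect"] == aspect].dropna(
            subset=["normed_frequency"]
        )
        colors = [
            "#c0392b" if sig else "#95a5a6" for sig in sub["significant"]
        ]
        ax.barh(
            sub["category"], sub["normed_frequency"],
            xerr=sub["bootstrap_sd"], color=colors,
        )
        ax.axvline(1.0, color="black", lw=0.8, ls="--")
        ax.set_title(aspect.replace("_", " "))
        ax.set_xlabel("normed frequency")
        ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
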