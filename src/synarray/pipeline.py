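"""Stage drivers binding simulation, normalization, DE, classification and
enrichment into reproducible directory-to-directory runs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrich, interaction, io, preprocess, simulate

log = logging.getLogger("synarray")

DEFAULT_CLASS_PROPORTIONS = {
    "null": 0.60,
    "naa_only": 0.20,
    "nf_only": 0.01,
    "additive": 0.08,
    "syn_group1": 0.05,
    "syn_group2_enhanced": 0.02,
    "syn_group2_antagonized": 0.015,
    "syn_group3": 0.025,
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; every numeric default matches the study
    design where one is stated (alpha 0.05, lfc_min 0.75, 3 biological
    replicates, dye-swapped technical pairs, triplicated probes, 100
    bootstraps)."""

    # simulation
    n_genes: int = 2000
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    dye_swap: bool = True
    probes_per_gene: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    lfc_mag: float = 1.5
    bio_sd: float = 0.3
    spot_sd: float = 0.2
    dye_bias: str = "sigmoid"  # "sigmoid", "zero" or "constant:<offset>"
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    # annotation simulation
    n_slim_per_aspect: int = 15
    dag_depth: int = 3
    plant_enrichment: bool = True
    planted_min_factor: float = 3.0
    # normalization
    loess_span: float = 0.4
    loess_iterations: int = 3
    # differential expression
    alpha: float = 0.05
    lfc_min: float = 0.75
    p_reference: str = "normal"
    # interaction groups
    group3_rel_threshold: float = 0.30
    group3_scale: str = "linear"
    group2_basis: str = "vs_control"
    # enrichment
    n_boot: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def design(self) -> simulate.DesignSpec:
        return simulate.DesignSpec(
            n_genes=self.n_genes,
            n_bio_reps=self.n_bio_reps,
            n_tech_reps=self.n_tech_reps,
            dye_swap=self.dye_swap,
            probes_per_gene=self.probes_per_gene,
        )

    def noise(self) -> simulate.NoiseSpec:
        if self.dye_bias == "sigmoid":
            bias = simulate.sigmoid_dye_bias(center=self.baseline_mean)
        elif self.dye_bias == "zero":
            bias = simulate.zero_dye_bias
        elif self.dye_bias.startswith("constant:"):
            bias = simulate.constant_dye_bias(float(self.dye_bias.split(":", 1)[1]))
        else:
            raise ValueError(f"unknown dye_bias spec {self.dye_bias!r}")
        return simulate.NoiseSpec(
            bio_sd=self.bio_sd,
            spot_sd=self.spot_sd,
            dye_bias_fn=bias,
            baseline_mean=self.baseline_mean,
            baseline_sd=self.baseline_sd,
            seed=self.seed + 1,
        )

    def effects(self) -> simulate.EffectParams:
        return simulate.EffectParams(lfc_mag=self.lfc_mag, lfc_min=self.lfc_min)


def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic experiment: arrays, truth, design manifest,
    ontology, annotation and slim list."""
    outdir = Path(outdir)
    (outdir / "arrays").mkdir(parents=True, exist_ok=True)
    design = config.design()
    truth = simulate.simulate_truth(
        design, config.class_proportions, config.effects(), seed=config.seed
    )
    arrays = simulate.simulate_experiment(truth, design, config.noise())
    io.write_truth(truth, outdir / "truth.tsv")
    entries = []
    for arr in arrays:
        rel = f"arrays/{arr.array_id}.tsv"
        io.write_array_tsv(arr, outdir / rel)
        entries.append(
            {
                "file": rel,
                "array_id": arr.array_id,
                "contrast_id": arr.contrast_id,
                "bio_rep": arr.bio_rep,
                "dye_orientation": arr.dye_orientation,
            }
        )
    (outdir / "design.json").write_text(
        json.dumps({"arrays": entries, "contrasts": list(design.contrast_ids)},
                   indent=2) + "\n"
    )
    planted = {}
    if config.plant_enrichment:
        group1_genes = truth.loc[
            truth["response_class"] == "syn_group1", "gene_id"
        ].tolist()
        if group1_genes:
            # plant the first biological_process slim with the group-1 genes
            planted = {"_first_bp_slim": group1_genes}
    graph, annotation, slim_terms = simulate.simulate_annotation(
        truth["gene_id"].tolist(),
        n_slim_per_aspect=config.n_slim_per_aspect,
        dag_depth=config.dag_depth,
        planted=_resolve_planted(planted, config) if planted else None,
        min_planted_factor=config.planted_min_factor,
        seed=config.seed + 2,
    )
    io.write_obo(graph, outdir / "ontology.obo")
    io.write_gaf(annotation, outdir / "annotation.gaf")
    io.write_slim_list(slim_terms, outdir / "slim.txt")
    io.write_manifest(outdir / "manifest.json", config.to_dict())
    log.info("simulated %d arrays, %d genes", len(arrays), config.n_genes)
    return {"n_arrays": len(arrays), "n_genes": config.n_genes}


def _resolve_planted(planted: dict, config: PipelineConfig) -> dict:
    """Map the placeholder key to the first biological_process slim term id.

    Slim term ids are assigned deterministically by the generator: per
    aspect, the root takes one id, then each slim block takes
    1 + (dag_depth - 2) + leaves_per_slim ids, plus two extra terms per
    aspect (the multi-parent and orphan terms).
    """
    leaves_per_slim = 3
    per_slim_block = 1 + (config.dag_depth - 2) + leaves_per_slim
    per_aspect = 1 + config.n_slim_per_aspect * per_slim_block + 2
    # first BP slim = after the whole MF aspect, skip BP root
    first_bp_slim = per_aspect + 2
    return {f"GO:{first_bp_slim:07d}": genes for genes in planted.values()}


def _load_arrays(indir: Path) -> list[simulate.HybridizationArray]:
    design = json.loads((indir / "design.json").read_text())
    return [
        io.read_array_tsv(
            indir / e["file"], e["array_id"], e["contrast_id"], e["bio_rep"]
        )
        for e in design["arrays"]
    ]


def cmd_normalize(config: PipelineConfig, indir: str | Path,
                  outdir: str | Path) -> dict[str, preprocess.ContrastMatrix]:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = _load_arrays(indir)
    matrices = preprocess.preprocess_contrasts(
        arrays, span=config.loess_span, iterations=config.loess_iterations
    )
    for cid, matrix in matrices.items():
        io.write_contrast_matrix(matrix, outdir / f"contrast_{cid}.tsv")
        log.info("contrast %s: %d genes", cid, len(matrix.table))
    return matrices


def cmd_de(config: PipelineConfig, indir: str | Path,
           outdir: str | Path) -> dict[str, pd.DataFrame]:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for path in sorted(indir.glob("contrast_*.tsv")):
        cid = path.stem.removeprefix("contrast_")
        matrix = io.read_contrast_matrix(path, cid)
        de = diffexpr.de_table(
            matrix,
            alpha=config.alpha,
            lfc_min=config.lfc_min,
            reference=config.p_reference,
        )
        io.write_de_table(de, outdir / f"de_{cid}.tsv")
        n_up = int((de["call"] == "up").sum())
        n_down = int((de["call"] == "down").sum())
        log.info("contrast %s: %d up, %d down of %d genes",
                 cid, n_up, n_down, len(de))
        tables[cid] = de
    return tables


def cmd_classify(config: PipelineConfig, indir: str | Path,
                 outdir: str | Path) -> interaction.InteractionGroups:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_tables = {
        path.stem.removeprefix("de_"): io.read_de_table(path)
        for path in sorted(indir.glob("de_*.tsv"))
    }
    groups = interaction.classify_all(
        de_tables,
        rel_threshold=config.group3_rel_threshold,
        group3_scale=config.group3_scale,
        group2_basis=config.group2_basis,
    )
    rows = []
    for gene in groups.group1_up:
        rows.append((gene, "group1", "up"))
    for gene in groups.group1_down:
        rows.append((gene, "group1", "down"))
    for gene, sub in groups.group2["sublabel"].items():
        rows.append((gene, "group2", sub))
    for gene in groups.group3_candidates:
        rows.append((gene, "group3_candidate", ""))
    for gene in groups.group3:
        rows.append((gene, "group3", ""))
    members = pd.DataFrame(rows, columns=["gene_id", "group", "sublabel"])
    lfcs = pd.DataFrame(
        {
            f"lfc_{cid}": de_tables[cid]["lfc"]
            for cid in interaction.REQUIRED_CONTRASTS
        }
    )
    members = members.join(lfcs, on="gene_id")
    members.to_csv(outdir / "groups.tsv", sep="\t", index=False,
                   float_format="%.10g")
    (outdir / "venn.json").write_text(json.dumps(groups.venn, indent=2) + "\n")
    group1 = groups.group1
    if group1:
        lfc_matrix = lfcs.loc[
            group1, [f"lfc_{c}" for c in interaction.VS_CONTROL]
        ]
        order, _ = interaction.cluster_group1(lfc_matrix)
        pd.Series(order, name="gene_id").to_csv(
            outdir / "group1_cluster_order.tsv", sep="\t", index=False
        )
    log.info("groups: %s", groups.summary())
    return groups


def cmd_enrich(
    config: PipelineConfig,
    input_genes: list[str],
    obo: str | Path,
    gaf: str | Path,
    slim: str | Path,
    reference_genes: list[str],
    out_tsv: str | Path,
) -> pd.DataFrame:
    dag = enrich.OntologyDAG.from_obo(str(obo), io.read_slim_list(slim))
    annotation = enrich.AnnotationSet.from_table(
        io.read_gaf(gaf), dag, reference_genes
    )
    report = enrich.enrichment_report(
        input_genes, annotation,
        n_boot=config.n_boot, seed=config.seed + 3, alpha=config.alpha,
    )
    report.to_csv(out_tsv, sep="\t", index=False, float_format="%.10g")
    log.info("enrichment on %d genes: %d significant categories",
             len(input_genes), int(report["significant"].sum())
             if len(report) else 0)
    return report


def cmd_run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """simulate -> normalize -> de -> classify -> enrich, each stage in its
    own subdirectory; enrichment runs on the group-1 up and down lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cmd_simulate(config, outdir / "sim")
    cmd_normalize(config, outdir / "sim", outdir / "norm")
    cmd_de(config, outdir / "norm", outdir / "de")
    groups = cmd_classify(config, outdir / "de", outdir / "classify")
    truth = io.read_truth(outdir / "sim" / "truth.tsv")
    reference = truth["gene_id"].tolist()
    (outdir / "enrich").mkdir(exist_ok=True)
    for label, genes in (
        ("group1_up", groups.group1_up),
        ("group1_down", groups.group1_down),
        ("group2_enhanced",
         sorted(groups.group2.index[groups.group2["sublabel"] == "enhanced"])),
        ("group2_antagonized",
         sorted(groups.group2.index[groups.group2["sublabel"] == "antagonized"])),
    ):
        if not genes:
            continue
        cmd_enrich(
            config, genes,
            obo=outdir / "sim" / "ontology.obo",
            gaf=outdir / "sim" / "annotation.gaf",
            slim=outdir / "sim" / "slim.txt",
            reference_genes=reference,
            out_tsv=outdir / "enrich" / f"enrichment_{label}.tsv",
        )
    io.write_manifest(outdir / "manifest.json", config.to_dict())
    return groups.summary()
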