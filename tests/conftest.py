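import numpy as np
import pandas as pd
import pytest

from synarray import diffexpr, interaction, preprocess, simulate
from synarray.pipeline import DEFAULT_CLASS_PROPORTIONS

from synarray.validation import (
    NOISELESS_VALIDATION_PROPORTIONS as NOISELESS_PROPORTIONS,
)


def make_de_table(entries: dict[str, tuple[float, str]]) -> pd.DataFrame:
    """Minimal DE table for interaction tests: gene -> (lfc, call)."""
    genes = sorted(entries)
    return pd.DataFrame(
        {
            "lfc": [entries[g][0] for g in genes],
            "call": [entries[g][1] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline on a noiseless experiment with 100 genes per class."""
    from synarray.pipeline import PipelineConfig, cmd_run_all

    outdir = tmp_path_factory.mktemp("noiseless")
    cfg = PipelineConfig(
        n_genes=1600,
        seed=7,
        bio_sd=0.0,
        spot_sd=0.0,
        class_proportions=dict(NOISELESS_PROPORTIONS),
    )
    summary = cmd_run_all(cfg, outdir)
    from synarray.io import read_truth

    truth = read_truth(outdir / "sim" / "truth.tsv")
    groups = pd.read_csv(outdir / "classify" / "groups.tsv", sep="\t")
    return {
        "config": cfg,
        "outdir": outdir,
        "summary": summary,
        "truth": truth,
        "groups": groups,
    }


@pytest.fixture(scope="session")
def noisy_run():
    """The reference noisy experiment: 20000 genes, bio_sd 0.3, spot_sd 0.2,
    sigmoidal dye bias, planted |LFC| 1.5, analysed end to end in memory."""
    design = simulate.DesignSpec(n_genes=20000)
    truth = simulate.simulate_truth(
        design, DEFAULT_CLASS_PROPORTIONS, simulate.EffectParams(), seed=11
    )
    noise = simulate.NoiseSpec(bio_sd=0.3, spot_sd=0.2, seed=12)
    arrays = simulate.simulate_experiment(truth, design, noise)
    matrices = preprocess.preprocess_contrasts(arrays)
    de = {cid: diffexpr.de_table(m) for cid, m in matrices.items()}
    groups = interaction.classify_all(de)
    return {
        "design": design,
        "truth": truth,
        "noise": noise,
        "arrays": arrays,
        "matrices": matrices,
        "de": de,
        "groups": groups,
    }
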