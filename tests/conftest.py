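import pandas as pd
import pytest

import dosagecomp as dc
from dosagecomp import expression as ex

# compact genome: keeps simulation and file round-trips fast while still
# exercising every gene class and a multi-window PAR
SMALL_KWARGS = dict(
    n_autosomal=300, n_x_specific=60, n_par=12, n_xy_shared=10,
    n_y_specific=4, n_silent_xy_shared=2,
    autosome_lengths=(8_000_000,), x_length=4_000_000, y_length=2_000_000,
    par_length=800_000, library_size=1_000_000,
)


def small_config(**overrides) -> dc.SimulationConfig:
    kwargs = {**SMALL_KWARGS, **overrides}
    return dc.SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cfg() -> dc.SimulationConfig:
    return small_config(seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    genes, features, layout = dc.generate_annotation(small_cfg)
    counts, samples = dc.generate_counts(genes, small_cfg)
    return {
        "config": small_cfg,
        "genes": genes,
        "features": features,
        "layout": layout,
        "counts": counts,
        "samples": samples,
        "lengths": ex.gene_lengths(features),
    }


@pytest.fixture(scope="session")
def default_annotation():
    """Full-size annotation with the study's gene-class counts."""
    cfg = dc.SimulationConfig(seed=0)
    genes, features, layout = dc.generate_annotation(cfg)
    return cfg, genes, features, layout


@pytest.fixture(scope="session")
def default_run(default_annotation):
    """Full-size counts plus normalised group means at rho=0.7."""
    cfg, genes, features, layout = default_annotation
    counts, samples = dc.generate_counts(genes, cfg)
    lengths = ex.gene_lengths(features)
    means = ex.group_mean_rpkm(ex.rpkm(counts, lengths), samples)
    return {
        "config": cfg, "genes": genes, "features": features,
        "layout": layout, "counts": counts, "samples": samples,
        "lengths": lengths, "means": means,
    }


def pairs_from_genes(genes) -> pd.DataFrame:
    pr = genes.loc[genes["region"] == "XY_shared_X", "partner"]
    return pd.DataFrame({"x_gene": pr.index, "y_gene": pr.to_numpy()})
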