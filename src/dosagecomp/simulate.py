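"""Synthetic genomes, annotations, RNA-seq counts and depth tracks with a
known dosage-compensation structure.

The simulated system mirrors a heterogametic XY species with a recently
differentiated Y: an X scaffold carrying a pseudoautosomal region (PAR) at
one end, an X-specific region elsewhere, a Y scaffold with X/Y-shared
gametologues plus a handful of Y-only genes, and a set of autosomal
scaffolds. Three genotype/phenotype groups are supported: concordant XX
females (XXf), concordant XY males (XYm), and sex-reversed XX males (XXm).

The dosage model is multiplicative on the negative-binomial mean:

    mu[g, s] = baseline[g] * dosage(class[g], genotype[s])
               * length[g] / 1e3 * library_size[s] / 1e6

with dosage 1 everywhere diploid, ``rho`` for X-specific genes in XY
individuals (rho = 1 is full compensation, rho = 0.5 none), and an X/Y
split ``kappa`` / ``1 - kappa`` for gametologue pairs in XY individuals so
that the pair's summed output is conserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionClass

__all__ = [
    "SimulationConfig",
    "GenomeLayout",
    "SizingError",
    "generate_annotation",
    "generate_counts",
    "generate_depth",
    "write_fixtures",
]

GROUPS = ("XXf", "XYm", "XXm")
GROUP_GENOTYPE = {"XXf": "XX", "XYm": "XY", "XXm": "XX"}
GROUP_PHENOTYPE = {"XXf": "female", "XYm": "male", "XXm": "male"}


class SizingError(ValueError):
    """Total gene footprint does not fit on the configured scaffolds."""


@dataclass(frozen=True)
class GenomeLayout:
    """Scaffold names/lengths plus the true PAR interval on the X."""

    scaffold_lengths: dict[str, int]
    autosomes: tuple[str, ...]
    x_scaffold: str
    y_scaffold: str
    par_start: int
    par_end: int  # true PAR boundary position (bp, 0-based half-open)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated study.

    Gene-class sizes default to the annotated counts of the modelled
    genome (13,979 genes total: 667 X-specific, 39 PAR, 47 X/Y-shared
    pairs, 15 Y-only, remainder autosomal). ``rho`` is the X compensation
    factor (X-specific expression in XY relative to XX); ``kappa`` the
    fraction of a gametologue pair's XY output produced by the X copy.
    ``n_silent_xy_shared`` pairs are given zero baseline so the expression
    filter leaves 42 of 47 pairs, as in the modelled data set.
    """

    n_autosomal: int = 13_164
    n_x_specific: int = 667
    n_par: int = 39
    n_xy_shared: int = 47
    n_y_specific: int = 15
    n_silent_xy_shared: int = 5

    rho: float = 0.7
    kappa: float = 0.5
    dispersion: float = 0.1  # NB variance = mu + dispersion * mu^2

    baseline_log_mean: float = 2.1
    baseline_log_sd: float = 1.0

    library_size: int = 5_000_000
    replicates: dict[str, int] = field(
        default_factory=lambda: {"XXf": 3, "XYm": 3, "XXm": 2}
    )
    tissue: str = "brain"

    autosome_lengths: tuple[int, ...] = (80_000_000, 80_000_000, 80_000_000)
    x_length: int = 71_200_000
    y_length: int = 21_700_000
    par_length: int = 2_800_000

    window_size: int = 20_000
    depth_mean: float = 100.0
    depth_noiseless: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_autosomal": self.n_autosomal,
            "n_x_specific": self.n_x_specific,
            "n_par": self.n_par,
            "n_xy_shared": self.n_xy_shared,
            "n_y_specific": self.n_y_specific,
            "n_silent_xy_shared": self.n_silent_xy_shared,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_silent_xy_shared > self.n_xy_shared:
            raise ValueError("n_silent_xy_shared cannot exceed n_xy_shared")
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if not 0 <= self.par_length < self.x_length:
            raise ValueError("par_length must be in [0, X scaffold length)")
        if self.window_size <= 0:
            raise ValueError(f"window_size must be > 0, got {self.window_size}")
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean must be > 0, got {self.depth_mean}")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for g in self.replicates:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in replicates")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def layout(self) -> GenomeLayout:
        lengths = {
            f"contig_a{i + 1}": int(n) for i, n in enumerate(self.autosome_lengths)
        }
        autosomes = tuple(lengths)
        lengths["contig_X"] = int(self.x_length)
        lengths["contig_Y"] = int(self.y_length)
        return GenomeLayout(
            scaffold_lengths=lengths,
            autosomes=autosomes,
            x_scaffold="contig_X",
            y_scaffold="contig_Y",
            par_start=0,
            par_end=int(self.par_length),
        )

    @classmethod
    def adult_preset(cls, tissue: str = "brain", **kwargs) -> "SimulationConfig":
        """Adult single-individual design: one XXf and one XYm sample."""
        return cls(replicates={"XXf": 1, "XYm": 1}, tissue=tissue, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams so each generator is deterministic on its own
    return np.random.default_rng([int(config.seed), stream])


def _make_gene_structures(rng, n):
    """Draw exonic length, feature split and spans for ``n`` genes."""
    exon_len = rng.integers(500, 10_001, size=n)
    n_feat = rng.integers(1, 4, size=n)
    structures = []
    for L, k in zip(exon_len, n_feat):
        k = int(min(k, L // 200))  # keep every feature >= ~200 bp
        k = max(k, 1)
        cuts = np.sort(rng.integers(1, int(L), size=k - 1)) if k > 1 else np.array([], int)
        parts = np.diff(np.concatenate([[0], cuts, [int(L)]]))
        if (parts <= 0).any():  # degenerate cut; fall back to single feature
            parts = np.array([int(L)])
        gaps = rng.integers(100, 2_001, size=len(parts) - 1)
        structures.append((parts, gaps))
    return exon_len, structures


_FEATURE_TYPES = ("CDS", "five_prime_utr", "three_prime_utr")


def _place_genes(rng, gene_ids, structures, scaffold, region_start, region_end,
                 genes_out, feats_out):
    """Place genes sequentially with random intergenic gaps inside a region."""
    pos = region_start
    for gid, (parts, gaps) in zip(gene_ids, structures):
        pos += int(rng.integers(1_000, 5_001))
        start = pos
        fpos = start
        for j, part in enumerate(parts):
            feats_out.append((gid, _FEATURE_TYPES[j % 3], fpos, fpos + int(part)))
            fpos += int(part)
            if j < len(gaps):
                fpos += int(gaps[j])
        end = fpos
        if end > region_end:
            raise SizingError(
                f"gene footprint exceeds region [{region_start}, {region_end}) "
                f"on {scaffold} at gene {gid}"
            )
        genes_out.append((gid, scaffold, start, end, int(sum(parts))))
        pos = end


def generate_annotation(config: SimulationConfig):
    """Lay genes out on the simulated genome.

    Returns ``(genes, features, layout)``: a per-gene table (gene_id,
    scaffold, start, end 0-based half-open, exonic length, true region
    class, gametologue partner, silent flag), a per-feature table of
    CDS/UTR intervals, and the :class:`GenomeLayout` with the true PAR
    boundary.
    """
    rng = _rng(config, 0)
    layout = config.layout()

    classes = (
        [RegionClass.AUTOSOME] * config.n_autosomal
        + [RegionClass.PAR] * config.n_par
        + [RegionClass.X_SPECIFIC] * config.n_x_specific
        + [RegionClass.XY_SHARED_X] * config.n_xy_shared
        + [RegionClass.XY_SHARED_Y] * config.n_xy_shared
        + [RegionClass.Y_SPECIFIC] * config.n_y_specific
    )
    n_total = len(classes)
    gene_ids = [f"gene{str(i + 1).zfill(5)}" for i in range(n_total)]
    _, structures = _make_gene_structures(rng, n_total)

    genes_rows: list[tuple] = []
    feat_rows: list[tuple] = []

    idx = 0
    blocks: dict[RegionClass, tuple[list, list]] = {}
    for cls_ in (RegionClass.AUTOSOME, RegionClass.PAR, RegionClass.X_SPECIFIC,
                 RegionClass.XY_SHARED_X, RegionClass.XY_SHARED_Y,
                 RegionClass.Y_SPECIFIC):
        n = classes.count(cls_)
        blocks[cls_] = (gene_ids[idx:idx + n], structures[idx:idx + n])
        idx += n

    # autosomal genes split across autosome scaffolds proportional to length
    a_ids, a_structs = blocks[RegionClass.AUTOSOME]
    lengths = np.array([layout.scaffold_lengths[s] for s in layout.autosomes], float)
    shares = np.floor(lengths / lengths.sum() * len(a_ids)).astype(int)
    shares[-1] = len(a_ids) - shares[:-1].sum()
    off = 0
    for scaf, n in zip(layout.autosomes, shares):
        _place_genes(rng, a_ids[off:off + n], a_structs[off:off + n], scaf,
                     0, layout.scaffold_lengths[scaf], genes_rows, feat_rows)
        off += n

    x = layout.x_scaffold
    _place_genes(rng, *blocks[RegionClass.PAR], x, layout.par_start,
                 layout.par_end, genes_rows, feat_rows)
    # X-specific and shared-X genes interleave beyond the PAR boundary
    xs_ids, xs_structs = blocks[RegionClass.X_SPECIFIC]
    sh_ids, sh_structs = blocks[RegionClass.XY_SHARED_X]
    merged_ids = xs_ids + sh_ids
    merged_structs = xs_structs + sh_structs
    order = rng.permutation(len(merged_ids))
    _place_genes(rng, [merged_ids[i] for i in order],
                 [merged_structs[i] for i in order], x,
                 layout.par_end, layout.scaffold_lengths[x], genes_rows, feat_rows)

    y = layout.y_scaffold
    yy_ids = blocks[RegionClass.XY_SHARED_Y][0] + blocks[RegionClass.Y_SPECIFIC][0]
    yy_structs = blocks[RegionClass.XY_SHARED_Y][1] + blocks[RegionClass.Y_SPECIFIC][1]
    _place_genes(rng, yy_ids, yy_structs, y, 0, layout.scaffold_lengths[y],
                 genes_rows, feat_rows)

    genes = pd.DataFrame(
        genes_rows, columns=["gene_id", "scaffold", "start", "end", "length"]
    ).set_index("gene_id")
    genes["region"] = pd.Series(dict(zip(gene_ids, [c.value for c in classes])))

    partner = pd.Series("", index=genes.index, dtype=object)
    x_sh, y_sh = blocks[RegionClass.XY_SHARED_X][0], blocks[RegionClass.XY_SHARED_Y][0]
    for xg, yg in zip(x_sh, y_sh):
        partner[xg], partner[yg] = yg, xg
    genes["partner"] = partner

    silent = pd.Series(False, index=genes.index)
    for xg, yg in zip(x_sh[: config.n_silent_xy_shared],
                      y_sh[: config.n_silent_xy_shared]):
        silent[xg] = silent[yg] = True
    genes["silent"] = silent

    features = pd.DataFrame(
        feat_rows, columns=["gene_id", "feature", "start", "end"]
    )
    return genes, features, layout


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        for r in range(config.replicates.get(group, 0)):
            rows.append(
                {
                    "sample": f"{group}_{r + 1}",
                    "genotype": GROUP_GENOTYPE[group],
                    "phenotype": GROUP_PHENOTYPE[group],
                    "group": group,
                    "tissue": config.tissue,
                }
            )
    if not rows:
        raise ValueError("no groups with replicates > 0")
    return pd.DataFrame(rows)


def _dosage_factor(region: np.ndarray, genotype: str, rho: float,
                   kappa: float) -> np.ndarray:
    d = np.ones(len(region))
    is_xy = genotype == "XY"
    d[region == RegionClass.X_SPECIFIC.value] = rho if is_xy else 1.0
    d[region == RegionClass.XY_SHARED_X.value] = kappa if is_xy else 1.0
    d[region == RegionClass.XY_SHARED_Y.value] = (1.0 - kappa) if is_xy else 0.0
    d[region == RegionClass.Y_SPECIFIC.value] = 1.0 if is_xy else 0.0
    return d


def generate_counts(genes: pd.DataFrame, config: SimulationConfig):
    """Negative-binomial counts for every sample group.

    Baselines are drawn log-normal per gene (gametologue pairs share one
    baseline so their summed XY output equals the XX X-copy output) and
    rescaled so that the expected total count of an XX sample equals the
    configured library size exactly. Returns ``(counts, samples)``.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    rng = _rng(config, 1)
    samples = sample_sheet(config)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=len(genes))
    baseline = pd.Series(baseline, index=genes.index)
    # a pair's Y copy inherits the X copy's baseline: summed output conserved
    shared_x = genes.index[genes["region"] == RegionClass.XY_SHARED_X.value]
    for xg in shared_x:
        baseline[genes.loc[xg, "partner"]] = baseline[xg]
    baseline[genes["silent"]] = 0.0

    region = genes["region"].to_numpy()
    lengths = genes["length"].to_numpy(float)
    # anchor expected XX-sample totals at the library size
    xx_dosage = _dosage_factor(region, "XX", config.rho, config.kappa)
    mass = float((baseline.to_numpy() * xx_dosage * lengths / 1e3).sum())
    if mass <= 0:
        raise ValueError("all baselines are zero; nothing to simulate")
    baseline *= 1e6 / mass

    phi = config.dispersion
    cols = {}
    for _, row in samples.iterrows():
        dos = _dosage_factor(region, row["genotype"], config.rho, config.kappa)
        mu = (baseline.to_numpy() * dos * lengths / 1e3
              * config.library_size / 1e6)
        if phi == 0:
            draw = rng.poisson(mu)
        else:
            n = 1.0 / phi
            p = n / (n + np.where(mu > 0, mu, 1.0))
            draw = np.where(mu > 0, rng.negative_binomial(n, p), 0)
        cols[row["sample"]] = draw
    counts = pd.DataFrame(cols, index=genes.index)
    return counts, samples


def _windows(length: int, window: int) -> np.ndarray:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return starts, ends


def generate_depth(config: SimulationConfig, layout: GenomeLayout | None = None):
    """Windowed male DNA read-depth tracks, one per scaffold.

    Depth per window is Poisson with mean ``depth_mean`` on diploid
    sequence (autosomes, PAR) and ``depth_mean / 2`` on hemizygous
    sequence (X-specific, whole Y), scaled by window width for a partial
    last window. ``depth_noiseless`` replaces the draw by the mean.
    Windows are 0-based half-open on a fixed grid.
    """
    rng = _rng(config, 2)
    if layout is None:
        layout = config.layout()
    w = config.window_size
    tracks: dict[str, pd.DataFrame] = {}
    for scaf, length in layout.scaffold_lengths.items():
        starts, ends = _windows(length, w)
        mids = (starts + ends) / 2
        if scaf == layout.x_scaffold:
            diploid = (mids >= layout.par_start) & (mids < layout.par_end)
        elif scaf == layout.y_scaffold:
            diploid = np.zeros(len(starts), bool)
        else:
            diploid = np.ones(len(starts), bool)
        mean = np.where(diploid, config.depth_mean, config.depth_mean / 2.0)
        mean = mean * (ends - starts) / w
        depth = mean if config.depth_noiseless else rng.poisson(mean).astype(float)
        tracks[scaf] = pd.DataFrame(
            {"scaffold": scaf, "start": starts, "end": ends, "depth": depth}
        )
    return tracks


def write_fixtures(genes: pd.DataFrame, features: pd.DataFrame,
                   counts: pd.DataFrame, samples: pd.DataFrame,
                   tracks: dict[str, pd.DataFrame], layout: GenomeLayout,
                   outdir) -> dict[str, str]:
    """Write the five-file fixture set (GFF3, three TSVs, one bedGraph)."""
    from . import io as dcio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "pairs": outdir / "pairs.tsv",
        "depth": outdir / "depth.bedgraph",
    }
    dcio.write_gff3(genes, features, layout, paths["annotation"])
    dcio.write_counts(counts, paths["counts"])
    dcio.write_samples(samples, paths["samples"])
    pairs = genes.loc[genes["region"] == RegionClass.XY_SHARED_X.value, "partner"]
    dcio.write_pairs(
        pd.DataFrame({"x_gene": pairs.index, "y_gene": pairs.to_numpy()}),
        paths["pairs"],
    )
    dcio.write_bedgraph(tracks, paths["depth"])
    return {k: str(v) for k, v in paths.items()}
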