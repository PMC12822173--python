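"""End-to-end orchestration: simulate, classify, analyze.

Each stage reads only the previous stage's declared files, so a run can
be resumed from any intermediate. All outputs are TSV tables with a
commented metadata header recording the seed, thresholds and the
normalisation/test conventions in force, and a fixed configuration plus
seed reproduces every output byte for byte (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, expression, io as dcio, regions, stats
from .regions import RegionClass
from .simulate import (SimulationConfig, generate_annotation, generate_counts,
                       generate_depth, write_fixtures)

__all__ = ["AnalysisConfig", "run_simulate", "run_classify", "run_analyze",
           "run_all"]

log = logging.getLogger("dosagecomp")

COMPARISONS = (("XYm", "XXf"), ("XYm", "XXm"), ("XXm", "XXf"))


@dataclass
class AnalysisConfig:
    """Declarative configuration of a pipeline run."""

    annotation: str = "annotation.gff3"
    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    pairs: str = "pairs.tsv"
    depth: str | None = "depth.bedgraph"
    outdir: str = "results"

    x_scaffold: str | None = None      # default: GFF3 pragma
    y_scaffold: str | None = None
    par_interval: tuple[int, int] | None = None  # bypass when no depth track

    window_size: int = 20_000
    hemizygous_max: float = 0.75
    diploid_min: float = 0.85
    min_sse_reduction: float = 0.10
    min_delta_mean: float = 0.2

    min_rpkm: float = 0.0
    tmm: bool = False
    n_perm: int = 10_000
    seed: int = 0
    comparisons: tuple[tuple[str, str], ...] = COMPARISONS

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValueError("comparisons must be non-empty")
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in dcio.VALID_GROUPS:
                    raise ValueError(f"unknown group in comparison: {g}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        # a combined config file may carry a "simulate:" section for the
        # generator and an "analyze:" section for this stage
        data.pop("simulate", None)
        if "analyze" in data:
            data = data["analyze"] or {}
        if "comparisons" in data:
            data["comparisons"] = tuple(
                tuple(c.split("/")) if isinstance(c, str) else tuple(c)
                for c in data["comparisons"])
        if "par_interval" in data and data["par_interval"] is not None:
            data["par_interval"] = tuple(data["par_interval"])
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def check_inputs(self, need_depth: bool = False) -> None:
        required = [self.annotation, self.counts, self.samples, self.pairs]
        if need_depth and self.depth is not None:
            required.append(self.depth)
        for p in required:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")

    def _metadata(self) -> dict:
        return {
            "dosagecomp_version": __version__,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "min_rpkm": self.min_rpkm,
            "tmm": self.tmm,
            "window_size": self.window_size,
            "scaffold_call_thresholds":
                f"hemizygous<={self.hemizygous_max},diploid>={self.diploid_min}",
            "boundary_thresholds":
                f"sse_reduction>={self.min_sse_reduction},"
                f"delta_mean>={self.min_delta_mean}",
            "comparisons": ",".join(f"{a}/{b}" for a, b in self.comparisons),
            "normalisation": "library size = column total"
                             + (" * TMM factor" if self.tmm else ""),
            "ratio_convention": "log2(group-mean RPKM A / group-mean RPKM B)",
            "zero_handling": "genes with mean RPKM <= min_rpkm in either "
                             "group excluded (no pseudocounts)",
            "permutation_statistic": "absolute difference of medians",
            "median_test_ties": "at-or-below row",
        }


def run_simulate(simconfig: SimulationConfig, outdir) -> dict[str, str]:
    """Generate a full fixture set on disk; returns the file paths."""
    log.info("simulating with seed %d", simconfig.seed)
    genes, features, layout = generate_annotation(simconfig)
    counts, samples = generate_counts(genes, simconfig)
    tracks = generate_depth(simconfig, layout)
    return write_fixtures(genes, features, counts, samples, tracks, layout,
                          outdir)


def run_classify(cfg: AnalysisConfig):
    """Depth normalisation, scaffold calls, PAR boundary, gene classes.

    When ``cfg.depth`` is None the boundary step is bypassed and the PAR
    interval must be supplied explicitly in the config.
    """
    cfg.check_inputs(need_depth=True)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, _features, layout = dcio.read_gff3(cfg.annotation)
    x_scaf = cfg.x_scaffold or (layout.x_scaffold if layout else None)
    y_scaf = cfg.y_scaffold or (layout.y_scaffold if layout else None)
    if x_scaf is None or y_scaf is None:
        raise ValueError("X/Y scaffolds not given and not in the annotation")
    pairs = dcio.read_pairs(cfg.pairs)
    meta = cfg._metadata()

    boundary = None
    calls = []
    if cfg.depth is not None:
        tracks = dcio.read_bedgraph(cfg.depth)
        autosomal = [s for s in tracks if s not in (x_scaf, y_scaf)]
        ratio_tracks, auto_median = regions.normalize_depth(tracks, autosomal)
        meta["autosomal_median_depth"] = auto_median
        for scaf, track in ratio_tracks.items():
            calls.append(regions.call_scaffold_class(
                track, hemizygous_max=cfg.hemizygous_max,
                diploid_min=cfg.diploid_min,
                min_sse_reduction=cfg.min_sse_reduction,
                min_delta_mean=cfg.min_delta_mean))
        boundary = regions.detect_par_boundary(
            ratio_tracks[x_scaf], min_sse_reduction=cfg.min_sse_reduction,
            min_delta_mean=cfg.min_delta_mean)
        log.info("PAR boundary: %s", boundary)
        if boundary is not None:
            scaf_len = int(ratio_tracks[x_scaf]["end"].iloc[-1])
            par_interval = ((0, boundary.boundary_bp)
                            if boundary.diploid_side == "left"
                            else (boundary.boundary_bp, scaf_len))
        else:
            par_interval = cfg.par_interval
    else:
        par_interval = cfg.par_interval
    if par_interval is None:
        raise ValueError("no PAR boundary detected and no explicit "
                         "par_interval configured")

    classified = regions.classify_genes(genes, x_scaf, y_scaf, par_interval,
                                        pairs)
    calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    boundary_df = pd.DataFrame(
        [dataclasses.asdict(boundary)] if boundary is not None else [])
    dcio.write_report_table(calls_df, outdir / "scaffold_calls.tsv", meta)
    dcio.write_report_table(boundary_df, outdir / "par_boundary.tsv", meta)
    out_genes = classified.reset_index()[
        ["gene_id", "scaffold", "start", "end", "region", "partner",
         "midpoint", "spans_boundary"]]
    dcio.write_report_table(out_genes, outdir / "genes_classified.tsv", meta)
    return {"scaffold_calls": calls_df, "par_boundary": boundary,
            "genes": classified, "par_interval": par_interval}


def _gene_table(cfg: AnalysisConfig):
    """Classified gene table: from a classify run if present, else truth
    classes carried in the annotation."""
    classified_path = Path(cfg.outdir) / "genes_classified.tsv"
    genes, features, _ = dcio.read_gff3(cfg.annotation)
    if classified_path.exists():
        df, _ = dcio.read_report_table(classified_path)
        df = df.set_index("gene_id")
        genes = genes.drop(columns=["region", "partner"], errors="ignore")
        genes = genes.join(df[["region", "partner", "midpoint"]])
    else:
        genes["midpoint"] = (genes["start"] + genes["end"]) / 2.0
    return genes, features


def run_analyze(cfg: AnalysisConfig):
    """Compute every expression panel and test table of the dosage report."""
    cfg.check_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, features = _gene_table(cfg)
    counts = dcio.read_counts(cfg.counts)
    samples = dcio.read_samples(cfg.samples)
    pairs = dcio.read_pairs(cfg.pairs)
    meta = cfg._metadata()

    lengths = expression.gene_lengths(features)
    factors = expression.tmm_factors(counts) if cfg.tmm else None
    rpkm = expression.rpkm(counts, lengths, factors)
    cpm = expression.cpm(counts, factors)
    means = expression.group_mean_rpkm(rpkm, samples)
    cpm_means = expression.group_mean_rpkm(cpm, samples)
    classes = genes["region"]

    # per-comparison per-gene ratios, class medians and slopes
    ratio_frames, median_frames, slope_frames = [], [], []
    for a, b in cfg.comparisons:
        rt = expression.per_gene_ratio(means, a, b, classes,
                                       midpoints=genes["midpoint"],
                                       min_rpkm=cfg.min_rpkm)
        med = expression.median_ratio_by_class(rt)
        med.insert(0, "comparison", f"{a}/{b}")
        median_frames.append(med)
        pos = rt.reset_index(names="gene_id")
        pos.insert(0, "comparison", f"{a}/{b}")
        ratio_frames.append(pos)
        sl = expression.class_slope(cpm_means[a], cpm_means[b], classes)
        sl.insert(0, "comparison", f"{a}/{b}")
        slope_frames.append(sl)

    per_gene_auto, auto_medians = expression.ratio_to_autosomal_median(
        means, classes, min_rpkm=cfg.min_rpkm)
    pair_table, pair_medians = expression.gametologue_sum(
        means, pairs, samples, min_rpkm=cfg.min_rpkm)

    tests = _run_tests(cfg, ratio_frames, per_gene_auto, means)

    report = {
        "median_ratios": pd.concat(median_frames, ignore_index=True),
        "ratio_to_autosomal": auto_medians,
        "gametologue_pairs": pair_table,
        "gametologue_medians": pair_medians,
        "class_slopes": pd.concat(slope_frames, ignore_index=True),
        "positional_ratios": pd.concat(ratio_frames, ignore_index=True),
        "tests": tests,
    }
    for name, df in report.items():
        dcio.write_report_table(df, outdir / f"{name}.tsv", meta)
    report["metadata"] = meta
    return report


def _run_tests(cfg: AnalysisConfig, ratio_frames, per_gene_auto, means):
    """Mood's tests on ratio distributions; permutation tests on
    within-group expression relative to the autosomal median."""
    rows = []

    def add(comparison, class_a, class_b, va, vb, test, result):
        rows.append({
            "comparison": comparison, "class_a": class_a, "class_b": class_b,
            "n_a": len(va), "n_b": len(vb), "test": test,
            "statistic": (result.statistic if test == "moods"
                          else result.observed),
            "p_value": result.p_value,
            "p_formatted": stats.format_p(result.p_value),
            "method": (result.method if test == "moods"
                       else ("exhaustive" if result.exact else "monte-carlo")),
        })

    auto = RegionClass.AUTOSOME.value
    for rt in ratio_frames:
        comparison = rt["comparison"].iloc[0]
        vals = {
            auto: rt.loc[rt["region"] == auto, "log2_ratio"].to_numpy(),
            expression.X_TOTAL: rt.loc[
                rt["region"].isin([RegionClass.X_SPECIFIC.value,
                                   RegionClass.XY_SHARED_X.value]),
                "log2_ratio"].to_numpy(),
            RegionClass.PAR.value: rt.loc[
                rt["region"] == RegionClass.PAR.value, "log2_ratio"].to_numpy(),
            RegionClass.XY_SHARED_X.value: rt.loc[
                rt["region"] == RegionClass.XY_SHARED_X.value,
                "log2_ratio"].to_numpy(),
        }
        for cls_ in (expression.X_TOTAL, RegionClass.PAR.value,
                     RegionClass.XY_SHARED_X.value):
            if len(vals[cls_]) >= 2 and len(vals[auto]) >= 2:
                res = stats.moods_median_test(vals[cls_], vals[auto])
                add(comparison, cls_, auto, vals[cls_], vals[auto],
                    "moods", res)

    xs = RegionClass.X_SPECIFIC.value
    par = RegionClass.PAR.value
    for gi, group in enumerate(means.columns):
        sub = per_gene_auto[[group, "region"]]
        sub = sub[sub[group] > cfg.min_rpkm]
        byclass = {c: sub.loc[sub["region"] == c, group].to_numpy()
                   for c in (auto, xs, par)}
        for ca, cb in ((xs, auto), (par, auto), (par, xs)):
            if len(byclass[ca]) >= 2 and len(byclass[cb]) >= 2:
                res = stats.permutation_median_diff_test(
                    byclass[ca], byclass[cb], n_perm=cfg.n_perm,
                    seed=cfg.seed * 100 + gi)
                add(f"within {group}", ca, cb, byclass[ca], byclass[cb],
                    "permutation", res)
    return pd.DataFrame(rows)


def run_all(simconfig: SimulationConfig, cfg: AnalysisConfig):
    """simulate -> classify -> analyze in one call."""
    fixture_dir = Path(cfg.annotation).parent
    run_simulate(simconfig, fixture_dir)
    run_classify(cfg)
    return run_analyze(cfg)
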