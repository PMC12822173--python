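"""Count normalisation and class-level dosage statistics.

Counts are normalised to CPM (counts per million) and RPKM (reads per
kilobase of exonic gene model per million counted reads); library size is
the column total of the count matrix. Dosage is then summarised four
ways, all on group-mean RPKM:

* per-gene log2 expression ratios between two groups, with per-class
  medians ("total X output" pools X-specific and X-borne gametologues);
* per-gene RPKM relative to the group's autosomal median, within each
  group independently;
* gametologue-pair output: X copy, Y copy and their sum per group;
* per-class zero-intercept regression slopes of one group's mean CPM on
  another's.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger("dosagecomp")

from .regions import RegionClass

__all__ = [
    "gene_lengths",
    "cpm",
    "rpkm",
    "group_mean_rpkm",
    "filter_expressed",
    "per_gene_ratio",
    "median_ratio_by_class",
    "ratio_to_autosomal_median",
    "gametologue_sum",
    "class_slope",
    "X_TOTAL",
]

#: pseudo-class pooling X-specific genes with X-borne gametologues
X_TOTAL = "X_total"


def gene_lengths(features: pd.DataFrame) -> pd.Series:
    """Exonic length per gene: size of the union of its CDS/UTR intervals.

    Overlapping features are merged, not summed, matching how reads
    overlapping any exonic feature of a gene are counted once.
    """
    if features.empty:
        raise ValueError("empty feature table")
    f = features.sort_values(["gene_id", "start"], kind="mergesort")
    cummax_end = f.groupby("gene_id")["end"].cummax()
    prev_end = cummax_end.groupby(f["gene_id"]).shift(1)
    covered = (f["end"].combine(cummax_end, min)
               - np.maximum(f["start"], prev_end.fillna(-np.inf)))
    # take each interval's novel contribution beyond what is already covered
    novel = np.minimum(covered, f["end"] - f["start"]).clip(lower=0)
    lengths = novel.groupby(f["gene_id"]).sum().astype(int)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0][:3])
        raise ValueError(f"zero-length gene model(s): {bad}")
    lengths.name = "length"
    return lengths


def _libsizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    return lib


def cpm(counts: pd.DataFrame,
        norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / effective library size.

    The library size is the sample's column total, optionally scaled by
    TMM ``norm_factors``.
    """
    lib = _libsizes(counts)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    return counts * 1e6 / lib


def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (libsize * length)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:3])
        raise ValueError(f"no length for gene(s): {missing}")
    return cpm(counts, norm_factors) * 1e3 / lengths.to_numpy()[:, None]


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values composition factors.

    Effective library size = raw library size * factor. The reference
    sample is the one whose 75th count-fraction percentile is closest to
    the mean across samples; per sample, gene-wise log ratios (M) are
    trimmed symmetrically by ``trim_m`` and absolute expression (A) by
    ``trim_a``, and the factor is 2 to the inverse-variance-weighted
    mean M. Factors are rescaled to geometric mean 1. Off by default:
    plain library-size normalisation is used unless composition bias is
    a concern.
    """
    lib = _libsizes(counts)
    frac = counts / lib
    q75 = frac.quantile(0.75)
    ref = (q75 - q75.mean()).abs().idxmin()

    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        x, r = counts[s].to_numpy(float), counts[ref].to_numpy(float)
        nx, nr = float(lib[s]), float(lib[ref])
        keep = (x > 0) & (r > 0)
        x, r = x[keep], r[keep]
        m = np.log2((x / nx) / (r / nr))
        a = 0.5 * np.log2((x / nx) * (r / nr))
        w = 1.0 / ((nx - x) / (nx * x) + (nr - r) / (nr * r))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        factors[s] = float(2 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def group_mean_rpkm(rpkm_matrix: pd.DataFrame,
                    samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean expression per gene within each sample group."""
    known = {"XXf", "XYm", "XXm"}
    unknown = set(samples["group"]) - known
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    if set(samples["sample"]) != set(rpkm_matrix.columns):
        raise ValueError("sample sheet does not match matrix columns")
    groups = samples.set_index("sample")["group"]
    return rpkm_matrix.T.groupby(groups).mean().T


def filter_expressed(means: pd.DataFrame, comparison: tuple[str, str],
                     min_rpkm: float = 0.0,
                     classes: pd.Series | None = None) -> pd.Index:
    """Genes with mean expression above ``min_rpkm`` in both groups.

    When ``classes`` is given the number of removed genes is logged per
    region class.
    """
    a, b = comparison
    keep = (means[a] > min_rpkm) & (means[b] > min_rpkm)
    if classes is not None and (~keep).any():
        removed = classes.reindex(means.index[~keep]).value_counts()
        log.info("filter (%s/%s, min_rpkm=%g) removed: %s", a, b, min_rpkm,
                 removed.to_dict())
    return means.index[keep]


def per_gene_ratio(means: pd.DataFrame, a: str, b: str,
                   classes: pd.Series,
                   midpoints: pd.Series | None = None,
                   min_rpkm: float = 0.0) -> pd.DataFrame:
    """log2(mean A / mean B) per expressed gene, with region class.

    Zero-expression genes are excluded (not pseudocounted): class medians
    are robust to the exclusion and only finite ratios are meaningful.
    """
    keep = filter_expressed(means, (a, b), min_rpkm, classes)
    ratio = np.log2(means.loc[keep, a] / means.loc[keep, b])
    out = pd.DataFrame({
        "log2_ratio": ratio,
        "region": classes.reindex(keep),
    })
    out.attrs["comparison"] = f"{a}/{b}"
    if midpoints is not None:
        out["midpoint"] = midpoints.reindex(keep)
    return out


def median_ratio_by_class(ratio_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class median log2 ratio and gene count.

    Reports the plain location classes plus ``X_total`` (X-specific and
    X-borne gametologues pooled, the X chromosome's whole output); the
    "XY shared" entry is the X-copy class alone. Empty classes are
    omitted.
    """
    rows = []
    class_sets = {
        RegionClass.AUTOSOME.value: [RegionClass.AUTOSOME.value],
        RegionClass.PAR.value: [RegionClass.PAR.value],
        X_TOTAL: [RegionClass.X_SPECIFIC.value, RegionClass.XY_SHARED_X.value],
        RegionClass.X_SPECIFIC.value: [RegionClass.X_SPECIFIC.value],
        RegionClass.XY_SHARED_X.value: [RegionClass.XY_SHARED_X.value],
    }
    for label, members in class_sets.items():
        vals = ratio_table.loc[ratio_table["region"].isin(members), "log2_ratio"]
        if len(vals) == 0:
            continue
        med = float(vals.median())
        rows.append({
            "class": label,
            "n": len(vals),
            "median_log2_ratio": med,
            "median_ratio": 2.0 ** med,
        })
    out = pd.DataFrame(rows)
    out.attrs["comparison"] = ratio_table.attrs.get("comparison", "")
    return out


def ratio_to_autosomal_median(means: pd.DataFrame, classes: pd.Series,
                              min_rpkm: float = 0.0):
    """Expression relative to the autosomal median, within each group.

    Every gene's group-mean RPKM is divided by that group's median RPKM
    over expressed autosomal genes, so the autosome class median is 1 by
    construction and the X-specific and PAR medians read directly as
    X:autosome and PAR:autosome output. Returns ``(per_gene, class_medians)``.
    """
    classes = classes.reindex(means.index)
    auto = means.index[(classes == RegionClass.AUTOSOME.value)]
    per_gene = {}
    for group in means.columns:
        expressed = means.loc[auto, group]
        expressed = expressed[expressed > min_rpkm]
        if len(expressed) == 0:
            raise ValueError(f"no expressed autosomal gene in group {group}")
        med = float(expressed.median())
        if med <= 0:
            raise ValueError(f"autosomal median RPKM is zero in group {group}")
        per_gene[group] = means[group] / med
    per_gene = pd.DataFrame(per_gene)
    per_gene["region"] = classes

    rows = []
    for group in means.columns:
        for label in (RegionClass.AUTOSOME.value, RegionClass.X_SPECIFIC.value,
                      RegionClass.PAR.value):
            sub = per_gene.loc[(per_gene["region"] == label)
                               & (means[group] > min_rpkm), group]
            if len(sub) == 0:
                continue
            rows.append({
                "group": group,
                "class": label,
                "n": len(sub),
                "median_ratio_to_autosomal": float(sub.median()),
            })
    return per_gene, pd.DataFrame(rows)


def gametologue_sum(means: pd.DataFrame, pairs: pd.DataFrame,
                    samples: pd.DataFrame, min_rpkm: float = 0.0):
    """X-copy, Y-copy and summed gametologue output per pair and group.

    For XY groups the pair's total output is X-copy + Y-copy RPKM (each
    length-corrected with its own gene model); for XX groups the Y copy
    is absent and the total is the X copy alone. Pairs whose X copy is
    unexpressed in every group are dropped. Returns ``(per_pair,
    class_medians)`` where the summary holds per-group medians of the
    X-copy, Y-copy and summed output.
    """
    missing = [g for col in ("x_gene", "y_gene") for g in pairs[col]
               if g not in means.index]
    if missing:
        raise ValueError(f"pairs reference genes absent from the matrix: "
                         f"{missing[:3]}")
    genotype = samples.drop_duplicates("group").set_index("group")["genotype"]
    x = means.loc[pairs["x_gene"].to_numpy()].set_axis(pairs.index)
    y = means.loc[pairs["y_gene"].to_numpy()].set_axis(pairs.index)
    expressed = (x > min_rpkm).any(axis=1)
    x, y = x[expressed], y[expressed]
    kept = pairs[expressed.to_numpy()]

    per_pair = pd.DataFrame({"x_gene": kept["x_gene"].to_numpy(),
                             "y_gene": kept["y_gene"].to_numpy()},
                            index=kept.index)
    rows = []
    for group in means.columns:
        is_xy = genotype.get(group) == "XY"
        total = x[group] + y[group] if is_xy else x[group]
        per_pair[f"{group}_x"] = x[group].to_numpy()
        per_pair[f"{group}_y"] = y[group].to_numpy() if is_xy else 0.0
        per_pair[f"{group}_sum"] = total.to_numpy()
        rows += [
            {"group": group, "component": "x_copy",
             "median_rpkm": float(x[group].median()), "n": len(x)},
            {"group": group, "component": "y_copy",
             "median_rpkm": float(y[group].median()) if is_xy else 0.0,
             "n": len(y)},
            {"group": group, "component": "sum",
             "median_rpkm": float(total.median()), "n": len(total)},
        ]
    return per_pair, pd.DataFrame(rows)


def class_slope(means_a: pd.Series, means_b: pd.Series,
                classes: pd.Series) -> pd.DataFrame:
    """Zero-intercept least-squares slope of A on B per region class.

    The dosage hypothesis is proportional scaling through the origin, so
    the fit is A = slope * B with no intercept; R-squared is computed
    against that same zero-intercept fit (uncentred total sum of
    squares). X here means total X output (X-specific plus X-borne
    gametologues); autosomes are reported separately.
    """
    classes = classes.reindex(means_a.index)
    rows = []
    for label, members in {
        RegionClass.AUTOSOME.value: [RegionClass.AUTOSOME.value],
        X_TOTAL: [RegionClass.X_SPECIFIC.value, RegionClass.XY_SHARED_X.value],
    }.items():
        mask = classes.isin(members)
        a = means_a[mask].to_numpy(float)
        b = means_b[mask].to_numpy(float)
        if len(a) < 2:
            raise ValueError(f"need >= 2 genes in class {label}")
        ssb = float(b @ b)
        if ssb == 0:
            raise ValueError(f"all-zero predictor in class {label}")
        slope = float(a @ b) / ssb
        resid = a - slope * b
        ss_tot = float(a @ a)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else math.nan
        rows.append({"class": label, "n": len(a), "slope": slope, "r2": r2})
    return pd.DataFrame(rows)
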