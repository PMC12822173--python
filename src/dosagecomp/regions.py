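"""Sex-linked region identification from windowed DNA read depth.

In an XY male, single-copy (hemizygous) sequence — the X-specific region
and the whole Y — is sequenced at roughly half the depth of diploid
sequence, while the pseudoautosomal region (PAR) stays diploid. Windowed
depth normalised to the autosomal median therefore sits near 1.0 over
autosomes and the PAR and near 0.5 over X-specific and Y sequence, and
the PAR boundary appears as a step change on the X scaffold. The boundary
is located with an exhaustive single-changepoint fit: the split that
minimises the total within-segment sum of squared deviations of the
depth ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionClass",
    "ScaffoldCall",
    "ParBoundary",
    "normalize_depth",
    "call_scaffold_class",
    "detect_par_boundary",
    "classify_genes",
]


class RegionClass(str, enum.Enum):
    """Exhaustive, mutually exclusive gene location classes."""

    AUTOSOME = "autosome"
    PAR = "PAR"
    X_SPECIFIC = "X_specific"
    XY_SHARED_X = "XY_shared_X"
    XY_SHARED_Y = "XY_shared_Y"
    Y_SPECIFIC = "Y_specific"


@dataclass(frozen=True)
class ScaffoldCall:
    scaffold: str
    median_ratio: float
    by_median: str          # diploid-like | hemizygous-like | mixed
    call: str               # final call; "mixed" when a ploidy step is found
    n_windows: int


@dataclass(frozen=True)
class ParBoundary:
    """A ploidy changepoint on a scaffold.

    ``boundary_bp`` is the changepoint position: the start of the first
    window after the split, i.e. the first hemizygous window when the
    diploid segment comes first, and the first diploid window otherwise.
    """

    scaffold: str
    boundary_bp: int
    diploid_side: str       # "left" | "right"
    diploid_mean: float
    hemizygous_mean: float
    sse_reduction: float


def _check_track(track: pd.DataFrame) -> None:
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    if (np.diff(starts) <= 0).any():
        raise ValueError("windows must be sorted and non-overlapping")
    if (ends[:-1] > starts[1:]).any():
        raise ValueError("windows overlap")
    widths = ends - starts
    if len(widths) > 1 and not (widths[:-1] == widths[0]).all():
        raise ValueError("windows must have constant width except the last")
    if (track["depth"].to_numpy() < 0).any():
        raise ValueError("negative depth")


def normalize_depth(tracks: dict[str, pd.DataFrame],
                    autosomal_scaffolds) -> tuple[dict[str, pd.DataFrame], float]:
    """Divide every window's depth by the median autosomal window depth.

    The autosomal *median* (not mean) is used so that collapsed repeats or
    other high-coverage outliers do not shift the diploid reference level.
    Returns the ratio tracks (original columns plus ``ratio``) and the
    median used, which callers should record as track metadata.
    """
    autosomal_scaffolds = set(autosomal_scaffolds)
    if not autosomal_scaffolds & set(tracks):
        raise ValueError("no autosomal scaffold present in the depth tracks")
    for track in tracks.values():
        _check_track(track)
    auto_depths = np.concatenate(
        [tracks[s]["depth"].to_numpy(float) for s in tracks
         if s in autosomal_scaffolds]
    )
    if auto_depths.size == 0:
        raise ValueError("autosomal scaffolds contain no windows")
    med = float(np.median(auto_depths))
    if med <= 0:
        raise ValueError("autosomal median depth is zero")
    out = {}
    for scaf, track in tracks.items():
        t = track.copy()
        t["ratio"] = t["depth"].to_numpy(float) / med
        t.attrs["autosomal_median_depth"] = med
        out[scaf] = t
    return out, med


def _two_segment_fit(ratio: np.ndarray):
    """Exhaustive single-changepoint SSE fit.

    Returns ``(split, sse_best, sse_total, mean_left, mean_right)`` where
    ``split`` is the number of windows in the left segment. O(n) via
    prefix sums; equivalent to brute force over every split point.
    """
    n = len(ratio)
    csum = np.cumsum(ratio)
    csq = np.cumsum(ratio ** 2)
    total_sum, total_sq = csum[-1], csq[-1]
    k = np.arange(1, n)  # left segment sizes
    left_sum = csum[:-1]
    left_sq = csq[:-1]
    sse_left = left_sq - left_sum ** 2 / k
    right_sum = total_sum - left_sum
    right_sq = total_sq - left_sq
    sse_right = right_sq - right_sum ** 2 / (n - k)
    sse = sse_left + sse_right
    best = int(np.argmin(sse))
    split = best + 1
    sse_total = float(total_sq - total_sum ** 2 / n)
    return (split, float(sse[best]), sse_total,
            float(left_sum[best] / split),
            float(right_sum[best] / (n - split)))


def detect_par_boundary(ratio_track: pd.DataFrame, *,
                        min_sse_reduction: float = 0.10,
                        min_delta_mean: float = 0.2) -> ParBoundary | None:
    """Locate a single ploidy changepoint in a depth-ratio track.

    Returns ``None`` when no convincing step exists: the best split must
    cut the total SSE by at least ``min_sse_reduction`` and separate
    segment means by at least ``min_delta_mean`` (diploid-vs-hemizygous
    geometry puts the true gap near 0.5). Orientation-agnostic: the fit
    is symmetric, so a PAR at either end of the scaffold is found.
    """
    _check_track(ratio_track)
    ratio = ratio_track["ratio"].to_numpy(float)
    if len(ratio) < 4:
        raise ValueError("need at least 4 windows to detect a boundary")
    split, sse_best, sse_total, mean_l, mean_r = _two_segment_fit(ratio)
    if sse_total <= 0:  # constant track
        return None
    reduction = 1.0 - sse_best / sse_total
    if reduction < min_sse_reduction or abs(mean_l - mean_r) < min_delta_mean:
        return None
    diploid_side = "left" if mean_l > mean_r else "right"
    dip, hemi = (mean_l, mean_r) if diploid_side == "left" else (mean_r, mean_l)
    return ParBoundary(
        scaffold=str(ratio_track["scaffold"].iloc[0]),
        boundary_bp=int(ratio_track["start"].iloc[split]),
        diploid_side=diploid_side,
        diploid_mean=dip,
        hemizygous_mean=hemi,
        sse_reduction=float(reduction),
    )


def call_scaffold_class(ratio_track: pd.DataFrame, *,
                        hemizygous_max: float = 0.75,
                        diploid_min: float = 0.85,
                        **boundary_kwargs) -> ScaffoldCall:
    """Call a scaffold diploid-like, hemizygous-like or mixed.

    The primary call uses the median depth ratio (<= ``hemizygous_max``
    hemizygous-like, >= ``diploid_min`` diploid-like, mixed between). A
    scaffold dominated by hemizygous sequence but carrying a diploid
    segment — an X with a PAR — would be miscalled by the median alone,
    so a segment scan upgrades the call to mixed when a changepoint
    separates a diploid-level and a hemizygous-level segment.
    """
    _check_track(ratio_track)
    if len(ratio_track) < 4:
        raise ValueError("need at least 4 windows to call a scaffold")
    med = float(ratio_track["ratio"].median())
    if med <= hemizygous_max:
        by_median = "hemizygous-like"
    elif med >= diploid_min:
        by_median = "diploid-like"
    else:
        by_median = "mixed"
    call = by_median
    boundary = detect_par_boundary(ratio_track, **boundary_kwargs)
    if boundary is not None and (boundary.diploid_mean >= diploid_min
                                 and boundary.hemizygous_mean <= hemizygous_max):
        call = "mixed"
    return ScaffoldCall(
        scaffold=str(ratio_track["scaffold"].iloc[0]),
        median_ratio=med,
        by_median=by_median,
        call=call,
        n_windows=len(ratio_track),
    )


def classify_genes(genes: pd.DataFrame, x_scaffold: str, y_scaffold: str,
                   par_interval: tuple[int, int] | None,
                   pairs: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene one region class from its location and pairing.

    A gene on the X scaffold whose midpoint falls inside ``par_interval``
    (0-based half-open, on the X) is PAR; elsewhere on the X it is
    XY_shared_X when listed in ``pairs`` else X_specific; on the Y it is
    XY_shared_Y when paired else Y_specific; anywhere else, autosome.
    Genes spanning the PAR boundary are classified by midpoint and
    flagged in the ``spans_boundary`` column.
    """
    x_paired = set(pairs["x_gene"])
    y_paired = set(pairs["y_gene"])
    for col, scaf, label in (("x_gene", x_scaffold, "X"),
                             ("y_gene", y_scaffold, "Y")):
        missing = [g for g in pairs[col] if g not in genes.index]
        if missing:
            raise ValueError(f"pairs reference unknown genes: {missing[:3]}")
        wrong = genes.loc[list(pairs[col])]
        wrong = wrong[wrong["scaffold"] != scaf]
        if len(wrong):
            raise ValueError(
                f"pair gene(s) not on the {label} scaffold: "
                f"{list(wrong.index[:3])}"
            )

    partner = pd.Series("", index=genes.index, dtype=object)
    for xg, yg in zip(pairs["x_gene"], pairs["y_gene"]):
        partner[xg], partner[yg] = yg, xg

    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    scaf = genes["scaffold"].to_numpy()
    region = np.full(len(genes), RegionClass.AUTOSOME.value, dtype=object)
    spans = np.zeros(len(genes), bool)

    on_x = scaf == x_scaffold
    on_y = scaf == y_scaffold
    in_par = np.zeros(len(genes), bool)
    if par_interval is not None:
        lo, hi = par_interval
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        in_par = on_x & (mid >= lo) & (mid < hi)
        spans = on_x & (((starts < lo) & (ends > lo))
                        | ((starts < hi) & (ends > hi)))
    paired = genes.index.isin(x_paired | y_paired)
    region[in_par] = RegionClass.PAR.value
    region[on_x & ~in_par & paired] = RegionClass.XY_SHARED_X.value
    region[on_x & ~in_par & ~paired] = RegionClass.X_SPECIFIC.value
    region[on_y & paired] = RegionClass.XY_SHARED_Y.value
    region[on_y & ~paired] = RegionClass.Y_SPECIFIC.value

    out = genes.copy()
    out["region"] = region
    out["partner"] = partner
    out["midpoint"] = mid
    out["spans_boundary"] = spans
    return out
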