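"""Per-bin / per-gene read depth extraction and LOESS GC-bias correction.

The GC smoother is a tricube-weighted local polynomial regression (degree 2
by default) fitted on bin-level depths and evaluable at arbitrary GC values,
so the same per-sample curve fitted on genome bins can correct the 33 gene
bodies (too few to fit on directly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .panel import BinGrid, GenePanelEntry

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "feature_id", "kind", "chrom", "start", "end",
    "gc", "raw_depth", "norm_depth", "flag",
]


@dataclass
class NormalizationConfig:
    """Parameters of the GC correction (the source method names the algorithm
    but fixes no parameters; defaults here are the standard ones)."""

    loess_span: float = 0.75
    degree: int = 2
    correction_mode: str = "ratio"  # or "subtract"
    min_gc: float = 0.28
    max_gc: float = 0.68
    depth_floor: float = 0.0
    min_features: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.min_gc >= self.max_gc:
            raise ValueError("min_gc must be < max_gc")
        if self.correction_mode not in {"ratio", "subtract"}:
            raise ValueError(f"unknown correction_mode {self.correction_mode!r}")


@dataclass
class DepthProfile:
    """Per-feature depth for one sample.

    ``features`` columns: feature_id, kind ("bin"/"gene"), chrom, start, end,
    gc, raw_depth, norm_depth (NaN until normalized), flag (True = excluded
    from downstream scoring).
    """

    sample_id: str
    features: pd.DataFrame
    total_reads: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"profile missing columns {missing}")
        if (self.features["raw_depth"] < 0).any():
            raise ValueError("raw_depth must be nonnegative")
        self.features = self.features.reset_index(drop=True)

    @property
    def feature_ids(self) -> list[str]:
        return self.features["feature_id"].tolist()

    def subset(self, kind: str) -> pd.DataFrame:
        return self.features[self.features["kind"] == kind]

    @property
    def depth_for_scoring(self) -> pd.Series:
        """norm_depth when normalized, raw_depth otherwise, indexed by feature_id."""
        col = "norm_depth" if self.normalized else "raw_depth"
        s = self.features.set_index("feature_id")[col].copy()
        s[self.features.set_index("feature_id")["flag"]] = np.nan
        return s


def empty_feature_table(
    grid: BinGrid | None = None,
    panel: Sequence[GenePanelEntry] | None = None,
) -> pd.DataFrame:
    """Feature table skeleton: grid bins first, then panel gene bodies."""
    rows = []
    if grid is not None:
        gcs = grid.bins["gc"].values
        for (chrom, start, end), gc in zip(
            zip(grid.bins["chrom"], grid.bins["start"], grid.bins["end"]), gcs
        ):
            rows.append((f"{chrom}:{start}-{end}", "bin", chrom, start, end, gc))
    if panel is not None:
        for e in panel:
            gc = np.nan
            if grid is not None:
                gc = _gene_gc_from_grid(grid, e)
            rows.append((e.gene_symbol, "gene", e.chrom, e.start0, e.end0, gc))
    df = pd.DataFrame(rows, columns=["feature_id", "kind", "chrom", "start", "end", "gc"])
    df["raw_depth"] = 0.0
    df["norm_depth"] = np.nan
    df["flag"] = False
    return df


def _gene_gc_from_grid(grid: BinGrid, entry: GenePanelEntry) -> float:
    """Length-weighted mean GC of the grid bins overlapping a gene body."""
    b = grid.bins
    sub = b[(b["chrom"] == entry.chrom)
            & (b["end"] > entry.start0) & (b["start"] < entry.end0)]
    if sub.empty or sub["gc"].isna().all():
        return np.nan
    ov = np.minimum(sub["end"], entry.end0) - np.maximum(sub["start"], entry.start0)
    w = ov.values.astype(float)
    gc = sub["gc"].values
    ok = ~np.isnan(gc)
    return float(np.average(gc[ok], weights=w[ok]))


# ---------------------------------------------------------------------------
# Depth extraction


def depth_from_alignments(
    alignment_file: str | Path,
    grid: BinGrid,
    gene_panel: Sequence[GenePanelEntry] | None = None,
    sample_id: str | None = None,
) -> DepthProfile:
    """Mean depth per bin and per gene body from a coordinate-sorted BAM.

    Depth = aligned read-bases overlapping the feature / feature length.
    """
    import pysam  # optional dependency

    path = Path(alignment_file)
    sample_id = sample_id or path.stem
    table = empty_feature_table(grid, gene_panel)
    with pysam.AlignmentFile(str(path)) as bam:
        contigs = set(bam.references)
        wanted = set(table["chrom"])
        missing = sorted(wanted - contigs)
        if missing and bam.mapped > 0:
            raise ValueError(f"contigs absent from BAM header: {missing}")
        depths = np.zeros(len(table))
        for i, (chrom, start, end) in enumerate(
            zip(table["chrom"], table["start"], table["end"])
        ):
            if chrom not in contigs:
                continue
            bases = 0
            for read in bam.fetch(chrom, start, end):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                bases += read.get_overlap(start, end) or 0
            depths[i] = bases / (end - start)
        total = bam.mapped
    table["raw_depth"] = depths
    return DepthProfile(sample_id=sample_id, features=table, total_reads=int(total))


def depth_from_table(
    path: str | Path,
    grid: BinGrid,
    gene_panel: Sequence[GenePanelEntry] | None = None,
    sample_id: str | None = None,
) -> DepthProfile:
    """Load binned depth from a bedGraph (chrom, start, end, depth; no header)
    or a profile TSV previously written by :func:`write_profile`.

    bedGraph intervals must tile or subdivide the grid without overlapping;
    depth is aggregated onto grid bins as a length-weighted mean.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("feature_id"):
        table = pd.read_csv(path, sep="\t")
        missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        normalized = table["norm_depth"].notna().any()
        return DepthProfile(sample_id=sample_id, features=table[PROFILE_COLUMNS],
                            normalized=bool(normalized))

    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "depth"])
    table = empty_feature_table(grid, gene_panel)
    bins = grid.bins
    chrom_bounds = {c: (s["start"].min(), s["end"].max())
                    for c, s in bins.groupby("chrom")}
    accum = np.zeros(len(bins))
    for chrom, sub in bed.groupby("chrom", sort=False):
        if chrom not in chrom_bounds:
            raise ValueError(f"{path}: interval chromosome {chrom!r} not in grid")
        sub = sub.sort_values("start")
        if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        lo, hi = chrom_bounds[chrom]
        if (sub["start"].values < lo).any() or (sub["end"].values > hi).any():
            bad = sub[(sub["start"] < lo) | (sub["end"] > hi)].iloc[0]
            raise ValueError(
                f"{path}: interval {chrom}:{bad.start}-{bad.end} outside grid"
            )
        mask = bins["chrom"] == chrom
        idx = np.flatnonzero(mask)
        starts = bins.loc[mask, "start"].values
        ends = bins.loc[mask, "end"].values
        for start, end, depth in zip(sub["start"], sub["end"], sub["depth"]):
            first_bin = np.searchsorted(ends, start, side="right")
            j = first_bin
            while j < len(starts) and starts[j] < end:
                ov = min(end, ends[j]) - max(start, starts[j])
                accum[idx[j]] += depth * ov
                j += 1
    lengths = (bins["end"] - bins["start"]).values
    nbins = len(bins)
    table.loc[: nbins - 1, "raw_depth"] = accum / lengths
    # gene-body depth from overlapping bins, length-weighted
    for i in range(nbins, len(table)):
        chrom, gstart, gend = table.loc[i, ["chrom", "start", "end"]]
        mask = (bins["chrom"] == chrom) & (bins["end"] > gstart) & (bins["start"] < gend)
        if not mask.any():
            continue
        ov = (np.minimum(bins.loc[mask, "end"], gend)
              - np.maximum(bins.loc[mask, "start"], gstart)).values
        table.loc[i, "raw_depth"] = float(
            np.average(table.loc[np.flatnonzero(mask), "raw_depth"], weights=ov)
        )
    return DepthProfile(sample_id=sample_id, features=table)


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    profile.features[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LOESS


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_anchors: int = 200,
) -> Callable[[np.ndarray], np.ndarray]:
    """Tricube-weighted local polynomial fit of y on x; returns a predictor.

    The curve is evaluated exactly at up to ``n_anchors`` quantile anchor
    points and linearly interpolated between them; queries outside the data
    range are clamped to the boundary anchors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    if n < degree + 2:
        raise ValueError("too few points for a local fit")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)

    if n <= n_anchors:
        anchors = np.unique(xs)
    else:
        anchors = np.unique(np.quantile(xs, np.linspace(0, 1, n_anchors)))

    fitted = np.empty(len(anchors))
    for i, x0 in enumerate(anchors):
        left = np.searchsorted(xs, x0)
        lo = max(0, min(left - k // 2, n - k))
        window = slice(lo, lo + k)
        xw, yw = xs[window], ys[window]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            fitted[i] = yw.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        deg = min(degree, len(np.unique(xw)) - 1)
        xc = xw - x0  # center for conditioning
        coeffs = np.polyfit(xc, yw, deg, w=np.sqrt(w))
        fitted[i] = coeffs[-1]

    def predict(xq: np.ndarray) -> np.ndarray:
        xq = np.asarray(xq, float)
        return np.interp(xq, anchors, fitted)

    return predict


def loess_gc_normalize(
    profile: DepthProfile,
    cfg: NormalizationConfig | None = None,
) -> DepthProfile:
    """Remove GC bias: fit depth ~ loess(gc) on eligible bins, correct all
    features with the fitted curve evaluated at their GC.

    ratio mode: norm = raw * median(fitted)/fitted(gc), then rescaled so the
    median normalized depth over eligible features equals the median raw
    depth over the same features. Features with GC outside
    [min_gc, max_gc] (or missing GC) are flagged and propagate as missing.
    """
    cfg = cfg or NormalizationConfig()
    feats = profile.features.copy()
    gc = feats["gc"].values.astype(float)
    raw = feats["raw_depth"].values.astype(float)

    in_window = (gc >= cfg.min_gc) & (gc <= cfg.max_gc) & ~np.isnan(gc)
    eligible = in_window & (raw > cfg.depth_floor)
    feats["flag"] = ~in_window

    is_bin = (feats["kind"] == "bin").values
    fit_mask = eligible & is_bin if (eligible & is_bin).sum() >= cfg.min_features \
        else eligible
    if fit_mask.sum() < cfg.min_features:
        raise ValueError(
            f"only {int(fit_mask.sum())} eligible features "
            f"(need >= {cfg.min_features}); provide a larger input"
        )

    if np.ptp(gc[fit_mask]) < 1e-9:
        # degenerate: one shared GC value, no bias estimable
        logger.warning("%s: constant GC among eligible features; "
                       "returning depths unchanged", profile.sample_id)
        feats["norm_depth"] = np.where(in_window, raw, np.nan)
        return DepthProfile(profile.sample_id, feats, profile.total_reads,
                            normalized=True)

    predict = loess_fit(gc[fit_mask], raw[fit_mask],
                        span=cfg.loess_span, degree=cfg.degree)
    fitted = np.full(len(feats), np.nan)
    fitted[in_window] = predict(gc[in_window])

    norm = np.full(len(feats), np.nan)
    if cfg.correction_mode == "ratio":
        center = np.median(fitted[eligible])
        safe = np.where(np.abs(fitted) > 1e-12, fitted, np.nan)
        norm[in_window] = raw[in_window] * center / safe[in_window]
        med = np.nanmedian(norm[eligible])
        raw_med = np.median(raw[eligible])
        if med > 0:
            norm[in_window] *= raw_med / med
    else:  # subtract
        center = np.median(fitted[eligible])
        norm[in_window] = raw[in_window] - fitted[in_window] + center
        norm = np.clip(norm, 0, None)

    feats["norm_depth"] = norm
    return DepthProfile(profile.sample_id, feats, profile.total_reads,
                        normalized=True)


def thin_profile(
    profile: DepthProfile,
    target_fraction: float,
    seed: int | None = None,
    read_length: int = 100,
) -> DepthProfile:
    """Binomially thin per-feature depths to ``target_fraction`` of the reads.

    Depths are converted to pseudo read counts (depth x length / read_length),
    thinned count-wise, and converted back; the thinned profile is
    un-normalized (callers renormalize before rescoring).
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    feats = profile.features.copy()
    lengths = (feats["end"] - feats["start"]).values.astype(float)
    counts = np.round(feats["raw_depth"].values * lengths / read_length).astype(int)
    thinned = rng.binomial(counts, target_fraction)
    feats["raw_depth"] = thinned * read_length / lengths
    feats["norm_depth"] = np.nan
    feats["flag"] = False
    return DepthProfile(profile.sample_id + f"@{target_fraction:g}x", feats,
                        total_reads=int(round(profile.total_reads * target_fraction)),
                        normalized=False)
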