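"""Windowed SSV density segmentation into High/Low Variability Regions.

The genome is tiled with non-overlapping windows (default 10 kb). Raw window
counts are smoothed with a triangular floating mean of half-width ``k``
(weights ``k - |i|``, fixed denominator ``sum_i (k - |i|) = k**2``, windows
beyond the chromosome contributing zero). The empirical distribution of
smoothed densities is bimodal; the valley between the two main modes is the
HVR/LVR threshold. Maximal runs of at least ``min_run`` same-label windows
become regions; unmappable windows are excluded and break runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hvrkit.intervals import points_in_any
from hvrkit.layout import GenomeLayout
from hvrkit.ssv import SSVSet

logger = logging.getLogger(__name__)

REGION_COLUMNS = ["chrom", "start", "end", "region_type", "n_windows", "n_ssvs"]

#: Default threshold when the smoothed-density histogram is not bimodal;
#: all three study strain-vs-reference comparisons yielded this value.
DEFAULT_THRESHOLD = 3.0


def empty_regions() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype="object"),
        "start": pd.Series(dtype="int64"),
        "end": pd.Series(dtype="int64"),
        "region_type": pd.Series(dtype="object"),
        "n_windows": pd.Series(dtype="int64"),
        "n_ssvs": pd.Series(dtype="int64"),
    })


def write_regions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=REGION_COLUMNS)


def read_regions(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS,
                           dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return empty_regions()


@dataclass
class WindowTrack:
    """Per-chromosome window counts and (optionally) smoothed densities."""

    layout: GenomeLayout
    window_bp: int
    counts: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray] = field(default_factory=dict)

    def n_windows(self, chrom: str) -> int:
        return self.layout.n_windows(chrom, self.window_bp)

    def total_count(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def all_smoothed(self) -> np.ndarray:
        return np.concatenate([self.smoothed[c] for c in self.layout]) \
            if self.smoothed else np.array([])

    def window_interval(self, chrom: str, idx: int) -> tuple[int, int]:
        start = idx * self.window_bp
        return start, min(start + self.window_bp, self.layout[chrom])

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for chrom in self.layout:
            n = self.n_windows(chrom)
            frame = pd.DataFrame({
                "chrom": chrom,
                "window_index": np.arange(n),
                "start": np.arange(n) * self.window_bp,
                "end": np.minimum((np.arange(n) + 1) * self.window_bp, self.layout[chrom]),
                "count": self.counts[chrom],
            })
            if chrom in self.smoothed:
                frame["smoothed"] = self.smoothed[chrom]
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, layout: GenomeLayout, window_bp: int) -> "WindowTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        counts, smoothed = {}, {}
        for chrom in layout:
            sub = df[df["chrom"] == chrom].sort_values("window_index")
            counts[chrom] = sub["count"].to_numpy()
            if "smoothed" in sub.columns:
                smoothed[chrom] = sub["smoothed"].to_numpy(dtype=float)
        return cls(layout, window_bp, counts, smoothed)


def count_ssvs_per_window(ssvs: SSVSet, layout: GenomeLayout, window_bp: int = 10_000) -> WindowTrack:
    """Bin 0-based SSV positions into half-open windows ``[i*w, (i+1)*w)``."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    counts = {c: np.zeros(layout.n_windows(c, window_bp), dtype=np.int64) for c in layout}
    for chrom, sub in ssvs.df.groupby("chrom", sort=False):
        if chrom not in layout:
            raise ValueError(f"SSV on unknown chromosome {chrom!r}")
        pos = sub["pos"].to_numpy(np.int64)
        if (pos < 0).any() or (pos >= layout[chrom]).any():
            bad = pos[(pos < 0) | (pos >= layout[chrom])][0]
            raise ValueError(f"SSV position {chrom}:{bad} outside chromosome")
        np.add.at(counts[chrom], pos // window_bp, 1)
    return WindowTrack(layout, window_bp, counts)


def triangular_weights(k: int) -> np.ndarray:
    """Weights ``k - |i|`` for ``i = -k .. k`` (zero at the extremes)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    i = np.arange(-k, k + 1)
    return (k - np.abs(i)).astype(float)


def smooth_track(track: WindowTrack, k: int = 3) -> WindowTrack:
    """Triangular floating mean with a fixed denominator of ``k**2``.

    Windows past either chromosome end contribute zero to the numerator while
    the denominator stays fixed, so total mass is conserved.
    """
    w = triangular_weights(k)
    denom = w.sum()  # == k**2
    smoothed = {}
    for chrom in track.layout:
        padded = np.pad(track.counts[chrom].astype(float), k)
        smoothed[chrom] = np.convolve(padded, w, mode="valid") / denom
    return WindowTrack(track.layout, track.window_bp, track.counts, smoothed)


def find_threshold(
    values: np.ndarray,
    bin_width: float = 1.0,
    fallback: float = DEFAULT_THRESHOLD,
) -> float:
    """Valley between the two main modes of the smoothed-density histogram.

    Densities are binned with ``bin_width``-wide bins from zero; modes are
    local maxima with prominence above a small noise floor, and the threshold
    is the centre of the lowest bin between the two most populated modes
    (ties resolved towards their midpoint). With fewer than two modes
    (unimodal or degenerate input), ``fallback`` is returned.
    """
    from scipy.signal import find_peaks

    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.allclose(values, values.flat[0]):
        logger.warning("threshold search: degenerate input, using fallback %.3g", fallback)
        return float(fallback)
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(values, bins=edges)

    # pad so boundary bins (e.g. the mode at zero) count as peaks
    noise_floor = max(2.0, 0.005 * values.size)
    padded = np.concatenate([[-1.0], hist.astype(float), [-1.0]])
    peaks, _ = find_peaks(padded, prominence=noise_floor)
    maxima = peaks - 1
    if len(maxima) < 2:
        logger.warning("threshold search: histogram not bimodal, using fallback %.3g", fallback)
        return float(fallback)
    # two most populated modes, ordered by position
    top2 = sorted(sorted(maxima, key=lambda i: hist[i], reverse=True)[:2])
    lo, hi = top2
    if hi == lo + 1:
        valley = lo
    else:
        between = hist[lo + 1:hi]
        ties = lo + 1 + np.flatnonzero(between == between.min())
        # tie-break towards the midpoint of the two modes for stability
        midpoint = (lo + hi) / 2.0
        valley = int(ties[np.argmin(np.abs(ties - midpoint))])
    return float((valley + 0.5) * bin_width)


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of equal labels as (label, start_idx, end_idx_exclusive)."""
    out = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], i, j))
        i = j
    return out


def _unmappable_flags(track: WindowTrack, unmappable: pd.DataFrame | None) -> dict[str, np.ndarray]:
    flags = {c: np.zeros(track.n_windows(c), dtype=bool) for c in track.layout}
    if unmappable is None or len(unmappable) == 0:
        return flags
    w = track.window_bp
    for row in unmappable.itertuples(index=False):
        if row.chrom not in flags:
            continue
        first = row.start // w
        last = (row.end - 1) // w
        flags[row.chrom][first:last + 1] = True
    return flags


def call_regions(
    track: WindowTrack,
    threshold: float,
    min_run: int = 3,
    unmappable: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Emit HVR/LVR/UNMAP regions from smoothed window densities.

    A window is HVR-like iff smoothed density > ``threshold`` (ties go to
    LVR). Unmappable windows are excluded from labelling and break runs. Runs
    shorter than ``min_run`` stay unclassified.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not track.smoothed:
        raise ValueError("track has no smoothed densities; run smooth_track first")
    unmap_flags = _unmappable_flags(track, unmappable)

    rows = []
    for chrom in track.layout:
        sm = track.smoothed[chrom]
        labels = np.where(sm > threshold, "H", "L")
        labels[unmap_flags[chrom]] = "U"
        for label, i, j in _runs(labels):
            if label == "U":
                region_type = "UNMAP"
            elif j - i < min_run:
                continue  # unclassified
            else:
                region_type = "HVR" if label == "H" else "LVR"
            start = i * track.window_bp
            end = min(j * track.window_bp, track.layout[chrom])
            n_ssvs = int(track.counts[chrom][i:j].sum())
            rows.append((chrom, start, end, region_type, j - i, n_ssvs))
    if not rows:
        return empty_regions()
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def detect_unmappable(
    window_stats: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 10_000,
    mapq_max: float = 30.0,
    cov_min: float = 100.0,
    min_run: int = 3,
) -> pd.DataFrame:
    """Flag windows with mean MAPQ <= ``mapq_max`` or mean coverage >=
    ``cov_min``; runs of >= ``min_run`` flagged windows become UNMAP regions.

    ``window_stats`` columns: chrom, window_index, mean_mapq, mean_coverage.
    Windows absent from the table are treated as mappable.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    flags = {c: np.zeros(layout.n_windows(c, window_bp), dtype=bool) for c in layout}
    for row in window_stats.itertuples(index=False):
        if row.chrom not in flags:
            raise ValueError(f"window stats on unknown chromosome {row.chrom!r}")
        idx = int(row.window_index)
        if not 0 <= idx < len(flags[row.chrom]):
            raise ValueError(
                f"window index {idx} outside grid for {row.chrom} "
                f"(mismatched window grid?)")
        flags[row.chrom][idx] = (row.mean_mapq <= mapq_max) or (row.mean_coverage >= cov_min)

    rows = []
    for chrom in layout:
        for flagged, i, j in _runs(flags[chrom]):
            if flagged and j - i >= min_run:
                start = i * window_bp
                end = min(j * window_bp, layout[chrom])
                rows.append((chrom, start, end, "UNMAP", j - i, 0))
    if not rows:
        return empty_regions()
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def pct(part: float, total: float, ndigits: int = 2) -> float:
    """Percentage ``100 * part / total`` rounded; 0.0 when total is zero."""
    if total == 0:
        return 0.0
    return round(100.0 * part / total, ndigits)


def summarize_counts(total_ssvs: int, ssvs_in_hvrs: int) -> dict:
    """Table-1-style summary row from raw totals."""
    return {
        "total_ssvs": int(total_ssvs),
        "ssvs_in_hvrs": int(ssvs_in_hvrs),
        "pct_ssvs_in_hvrs": pct(ssvs_in_hvrs, total_ssvs),
        "undefined": total_ssvs == 0,
    }


def summarize_comparison(ssvs: SSVSet, regions: pd.DataFrame, layout: GenomeLayout) -> dict:
    """Descriptive statistics for one comparison: SSV totals, HVR counts/span."""
    hvrs = regions[regions["region_type"] == "HVR"]
    if len(ssvs) > 0 and len(hvrs) > 0:
        in_hvr = int(points_in_any(ssvs.df, hvrs).sum())
    else:
        in_hvr = 0
    hvr_bp = int((hvrs["end"] - hvrs["start"]).sum())
    out = summarize_counts(len(ssvs), in_hvr)
    out.update({
        "hvr_count": int(len(hvrs)),
        "hvr_bp": hvr_bp,
        "pct_genome_hvr": pct(hvr_bp, layout.total_bp),
    })
    return out


def hvr_overlap_fraction(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Fraction of HVRs in ``a`` intersecting at least one HVR in ``b``."""
    from hvrkit.intervals import overlaps_any

    a_hvr = a[a["region_type"] == "HVR"]
    b_hvr = b[b["region_type"] == "HVR"]
    if len(a_hvr) == 0:
        return 0.0
    return float(overlaps_any(a_hvr, b_hvr).mean())
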