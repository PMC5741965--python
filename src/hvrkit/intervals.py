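"""Pure-numpy half-open interval operations used across the pipeline.

Interval tables are pandas DataFrames with at least ``chrom`` (str),
``start``/``end`` (int, 0-based half-open) columns. Point tables carry
``chrom`` and ``pos`` (0-based).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def check_intervals(df: pd.DataFrame, *, name: str = "intervals") -> None:
    """Raise ValueError on malformed interval rows (start >= end, negatives)."""
    if len(df) == 0:
        return
    if (df["start"] < 0).any():
        raise ValueError(f"{name}: negative start coordinate")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{name}: empty or inverted interval (start >= end)")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def is_sorted(df: pd.DataFrame) -> bool:
    if len(df) <= 1:
        return True
    s = df[["chrom", "start", "end"]]
    return s.equals(sort_intervals(df)[["chrom", "start", "end"]])


def _prefix_max_ends(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    return starts[order], np.maximum.accumulate(ends[order])


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it intersect (>= 1 bp) any subject interval?"""
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts, run_ends = _prefix_max_ends(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        qs = query.loc[mask, "start"].to_numpy(np.int64)
        qe = query.loc[mask, "end"].to_numpy(np.int64)
        # subjects with start < query.end; overlap iff any of their ends > query.start
        idx = np.searchsorted(starts, qe, side="left")
        hit = np.zeros(len(qs), dtype=bool)
        nz = idx > 0
        hit[nz] = run_ends[idx[nz] - 1] > qs[nz]
        out[mask] = hit
    return out


def count_overlapping(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals intersecting each query interval."""
    out = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return out
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        ss = np.sort(sub["start"].to_numpy(np.int64), kind="stable")
        se = np.sort(sub["end"].to_numpy(np.int64), kind="stable")
        qs = query.loc[mask, "start"].to_numpy(np.int64)
        qe = query.loc[mask, "end"].to_numpy(np.int64)
        # count = #(start < q.end) - #(end <= q.start)
        out[mask] = np.searchsorted(ss, qe, side="left") - np.searchsorted(se, qs, side="right")
    return out


def points_in_any(points: pd.DataFrame, subject: pd.DataFrame, pos_col: str = "pos") -> np.ndarray:
    """Boolean per point row: does the 0-based position fall inside any interval?"""
    q = pd.DataFrame(
        {
            "chrom": points["chrom"],
            "start": points[pos_col].to_numpy(np.int64),
            "end": points[pos_col].to_numpy(np.int64) + 1,
        }
    )
    return overlaps_any(q, subject)
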