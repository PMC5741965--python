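"""Cluster-preserving permutation test for HVR enrichment.

HVRs within ``max_gap`` (default 1 Mb) on a chromosome are merged into
clusters; each permutation relocates every cluster independently to a
chromosome drawn with probability proportional to length among chromosomes
long enough to hold it, with a uniform start, preserving the relative
coordinates of member HVRs. The two-tailed empirical p-value is

    p = [card(|EV - mean(EV)| >= |OV - mean(EV)|) + 1] / (N + 1)

with a floor of 1/(N+1). Shuffled clusters may overlap one another and may
land in unmappable regions unless an exclusion mask is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hvrkit.intervals import overlaps_any
from hvrkit.layout import GenomeLayout

STAT_MODES = ("n_elements_overlapping", "n_points_in", "mean_score")

DEFAULT_MAX_GAP = 1_000_000
DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class Cluster:
    """A group of nearby HVRs relocated as a rigid unit."""

    chrom: str
    start: int
    span: int  # total extent from first HVR start to last HVR end
    member_offsets: np.ndarray  # starts relative to cluster start
    member_lengths: np.ndarray

    def members(self, chrom: str | None = None, start: int | None = None) -> list[tuple[str, int, int]]:
        chrom = self.chrom if chrom is None else chrom
        start = self.start if start is None else start
        return [
            (chrom, int(start + o), int(start + o + ln))
            for o, ln in zip(self.member_offsets, self.member_lengths)
        ]


def cluster_hvrs(hvrs: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> list[Cluster]:
    """Single-linkage merge of sorted, non-overlapping HVRs by gap <= max_gap."""
    clusters: list[Cluster] = []
    df = hvrs.sort_values(["chrom", "start"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping HVRs on {chrom}")
        group_start = 0
        for i in range(1, len(starts) + 1):
            if i == len(starts) or starts[i] - ends[i - 1] > max_gap:
                s, e = starts[group_start:i], ends[group_start:i]
                clusters.append(Cluster(
                    chrom=chrom,
                    start=int(s[0]),
                    span=int(e[-1] - s[0]),
                    member_offsets=s - s[0],
                    member_lengths=e - s,
                ))
                group_start = i
    return clusters


def shuffle_clusters(
    clusters: list[Cluster],
    layout: GenomeLayout,
    rng: np.random.Generator,
    exclude: pd.DataFrame | None = None,
    max_tries: int = 100,
) -> list[tuple[str, int, int]]:
    """Relocate each cluster; returns the flat list of relocated HVR intervals.

    ``exclude`` (optional region table) rejects placements whose span
    intersects an excluded interval, retrying up to ``max_tries`` times.
    """
    chrom_names = layout.chromosomes
    chrom_lengths = np.array([layout[c] for c in chrom_names], dtype=np.int64)
    placed: list[tuple[str, int, int]] = []
    for cluster in clusters:
        feasible = np.flatnonzero(chrom_lengths >= cluster.span)
        if len(feasible) == 0:
            raise ValueError(
                f"cluster of span {cluster.span} bp longer than every chromosome")
        cum = np.cumsum(chrom_lengths[feasible])
        for _ in range(max_tries):
            # chromosome weighted by length among those able to hold the span
            ci = int(feasible[np.searchsorted(cum, rng.random() * cum[-1], side="right")])
            chrom = chrom_names[ci]
            start = int(rng.integers(0, chrom_lengths[ci] - cluster.span + 1))
            if exclude is not None and len(exclude):
                span_df = pd.DataFrame(
                    {"chrom": [chrom], "start": [start], "end": [start + cluster.span]})
                if overlaps_any(span_df, exclude)[0]:
                    continue
            break
        else:
            raise ValueError("could not place cluster outside exclusion mask")
        placed.extend(cluster.members(chrom, start))
    return placed


class _StatEngine:
    """Precomputed element index for fast per-permutation statistics."""

    def __init__(self, elements: pd.DataFrame, mode: str):
        if mode not in STAT_MODES:
            raise ValueError(f"unknown statistic mode {mode!r}")
        self.mode = mode
        self.n_elements = len(elements)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._scores = np.zeros(self.n_elements)
        if len(elements):
            elements = elements.reset_index(drop=True)
            if "pos" in elements.columns and "start" not in elements.columns:
                elements = elements.assign(start=elements["pos"], end=elements["pos"] + 1)
            if "score" in elements.columns:
                self._scores = elements["score"].to_numpy(float)
            for chrom, sub in elements.groupby("chrom", sort=False):
                order = np.argsort(sub["start"].to_numpy(np.int64), kind="stable")
                self._by_chrom[chrom] = (
                    sub["start"].to_numpy(np.int64)[order],
                    sub["end"].to_numpy(np.int64)[order],
                    sub.index.to_numpy()[order],  # global element indices
                )

    def value(self, regions: list[tuple[str, int, int]]) -> float:
        """Statistic over a set of (possibly overlapping) regions.

        Every element contributes at most once regardless of how many regions
        it intersects.
        """
        hit = np.zeros(self.n_elements, dtype=bool)
        for chrom, rstart, rend in regions:
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            starts, ends, global_idx = entry
            cand = (starts < rend) & (ends > rstart)
            if cand.any():
                hit[global_idx[cand]] = True
        if self.mode == "mean_score":
            if not hit.any():
                return math.nan  # undefined: no intersecting elements
            return float(self._scores[hit].mean())
        return float(hit.sum())


def overlap_statistic(regions: pd.DataFrame, elements: pd.DataFrame, mode: str) -> float:
    """Overlap statistic of element set against a region set.

    Modes: ``n_elements_overlapping`` (elements intersecting >= 1 region,
    each counted once), ``n_points_in`` (point elements inside regions),
    ``mean_score`` (mean ``score`` of intersecting elements; NaN if none).
    """
    engine = _StatEngine(elements, mode)
    return engine.value(list(zip(regions["chrom"], regions["start"], regions["end"])))


@dataclass
class PermutationResult:
    """Observed statistic, permutation null sample and empirical p-values."""

    observed: float
    ev: np.ndarray
    n_permutations: int
    seed: int
    mode: str
    max_gap: int
    n_undefined: int = 0

    ev_mean: float = field(init=False)
    p_two_tailed: float = field(init=False)
    p_enrichment: float = field(init=False)

    def __post_init__(self):
        ev = np.asarray(self.ev, dtype=float)
        n = self.n_permutations
        self.ev_mean = float(ev.mean()) if len(ev) else math.nan
        self.p_two_tailed = float(
            (np.sum(np.abs(ev - self.ev_mean) >= abs(self.observed - self.ev_mean)) + 1)
            / (n + 1))
        self.p_enrichment = float((np.sum(ev >= self.observed) + 1) / (n + 1))

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "ev_mean": self.ev_mean,
            "p_two_tailed": self.p_two_tailed,
            "p_enrichment": self.p_enrichment,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "mode": self.mode,
            "max_gap": self.max_gap,
            "n_undefined": self.n_undefined,
        }

    def to_json(self, path: str | Path) -> None:
        from hvrkit.io import write_json

        write_json(self.to_dict(), path)


def permutation_test(
    hvrs: pd.DataFrame,
    elements: pd.DataFrame,
    layout: GenomeLayout,
    mode: str = "n_elements_overlapping",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    max_gap: int = DEFAULT_MAX_GAP,
    exclude: pd.DataFrame | None = None,
) -> PermutationResult:
    """Cluster-preserving permutation test of element enrichment in HVRs.

    Per-permutation RNG substreams are spawned deterministically from
    ``seed``, so the EV multiset is independent of evaluation order.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    engine = _StatEngine(elements, mode)
    observed = engine.value(list(zip(hvrs["chrom"], hvrs["start"], hvrs["end"])))
    clusters = cluster_hvrs(hvrs, max_gap=max_gap)

    seeds = np.random.SeedSequence(seed).spawn(n_permutations)
    ev = np.empty(n_permutations)
    n_undefined = 0
    for i in range(n_permutations):
        rng = np.random.default_rng(seeds[i])
        placed = shuffle_clusters(clusters, layout, rng, exclude=exclude)
        v = engine.value(placed)
        if math.isnan(v):
            n_undefined += 1
            v = 0.0
        ev[i] = v
    return PermutationResult(
        observed=observed, ev=ev, n_permutations=n_permutations, seed=seed,
        mode=mode, max_gap=max_gap, n_undefined=n_undefined)
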