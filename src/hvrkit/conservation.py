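"""Cross-species conservation of TF occupancy and HVR Conservation Enrichment.

A rat peak is *conserved* iff it overlaps (>= 1 bp) a peak of the same factor
in at least one comparison species (all peak sets pre-projected to rat
coordinates). Per HVR and factor, the Conservation Enrichment score is either
the number of conserved peaks per 10 kb of HVR (``density_per_10kb``) or the
conserved fraction of peaks overlapping the HVR (``fraction``). Both readings
are provided; density is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hvrkit.intervals import check_intervals, count_overlapping, overlaps_any, sort_intervals

CE_MODES = ("density_per_10kb", "fraction")
CE_THRESHOLDS = (0.0, 0.2, 0.4, 0.6, 0.8)
NTF_LEVELS = (1, 2, 3)


@dataclass
class PeakSet:
    """TF peak intervals for one factor in one species (rat coordinates)."""

    factor: str
    species: str
    df: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        check_intervals(self.df, name=f"peaks[{self.factor}/{self.species}]")
        self.df = sort_intervals(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, factor: str, species: str) -> "PeakSet":
        from hvrkit.io import read_bed

        return cls(factor, species, read_bed(path))


def annotate_conservation(rat: PeakSet, others: Sequence[PeakSet]) -> pd.DataFrame:
    """Flag each rat peak as conserved and list supporting species.

    Returns the rat peak table with ``conserved`` (bool) and ``species``
    (comma-joined supporting species, empty string if none) columns added.
    """
    for other in others:
        if other.factor != rat.factor:
            raise ValueError(
                f"factor mismatch: rat peaks are {rat.factor!r}, "
                f"comparison set is {other.factor!r} ({other.species})")
    out = rat.df.copy().reset_index(drop=True)
    support: list[list[str]] = [[] for _ in range(len(out))]
    for other in others:
        hit = overlaps_any(out, other.df)
        for i in np.flatnonzero(hit):
            support[i].append(other.species)
    out["conserved"] = [len(s) > 0 for s in support]
    out["species"] = [",".join(s) for s in support]
    return out


def add_hvr_ids(regions: pd.DataFrame) -> pd.DataFrame:
    """Attach a stable ``hvr_id`` (chrom:start-end) to HVR rows."""
    hvrs = regions[regions["region_type"] == "HVR"].reset_index(drop=True).copy()
    hvrs["hvr_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(hvrs["chrom"], hvrs["start"], hvrs["end"])
    ]
    return hvrs


def compute_ce(
    hvr: pd.Series,
    annotation: pd.DataFrame,
    mode: str = "density_per_10kb",
) -> float:
    """CE score of a single HVR row against one factor's annotated peaks."""
    table = compute_ce_table(pd.DataFrame([hvr]), annotation, factor="", mode=mode)
    return float(table["value"].iloc[0])


def compute_ce_table(
    hvrs: pd.DataFrame,
    annotation: pd.DataFrame,
    factor: str,
    mode: str = "density_per_10kb",
) -> pd.DataFrame:
    """Per-HVR CE scores for one factor.

    Returns columns: hvr_id, factor, n_peaks, n_conserved, mode, value.
    """
    if mode not in CE_MODES:
        raise ValueError(f"unknown CE mode {mode!r}")
    if ((hvrs["end"] - hvrs["start"]) <= 0).any():
        raise ValueError("zero-length HVR")
    hvrs = hvrs.reset_index(drop=True)
    n_total = count_overlapping(hvrs, annotation)
    conserved_peaks = annotation[annotation["conserved"]] if len(annotation) else annotation
    n_cons = count_overlapping(hvrs, conserved_peaks)
    length = (hvrs["end"] - hvrs["start"]).to_numpy(float)
    if mode == "density_per_10kb":
        value = n_cons / (length / 10_000.0)
    else:
        with np.errstate(invalid="ignore"):
            value = np.where(n_total > 0, n_cons / np.maximum(n_total, 1), 0.0)
    ids = hvrs["hvr_id"] if "hvr_id" in hvrs.columns else [
        f"{c}:{s}-{e}" for c, s, e in zip(hvrs["chrom"], hvrs["start"], hvrs["end"])
    ]
    return pd.DataFrame({
        "hvr_id": ids,
        "factor": factor,
        "n_peaks": n_total,
        "n_conserved": n_cons,
        "mode": mode,
        "value": value.astype(float),
    })


def build_subsets(
    hvrs: pd.DataFrame,
    ce_tables: Iterable[pd.DataFrame],
    ce_thresholds: Sequence[float] = CE_THRESHOLDS,
    ntf_levels: Sequence[int] = NTF_LEVELS,
) -> dict[str, set[str]]:
    """HVR prioritisation subsets.

    Per factor ``f``: ``f:W_TFBS`` (>= 1 peak regardless of conservation) and
    ``f:CE>t`` for each threshold. Across factors: ``NTF>=m`` (conserved
    peaks for at least ``m`` distinct factors). ``ALL`` is every HVR.
    """
    all_ids = set(hvrs["hvr_id"] if "hvr_id" in hvrs.columns else add_hvr_ids(hvrs)["hvr_id"])
    subsets: dict[str, set[str]] = {"ALL": all_ids}
    ce = pd.concat(list(ce_tables), ignore_index=True)
    for factor, sub in ce.groupby("factor", sort=False):
        subsets[f"{factor}:W_TFBS"] = set(sub.loc[sub["n_peaks"] > 0, "hvr_id"])
        for t in ce_thresholds:
            subsets[f"{factor}:CE>{t:g}"] = set(sub.loc[sub["value"] > t, "hvr_id"])
    n_factors_conserved = (
        ce[ce["n_conserved"] > 0].groupby("hvr_id")["factor"].nunique()
    )
    for m in ntf_levels:
        subsets[f"NTF>={m}"] = set(n_factors_conserved[n_factors_conserved >= m].index)
    return subsets


NSC_TERMS = frozenset({"missense_variant", "stop_gained", "stop_lost"})
SC_TERMS = frozenset({"synonymous_variant"})


def nsc_sc_ratio(most_severe_terms: Iterable[str]) -> dict:
    """Counts and proportion of non-synonymous vs synonymous coding SSVs.

    ``proportion`` is NSC / (NSC + SC), or None (``undefined`` flag set) when
    there are no coding SSVs.
    """
    terms = list(most_severe_terms)
    nsc = sum(t in NSC_TERMS for t in terms)
    sc = sum(t in SC_TERMS for t in terms)
    coding = nsc + sc
    return {
        "nsc": nsc,
        "sc": sc,
        "proportion_nsc": (nsc / coding) if coding else None,
        "undefined": coding == 0,
    }
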