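"""Per-cytosine methylation trajectories, adjacent-passage DMS calling,
region/TFBS aggregation with trend testing, and DMR-to-gene mapping.

The DMS rule operates on per-series trajectories: a cytosine is an
RS-associated *increased* DMS when, in **every** replicate series, every
adjacent-passage change of its methylation level strictly exceeds
``delta_up`` (default 0.05); *decreased* DMSs use the lower ``delta_down``
threshold (default 0.03) on the negative steps.  The two sets are disjoint
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, SampleDesign, promoter_window

# comparisons are strict (">" as stated); an absolute guard keeps binary float
# representation of m/n levels from flipping exact-boundary cases
_FLOAT_GUARD = 1e-12


def methylation_level(m: int, n: int) -> float:
    """Methylation level of one cytosine: methylated reads / total reads."""
    if n < 1:
        raise ValueError("total read count must be >= 1")
    if not (0 <= m <= n):
        raise ValueError(f"need 0 <= methylated <= total, got m={m} n={n}")
    return m / n


@dataclass
class MethylationTrajectories:
    """Per-cytosine levels on a series x timepoint grid.

    ``levels`` and ``coverage`` are (cytosines, series, timepoints) arrays;
    ``keys[i]`` is the (chrom, pos) of row i.  Only cytosines observed in
    every series/timepoint cell are kept.
    """

    keys: list[tuple[str, int]]
    levels: np.ndarray
    coverage: np.ndarray
    series_ids: list[str]
    timepoint_labels: list[str]

    def __post_init__(self):
        n, s, t = self.levels.shape
        if self.coverage.shape != (n, s, t):
            raise ValueError("levels and coverage shapes differ")
        if len(self.keys) != n:
            raise ValueError("keys length does not match levels")
        if ((self.levels < 0) | (self.levels > 1)).any():
            raise ValueError("levels must lie in [0, 1]")


def build_trajectories(
    calls: pd.DataFrame, design: SampleDesign
) -> MethylationTrajectories:
    """Assemble per-cytosine series x timepoint level grids from call records.

    ``calls`` has columns chrom, pos, sample_id, methylated, total.  Counts
    from multiple samples of the same (series, timepoint) cell are pooled
    before computing the level.  Cytosines missing from any cell are dropped.
    """
    series_ids = design.series_ids
    n_t = design.n_timepoints
    cell_of = {
        s.sample_id: (series_ids.index(s.series), s.timepoint) for s in design.samples
    }
    unknown = set(calls["sample_id"]) - set(cell_of)
    if unknown:
        raise ValueError(f"calls reference samples absent from design: {sorted(unknown)}")

    df = calls.copy()
    df["series_idx"] = df["sample_id"].map(lambda x: cell_of[x][0])
    df["timepoint_idx"] = df["sample_id"].map(lambda x: cell_of[x][1])
    pooled = (
        df.groupby(["chrom", "pos", "series_idx", "timepoint_idx"], sort=True)[
            ["methylated", "total"]
        ]
        .sum()
        .reset_index()
    )
    counts_per_site = pooled.groupby(["chrom", "pos"], sort=True).size()
    complete = counts_per_site[counts_per_site == len(series_ids) * n_t].index
    pooled = pooled.set_index(["chrom", "pos"]).loc[complete].reset_index()

    keys = list(complete)
    key_row = {k: i for i, k in enumerate(keys)}
    levels = np.zeros((len(keys), len(series_ids), n_t))
    coverage = np.zeros_like(levels)
    rows = pooled[["chrom", "pos"]].apply(tuple, axis=1).map(key_row).to_numpy()
    si = pooled["series_idx"].to_numpy()
    ti = pooled["timepoint_idx"].to_numpy()
    m = pooled["methylated"].to_numpy(dtype=float)
    n = pooled["total"].to_numpy(dtype=float)
    levels[rows, si, ti] = m / n
    coverage[rows, si, ti] = n
    return MethylationTrajectories(
        keys=[(str(c), int(p)) for c, p in keys],
        levels=levels,
        coverage=coverage,
        series_ids=series_ids,
        timepoint_labels=list(design.timepoint_labels),
    )


def identify_dms(
    trajectories: MethylationTrajectories,
    delta_up: float = 0.05,
    delta_down: float = 0.03,
    min_coverage: int = 5,
    mode: str = "per-series",
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Call RS-associated increased/decreased DMSs by adjacent-passage deltas.

    ``up``: every adjacent difference > ``delta_up`` in every series;
    ``down``: every adjacent difference < ``-delta_down`` in every series.
    Cytosines with coverage below ``min_coverage`` in any cell are excluded.
    ``mode="series-mean"`` applies the rule to the across-series mean
    trajectory instead of per series.  The returned sets are disjoint.
    """
    if delta_up <= 0 or delta_down <= 0:
        raise ValueError("delta thresholds must be > 0")
    if mode not in ("per-series", "series-mean"):
        raise ValueError(f"unknown mode {mode!r}")
    covered = (trajectories.coverage >= min_coverage).all(axis=(1, 2))
    levels = trajectories.levels
    if mode == "series-mean":
        levels = levels.mean(axis=1, keepdims=True)
    d = np.diff(levels, axis=2)  # (N, S, T-1)
    up_mask = covered & (d > delta_up + _FLOAT_GUARD).all(axis=(1, 2))
    down_mask = covered & (d < -(delta_down + _FLOAT_GUARD)).all(axis=(1, 2))
    keys = trajectories.keys
    up = {keys[i] for i in np.flatnonzero(up_mask)}
    down = {keys[i] for i in np.flatnonzero(down_mask)}
    return up, down


def region_mean_methylation(
    calls: pd.DataFrame,
    region: GenomicInterval,
    weighted: bool = False,
) -> float | None:
    """Mean methylation level of the cytosines inside ``region``.

    Unweighted by default (each cytosine contributes equally, the standard
    TFBS aggregation); ``weighted=True`` weights by read coverage.  Returns
    ``None`` — never 0 — when the region holds no cytosine.  Multiple records
    per position (replicates) are pooled by summing counts first.
    """
    sub = calls[
        (calls["chrom"] == region.chrom)
        & (calls["pos"] >= region.start)
        & (calls["pos"] < region.end)
    ]
    if sub.empty:
        return None
    pooled = sub.groupby("pos")[["methylated", "total"]].sum()
    levels = pooled["methylated"] / pooled["total"]
    if weighted:
        return float(np.average(levels, weights=pooled["total"]))
    return float(levels.mean())


def tfbs_methylation_trend(
    tfbs: Sequence[GenomicInterval],
    calls_by_timepoint: Mapping[str, pd.DataFrame],
    weighted: bool = False,
) -> tuple[dict[str, np.ndarray], float]:
    """Per-timepoint TFBS methylation distributions and a one-way ANOVA p.

    For each timepoint, each TFBS contributes its mean cytosine level (empty
    TFBS are dropped); the trend across timepoints is tested with one-way
    ANOVA.  Requires >= 2 timepoints with >= 2 values each.  When all values
    are identical the between-group variance is zero and p = 1 by convention.
    """
    if len(calls_by_timepoint) < 2:
        raise ValueError("need >= 2 timepoints for a trend test")
    distributions: dict[str, np.ndarray] = {}
    for label, calls in calls_by_timepoint.items():
        vals = [
            v
            for region in tfbs
            if (v := region_mean_methylation(calls, region, weighted=weighted)) is not None
        ]
        if len(vals) < 2:
            raise ValueError(f"timepoint {label!r} has fewer than 2 TFBS values")
        distributions[label] = np.asarray(vals, dtype=float)
    groups = list(distributions.values())
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return distributions, 1.0
    p = float(stats.f_oneway(*groups).pvalue)
    if not np.isfinite(p):
        p = 1.0
    return distributions, p


@dataclass(frozen=True)
class DMRRecord:
    """A differentially methylated region with its per-passage mean levels."""

    interval: GenomicInterval
    group_means: tuple[float, ...]

    def __post_init__(self):
        if any(not (0 <= x <= 1) for x in self.group_means):
            raise ValueError("DMR group means must lie in [0, 1]")


def dmr_to_genes(
    dmrs: Sequence[DMRRecord | GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = 5000,
) -> dict[int, set[str]]:
    """Map each DMR to the genes whose ±flank TSS window it overlaps.

    Returns {dmr index -> set of gene ids}; half-open overlap, so a DMR that
    merely touches the window boundary is not associated.
    """
    windows = [(g.gene_id, promoter_window(g, flank)) for g in genes]
    out: dict[int, set[str]] = {}
    for i, d in enumerate(dmrs):
        iv = d.interval if isinstance(d, DMRRecord) else d
        hits = {gid for gid, w in windows if iv.overlaps(w)}
        if hits:
            out[i] = hits
    return out


def merge_dms_to_regions(
    dms: Iterable[tuple[str, int, str]], max_gap: int
) -> list[tuple[GenomicInterval, str]]:
    """Naive DMS-to-region merge: same-direction sites within ``max_gap`` bp.

    ``dms`` holds (chrom, pos, direction) records; each output interval spans
    [first site, last site + 1) and carries its direction.  This is plumbing
    for callers without externally supplied DMR intervals, not a statistical
    DMR caller.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    items = sorted(dms, key=lambda x: (x[0], x[2], x[1]))
    out: list[tuple[GenomicInterval, str]] = []
    run: list[tuple[str, int, str]] = []
    for rec in items:
        if run and rec[0] == run[-1][0] and rec[2] == run[-1][2] and rec[1] - run[-1][1] <= max_gap:
            run.append(rec)
        else:
            if run:
                out.append(
                    (GenomicInterval(run[0][0], run[0][1], run[-1][1] + 1), run[0][2])
                )
            run = [rec]
    if run:
        out.append((GenomicInterval(run[0][0], run[0][1], run[-1][1] + 1), run[0][2]))
    return sorted(out, key=lambda x: (x[0].chrom, x[0].start, x[1]))
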