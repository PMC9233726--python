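"""Consensus peak-atlas construction and downstream accessibility analyses.

The atlas rule follows the replicate-presence convention: candidate regions
are the single-linkage union-merge of every sample's peaks, and a candidate
is retained when, in at least one passage group, strictly more than
``min_fraction`` (default 60%) of that group's replicates have an overlapping
peak.  Appearing/disappearing peaks, the high-coverage open/closed MA counts,
H3K4me1 ∩ H3K27ac enhancer calls, promoter annotation and the
promoter-accessibility shift test all operate on that atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    SampleDesign,
    _MergedIndex,
    intersect,
    merge_intervals,
    promoter_window,
)
from .trajectory import FeatureMatrix, normalize_library_size, test_differential


@dataclass
class PeakAtlas:
    """Consensus intervals plus a peaks x samples presence matrix.

    ``presence`` rows are labelled ``chrom:start-end``; ``signal`` (same
    shape, float) is attached by :func:`quantify_atlas`.
    """

    intervals: list[GenomicInterval]
    presence: pd.DataFrame
    design: SampleDesign
    signal: pd.DataFrame | None = None

    def __post_init__(self):
        labels = [iv.label for iv in self.intervals]
        if list(self.presence.index) != labels:
            raise ValueError("presence rows do not match atlas intervals")
        if self.signal is not None and list(self.signal.index) != labels:
            raise ValueError("signal rows do not match atlas intervals")

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]


def _check_fraction(min_fraction: float) -> None:
    if not (0 < min_fraction < 1):
        raise ValueError(f"min_fraction must lie in (0, 1), got {min_fraction}")


def build_atlas(
    per_sample_peaks: Mapping[str, Sequence[GenomicInterval]],
    design: SampleDesign,
    min_fraction: float = 0.6,
) -> PeakAtlas:
    """Build the consensus atlas from per-sample peak sets.

    Every design sample must appear in ``per_sample_peaks`` (an empty list is
    allowed).  Retention requires a group-presence fraction STRICTLY greater
    than ``min_fraction`` in at least one passage group, so e.g. 3/4 (0.75)
    and 2/3 (0.667) replicates retain a peak while 3/5 (0.6 exactly) does not.
    """
    _check_fraction(min_fraction)
    missing = [s for s in design.sample_ids if s not in per_sample_peaks]
    if missing:
        raise ValueError(f"samples without a peak list: {missing}")
    all_peaks = [iv for sid in design.sample_ids for iv in per_sample_peaks[sid]]
    candidates = merge_intervals(all_peaks)
    indexes = {sid: _MergedIndex(per_sample_peaks[sid]) for sid in design.sample_ids}
    presence = pd.DataFrame(
        {
            sid: [indexes[sid].overlaps(c) for c in candidates]
            for sid in design.sample_ids
        },
        index=[c.label for c in candidates],
        dtype=bool,
    )
    keep = np.zeros(len(candidates), dtype=bool)
    for t in range(design.n_timepoints):
        ids = [s.sample_id for s in design.samples_at(t)]
        frac = presence[ids].mean(axis=1).to_numpy()
        keep |= frac > min_fraction
    retained = [c for c, k in zip(candidates, keep) if k]
    return PeakAtlas(
        intervals=retained,
        presence=presence.loc[[c.label for c in retained]],
        design=design,
    )


def group_presence_fractions(atlas: PeakAtlas) -> pd.DataFrame:
    """Peaks x timepoints matrix of replicate-presence fractions."""
    design = atlas.design
    cols = {}
    for t in range(design.n_timepoints):
        ids = [s.sample_id for s in design.samples_at(t)]
        cols[design.timepoint_labels[t]] = atlas.presence[ids].mean(axis=1)
    return pd.DataFrame(cols)


def quantify_atlas(
    atlas: PeakAtlas,
    coverage_by_sample: Mapping[str, CoverageTrack],
    normalize: bool = True,
) -> FeatureMatrix:
    """Per-peak signal: summed coverage inside each consensus interval.

    With ``normalize=True`` the peaks x samples matrix is library-size scaled
    by median-of-ratios size factors (total-count fallback).  The matrix is
    also attached to ``atlas.signal``.
    """
    raw = pd.DataFrame(
        {
            sid: [float(coverage_by_sample[sid].values(iv).sum()) for iv in atlas.intervals]
            for sid in atlas.design.sample_ids
        },
        index=atlas.labels,
    )
    fm = FeatureMatrix(raw, atlas.design, kind="counts")
    if normalize:
        fm, _ = normalize_library_size(fm)
    atlas.signal = fm.values
    return fm


def ma_high_coverage_counts(
    signal: FeatureMatrix,
    t_ref: int,
    t_cmp: int,
    mean_threshold: float = 800.0,
    alpha: float = 0.05,
    min_fold: float = 1.0,
) -> tuple[int, int, pd.DataFrame]:
    """Open/closed peak counts among high-coverage peaks between two passages.

    Peaks whose mean normalized signal over the two compared groups strictly
    exceeds ``mean_threshold`` are tested (Welch t on log2(signal+1), BH
    within the contrast); *open* peaks are significantly higher at ``t_cmp``
    than ``t_ref``, *closed* significantly lower.  Significance alone decides
    the call (min_fold=1), since open/closed is a direction, not an effect
    size.  Returns (n_open, n_closed, per-peak table).
    """
    design = signal.design
    if t_ref == t_cmp:
        raise ValueError("t_ref and t_cmp must differ")
    ids = [
        s.sample_id
        for t in (t_ref, t_cmp)
        for s in design.samples_at(t)
    ]
    mean_signal = signal.values[ids].mean(axis=1)
    high = mean_signal > mean_threshold
    table = pd.DataFrame({"mean_signal": mean_signal, "high_coverage": high})
    table["log2fc"] = np.nan
    table["padj"] = np.nan
    table["call"] = "none"
    if high.sum() == 0:
        return 0, 0, table
    sub = FeatureMatrix(signal.values.loc[high], design, kind=signal.kind)
    diff = test_differential(sub, reference_timepoint=t_ref, alpha=alpha, min_fold=min_fold)
    label = f"{design.timepoint_labels[t_cmp]}_vs_{design.timepoint_labels[t_ref]}"
    contrast = diff.table[diff.table["contrast"] == label].set_index("feature_id")
    open_mask = contrast["significant"] & (contrast["log2fc"] > 0)
    closed_mask = contrast["significant"] & (contrast["log2fc"] < 0)
    table.loc[contrast.index, "log2fc"] = contrast["log2fc"]
    table.loc[contrast.index, "padj"] = contrast["padj"]
    table.loc[open_mask.index[open_mask], "call"] = "open"
    table.loc[closed_mask.index[closed_mask], "call"] = "closed"
    return int(open_mask.sum()), int(closed_mask.sum()), table


def detect_appearing_peaks(
    atlas: PeakAtlas, min_fraction: float = 0.6
) -> dict[int, list[GenomicInterval]]:
    """Newly appeared peaks per timepoint.

    A peak appears at t when its group-presence fraction is strictly above
    ``min_fraction`` at t and at or below it at EVERY earlier timepoint —
    i.e. t is the first above-threshold passage.  A later re-gain after a
    loss is not "newly appeared".
    """
    _check_fraction(min_fraction)
    frac = group_presence_fractions(atlas).to_numpy()
    out: dict[int, list[GenomicInterval]] = {}
    above = frac > min_fraction
    for i, iv in enumerate(atlas.intervals):
        ts = np.flatnonzero(above[i])
        if len(ts) == 0:
            continue
        t = int(ts[0])
        out.setdefault(t, []).append(iv)
    return out


def detect_disappearing_peaks(
    atlas: PeakAtlas, min_fraction: float = 0.6, mode: str = "sustained"
) -> dict[int, list[GenomicInterval]]:
    """Peaks disappearing at each timepoint (mirror of appearance).

    A peak disappears at t >= 1 when it is present (fraction strictly above
    ``min_fraction``) at every earlier timepoint and absent at t; with the
    default ``mode="sustained"`` it must also stay absent at every later
    timepoint, while ``mode="first"`` only requires absence at t itself.
    Never-present peaks are not reported.
    """
    _check_fraction(min_fraction)
    if mode not in ("sustained", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    frac = group_presence_fractions(atlas).to_numpy()
    above = frac > min_fraction
    n_t = frac.shape[1]
    out: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(atlas.intervals):
        for t in range(1, n_t):
            if not above[i, :t].all():
                continue
            if above[i, t]:
                continue
            if mode == "sustained" and above[i, t:].any():
                continue
            out.setdefault(t, []).append(iv)
            break
    return out


def identify_enhancers(
    h3k4me1: Iterable[GenomicInterval], h3k27ac: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Enhancers: regions double-positive for H3K4me1 and H3K27ac peaks."""
    return intersect(list(h3k4me1), list(h3k27ac))


def annotate_promoter_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Associate peaks with the genes whose ±flank TSS windows they overlap.

    Returns (peak label -> gene ids, gene id -> peak labels); half-open
    overlap semantics, so touching a window boundary does not associate.
    This also implements the downstream-gene rule for factor-binding peak
    sets: a gene whose promoter overlaps a peak is a downstream gene.
    """
    windows = [(g.gene_id, promoter_window(g, flank)) for g in genes]
    peak_to_genes: dict[str, set[str]] = {}
    gene_to_peaks: dict[str, set[str]] = {}
    for iv in peaks:
        for gid, w in windows:
            if iv.overlaps(w):
                peak_to_genes.setdefault(iv.label, set()).add(gid)
                gene_to_peaks.setdefault(gid, set()).add(iv.label)
    return peak_to_genes, gene_to_peaks


@dataclass
class ShiftTestResult:
    """Per-class promoter-peak log2FC values and the two Welch tests.

    ``values`` maps class name -> sorted array (the ECDF support); ``tests``
    maps "up_vs_all"/"down_vs_all" -> (t statistic, p value); the sign of t
    is positive when the class mean exceeds the all-genes mean.
    """

    values: dict[str, np.ndarray]
    tests: dict[str, tuple[float, float]]

    def ecdf_table(self) -> pd.DataFrame:
        rows = []
        for cls, vals in self.values.items():
            n = len(vals)
            for i, v in enumerate(vals, start=1):
                rows.append({"class": cls, "log2fc": v, "ecdf": i / n})
        return pd.DataFrame(rows)


def promoter_shift_test(
    peak_log2fc: Mapping[str, float] | pd.Series,
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    all_genes: Iterable[str],
    gene_to_peaks: Mapping[str, set[str]],
) -> ShiftTestResult:
    """Compare promoter-peak accessibility changes of up/down genes vs all genes.

    Each gene class maps to the unique promoter peaks of its genes; the class
    value set is the log2 fold changes of those peaks.  Welch t-tests compare
    up-vs-all and down-vs-all.  A class that maps to fewer than 2 peaks is an
    error naming the class.
    """
    fc = pd.Series(peak_log2fc, dtype=float)

    def class_values(genes: Iterable[str], name: str) -> np.ndarray:
        labels: set[str] = set()
        for g in genes:
            labels |= gene_to_peaks.get(g, set())
        labels &= set(fc.index)
        if len(labels) < 2:
            raise ValueError(
                f"gene class {name!r} maps to {len(labels)} promoter peak(s); need >= 2"
            )
        return np.sort(fc[sorted(labels)].to_numpy())

    values = {
        "up": class_values(up_genes, "up"),
        "down": class_values(down_genes, "down"),
        "all": class_values(all_genes, "all"),
    }
    tests = {}
    for cls in ("up", "down"):
        res = stats.ttest_ind(values[cls], values["all"], equal_var=False)
        tests[f"{cls}_vs_all"] = (float(res.statistic), float(res.pvalue))
    return ShiftTestResult(values=values, tests=tests)
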