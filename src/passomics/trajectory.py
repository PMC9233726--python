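"""Time-course feature selection: normalization, any-vs-reference differential
testing, module clustering and the monotone-trajectory rule.

The selection semantics mirror the standard passage-series workflow: counts
are normalized by median-of-ratios size factors, each later passage is
contrasted against the reference passage, a feature is *selected* when any
contrast reaches BH-adjusted p < alpha with fold change > ``min_fold`` (or
< 1/``min_fold``), and selected features whose per-passage group means change
strictly monotonically are the senescence-associated (RS) features.

The per-contrast test is a two-sided Welch t-test on log2(normalized + 1);
the function is pluggable via the ``test`` argument of
:func:`test_differential` for callers that want a different two-sample test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .core import SampleDesign

MONOTONE_UP = "monotone_up"
MONOTONE_DOWN = "monotone_down"
NON_MONOTONE = "non_monotone"


@dataclass
class FeatureMatrix:
    """Features x samples matrix tied to a :class:`SampleDesign`.

    ``kind`` is one of ``counts``, ``normalized`` or ``methylation-level``;
    methylation levels must lie in [0, 1].
    """

    values: pd.DataFrame
    design: SampleDesign
    kind: str = "counts"

    def __post_init__(self):
        if self.kind not in ("counts", "normalized", "methylation-level"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        design_ids = list(self.design.sample_ids)
        if list(self.values.columns) != design_ids:
            if set(self.values.columns) == set(design_ids):
                self.values = self.values[design_ids]
            else:
                raise ValueError("matrix columns do not match design sample ids")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative entries in feature matrix")
        if self.kind == "methylation-level" and (arr > 1).any():
            raise ValueError("methylation levels must be in [0, 1]")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)


@dataclass
class DifferentialResult:
    """Per-contrast statistics plus the per-feature ``selected`` flag.

    ``table`` is tidy: one row per (feature, contrast) with columns
    feature_id, contrast, log2fc, pvalue, padj, significant.  ``selected``
    marks features significant in at least one contrast.
    """

    table: pd.DataFrame
    selected: pd.Series
    reference: str

    def selected_features(self) -> set:
        return set(self.selected.index[self.selected])


def normalize_library_size(matrix: FeatureMatrix) -> tuple[FeatureMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization.

    Size factors are the per-sample median ratio to the geometric-mean
    reference over features positive in every sample, rescaled to geometric
    mean 1.  If no feature is positive everywhere the function falls back to
    total-count scaling with a warning.  Normalized value = raw / size factor.
    """
    if matrix.kind != "counts":
        raise ValueError("normalize_library_size expects a counts matrix")
    counts = matrix.values.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        warnings.warn(
            "no feature positive in all samples; falling back to total-count scaling"
        )
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalize: a sample has zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    factors = pd.Series(sf, index=matrix.values.columns, name="size_factor")
    normalized = matrix.values.div(factors, axis=1)
    return FeatureMatrix(normalized, matrix.design, kind="normalized"), factors


def group_means(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-timepoint mean across replicate samples; columns are passage labels."""
    design = matrix.design
    cols = {}
    for t in range(design.n_timepoints):
        ids = [s.sample_id for s in design.samples_at(t)]
        cols[design.timepoint_labels[t]] = matrix.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups => undefined test; conservative p=1
    return np.where(np.isfinite(p), p, 1.0)


def test_differential(
    matrix: FeatureMatrix,
    reference_timepoint: int = 0,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = _welch,
) -> DifferentialResult:
    """Any-vs-reference differential testing with BH correction per contrast.

    For every timepoint t != reference the per-feature p-value comes from
    ``test`` applied to log2(normalized + 1) replicate values, BH-adjusted
    across features within that contrast.  log2 fold change is computed on
    group means with ``pseudocount``.  A contrast row is ``significant`` when
    padj < alpha and the fold change exceeds ``min_fold`` (strictly) in either
    direction; a feature is ``selected`` when any contrast is significant.

    Timepoints with fewer than 2 replicates are skipped with a warning; a
    reference with fewer than 2 replicates is an error.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    design = matrix.design
    if not (0 <= reference_timepoint < design.n_timepoints):
        raise ValueError(f"reference timepoint {reference_timepoint} out of range")
    ref_ids = [s.sample_id for s in design.samples_at(reference_timepoint)]
    if len(ref_ids) < 2:
        raise ValueError("reference timepoint needs >= 2 replicates")

    ref_vals = matrix.values[ref_ids].to_numpy(dtype=float)
    ref_log = np.log2(ref_vals + 1.0)
    ref_mean = ref_vals.mean(axis=1)
    features = matrix.values.index
    min_l2fc = np.log2(min_fold)

    rows = []
    for t in range(design.n_timepoints):
        if t == reference_timepoint:
            continue
        ids = [s.sample_id for s in design.samples_at(t)]
        label = f"{design.timepoint_labels[t]}_vs_{design.timepoint_labels[reference_timepoint]}"
        if len(ids) < 2:
            warnings.warn(f"contrast {label}: fewer than 2 replicates, skipped")
            continue
        vals = matrix.values[ids].to_numpy(dtype=float)
        p = test(np.log2(vals + 1.0), ref_log)
        padj = multipletests(p, method="fdr_bh")[1]
        l2fc = np.log2((vals.mean(axis=1) + pseudocount) / (ref_mean + pseudocount))
        significant = (padj < alpha) & (np.abs(l2fc) > min_l2fc)
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": features,
                    "contrast": label,
                    "log2fc": l2fc,
                    "pvalue": p,
                    "padj": padj,
                    "significant": significant,
                }
            )
        )
    if not rows:
        raise ValueError("no testable contrast (all non-reference timepoints skipped)")
    table = pd.concat(rows, ignore_index=True)
    selected = table.groupby("feature_id", sort=False)["significant"].any()
    selected = selected.reindex(features, fill_value=False)
    return DifferentialResult(
        table=table,
        selected=selected,
        reference=design.timepoint_labels[reference_timepoint],
    )


def classify_trajectory(means: Sequence[float], min_step: float = 0.0) -> str:
    """Label a per-timepoint mean vector as monotone up/down or neither.

    Strict policy: every adjacent difference must exceed ``min_step`` (up) or
    fall below ``-min_step`` (down); with the default min_step=0 flat segments
    fail.  The label is invariant under strictly increasing transforms of the
    means when min_step=0.
    """
    arr = np.asarray(means, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("need a 1-D vector of >= 2 group means")
    if not np.isfinite(arr).all():
        raise ValueError("group means must be finite")
    d = np.diff(arr)
    if (d > min_step).all():
        return MONOTONE_UP
    if (d < -min_step).all():
        return MONOTONE_DOWN
    return NON_MONOTONE


def classify_trajectories(means: pd.DataFrame, min_step: float = 0.0) -> pd.Series:
    """Vectorized :func:`classify_trajectory` over a features x timepoints frame."""
    arr = means.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    if not np.isfinite(arr).all():
        raise ValueError("group means must be finite")
    d = np.diff(arr, axis=1)
    up = (d > min_step).all(axis=1)
    down = (d < -min_step).all(axis=1)
    labels = np.where(up, MONOTONE_UP, np.where(down, MONOTONE_DOWN, NON_MONOTONE))
    return pd.Series(labels, index=means.index, name="trajectory")


def cluster_modules(matrix: FeatureMatrix, k: int) -> pd.Series:
    """Hierarchical (Ward, Euclidean) module assignment on z-scored group means.

    Each feature's per-timepoint group-mean vector is z-scored (constant
    vectors map to zeros) and the Ward dendrogram is cut at ``k`` clusters.
    Duplicated feature rows have zero distance and land in the same module.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    gm = group_means(matrix)
    if k > len(gm):
        raise ValueError(f"k={k} exceeds number of features {len(gm)}")
    arr = gm.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    modules = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    return pd.Series(modules, index=gm.index, name="module")


def select_rs_features(
    diff: DifferentialResult, labels: pd.Series
) -> tuple[set, set]:
    """Senescence-associated features: selected AND strictly monotone.

    Returns (rs_up, rs_down); the two sets are disjoint because a trajectory
    carries exactly one label.
    """
    selected = diff.selected_features()
    rs_up = {f for f in selected if labels.get(f) == MONOTONE_UP}
    rs_down = {f for f in selected if labels.get(f) == MONOTONE_DOWN}
    return rs_up, rs_down
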