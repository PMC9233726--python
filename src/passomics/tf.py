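"""Transcription-factor layer: PWM scanning, hypergeometric motif enrichment
against a peak background, aggregate footprint profiles with an activity
statistic, and pioneer/settler/migrator classification.

Footprint activity is a transparent flank-minus-body depth statistic on the
±flank strand-averaged aggregate profile: occupied motifs protect the motif
body from transposase insertion, so deeper dips mean more binding and the
depth difference between two passages measures the activity change.
Chromatin dependence (CD) and the chromatin opening index (COI) are taken as
inputs; only the threshold classification is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CoverageTrack, GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PWM_PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x L probabilities over A, C, G, T."""

    name: str
    matrix: np.ndarray
    family: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L")
        if m.shape[1] < 4:
            raise ValueError("PWM length must be >= 4")
        if (m < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1 (±1e-6)")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float


def read_jaspar(path) -> list[PWM]:
    """Parse JASPAR-style plain-text matrices (``>id name`` + 4 base rows).

    Rows may carry counts or probabilities, bracketed or not; columns are
    normalized to probabilities.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"motif {name!r}: missing base rows {set(BASES) - set(rows)}")
        m = np.array([rows[b] for b in BASES], dtype=float)
        colsum = m.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError(f"motif {name!r}: zero column sum")
        pwms.append(PWM(name=name, matrix=m / colsum))
        name, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[1] if len(parts) > 1 else parts[0]
            else:
                fields = line.replace("[", " ").replace("]", " ").split()
                base = fields[0].upper()
                if base not in _BASE_INDEX:
                    raise ValueError(f"unexpected matrix row {line!r}")
                rows[base] = [float(x) for x in fields[1:]]
    flush()
    return pwms


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for i, pwm in enumerate(pwms, start=1):
            fh.write(f">M{i:04d} {pwm.name}\n")
            for b in BASES:
                vals = " ".join(f"{x:.6f}" for x in pwm.matrix[_BASE_INDEX[b]])
                fh.write(f"{b} [ {vals} ]\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _log_odds(pwm: PWM, background: np.ndarray) -> np.ndarray:
    """5 x L score matrix (row 4 = non-ACGT sentinel, effectively -inf)."""
    w = np.log2((pwm.matrix + _PWM_PSEUDOCOUNT) / background[:, None])
    return np.vstack([w, np.full((1, pwm.length), -1e9)])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(encoded: np.ndarray, w: np.ndarray) -> np.ndarray:
    L = w.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(n)[:, None] + np.arange(L)[None, :]
    return w[encoded[idx], np.arange(L)[None, :]].sum(axis=1)


def scan_pwm(
    sequences: Mapping[str, str],
    regions: Sequence[GenomicInterval],
    pwm: PWM,
    background: Sequence[float] | None = None,
    min_score_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan regions on both strands for PWM matches above a score threshold.

    The score of a window is the summed log2 odds of base probability (with a
    1e-3 pseudocount) over background frequency; a hit requires score >=
    ``min_score_fraction`` x the maximum attainable score.  Minus-strand hits
    score the reverse complement of the window and are reported on ``-`` at
    the same coordinates.  Regions shorter than the motif are skipped with a
    warning.
    """
    if background is None:
        background = np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    if not (0 < min_score_fraction <= 1):
        raise ValueError("min_score_fraction must lie in (0, 1]")
    w_fwd = _log_odds(pwm, bg)
    # scanning the forward sequence with the reverse-complemented matrix finds
    # minus-strand occurrences in place
    w_rev = np.vstack([w_fwd[:4][::-1, ::-1], w_fwd[4:]])
    threshold = min_score_fraction * float(w_fwd[:4].max(axis=0).sum())
    hits: list[MotifHit] = []
    L = pwm.length
    for region in regions:
        if region.length < L:
            warnings.warn(f"region {region.label} shorter than motif ({L} bp); skipped")
            continue
        seq = sequences[region.chrom][region.start : region.end]
        encoded = _encode(seq)
        for strand, w in (("+", w_fwd), ("-", w_rev)):
            scores = _window_scores(encoded, w)
            for off in np.flatnonzero(scores >= threshold):
                start = region.start + int(off)
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(region.chrom, start, start + L, strand),
                        strand=strand,
                        score=float(scores[off]),
                    )
                )
    return sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start, h.strand))


def enrichment_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for X ~ Hypergeom(N, K, n).

    N background regions, K of them motif-positive, n targets drawn, k
    motif-positive targets observed.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def motif_enrichment(
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    background_freqs: Sequence[float] | None = None,
    min_score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Hypergeometric motif enrichment of target regions against a background.

    Counting is region-level: a region counts once per motif however many
    hits it holds.  With N background regions, K of them motif-positive, and
    k of the n target regions motif-positive, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); BH adjustment runs across motifs and the result
    is ranked by adjusted then raw p.  Targets are expected to be a subset of
    the background (warned otherwise, as the hypergeometric model assumes it).
    """
    if not target_regions or not background_regions:
        raise ValueError("target and background region sets must be non-empty")
    bg_keys = {(r.chrom, r.start, r.end) for r in background_regions}
    stray = [r for r in target_regions if (r.chrom, r.start, r.end) not in bg_keys]
    if stray:
        warnings.warn(
            f"{len(stray)} target region(s) absent from the background set; "
            "hypergeometric model assumes target ⊆ background"
        )
    N, n = len(background_regions), len(target_regions)
    rows = []
    for pwm in pwms:
        scan_universe = list(background_regions) + stray
        hits = scan_pwm(
            sequences,
            scan_universe,
            pwm,
            background=background_freqs,
            min_score_fraction=min_score_fraction,
        )
        positive = _regions_with_hits(scan_universe, hits)
        K = sum(positive[: len(background_regions)])
        pos_keys = {
            (r.chrom, r.start, r.end)
            for r, flag in zip(scan_universe, positive)
            if flag
        }
        k = sum((r.chrom, r.start, r.end) in pos_keys for r in target_regions)
        p = enrichment_pvalue(k, N, K, n)
        rows.append({"motif": pwm.name, "k": k, "n": n, "K": K, "N": N, "pvalue": p})
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df = df.sort_values(["padj", "pvalue", "motif"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _regions_with_hits(
    regions: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> list[bool]:
    """Which regions contain at least one hit (hit fully inside the region)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append((h.interval.start, h.interval.end))
    out = []
    for r in regions:
        spans = by_chrom.get(r.chrom, ())
        out.append(any(s >= r.start and e <= r.end for s, e in spans))
    return out


@dataclass
class FootprintProfile:
    """Aggregate strand-averaged coverage around motif occurrences.

    ``values[i]`` is the mean normalized coverage at position ``i - flank``
    relative to the motif start, after orienting each occurrence by its
    strand; length = motif length + 2*flank.
    """

    motif: str
    flank: int
    motif_length: int
    values: np.ndarray = field(repr=False)
    n_hits: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.motif_length + 2 * self.flank:
            raise ValueError("profile length must equal motif length + 2*flank")
        if (v < 0).any():
            raise ValueError("profile values must be non-negative")
        self.values = v

    def depth(self) -> float:
        """Footprint depth: mean flank coverage minus mean motif-body coverage."""
        body = self.values[self.flank : self.flank + self.motif_length]
        flanks = np.concatenate(
            [self.values[: self.flank], self.values[self.flank + self.motif_length :]]
        )
        return float(flanks.mean() - body.mean())


def footprint_profile(
    coverage_fwd: CoverageTrack,
    coverage_rev: CoverageTrack,
    hits: Sequence[MotifHit],
    flank: int = 100,
) -> FootprintProfile:
    """Aggregate footprint profile over motif occurrences.

    For each hit the window motif ± ``flank`` is extracted, forward- and
    reverse-strand coverage are averaged per position, minus-strand hits are
    reversed so profiles stay oriented to the motif, and the per-position
    mean across hits is returned.  Hits whose window leaves the chromosome
    are skipped with a warning; zero usable hits is an error.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if not hits:
        raise ValueError("need at least one motif hit")
    L = hits[0].interval.length
    if any(h.interval.length != L for h in hits):
        raise ValueError("all hits must share the motif length")
    windows = []
    for h in hits:
        s, e = h.interval.start - flank, h.interval.end + flank
        chrom_arr = coverage_fwd.data.get(h.interval.chrom)
        if chrom_arr is None or s < 0 or e > len(chrom_arr):
            warnings.warn(f"hit window {h.interval.label}±{flank} out of bounds; skipped")
            continue
        fwd = coverage_fwd.data[h.interval.chrom][s:e]
        rev = coverage_rev.data[h.interval.chrom][s:e]
        win = (fwd + rev) / 2.0
        if h.strand == "-":
            win = win[::-1]
        windows.append(win)
    if not windows:
        raise ValueError("no hit window lies within chromosome bounds")
    values = np.mean(windows, axis=0)
    return FootprintProfile(
        motif=f"L{L}", flank=flank, motif_length=L, values=values, n_hits=len(windows)
    )


def footprint_activity_delta(
    profile_t1: FootprintProfile, profile_t2: FootprintProfile
) -> tuple[float, float, float]:
    """Footprint activity change between two passages.

    Returns (depth(t2) - depth(t1), depth(t1), depth(t2)); positive delta
    means a deeper protection dip, i.e. increased occupancy/activity.
    """
    if len(profile_t1.values) != len(profile_t2.values):
        raise ValueError("profiles have different lengths")
    d1, d2 = profile_t1.depth(), profile_t2.depth()
    return d2 - d1, d1, d2


PIONEER = "pioneer"
SETTLER = "settler"
MIGRATOR = "migrator"


@dataclass(frozen=True)
class TFClass:
    name: str
    cd: float
    coi: float
    label: str


def classify_tf(
    cd: float,
    coi: float,
    name: str = "",
    cd_threshold: float = 0.45,
    coi_threshold: float = 4.0,
    boundary: str = "lesser",
) -> TFClass:
    """Classify a TF by chromatin dependence (CD) and chromatin opening index.

    pioneer: CD > cd_threshold and COI > coi_threshold; settler: CD >
    cd_threshold and COI <= coi_threshold; migrator: CD <= cd_threshold.
    The stated rule uses three strict inequalities, which leaves exact
    boundary values unassigned; ``boundary="lesser"`` (default) sends them to
    the lesser class (settler/migrator), ``boundary="greater"`` to the
    greater one.  Every finite (CD, COI) point gets exactly one class.
    """
    if not (np.isfinite(cd) and np.isfinite(coi)):
        raise ValueError("CD and COI must be finite")
    if boundary not in ("lesser", "greater"):
        raise ValueError(f"unknown boundary policy {boundary!r}")
    if boundary == "lesser":
        high_cd = cd > cd_threshold
        high_coi = coi > coi_threshold
    else:
        high_cd = cd >= cd_threshold
        high_coi = coi >= coi_threshold
    if high_cd:
        label = PIONEER if high_coi else SETTLER
    else:
        label = MIGRATOR
    return TFClass(name=name, cd=float(cd), coi=float(coi), label=label)


def classify_tf_table(
    metrics: pd.DataFrame,
    cd_threshold: float = 0.45,
    coi_threshold: float = 4.0,
    boundary: str = "lesser",
) -> pd.DataFrame:
    """Vector version of :func:`classify_tf` over a (tf, cd, coi) table."""
    out = metrics.copy()
    out["class"] = [
        classify_tf(row.cd, row.coi, cd_threshold=cd_threshold,
                    coi_threshold=coi_threshold, boundary=boundary).label
        for row in metrics.itertuples()
    ]
    return out
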