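"""Seeded synthetic-data generators with planted ground truth.

The generators emulate a serial-passaging multi-omics study of primary
fibroblasts: four ordered passages (P1, P3, P5, P7); RNA-seq with 4
replicates per passage and negative-binomial counts carrying planted
monotone modules; RRBS-style cytosine calls from 3 independent replicate
series with planted adjacent-passage level deltas; and ATAC-seq peak sets
plus strand-resolved coverage tracks with planted appearing/disappearing
peaks, motif occurrences and occupancy-dependent footprint dips.  Histone
mark peak sets and a CD/COI metric table complete the inputs the pipeline
consumes.

Every generator is a pure function of :class:`SimConfig`: the same seed
yields byte-identical output files.  Sub-streams are derived per generator
from fixed offsets so adding one generator never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Sample,
    SampleDesign,
    write_bed,
    write_bedgraph,
    write_counts_table,
    write_design,
    write_fasta,
    write_gene_models,
    write_methyl_calls,
)
from .tf import PWM, reverse_complement, write_jaspar

_STREAMS = {
    "genome": 1,
    "expression": 2,
    "methylome": 3,
    "accessibility": 4,
    "tf_metrics": 5,
    "schedule": 6,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults mirror the study design.

    Four passages; 4 RNA replicates, 3 methylation series, ATAC replicates
    (4, 3, 3, 3).  Planted effects: per-step log2FC 1 monotone genes (NB
    dispersion 0.1), per-step methylation deltas +0.10 / -0.04, scheduled
    peak appearance/disappearance with 0.95/0.05 presence noise, and motif
    footprint dips scaling with a per-passage bound fraction.
    """

    seed: int = 0
    timepoint_labels: tuple[str, ...] = ("P1", "P3", "P5", "P7")

    # expression
    n_genes: int = 5000
    expr_replicates: int = 4
    n_up_genes: int = 200
    n_down_genes: int = 200
    step_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    null_mean_log: float = float(np.log(100.0))
    null_mean_sd: float = 1.0
    planted_mean_log: float = float(np.log(256.0))
    planted_mean_sd: float = 0.5

    # methylome
    n_cytosines: int = 1000
    meth_series: int = 3
    n_up_cytosines: int = 50
    n_down_cytosines: int = 50
    n_tfbs_cytosines: int = 300
    meth_delta_up: float = 0.10
    meth_delta_down: float = 0.04
    tfbs_trend_delta: float = 0.03
    meth_depth: int = 30
    exact_levels: bool = False   # noise-free mode: m = round(level * n), huge n
    exact_depth: int = 10000

    # genome / accessibility
    chrom: str = "chr1"
    genome_length: int = 400_000
    gc: float = 0.5
    n_gene_models: int = 60
    promoter_flank: int = 1000
    atac_replicates: tuple[int, ...] = (4, 3, 3, 3)
    n_peaks: int = 200
    peak_width: int = 240
    n_appearing_per_timepoint: int = 15
    n_disappearing_per_timepoint: int = 15
    present_prob: float = 0.95
    absent_prob: float = 0.05
    peak_height: float = 8.0
    background_coverage: float = 1.0
    coverage_noise_sd: float = 0.3
    coverage_bin: int = 10
    footprint_dip: float = 0.5
    bound_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    n_footprint_peaks: int = 50
    motif_in_appearing_frac: float = 0.8
    motif_elsewhere_frac: float = 0.1

    # histone marks / enhancers
    n_enhancer_peaks: int = 40
    n_histone_decoys: int = 20

    # pioneer classification inputs
    n_tfs: int = 20

    def __post_init__(self):
        T = len(self.timepoint_labels)
        if T < 2:
            raise ValueError("need >= 2 timepoints")
        if len(self.atac_replicates) != T:
            raise ValueError("atac_replicates must give one count per timepoint")
        for name in ("present_prob", "absent_prob", "gc", "motif_in_appearing_frac",
                     "motif_elsewhere_frac", "footprint_dip"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(not (0 <= f <= 1) for f in self.bound_fractions):
            raise ValueError("bound fractions must lie in [0, 1]")
        if len(self.bound_fractions) != T:
            raise ValueError("bound_fractions must give one value per timepoint")
        # planted methylation trajectories must stay inside [0, 1]
        if 0.2 + self.meth_delta_up * (T - 1) > 1:
            raise ValueError("meth_delta_up escapes [0, 1] over the time course")
        if 0.7 - self.meth_delta_down * (T - 1) < 0:
            raise ValueError("meth_delta_down escapes [0, 1] over the time course")
        if self.genome_length < 10_000:
            raise ValueError("genome length must be >= 10 kb")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_labels)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Peak layout & schedule (shared between genome and accessibility)
# ---------------------------------------------------------------------------

def peak_layout(config: SimConfig) -> list[GenomicInterval]:
    """Evenly spaced non-overlapping peak intervals along the chromosome."""
    spacing = config.genome_length // (config.n_peaks + 1)
    if spacing <= config.peak_width:
        raise ValueError("too many peaks for the genome length")
    return [
        GenomicInterval(
            config.chrom,
            (i + 1) * spacing - config.peak_width // 2,
            (i + 1) * spacing - config.peak_width // 2 + config.peak_width,
        )
        for i in range(config.n_peaks)
    ]


def peak_schedule(config: SimConfig) -> pd.DataFrame:
    """Scheduled presence category per peak.

    Categories: ``constitutive`` (present throughout, i.e. appearing at the
    first passage by the first-above-threshold definition), ``appear_t{t}``
    and ``disappear_t{t}`` for t in 1..T-1.  Assignment is a deterministic
    function of the seed.
    """
    rng = _rng(config, "schedule")
    T = config.n_timepoints
    n_dyn = (config.n_appearing_per_timepoint + config.n_disappearing_per_timepoint) * (T - 1)
    if n_dyn > config.n_peaks:
        raise ValueError("dynamic peak schedule exceeds the number of peaks")
    order = rng.permutation(config.n_peaks)
    categories = np.array(["constitutive"] * config.n_peaks, dtype=object)
    pos = 0
    for t in range(1, T):
        for _ in range(config.n_appearing_per_timepoint):
            categories[order[pos]] = f"appear_t{t}"
            pos += 1
        for _ in range(config.n_disappearing_per_timepoint):
            categories[order[pos]] = f"disappear_t{t}"
            pos += 1
    layout = peak_layout(config)
    scheduled = np.ones((config.n_peaks, T), dtype=bool)
    for i, cat in enumerate(categories):
        if cat.startswith("appear_t"):
            t = int(cat.split("appear_t")[1])
            scheduled[i, :t] = False
        elif cat.startswith("disappear_t"):
            t = int(cat.split("disappear_t")[1])
            scheduled[i, t:] = False
    return pd.DataFrame(
        {
            "peak": [iv.label for iv in layout],
            "chrom": [iv.chrom for iv in layout],
            "start": [iv.start for iv in layout],
            "end": [iv.end for iv in layout],
            "category": categories,
            **{
                f"scheduled_{config.timepoint_labels[t]}": scheduled[:, t]
                for t in range(T)
            },
        }
    )


def _footprint_pwm() -> PWM:
    return _consensus_pwm("FP_TF", "ACGTACGTAC")


def _appearing_pwm() -> PWM:
    return _consensus_pwm("APPEAR_TF", "TGACGTCATG")


def _decoy_pwm() -> PWM:
    return _consensus_pwm("NULL_TF", "CCGGTTAACC")


def _consensus_pwm(name: str, consensus: str) -> PWM:
    m = np.full((4, len(consensus)), 0.03)
    for j, b in enumerate(consensus):
        m["ACGT".index(b), j] = 0.91
    return PWM(name=name, matrix=m)


def motif_placements(config: SimConfig) -> pd.DataFrame:
    """Planted motif instances: (motif, chrom, start, end, strand, peak).

    The footprint motif sits at the centre of the first
    ``n_footprint_peaks`` constitutive peaks; the appearing-enriched motif is
    planted in ``motif_in_appearing_frac`` of appearing peaks and
    ``motif_elsewhere_frac`` of all other peaks, offset from the centre so
    the two motifs never collide.  The decoy motif is never planted.
    """
    rng = _rng(config, "schedule")
    rng = np.random.default_rng(rng.integers(2**31))  # second draw stream
    sched = peak_schedule(config)
    layout = peak_layout(config)
    fp = _footprint_pwm()
    ap = _appearing_pwm()
    rows = []
    const_idx = [i for i, c in enumerate(sched["category"]) if c == "constitutive"]
    for i in const_idx[: config.n_footprint_peaks]:
        iv = layout[i]
        center = (iv.start + iv.end) // 2
        start = center - fp.length // 2
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((fp.name, iv.chrom, start, start + fp.length, strand, iv.label))
    for i, cat in enumerate(sched["category"]):
        appearing = cat.startswith("appear_t")
        prob = config.motif_in_appearing_frac if appearing else config.motif_elsewhere_frac
        if rng.random() < prob:
            iv = layout[i]
            start = iv.start + 20
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((ap.name, iv.chrom, start, start + ap.length, strand, iv.label))
    return pd.DataFrame(
        rows, columns=["motif", "chrom", "start", "end", "strand", "peak"]
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome at the requested GC with planted motifs and gene models.

    Gene TSSs sit at the centres of every third peak, which keeps adjacent
    TSSs at least 2 x ``promoter_flank`` apart so promoter windows never
    overlap.
    """
    rng = _rng(config, "genome")
    p_gc = config.gc / 2
    p_at = (1 - config.gc) / 2
    bases = rng.choice(list("ACGT"), size=config.genome_length, p=[p_at, p_gc, p_gc, p_at])
    seq = bases.copy()
    for rec in motif_placements(config).itertuples():
        pwm = {p.name: p for p in (_footprint_pwm(), _appearing_pwm())}[rec.motif]
        word = pwm.consensus()
        if rec.strand == "-":
            word = reverse_complement(word)
        seq[rec.start : rec.end] = list(word)
    genome = {config.chrom: "".join(seq)}

    layout = peak_layout(config)
    gene_peak_idx = range(0, config.n_peaks, 3)
    if config.n_gene_models > len(list(gene_peak_idx)):
        raise ValueError("too many gene models for the genome length / peak count")
    genes = []
    for g, i in zip(range(config.n_gene_models), gene_peak_idx):
        iv = layout[i]
        tss = (iv.start + iv.end) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{g + 1:05d}", config.chrom, strand, tss))
    spacing_ok = all(
        b.tss - a.tss >= 2 * config.promoter_flank for a, b in zip(genes, genes[1:])
    )
    if not spacing_ok:
        raise ValueError("gene TSS spacing below 2 x promoter flank")
    return genome, genes


def expression_design(config: SimConfig) -> SampleDesign:
    samples = [
        Sample(f"{lab}_rna_r{r + 1}", t, r + 1, "rna")
        for t, lab in enumerate(config.timepoint_labels)
        for r in range(config.expr_replicates)
    ]
    return SampleDesign(samples, list(config.timepoint_labels))


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame]:
    """NB counts with planted monotone-up/-down genes.

    Null genes keep a constant mean over passages; planted genes multiply
    their mean by 2**(±step_log2fc) per passage step.  Counts are negative
    binomial with variance mu + dispersion * mu**2.  Returns (counts, design,
    truth) where truth labels each gene monotone_up / monotone_down / null.
    """
    rng = _rng(config, "expression")
    design = expression_design(config)
    n, T = config.n_genes, config.n_timepoints
    n_planted = config.n_up_genes + config.n_down_genes
    if n_planted > n:
        raise ValueError("more planted genes than genes")
    labels = np.array(["null"] * n, dtype=object)
    # genes whose promoter peak is scheduled to appear are planted up, those
    # whose peak disappears are planted down (gene g{i+1} sits at peak 3*i),
    # coupling expression with promoter accessibility as in the real system
    n_models = min(config.n_gene_models, n)
    if n_models * 3 <= config.n_peaks:
        categories = peak_schedule(config)["category"]
        model_up = [i for i in range(n_models) if categories[3 * i].startswith("appear")]
        model_down = [i for i in range(n_models) if categories[3 * i].startswith("disappear")]
    else:
        model_up, model_down = [], []
    model_up = model_up[: config.n_up_genes]
    model_down = model_down[: config.n_down_genes]
    pool = np.arange(n_models, n)
    rest = rng.choice(pool, size=n_planted - len(model_up) - len(model_down), replace=False)
    up_idx = np.concatenate([model_up, rest[: config.n_up_genes - len(model_up)]]).astype(int)
    down_idx = np.concatenate(
        [model_down, rest[config.n_up_genes - len(model_up) :]]
    ).astype(int)
    labels[up_idx] = "monotone_up"
    labels[down_idx] = "monotone_down"

    base = np.exp(rng.normal(config.null_mean_log, config.null_mean_sd, size=n))
    base[labels != "null"] = np.exp(
        rng.normal(config.planted_mean_log, config.planted_mean_sd, size=n_planted)
    )
    step = np.zeros(n)
    step[labels == "monotone_up"] = config.step_log2fc
    step[labels == "monotone_down"] = -config.step_log2fc

    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    cols = {}
    for s in design.samples:
        mu = base * 2.0 ** (step * s.timepoint)
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            cols[s.sample_id] = rng.negative_binomial(r, p)
        else:
            cols[s.sample_id] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=gene_ids)
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels})
    return counts, design, truth


def methylation_design(config: SimConfig) -> SampleDesign:
    samples = [
        Sample(f"{lab}_meth_s{s + 1}", t, 1, f"series{s + 1}")
        for s in range(config.meth_series)
        for t, lab in enumerate(config.timepoint_labels)
    ]
    return SampleDesign(samples, list(config.timepoint_labels))


def simulate_methylome(config: SimConfig) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Cytosine calls with planted per-step level deltas.

    Planted *up* cytosines climb by ``meth_delta_up`` per step from 0.2 in
    every series; planted *down* cytosines fall by ``meth_delta_down`` from
    0.7.  A further ``n_tfbs_cytosines`` sit inside peak intervals and climb
    gently (``tfbs_trend_delta``/step) to emulate rising TFBS methylation;
    the remainder are stable with uniform base levels.  Observed counts are
    Binomial(depth, level); ``exact_levels`` substitutes m = round(level*n)
    at large n for noise-free recovery experiments.
    """
    rng = _rng(config, "methylome")
    design = methylation_design(config)
    T, S = config.n_timepoints, config.meth_series
    n = config.n_cytosines
    n_special = config.n_up_cytosines + config.n_down_cytosines + config.n_tfbs_cytosines
    if n_special > n:
        raise ValueError("planted cytosines exceed n_cytosines")

    layout = peak_layout(config)
    in_peak_pos = np.concatenate(
        [np.arange(iv.start + 5, iv.end - 5, 9) for iv in layout]
    )
    rng.shuffle(in_peak_pos)
    tfbs_pos = np.sort(in_peak_pos[: config.n_tfbs_cytosines])
    outside = rng.choice(
        np.setdiff1d(
            rng.integers(0, config.genome_length, size=4 * n), in_peak_pos
        ),
        size=n - config.n_tfbs_cytosines,
        replace=False,
    )
    outside = np.sort(outside)

    labels = np.array(["null"] * n, dtype=object)
    positions = np.concatenate([tfbs_pos, outside])
    labels[: config.n_tfbs_cytosines] = "tfbs_trend"
    k = config.n_tfbs_cytosines
    labels[k : k + config.n_up_cytosines] = "up"
    labels[k + config.n_up_cytosines : k + config.n_up_cytosines + config.n_down_cytosines] = "down"

    base = np.empty(n)
    step = np.zeros(n)
    base[labels == "tfbs_trend"] = rng.uniform(0.3, 0.5, size=(labels == "tfbs_trend").sum())
    step[labels == "tfbs_trend"] = config.tfbs_trend_delta
    base[labels == "up"] = 0.2
    step[labels == "up"] = config.meth_delta_up
    base[labels == "down"] = 0.7
    step[labels == "down"] = -config.meth_delta_down
    null_mask = labels == "null"
    base[null_mask] = rng.uniform(0.05, 0.95, size=null_mask.sum())

    rows = []
    for s in design.samples:
        level = np.clip(base + step * s.timepoint, 0.0, 1.0)
        if config.exact_levels:
            total = np.full(n, config.exact_depth)
            meth = np.rint(level * config.exact_depth).astype(int)
        else:
            total = np.full(n, config.meth_depth)
            meth = rng.binomial(total, level)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "pos": positions,
                    "sample_id": s.sample_id,
                    "methylated": meth,
                    "total": total,
                }
            )
        )
    calls = pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "pos", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        {"chrom": config.chrom, "pos": positions, "label": labels}
    ).sort_values("pos", kind="mergesort").reset_index(drop=True)
    return calls, design, truth


def atac_design(config: SimConfig) -> SampleDesign:
    samples = [
        Sample(f"{lab}_atac_r{r + 1}", t, r + 1, "atac")
        for t, lab in enumerate(config.timepoint_labels)
        for r in range(config.atac_replicates[t])
    ]
    return SampleDesign(samples, list(config.timepoint_labels))


@dataclass
class SimulatedAccessibility:
    """Everything the accessibility/TF stages consume, plus planted truth."""

    design: SampleDesign
    per_sample_peaks: dict[str, list[GenomicInterval]]
    coverage_fwd: dict[str, CoverageTrack]
    coverage_rev: dict[str, CoverageTrack]
    schedule: pd.DataFrame
    motifs: list[PWM]
    motif_truth: pd.DataFrame
    h3k4me1: list[GenomicInterval] = field(default_factory=list)
    h3k27ac: list[GenomicInterval] = field(default_factory=list)
    enhancer_truth: list[GenomicInterval] = field(default_factory=list)


def simulate_accessibility(config: SimConfig) -> SimulatedAccessibility:
    """Per-sample peak sets and strand coverage with planted dynamics.

    Peak presence per sample is Bernoulli(0.95) when the schedule says
    present and Bernoulli(0.05) otherwise.  Coverage is a flat background
    plus a boxcar enrichment over each present peak with binned Gaussian
    noise; bound motif instances multiply coverage over the motif body by
    ``footprint_dip``, with the per-passage bound fraction setting the
    probability that an instance is bound in a given sample.
    """
    rng = _rng(config, "accessibility")
    design = atac_design(config)
    layout = peak_layout(config)
    sched = peak_schedule(config)
    T = config.n_timepoints
    scheduled = sched[[f"scheduled_{lab}" for lab in config.timepoint_labels]].to_numpy()
    placements = motif_placements(config)
    peak_index = {iv.label: i for i, iv in enumerate(layout)}

    nbins = -(-config.genome_length // config.coverage_bin)
    per_sample_peaks: dict[str, list[GenomicInterval]] = {}
    coverage_fwd: dict[str, CoverageTrack] = {}
    coverage_rev: dict[str, CoverageTrack] = {}
    for s in design.samples:
        prob = np.where(scheduled[:, s.timepoint], config.present_prob, config.absent_prob)
        present = rng.random(config.n_peaks) < prob
        per_sample_peaks[s.sample_id] = [iv for iv, p in zip(layout, present) if p]

        base = np.full(config.genome_length, config.background_coverage)
        for iv, p in zip(layout, present):
            if p:
                noise = rng.normal(0.0, config.coverage_noise_sd, size=nbins_for(iv, config))
                bins = np.repeat(noise, config.coverage_bin)[: iv.length]
                base[iv.start : iv.end] += config.peak_height + bins
        bound_frac = config.bound_fractions[s.timepoint]
        for rec in placements.itertuples():
            if not present[peak_index[rec.peak]]:
                continue
            if rng.random() < bound_frac:
                base[rec.start : rec.end] *= config.footprint_dip
        base = np.clip(base, 0.0, None)
        # split total signal between strands with a mild asymmetry
        frac = 0.5 + rng.normal(0.0, 0.01)
        frac = float(np.clip(frac, 0.4, 0.6))
        coverage_fwd[s.sample_id] = CoverageTrack({config.chrom: base * frac})
        coverage_rev[s.sample_id] = CoverageTrack({config.chrom: base * (1 - frac)})

    # histone marks: enhancer peaks straddle a subset of constitutive peaks
    const_idx = [i for i, c in enumerate(sched["category"]) if c == "constitutive"]
    enh_idx = const_idx[config.n_footprint_peaks :][: config.n_enhancer_peaks]
    k4, k27, enh_truth = [], [], []
    for i in enh_idx:
        iv = layout[i]
        k4.append(GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.end + 200))
        k27.append(GenomicInterval(iv.chrom, max(0, iv.start - 150), iv.end + 150))
        enh_truth.append(GenomicInterval(iv.chrom, max(0, iv.start - 150), iv.end + 150))
    decoy_gap = config.genome_length // (config.n_histone_decoys + 1)
    for d in range(config.n_histone_decoys):
        pos = d * decoy_gap + decoy_gap // 2
        k4.append(GenomicInterval(config.chrom, pos, pos + 120))
        pos2 = pos + 5000
        if pos2 + 120 <= config.genome_length:
            k27.append(GenomicInterval(config.chrom, pos2, pos2 + 120))
    # decoys may coincidentally overlap scheduled peaks: keep truth = k4 ∩ k27
    return SimulatedAccessibility(
        design=design,
        per_sample_peaks=per_sample_peaks,
        coverage_fwd=coverage_fwd,
        coverage_rev=coverage_rev,
        schedule=sched,
        motifs=[_footprint_pwm(), _appearing_pwm(), _decoy_pwm()],
        motif_truth=placements,
        h3k4me1=sorted(k4),
        h3k27ac=sorted(k27),
        enhancer_truth=sorted(enh_truth),
    )


def nbins_for(iv: GenomicInterval, config: SimConfig) -> int:
    return -(-iv.length // config.coverage_bin)


def simulate_tf_metrics(config: SimConfig) -> pd.DataFrame:
    """CD/COI input table for pioneer-factor classification (random draws)."""
    rng = _rng(config, "tf_metrics")
    names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    return pd.DataFrame(
        {
            "tf": names,
            "cd": np.round(rng.uniform(0.2, 0.7, size=config.n_tfs), 4),
            "coi": np.round(rng.uniform(1.0, 8.0, size=config.n_tfs), 4),
        }
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def simulate_to_dir(config: SimConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` and return the manifest.

    The manifest (also written as ``manifest.json``) lists the emitted paths
    and the full config; it carries no timestamps, so a rerun with the same
    seed reproduces every file byte for byte.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def reg(key: str, relpath: str) -> Path:
        paths[key] = relpath
        p = out / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    genome, genes = simulate_genome(config)
    write_fasta(genome, reg("genome", "genome.fa"))
    write_gene_models(genes, reg("gene_models", "gene_models.tsv"))

    counts, expr_design, expr_truth = simulate_expression(config)
    write_counts_table(counts, reg("counts", "counts.tsv"))
    write_design(expr_design, reg("design_expression", "design_expression.tsv"))
    expr_truth.to_csv(reg("truth_expression", "truth/expression.tsv"), sep="\t", index=False)

    calls, meth_design, meth_truth = simulate_methylome(config)
    write_methyl_calls(calls, reg("methyl_calls", "methylation_calls.tsv"))
    write_design(meth_design, reg("design_methylation", "design_methylation.tsv"))
    meth_truth.to_csv(reg("truth_methylation", "truth/methylation.tsv"), sep="\t", index=False)

    acc = simulate_accessibility(config)
    write_design(acc.design, reg("design_atac", "design_atac.tsv"))
    for sid in acc.design.sample_ids:
        write_bed(acc.per_sample_peaks[sid], reg(f"peaks_{sid}", f"peaks/{sid}.bed"))
        write_bedgraph(acc.coverage_fwd[sid], reg(f"coverage_fwd_{sid}", f"coverage/{sid}.fwd.bedGraph"))
        write_bedgraph(acc.coverage_rev[sid], reg(f"coverage_rev_{sid}", f"coverage/{sid}.rev.bedGraph"))
    acc.schedule.to_csv(reg("truth_peaks", "truth/peak_schedule.tsv"), sep="\t", index=False)
    acc.motif_truth.to_csv(reg("truth_motifs", "truth/motif_placements.tsv"), sep="\t", index=False)
    write_jaspar(acc.motifs, reg("motifs", "motifs.jaspar"))
    write_bed(acc.h3k4me1, reg("h3k4me1", "histone/h3k4me1.bed"))
    write_bed(acc.h3k27ac, reg("h3k27ac", "histone/h3k27ac.bed"))
    write_bed(acc.enhancer_truth, reg("truth_enhancers", "truth/enhancers.bed"))

    simulate_tf_metrics(config).to_csv(reg("tf_metrics", "tf_metrics.tsv"), sep="\t", index=False)

    manifest = {"config": asdict(config), "paths": paths}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
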