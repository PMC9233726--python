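"""Genomic coordinate primitives and plain-text format I/O.

All coordinates are 0-based, half-open ``[start, end)`` internally.  BED and
bedGraph are read/written natively in that convention; the GTF-subset reader
converts from 1-based inclusive on the fly.  Chromosome names are matched by
exact string comparison everywhere — :func:`normalize_chrom_name` is provided
for callers that need to reconcile "chr1"/"1" style differences, but it is
never applied implicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).  Touching
    intervals (``a.end == b.start``) do not overlap.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test; intervals on different chromosomes never overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its identifier, strand and transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    timepoint: int
    replicate: int
    series: str = "s1"


@dataclass
class SampleDesign:
    """Ordered timepoints x replicates (x replicate series) sample layout.

    ``timepoint_labels`` gives the ordered passage labels (e.g. P1, P3, P5,
    P7); ``samples[i].timepoint`` indexes into it.  ``series`` partitions the
    samples into independent replicate series; for assays without series
    structure every sample shares one series id.
    """

    samples: list[Sample]
    timepoint_labels: list[str]

    def __post_init__(self):
        if len(self.timepoint_labels) < 2:
            raise ValueError("need at least 2 timepoints")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        seen = {s.timepoint for s in self.samples}
        for t in range(len(self.timepoint_labels)):
            if t not in seen:
                raise ValueError(f"timepoint {t} ({self.timepoint_labels[t]}) has no samples")
        for s in self.samples:
            if not (0 <= s.timepoint < len(self.timepoint_labels)):
                raise ValueError(f"sample {s.sample_id} has out-of-range timepoint {s.timepoint}")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_labels)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def series_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.series not in out:
                out.append(s.series)
        return out

    def samples_at(self, timepoint: int) -> list[Sample]:
        return [s for s in self.samples if s.timepoint == timepoint]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "timepoint": [self.timepoint_labels[s.timepoint] for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "series": [s.series for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, timepoint_labels: Sequence[str] | None = None) -> "SampleDesign":
        if timepoint_labels is None:
            # first-appearance order of the timepoint column
            timepoint_labels = list(dict.fromkeys(df["timepoint"].astype(str)))
        labels = list(timepoint_labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        samples = [
            Sample(
                sample_id=str(r.sample_id),
                timepoint=idx[str(r.timepoint)],
                replicate=int(r.replicate),
                series=str(r.series),
            )
            for r in df.itertuples()
        ]
        return cls(samples, labels)


@dataclass
class CoverageTrack:
    """Per-base signal arrays keyed by chromosome; values are non-negative."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    def chrom(self, name: str) -> np.ndarray:
        return self.data[name]

    def values(self, interval: GenomicInterval) -> np.ndarray:
        arr = self.data[interval.chrom]
        return arr[interval.start : interval.end]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if set(self.data) != set(other.data):
            raise ValueError("coverage tracks cover different chromosomes")
        return CoverageTrack({c: self.data[c] + other.data[c] for c in self.data})


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge: maximal intervals covered by at least one input interval.

    Touching intervals ([0,5) and [5,10)) produce contiguous coverage and are
    merged.  Output is sorted and disjoint; strand is dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least one interval of each set.

    Half-open semantics: intervals that merely touch (end == start) do not
    intersect.  Empty input yields empty output.  The result is disjoint and
    sorted; the operation is commutative and idempotent.
    """
    a = merge_intervals(set_a) if set_a else []
    b = merge_intervals(set_b) if set_b else []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, ()):
            s, e = max(iv.start, jv.start), min(iv.end, jv.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out)


class _MergedIndex:
    """Sorted disjoint interval index for fast any-overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in merge_intervals(list(intervals)):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs, dtype=int)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if starts is None or len(starts) == 0:
            return False
        idx = int(np.searchsorted(starts, query.end, side="left")) - 1
        if idx < 0:
            return False
        return bool(self._ends[query.chrom][idx] > query.start)


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Iterable[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: does each query overlap at least one subject interval."""
    index = _MergedIndex(subjects)
    return np.array([index.overlaps(q) for q in queries], dtype=bool)


def promoter_window(gene: GeneModel, flank: int) -> GenomicInterval:
    """Symmetric window of ``flank`` bp either side of the TSS, clipped at 0.

    Strand-agnostic by design: the promoter definition used throughout is the
    plain +/- flank window around the TSS with no strand orientation.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    return GenomicInterval(gene.chrom, max(0, gene.tss - flank), gene.tss + flank)


def normalize_chrom_name(name: str, style: str = "ucsc") -> str:
    """Convert between "chr1" (ucsc) and "1" (plain) naming styles."""
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "ucsc":
        return f"chr{bare}"
    if style == "plain":
        return bare
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    """One BED/narrowPeak line; columns beyond strand kept opaque in ``extra``."""

    interval: GenomicInterval
    name: str = "."
    score: str = "."
    extra: tuple[str, ...] = ()


def _split_bed_line(line: str) -> list[str]:
    return re.split(r"\s+", line.strip())


def read_bed_records(path) -> list[BedRecord]:
    """Parse BED3/BED6/narrowPeak; malformed lines raise :class:`ParseError`."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_bed_line(line)
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative start {start}")
            if end <= start:
                raise ParseError(path, lineno, f"empty or inverted interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in STRANDS:
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            records.append(
                BedRecord(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=fields[3] if len(fields) >= 4 else ".",
                    score=fields[4] if len(fields) >= 5 else ".",
                    extra=tuple(fields[6:]),
                )
            )
    return records


def read_bed(path) -> list[GenomicInterval]:
    return [r.interval for r in read_bed_records(path)]


def write_bed(items: Iterable[GenomicInterval | BedRecord], path) -> None:
    """Write intervals/records as BED; plain intervals emit 6 columns."""
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, GenomicInterval):
                item = BedRecord(interval=item)
            iv = item.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), item.name, item.score, iv.strand]
            cols.extend(item.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """TSV with header gene_id, chrom, strand, tss (0-based)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chrom", "strand", "tss"]
        if header[: len(required)] != required:
            raise ParseError(path, 1, f"expected header {required}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 columns")
            gene_id, chrom, strand, tss_s = fields[:4]
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                tss = int(tss_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer tss {tss_s!r}") from None
            try:
                genes.append(GeneModel(gene_id, chrom, strand, tss))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_gtf_genes(path) -> list[GeneModel]:
    """GTF subset reader: ``gene`` feature lines only.

    GTF is 1-based inclusive; the TSS is derived from strand (start for +,
    end for -) and converted to the internal 0-based convention.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, "expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start_s, end_s, strand = fields[0], fields[3], fields[4], fields[6]
            m = re.search(r'gene_id "([^"]+)"', fields[8])
            if m is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            gene_id = m.group(1)
            if gene_id in seen:
                continue
            seen.add(gene_id)
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ParseError(path, lineno, f"inverted interval {start}-{end}")
            tss = start - 1 if strand == "+" else end - 1
            try:
                genes.append(GeneModel(gene_id, chrom, strand, tss))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return genes


# ---------------------------------------------------------------------------
# Coverage (bedGraph)
# ---------------------------------------------------------------------------

def read_bedgraph(path, chrom_lengths: Mapping[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph into per-base arrays.

    If ``chrom_lengths`` is not given, each chromosome's length is the maximum
    end coordinate seen; positions not covered by any record are 0.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_bed_line(line)
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if end <= start or start < 0:
                raise ParseError(path, lineno, f"bad span [{start}, {end})")
            if value < 0:
                raise ParseError(path, lineno, f"negative coverage {value}")
            spans.setdefault(chrom, []).append((start, end, value))
    data: dict[str, np.ndarray] = {}
    for chrom, recs in spans.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else max(e for _, e, _ in recs)
        )
        arr = np.zeros(length, dtype=float)
        for start, end, value in recs:
            if end > length:
                raise ValueError(f"{chrom}: span end {end} exceeds declared length {length}")
            arr[start:end] = value
        data[chrom] = arr
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            data.setdefault(chrom, np.zeros(length, dtype=float))
    return CoverageTrack(data)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write run-length-encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_counts_table(path) -> pd.DataFrame:
    """Feature x sample count matrix from TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        feat = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"{path}: non-numeric count for feature {feat!r}")
    if (values < 0).any().any():
        feat = values.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count for feature {feat!r}")
    return values


def write_counts_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_methyl_calls(path) -> pd.DataFrame:
    """Cytosine call table: chrom, pos, sample_id, methylated, total.

    Rejects records with total < 1, methylated > total or negative values,
    reporting the offending line number.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": int, "sample_id": str, "methylated": int, "total": int},
    )
    required = ["chrom", "pos", "sample_id", "methylated", "total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    bad = (
        (df["pos"] < 0)
        | (df["total"] < 1)
        | (df["methylated"] < 0)
        | (df["methylated"] > df["total"])
    )
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = df.iloc[i]
        raise ParseError(
            path,
            i + 2,  # header is line 1
            f"invalid call chrom={row['chrom']} pos={row['pos']} "
            f"m={row['methylated']} n={row['total']}",
        )
    return df[required]


def write_methyl_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "timepoint", "replicate", "series"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    return SampleDesign.from_frame(df)


def write_design(design: SampleDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA (via Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
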