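"""Atlas rule, appearing/disappearing detection, MA counts, enhancers,
promoter annotation and the accessibility shift test."""

import numpy as np
import pandas as pd
import pytest

from passomics.accessibility import (
    PeakAtlas,
    annotate_promoter_peaks,
    build_atlas,
    detect_appearing_peaks,
    detect_disappearing_peaks,
    group_presence_fractions,
    identify_enhancers,
    ma_high_coverage_counts,
    promoter_shift_test,
    quantify_atlas,
)
from passomics.core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Sample,
    SampleDesign,
    intersect,
)
from passomics.trajectory import FeatureMatrix


def _design(reps_per_tp):
    samples = [
        Sample(f"P{t}_r{r}", t, r, "atac")
        for t, n in enumerate(reps_per_tp)
        for r in range(1, n + 1)
    ]
    return SampleDesign(samples, [f"P{t}" for t in range(len(reps_per_tp))])


def _atlas_from_fractions(fracs, reps_per_tp):
    """Build an atlas whose presence matrix realizes exact group fractions."""
    design = _design(reps_per_tp)
    intervals = [GenomicInterval("chr1", 1000 * i, 1000 * i + 200) for i in range(len(fracs))]
    presence = {}
    for t, n in enumerate(reps_per_tp):
        for r in range(1, n + 1):
            col = []
            for row in fracs:
                col.append(r <= round(row[t] * n))
            presence[f"P{t}_r{r}"] = col
    df = pd.DataFrame(presence, index=[iv.label for iv in intervals], dtype=bool)
    return PeakAtlas(intervals=intervals, presence=df, design=design)


class TestBuildAtlas:
    def _peaks(self, present):
        return [GenomicInterval("chr1", 100, 300)] if present else []

    @pytest.mark.parametrize(
        "present_count,reps,expected",
        [
            (3, 4, True),   # 0.75 > 0.6
            (2, 4, False),  # 0.50
            (2, 3, True),   # 0.667 > 0.6, the n=3 passage groups
            (3, 5, False),  # 0.6 exactly: strictly-greater rule
        ],
    )
    def test_replicate_fraction_boundaries(self, present_count, reps, expected):
        design = _design([reps, reps])
        peaks = {}
        for t in range(2):
            for r in range(1, reps + 1):
                # only the first group carries the peak
                has = t == 0 and r <= present_count
                peaks[f"P{t}_r{r}"] = self._peaks(has)
        atlas = build_atlas(peaks, design)
        assert (len(atlas.intervals) == 1) is expected

    def test_missing_sample_rejected(self):
        design = _design([2, 2])
        with pytest.raises(ValueError, match="without a peak list"):
            build_atlas({"P0_r1": []}, design)

    def test_invalid_fraction_rejected(self):
        design = _design([2, 2])
        peaks = {s: [] for s in design.sample_ids}
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                build_atlas(peaks, design, min_fraction=bad)

    def test_matches_brute_force_oracle_on_random_peaks(self, rng):
        design = _design([4, 4, 4])  # 12 samples
        base_peaks = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(
                np.arange(200) * 500, rng.integers(100, 400, 200)
            )
        ]
        per_sample = {
            sid: [iv for iv in base_peaks if rng.random() < 0.5]
            for sid in design.sample_ids
        }
        atlas = build_atlas(per_sample, design, min_fraction=0.6)
        # brute-force: candidates are the merged union; count overlaps directly
        from passomics.core import merge_intervals

        candidates = merge_intervals([iv for ivs in per_sample.values() for iv in ivs])
        expected = []
        for c in candidates:
            retained = False
            for t in range(3):
                ids = [s.sample_id for s in design.samples_at(t)]
                frac = np.mean(
                    [any(c.overlaps(p) for p in per_sample[sid]) for sid in ids]
                )
                if frac > 0.6:
                    retained = True
            if retained:
                expected.append(c)
        assert atlas.intervals == expected
        # presence matrix agrees with direct overlap checks
        for sid in design.sample_ids:
            for iv in atlas.intervals:
                direct = any(iv.overlaps(p) for p in per_sample[sid])
                assert atlas.presence.loc[iv.label, sid] == direct

    def test_invariant_to_sample_order_and_monotone_in_fraction(self, rng):
        design = _design([3, 3])
        base = [GenomicInterval("chr1", i * 1000, i * 1000 + 300) for i in range(30)]
        per_sample = {
            sid: [iv for iv in base if rng.random() < 0.6] for sid in design.sample_ids
        }
        a1 = build_atlas(per_sample, design)
        shuffled = dict(reversed(list(per_sample.items())))
        a2 = build_atlas(shuffled, design)
        assert a1.intervals == a2.intervals
        strict = build_atlas(per_sample, design, min_fraction=0.9)
        assert set(iv.label for iv in strict.intervals) <= set(
            iv.label for iv in a1.intervals
        )


class TestAppearingDisappearing:
    def test_first_above_threshold_is_the_appearance(self):
        atlas = _atlas_from_fractions([(0.25, 0.75, 1.0, 1.0)], [4, 4, 4, 4])
        out = detect_appearing_peaks(atlas)
        assert list(out) == [1]

    def test_regain_is_not_newly_appeared(self):
        atlas = _atlas_from_fractions([(0.75, 0.25, 0.75, 0.75)], [4, 4, 4, 4])
        out = detect_appearing_peaks(atlas)
        assert list(out) == [0]

    def test_disappearance_requires_sustained_absence_by_default(self):
        atlas = _atlas_from_fractions(
            [(1.0, 1.0, 0.25, 0.25), (1.0, 1.0, 0.25, 1.0), (0.0, 0.0, 0.0, 0.0)],
            [4, 4, 4, 4],
        )
        out = detect_disappearing_peaks(atlas)
        assert {t: [iv.label for iv in v] for t, v in out.items()} == {
            2: ["chr1:0-200"]
        }
        first = detect_disappearing_peaks(atlas, mode="first")
        assert {t: [iv.label for iv in v] for t, v in first.items()} == {
            2: ["chr1:0-200", "chr1:1000-1200"]
        }

    def test_appearing_and_disappearing_disjoint_at_each_timepoint(self, rng):
        fracs = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(50, 4))
        atlas = _atlas_from_fractions([tuple(r) for r in fracs], [4, 4, 4, 4])
        app = detect_appearing_peaks(atlas)
        dis = detect_disappearing_peaks(atlas)
        for t in set(app) & set(dis):
            assert {iv.label for iv in app[t]}.isdisjoint(
                {iv.label for iv in dis[t]}
            )

    def test_matches_definition_oracle_on_random_presence(self, rng):
        fracs = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(80, 4))
        atlas = _atlas_from_fractions([tuple(r) for r in fracs], [4, 4, 4, 4])
        realized = group_presence_fractions(atlas).to_numpy()
        app = detect_appearing_peaks(atlas)
        dis = detect_disappearing_peaks(atlas)
        labels = atlas.labels
        for i in range(len(labels)):
            above = realized[i] > 0.6
            for t in range(4):
                in_app = any(
                    labels[i] == iv.label for iv in app.get(t, [])
                )
                expected_app = bool(above[t] and not above[:t].any())
                assert in_app == expected_app
                in_dis = any(labels[i] == iv.label for iv in dis.get(t, []))
                expected_dis = bool(
                    t >= 1 and above[:t].all() and not above[t:].any()
                )
                assert in_dis == expected_dis


class TestQuantifyAndMa:
    def _setup(self, rng, n_peaks=60, reps=(3, 3)):
        design = _design(list(reps))
        intervals = [
            GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(n_peaks)
        ]
        presence = pd.DataFrame(
            True, index=[iv.label for iv in intervals], columns=design.sample_ids
        )
        atlas = PeakAtlas(intervals=intervals, presence=presence, design=design)
        return design, intervals, atlas

    def test_signal_is_summed_coverage(self, rng):
        design, intervals, atlas = self._setup(rng, n_peaks=3)
        arr = np.zeros(5000)
        arr[0:200] = 2.0
        arr[1000:1200] = 1.0
        cov = {sid: CoverageTrack({"chr1": arr.copy()}) for sid in design.sample_ids}
        fm = quantify_atlas(atlas, cov, normalize=False)
        assert fm.values.iloc[0, 0] == pytest.approx(400.0)
        assert fm.values.iloc[1, 0] == pytest.approx(200.0)
        assert fm.values.iloc[2, 0] == pytest.approx(0.0)

    def test_planted_open_closed_counts(self, rng):
        # 30 peaks double, 60 halve, 110 stay flat; all well above threshold
        design = _design([4, 4])
        n = 200
        intervals = [GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(n)]
        presence = pd.DataFrame(
            True, index=[iv.label for iv in intervals], columns=design.sample_ids
        )
        atlas = PeakAtlas(intervals=intervals, presence=presence, design=design)
        base = np.full(n, 2000.0)
        values = {}
        for s in design.samples:
            mult = np.ones(n)
            if s.timepoint == 1:
                mult[:30] = 2.0
                mult[30:90] = 0.5
            noise = rng.normal(1.0, 0.02, n)
            values[s.sample_id] = base * mult * noise
        fm = FeatureMatrix(
            pd.DataFrame(values, index=[iv.label for iv in intervals]),
            design,
            kind="normalized",
        )
        # a mild fold criterion separates the planted 2-fold changes from
        # BH-boosted null jitter, which pure significance would sweep in
        n_open, n_closed, table = ma_high_coverage_counts(
            fm, 0, 1, mean_threshold=800, min_fold=1.3
        )
        assert (n_open, n_closed) == (30, 60)
        assert n_open + n_closed <= int(table["high_coverage"].sum())

    def test_strict_mean_threshold(self, rng):
        design = _design([2, 2])
        intervals = [GenomicInterval("chr1", 0, 200)]
        presence = pd.DataFrame(
            True, index=[iv.label for iv in intervals], columns=design.sample_ids
        )
        atlas = PeakAtlas(intervals=intervals, presence=presence, design=design)
        fm = FeatureMatrix(
            pd.DataFrame(
                {sid: [799.9] for sid in design.sample_ids},
                index=[iv.label for iv in intervals],
            ),
            design,
            kind="normalized",
        )
        n_open, n_closed, table = ma_high_coverage_counts(fm, 0, 1)
        assert (n_open, n_closed) == (0, 0)
        assert not table["high_coverage"].iloc[0]


class TestEnhancers:
    def test_basic_double_positive(self):
        out = identify_enhancers(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 50, 150)]
        )
        assert out == [GenomicInterval("chr1", 50, 100)]

    def test_disjoint_marks_no_enhancer(self):
        assert identify_enhancers(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 200, 300)]
        ) == []

    def test_equals_interval_intersection(self, rng):
        k4 = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 10000, 50), rng.integers(50, 500, 50))
        ]
        k27 = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 10000, 50), rng.integers(50, 500, 50))
        ]
        assert identify_enhancers(k4, k27) == intersect(k4, k27)


class TestPromoterAnnotation:
    def test_examples(self):
        genes = [GeneModel("g1", "chr1", "+", 10000)]
        p2g, g2p = annotate_promoter_peaks(
            [GenomicInterval("chr1", 9500, 9900), GenomicInterval("chr1", 11000, 11200)],
            genes,
            flank=1000,
        )
        assert p2g == {"chr1:9500-9900": {"g1"}}
        assert g2p == {"g1": {"chr1:9500-9900"}}

    def test_matches_all_pairs_brute_force(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", int(p))
            for i, p in enumerate(rng.integers(2000, 200000, 100))
        ]
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 200000, 300), rng.integers(100, 600, 300))
        ]
        p2g, g2p = annotate_promoter_peaks(peaks, genes, flank=1000)
        for iv in peaks:
            for g in genes:
                lo, hi = max(0, g.tss - 1000), g.tss + 1000
                hit = iv.start < hi and lo < iv.end
                assert (g.gene_id in p2g.get(iv.label, set())) == hit
                assert (iv.label in g2p.get(g.gene_id, set())) == hit


class TestPromoterShiftTest:
    def _annotation(self, n=600):
        gene_to_peaks = {f"g{i}": {f"peak{i}"} for i in range(n)}
        return gene_to_peaks

    def test_null_classes_rarely_significant(self, rng):
        hits = 0
        runs = 40
        for _ in range(runs):
            fc = pd.Series(rng.normal(0, 1, 600), index=[f"peak{i}" for i in range(600)])
            g2p = self._annotation()
            res = promoter_shift_test(
                fc,
                [f"g{i}" for i in range(200)],
                [f"g{i}" for i in range(200, 400)],
                [f"g{i}" for i in range(600)],
                g2p,
            )
            if res.tests["up_vs_all"][1] < 0.05:
                hits += 1
        assert hits / runs <= 0.20

    def test_planted_shift_detected(self, rng):
        # three disjoint classes of 200 genes each, sd=1; up class shifted +0.5
        detected = 0
        runs = 20
        for _ in range(runs):
            vals = rng.normal(0, 1, 600)
            vals[:200] += 0.5
            fc = pd.Series(vals, index=[f"peak{i}" for i in range(600)])
            res = promoter_shift_test(
                fc,
                [f"g{i}" for i in range(200)],
                [f"g{i}" for i in range(200, 400)],
                [f"g{i}" for i in range(400, 600)],
                self._annotation(),
            )
            t, p = res.tests["up_vs_all"]
            if p < 1e-3 and t > 0:
                detected += 1
        assert detected / runs >= 0.95

    def test_small_class_is_error_naming_the_class(self):
        fc = pd.Series([0.1, 0.2, 0.3], index=["peak0", "peak1", "peak2"])
        g2p = {"g0": {"peak0"}, "g1": {"peak1"}, "g2": {"peak2"}}
        with pytest.raises(ValueError, match="'up'"):
            promoter_shift_test(fc, ["g0"], ["g1", "g2"], ["g0", "g1", "g2"], g2p)

    def test_ecdf_table_reaches_one(self, rng):
        fc = pd.Series(rng.normal(0, 1, 30), index=[f"peak{i}" for i in range(30)])
        g2p = {f"g{i}": {f"peak{i}"} for i in range(30)}
        res = promoter_shift_test(
            fc, ["g0", "g1"], ["g2", "g3"], [f"g{i}" for i in range(30)], g2p
        )
        tbl = res.ecdf_table()
        assert tbl.groupby("class")["ecdf"].max().eq(1.0).all()
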