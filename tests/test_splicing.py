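"""Splicing quantification, matching, support metrics, case-study detectors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pccr.intervals import GenomicInterval
from pccr.splicing import (
    SpliceSite,
    benchmark_score,
    classify_splice_sites,
    cryptic_sites,
    detect_loopouts,
    detect_rna_bridges,
    editing_site_or,
    loopout_psi_comparison,
    match_iwp_iwo,
    psi,
    reactivity_delta,
    structure_support,
)


class TestPsi:
    @pytest.mark.parametrize(
        "inc, exc, expected",
        [(8, 1, 0.8), (0, 5, 0.0), (10, 0, 1.0), (4, 2, None), (9, 0, None)],
    )
    def test_formula_and_denominator_rule(self, inc, exc, expected):
        assert psi(inc, exc) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            psi(-1, 2)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(deadline=None)
    def test_bounds_and_monotonicity(self, inc, exc):
        value = psi(inc, exc)
        if value is not None:
            assert 0.0 <= value <= 1.0
            up = psi(inc + 1, exc)
            assert up is None or up >= value
            down = psi(inc, exc + 1)
            assert down is None or down <= value


class TestSpliceSiteClasses:
    def test_top_and_bottom_two_percent(self):
        sites = [SpliceSite(i, "donor", support=3 + i) for i in range(100)]
        labels = classify_splice_sites(sites)
        assert sorted(p for p, v in labels.items() if v == "active") == [98, 99]
        assert sorted(p for p, v in labels.items() if v == "inactive") == [0, 1]

    def test_low_support_excluded(self):
        sites = [SpliceSite(i, "donor", support=2) for i in range(100)]
        assert classify_splice_sites(sites) == {}

    def test_tie_break_deterministic(self):
        sites = [SpliceSite(i, "donor", support=5) for i in range(100)]
        a = classify_splice_sites(sites)
        b = classify_splice_sites(list(reversed(sites)))
        assert a == b and len(a) == 4


class TestCrypticSites:
    def test_threshold_and_exclusions(self):
        cands = [
            SpliceSite(10, "donor", 0, score=801.0),
            SpliceSite(20, "donor", 0, score=799.0),
            SpliceSite(30, "acceptor", 0, score=951.0),
            SpliceSite(40, "acceptor", 0, score=951.0),
        ]
        out = cryptic_sites(cands, expressed=set(), annotated={40})
        assert [s.position for s in out] == [10, 30]

    def test_empty(self):
        assert cryptic_sites([], set(), set()) == []


class TestMatchIwpIwo:
    def test_printed_counts_reproduce_or(self):
        """At genome-scale containment fractions (about a third of
        structure-bearing introns and a quarter of structure-free ones
        holding a 3' end) the odds ratio is about 1.50."""
        from pccr.nulls import ContingencyTable2x2, odds_ratio

        or_, ci, _, _ = odds_ratio(
            ContingencyTable2x2(12782, 38119 - 12782, 9575, 38119 - 9575)
        )
        assert or_ == pytest.approx(1.50, abs=0.01)

    def test_random_labels_give_unit_or(self):
        rng = np.random.default_rng(0)
        introns, with_pccr, ends = [], set(), []
        for i in range(3_000):
            L = int(10 ** rng.uniform(2.2, 3.8))
            s = i * 20_000
            iv = GenomicInterval("chr1", s, s + L)
            introns.append(iv)
            if rng.random() < 0.5:
                with_pccr.add((iv.chrom, iv.start, iv.end))
            if rng.random() < 0.3:
                ends.append(GenomicInterval("chr1", s + L // 2, s + L // 2 + 1))
        res = match_iwp_iwo(introns, with_pccr, ends, [], seed=1)
        or_, _, _, _ = res["or_3p"]
        assert or_ == pytest.approx(1.0, abs=0.25)
        assert res["n_matched"] > 1_000

    def test_length_matched_samples(self):
        rng = np.random.default_rng(2)
        introns, with_pccr = [], set()
        for i in range(2_000):
            # structures preferentially in long introns
            L = int(10 ** rng.uniform(2, 4))
            iv = GenomicInterval("chr1", i * 30_000, i * 30_000 + L)
            introns.append(iv)
            if rng.random() < (np.log10(L) - 2) / 2:
                with_pccr.add((iv.chrom, iv.start, iv.end))
        res = match_iwp_iwo(introns, with_pccr, [], [], seed=0)
        li = np.log10([len(iv) for iv in res["iwp"]])
        lo = np.log10([len(iv) for iv in res["iwo"]])
        assert abs(li.mean() - lo.mean()) < 0.05

    def test_empty_feature_set_flagged(self):
        introns = [GenomicInterval("chr1", 0, 1_000)]
        res = match_iwp_iwo(introns, set(), [], [], seed=0)
        assert res["or_3p"] is None


class FakePCCR:
    def __init__(self, chrom, s1, e1, s2, e2, group="I", pccr_id=None):
        self.chrom = chrom
        self.ccr1 = GenomicInterval(chrom, s1, e1)
        self.ccr2 = GenomicInterval(chrom, s2, e2)
        self.span = (s1, e2)
        self.inner_gap = (e1, s2)
        self.energy_group = group
        self.pccr_id = pccr_id
        self.gene_id = "g"


class TestLoopoutPsi:
    def _setup(self, delta, n=400, seed=0):
        rng = np.random.default_rng(seed)
        exons, rows, pccrs = [], [], []
        for i in range(n):
            s = i * 1_000
            exon = GenomicInterval("chr1", s + 100, s + 150, name=f"e{i}")
            exons.append(exon)
            looped = i % 2 == 0
            if looped:
                pccrs.append(FakePCCR("chr1", s + 50, s + 80, s + 200, s + 230))
            mean = 0.75 + (delta if looped else 0.0)
            p = float(np.clip(rng.normal(mean, 0.08), 0.01, 0.99))
            total = 200
            inc = int(rng.binomial(total, p))
            rows.append((f"e{i}", inc, (total - inc) // 2))
        quants = pd.DataFrame(rows, columns=["exon_id", "inc", "exc"])
        return exons, pccrs, quants

    def test_identical_distributions(self):
        exons, pccrs, quants = self._setup(delta=0.0)
        res = loopout_psi_comparison(exons, pccrs, quants, by_group=False)
        assert res["all"]["p_value"] > 0.001

    def test_planted_shift_detected(self):
        exons, pccrs, quants = self._setup(delta=-0.2)
        res = loopout_psi_comparison(exons, pccrs, quants, by_group=False)
        assert res["all"]["p_value"] < 1e-6
        assert np.mean(res["all"]["looped_psi"]) < np.mean(
            res["all"]["control_psi"]
        )

    def test_all_exons_looped_is_error(self):
        exons, pccrs, quants = self._setup(delta=0.0, n=4)
        pccrs = [
            FakePCCR("chr1", e.start - 50, e.start - 20, e.end + 20, e.end + 50)
            for e in exons
        ]
        with pytest.raises(ValueError):
            loopout_psi_comparison(exons, pccrs, quants, by_group=False)


class TestStructureSupport:
    def _pccr(self, s1, e1, s2, e2):
        return FakePCCR("chr1", s1, e1, s2, e2)

    def test_identical_sets(self):
        pccrs = [self._pccr(0, 10, 50, 60), self._pccr(100, 110, 150, 160)]
        pairs = [
            (GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 60)),
            (GenomicInterval("chr1", 100, 110), GenomicInterval("chr1", 150, 160)),
        ]
        res = structure_support(pccrs, pairs)
        assert (res.P, res.R, res.pi) == (100.0, 100.0, 100.0)

    def test_disjoint_sets(self):
        pccrs = [self._pccr(0, 10, 50, 60)]
        pairs = [
            (GenomicInterval("chr1", 500, 510), GenomicInterval("chr1", 550, 560))
        ]
        res = structure_support(pccrs, pairs)
        assert (res.P, res.R) == (0.0, 0.0)

    def test_one_sided_overlap_feeds_pi_denominator(self):
        pccrs = [self._pccr(0, 10, 50, 60)]
        pairs = [
            (GenomicInterval("chr1", 5, 15), GenomicInterval("chr1", 500, 510))
        ]
        res = structure_support(pccrs, pairs)
        assert res.P == 0.0 and res.pi == 0.0  # denominator 1, no full match

    def test_swapped_sides_still_match(self):
        pccrs = [self._pccr(0, 10, 50, 60)]
        pairs = [
            (GenomicInterval("chr1", 50, 60), GenomicInterval("chr1", 0, 10))
        ]
        assert structure_support(pccrs, pairs).P == 100.0

    def test_empty_experimental_set(self):
        with pytest.raises(ValueError):
            structure_support([self._pccr(0, 10, 50, 60)], [])

    def test_order_invariance(self):
        pccrs = [self._pccr(0, 10, 50, 60), self._pccr(100, 110, 150, 160)]
        pairs = [
            (GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 60)),
        ]
        a = structure_support(pccrs, pairs)
        b = structure_support(list(reversed(pccrs)), pairs)
        assert a.P == b.P and a.R == b.R and a.pi == b.pi


class TestCaseStudyDetectors:
    def _scene(self):
        """A bridge geometry: peak near arm 1, exon near arm 2; and a
        loop-out geometry: exon between arms, peak on an arm."""
        bridge = FakePCCR("chr1", 1_000, 1_020, 3_000, 3_020, pccr_id=1)
        loop = FakePCCR("chr1", 10_000, 10_030, 10_500, 10_530, pccr_id=2)
        peaks = {
            "RBFOX2": [GenomicInterval("chr1", 950, 990)],  # 10 nts from arm 1
            "QKI": [GenomicInterval("chr1", 10_010, 10_040)],  # on loop arm
        }
        exons = [
            GenomicInterval("chr1", 3_040, 3_100, name="target"),  # 20 nts away
            GenomicInterval("chr1", 10_200, 10_260, name="looped"),
        ]
        kd = pd.DataFrame(
            [
                ("target", "RBFOX2", -0.43, 0.001),
                ("looped", "QKI", -0.56, 0.002),
            ],
            columns=["exon_id", "rbp", "delta_psi", "q_value"],
        )
        return [bridge, loop], peaks, exons, kd

    def test_bridge_detected(self):
        pccrs, peaks, exons, kd = self._scene()
        out = detect_rna_bridges(pccrs, peaks, exons, kd, window=50)
        assert len(out) == 1
        assert out[0].rbp == "RBFOX2" and out[0].delta_psi == -0.43

    def test_bridge_window_excludes_far_peak(self):
        pccrs, peaks, exons, kd = self._scene()
        peaks["RBFOX2"] = [GenomicInterval("chr1", 900, 949)]  # 51 nts away
        assert detect_rna_bridges(pccrs, peaks, exons, kd, window=50) == []

    def test_bridge_requires_significance(self):
        pccrs, peaks, exons, kd = self._scene()
        kd.loc[kd.exon_id == "target", "q_value"] = 0.02
        assert detect_rna_bridges(pccrs, peaks, exons, kd, window=50) == []

    def test_loopout_detected(self):
        pccrs, peaks, exons, kd = self._scene()
        out = detect_loopouts(pccrs, peaks, exons, kd)
        assert len(out) == 1
        assert out[0].rbp == "QKI" and out[0].delta_psi == -0.56

    def test_loopout_needs_peak_on_arm(self):
        pccrs, peaks, exons, kd = self._scene()
        peaks["QKI"] = [GenomicInterval("chr1", 10_100, 10_140)]  # in the loop
        assert detect_loopouts(pccrs, peaks, exons, kd) == []


class TestBenchmarkScore:
    def test_identity(self):
        s = {(1, 2), (3, 4)}
        assert benchmark_score(s, s) == 1.0

    def test_disjoint(self):
        assert benchmark_score({(1, 2)}, {(3, 4)}) == 0.0

    def test_fraction(self):
        s1 = {(i, i) for i in range(10)}
        s2 = {(i, i) for i in range(8)} | {(99, 99)}
        assert benchmark_score(s1, s2) == 0.8

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            benchmark_score(set(), {(1, 2)})


class TestReactivityAndEditing:
    def test_constant_track_zero_deltas(self, small_catalog, small_cirs):
        from pccr.tracks import ScoreTrack

        size = max(c.interval.end for c in small_cirs) + 10
        track = ScoreTrack({"chr1": np.full(size, 0.5)})
        res = reactivity_delta(small_catalog, small_cirs, track, seed=0)
        assert np.allclose(res["deltas"], 0.0)
        assert res["beta1"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_depression_gives_negative_slope(
        self, small_toy, small_catalog, small_cirs, small_tracks
    ):
        from pccr.tracks import ScoreTrack

        track = ScoreTrack(small_tracks.reactivity)
        res = reactivity_delta(small_catalog, small_cirs, track, seed=1)
        assert np.mean(res["deltas"]) < 0
        assert res["beta1"] < 0

    def test_editing_enriched_in_arms(
        self, small_toy, small_catalog, small_cirs, small_tracks
    ):
        ccrs = [p.ccr1 for p in small_catalog] + [p.ccr2 for p in small_catalog]
        or_, ci, p, _ = editing_site_or(
            ccrs, small_cirs, small_tracks.editing_sites, small_toy.genome
        )
        assert or_ > 2.0 and p < 0.01

    def test_empty_editing_set_rejected(
        self, small_toy, small_catalog, small_cirs
    ):
        ccrs = [p.ccr1 for p in small_catalog]
        with pytest.raises(ValueError):
            editing_site_or(ccrs, small_cirs, [], small_toy.genome)
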