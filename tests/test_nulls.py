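"""Resampling controls, enrichment, FDR by re-wiring, odds ratios."""

import numpy as np
import pytest
from scipy import stats

from pccr.annotation import CIR, Gene
from pccr.intervals import GenomicInterval
from pccr.nulls import (
    ContingencyTable2x2,
    classify_overlap,
    enrichment,
    forked_peak_or,
    ccr_peak_enrichment,
    odds_ratio,
    random_gene_control,
    random_shift_control,
    rewire_fdr,
)
from pccr.tracks import Genome


class FakePCCR:
    def __init__(self, chrom, s1, e1, s2, e2, gene_id="g"):
        self.chrom = chrom
        self.gene_id = gene_id
        self.ccr1 = GenomicInterval(chrom, s1, e1)
        self.ccr2 = GenomicInterval(chrom, s2, e2)
        self.span = (s1, e2)
        self.inner_gap = (e1, s2)


class TestClassifyOverlap:
    def setup_method(self):
        self.p = FakePCCR("chr1", 10, 15, 40, 45)

    def test_inside(self):
        assert classify_overlap(self.p, GenomicInterval("chr1", 0, 100)) == "inside"

    def test_outside_looped_exon(self):
        assert (
            classify_overlap(self.p, GenomicInterval("chr1", 20, 30)) == "outside"
        )

    def test_crossing(self):
        assert (
            classify_overlap(self.p, GenomicInterval("chr1", 0, 30)) == "crossing"
        )

    def test_disjoint(self):
        assert (
            classify_overlap(self.p, GenomicInterval("chr1", 60, 90)) == "disjoint"
        )
        assert (
            classify_overlap(self.p, GenomicInterval("chr2", 0, 100)) == "disjoint"
        )

    def test_feature_overlapping_arm_not_outside(self):
        # straddles the left arm: crossing, not looped out
        assert (
            classify_overlap(self.p, GenomicInterval("chr1", 12, 30)) == "crossing"
        )


def _gene(gid, start, end, chrom="chr1", strand="+"):
    return Gene(
        id=gid,
        interval=GenomicInterval(chrom, start, end, strand, name=gid),
        exons=(),
    )


class TestRandomShift:
    def test_gene_equal_to_span_pins_structure(self):
        gene = _gene("g", 100, 150)
        p = FakePCCR("chr1", 100, 110, 140, 150)
        (cat,) = random_shift_control([p], [gene], n=1, seed=0)
        assert cat[0].span == (100, 150)

    def test_preserves_cardinality_geometry(self):
        gene = _gene("g", 0, 10_000)
        pccrs = [FakePCCR("chr1", 100, 120, 400, 430) for _ in range(5)]
        cats = random_shift_control(pccrs, [gene], n=40, seed=1)
        assert len(cats) == 40
        for cat in cats:
            assert len(cat) == 5
            for q in cat:
                assert q.len1 == 20 and q.len2 == 30
                assert q.inner_gap[1] - q.inner_gap[0] == 280

    def test_shift_offsets_uniform(self):
        """Goodness of fit of placement offsets over many draws."""
        gene = _gene("g", 0, 1_030)
        p = FakePCCR("chr1", 0, 10, 20, 30)
        cats = random_shift_control([p], [gene], n=10_000, seed=2)
        starts = np.array([cat[0].span[0] for cat in cats])
        hist, _ = np.histogram(starts, bins=10, range=(0, 1_000))
        assert stats.chisquare(hist).pvalue > 1e-3

    def test_reproducible_under_seed(self):
        gene = _gene("g", 0, 10_000)
        p = [FakePCCR("chr1", 100, 120, 400, 430)]
        a = random_shift_control(p, [gene], n=3, seed=5)
        b = random_shift_control(p, [gene], n=3, seed=5)
        assert a == b


class TestRandomGene:
    def test_single_gene_universe(self):
        gene = _gene("g", 0, 10_000)
        p = FakePCCR("chr1", 1_000, 1_020, 1_400, 1_430)
        (cat,) = random_gene_control([p], [gene], n=1, seed=0)
        assert cat[0].gene_id == "g"
        assert cat[0].span == (1_000, 1_430)  # same relative position

    def test_relative_position_preserved(self):
        genes = [_gene("a", 0, 10_000), _gene("b", 50_000, 60_000)]
        p = FakePCCR("chr1", 4_000, 4_020, 4_400, 4_430, gene_id="a")
        cats = random_gene_control([p], genes, n=20, seed=1)
        for cat in cats:
            q = cat[0]
            gene = next(g for g in genes if g.id == q.gene_id)
            rel = (q.span[0] - gene.interval.start) / (
                len(gene) - (q.span[1] - q.span[0])
            )
            assert rel == pytest.approx(4_000 / (10_000 - 430), abs=0.01)

    def test_length_matching(self):
        rng = np.random.default_rng(0)
        genes = [
            _gene(f"g{i}", i * 50_000, i * 50_000 + int(L))
            for i, L in enumerate(rng.uniform(5_000, 50_000, 30))
        ]
        src = genes[0]
        p = FakePCCR(
            "chr1",
            src.interval.start + 10,
            src.interval.start + 30,
            src.interval.start + 200,
            src.interval.start + 230,
            gene_id=src.id,
        )
        cats = random_gene_control([p], genes, n=50, seed=3)
        matched = 0
        for cat in cats:
            tgt = next(g for g in genes if g.id == cat[0].gene_id)
            matched += abs(len(tgt) - len(src)) <= 0.1 * len(src)
        assert matched >= 47  # ≥95% of draws length-matched


class TestEnrichment:
    def test_features_covering_everything(self):
        gene = _gene("g", 0, 10_000)
        pccrs = [FakePCCR("chr1", s, s + 20, s + 100, s + 130)
                 for s in range(500, 5_000, 500)]
        features = [GenomicInterval("chr1", 0, 10_000)]
        controls = random_shift_control(pccrs, [gene], n=20, seed=0)
        res = enrichment(pccrs, features, controls, "inside")
        assert res.enrichment == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_empty_feature_set(self):
        pccrs = [FakePCCR("chr1", 0, 10, 50, 60)]
        res = enrichment(pccrs, [], [[p] for p in [pccrs]], "inside")
        assert res.observed == 0

    def test_planted_inside_enrichment(self):
        """Structures placed only inside narrow features are enriched
        inside and depleted crossing, against random shifts."""
        rng = np.random.default_rng(4)
        gene = _gene("g", 0, 100_000)
        features = [
            GenomicInterval("chr1", s, s + 400) for s in range(0, 100_000, 2_000)
        ]
        pccrs = []
        for f in features[:25]:
            pccrs.append(FakePCCR("chr1", f.start + 10, f.start + 30,
                                  f.start + 300, f.start + 330))
        controls = random_shift_control(pccrs, [gene], n=40, seed=5)
        res_in = enrichment(pccrs, features, controls, "inside")
        assert res_in.enrichment > 1.5 and res_in.p_value < 0.01
        res_x = enrichment(pccrs, features, controls, "crossing")
        assert res_x.enrichment < 1.0


class TestOddsRatio:
    def test_printed_transcript_end_counts(self):
        or_, ci, p, corrected = odds_ratio(
            ContingencyTable2x2(12782, 25337, 9575, 28544)
        )
        assert or_ == pytest.approx(1.50, abs=0.01)
        assert ci[1] - or_ == pytest.approx(0.05, abs=0.02)
        assert not corrected

    def test_unit_table(self):
        assert odds_ratio(ContingencyTable2x2(1, 1, 1, 1))[0] == 1.0

    def test_zero_cell_haldane(self):
        or_, _, _, corrected = odds_ratio(ContingencyTable2x2(10, 0, 5, 5))
        assert corrected and np.isfinite(or_)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)

    def test_transpose_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            o1 = odds_ratio(ContingencyTable2x2(a, b, c, d))[0]
            o2 = odds_ratio(ContingencyTable2x2(d, c, b, a))[0]
            assert o1 == pytest.approx(o2)


class TestForkedPeaks:
    def test_independent_placement_gives_unit_or(self, small_catalog):
        """Peaks placed independently at the two arms: OR ≈ 1."""
        rng = np.random.default_rng(0)
        logs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            peaks = []
            for p in small_catalog:
                for arm in (p.ccr1, p.ccr2):
                    if rng.random() < 0.4:
                        peaks.append(
                            GenomicInterval(arm.chrom, arm.start, arm.end)
                        )
            res = forked_peak_or(small_catalog, {"X": peaks}, window=10)
            if "X" in res:
                logs.append(np.log(res["X"][0]))
        assert abs(np.mean(logs)) < 0.35

    def test_always_forked_degenerate(self, small_catalog):
        peaks = []
        for p in small_catalog:
            for arm in (p.ccr1, p.ccr2):
                peaks.append(GenomicInterval(arm.chrom, arm.start, arm.end))
        res = forked_peak_or(small_catalog, {"X": peaks}, window=10)
        or_, _, _, corrected = res["X"]
        assert corrected and or_ > 10

    def test_no_pccrs(self):
        assert forked_peak_or([], {"X": []}) == {}


class TestCCRPeakEnrichment:
    def test_half_coverage_threshold(self, small_catalog, small_cirs):
        ccrs = [small_catalog[0].ccr1]
        short = GenomicInterval(
            ccrs[0].chrom, ccrs[0].start, ccrs[0].start + int(0.49 * len(ccrs[0]))
        )
        res = ccr_peak_enrichment(ccrs, small_cirs, [short], n=5, seed=0)
        assert res.observed == 0

    def test_peaks_tiling_everything(self, small_catalog, small_cirs):
        ccrs = [p.ccr1 for p in small_catalog[:10]]
        peaks = [c.interval for c in small_cirs]
        res = ccr_peak_enrichment(ccrs, small_cirs, peaks, n=10, seed=0)
        assert res.enrichment == pytest.approx(1.0)

    def test_peaks_planted_on_ccrs(self):
        """Peaks sitting exactly on arms that occupy a small part of wide
        conserved regions: observed coverage beats random shifts."""
        gene = _gene("g", 0, 100_000)
        cirs, ccrs, peaks = [], [], []
        for i in range(20):
            s = 1_000 + i * 400
            cirs.append(
                CIR(GenomicInterval("chr1", s, s + 200, "+", "g"), "g",
                    gene.interval)
            )
            ccr = GenomicInterval("chr1", s + 80, s + 110)
            ccrs.append(ccr)
            peaks.append(GenomicInterval("chr1", ccr.start, ccr.end))
        res = ccr_peak_enrichment(ccrs, cirs, peaks, n=20, seed=1)
        assert res.observed == len(ccrs)
        assert res.enrichment > 2.0 and res.p_value < 0.01


def _cognate_gene(gid, start, stems, genome_seq, chrom="chr1"):
    """Write cognate complementary island pairs into a background string
    and return (gene, cirs); mutates genome_seq (a list)."""
    from pccr.energies import revcomp_dna

    cirs = []
    pos = start + 300
    gene_end = start + 300 + 4_000
    for stem in stems:
        s1 = stem
        s2 = revcomp_dna(stem)
        genome_seq[pos : pos + len(s1)] = list(s1)
        cirs.append((pos, pos + len(s1)))
        pos2 = pos + 1_000
        genome_seq[pos2 : pos2 + len(s2)] = list(s2)
        cirs.append((pos2, pos2 + len(s2)))
        pos += 2_000
    gene = Gene(
        id=gid,
        interval=GenomicInterval(chrom, start, gene_end, "+", name=gid),
        exons=(
            GenomicInterval(chrom, start, start + 50, "+"),
            GenomicInterval(chrom, gene_end - 50, gene_end, "+"),
        ),
    )
    out = [
        CIR(GenomicInterval(chrom, s, e, "+", gid), gid, gene.interval)
        for s, e in cirs
    ]
    return gene, out


class TestRewireFDR:
    # stems of clearly distinct lengths so length matching pairs twins
    STEMS = ["GCGCGCGCGCGC", "GGCCAATTGGCCAATTGGCC",
             "GCATGCATGCATGCATGCATGCATGCAT"]

    def test_duplicated_genes_give_unit_fdr(self):
        seq = list("T" * 20_000)
        g1, c1 = _cognate_gene("a", 100, self.STEMS, seq)
        g2, c2 = _cognate_gene("b", 10_100, self.STEMS, seq)
        genome = Genome({"chr1": "".join(seq)})
        est = rewire_fdr(c1 + c2, [g1, g2], genome, n=4, seed=0)
        assert est.n_real > 0
        assert est.fdr == pytest.approx(1.0, abs=0.01)

    def test_zero_cross_complementarity_gives_zero_fdr(self):
        seq = list("T" * 20_000)
        g1, c1 = _cognate_gene("a", 100, self.STEMS, seq)
        # second gene: conserved islands with no pairing potential at all
        g2 = _gene("b", 10_100, 14_400)
        c2 = [
            CIR(GenomicInterval("chr1", s, s + 20, "+", "b"), "b", g2.interval)
            for s in range(10_500, 11_500, 300)
        ]
        genome = Genome({"chr1": "".join(seq)})
        est = rewire_fdr(c1 + c2, [g1, g2], genome, n=2, seed=0)
        assert est.n_real > 0
        assert est.fdr == 0.0

    def test_needs_two_genes(self):
        g = _gene("a", 0, 1_000)
        with pytest.raises(ValueError):
            rewire_fdr([], [g], Genome({"chr1": "A" * 1000}))
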