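"""Peak I/O, q-filtering, replicate reconciliation, binding classes."""

import numpy as np
import pytest

from chipcross.genome import GenomicInterval
from chipcross.peaks import (
    Peak,
    PeakSet,
    assign_binding_class,
    classify_by_tss_distance,
    common_peaks,
    filter_peaks_by_q,
    merged_peaks,
    peak_tss_distance,
    read_narrowpeak,
    replicate_correlation,
    write_narrowpeak,
)
from chipcross.synthetic import generate_chip

from conftest import make_gene


def peak(chrom, start, end, name="p", q=5.0):
    return Peak(
        interval=GenomicInterval(chrom, start, end), name=name, neg_log10_q=q
    )


class TestNarrowPeakIO:
    def test_field_mapping(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr2L\t100\t200\tp1\t50\t.\t3.1\t5.2\t4.8\t60\n")
        ps = read_narrowpeak(f)
        (p,) = ps.peaks
        assert (p.interval.start, p.interval.end) == (100, 200)
        assert p.neg_log10_q == 4.8 and p.summit_offset == 60
        assert p.score == 50 and p.signal == 3.1

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.narrowPeak"
        f.write_text("")
        assert len(read_narrowpeak(f)) == 0

    def test_round_trip(self, tmp_path, small_chip):
        rep1, _, _ = small_chip
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(rep1, path)
        back = read_narrowpeak(path, label=rep1.label)
        assert [p.interval for p in back] == [p.interval for p in rep1]
        assert [p.neg_log10_q for p in back] == pytest.approx(
            [p.neg_log10_q for p in rep1]
        )

    def test_wrong_column_count(self, tmp_path):
        f = tmp_path / "bad.narrowPeak"
        f.write_text("chr1\t1\t2\tp\n")
        with pytest.raises(ValueError, match="line 1"):
            read_narrowpeak(f)


class TestQFilter:
    def test_hyper_significant_removed_boundary_kept(self):
        ps = PeakSet("x", [peak("c", 0, 10, "a", 150.0),
                           peak("c", 20, 30, "b", 100.0),
                           peak("c", 40, 50, "c", 99.0)])
        out = filter_peaks_by_q(ps)
        assert [p.name for p in out] == ["b", "c"]  # strict inequality

    def test_matches_comprehension_oracle(self, rng):
        qs = rng.uniform(0, 200, 10)
        ps = PeakSet("x", [
            peak("c", 100 * i, 100 * i + 50, f"p{i}", q)
            for i, q in enumerate(qs)
        ])
        out = filter_peaks_by_q(ps, 100.0)
        assert {p.name for p in out} == {
            f"p{i}" for i, q in enumerate(qs) if q <= 100.0
        }


class TestCommonPeaks:
    def test_intersection_geometry(self):
        a = PeakSet("a", [peak("c", 100, 200, "a1", 5.0)])
        b = PeakSet("b", [peak("c", 150, 250, "b1", 3.0)])
        (p,) = common_peaks(a, b).peaks
        assert (p.interval.start, p.interval.end) == (150, 200)
        assert p.neg_log10_q == 3.0  # min of the pair

    def test_abutting_intervals_excluded(self):
        a = PeakSet("a", [peak("c", 100, 200)])
        b = PeakSet("b", [peak("c", 200, 300)])
        assert len(common_peaks(a, b)) == 0

    def test_one_to_many_yields_many(self):
        a = PeakSet("a", [peak("c", 100, 500, "a1")])
        b = PeakSet("b", [peak("c", 150, 200, "b1"),
                          peak("c", 300, 400, "b2")])
        out = common_peaks(a, b)
        assert [(p.interval.start, p.interval.end) for p in out] == [
            (150, 200), (300, 400)
        ]

    def test_matches_all_pairs_oracle(self, rng):
        def random_set(label):
            ps = []
            for i in range(200):
                s = int(rng.integers(0, 50_000))
                w = int(rng.integers(1, 400))
                ps.append(peak("c", s, s + w, f"{label}{i}",
                               float(rng.uniform(0, 50))))
            return PeakSet(label, ps)

        a, b = random_set("a"), random_set("b")
        got = {
            (p.interval.start, p.interval.end)
            for p in common_peaks(a, b)
        }
        oracle = set()
        for p1 in a:
            for p2 in b:
                lo = max(p1.interval.start, p2.interval.start)
                hi = min(p1.interval.end, p2.interval.end)
                if lo < hi:
                    oracle.add((lo, hi))
        assert got == oracle

    def test_commutative_and_contained(self, small_chip):
        rep1, rep2, _ = small_chip
        ab = common_peaks(rep1, rep2)
        ba = common_peaks(rep2, rep1)
        assert sorted(
            (p.interval.chrom, p.interval.start, p.interval.end) for p in ab
        ) == sorted(
            (p.interval.chrom, p.interval.start, p.interval.end) for p in ba
        )
        for p in ab:
            assert any(p.interval.overlaps(q.interval)
                       and q.interval.start <= p.interval.start
                       and p.interval.end <= q.interval.end
                       for q in rep1)


class TestBindingClassification:
    def test_promoter_precedence_and_multigene_support(self):
        # one peak in gene A's promoter window that also lies inside gene
        # B's intron region (overlapping spans built explicitly)
        gene_a = make_gene("a", "chr1", 10000, 14000, strand="+")
        gene_b = make_gene("b", "chr1", 5000, 9900, strand="+")
        p = peak("chr1", 9650, 9800, "shared")  # in A's window, in B's span
        calls = assign_binding_class([gene_a, gene_b], PeakSet("x", [p]))
        by_id = {c.gene_id: c for c in calls}
        assert by_id["a"].binding_class == "promoter"
        assert by_id["b"].binding_class == "nonpromoter_genic"
        assert by_id["a"].supporting_peaks == ["shared"]

    def test_distant_peak_leaves_gene_unbound(self):
        gene = make_gene("g", "chr1", 100_000, 105_000)
        calls = assign_binding_class(
            [gene], PeakSet("x", [peak("chr1", 200_000, 200_500)])
        )
        assert calls[0].binding_class == "unbound"
        assert calls[0].supporting_peaks == []
        assert calls[0].min_tss_distance is None

    def test_classes_partition_universe(self, small_genome, small_chip):
        genes, _ = small_genome
        rep1, rep2, _ = small_chip
        calls = assign_binding_class(genes, common_peaks(rep1, rep2))
        assert len(calls) == len(genes)
        assert {c.gene_id for c in calls} == {g.gene_id for g in genes}

    def test_noise_free_planted_classes_recovered(self, small_genome):
        genes, sizes = small_genome
        rep1, rep2, classes = generate_chip(
            genes, sizes, "f", noise_peaks_per_mb=0.0,
            replicate_jitter=0, seed=3,
        )
        calls = assign_binding_class(genes, common_peaks(rep1, rep2))
        assert all(c.binding_class == classes[c.gene_id] for c in calls)

    def test_adding_peaks_never_demotes(self, small_genome, small_chip):
        genes, _ = small_genome
        rep1, rep2, _ = small_chip
        common = common_peaks(rep1, rep2)
        rank = {"unbound": 0, "nonpromoter_genic": 1, "promoter": 2}
        before = {
            c.gene_id: rank[c.binding_class]
            for c in assign_binding_class(genes, common)
        }
        extra = PeakSet(
            "more", list(common.peaks) + [peak("chr1", 5, 10, "xx")]
        )
        after = {
            c.gene_id: rank[c.binding_class]
            for c in assign_binding_class(genes, extra)
        }
        assert all(after[g] >= before[g] for g in before)


class TestTssDistance:
    def test_tss_inside_peak_is_zero(self):
        gene = make_gene("g", "chr1", 10000, 15000)
        p = peak("chr1", 9900, 10100)
        assert peak_tss_distance(p, gene.tss_positions) == 0

    def test_gap_arithmetic(self):
        gene = make_gene("g", "chr1", 1600, 3000)
        p = peak("chr1", 1000, 1100)
        assert peak_tss_distance(p, gene.tss_positions) == 500

    def test_binning_matches_exhaustive_min(self, small_genome, small_chip):
        genes, _ = small_genome
        rep1, rep2, _ = small_chip
        common = common_peaks(rep1, rep2)
        edges = [0, 100, 500, 2000, 10000]
        bins = classify_by_tss_distance(genes, common, edges)
        calls = {
            c.gene_id: c
            for c in assign_binding_class(genes, common)
        }
        for gid, b in bins.items():
            d = calls[gid].min_tss_distance
            expected = int(np.searchsorted(edges, d, side="right") - 1)
            assert b == expected

    def test_decreasing_edges_rejected(self, small_genome, small_chip):
        genes, _ = small_genome
        rep1, _, _ = small_chip
        with pytest.raises(ValueError):
            classify_by_tss_distance(genes, rep1, [100, 100])


class TestReplicateCorrelation:
    def test_identity_and_negation(self):
        x = np.arange(10.0)
        assert replicate_correlation(x, x) == pytest.approx(1.0)
        assert replicate_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        mu = rng.lognormal(3, 1, 500)
        x = mu + rng.normal(0, 1, 500)
        y = mu + rng.normal(0, 1, 500)
        r = replicate_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float(
            (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            replicate_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_merged_peaks_union_geometry():
    a = PeakSet("a", [peak("c", 100, 200), peak("c", 500, 600)])
    b = PeakSet("b", [peak("c", 150, 300)])
    out = merged_peaks(a, b)
    assert [(p.interval.start, p.interval.end) for p in out] == [
        (100, 300), (500, 600)
    ]
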