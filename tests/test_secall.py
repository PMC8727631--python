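"""Promoter filtering, the LOESS slope-1 SE call, and constituents."""

import numpy as np
import pytest

from sescope.intervals import GenomicInterval, TSS
from sescope.secall import (
    DegenerateDistributionError,
    EnhancerRegion,
    call_super_enhancers,
    constituent_enhancers,
    filter_promoters,
)


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestFilterPromoters:
    def test_overlapping_region_removed(self):
        tss = [TSS("g", "chr1", 10_000, "+")]
        kept = filter_promoters([iv(7_600, 8_000)], tss)
        assert kept == []

    def test_half_open_boundary_kept(self):
        """[12500, 13000) does not overlap the half-open window [7500, 12500)."""
        tss = [TSS("g", "chr1", 10_000, "+")]
        kept = filter_promoters([iv(12_500, 13_000)], tss)
        assert len(kept) == 1

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            filter_promoters([iv(0, 10)], [], window=-1)

    def test_matches_quadratic_oracle(self, rng):
        regions = [
            iv(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 500_000, 100), rng.integers(100, 5_000, 100))
        ]
        tss = [
            TSS(f"g{i}", "chr1", int(p), "+")
            for i, p in enumerate(rng.integers(0, 500_000, 20))
        ]
        kept = {(r.interval.start, r.interval.end) for r in filter_promoters(regions, tss)}
        expected = set()
        for r in regions:
            hit = any(
                r.start < t.pos + 2500 and max(0, t.pos - 2500) < r.end for t in tss
            )
            if not hit:
                expected.add((r.start, r.end))
        assert kept == expected

    def test_idempotent_and_never_enlarges(self, rng):
        regions = [iv(int(s), int(s) + 500) for s in rng.integers(0, 100_000, 50)]
        tss = [TSS(f"g{i}", "chr1", int(p), "-") for i, p in enumerate(rng.integers(0, 100_000, 10))]
        once = filter_promoters(regions, tss)
        twice = filter_promoters(once, tss)
        assert len(once) <= len(regions)
        assert [r.interval for r in twice] == [r.interval for r in once]


def planted_sizes(seed=0, n_typical=95, n_super=5):
    rng = np.random.default_rng(seed)
    typ = rng.uniform(1_000, 8_000, n_typical)
    sup = rng.uniform(40_000, 80_000, n_super)
    return typ, sup


def regions_from_sizes(sizes):
    out, pos = [], 0
    for s in sizes:
        out.append(iv(pos, pos + int(s)))
        pos += int(s) + 10_000
    return out


def oracle_slope1_call(sizes, span=0.3):
    """Independent reimplementation of the scaled slope-1 cutoff."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    v = np.sort(np.asarray(sizes, float))
    n = v.size
    x = np.arange(n) / (n - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    fit = lowess(y, x, frac=span, it=0, return_sorted=False)
    d = np.gradient(fit, x)
    i0 = int(np.nonzero(d >= 1)[0][0])
    cut = fit[i0] * (v[-1] - v[0]) + v[0]
    return np.asarray(sizes, float) >= cut


class TestCallSuperEnhancers:
    def test_planted_wide_regions_called_super(self):
        typ, sup = planted_sizes(seed=4)
        sizes = np.concatenate([typ, sup])
        regions = regions_from_sizes(sizes)
        result = call_super_enhancers(regions)
        called = {r.interval.length for r in result.supers}
        assert called == {int(s) for s in sup}
        # and it matches the independent reimplementation
        expected_mask = oracle_slope1_call([r.length for r in regions])
        got_mask = np.array(
            [r.enh_class == "super" for r in sorted(result.regions, key=lambda r: r.rank)]
        )
        np.testing.assert_array_equal(np.sort(got_mask), np.sort(expected_mask))

    def test_scale_invariance(self):
        typ, sup = planted_sizes(seed=9)
        sizes = np.concatenate([typ, sup]).astype(int)
        r1 = call_super_enhancers(regions_from_sizes(sizes))
        r2 = call_super_enhancers(regions_from_sizes(sizes * 10))
        c1 = sorted(r.rank for r in r1.supers)
        c2 = sorted(r.rank for r in r2.supers)
        assert c1 == c2

    def test_all_equal_sizes_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            call_super_enhancers(regions_from_sizes([5000] * 20))

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            call_super_enhancers(regions_from_sizes([100, 200, 300]))

    def test_partition_and_monotonicity(self):
        typ, sup = planted_sizes(seed=13)
        regions = regions_from_sizes(np.concatenate([typ, sup]))
        result = call_super_enhancers(regions)
        assert len(result.supers) + len(result.typicals) == len(regions)
        # if A is super, any region with larger ranking value is super
        sizes_super = [r.size for r in result.supers]
        sizes_typical = [r.size for r in result.typicals]
        assert min(sizes_super) > max(sizes_typical)
        assert min(sizes_super) >= result.cutoff_value

    def test_signal_ranking_option(self):
        typ, sup = planted_sizes(seed=4)
        regions = []
        pos = 0
        # constant sizes, signal carries the separation
        for s in np.concatenate([typ, sup]):
            regions.append(EnhancerRegion(iv(pos, pos + 1000), signal=float(s)))
            pos += 12_000
        result = call_super_enhancers(regions, ranking="signal")
        assert len(result.supers) == 5


class TestConstituents:
    def _se(self, start=0, end=50_000):
        return EnhancerRegion(iv(start, end), enh_class="super")

    def test_ordering_by_score(self):
        peaks = [iv(100, 600, score=40), iv(1_000, 2_000, score=100)]
        out = constituent_enhancers(self._se(), peaks)
        assert [p.name for p in out] == ["e1", "e2"]
        assert out[0].score == 100

    def test_no_overlap_empty(self):
        assert constituent_enhancers(self._se(0, 1_000), [iv(5_000, 6_000, score=1)]) == []

    def test_non_super_rejected(self):
        with pytest.raises(ValueError):
            constituent_enhancers(EnhancerRegion(iv(0, 10), enh_class="typical"), [])

    def test_matches_bruteforce_overlap_sort(self, rng):
        ses = [self._se(int(s), int(s) + 40_000) for s in rng.integers(0, 1_000_000, 5)]
        peaks = [
            iv(int(p), int(p) + int(w), score=float(sc))
            for p, w, sc in zip(
                rng.integers(0, 1_040_000, 50),
                rng.integers(200, 2_000, 50),
                rng.integers(1, 200, 50),
            )
        ]
        for se in ses:
            got = constituent_enhancers(se, peaks)
            expect = sorted(
                (p for p in peaks if p.start < se.interval.end and se.interval.start < p.end),
                key=lambda p: (-p.score, -(p.end - p.start), p.start),
            )
            assert [(p.start, p.end) for p in got] == [(p.start, p.end) for p in expect]
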