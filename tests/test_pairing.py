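"""Subtype-specific SE merging and strand-aware upstream gene pairing."""

import numpy as np
import pytest

from sescope.expression import DEResult
from sescope.intervals import GenomicInterval, TSS, reciprocal_overlap
from sescope.pairing import (
    SELocus,
    merge_se_loci,
    pair_se_genes,
    subtype_specific_ses,
    upstream_gap,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def de(gene_id, up=True):
    return DEResult(gene_id=gene_id, log2fc=1.0 if up else 0.0, statistic=3.0,
                    p_value=0.001, adj_p=0.01 if up else 0.9, upregulated=up)


def locus(start, end, se_id="SE1"):
    return SELocus(se_id=se_id, interval=iv(start, end), supporting_tracks=())


class TestUpstreamGap:
    def test_plus_strand_38kb_toy(self):
        """The SE at [952 kb, 962 kb) sits 38 kb upstream of a + gene at 1 Mb."""
        gap = upstream_gap(iv(952_000, 962_000), TSS("g", "chr1", 1_000_000, "+"))
        assert gap == 38_000

    def test_tss_inside_se_distance_zero(self):
        assert upstream_gap(iv(900, 2_000), TSS("g", "chr1", 1_000, "+")) == 0

    def test_downstream_se_excluded(self):
        assert upstream_gap(iv(1_100_000, 1_110_000), TSS("g", "chr1", 1_000_000, "+")) is None
        assert upstream_gap(iv(0, 10_000), TSS("g", "chr1", 50_000, "-")) is None

    def test_minus_strand_upstream_is_higher_coords(self):
        assert upstream_gap(iv(60_000, 70_000), TSS("g", "chr1", 50_000, "-")) == 10_000


class TestPairing:
    def test_toy_geometries(self):
        tss = [TSS("TCOF1_like", "chr1", 1_000_000, "+")]
        des = [de("TCOF1_like")]
        paired = pair_se_genes([locus(952_000, 962_000)], tss, des)
        assert [(p.se_id, p.gene_id, p.distance) for p in paired] == [
            ("SE1", "TCOF1_like", 38_000)
        ]
        # 600 kb upstream: outside the window
        assert pair_se_genes([locus(390_000, 400_000)], tss, des) == []
        # strictly downstream: excluded regardless of distance
        assert pair_se_genes([locus(1_010_000, 1_020_000)], tss, des) == []

    def test_not_upregulated_not_paired(self):
        tss = [TSS("g", "chr1", 1_000_000, "+")]
        assert pair_se_genes([locus(952_000, 962_000)], tss, [de("g", up=False)]) == []

    def test_matches_quadratic_bruteforce(self, rng):
        ses = [
            locus(int(s), int(s) + int(w), se_id=f"SE{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 3_000_000, 30), rng.integers(5_000, 60_000, 30))
            )
        ]
        tss = [
            TSS(f"g{i}", "chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for i, p in enumerate(rng.integers(0, 3_100_000, 60))
        ]
        des = [de(f"g{i}", up=bool(rng.random() < 0.5)) for i in range(60)]
        got = {(p.se_id, p.gene_id) for p in pair_se_genes(ses, tss, des)}
        up = {d.gene_id for d in des if d.upregulated}
        expected = set()
        for se in ses:
            for t in tss:
                if t.gene_id not in up:
                    continue
                s, e = se.interval.start, se.interval.end
                if s <= t.pos < e:
                    d = 0
                elif t.strand == "+" and e <= t.pos:
                    d = t.pos - e
                elif t.strand == "-" and s > t.pos:
                    d = s - t.pos
                else:
                    continue
                if d <= 500_000:
                    expected.add((se.se_id, t.gene_id))
        assert got == expected


class TestSubtypeSpecific:
    def test_present_in_all_tnbc_absent_elsewhere(self):
        calls = {
            "T1": [iv(100_000, 150_000)],
            "T2": [iv(101_000, 151_000)],
            "T3": [iv(99_000, 149_000)],
            "N1": [], "N2": [], "N3": [],
        }
        labels = {"T1": "TNBC", "T2": "TNBC", "T3": "TNBC",
                  "N1": "nonTNBC", "N2": "nonTNBC", "N3": "nonTNBC"}
        specific = subtype_specific_ses(calls, labels)
        assert len(specific) == 1
        assert specific[0].interval.start == 99_000

    def test_one_track_each_subtype_not_specific(self):
        calls = {"T1": [iv(0, 50_000)], "N1": [iv(0, 50_000)]}
        labels = {"T1": "TNBC", "N1": "nonTNBC"}
        assert subtype_specific_ses(calls, labels) == []

    def test_unlabelled_track_rejected(self):
        with pytest.raises(ValueError):
            subtype_specific_ses({"T1": []}, {})

    def test_matches_bruteforce_merge_and_count(self, rng):
        labels = {f"T{i}": "TNBC" for i in range(3)} | {f"N{i}": "nonTNBC" for i in range(3)}
        calls = {}
        for track in labels:
            n = int(rng.integers(0, 6))
            calls[track] = [
                iv(int(s) * 1_000, int(s) * 1_000 + int(w) * 1_000)
                for s, w in zip(rng.integers(0, 300, n), rng.integers(20, 60, n))
            ]
        got = {(l.interval.start, l.interval.end) for l in subtype_specific_ses(calls, labels)}

        # brute force: union-find over all SEs with >= 50% reciprocal overlap
        members = [(t, s) for t, ses in calls.items() for s in ses]
        n = len(members)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                if i != j and reciprocal_overlap(members[i][1], members[j][1]) >= 0.5:
                    parent[find(j)] = find(i)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        expected = set()
        for idxs in groups.values():
            tracks = {members[i][0] for i in idxs}
            n_t = sum(1 for t in tracks if labels[t] == "TNBC")
            n_o = len(tracks) - n_t
            if n_t >= 2 and n_o == 0:
                span = (
                    min(members[i][1].start for i in idxs),
                    max(members[i][1].end for i in idxs),
                )
                expected.add(span)
        assert got == expected

    def test_merge_labels_in_genomic_order(self):
        calls = {"T1": [iv(500_000, 550_000), iv(100, 50_100)], "T2": [iv(500_000, 550_000), iv(100, 50_100)]}
        loci = merge_se_loci(calls)
        assert [l.se_id for l in loci] == ["SE1", "SE2"]
        assert loci[0].interval.start == 100
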