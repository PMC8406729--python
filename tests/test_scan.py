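"""Sliding-window ROH scan: run index, classing, screening, aggregation."""

import numpy as np
import pytest

from rohscan.data import MISSING, GenotypeMatrix, ScanParams, SNPMap
from rohscan.scan import (CandidateWindow, aggregate_windows,
                          build_run_index, class_window, drop_nested,
                          scan_genome, screen_classes)


def make_gm(vals, chroms=None):
    vals = np.asarray(vals, dtype=np.int8)
    m = vals.shape[1]
    chroms = np.array(chroms if chroms is not None else [1] * m)
    smap = SNPMap(np.array([f"s{i}" for i in range(m)], dtype=object),
                  chroms, np.arange(1, m + 1) * 1000)
    ids = np.array([f"a{i}" for i in range(vals.shape[0])], dtype=object)
    return GenotypeMatrix(vals, ids, smap)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_carriers(gm, start, end):
    """Animals fully homozygous with no missing call over [start, end)."""
    block = gm.values[:, start:end]
    return np.flatnonzero(np.all((block == 0) | (block == 2), axis=1))


def brute_partition(gm, start, end, min_freq):
    groups = {}
    for a in brute_carriers(gm, start, end):
        groups.setdefault(gm.values[a, start:end].tobytes(), []).append(a)
    return {s: m for s, m in groups.items()
            if len(m) > min_freq * gm.n_animals}


def brute_scan(gm, phenotype, cutoff, direction, params):
    """Exhaustive scan with its own aggregation (union-find) and nesting."""
    bounds = gm.snp_map.chrom_bounds()
    all_cands = []
    for size in params.window_sizes:
        raw = []
        for chrom, (lo, hi) in bounds.items():
            if hi - lo < size:
                continue
            for start in range(lo, hi - size + 1):
                part = brute_partition(gm, start, start + size,
                                       params.min_class_frequency)
                kept = {}
                for s, mem in part.items():
                    vals = phenotype[mem]
                    vals = vals[~np.isnan(vals)]
                    if len(vals) == 0:
                        continue
                    mu = vals.mean()
                    if (mu < cutoff) if direction == "lower" else (mu > cutoff):
                        kept[s] = mem
                if kept:
                    raw.append((chrom, start, start + size,
                                frozenset(frozenset(m) for m in
                                          kept.values())))
        # union-find over "adjacent start and identical partition"
        parent = list(range(len(raw)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, (c1, s1, e1, k1) in enumerate(raw):
            for j, (c2, s2, e2, k2) in enumerate(raw):
                if c1 == c2 and s2 == s1 + 1 and k1 == k2:
                    parent[find(j)] = find(i)
        merged = {}
        for i, (c, s, e, k) in enumerate(raw):
            r = find(i)
            if r not in merged:
                merged[r] = [c, s, e, k]
            else:
                merged[r][1] = min(merged[r][1], s)
                merged[r][2] = max(merged[r][2], e)
        all_cands.extend((c, s, e, size, k)
                         for c, s, e, k in merged.values())
    # quadratic nesting discard
    out = []
    for i, (c1, s1, e1, z1, k1) in enumerate(all_cands):
        nested = False
        for j, (c2, s2, e2, z2, k2) in enumerate(all_cands):
            if i == j or c1 != c2 or k1 != k2:
                continue
            if s2 <= s1 and e1 <= e2:
                if (s1, e1) == (s2, e2):
                    if (z2, -j) > (z1, -i):
                        nested = True
                else:
                    nested = True
        if not nested:
            out.append((c1, s1, e1, z1, k1))
    return set(out)


def cand_key(c: CandidateWindow):
    return (c.chrom, c.start, c.end, c.orig_size, c.partition_key())


# ---------------------------------------------------------------------------
# run index
# ---------------------------------------------------------------------------

class TestRunIndex:
    def test_minimum_run_length(self):
        row = [0] * 16 + [1] + [2] * 14
        gm = make_gm([row])
        ri = build_run_index(gm, 15)
        anim, starts, ends = ri.runs[1]
        assert list(zip(starts, ends)) == [(0, 16)]

    def test_short_run_discarded(self):
        row = [1] + [0] * 14 + [1]
        ri = build_run_index(make_gm([row]), 15)
        assert len(ri.runs[1][0]) == 0

    def test_missing_breaks_run(self):
        row = [0] * 10 + [MISSING] + [0] * 10
        ri = build_run_index(make_gm([row]), 15)
        assert len(ri.runs[1][0]) == 0  # both halves below 15

    def test_containment_matches_naive(self):
        rng = np.random.default_rng(42)
        vals = rng.choice([0, 1, 2], size=(40, 120), p=[0.45, 0.1, 0.45])
        vals[rng.random(vals.shape) < 0.01] = MISSING
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        for size in (15, 20, 33):
            cov = ri.coverage(1, size)
            for start in range(0, 120 - size + 1, 3):
                naive = np.zeros(40, dtype=bool)
                naive[brute_carriers(gm, start, start + size)] = True
                assert np.array_equal(cov[:, start], naive)


# ---------------------------------------------------------------------------
# classing and screening
# ---------------------------------------------------------------------------

class TestClassWindow:
    def test_shared_string_above_frequency(self):
        rng = np.random.default_rng(0)
        n, w = 200, 20
        vals = np.ones((n, w), dtype=np.int8)  # het everywhere
        s1 = np.array([0, 2] * 10, dtype=np.int8)
        s2 = np.array([2, 0] * 10, dtype=np.int8)
        vals[:3] = s1          # 1.5% > 0.75%
        vals[3] = s2           # 0.5% -> non-ROH
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        cw = class_window(gm, ri, 1, 0, w, 0.0075)
        assert len(cw.classes) == 1
        (members,) = cw.classes.values()
        assert set(members) == {0, 1, 2}
        assert 3 in cw.non_roh

    def test_all_het_window(self):
        vals = np.ones((10, 20), dtype=np.int8)
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        cw = class_window(gm, ri, 1, 0, 20, 0.0075)
        assert not cw.classes and len(cw.non_roh) == 10

    def test_zero_size_window_rejected(self):
        gm = make_gm(np.zeros((3, 20), dtype=np.int8))
        ri = build_run_index(gm, 15)
        with pytest.raises(ValueError):
            class_window(gm, ri, 1, 5, 5, 0.0075)

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(9)
        vals = rng.choice([0, 1, 2], size=(120, 80), p=[0.48, 0.04, 0.48])
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        for start in (0, 17, 40):
            cw = class_window(gm, ri, 1, start, start + 20, 0.01)
            brute = brute_partition(gm, start, start + 20, 0.01)
            assert {s: set(m) for s, m in cw.classes.items()} == \
                   {s: set(m) for s, m in brute.items()}

    def test_lower_frequency_never_removes_classes(self):
        rng = np.random.default_rng(10)
        vals = rng.choice([0, 1, 2], size=(150, 40), p=[0.48, 0.04, 0.48])
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        hi = class_window(gm, ri, 1, 0, 20, 0.02)
        lo = class_window(gm, ri, 1, 0, 20, 0.005)
        assert set(hi.classes) <= set(lo.classes)


class TestScreening:
    def make_classing(self, mean_val):
        vals = np.ones((100, 20), dtype=np.int8)
        vals[:5] = 0
        gm = make_gm(vals)
        ri = build_run_index(gm, 15)
        cw = class_window(gm, ri, 1, 0, 20, 0.0075)
        pheno = np.full(100, 10_000.0)
        pheno[:5] = mean_val
        return cw, pheno

    def test_lower_direction_kept_and_boundary(self):
        cw, pheno = self.make_classing(8_500.0)
        assert screen_classes(cw, pheno, 8_800.0, "lower") is not None
        # carrier mean equal to the cut-off is dropped (strict inequality)
        assert screen_classes(cw, pheno, 8_500.0, "lower") is None

    def test_higher_direction(self):
        cw, pheno = self.make_classing(25.0)
        assert screen_classes(cw, pheno, 22.0, "higher") is not None
        assert screen_classes(cw, pheno, 30.0, "higher") is None

    def test_all_carriers_missing_phenotype_skipped(self):
        cw, pheno = self.make_classing(0.0)
        pheno[:5] = np.nan
        assert screen_classes(cw, pheno, 1e9, "lower") is None


# ---------------------------------------------------------------------------
# aggregation and nesting
# ---------------------------------------------------------------------------

def mk_cand(chrom, start, size, classes):
    classes = {s: np.array(m) for s, m in classes.items()}
    return CandidateWindow(chrom, start, start + size, size, classes,
                           {s: 0.0 for s in classes}, np.array([]))


class TestAggregation:
    def test_adjacent_identical_merged(self):
        c1 = mk_cand(1, 10, 50, {b"x": [1, 2, 3]})
        c2 = mk_cand(1, 11, 50, {b"y": [1, 2, 3]})
        merged = aggregate_windows([c1, c2])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (10, 61)

    def test_differing_carrier_not_merged(self):
        c1 = mk_cand(1, 10, 50, {b"x": [1, 2, 3]})
        c2 = mk_cand(1, 11, 50, {b"y": [1, 2, 4]})
        assert len(aggregate_windows([c1, c2])) == 2

    def test_random_chains_match_union_find(self):
        rng = np.random.default_rng(3)
        carriers = [rng.choice(50, size=5, replace=False).tolist()
                    for _ in range(4)]
        cands = []
        for start in range(30):
            if rng.random() < 0.6:
                k = rng.integers(0, 4)
                cands.append(mk_cand(1, start, 20,
                                     {b"s": carriers[k]}))
        merged = aggregate_windows(cands)
        # brute force: walk sorted starts, break chain when partition changes
        expected = []
        chain = None
        for c in sorted(cands, key=lambda c: c.start):
            key = c.partition_key()
            if chain and c.start == chain[1] + 1 and key == chain[3]:
                chain[1], chain[2] = c.start, c.end
            else:
                if chain:
                    expected.append(tuple(chain[:1] + [chain[4], chain[2]]))
                chain = [c.chrom, c.start, c.end, key, c.start]
        if chain:
            expected.append(tuple(chain[:1] + [chain[4], chain[2]]))
        got = [(c.chrom, c.start, c.end) for c in merged]
        assert sorted(got) == sorted(expected)


class TestDropNested:
    def test_nested_identical_discarded(self):
        inner = mk_cand(1, 100, 50, {b"x": [1, 2]})
        outer = mk_cand(1, 90, 70, {b"y": [1, 2]})
        kept = drop_nested([inner, outer])
        assert kept == [outer]

    def test_disjoint_kept(self):
        a = mk_cand(1, 0, 50, {b"x": [1, 2]})
        b = mk_cand(1, 100, 50, {b"y": [1, 2]})
        assert len(drop_nested([a, b])) == 2

    def test_identical_interval_keeps_larger_window_record(self):
        a = mk_cand(1, 0, 55, {b"x": [1, 2]})
        b = mk_cand(1, 0, 55, {b"y": [1, 2]})
        b.orig_size = 50
        kept = drop_nested([a, b])
        assert kept == [a]

    def test_random_nests_match_quadratic(self):
        rng = np.random.default_rng(8)
        carriers = [frozenset(rng.choice(40, 4, replace=False).tolist())
                    for _ in range(3)]
        cands = []
        for _ in range(25):
            s = int(rng.integers(0, 50))
            e = s + int(rng.integers(10, 40))
            k = int(rng.integers(0, 3))
            cands.append(mk_cand(1, s, e - s, {b"s": sorted(carriers[k])}))
        kept = drop_nested(cands)
        # quadratic reference
        ref = []
        for i, ci in enumerate(cands):
            ki = ci.partition_key()
            drop = False
            for j, cj in enumerate(cands):
                if i == j or cj.partition_key() != ki:
                    continue
                if cj.start <= ci.start and ci.end <= cj.end:
                    if (ci.start, ci.end) == (cj.start, cj.end):
                        if (cj.orig_size, -j) > (ci.orig_size, -i):
                            drop = True
                    else:
                        drop = True
            if not drop:
                ref.append(ci)
        assert [cand_key(c) for c in kept] == [cand_key(c) for c in ref]


class TestScanGenome:
    def test_planted_class_recovered_and_matches_brute_force(self):
        rng = np.random.default_rng(21)
        n, m = 100, 160
        vals = rng.choice([0, 1, 2], size=(n, m), p=[0.45, 0.1, 0.45])
        string = rng.choice([0, 2], size=60)
        carriers = rng.choice(n, size=5, replace=False)
        vals[np.ix_(carriers, np.arange(40, 100))] = string
        gm = make_gm(vals)
        params = ScanParams(initial_window=60, min_window=50)
        ri = build_run_index(gm, params.min_run)
        pheno = rng.normal(100.0, 10.0, size=n)
        pheno[carriers] -= 30.0
        cutoff = 95.0
        cands = drop_nested(scan_genome(gm, ri, pheno, cutoff, "lower",
                                        params))
        assert any(c.start < 100 and 40 < c.end for c in cands)
        brute = brute_scan(gm, pheno, cutoff, "lower", params)
        assert {cand_key(c) for c in cands} == brute

    def test_no_runs_gives_empty(self):
        vals = np.ones((20, 120), dtype=np.int8)
        gm = make_gm(vals)
        params = ScanParams()
        ri = build_run_index(gm, params.min_run)
        assert scan_genome(gm, ri, np.zeros(20), 1.0, "lower", params) == []

    def test_rare_class_not_reported(self):
        rng = np.random.default_rng(22)
        n, m = 300, 120
        vals = np.ones((n, m), dtype=np.int8)
        vals[0, :] = 0  # single carrier: 0.33% < 0.75%
        gm = make_gm(vals)
        params = ScanParams()
        ri = build_run_index(gm, params.min_run)
        pheno = np.zeros(n)
        assert scan_genome(gm, ri, pheno, 1.0, "lower", params) == []
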