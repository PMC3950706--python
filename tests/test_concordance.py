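"""Merged regions, fold-tolerance Venn partitioning, summit calling."""

import numpy as np
import pytest

from chipconcord import (
    Interval,
    MergedRegion,
    Peak,
    Tag,
    ValidationError,
    compute_summit,
    coverage,
    fold_membership,
    merge_peak_sets,
    region_counts,
    summit_windows,
    venn_partition,
)


def mkpeak(chrom, start, end, dataset=""):
    return Peak(Interval(chrom, start, end), 0.0, 0.0, dataset_id=dataset)


def union_components_oracle(peak_sets, space=5000):
    """Per-base boolean-array connected components over all intervals."""
    occupied = {}
    for peaks in peak_sets.values():
        for p in peaks:
            arr = occupied.setdefault(p.interval.chrom, np.zeros(space, dtype=bool))
            arr[p.interval.start : p.interval.end] = True
    regions = []
    for chrom in sorted(occupied):
        arr = occupied[chrom]
        diff = np.diff(arr.astype(int), prepend=0, append=0)
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            regions.append((chrom, int(s), int(e)))
    return regions


class TestMergePeakSets:
    def test_identical_peaks_merge_to_one_region(self):
        sets = {d: [mkpeak("chr1", 100, 200)] for d in ("d1", "d2", "d3")}
        (region,) = merge_peak_sets(sets)
        assert (region.interval.start, region.interval.end) == (100, 200)
        assert region.contributing_datasets == {"d1", "d2", "d3"}

    def test_disjoint_peaks_stay_separate(self):
        sets = {"d1": [mkpeak("chr1", 100, 200)], "d2": [mkpeak("chr1", 300, 400)]}
        regions = merge_peak_sets(sets)
        assert len(regions) == 2
        assert [r.contributing_datasets for r in regions] == [{"d1"}, {"d2"}]

    def test_book_ended_intervals_merge(self):
        # consistent with per-base union connected components
        sets = {"d1": [mkpeak("chr1", 100, 200)], "d2": [mkpeak("chr1", 200, 300)]}
        (region,) = merge_peak_sets(sets)
        assert (region.interval.start, region.interval.end) == (100, 300)
        assert region.contributing_datasets == {"d1", "d2"}

    def test_empty_input_empty_output(self):
        assert merge_peak_sets({}) == []
        assert merge_peak_sets({"d1": []}) == []

    def test_matches_per_base_union_oracle(self, rng):
        sets = {}
        for d in ("d1", "d2", "d3"):
            peaks = []
            for _ in range(100):
                s = int(rng.integers(0, 4800))
                peaks.append(mkpeak(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 150)), d))
            sets[d] = peaks
        regions = merge_peak_sets(sets)
        got = [(r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        assert sorted(got) == union_components_oracle(sets)

    def test_permutation_invariant_and_idempotent(self, rng):
        sets = {
            "a": [mkpeak("chr1", 10, 60), mkpeak("chr1", 50, 120)],
            "b": [mkpeak("chr1", 100, 180)],
        }
        fwd = merge_peak_sets(sets)
        rev = merge_peak_sets(dict(reversed(list(sets.items()))))
        assert [(r.interval, r.contributing_datasets) for r in fwd] == [
            (r.interval, r.contributing_datasets) for r in rev
        ]
        again = merge_peak_sets(
            {
                d: [mkpeak(r.interval.chrom, r.interval.start, r.interval.end, d)]
                for d in ("x",)
                for r in fwd
            }
        )
        assert [r.interval for r in again] == [r.interval for r in fwd]


class TestRegionCounts:
    def region(self, start=1000, end=1400):
        return MergedRegion(Interval("chr1", start, end), frozenset({"d1"}))

    def test_library_scaling(self):
        tags = {"d1": [Tag("chr1", 1000 + i, "+") for i in range(10)]}
        (r,) = region_counts([self.region()], tags, {"d1": 20_000_000})
        assert r.counts["d1"] == pytest.approx(10.0)
        (r,) = region_counts([self.region()], tags, {"d1": 10_000_000})
        assert r.counts["d1"] == pytest.approx(20.0)

    def test_matches_brute_force_composition(self, rng):
        tags = {
            d: [Tag("chr1", int(rng.integers(0, 3000)), "+") for _ in range(300)]
            for d in ("d1", "d2")
        }
        sizes = {"d1": 5_000_000, "d2": 40_000_000}
        regions = [
            MergedRegion(Interval("chr1", s, s + 200), frozenset({"d1", "d2"}))
            for s in (0, 500, 1500, 2500)
        ]
        region_counts(regions, tags, sizes)
        for r in regions:
            for d in ("d1", "d2"):
                raw = sum(
                    1 for t in tags[d] if r.interval.start <= t.five_prime < r.interval.end
                )
                assert r.counts[d] == pytest.approx(raw * 20e6 / sizes[d])

    def test_missing_tag_set_is_configuration_error(self):
        from chipconcord.model import ConfigurationError

        with pytest.raises(ConfigurationError):
            region_counts([self.region()], {}, {})


class TestFoldMembership:
    def region_with_counts(self, counts, contributors=("d2",)):
        r = MergedRegion(Interval("chr1", 0, 100), frozenset(contributors))
        r.counts = dict(counts)
        return r

    def test_threshold_against_maximum(self):
        r = self.region_with_counts({"d1": 100.0, "d2": 60.0, "d3": 30.0})
        assert fold_membership(r, 2) == {"d1", "d2"}
        assert fold_membership(r, 4) == {"d1", "d2", "d3"}

    def test_zero_counts_fall_back_to_contributors(self):
        r = self.region_with_counts({"d1": 0.0, "d2": 0.0}, contributors=("d2",))
        assert fold_membership(r, 2) == {"d2"}

    def test_k_below_one_rejected(self):
        r = self.region_with_counts({"d1": 1.0})
        with pytest.raises(ValidationError):
            fold_membership(r, 0.5)

    def test_monotone_in_k(self, rng):
        for _ in range(100):
            counts = {f"d{i}": float(rng.uniform(0, 50)) for i in range(4)}
            r = self.region_with_counts(counts)
            previous = None
            for k in (1, 1.5, 2, 3, 4, 8, 16):
                members = fold_membership(r, k)
                if previous is not None:
                    assert previous <= members
                previous = members


class TestVennPartition:
    def test_single_cell(self):
        regions = [
            MergedRegion(Interval("chr1", i * 200, i * 200 + 100), frozenset({"d1"}))
            for i in range(3)
        ]
        for r in regions:
            r.membership[2] = frozenset({"d1", "d2", "d3"})
        vp = venn_partition(regions, 2)
        assert vp.cells == {frozenset({"d1", "d2", "d3"}): 3}

    def test_distinct_cells(self):
        memberships = [{"d1"}, {"d1", "d2"}, {"d1", "d2", "d3"}]
        regions = []
        for i, m in enumerate(memberships):
            r = MergedRegion(Interval("chr1", i * 200, i * 200 + 100), frozenset({"d1"}))
            r.membership[3] = frozenset(m)
            regions.append(r)
        vp = venn_partition(regions, 3)
        assert all(vp.cell(m) == 1 for m in memberships)

    def test_tally_oracle_and_conservation(self, rng):
        labels = ("d1", "d2", "d3")
        regions = []
        for i in range(500):
            r = MergedRegion(Interval("chr1", i * 10, i * 10 + 5), frozenset({"d1"}))
            r.counts = {d: float(rng.uniform(0, 100)) for d in labels}
            regions.append(r)
        for k in (2, 3, 4):
            vp = venn_partition(regions, k)
            assert vp.total() == len(regions)
            tally = {}
            for r in regions:
                m = max(r.counts.values())
                cell = frozenset(d for d, c in r.counts.items() if c >= m / k)
                tally[cell] = tally.get(cell, 0) + 1
            assert vp.cells == tally


class TestComputeSummit:
    def test_single_tag_plateau_midpoint(self):
        region = Interval("chr1", 900, 1300)
        s = compute_summit(region, [Tag("chr1", 1000, "+")], 200)
        assert (s.plateau.start, s.plateau.end) == (1000, 1200)
        assert s.position == 1099 and s.height == 1 and not s.flagged

    def test_two_tag_overlap(self):
        s = compute_summit(
            Interval("chr1", 900, 1400),
            [Tag("chr1", 1000, "+"), Tag("chr1", 1100, "+")],
            200,
        )
        assert (s.plateau.start, s.plateau.end) == (1100, 1200)
        assert s.position == 1149 and s.height == 2

    def test_zero_coverage_flagged_at_midpoint(self):
        s = compute_summit(Interval("chr1", 100, 201), [], 200)
        assert s.flagged and s.height == 0 and s.position == 150

    def test_matches_per_base_pileup_oracle(self, rng):
        region = Interval("chr1", 500, 2500)
        tags = [
            Tag("chr1", int(rng.integers(400, 2600)), "+" if rng.random() < 0.5 else "-")
            for _ in range(300)
        ]
        s = compute_summit(region, tags, 200)
        pileup = coverage(tags, region, 200)
        assert s.height == pileup.max()
        assert pileup[s.position - region.start] == pileup.max()


class TestSummitWindows:
    def test_standard_window(self):
        s = compute_summit(Interval("chr1", 900, 1300), [Tag("chr1", 1000, "+")], 200)
        (w,) = summit_windows([s], 150)
        assert (w.start, w.end) == (949, 1250) and len(w) == 301

    def test_clipped_at_chromosome_start(self):
        s = compute_summit(Interval("chr1", 50, 300), [Tag("chr1", 100, "+")], 100)
        (w,) = summit_windows([s], 150)
        assert w.start == 0

    def test_interior_windows_have_length_301(self, rng):
        summits = []
        for _ in range(20):
            pos = int(rng.integers(1000, 50_000))
            summits.append(
                compute_summit(
                    Interval("chr1", pos - 100, pos + 100), [Tag("chr1", pos, "+")], 50
                )
            )
        for w in summit_windows(summits, 150):
            assert len(w) == 301
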