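"""Median reference, relative segments, clonal masking and quantification."""

import numpy as np
import pytest

from ectoseed.cna import (
    BinGrid,
    ClonalEvent,
    ClonalEventSet,
    CNASegment,
    CopyNumberProfile,
    build_median_reference,
    call_relative_segments,
    chisq_rate_comparison,
    flag_widespread_aneuploidy,
    identify_clonal_events,
    mask_clonal,
    pileup,
    stratify_and_quantify,
)

BIN = 500_000
LENGTHS = {"c1": 20 * BIN, "c2": 10 * BIN}


@pytest.fixture
def grid():
    return BinGrid.from_chrom_lengths(LENGTHS, BIN)


def _profile(grid, states, cell_id="cell", condition="ctrl"):
    return CopyNumberProfile(cell_id, condition, grid,
                             np.asarray(states, dtype=np.int64))


def _seg(cell, chrom, b0, b1, delta):
    """Segment over bins [b0, b1) of a 500-kb grid."""
    return CNASegment(cell, chrom, b0 * BIN, b1 * BIN, delta)


class TestMedianReference:
    def test_constant_states(self, grid):
        profs = [_profile(grid, [3] * grid.n_bins, f"c{i}") for i in range(3)]
        ref = build_median_reference(profs)
        assert (ref.median_state == 3).all()

    def test_even_count_takes_lower_median(self, grid):
        profs = [
            _profile(grid, [2] * grid.n_bins, "a"),
            _profile(grid, [3] * grid.n_bins, "b"),
        ]
        ref = build_median_reference(profs)
        assert (ref.median_state == 2).all()

    def test_matches_sort_oracle(self, grid):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 6, size=(7, grid.n_bins))
        profs = [_profile(grid, mat[i], f"c{i}") for i in range(7)]
        ref = build_median_reference(profs)
        for b in range(grid.n_bins):
            assert ref.median_state[b] == sorted(mat[:, b])[(7 - 1) // 2]

    def test_grid_mismatch_errors(self, grid):
        other = BinGrid.from_chrom_lengths({"c1": 5 * BIN}, BIN)
        with pytest.raises(ValueError):
            build_median_reference(
                [_profile(grid, [2] * grid.n_bins), _profile(other, [2] * other.n_bins)]
            )


class TestRelativeSegments:
    def test_identical_profile_yields_nothing(self, grid):
        ref = build_median_reference([_profile(grid, [3] * grid.n_bins)])
        assert call_relative_segments(_profile(grid, [3] * grid.n_bins), ref) == []

    def test_single_gain_run(self, grid):
        ref = build_median_reference([_profile(grid, [3] * grid.n_bins)])
        states = [3] * grid.n_bins
        for b in range(10, 20):
            states[b] = 4
        segs = call_relative_segments(_profile(grid, states, "x"), ref)
        assert segs == [_seg("x", "c1", 10, 20, 1)]

    def test_chromosome_boundary_breaks_runs(self, grid):
        ref = build_median_reference([_profile(grid, [2] * grid.n_bins)])
        states = [3] * grid.n_bins  # +1 everywhere
        segs = call_relative_segments(_profile(grid, states, "x"), ref)
        assert [(s.chrom, s.start, s.end) for s in segs] == [
            ("c1", 0, LENGTHS["c1"]),
            ("c2", 0, LENGTHS["c2"]),
        ]

    def test_matches_run_length_oracle_and_round_trips(self, grid):
        rng = np.random.default_rng(4)
        ref_states = rng.integers(1, 5, size=grid.n_bins)
        ref = build_median_reference([_profile(grid, ref_states)])
        states = ref_states + rng.choice([-1, 0, 0, 1, 2], size=grid.n_bins)
        states = np.clip(states, 0, None)
        segs = call_relative_segments(_profile(grid, states, "x"), ref)
        # oracle: per-bin delta rebuilt from segments must reproduce states
        rebuilt = ref.median_state.copy()
        slices = grid.chrom_slices()
        for s in segs:
            sl = slices[s.chrom]
            for b in range(sl.start, sl.stop):
                if grid.starts[b] >= s.start and grid.ends[b] <= s.end:
                    rebuilt[b] += s.delta
        assert (rebuilt == states).all()
        # maximality: flanking bins differ in delta
        delta = states - ref.median_state
        for s in segs:
            sl = slices[s.chrom]
            first = next(b for b in range(sl.start, sl.stop)
                         if grid.starts[b] == s.start)
            last = next(b for b in range(sl.start, sl.stop)
                        if grid.ends[b] == s.end)
            if first > sl.start:
                assert delta[first - 1] != delta[first]
            if last < sl.stop - 1:
                assert delta[last + 1] != delta[last]


class TestWidespreadAneuploidy:
    def test_identical_profile_not_flagged(self, grid):
        ref = build_median_reference([_profile(grid, [3] * grid.n_bins)])
        assert not flag_widespread_aneuploidy(_profile(grid, [3] * grid.n_bins), ref)

    def test_fully_altered_flagged(self, grid):
        ref = build_median_reference([_profile(grid, [3] * grid.n_bins)])
        assert flag_widespread_aneuploidy(_profile(grid, [4] * grid.n_bins), ref)

    def test_exactly_half_is_not_flagged(self, grid):
        ref = build_median_reference([_profile(grid, [3] * grid.n_bins)])
        states = [4] * (grid.n_bins // 2) + [3] * (grid.n_bins - grid.n_bins // 2)
        assert not flag_widespread_aneuploidy(
            _profile(grid, states), ref, max_altered_fraction=0.5
        )


class TestClonalEvents:
    def test_four_cells_make_an_event_three_do_not(self):
        segs3 = [_seg(f"c{i}", "c1", 2, 10, 1) for i in range(3)]
        assert len(identify_clonal_events(segs3, min_cells=4)) == 0
        segs4 = segs3 + [_seg("c3", "c1", 2, 10, 1)]
        events = identify_clonal_events(segs4, min_cells=4)
        assert len(events) == 1
        assert events.events[0].n_cells == 4

    def test_49_percent_reciprocal_overlap_not_grouped(self):
        # 100-bin segments shifted by 51 bins: reciprocal overlap 49%
        a = [_seg(f"a{i}", "c1", 0, 100, 1) for i in range(4)]
        b = [_seg(f"b{i}", "c1", 51, 151, 1) for i in range(4)]
        events = identify_clonal_events(a + b, min_cells=5)
        assert len(events) == 0  # neither group alone reaches 5 cells

    def test_50_percent_reciprocal_overlap_grouped(self):
        a = [_seg(f"a{i}", "c1", 0, 100, 1) for i in range(3)]
        b = [_seg(f"b{i}", "c1", 50, 150, 1) for i in range(3)]
        events = identify_clonal_events(a + b, min_cells=5)
        assert len(events) == 1
        assert events.events[0].n_cells == 6
        assert (events.events[0].start, events.events[0].end) == (0, 150 * BIN)

    def test_opposite_signs_never_grouped(self):
        segs = [_seg(f"c{i}", "c1", 0, 10, 1) for i in range(4)] + [
            _seg(f"d{i}", "c1", 0, 10, -1) for i in range(4)
        ]
        events = identify_clonal_events(segs, min_cells=4)
        assert sorted(e.sign for e in events) == [-1, 1]

    def test_components_match_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        segs = []
        for i in range(40):
            b0 = int(rng.integers(0, 30))
            segs.append(
                _seg(f"cell{rng.integers(10)}", "c1", b0,
                     b0 + int(rng.integers(1, 12)), int(rng.choice([-1, 1])))
            )
        events = identify_clonal_events(segs, min_cells=1, min_overlap=0.5)

        def same(a, b):
            if a.chrom != b.chrom or a.sign != b.sign:
                return False
            inter = min(a.end, b.end) - max(a.start, b.start)
            return inter > 0 and inter >= 0.5 * a.size_bp and inter >= 0.5 * b.size_bp

        # brute-force transitive closure
        groups = []
        for s in segs:
            hits = [g for g in groups if any(same(s, m) for m in g)]
            merged = [s]
            for g in hits:
                merged.extend(g)
                groups.remove(g)
            groups.append(merged)
        expected = sorted(
            (min(m.start for m in g), max(m.end for m in g), g[0].sign, len(g))
            for g in groups
        )
        got = sorted((e.start, e.end, e.sign, len(e.segments)) for e in events)
        assert got == expected

    def test_raising_min_cells_shrinks_event_set(self):
        segs = [_seg(f"c{i}", "c1", 0, 10, 1) for i in range(6)]
        for k in range(1, 8):
            lo = identify_clonal_events(segs, min_cells=k)
            hi = identify_clonal_events(segs, min_cells=k + 1)
            assert len(hi) <= len(lo)


class TestMasking:
    def _event(self, b0, b1, sign=1):
        seg = _seg("ctrl", "c1", b0, b1, sign)
        return ClonalEventSet(
            [ClonalEvent("c1", b0 * BIN, b1 * BIN, sign, 4, (seg,))]
        )

    def test_identical_segment_is_removed(self):
        assert mask_clonal([_seg("t", "c1", 2, 12, 1)], self._event(2, 12)) == []

    def test_disjoint_large_segment_is_retained(self):
        seg = _seg("t", "c1", 50, 60, 1)  # 5 Mb
        assert mask_clonal([seg], self._event(2, 12)) == [seg]

    def test_opposite_sign_is_not_masked(self):
        seg = _seg("t", "c1", 2, 12, -1)
        assert mask_clonal([seg], self._event(2, 12, sign=1)) == [seg]

    def test_size_boundary_1mb_dropped_1p5mb_kept(self):
        short = _seg("t", "c1", 0, 2, 1)  # exactly 1.0 Mb
        kept = _seg("t", "c1", 0, 3, 1)  # 1.5 Mb
        out = mask_clonal([short, kept], ClonalEventSet([]))
        assert out == [kept]

    def test_overlap_boundary_50_vs_49(self):
        ev = self._event(0, 100)
        at50 = _seg("t", "c1", 50, 150, 1)
        at49 = _seg("t", "c1", 51, 151, 1)
        assert mask_clonal([at50], ev) == []
        assert mask_clonal([at49], ev) == [at49]

    def test_masking_never_creates_segments_and_is_idempotent(self):
        rng = np.random.default_rng(8)
        segs = [
            _seg(f"t{i}", "c1", int(b), int(b) + int(w), int(rng.choice([-1, 1])))
            for i, (b, w) in enumerate(zip(rng.integers(0, 15, 30),
                                           rng.integers(1, 6, 30)))
        ]
        ev = self._event(5, 9)
        out = mask_clonal(segs, ev)
        assert len(out) <= len(segs)
        assert mask_clonal(out, ClonalEventSet([])) == out

    def test_segment_mode_masks_via_supporting_segments(self):
        # event hull is wide; an individual supporting segment matches
        support = (_seg("ctrl1", "c1", 0, 10, 1), _seg("ctrl2", "c1", 90, 100, 1))
        ev = ClonalEventSet([ClonalEvent("c1", 0, 100 * BIN, 1, 4, support)])
        probe = _seg("t", "c1", 0, 10, 1)
        assert mask_clonal([probe], ev, against="segments") == []
        assert mask_clonal([probe], ev, against="events") == [probe]


class TestQuantification:
    def test_large_rate_arithmetic(self):
        segs = [_seg(f"t{i}", "c9", 0, 50, 1) for i in range(6)]  # 25 Mb each
        tables = stratify_and_quantify(segs, n_cells=30)
        row = tables["large_per_chromosome"].set_index("chrom").loc["c9"]
        assert row["count"] == 6
        assert row["rate_per_cell"] == pytest.approx(0.2)

    def test_one_bp_window_overlap_counts(self):
        seg = CNASegment("t", "c1", 0, 10_000_000, 1)  # 10 Mb, small class
        # window = locus - 0.5 Mb starts at 9,999,999: 1 bp of overlap
        tables = stratify_and_quantify(
            [seg], n_cells=10, locus=("c1", 10_499_999, 12_000_000),
            locus_window_bp=500_000,
        )
        small = tables["small_by_locus"].set_index("region")
        assert small.loc["locus_window", "count"] == 1
        assert small.loc["rest_of_genome", "count"] == 0

    def test_exact_cut_size_in_neither_class(self):
        seg = CNASegment("t", "c1", 0, 20_000_000, 1)
        tables = stratify_and_quantify(
            [seg], n_cells=5, locus=("c1", 0, 1_000_000)
        )
        assert tables["large_per_chromosome"]["count"].sum() == 0
        assert tables["small_by_locus"]["count"].sum() == 0

    def test_unknown_locus_chromosome_errors(self):
        with pytest.raises(KeyError):
            stratify_and_quantify(
                [], n_cells=1, locus=("cX", 0, 10), chromosomes=["c1"]
            )

    def test_rates_invariant_to_ordering(self):
        rng = np.random.default_rng(10)
        segs = [
            _seg(f"t{i}", "c1", int(b), int(b) + 45, int(rng.choice([-1, 1])))
            for i, b in enumerate(rng.integers(0, 10, 20))
        ]
        shuffled = list(segs)
        rng.shuffle(shuffled)
        a = stratify_and_quantify(segs, n_cells=20)["large_per_chromosome"]
        b = stratify_and_quantify(shuffled, n_cells=20)["large_per_chromosome"]
        assert a.equals(b)


class TestPileup:
    def test_single_gain_covers_its_bins(self, grid):
        seg = _seg("t", "c1", 0, 10, 1)
        df = pileup([seg], grid)
        gain = df["gain_small"].to_numpy()
        assert gain[:10].tolist() == [1] * 10
        assert gain[10:].sum() == 0

    def test_gain_and_loss_same_bin(self, grid):
        segs = [_seg("a", "c1", 0, 5, 1), _seg("b", "c1", 0, 5, -1)]
        df = pileup(segs, grid)
        assert df.loc[0, "gain_small"] == 1 and df.loc[0, "loss_small"] == 1

    def test_matches_bruteforce_counter(self, grid):
        rng = np.random.default_rng(12)
        segs = []
        for i in range(50):
            chrom = str(rng.choice(["c1", "c2"]))
            hi = 20 if chrom == "c1" else 10
            b0 = int(rng.integers(0, hi - 1))
            b1 = int(rng.integers(b0 + 1, hi + 1))
            segs.append(_seg(f"t{i}", chrom, b0, b1, int(rng.choice([-2, -1, 1, 2]))))
        df = pileup(segs, grid, size_cut_bp=3 * BIN)
        for b in range(grid.n_bins):
            for sign, cls in (("gain", "large"), ("gain", "small"),
                              ("loss", "large"), ("loss", "small")):
                expected = sum(
                    1 for s in segs
                    if s.chrom == grid.chroms[b]
                    and s.start < grid.ends[b] and grid.starts[b] < s.end
                    and (s.delta > 0) == (sign == "gain")
                    and (s.size_bp > 3 * BIN) == (cls == "large")
                )
                assert df.loc[b, f"{sign}_{cls}"] == expected


class TestChiSquared:
    def test_identical_proportions_give_zero(self):
        stat, p = chisq_rate_comparison(5, 50, 5, 50)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError):
            chisq_rate_comparison(0, 10, 0, 10)

    def test_matches_pearson_formula(self):
        stat, p = chisq_rate_comparison(8, 32, 2, 38)
        table = np.array([[8, 32], [2, 38]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(by_hand)
        assert 0 <= p <= 1
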