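"""CIRCUS schedule construction, view sharing and acceleration arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cine5d.sampling import (SamplingSchedule, circus_schedule,
                             partial_fourier_keep, psf_peak_sidelobe_ratio,
                             ring_partition, sampling_mask,
                             undersampling_factor, view_share_fill,
                             _ring_perimeter_points, _GOLDEN)


class TestRingPartition:
    def test_smallest_grid_two_rings_center_block(self):
        rings = ring_partition((4, 4))
        assert rings.max() == 1
        assert np.all(rings[1:3, 1:3] == 0)

    def test_partition_covers_every_point_once(self):
        rings = ring_partition((8, 8))
        assert rings.size == 64 and rings.min() == 0
        sizes = np.bincount(rings.ravel())
        assert sizes.sum() == 64
        assert list(sizes) == [4, 12, 20, 28]

    def test_anisotropic_grid_max_ring_matches_brute_force(self):
        rings = ring_partition((144, 30))
        # brute force: ring of a point = number of square shells between it
        # and the 2x2 DC block
        def ring_of(iy, iz):
            def g(d):
                return max(d, -1 - d)
            return max(g(iy - 72), g(iz - 15))
        brute = max(ring_of(iy, iz) for iy in (0, 143) for iz in (0, 29))
        assert rings.max() == brute == int(np.ceil(144 / 2)) - 1 == 71

    def test_rejects_degenerate_grid(self):
        with pytest.raises(ValueError):
            ring_partition((1, 8))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(ny=st.integers(2, 40), nz=st.integers(2, 40))
    def test_partition_property_any_grid(self, ny, nz):
        """Every point belongs to exactly one ring; ring ids are dense
        from 0; ring sizes are positive."""
        rings = ring_partition((ny, nz))
        assert rings.shape == (ny, nz)
        ids = np.unique(rings)
        assert ids[0] == 0 and np.array_equal(ids, np.arange(len(ids)))
        assert np.bincount(rings.ravel()).min() > 0


class TestCircusSchedule:
    def test_c_zero_degenerates_to_radial_spoke(self):
        """With no spiral twist every ring picks the same fractional
        perimeter position within one interleave."""
        s = circus_schedule((32, 32), circus_c=0.0, partial_fourier=1.0,
                            n_interleaves=1, seed=0)
        rings = ring_partition((32, 32))
        target = 0.0  # t=0, seed=0 -> u = 0 for every ring
        for ky, kz, _, r in s.entries:
            pts = _ring_perimeter_points(rings, r)
            j = int(np.where((pts[:, 0] == ky) & (pts[:, 1] == kz))[0][0])
            assert abs(j / len(pts) - target) <= 1.5 / len(pts)

    def test_full_coverage_without_partial_fourier(self):
        grid = (16, 16)
        s = circus_schedule(grid, partial_fourier=1.0, n_interleaves=60,
                            seed=0)
        rings = ring_partition(grid)
        # each ring's points are all visited before any repeats
        for r in range(rings.max() + 1):
            picks = [(ky, kz) for ky, kz, _, rr in s.entries if rr == r]
            n_ring = (rings == r).sum()
            assert len(set(picks[:n_ring])) == n_ring
        covered = {(ky, kz) for ky, kz, _, _ in s.entries}
        assert len(covered) == 256

    def test_unique_positions_within_interleave(self):
        s = circus_schedule((24, 24), n_interleaves=10, seed=3)
        for t in range(10):
            il = [(e[0], e[1]) for e in s.entries if e[2] == t]
            assert len(set(il)) == len(il)

    def test_partial_fourier_span_is_three_quarters(self):
        s = circus_schedule((64, 64), partial_fourier=0.75,
                            n_interleaves=48, seed=0)
        ky = np.array([e[0] for e in s.entries])
        kz = np.array([e[1] for e in s.entries])
        assert abs((ky.max() - ky.min() + 1) / 64 - 0.75) <= 1 / 64
        assert abs((kz.max() - kz.min() + 1) / 64 - 0.75) <= 1 / 64
        assert 32 in ky and 32 in kz   # DC retained

    def test_determinism(self):
        a = circus_schedule((40, 20), 1.5, 0.75, n_interleaves=16, seed=7)
        b = circus_schedule((40, 20), 1.5, 0.75, n_interleaves=16, seed=7)
        assert a.entries == b.entries

    def test_interleave_count_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            s = circus_schedule((8, 8), partial_fourier=1.0,
                                n_interleaves=500, seed=0)
        assert s.n_interleaves <= 28

    def test_psf_sidelobe_ratio_grows_with_interleaves(self):
        s = circus_schedule((64, 64), 1.5, partial_fourier=1.0,
                            n_interleaves=16, seed=0)
        ratios = [psf_peak_sidelobe_ratio(sampling_mask(s, m))
                  for m in (1, 2, 4, 8)]
        assert np.all(np.diff(ratios) >= 0)

    def test_variable_density_center_heavier_than_periphery(self):
        grid = (64, 64)
        s = circus_schedule(grid, n_interleaves=8, seed=0)
        rings = ring_partition(grid)
        mask = sampling_mask(s, 8)
        inner = mask[rings <= 4].mean()
        outer = mask[rings >= 20].mean()
        assert inner > 3 * outer


class TestUndersamplingFactor:
    @pytest.mark.parametrize("grid,lines,expected", [
        ((144, 30), 250, 17.28),   # protocol arithmetic: rounds to ~17
        ((8, 8), 64, 1.0),
        ((8, 8), 16, 4.0),
    ])
    def test_examples(self, grid, lines, expected):
        assert undersampling_factor(grid, lines) == pytest.approx(expected)

    def test_paper_protocol_rounds_to_seventeen(self):
        assert round(undersampling_factor((144, 30), 250)) == 17

    def test_rejects_zero_lines(self):
        with pytest.raises(ValueError):
            undersampling_factor((8, 8), 0)


class TestViewSharing:
    def test_no_sharing_when_beat_complete(self):
        beat = {(0, 0): 10, (1, 0): 11}
        all_lines = {(0, 0): (np.array([0.0]), np.array([10])),
                     (1, 0): (np.array([4.0]), np.array([11]))}
        filled, prov, unfilled = view_share_fill(beat, all_lines, 2.0)
        assert filled == beat and prov == {} and unfilled == 0

    def test_nearest_beat_wins(self):
        """A position acquired only in earlier/later beats is taken from
        the temporally nearest one."""
        beat = {}
        all_lines = {(3, 2): (np.array([100.0, 3100.0]), np.array([5, 77]))}
        filled, prov, _ = view_share_fill(beat, all_lines,
                                          beat_center_ms=1000.0)
        assert filled[(3, 2)] == 5 and prov[(3, 2)] == 5

    def test_shared_count_matches_set_difference(self):
        """Two-beat toy stream: shared lines = positions the beat missed."""
        rng = np.random.default_rng(0)
        grid = [(y, z) for y in range(6) for z in range(4)]
        beat1 = {p: i for i, p in enumerate(grid[:10])}
        all_lines = {}
        for i, p in enumerate(grid):
            t = 100.0 * i if p in beat1 else 5000.0 + 10 * i
            all_lines[p] = (np.array([t]), np.array([i]))
        filled, prov, _ = view_share_fill(beat1, all_lines, 500.0)
        expected_shared = set(grid) - set(beat1)
        assert set(prov) == expected_shared
        assert len(filled) == len(grid)
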