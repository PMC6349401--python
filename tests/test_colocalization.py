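"""Volume-overlap metric, Pearson readout, and the randomized-placement null."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import punctaloc as pl
from punctaloc.colocalization import (
    PlacementLimitError,
    background_overlap,
    mean_overlap,
    overlap_fraction,
    overlap_records,
    pearson_within_cell,
    randomize_puncta,
)
from punctaloc.stack_model import CellMask, TwoChannelStack
from tests.conftest import make_punctum

SHAPE = (6, 32, 32)


def full_mask(shape=SHAPE):
    return CellMask(layers=np.ones(shape, dtype=bool))


def brute_force_overlap(p, others):
    """Oracle: explicit voxel-set intersection."""
    mine = {tuple(v) for v in p.voxels()}
    theirs = set()
    for o in others:
        theirs |= {tuple(v) for v in o.voxels()}
    return len(mine & theirs) / len(mine)


class TestOverlapFraction:
    def test_fully_contained_is_one(self):
        inner = make_punctum(1, "red", [(1, 5, 5), (1, 5, 6)])
        outer = make_punctum(2, "green",
                             [(1, y, x) for y in range(4, 8) for x in range(4, 8)])
        rec = overlap_fraction(inner, [outer], SHAPE)
        assert rec.overlap_fraction == 1.0

    def test_disjoint_is_zero(self):
        a = make_punctum(1, "red", [(0, 1, 1)])
        b = make_punctum(2, "green", [(3, 20, 20)])
        assert overlap_fraction(a, [b], SHAPE).overlap_fraction == 0.0

    def test_partial_overlap_hand_computed(self):
        # 10 px in each of 2 layers; 5 px of the first layer overlapped
        p = make_punctum(1, "red",
                         [(1, 5, x) for x in range(10)] +
                         [(2, 5, x) for x in range(10)])
        other = make_punctum(2, "green", [(1, 5, x) for x in range(5)])
        rec = overlap_fraction(p, [other], SHAPE)
        assert rec.overlap_fraction == pytest.approx(0.25)
        assert rec.overlapped_volume == 5 and rec.total_volume == 20

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def random_punctum(pid, ch):
            n = int(rng.integers(1, 30))
            vox = np.column_stack([
                rng.integers(0, SHAPE[0], n),
                rng.integers(0, SHAPE[1], n),
                rng.integers(0, SHAPE[2], n),
            ])
            vox = np.unique(vox, axis=0)
            return make_punctum(pid, ch, vox)

        p = random_punctum(1, "red")
        others = [random_punctum(10 + i, "green") for i in range(3)]
        rec = overlap_fraction(p, others, SHAPE)
        assert rec.overlap_fraction == pytest.approx(brute_force_overlap(p, others))


class TestPearson:
    def _stack(self, g, r):
        return TwoChannelStack(green=g, red=r, pixel_size_xy=0.1, z_step=0.5)

    def test_identical_channels_r_one(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(1, 100, SHAPE)
        st = self._stack(g, g.copy())
        assert pearson_within_cell(st, full_mask()) == pytest.approx(1.0)

    def test_inverted_channel_r_minus_one(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(1, 100, SHAPE)
        st = self._stack(g, 200.0 - g)
        assert pearson_within_cell(st, full_mask()) == pytest.approx(-1.0)

    def test_constant_channel_nan_with_warning(self):
        g = np.random.default_rng(2).uniform(1, 10, SHAPE)
        st = self._stack(g, np.full(SHAPE, 5.0))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pearson_within_cell(st, full_mask()))

    @pytest.mark.parametrize("seed", range(10))
    def test_independent_channels_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        shape = (10, 40, 40)  # 16000 in-mask voxels
        st = self._stack(rng.uniform(0, 100, shape), rng.uniform(0, 100, shape))
        assert abs(pearson_within_cell(st, full_mask(shape))) < 0.05


def blocky_puncta(rng, mask, n, channel, start_id, size=2):
    """Random non-overlapping axis-aligned blocks fully inside the mask."""
    out = []
    occ = np.zeros(mask.layers.shape, dtype=bool)
    nz, ny, nx = mask.layers.shape
    pid = start_id
    while len(out) < n:
        z = int(rng.integers(0, nz))
        y = int(rng.integers(0, ny - size))
        x = int(rng.integers(0, nx - size))
        vox = [(z, yy, xx) for yy in range(y, y + size)
               for xx in range(x, x + size)]
        if any(not mask.layers[v] for v in vox) or any(occ[v] for v in vox):
            continue
        for v in vox:
            occ[v] = True
        out.append(make_punctum(pid, channel, vox))
        pid += 1
    return out


class TestRandomizePuncta:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(42)
        layers = np.zeros((6, 40, 40), dtype=bool)
        layers[:, 4:36, 4:36] = True
        mask = CellMask(layers=layers)
        puncta = blocky_puncta(rng, mask, 6, "green", 1, size=3)
        return mask, puncta

    def test_volume_and_shape_preserved(self, setup):
        mask, puncta = setup
        placed = randomize_puncta(puncta, mask, rng=1)
        by_id = {p.id: p for p in placed}
        for p in puncta:
            q = by_id[p.id]
            assert q.volume == p.volume
            assert len(q.slices) == len(p.slices)
            # per-layer shapes identical up to a common rigid shift
            shifts = {
                (qs.layer - ps.layer,
                 tuple((qs.pixels - ps.pixels)[0]))
                for ps, qs in zip(p.slices, q.slices)
            }
            assert len(shifts) == 1

    def test_in_mask_and_disjoint(self, setup):
        mask, puncta = setup
        placed = randomize_puncta(puncta, mask, rng=2)
        seen = set()
        for p in placed:
            for v in map(tuple, p.voxels()):
                assert mask.layers[v]
                assert v not in seen
                seen.add(v)

    def test_seed_reproducibility(self, setup):
        mask, puncta = setup
        a = randomize_puncta(puncta, mask, rng=7)
        b = randomize_puncta(puncta, mask, rng=7)
        c = randomize_puncta(puncta, mask, rng=8)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.voxels(), pb.voxels())
        assert any(
            not np.array_equal(pa.voxels(), pc.voxels()) for pa, pc in zip(a, c)
        )

    def test_near_packing_raises_placement_limit(self):
        layers = np.zeros((1, 8, 8), dtype=bool)
        layers[0, 2:6, 2:6] = True  # 16 px cell
        mask = CellMask(layers=layers)
        # two 3x3 puncta cannot both fit in a 4x4 mask
        a = make_punctum(1, "green",
                         [(0, y, x) for y in range(2, 5) for x in range(2, 5)])
        b = make_punctum(2, "green",
                         [(0, y, x) for y in range(3, 6) for x in range(3, 6)])
        with pytest.raises(PlacementLimitError, match="placement limit"):
            randomize_puncta([a, b], mask, rng=0, max_attempts_per_punctum=50)

    def test_centroid_marginal_uniform_over_feasible_offsets(self):
        """A 1-voxel punctum's randomized position should be uniform over the
        mask (chi-square goodness of fit on a coarse grid, alpha = 0.01)."""
        layers = np.ones((1, 16, 16), dtype=bool)
        mask = CellMask(layers=layers)
        p = make_punctum(1, "green", [(0, 0, 0)])
        counts = np.zeros((4, 4))
        n_rep = 4000
        rng = np.random.default_rng(123)
        for _ in range(n_rep):
            placed = randomize_puncta([p], mask, rng=rng)
            _, y, x = placed[0].voxels()[0]
            counts[y // 4, x // 4] += 1
        chi2 = ((counts - n_rep / 16) ** 2 / (n_rep / 16)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=15)


class TestBackgroundOverlap:
    def test_ten_replicates_ten_fractions(self):
        rng = np.random.default_rng(0)
        mask = full_mask((4, 24, 24))
        green = blocky_puncta(rng, mask, 3, "green", 1)
        red = blocky_puncta(rng, mask, 3, "red", 10)
        rates = background_overlap(green, red, mask, n_replicates=10, seed=5)
        assert rates["green"].n_replicates == 10
        assert len(rates["red"].replicate_fractions) == 10
        assert all(0 <= f <= 1 for f in rates["green"].replicate_fractions)

    def test_coincident_puncta_exceed_background(self):
        """Perfectly coincident channels: observed ~1, randomized far lower,
        exceedance count 0 (sparse occupancy)."""
        rng = np.random.default_rng(1)
        mask = full_mask((6, 48, 48))
        green = blocky_puncta(rng, mask, 5, "green", 1, size=3)
        red = [make_punctum(20 + i, "red", p.voxels()) for i, p in enumerate(green)]
        rates = background_overlap(green, red, mask, n_replicates=10, seed=2)
        for ch in ("green", "red"):
            assert rates[ch].observed_mean == pytest.approx(1.0)
            assert rates[ch].mean < 0.3
            assert rates[ch].exceedance_count == 0

    def test_sparse_case_matches_uniform_expectation(self):
        """1-voxel red puncta in a large mask: the randomized mean overlap
        equals the green occupied fraction within 3 binomial sd."""
        rng = np.random.default_rng(3)
        shape = (5, 30, 30)
        mask = full_mask(shape)
        n_mask = np.prod(shape)
        green = blocky_puncta(rng, mask, 12, "green", 1, size=3)
        green_vol = sum(p.volume for p in green)
        red = blocky_puncta(rng, mask, 15, "red", 100, size=1)
        n_rep = 40
        rates = background_overlap(green, red, mask, n_replicates=n_rep, seed=4)
        p_hit = green_vol / n_mask
        n_trials = len(red) * n_rep
        sd = np.sqrt(p_hit * (1 - p_hit) / n_trials)
        assert rates["red"].mean == pytest.approx(p_hit, abs=3 * sd)


def test_mean_overlap_weighting(punctum_factory):
    recs = overlap_records(
        [punctum_factory(1, "red", [(0, 0, 0)]),
         punctum_factory(2, "red", [(1, y, x) for y in range(3) for x in range(3)])],
        [punctum_factory(3, "green", [(1, y, x) for y in range(3) for x in range(3)])],
        SHAPE,
    )
    assert mean_overlap(recs) == pytest.approx(0.5)  # (0 + 1) / 2
    assert mean_overlap(recs, volume_weighted=True) == pytest.approx(9 / 10)
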