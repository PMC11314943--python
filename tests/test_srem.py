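import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import radarposture as rp
from radarposture.geometry import azimuth_mask


def toy_radar(position=(-3.0, 5.0), n_bins=40, half_angle=65.0):
    # bin spacing 0.643 cm, short range suited to a 10 x 10 cm toy grid
    return rp.RadarSpec("HC", position=position, boresight=(1.0, 0.0),
                        azimuth_half_angle=half_angle,
                        bin_length=0.00643, n_bins=n_bins, max_range=0.00643 * n_bins)


def toy_grid():
    return rp.GridSpec(origin=(0.0, 0.0), extent=(10.0, 10.0), cell_size=1.0)


def profile(values, radar):
    return rp.IntensityProfile(values=np.asarray(values, float), radar_id=radar.radar_id,
                               bin_length=radar.bin_length)


def brute_force_srem(prof, radar, grid, interp, masked):
    """Independent per-cell re-derivation of the echo-map recipe."""
    d = radar.bin_length * 100.0
    out = np.zeros(grid.shape)
    sector = azimuth_mask(radar, grid)
    for i in range(grid.n_x):
        for j in range(grid.n_y):
            cx, cy = rp.cell_center(grid, i, j)
            D = math.hypot(cx - radar.position[0], cy - radar.position[1])
            b_small = math.floor(D / d)
            b_large = math.ceil(D / d)
            if b_large >= radar.n_bins:
                continue
            if masked and not sector[i, j]:
                continue
            frac = math.fmod(D, d) / d
            if interp == "as_printed":
                out[i, j] = prof.values[b_small] * frac + prof.values[b_large] * (1.0 - frac)
            else:
                out[i, j] = prof.values[b_small] * (1.0 - frac) + prof.values[b_large] * frac
    return out


class TestGenerateSREM:
    def test_zero_profile_gives_zero_map(self):
        radar = toy_radar()
        m = rp.generate_srem(profile(np.zeros(radar.n_bins), radar), radar, toy_grid())
        np.testing.assert_array_equal(m.values, 0.0)

    @pytest.mark.parametrize("interp", ["as_printed", "corrected"])
    def test_exact_bin_distance_collapses_weights(self, interp):
        # exactly representable geometry: 0.5 cm bins, 1 cm cells, radar at
        # a cell center, so cell (3, 0) sits at D = 3.0 cm = bin 6 with
        # D mod d identically zero
        grid = rp.GridSpec(origin=(0.0, 0.0), extent=(10.0, 10.0), cell_size=1.0)
        radar = rp.RadarSpec("HC", position=rp.cell_center(grid, 0, 0), boresight=(1.0, 0.0),
                             bin_length=0.005, n_bins=40, max_range=0.2)
        b = 6
        p = np.zeros(radar.n_bins)
        p[b] = 1.0
        m = rp.generate_srem(profile(p, radar), radar, grid, interp=interp, masked=False)
        assert m.values[3, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("interp", ["as_printed", "corrected"])
    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_brute_force_oracle(self, interp, masked):
        radar = toy_radar()
        grid = toy_grid()
        rng = np.random.default_rng(12)
        for _ in range(5):
            prof = profile(rng.uniform(0, 1, radar.n_bins), radar)
            m = rp.generate_srem(prof, radar, grid, interp=interp, masked=masked)
            np.testing.assert_allclose(
                m.values, brute_force_srem(prof, radar, grid, interp, masked), atol=1e-9
            )

    @pytest.mark.parametrize("interp", ["as_printed", "corrected"])
    def test_weights_sum_to_one_via_constant_profile(self, interp):
        radar = toy_radar(half_angle=90.0)
        grid = toy_grid()
        m = rp.generate_srem(profile(np.full(radar.n_bins, 3.5), radar), radar, grid,
                             interp=interp, masked=False)
        in_range = rp.distance_map(radar, grid) / (radar.bin_length * 100) < radar.n_bins - 1
        np.testing.assert_allclose(m.values[in_range], 3.5, atol=1e-9)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.integers(0, 10_000))
    def test_linear_in_profile(self, alpha, beta, seed):
        radar = toy_radar()
        grid = toy_grid()
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, radar.n_bins)
        q = rng.uniform(0, 1, radar.n_bins)
        combo = rp.generate_srem(profile(alpha * p + beta * q, radar), radar, grid)
        mp = rp.generate_srem(profile(p, radar), radar, grid)
        mq = rp.generate_srem(profile(q, radar), radar, grid)
        np.testing.assert_allclose(combo.values, alpha * mp.values + beta * mq.values, atol=1e-8)

    def test_masked_map_zero_outside_sector(self, grid, placement):
        radar = placement[1]  # HC, looking down the bed
        rng = np.random.default_rng(3)
        prof = profile(rng.uniform(0.1, 1.0, radar.n_bins), radar)
        m = rp.generate_srem(prof, radar, grid, masked=True)
        sector = azimuth_mask(radar, grid)
        assert np.all(m.values[~sector] == 0.0)
        assert m.values[sector].max() > 0

    def test_sector_shape_under_default_geometry(self, grid, placement):
        # non-zero support of a masked map from a constant profile is
        # exactly the 65-degree sector (every cell is within range here)
        radar = placement[1]
        m = rp.generate_srem(profile(np.ones(radar.n_bins), radar), radar, grid, masked=True)
        sector = azimuth_mask(radar, grid)
        np.testing.assert_array_equal(m.values > 0, sector)

    def test_profile_length_mismatch_rejected(self):
        radar = toy_radar()
        with pytest.raises(ValueError):
            rp.generate_srem(profile(np.zeros(10), radar), radar, toy_grid())

    def test_unknown_interp_rejected(self):
        radar = toy_radar()
        with pytest.raises(ValueError):
            rp.generate_srem(profile(np.zeros(radar.n_bins), radar), radar, toy_grid(),
                             interp="cubic")


class TestAccumulateSREM:
    def test_single_profile_equals_generate(self):
        radar = toy_radar()
        rng = np.random.default_rng(0)
        p = profile(rng.uniform(0, 1, radar.n_bins), radar)
        acc = rp.accumulate_srem([p], radar, toy_grid())
        one = rp.generate_srem(p, radar, toy_grid())
        np.testing.assert_array_equal(acc.values, one.values)

    def test_duplicate_profile_doubles(self):
        radar = toy_radar()
        rng = np.random.default_rng(1)
        p = profile(rng.uniform(0, 1, radar.n_bins), radar)
        acc = rp.accumulate_srem([p, p], radar, toy_grid())
        one = rp.generate_srem(p, radar, toy_grid())
        np.testing.assert_allclose(acc.values, 2.0 * one.values, atol=1e-12)

    def test_additivity_three_profiles(self):
        radar = toy_radar()
        rng = np.random.default_rng(2)
        ps = [profile(rng.uniform(0, 1, radar.n_bins), radar) for _ in range(3)]
        acc = rp.accumulate_srem(ps, radar, toy_grid())
        total = sum(rp.generate_srem(p, radar, toy_grid()).values for p in ps)
        np.testing.assert_allclose(acc.values, total, atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rp.accumulate_srem([], toy_radar(), toy_grid())


class TestBuildViewStack:
    def test_full_stack_has_eight_views(self, small_records, placement, grid):
        records, _ = small_records
        stack = rp.build_view_stack(records[0], placement, grid)
        assert len(stack) == 8
        assert stack.radar_ids == rp.CANONICAL_RADAR_ORDER

    def test_two_radar_mask_in_canonical_order(self, small_records, placement, grid):
        records, _ = small_records
        stack = rp.build_view_stack(records[0], placement, grid, mask={"S3", "HC"})
        assert stack.radar_ids == ("HC", "S3")

    def test_ensemble_config_as_mask(self, small_records, placement, grid):
        records, _ = small_records
        cfg = [c for c in rp.config_registry() if c.config_id == 22][0]
        stack = rp.build_view_stack(records[0], placement, grid, mask=cfg)
        assert stack.radar_ids == ("HC", "S3")

    def test_minmax_handles_constant_view(self, placement, grid):
        # zero frames produce constant (all-zero) maps: normalisation must
        # return zeros, not NaN
        frames = {
            r.radar_id: rp.RadarFrame(values=np.zeros((r.n_bins, 4)), radar_id=r.radar_id,
                                      bin_length=r.bin_length)
            for r in placement
        }
        rec = rp.SampleRecord(subject_id="sub000", posture="S", blanket="thin",
                              trial=1, frames=frames)
        stack = rp.build_view_stack(rec, placement, grid)
        arr = stack.as_array()
        assert np.all(np.isfinite(arr)) and np.all(arr == 0.0)

    def test_missing_radar_raises(self, small_records, placement, grid):
        records, _ = small_records
        rec = records[0]
        partial = rp.SampleRecord(subject_id=rec.subject_id, posture=rec.posture,
                                  blanket=rec.blanket, trial=rec.trial,
                                  frames={k: v for k, v in rec.frames.items() if k != "S2"})
        with pytest.raises(KeyError, match="S2"):
            rp.build_view_stack(partial, placement, grid)

    def test_views_normalised_to_unit_interval(self, small_records, placement, grid):
        records, _ = small_records
        arr = rp.build_view_stack(records[0], placement, grid).as_array()
        assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert arr.max() == pytest.approx(1.0)
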