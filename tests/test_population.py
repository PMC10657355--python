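"""Kymographs, velocities, contours and timing summaries vs loop oracles."""
import numpy as np
import pandas as pd
import pytest

from choreoquant.config import PipelineConfig
from choreoquant.cycles import fitted_lengths
from choreoquant.events import detect_events
from choreoquant.model import ChoreoQuantError, Dataset
from choreoquant.population import (contour_level, demograph, hu_kymograph,
                                    position_kymograph,
                                    stepwise_velocity,
                                    synchronized_kymograph, timing_summary)
from choreoquant.simulate import GeneratorParams, generate_dataset

from conftest import make_cycle, make_dataset


def fixed_r_cycle(cell_id, r, n=20, birth_length=26.0, channel="ori"):
    """Exponentially growing cycle with one focus pinned at relative
    position ``r`` every frame (exact lengths, so the fit is exact)."""
    c = make_cycle(cell_id, n=n, birth_length=birth_length)
    obs = [(f, (r + 0.5) * c.lengths_px[f]) for f in range(n)]
    return make_cycle(cell_id, n=n, birth_length=birth_length,
                      foci={channel: obs})


@pytest.fixture(scope="module")
def small_clean():
    p = GeneratorParams(n_cycles=400, seed=51, loc_noise_px=0.0,
                        p_missed=0.0, emit_profiles=False)
    ds, truth = generate_dataset(p)
    ev = detect_events(ds, PipelineConfig())
    return ds, truth, ev


class TestPositionKymograph:
    def test_single_cycle_constant_focus(self, config):
        ds = make_dataset(fixed_r_cycle("c0", 0.001, n=20))
        hist = position_kymograph(ds, "ori", 50, 60, config)
        populated = hist.matrix.sum(axis=0) > 0
        assert populated.sum() == 20  # 20 frames in distinct age bins
        assert np.allclose(hist.matrix.sum(axis=0)[populated], 1.0)
        hot_rows = np.unique(np.nonzero(hist.matrix)[0])
        assert len(hot_rows) == 1 and hot_rows[0] == 30  # r just above 0

    def test_two_symmetric_ridges(self, config):
        ds = make_dataset(fixed_r_cycle("a", -0.26, n=20),
                          fixed_r_cycle("b", 0.26, n=20))
        hist = position_kymograph(ds, "ori", 50, 60, config)
        rows = np.unique(np.nonzero(hist.matrix)[0])
        assert len(rows) == 2
        assert rows[0] + rows[1] == 59  # mirror bins about the centre
        # with both cycles present at every age, each ridge carries one
        # focus per two cycles; columns sum to the mean foci per cycle
        populated = hist.matrix.sum(axis=0) > 0
        assert np.allclose(hist.matrix.sum(axis=0)[populated], 1.0)
        assert hist.matrix.max() == pytest.approx(0.5)

    def test_matches_loop_oracle_on_random_cycles(self, config):
        rng = np.random.default_rng(12)
        cycles = []
        for i in range(50):
            n = int(rng.integers(10, 25))
            c = make_cycle(f"c{i}", n=n,
                           birth_length=float(rng.uniform(22, 30)))
            obs = [(f, float(rng.uniform(0, c.lengths_px[f])))
                   for f in range(n) for _ in range(rng.integers(0, 3))]
            cycles.append(make_cycle(
                f"c{i}", n=n, birth_length=c.lengths_px[0],
                foci={"ori": obs}))
        ds = make_dataset(*cycles)
        n_age, n_pos = 10, 12
        hist = position_kymograph(ds, "ori", n_age, n_pos, config)
        counts = np.zeros((n_pos, n_age))
        denom = np.zeros(n_age)
        age_edges = np.linspace(0, 1, n_age + 1)
        pos_edges = np.linspace(-0.5, 0.5, n_pos + 1)

        def bin_of(x, edges):
            if x >= edges[-1]:
                return len(edges) - 2
            return int(np.searchsorted(edges, x, side="right")) - 1

        for c in ds:
            lhat = fitted_lengths(c)
            ages = c.ages()
            for f in range(c.n_frames):
                denom[bin_of(ages[f], age_edges)] += 1
                for x in c.foci_at("ori", f):
                    r = np.clip((x - lhat[f] / 2) / lhat[f], -0.5, 0.5)
                    counts[bin_of(r, pos_edges),
                           bin_of(ages[f], age_edges)] += 1
        expected = np.divide(counts, denom[None, :],
                             out=np.zeros_like(counts),
                             where=denom[None, :] > 0)
        assert np.allclose(hist.matrix, expected)
        assert np.array_equal(hist.n_cycles_per_column, denom)

    def test_mass_conservation_and_reorder_invariance(self, config,
                                                      small_clean):
        ds, _, _ = small_clean
        hist = position_kymograph(ds, "ori", config=config)
        raw = hist.matrix * hist.n_cycles_per_column[None, :]
        total_foci = sum(len(c.foci["ori"]) for c in ds
                         if "ori" in c.foci)
        assert raw.sum() == pytest.approx(total_foci)
        shuffled = Dataset(list(reversed(ds.cycles)))
        hist2 = position_kymograph(shuffled, "ori", config=config)
        assert np.allclose(hist.matrix, hist2.matrix)


class TestDemograph:
    def test_single_cycle_midcell_focus(self, config):
        ds = make_dataset(fixed_r_cycle("c0", 0.0, n=20))
        hist = demograph(ds, "ori", 10, 11, config)
        populated = hist.matrix.sum(axis=0) > 0
        assert np.allclose(hist.matrix.sum(axis=0)[populated], 1.0)
        rows = np.unique(np.nonzero(hist.matrix)[0])
        assert rows.tolist() == [5]  # u = 0 sits in the central bin

    def test_matches_loop_oracle(self, config):
        rng = np.random.default_rng(13)
        cycles = []
        for i in range(30):
            n = int(rng.integers(10, 20))
            base = make_cycle(f"c{i}", n=n,
                              birth_length=float(rng.uniform(22, 30)))
            obs = [(f, float(rng.uniform(0, base.lengths_px[f])))
                   for f in range(n)]
            cycles.append(make_cycle(f"c{i}", n=n,
                                     birth_length=base.lengths_px[0],
                                     foci={"ori": obs}))
        ds = make_dataset(*cycles)
        hist = demograph(ds, "ori", 8, 9, config)
        raw = hist.matrix * hist.n_cycles_per_column[None, :]
        total = sum(len(c.foci["ori"]) for c in ds)
        assert raw.sum() == pytest.approx(total)


class TestSynchronizedKymograph:
    def test_window_zero_equals_event_frame_histogram(self, config,
                                                      small_clean):
        ds, truth, ev = small_clean
        events = dict(zip(ev.cell_id, ev.t_matp_frames))
        hist = synchronized_kymograph(ds, "matp", events, 0,
                                      config=config)
        assert hist.matrix.shape[1] == 1
        # every included cycle has exactly one matp focus at its event
        # frame, at mid-cell
        centre = hist.matrix[:, 0].argmax()
        assert centre in (29, 30)
        assert hist.matrix[:, 0].sum() == pytest.approx(1.0)

    def test_shift_equivariance(self, config, small_clean):
        ds, truth, ev = small_clean
        events = dict(zip(ev.cell_id, ev.t_matp_frames))
        shifted = {k: v + 1 for k, v in events.items()}
        a = synchronized_kymograph(ds, "matp", events, 5, config=config)
        b = synchronized_kymograph(ds, "matp", shifted, 5, config=config)
        # advancing every event by one frame shifts all columns back by one
        assert np.allclose(a.matrix[:, 1:], b.matrix[:, :-1])

    def test_ridge_jumps_to_midcell_at_column_zero(self, config,
                                                   small_clean):
        ds, truth, ev = small_clean
        events = dict(zip(ev.cell_id, ev.t_matp_frames))
        hist = synchronized_kymograph(ds, "matp", events, 3,
                                      config=config)
        w = 3
        centre_bins = (29, 30)
        before = hist.matrix[:, w - 1].argmax()
        at = hist.matrix[:, w].argmax()
        assert at in centre_bins
        # one frame earlier the ridge sits clearly new-pole-ward
        assert before < 29
        r_before = hist.position_edges[before]
        assert r_before < -0.2

    def test_cycles_without_event_are_excluded(self, config):
        ds = make_dataset(fixed_r_cycle("a", 0.0, channel="matp"),
                          fixed_r_cycle("b", 0.1, channel="matp"))
        hist = synchronized_kymograph(ds, "matp", {"a": 5}, 2,
                                      config=config)
        assert hist.n_cycles_per_column.max() == 1


class TestStepwiseVelocity:
    def test_stationary_focus_zero_velocity(self, config):
        ds = make_dataset(fixed_r_cycle("c0", 0.1, n=15, channel="matp"))
        vel = stepwise_velocity(ds, "matp", {"c0": 7}, "toward_old_pole",
                                5, config)
        moving = vel.dropna(subset=["mean_um_per_min"])
        # focus keeps the same relative position; growth drifts it
        # outward only slightly
        assert np.all(np.abs(moving.mean_um_per_min) < 0.01)

    def test_sign_flips_with_polarity(self, config):
        n = 12
        base = make_cycle("c0", n=n, growth=False, birth_length=30.0)
        obs = [(f, 10.0 + f) for f in range(n)]        # toward old pole
        obs_flip = [(f, 20.0 - f) for f in range(n)]   # mirrored
        a = make_cycle("a", n=n, growth=False, birth_length=30.0,
                       foci={"matp": obs})
        b = make_cycle("b", n=n, growth=False, birth_length=30.0,
                       foci={"matp": obs_flip})
        va = stepwise_velocity(make_dataset(a), "matp", {"a": 6},
                               "toward_old_pole", 4, config)
        vb = stepwise_velocity(make_dataset(b), "matp", {"b": 6},
                               "toward_old_pole", 4, config)
        ma = va.dropna(subset=["mean_um_per_min"]).mean_um_per_min
        mb = vb.dropna(subset=["mean_um_per_min"]).mean_um_per_min
        assert np.allclose(ma.values, -mb.values)
        assert (ma > 0).all()

    def test_matp_velocity_peaks_at_event(self, config, small_clean):
        ds, truth, ev = small_clean
        events = dict(zip(ev.cell_id, ev.t_matp_frames))
        vel = stepwise_velocity(ds, "matp", events, "toward_old_pole",
                                6, config)
        vel = vel.set_index("rel_frame")
        peak = vel.mean_um_per_min.idxmax()
        assert peak == 0
        after = vel.loc[1:4, "mean_um_per_min"]
        assert np.all(np.abs(after) < 0.01)
        before = vel.loc[-4:-1, "mean_um_per_min"]
        assert (before > 0).all()
        assert vel.loc[0, "mean_um_per_min"] > 5 * before.max()


class TestHuKymographContours:
    def test_uniform_column_any_fraction(self):
        col = np.full((8, 1), 3.0)
        for f in (0.2, 0.5, 0.8):
            assert contour_level(col, f) == pytest.approx(3.0)

    def test_interpolated_level_matches_threshold_scan(self):
        col = np.array([[4.0], [3.0], [2.0], [1.0]])
        level = contour_level(col, 0.7)
        assert level == pytest.approx(3.0)
        # brute-force scan over thresholds: achievable (fraction, level)
        # pairs, then linear interpolation
        vals = np.sort(col[:, 0])[::-1]
        fracs = np.cumsum(vals) / vals.sum()
        target = 0.55
        got = contour_level(col, target)
        k = int(np.searchsorted(fracs, target))
        t = (target - fracs[k - 1]) / (fracs[k] - fracs[k - 1])
        expected = vals[k - 1] + t * (vals[k] - vals[k - 1])
        assert got == pytest.approx(expected)

    def test_contour_monotonic_in_fraction(self):
        rng = np.random.default_rng(5)
        mat = rng.random((30, 6))
        assert contour_level(mat, 0.8) <= contour_level(mat, 0.5)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ChoreoQuantError):
            contour_level(np.ones((4, 2)), 1.5)

    def test_hu_kymograph_shape_and_bias(self, config):
        p = GeneratorParams(n_cycles=150, seed=61, profile_noise_sd=0.0,
                            loc_noise_px=0.0, p_missed=0.0)
        ds, _ = generate_dataset(p)
        hist = hu_kymograph(ds, 10, 60, config)
        assert hist.matrix.shape == (60, 10)
        grid = hist.position_edges
        # early columns: centroid biased toward the new pole
        col0 = hist.matrix[:, 0]
        centroid0 = (grid * col0).sum() / col0.sum()
        assert centroid0 < -0.01
        # late columns: central dip (constriction) present
        late = hist.matrix[:, -1]
        centre = np.abs(grid) < 0.05
        shoulder = (np.abs(grid) > 0.15) & (np.abs(grid) < 0.3)
        assert late[centre].mean() < late[shoulder].mean()


class TestTimingSummary:
    def test_hand_made_pairs(self, config):
        df = pd.DataFrame({
            "t_ori_min": [20.0, 30.0],
            "t_matp_min": [50.0, 60.0],
            "t_nuc_min": [np.nan, np.nan],
            "t_tersep_min": [np.nan, np.nan],
        })
        s = timing_summary(df, config)
        pair = s.pairs.set_index("event").loc["t_matp - t_ori"]
        assert pair.mean_min == 30.0 and pair.median_min == 30.0

    def test_single_cycle_sd_zero_with_flag(self, config):
        df = pd.DataFrame({"t_ori_min": [20.0], "t_matp_min": [50.0],
                           "t_nuc_min": [90.0], "t_tersep_min": [np.nan]})
        s = timing_summary(df, config)
        row = s.events.set_index("event").loc["t_ori"]
        assert row.sd_min == 0.0 and row.n == 1
        assert any("n=1" in f for f in s.flags)

    def test_pairs_only_over_joint_detections(self, config):
        df = pd.DataFrame({
            "t_ori_min": [20.0, np.nan, 10.0],
            "t_matp_min": [50.0, 55.0, np.nan],
            "t_nuc_min": [np.nan] * 3,
            "t_tersep_min": [np.nan] * 3,
        })
        s = timing_summary(df, config)
        pair = s.pairs.set_index("event").loc["t_matp - t_ori"]
        assert pair.n == 1 and pair.mean_min == 30.0

    def test_generator_statistics_recovered(self, config, small_clean):
        ds, truth, ev = small_clean
        sub = ev[ev.cell_id.isin(truth.table.cell_id)]
        s = timing_summary(sub, config)
        pair = s.pairs.set_index("event").loc["t_matp - t_ori"]
        assert pair.median_min == 30.0
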