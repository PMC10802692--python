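import numpy as np
import pandas as pd
import pytest

from patchywave.circular import circ_dist
from patchywave.features import (
    assign_evoked_motifs,
    channel_tuning,
    gain_modulation,
    motif_tuning,
    performance_modulation,
)
from patchywave.motifs import MotifSet
from patchywave.phase import PhasePattern


class TestChannelTuning:
    def test_flat_responses_excluded(self):
        ct = channel_tuning(np.ones(6))
        assert ct.length == pytest.approx(0.0, abs=1e-12)
        assert not ct.included

    def test_one_hot_response(self):
        r = np.zeros(6)
        r[2] = 1.0
        ct = channel_tuning(r)
        assert ct.preferred == pytest.approx(2 * np.pi / 6 * 2)
        assert ct.length == pytest.approx(1.0)
        assert ct.included

    def test_cosine_peak_recovered(self):
        theta0 = 1.1
        dirs = np.arange(6) * 2 * np.pi / 6
        r = 2.0 + np.cos(dirs - theta0)
        ct = channel_tuning(r, dirs)
        assert abs(circ_dist(ct.preferred, theta0)) < np.pi / 6

    def test_all_zero_excluded(self):
        ct = channel_tuning(np.zeros(6))
        assert not ct.included

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            channel_tuning(np.ones(3))


def synth_spikes(prefs, depth, arc_center, windows, baseline=5.0,
                 arc_halfwidth=np.pi / 6, total_ms=60000.0, seed=0):
    """Poisson trains with rate boosted inside the arc during windows."""
    rng = np.random.default_rng(seed)
    trains = []
    for p in prefs:
        gain = 1.0 + depth if abs(circ_dist(p, arc_center)) <= arc_halfwidth else 1.0 - depth / 2
        base = rng.poisson(baseline * total_ms / 1000.0)
        t = rng.uniform(0, total_ms, base)
        extra = []
        for (a, b) in windows:
            lam = baseline * gain * (b - a) / 1000.0
            n = rng.poisson(lam)
            extra.append(rng.uniform(a, b, n))
        trains.append(np.sort(np.concatenate([t] + extra)))
    return trains


class TestMotifTuning:
    def test_planted_arc_recovered(self):
        rng = np.random.default_rng(1)
        prefs = rng.uniform(0, 2 * np.pi, 64)
        arc = 2 * np.pi / 3
        windows = [(1000.0 * k + 300.0, 1000.0 * k + 400.0) for k in range(30)]
        trains = synth_spikes(prefs, depth=0.6, arc_center=arc, windows=windows, seed=2)
        mt = motif_tuning(windows, trains, prefs, total_duration_ms=60000.0,
                         n_bins=6, n_shuffles=100, seed=3)
        assert abs(circ_dist(mt.preferred, arc)) <= 2 * np.pi / 6
        assert mt.z > 2.0
        assert mt.significant

    def test_null_depth_zero_centered(self):
        rng = np.random.default_rng(4)
        zs = []
        for k in range(30):
            prefs = rng.uniform(0, 2 * np.pi, 48)
            windows = [(500.0 * j + 100.0, 500.0 * j + 200.0) for j in range(10)]
            trains = synth_spikes(prefs, depth=0.0, arc_center=0.0,
                                  windows=windows, total_ms=10000.0, seed=100 + k)
            mt = motif_tuning(windows, trains, prefs, total_duration_ms=10000.0,
                             n_bins=6, n_shuffles=60, seed=k)
            zs.append(mt.z)
        assert abs(np.nanmean(zs)) < 0.5

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            motif_tuning([], [np.array([1.0])], np.array([0.0]), total_duration_ms=100.0)


def make_trials(n, rng, n_motifs=3, boost=0.2, motif_dirs=None):
    dirs = np.arange(6) * 2 * np.pi / 6
    if motif_dirs is None:
        motif_dirs = {m: dirs[m] for m in range(n_motifs)}
    rows = []
    for i in range(n):
        d = rng.choice(dirs)
        loc = "upper" if rng.random() < 0.5 else "lower"
        m = int(rng.integers(-1, n_motifs))
        p = 0.5
        if m >= 0 and abs(circ_dist(d, motif_dirs[m])) <= np.pi / 3:
            p += boost
        out = "hit" if rng.random() < p else "miss"
        rows.append(dict(trial=i, t_target_ms=500.0, direction_rad=d, location=loc,
                         outcome=out, contrast_class="low", pattern_id=i, motif_id=m))
    return pd.DataFrame(rows), motif_dirs


class TestGainModulation:
    def test_modulation_index_arithmetic(self):
        from patchywave.features import _modulation_index

        assert _modulation_index(3.22, 2.55) == pytest.approx(0.116, abs=5e-4)
        assert _modulation_index(2.0, 2.0) == 0.0
        # antisymmetry under pool swap
        assert _modulation_index(2.55, 3.22) == pytest.approx(-0.116, abs=5e-4)

    def test_planted_gain_recovered(self):
        rng = np.random.default_rng(5)
        trials, motif_dirs = make_trials(4000, rng, boost=0.0)
        n_units = 6
        unit_prefs = np.arange(n_units) * 2 * np.pi / n_units
        unit_locs = np.array(["upper", "lower"] * 3)
        dirs = trials["direction_rad"].to_numpy()
        mid = trials["motif_id"].to_numpy()
        # evoked rates: higher when trial's motif prefers the target direction
        aligned = np.zeros(len(trials), bool)
        for t in range(len(trials)):
            if mid[t] >= 0:
                aligned[t] = abs(circ_dist(motif_dirs[mid[t]], dirs[t])) <= np.pi / 2
        evoked = 1.0 + 0.4 * aligned[None, :] + 0.05 * rng.standard_normal((n_units, len(trials)))
        res, ctrl = gain_modulation(
            trials, evoked, unit_prefs, unit_locs, motif_dirs,
            n_control=5, seed=0,
        )
        assert len(res) >= 3
        mis = [r.MI for r in res]
        assert np.mean(mis) > 0.05
        assert abs(np.mean(ctrl)) < np.mean(mis)

    def test_sign_flips_with_planted_direction(self):
        rng = np.random.default_rng(6)
        trials, motif_dirs = make_trials(4000, rng, boost=0.0)
        n_units = 6
        unit_prefs = np.arange(n_units) * 2 * np.pi / n_units
        unit_locs = np.array(["upper", "lower"] * 3)
        dirs = trials["direction_rad"].to_numpy()
        mid = trials["motif_id"].to_numpy()
        opposed = np.zeros(len(trials), bool)
        for t in range(len(trials)):
            if mid[t] >= 0:
                opposed[t] = abs(circ_dist(motif_dirs[mid[t]], dirs[t])) > np.pi / 2
        evoked = 1.0 + 0.4 * opposed[None, :] + 0.05 * rng.standard_normal((n_units, len(trials)))
        res, _ = gain_modulation(
            trials, evoked, unit_prefs, unit_locs, motif_dirs, n_control=2, seed=0
        )
        assert np.mean([r.MI for r in res]) < -0.05


class TestAssignEvokedMotifs:
    def _patterns(self, rng, n=20):
        side = 8
        ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        grid = np.column_stack([ii.ravel(), jj.ravel()])
        return [
            PhasePattern(phase=rng.uniform(-np.pi, np.pi, 64),
                         valid=np.ones(64, bool), channel_grid=grid, test_time=0.0)
            for _ in range(n)
        ]

    def test_exact_copy_assigned(self):
        rng = np.random.default_rng(7)
        spont = self._patterns(rng, 20)
        motifs = MotifSet([[0, 1, 2], [3, 4, 5]], [0, 3], np.zeros(20), 0.8, 3.0, 1.0)
        # make each motif's members near-identical
        for m in (0, 1):
            for j in motifs.motifs[m][1:]:
                spont[j].phase = spont[motifs.motifs[m][0]].phase.copy()
        n_tr = 40
        rows = [dict(trial=i, t_target_ms=500.0, direction_rad=0.0, location="upper",
                     outcome="hit", contrast_class="low", pattern_id=i, motif_id=-1)
                for i in range(n_tr)]
        trials = pd.DataFrame(rows)
        evoked = self._patterns(rng, n_tr)
        evoked[5].phase = spont[0].phase.copy()  # exact member copy
        evoked[9] = None  # no cycle in evoked window
        out = assign_evoked_motifs(trials, evoked, spont, motifs)
        assert out.loc[5, "motif_id"] == 0
        assert out.loc[9, "motif_id"] == -1

    def test_catch_trials_excluded(self):
        rng = np.random.default_rng(8)
        spont = self._patterns(rng, 10)
        motifs = MotifSet([[0, 1]], [0], np.zeros(10), 0.8, 3.0, 1.0)
        trials = pd.DataFrame([
            dict(trial=0, t_target_ms=0.0, direction_rad=0.0, location="upper",
                 outcome="catch", contrast_class="low", pattern_id=0, motif_id=-1)
        ])
        out = assign_evoked_motifs(trials, [spont[0]], spont, motifs)
        assert out.loc[0, "motif_id"] == -1


class TestPerformanceModulation:
    def test_planted_boost_detected(self):
        rng = np.random.default_rng(9)
        trials, motif_dirs = make_trials(4000, rng, boost=0.25)
        res = performance_modulation(trials, motif_dirs, n_perm=30, seed=0)
        assert len(res) >= 3
        diffs = [r.aligned_rate - r.opposed_rate for r in res]
        assert np.mean(diffs) > 0.1

    def test_angle_alignment_with_planted_preference(self):
        rng = np.random.default_rng(10)
        trials, motif_dirs = make_trials(6000, rng, boost=0.3)
        res = performance_modulation(trials, motif_dirs, n_perm=30, seed=0)
        diffs = [r.angle_diff for r in res]
        assert np.mean(diffs) < np.pi / 3

    def test_shuffled_outcomes_null_z(self):
        rng = np.random.default_rng(11)
        trials, motif_dirs = make_trials(3000, rng, boost=0.0)
        res = performance_modulation(trials, motif_dirs, n_perm=40, seed=1)
        zs = [r.z for r in res if np.isfinite(r.z)]
        assert abs(np.mean(zs)) < 0.8
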