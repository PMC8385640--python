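"""Delineation, amplitude operators, ROC search, classification, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from achmap import detection
from achmap.detection import (
    RepolWindow, classify, d_threshold_grid, delineate, depol_amplitude,
    ground_truth, metrics, r_threshold_grid, repol_amplitude,
    roc_optimal_threshold,
)
from achmap.egm import EgmGrid, ElectrodeGrid
from achmap.tissue import Patch, TissueModel


def _grid_from_phi(phi, sample_dt=1.0):
    nr, nc, _ = phi.shape
    g = ElectrodeGrid(n_rows=nr, n_cols=nc, footprint="punctual")
    pos = np.zeros((nr, nc, 2))
    return EgmGrid(phi=phi, sample_dt=sample_dt, grid=g, positions_mm=pos)


def _case_with_bump(nt=500, t_dep=50, t_bump=220, bump=0.5):
    """4 x 4 grid: sharp negative depolarization slope at t_dep, one
    electrode with a repolarization bump at t_bump."""
    t = np.arange(nt, dtype=float)
    base = 3.0 * np.exp(-0.5 * ((t - t_dep) / 1.5) ** 2)
    base = np.gradient(base)            # biphasic wave, steepest fall at t_dep
    phi = np.tile(base, (4, 4, 1))
    phi[1, 2] = phi[1, 2] + bump * np.exp(-0.5 * ((t - t_bump) / 8.0) ** 2)
    return _grid_from_phi(phi)


class TestDelineate:
    def test_window_around_known_bump(self):
        egm = _case_with_bump(t_bump=220)
        w = delineate(egm)
        assert w.t_R == pytest.approx(220, abs=2)
        assert w.tw_on == pytest.approx(w.t_R - 30)
        assert w.tw_off == pytest.approx(w.t_R + 150)

    def test_flat_after_depolarization_raises(self):
        egm = _case_with_bump(bump=0.0)
        phi = egm.phi.copy()
        phi[..., 160:] = 0.0
        with pytest.raises(ValueError):
            delineate(_grid_from_phi(phi))

    def test_translation_equivariance(self):
        a = _case_with_bump()
        shifted = np.roll(a.phi, 50, axis=-1)
        shifted[..., :50] = 0.0
        b = _grid_from_phi(shifted)
        wa, wb = delineate(a), delineate(b)
        assert wb.t_R - wa.t_R == pytest.approx(50, abs=2)
        assert wb.tw_on - wa.tw_on == pytest.approx(50, abs=2)

    def test_search_starts_100ms_after_reference(self):
        # a larger bump before t_ref + 100 must be ignored
        egm = _case_with_bump(t_bump=260)
        egm.phi[2, 2] += 5.0 * np.exp(
            -0.5 * ((np.arange(500) - 120.0) / 5.0) ** 2)
        w = delineate(egm)
        assert w.t_R == pytest.approx(260, abs=2)


class TestAmplitudeOperators:
    W = RepolWindow(t_ref=0.0, t_R=200.0, tw_on=170.0, tw_off=350.0)

    def _sig(self, extrema, nt=400):
        """Smooth signal whose in-window local extrema are as prescribed."""
        t = np.arange(nt, dtype=float)
        x = np.zeros(nt)
        for tc, amp in extrema:
            x += amp * np.exp(-0.5 * ((t - tc) / 6.0) ** 2)
        return t, x

    def test_largest_abs_keeps_sign(self):
        t, x = self._sig([(200, -0.2), (250, 0.5)])
        assert repol_amplitude(x, t, self.W) == pytest.approx(0.5, rel=1e-3)
        t, x = self._sig([(200, -0.6), (250, 0.5)])
        assert repol_amplitude(x, t, self.W) == pytest.approx(-0.6, rel=1e-3)

    def test_exact_tie_positive_and_flagged(self):
        t = np.arange(400, dtype=float)
        x = np.zeros(400)
        x[180:221] = -np.sin((t[180:221] - 180) / 40 * 2 * np.pi)  # -peak then +peak
        v, tie = repol_amplitude(x, t, self.W, with_flag=True)
        assert tie and v > 0

    def test_brute_force_oracle_random_signals(self):
        """Eq.-3 operator equals a brute-force scan over all local extrema."""
        rng = np.random.default_rng(7)
        t = np.arange(400, dtype=float)
        sel = (t >= self.W.tw_on) & (t <= self.W.tw_off)
        for _ in range(1000):
            x = rng.standard_normal(400).cumsum()
            x -= np.linspace(x[0], x[-1], 400)
            xs = x[sel]
            # oracle: every interior sample that is a local max or min
            cand = [xs[i] for i in range(1, xs.size - 1)
                    if (xs[i] - xs[i - 1]) * (xs[i + 1] - xs[i]) < 0]
            if not cand:
                continue
            expected = max(cand, key=abs)
            got = repol_amplitude(x, t, self.W)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_depol_peak_to_peak(self):
        t = np.arange(100, dtype=float)
        x = np.zeros(100)
        x[20], x[30] = 3.0, -4.0
        assert depol_amplitude(x, t, 0, 99) == pytest.approx(7.0)
        assert depol_amplitude(np.ones(100), t, 0, 99) == 0.0
        assert depol_amplitude(x + 5.0, t, 0, 99) == pytest.approx(7.0)

    def test_empty_segment_raises(self):
        t = np.arange(100, dtype=float)
        with pytest.raises(ValueError):
            depol_amplitude(np.zeros(100), t, 50, 40)
        with pytest.raises(ValueError):
            repol_amplitude(np.zeros(100), t, self.W)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        truth = scores > 0.5
        th, se, sp, roc = roc_optimal_threshold(scores, truth,
                                                np.linspace(-1, 2, 61))
        assert 0 < th < 1 and se == 1.0 and sp == 1.0

    def test_chance_level_distance(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(4000)
        truth = rng.random(4000) < 0.5
        _, se, sp, roc = roc_optimal_threshold(scores, truth,
                                               np.linspace(-3, 3, 161))
        d = np.min(roc["distance"])
        assert d == pytest.approx(np.sqrt(2) / 2, abs=0.06)

    def test_matches_midpoint_oracle(self):
        """Optimum ties or dominates an exhaustive scan over all midpoints
        between sorted unique scores (up to grid quantization)."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(20, 60)
            truth = np.zeros(n, dtype=bool)
            truth[: rng.integers(3, n - 3)] = True
            rng.shuffle(truth)
            scores = rng.standard_normal(n) + 1.5 * truth
            lo, hi = scores.min() - 1, scores.max() + 1
            grid = np.linspace(lo, hi, 400)
            th, se, sp, roc = roc_optimal_threshold(scores, truth, grid)
            best = np.min(roc["distance"])
            # oracle: every midpoint between sorted unique scores
            u = np.sort(np.unique(scores))
            mids = np.r_[u[0] - 1, (u[1:] + u[:-1]) / 2, u[-1] + 1]
            dists = []
            for m in mids:
                pred = scores > m
                tp = (pred & truth).sum()
                fp = (pred & ~truth).sum()
                dists.append(np.hypot(fp / (~truth).sum(),
                                      1 - tp / truth.sum()))
            # grid quantization: allow the spacing of adjacent score gaps
            assert best <= min(dists) + 0.08

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_optimal_threshold(np.arange(5.0), np.ones(5, bool),
                                  np.arange(5.0))

    def test_monotonicity_of_operating_points(self):
        """Raising the threshold never increases Se or FPR."""
        rng = np.random.default_rng(11)
        scores = rng.standard_normal(300)
        truth = scores + rng.standard_normal(300) > 0
        _, _, _, roc = roc_optimal_threshold(scores, truth,
                                             np.linspace(-3, 3, 121))
        assert np.all(np.diff(roc["se"]) <= 1e-12)
        assert np.all(np.diff(roc["fpr"]) <= 1e-12)

    def test_threshold_grids(self):
        d = d_threshold_grid(np.full(10, 5.0))
        assert d.size == 40
        assert np.allclose(np.diff(d), 0.1)
        assert np.isclose(d, 5.0).any() or (d.min() < 5.0 < d.max())
        r = r_threshold_grid(2.0)
        assert r.size == 161                      # about 160, 1% steps
        assert np.allclose(np.diff(r), 0.02)
        assert r.min() < 0 < r.max()              # spans negative percentages


class TestClassifyAndMetrics:
    def _amps(self, r_a, d_a):
        w = RepolWindow(0.0, 200.0, 170.0, 350.0)
        return detection.AmplitudeMap(r_a=r_a, d_a=d_a,
                                      r_tie=np.zeros(r_a.shape, bool),
                                      window=w, depol_onset=0.0)

    def test_two_stage_separable(self):
        r_a = np.array([[0.1, 0.9], [0.2, 0.8]])
        d_a = np.full((2, 2), 7.0)
        det = classify(self._amps(r_a, d_a), d_th=3.0, r_th_nonfibro=0.5,
                       r_th_fibro=0.0, mode="two_stage")
        assert det.pred_ach.tolist() == [[False, True], [False, True]]
        assert not det.pred_fibro.any()

    def test_negative_fibrotic_threshold_accepts_small_positive_peaks(self):
        r_a = np.array([[0.05, -0.2]])
        d_a = np.array([[1.0, 1.0]])          # all fibrotic
        det = classify(self._amps(r_a, d_a), d_th=3.0, r_th_nonfibro=0.5,
                       r_th_fibro=-0.1, mode="two_stage")
        assert det.label.tolist() == [[detection.LABEL_ACH_FIBRO,
                                       detection.LABEL_NONACH_FIBRO]]

    def test_one_stage_all_below(self):
        r_a = np.zeros((3, 3))
        det = classify(self._amps(r_a, np.ones((3, 3))), r_th_nonfibro=0.5)
        truth = np.zeros((3, 3), bool)
        truth[1, 1] = True
        ac, se, fpr = metrics(det.pred_ach, truth)
        assert se == 0.0 and fpr == 0.0

    def test_missing_threshold_raises(self):
        with pytest.raises(ValueError):
            classify(self._amps(np.zeros((2, 2)), np.ones((2, 2))),
                     d_th=1.0, r_th_nonfibro=0.1, mode="two_stage")

    def test_metrics_hand_computed(self):
        pred = np.zeros(256, bool)
        truth = np.zeros(256, bool)
        truth[:10] = True
        pred[:8] = True          # 8 TP, 2 FN
        pred[10:13] = True       # 3 FP, 243 TN
        ac, se, fpr = metrics(pred, truth)
        assert ac == pytest.approx(251 / 256)
        assert se == pytest.approx(0.8)
        assert fpr == pytest.approx(3 / 246)

    def test_perfect_prediction(self):
        truth = np.random.default_rng(0).random(100) < 0.3
        assert metrics(truth, truth) == (1.0, 1.0, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            metrics(np.zeros(0, bool), np.zeros(0, bool))


class TestGroundTruth:
    def test_center_boundary_and_outside(self):
        tissue = TissueModel(nx=51, ny=51, dx=0.04, patch_registry=[
            Patch(1.0, 1.0, 0.25, "ACh"), Patch(0.4, 1.6, 0.2, "fibrosis")])
        pos = np.array([[[10.0, 10.0], [12.5, 10.0], [19.0, 19.0],
                         [4.0, 16.0]]])   # mm; second sits exactly on the rim
        ach, fib = ground_truth(pos, tissue)
        assert ach.tolist() == [[True, True, False, False]]   # boundary is inside
        assert fib.tolist() == [[False, False, False, True]]


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_repol_amplitude_antisymmetric(seed):
    """Negating the signal negates the signed amplitude (no-tie case):
    min and max extrema swap roles but the magnitude ranking is unchanged."""
    rng = np.random.default_rng(seed)
    t = np.arange(400, dtype=float)
    x = rng.standard_normal(400).cumsum() / 10
    w = RepolWindow(0.0, 200.0, 170.0, 350.0)
    a, tie = repol_amplitude(x, t, w, with_flag=True)
    if not tie:
        assert repol_amplitude(-x, t, w) == pytest.approx(-a, rel=1e-12)
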