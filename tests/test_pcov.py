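"""Partial-covariance estimation, peak detection, jackknife scoring,
marker matching and quantification."""

import numpy as np
import pytest

import pcovms as pm
from pcovms.pcov import (
    GridSpec,
    PeakCandidate,
    ScanEnsemble,
    compute_cov_map,
    map_mad,
)


def make_grid_ensemble(intensities, lo=100.0, step=0.2, tic=None):
    n_bins = np.asarray(intensities).shape[1]
    grid = lo + step * (np.arange(n_bins) + 0.5)
    return ScanEnsemble(mz_grid=grid, intensities=np.asarray(intensities, float), tic=tic)


class TestScanEnsemble:
    def test_tic_defaults_to_row_sums(self):
        ens = make_grid_ensemble([[1, 2, 3], [4, 5, 6]])
        assert np.allclose(ens.tic, [6, 15])

    def test_rejects_single_scan(self):
        with pytest.raises(ValueError):
            make_grid_ensemble([[1, 2, 3]])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            make_grid_ensemble([[1, -2, 3], [0, 0, 1]])

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            ScanEnsemble(
                mz_grid=np.array([1.0, 2.0, 4.0]),
                intensities=np.ones((2, 3)),
            )


class TestComputePcov:
    @pytest.mark.parametrize("estimator", ["tic", "self_correcting"])
    def test_pure_common_mode_vanishes(self, estimator):
        # every channel an exact multiple of the TIC
        rng = np.random.default_rng(0)
        t = rng.lognormal(0, 0.4, 500)
        a = np.array([0.2, 0.5, 0.1, 0.2])
        X = np.outer(t, a)
        ens = make_grid_ensemble(X)
        M = pm.compute_pcov_map(ens, estimator=estimator).matrix.copy()
        scale = compute_cov_map(ens).matrix.max()
        if estimator == "self_correcting":
            # the per-pair TIC exclusion is degenerate on the diagonal when
            # one channel carries half the TIC; the diagonal is never used
            np.fill_diagonal(M, 0.0)
        assert np.abs(M).max() <= 1e-10 * scale

    def test_correlated_pair_stands_out(self):
        # two bins fed by one Poisson source, others independent
        rng = np.random.default_rng(1)
        n, nb = 10_000, 32
        src = rng.poisson(5.0, n).astype(float)
        X = rng.poisson(5.0, (n, nb)).astype(float)  # independent background
        X[:, 3] += src
        X[:, 20] += src
        ens = make_grid_ensemble(X)
        M = pm.compute_pcov_map(ens).matrix
        null = [
            abs(M[i, j])
            for i in range(nb)
            for j in range(i + 1, nb)
            if (i, j) != (3, 20) and i not in (3, 20) and j not in (3, 20)
        ]
        assert M[3, 20] > 10 * max(null)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        ens = make_grid_ensemble(rng.poisson(3.0, (200, 20)).astype(float))
        for est in ("tic", "self_correcting"):
            M = pm.compute_pcov_map(ens, estimator=est).matrix
            assert np.abs(M - M.T).max() <= 1e-9 * np.abs(M).max()

    def test_degenerate_tic_rejected(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0]])  # constant TIC
        with pytest.raises(ValueError, match="degenerate TIC"):
            pm.compute_pcov_map(make_grid_ensemble(X))

    def test_single_deviant_scan_is_finite(self):
        X = np.ones((5, 4))
        X[2] = [1, 2, 3, 4]
        M = pm.compute_pcov_map(make_grid_ensemble(X)).matrix
        assert np.all(np.isfinite(M))

    def test_unknown_estimator_rejected(self):
        ens = make_grid_ensemble(np.random.default_rng(3).poisson(2, (10, 4)).astype(float))
        with pytest.raises(ValueError):
            pm.compute_pcov_map(ens, estimator="magic")


def gaussian_bump_map(n=60, center=(15, 40), height=1.0, width=1.5):
    x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    b = height * np.exp(
        -0.5 * (((x - center[0]) / width) ** 2 + ((y - center[1]) / width) ** 2)
    )
    M = b + b.T
    return pm.PCovMap(matrix=M, mz_grid=100 + 0.2 * np.arange(n), n_scans=100)


class TestDetectPeaks:
    def test_all_zero_map_empty(self):
        pmap = pm.PCovMap(np.zeros((30, 30)), 100 + 0.2 * np.arange(30), 10)
        assert pm.detect_peaks(pmap, apex_threshold=0.0) == []

    def test_single_bump_found_at_apex(self):
        pmap = gaussian_bump_map()
        peaks = pm.detect_peaks(pmap, apex_threshold=0.5)
        assert len(peaks) == 1
        assert peaks[0].apex == (15, 40)
        assert peaks[0].volume > peaks[0].apex_height

    def test_diagonal_bump_excluded(self):
        pmap = gaussian_bump_map(center=(30, 31))
        assert pm.detect_peaks(pmap, apex_threshold=0.5, diag_exclusion=3) == []

    def test_window_larger_than_map_rejected(self):
        pmap = gaussian_bump_map(n=5)
        with pytest.raises(ValueError):
            pm.detect_peaks(pmap, window=4)

    def test_sorted_by_height(self):
        pmap = gaussian_bump_map()
        pmap.matrix[5, 50] = 3.0  # sharper, higher apex elsewhere
        peaks = pm.detect_peaks(pmap, apex_threshold=0.5)
        heights = [p.apex_height for p in peaks]
        assert heights == sorted(heights, reverse=True)

    def test_mad_threshold_default(self):
        pmap = gaussian_bump_map()
        assert map_mad(pmap) >= 0.0
        peaks = pm.detect_peaks(pmap)
        assert all(p.apex_height > 5 * map_mad(pmap) for p in peaks)


class TestJackknife:
    def test_identical_scans_give_inf_sentinel(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (400, 1))
        ens = make_grid_ensemble(X)
        peak = PeakCandidate(
            apex=(0, 2), apex_mz=(100.1, 100.5), apex_height=0.0, window=1, volume=0.0
        )
        with pytest.warns(RuntimeWarning, match="sigma_JK"):
            score = pm.jackknife_score(ens, peak)
        assert score == float("inf")

    def test_true_pair_beats_null_coordinates(self):
        rng = np.random.default_rng(7)
        n = 10_000
        g = rng.lognormal(0, 0.3, n)
        X = rng.poisson(2.0 * g[:, None], (n, 40)).astype(float)
        src = rng.poisson(3.0 * g)
        X[:, 10] += src
        X[:, 30] += src
        ens = make_grid_ensemble(X)
        pmap = pm.compute_pcov_map(ens, estimator="self_correcting")
        true = pm.score_at(ens, pmap, (10, 30), window=1)
        nulls = [
            pm.score_at(ens, pmap, (i, j), window=1).score
            for i, j in [(5, 20), (3, 35), (12, 25), (8, 33), (15, 36), (2, 27)]
        ]
        assert true.score > max(nulls)

    def test_score_increases_with_scans(self):
        def score_with(n, seed=11):
            rng = np.random.default_rng(seed)
            g = rng.lognormal(0, 0.3, n)
            X = rng.poisson(2.0 * g[:, None], (n, 20)).astype(float)
            src = rng.poisson(3.0 * g)
            X[:, 5] += src
            X[:, 15] += src
            ens = make_grid_ensemble(X)
            pmap = pm.compute_pcov_map(ens, estimator="self_correcting")
            return pm.score_at(ens, pmap, (5, 15), window=1).score

        assert score_with(20_000) > score_with(5_000)

    def test_needs_two_groups(self):
        ens = make_grid_ensemble(np.random.default_rng(0).poisson(2, (50, 4)).astype(float))
        peak = PeakCandidate((0, 2), (100.1, 100.5), 0.0, 1, 0.0)
        with pytest.raises(ValueError):
            pm.jackknife_score(ens, peak, n_groups=1)


class TestMatchMarkers:
    def _peak(self, mzx, mzy, score, volume=1.0):
        return PeakCandidate(
            apex=(0, 0), apex_mz=(mzx, mzy), apex_height=1.0, window=1,
            volume=volume, score=score,
        )

    def test_nearest_within_tolerance(self):
        peaks = [self._peak(512.3, 530.3, 8.0), self._peak(512.9, 530.3, 9.0)]
        ev = pm.match_markers(peaks, {"P4": [(512.28, 530.30)]}, tolerance=0.3)
        assert len(ev.matches["P4"]) == 1
        assert ev.matches["P4"][0].peak.apex_mz[0] == 512.3

    def test_unmatched_marker_absent(self):
        ev = pm.match_markers([], {"P4": [(512.28, 530.30)]})
        assert ev.matches["P4"] == []
        assert not ev.detected("P4")

    def test_empty_marker_list(self):
        ev = pm.match_markers([self._peak(500.0, 510.0, 9.0)], {})
        assert ev.isomers == []

    def test_equidistant_tie_breaks_to_higher_score(self):
        peaks = [self._peak(512.1, 530.3, 2.0), self._peak(512.5, 530.3, 7.0)]
        ev = pm.match_markers(peaks, {"P4": [(512.30, 530.30)]}, tolerance=0.3)
        assert ev.matches["P4"][0].peak.score == 7.0

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            pm.match_markers([], {}, tolerance=0.0)


class TestRelativeQuantify:
    def _evidence(self, volumes_by_iso):
        matches = {}
        for iso, vols in volumes_by_iso.items():
            matches[iso] = [
                pm.pcov.MarkerMatch(
                    marker=(500.0, 510.0),
                    peak=PeakCandidate((0, 0), (500.0, 510.0), 1.0, 1, v, score=5.0),
                    distance=0.0,
                )
                for v in vols
            ]
        return pm.IsomerEvidence(matches=matches, score_threshold=5.0)

    def test_single_isomer_fraction_one(self):
        ev = self._evidence({"A": [0.5]})
        assert pm.relative_quantify(ev) == {"A": 1.0}

    def test_median_rule_proportional(self):
        ev = self._evidence({"A": [0.6, 0.7, 0.8], "B": [0.3, 0.35, 0.25]})
        fr = pm.relative_quantify(ev)
        assert fr["A"] == pytest.approx(0.7)
        assert fr["B"] == pytest.approx(0.3)

    def test_all_nonpositive_rejected(self):
        ev = self._evidence({"A": [0.0], "B": [-1.0]})
        with pytest.raises(ValueError):
            pm.relative_quantify(ev)
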