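"""Spectral preprocessing: baseline, TIC, detection, two-pass clustering."""

import numpy as np
import pytest

from radmarkers.containers import Peak, PeakMatrix, Spectrum, SpectrumSet, meta_frame
from radmarkers.containers import SampleMeta
from radmarkers.seldi import (
    ClusterParams,
    cluster_peaks,
    detect_peaks,
    qc_cv,
    spectra_to_peak_matrix,
    subtract_baseline,
    tic_normalize,
)
from radmarkers.simulate import PeakSpec, SeldiSimConfig, generate_seldi_spectra

GRID = np.linspace(1800.0, 10000.0, 4000)


def gaussian(amp, center, sigma):
    return amp * np.exp(-0.5 * ((GRID - center) / sigma) ** 2)


class TestBaseline:
    def test_constant_offset_removed_exactly(self):
        out = subtract_baseline(Spectrum(GRID, np.full(GRID.size, 7.5)), window=200.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_zero_spectrum_stays_zero(self):
        out = subtract_baseline(Spectrum(GRID, np.zeros(GRID.size)), window=200.0)
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_gaussian_apex_preserved_on_flat_offset(self):
        spec = Spectrum(GRID, gaussian(100.0, 5000.0, 30.0) + 10.0)
        out = subtract_baseline(spec, window=400.0)
        apex = out.intensity.max()
        assert abs(apex - 100.0) < 5.0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([]), np.array([]))


class TestTicNormalize:
    def _sset(self, rows):
        metas = [SampleMeta(f"s{i}", 0.0, 3, 1) for i in range(len(rows))]
        return SpectrumSet(GRID[:10], np.asarray(rows, dtype=float), meta_frame(metas))

    def test_totals_scaled_to_common_mean(self):
        a = np.ones(10)          # total 10
        b = np.full(10, 3.0)     # total 30
        out = tic_normalize(self._sset([a, b]))
        np.testing.assert_allclose(out.intensities.sum(axis=1), [20.0, 20.0])

    def test_identical_spectra_unchanged(self):
        rows = [np.arange(10.0) + 1, np.arange(10.0) + 1]
        out = tic_normalize(self._sset(rows))
        np.testing.assert_allclose(out.intensities, rows)

    def test_single_spectrum_unchanged(self):
        rows = [np.arange(10.0) + 1]
        out = tic_normalize(self._sset(rows))
        np.testing.assert_allclose(out.intensities, rows)

    def test_zero_total_names_the_sample(self):
        with pytest.raises(ValueError, match="s1"):
            tic_normalize(self._sset([np.ones(10), np.zeros(10)]))


class TestDetectPeaks:
    def test_single_strong_peak_with_calibrated_snr(self):
        rng = np.random.default_rng(42)
        spec = Spectrum(GRID, gaussian(100.0, 5000.0, 30.0) + rng.normal(0, 1.0, GRID.size))
        out = subtract_baseline(spec, window=400.0)
        peaks = detect_peaks(out, snr_threshold=2.5)
        assert len(peaks) == 1
        assert 80.0 <= peaks[0].snr <= 120.0
        assert abs(peaks[0].mz - 5000.0) < 10.0

    def test_subthreshold_peak_ignored(self):
        rng = np.random.default_rng(43)
        spec = Spectrum(GRID, gaussian(2.0, 5000.0, 30.0) + rng.normal(0, 1.0, GRID.size))
        out = subtract_baseline(spec, window=400.0)
        assert detect_peaks(out, snr_threshold=2.5) == []

    def test_flat_zero_gives_no_peaks(self):
        assert detect_peaks(Spectrum(GRID, np.zeros(GRID.size)), 2.5) == []

    def test_non_ascending_axis_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))


def _plist(entries):
    """entries: list per sample of (mz, intensity, snr) tuples."""
    return [[Peak(*e) for e in sample] for sample in entries]


class TestClusterPeaks:
    def test_nearby_masses_merge_within_relative_window(self):
        # 7000 vs 7010 Da: 10 Da apart, window 0.3% ~ 21 Da -> one cluster
        pl = _plist([[(7000.0, 5.0, 5.0)], [(7010.0, 5.0, 5.0)]])
        pm = cluster_peaks(pl, ClusterParams())
        assert pm.n_clusters == 1

    def test_distant_masses_stay_separate(self):
        # 7000 vs 7200 Da: 200 Da >> 21 Da window -> two clusters
        pl = _plist([
            [(7000.0, 5.0, 5.0), (7200.0, 5.0, 5.0)],
            [(7000.0, 5.0, 5.0), (7200.0, 5.0, 5.0)],
        ])
        pm = cluster_peaks(pl, ClusterParams())
        assert pm.n_clusters == 2

    def test_completion_pass_rescues_minority_peak(self):
        """A peak in 51 of 128 samples at S/N 4 fails the 50% first pass
        (39.8%) but is retained by the completion pass (>= 10%, S/N >= 3)."""
        entries = []
        for i in range(128):
            sample = [(5000.0, 8.0, 6.0)]  # anchor present everywhere
            if i < 51:
                sample.append((7000.0, 4.0, 4.0))
            entries.append(sample)
        pm = cluster_peaks(_plist(entries), ClusterParams())
        assert pm.n_clusters == 2
        labels = dict(zip(np.round(pm.cluster_mz, 0), pm.provenance))
        assert labels[5000.0] == "first"
        assert labels[7000.0] == "completion"

    def test_low_snr_everywhere_peak_dropped(self):
        # S/N 2.7 passes the pooled 2.5 threshold but presence-fails pass 1
        # (40%) and S/N-fails completion (< 3.0)
        entries = []
        for i in range(10):
            sample = [(5000.0, 8.0, 6.0)]
            if i < 4:
                sample.append((7000.0, 2.7, 2.7))
            entries.append(sample)
        pm = cluster_peaks(_plist(entries), ClusterParams())
        assert pm.n_clusters == 1

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        entries = []
        for _ in range(12):
            sample = [(m * (1 + rng.normal(0, 2e-4)), 5.0, 5.0)
                      for m in (3000.0, 5000.0, 9000.0)]
            entries.append(sample)
        pl = _plist(entries)
        pm1 = cluster_peaks(pl, ClusterParams())
        order = rng.permutation(12)
        pm2 = cluster_peaks([pl[i] for i in order], ClusterParams())
        np.testing.assert_allclose(pm1.cluster_mz, pm2.cluster_mz)

    def test_missing_values_filled_from_spectrum_or_zero(self):
        entries = [[(5000.0, 9.0, 6.0)], [(5000.0, 9.0, 6.0)], []]
        pm = cluster_peaks(_plist(entries), ClusterParams())
        assert pm.values[0, 2] == 0.0
        # with spectra provided, the local intensity is read instead
        grid = np.linspace(4000, 6000, 500)
        traces = np.vstack([np.full(500, 1.0)] * 3)
        metas = [SampleMeta(f"s{i}", 0.0, 3, 1) for i in range(3)]
        sset = SpectrumSet(grid, traces, meta_frame(metas))
        pm2 = cluster_peaks(_plist(entries), ClusterParams(), spectra=sset)
        assert pm2.values[0, 2] == 1.0

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            cluster_peaks(_plist([[], []]), ClusterParams(window_frac=0.0))


class TestQcCv:
    def _pm(self, rows):
        rows = np.asarray(rows, dtype=float)
        mzs = 3000.0 * (1.01 ** np.arange(rows.shape[0]))
        return PeakMatrix(mzs, rows, ["first"] * rows.shape[0],
                          [f"q{i}" for i in range(rows.shape[1])])

    def test_hand_values(self):
        pm = self._pm([[10, 10, 10], [8, 10, 12]])
        cvs, mean_cv = qc_cv(pm, ["q0", "q1", "q2"])
        np.testing.assert_allclose(cvs, [0.0, 0.2])
        assert mean_cv == pytest.approx(0.1)

    def test_zero_mean_cluster_flagged_and_excluded(self):
        pm = self._pm([[0, 0, 0], [8, 10, 12]])
        with pytest.warns(UserWarning):
            cvs, mean_cv = qc_cv(pm, ["q0", "q1", "q2"])
        assert np.isnan(cvs[0])
        assert mean_cv == pytest.approx(0.2)

    def test_requires_three_qc(self):
        with pytest.raises(ValueError):
            qc_cv(self._pm([[1, 1, 1]]), ["q0", "q1"])


class TestPipelineOnSyntheticSpectra:
    def test_first_pass_clusters_match_generator_truth(self, small_spectra):
        """Every generated peak is strong and ubiquitous, so the first pass
        alone recovers exactly the three true masses."""
        spectra, _ = small_spectra
        pm = spectra_to_peak_matrix(spectra)
        assert pm.n_clusters == 3
        assert all(p == "first" for p in pm.provenance)
        np.testing.assert_allclose(
            pm.cluster_mz, [3000.0, 5000.0, 8000.0], rtol=2e-3
        )

    def test_simulated_qc_cv_within_band(self):
        """Mean QC CV computed through the full peak pipeline lands in the
        technical-reproducibility band around the generated 0.15."""
        peaks = [PeakSpec(float(m), 60.0, 0.25) for m in
                 np.linspace(2500, 9500, 12)]
        cfg = SeldiSimConfig(true_peaks=peaks, grid_points=3000, n_per_group=4,
                             n_qc_replicates=12, qc_cv=0.15, seed=21)
        spectra, _ = generate_seldi_spectra(cfg)
        pm = spectra_to_peak_matrix(spectra)
        qc_ids = spectra.meta.loc[spectra.meta["is_qc_pool"], "sample_id"].tolist()
        _, mean_cv = qc_cv(pm, qc_ids)
        assert 0.10 <= mean_cv <= 0.20
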