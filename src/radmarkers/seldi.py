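"""SELDI-TOF spectral preprocessing: baseline, normalization, peaks, clusters.

The processing chain mirrors vendor practice for ProteinChip profiling:
baseline subtraction, total-ion-current normalization, per-spectrum peak
auto-detection, then cross-spectrum peak clustering in two passes -- a
strict first pass (S/N >= 2.5, peak present in >= 50% of spectra) and a
lenient completion pass (S/N >= 3.0, presence >= 10%) with a cluster
window of 0.3% of mass.  The vendor's exact detection algorithm is
undisclosed; the noise estimator (MAD of first differences) and the
rolling-minimum baseline used here are documented, configurable stand-ins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .containers import Peak, PeakMatrix, Spectrum, SpectrumSet

__all__ = [
    "ClusterParams",
    "subtract_baseline",
    "tic_normalize",
    "estimate_noise",
    "detect_peaks",
    "cluster_peaks",
    "qc_cv",
    "spectra_to_peak_matrix",
]


@dataclass
class ClusterParams:
    """Thresholds of the two-pass peak clustering."""

    first_pass_snr: float = 2.5
    first_pass_min_presence: float = 0.50
    completion_snr: float = 3.0
    completion_min_presence: float = 0.10
    window_frac: float = 0.003

    def validate(self) -> None:
        if self.window_frac <= 0:
            raise ValueError("window_frac must be > 0")
        for frac in (self.first_pass_min_presence, self.completion_min_presence):
            if not 0 < frac <= 1:
                raise ValueError("presence fractions must be in (0, 1]")


def subtract_baseline(s: Spectrum, window: float) -> Spectrum:
    """Remove a rolling-minimum-then-smoothed baseline; clip at zero.

    ``window`` is the baseline scale in Daltons; it should exceed the
    widest peak so apex heights survive (a flat offset is removed exactly,
    an isolated peak loses < 5% of its apex for windows >> peak width).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    step = float(np.median(np.diff(s.mz))) if s.mz.size > 1 else 1.0
    size = max(3, int(round(window / step)) | 1)  # odd
    rough = minimum_filter1d(s.intensity, size=size, mode="nearest")
    smooth = uniform_filter1d(rough, size=size, mode="nearest")
    return Spectrum(s.mz, np.clip(s.intensity - smooth, 0.0, None))


def tic_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Scale every spectrum so its total ion current equals the set mean."""
    totals = spectra.intensities.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"zero total ion current for sample {spectra.sample_ids[bad[0]]!r}"
        )
    target = totals.mean()
    return spectra.with_intensities(spectra.intensities * (target / totals)[:, None])


def estimate_noise(intensity: np.ndarray) -> float:
    """Gaussian noise sd from the MAD of first differences.

    For white noise, successive differences have sd = noise_sd * sqrt(2)
    and are insensitive to smooth baseline or sparse peaks; the MAD makes
    the estimate robust to the peak flanks.
    """
    d = np.diff(np.asarray(intensity, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    s: Spectrum,
    snr_threshold: float,
    smooth_points: int = 5,
    median_points: int = 201,
) -> list[Peak]:
    """Local maxima of a baseline-subtracted spectrum with S/N >= threshold.

    Noise is estimated on the raw trace (MAD of first differences); maxima
    are located on a lightly smoothed copy (moving average,
    ``smooth_points`` wide) after removing the local noise floor (rolling
    median over ``median_points``, wide compared to any peak), so a
    residual offset left by the baseline step cannot masquerade as
    signal.  Both apex height above the floor and prominence must clear
    ``snr_threshold * noise``.
    """
    if np.any(np.diff(s.mz) <= 0):
        raise ValueError("mz axis must be strictly ascending")
    noise = estimate_noise(s.intensity)
    if noise == 0.0:
        noise = 1e-12  # noiseless synthetic trace: any real maximum passes
    smoothed = uniform_filter1d(s.intensity, size=max(1, smooth_points), mode="nearest")
    floor_line = median_filter(smoothed, size=max(3, median_points) | 1, mode="nearest")
    detrended = smoothed - floor_line
    floor = snr_threshold * noise
    idx, _props = find_peaks(detrended, height=floor, prominence=floor)
    return [
        Peak(float(s.mz[i]), float(detrended[i]), float(detrended[i] / noise))
        for i in idx
    ]


def _link_clusters(
    pooled_mz: np.ndarray, window_frac: float
) -> list[np.ndarray]:
    """Single-linkage grouping of sorted masses: chain while the gap to the
    previous member is within window_frac of the local mass."""
    order = np.argsort(pooled_mz, kind="stable")
    groups: list[list[int]] = []
    prev = None
    for i in order:
        m = pooled_mz[i]
        if prev is not None and (m - prev) <= window_frac * 0.5 * (m + prev):
            groups[-1].append(i)
        else:
            groups.append([i])
        prev = m
    return [np.asarray(g) for g in groups]


def cluster_peaks(
    peaklists: list[list[Peak]],
    params: ClusterParams,
    spectra: SpectrumSet | None = None,
) -> PeakMatrix:
    """Group per-sample peaks into cross-spectrum clusters in two passes.

    Pass 1 links peaks with S/N >= ``first_pass_snr`` by single linkage
    within ``window_frac`` of mass and keeps clusters represented in at
    least ``first_pass_min_presence`` of the samples.  Clusters failing
    that bar are re-examined at S/N >= ``completion_snr`` and kept when
    present in >= ``completion_min_presence`` of samples (the completion
    pass).  Every detected peak therefore belongs to at most one cluster.

    For samples missing a cluster member, the intensity is read from that
    sample's processed spectrum at the cluster mass when ``spectra`` is
    given, otherwise filled with 0.
    """
    params.validate()
    n_samples = len(peaklists)
    if n_samples < 2:
        raise ValueError("need at least two samples to cluster peaks")
    if spectra is not None and len(spectra) != n_samples:
        raise ValueError("spectra and peaklists must align sample-by-sample")

    pool_snr = min(params.first_pass_snr, params.completion_snr)
    rows = [
        (pk.mz, pk.intensity, pk.snr, si)
        for si, plist in enumerate(peaklists)
        for pk in plist
        if pk.snr >= pool_snr
    ]
    clusters: list[tuple[float, str, dict[int, float]]] = []
    if rows:
        arr = np.asarray(rows, dtype=float)
        for grp in _link_clusters(arr[:, 0], params.window_frac):
            members = arr[grp]
            sub = members[members[:, 2] >= params.first_pass_snr]
            presence = len(set(sub[:, 3].astype(int))) / n_samples if sub.size else 0.0
            if presence >= params.first_pass_min_presence:
                label = "first"
            else:
                sub = members[members[:, 2] >= params.completion_snr]
                presence = len(set(sub[:, 3].astype(int))) / n_samples if sub.size else 0.0
                if presence < params.completion_min_presence:
                    continue
                label = "completion"
            center = float(np.average(sub[:, 0], weights=sub[:, 1]))
            by_sample: dict[int, float] = {}
            for mz_i, inten, _snr, si in sub:
                si = int(si)
                by_sample[si] = max(by_sample.get(si, 0.0), float(inten))
            clusters.append((center, label, by_sample))

    clusters.sort(key=lambda c: c[0])
    # enforce separation: merge any centers still within one window
    merged: list[tuple[float, str, dict[int, float]]] = []
    for c in clusters:
        if merged and (c[0] - merged[-1][0]) <= params.window_frac * c[0]:
            prev = merged.pop()
            members = dict(prev[2])
            for si, v in c[2].items():
                members[si] = max(members.get(si, 0.0), v)
            label = "first" if "first" in (prev[1], c[1]) else "completion"
            w_prev, w_new = sum(prev[2].values()), sum(c[2].values())
            center = (prev[0] * w_prev + c[0] * w_new) / (w_prev + w_new)
            merged.append((center, label, members))
        else:
            merged.append(c)

    cluster_mz = np.array([c[0] for c in merged])
    provenance = [c[1] for c in merged]
    values = np.zeros((len(merged), n_samples))
    for ci, (center, _label, by_sample) in enumerate(merged):
        for si in range(n_samples):
            if si in by_sample:
                values[ci, si] = by_sample[si]
            elif spectra is not None:
                gi = int(np.searchsorted(spectra.mz, center))
                gi = min(max(gi, 0), spectra.mz.size - 1)
                values[ci, si] = max(0.0, float(spectra.intensities[si, gi]))

    sample_ids = spectra.sample_ids if spectra is not None else [
        f"sample{idx:03d}" for idx in range(n_samples)
    ]
    return PeakMatrix(cluster_mz, values, provenance, sample_ids, params.window_frac)


def qc_cv(pm: PeakMatrix, qc_sample_ids: list[str]) -> tuple[np.ndarray, float]:
    """Per-cluster coefficient of variation across QC-pool replicates.

    CV = sd / mean with the sample (ddof=1) convention.  Clusters whose QC
    mean is zero are flagged NaN and excluded from the summary mean.
    Returns (per-cluster CVs, mean CV over valid clusters).
    """
    if len(qc_sample_ids) < 3:
        raise ValueError("need at least 3 QC replicates")
    cols = [pm.sample_ids.index(sid) for sid in qc_sample_ids]
    q = pm.values[:, cols]
    means = q.mean(axis=1)
    cvs = np.full(pm.n_clusters, np.nan)
    ok = means != 0
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} cluster(s) with zero QC mean excluded from CV")
    cvs[ok] = q[ok].std(axis=1, ddof=1) / means[ok]
    return cvs, float(np.nanmean(cvs)) if ok.any() else float("nan")


def spectra_to_peak_matrix(
    spectra: SpectrumSet,
    params: ClusterParams | None = None,
    baseline_window: float = 250.0,
    normalize: bool = True,
) -> PeakMatrix:
    """Full chain: baseline subtraction, TIC normalization, detection and
    two-pass clustering, yielding a clusters x samples intensity table."""
    params = params or ClusterParams()
    processed = np.vstack(
        [subtract_baseline(spectra.spectrum(i), baseline_window).intensity
         for i in range(len(spectra))]
    )
    sset = spectra.with_intensities(processed)
    if normalize:
        sset = tic_normalize(sset)
    detect_at = min(params.first_pass_snr, params.completion_snr)
    peaklists = [detect_peaks(sset.spectrum(i), detect_at) for i in range(len(sset))]
    return cluster_peaks(peaklists, params, spectra=sset)
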