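"""Synthetic 2D-DIGE spot matrices and SELDI-TOF spectra with planted truth.

The generators emulate the study design of a mouse cutaneous-radiation-
syndrome experiment: four dose groups (0, 20, 40, 80 Gy), serum sampled on
day 3 or 7, two independent experimental series (batches), 16 animals per
dose and day for the gel platform and 32 for the MS platform.

Gel-spot abundances are modeled log-normally: a per-feature baseline
log-level, an additive per-(batch, feature) nuisance term, an additive
log fold-change for planted markers, and residual log-noise.  Dye effects
are folded into the batch term (the dye-swap design cancels them in
expectation).  SELDI spectra are sums of Gaussian peaks with per-spectrum
multiplicative mass jitter, a smooth decaying baseline and white noise;
the latent per-sample peak intensities are returned alongside for oracle
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import (
    BATCH_LEVELS,
    DOSE_LEVELS,
    ConfigurationError,
    DesignError,
    LabeledMatrix,
    SampleMeta,
    SpectrumSet,
    meta_frame,
)

__all__ = [
    "MarkerSpec",
    "DigeSimConfig",
    "PeakSpec",
    "SeldiSimConfig",
    "generate_dige_dataset",
    "generate_seldi_spectra",
    "default_seldi_peaks",
    "table1_like_markers",
]


@dataclass(frozen=True)
class MarkerSpec:
    """A planted differentially abundant feature.

    mode='exposure' multiplies all irradiated groups (dose > 0) by
    ``fold_change_per_level``; mode='dose_monotone' multiplies by
    ``fold_change_per_level ** level`` where level is the dose rank
    (0 Gy -> 0, 20 -> 1, 40 -> 2, 80 -> 3).  Ratios < 1 plant
    down-regulation, mirroring the signed fold-change convention in which
    -1.6 means a 1.6-fold decrease.
    """

    feature_index: int
    mode: str  # {"exposure", "dose_monotone"}
    fold_change_per_level: float

    def __post_init__(self) -> None:
        if self.mode not in ("exposure", "dose_monotone"):
            raise ConfigurationError(f"unknown marker mode {self.mode!r}")
        if self.fold_change_per_level <= 0:
            raise ConfigurationError("fold_change_per_level must be > 0")
        if self.fold_change_per_level == 1.0:
            raise ConfigurationError("a planted marker needs fold_change_per_level != 1")


@dataclass
class DigeSimConfig:
    """Parameters of the gel-spot matrix generator (log-normal model)."""

    n_features: int = 941
    n_per_group: int = 16
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.5
    batch_sd: float = 0.1
    residual_sd: float = 0.3
    markers: Sequence[MarkerSpec] = ()
    doses: Sequence[float] = DOSE_LEVELS
    n_qc_pool: int = 0
    qc_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_per_group < 2:
            raise DesignError("n_per_group must be >= 2")
        for sd in (self.baseline_log_sd, self.batch_sd, self.residual_sd):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        for mk in self.markers:
            if not 0 <= mk.feature_index < self.n_features:
                raise ConfigurationError(
                    f"marker feature_index {mk.feature_index} outside 0..{self.n_features - 1}"
                )


@dataclass(frozen=True)
class PeakSpec:
    """A true SELDI peak: nominal mass, mean apex intensity, biological CV,
    and the fraction of sample spectra in which it occurs."""

    mz: float
    mean_intensity: float
    cv: float
    presence: float = 1.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("peak cv must be >= 0")
        if not 0 < self.presence <= 1:
            raise ConfigurationError("peak presence must be in (0, 1]")


@dataclass
class SeldiSimConfig:
    """Parameters of the spectrum generator (low-mass acquisition window)."""

    mz_min: float = 1800.0
    mz_max: float = 10000.0
    grid_points: int = 6000
    true_peaks: Sequence[PeakSpec] | None = None
    mass_jitter_frac: float = 0.001
    noise_sd: float = 1.0
    baseline_amplitude: float = 20.0
    peak_width_frac: float = 0.002
    n_per_group: int = 32
    n_qc_replicates: int = 16
    qc_cv: float = 0.15
    doses: Sequence[float] = DOSE_LEVELS
    day: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ConfigurationError("mz_min must be < mz_max")
        if self.n_per_group < 2:
            raise DesignError("n_per_group must be >= 2")
        if self.true_peaks is not None:
            mzs = [p.mz for p in self.true_peaks]
            if sorted(mzs) != mzs:
                raise ConfigurationError("true_peaks must be sorted by mz")
            step = (self.mz_max - self.mz_min) / (self.grid_points - 1)
            gaps = np.diff(mzs)
            if gaps.size and gaps.min() < 3 * step:
                raise ConfigurationError(
                    "grid too coarse: adjacent true peaks closer than 3 grid steps"
                )


def _rng(seed_parts: Sequence[int]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(seed_parts)))


#: (exposure fold, max dose fold highest-vs-lowest irradiated) patterns of the
#: default planted acute-phase-like panel; None means no effect on that axis.
_DEFAULT_MARKER_PANEL: tuple[tuple[float | None, float | None], ...] = (
    (7.1, 2.5),     # strong positive acute-phase reactant (haptoglobin-like)
    (1.9, 1.6),     # strong up in both axes
    (1.7, None),    # exposure-only up
    (-1.6, -1.3),   # down-regulated protease inhibitor-like
    (-1.3, None),
    (1.2, 1.2),
    (-1.2, -1.3),
    (-1.2, None),
    (1.2, 1.1),
    (1.1, None),
    (1.1, 1.1),
    (-1.1, 1.2),    # opposite trends on the two axes
    (None, -1.3),
    (None, 1.3),
    (None, -1.3),
)


def table1_like_markers(n_features: int = 941) -> list[MarkerSpec]:
    """The default planted-marker panel used by the end-to-end study config.

    Fifteen features carry effects with the magnitude structure typical of
    acute-phase serum responses to high-dose skin irradiation: mostly
    small (1.1 to 2.0-fold, either direction) exposure and dose trends,
    one large 7.1-fold up-regulation.  Signed folds follow the convention
    that -1.6 is a 1.6-fold decrease.  Dose trends are planted per dose
    level: the per-level ratio is the square root of the max fold, since
    the highest and lowest irradiated groups sit two levels apart.
    """
    specs: list[MarkerSpec] = []
    step = max(1, n_features // (len(_DEFAULT_MARKER_PANEL) + 1))
    for k, (exp_fold, dose_fold) in enumerate(_DEFAULT_MARKER_PANEL):
        idx = k * step
        if exp_fold is not None:
            fc = exp_fold if exp_fold > 0 else -1.0 / exp_fold
            specs.append(MarkerSpec(idx, "exposure", fc))
        if dose_fold is not None:
            mag = dose_fold if dose_fold > 0 else -1.0 / dose_fold
            per_level = mag ** 0.5
            if dose_fold < 0:
                per_level = 1.0 / per_level
            specs.append(MarkerSpec(idx, "dose_monotone", per_level))
    return specs


def generate_dige_dataset(config: DigeSimConfig, day: int) -> LabeledMatrix:
    """Simulate a (doses x n_per_group) samples by n_features spot matrix.

    Reproducible from ``config.seed`` and ``day``; the two sampling days
    are independent draws, as they come from distinct animals.
    """
    config.validate()
    rng = _rng([config.seed, int(day)])
    doses = [float(d) for d in config.doses]
    n_grp = config.n_per_group
    p = config.n_features

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    batch_eff = {b: rng.normal(0.0, config.batch_sd, size=p) for b in BATCH_LEVELS}

    shift = np.zeros((len(doses), p))
    for mk in config.markers:
        log_fc = np.log(mk.fold_change_per_level)
        for gi, dose in enumerate(doses):
            if mk.mode == "exposure":
                level = 1 if dose > 0 else 0
            else:
                level = gi
            shift[gi, mk.feature_index] += log_fc * level

    rows, metas = [], []
    for gi, dose in enumerate(doses):
        for i in range(n_grp):
            batch = BATCH_LEVELS[0] if i < n_grp // 2 else BATCH_LEVELS[1]
            logv = (
                mu
                + batch_eff[batch]
                + shift[gi]
                + rng.normal(0.0, config.residual_sd, size=p)
            )
            rows.append(np.exp(logv))
            metas.append(
                SampleMeta(f"d{day}_g{int(dose):02d}_{i:02d}", dose, int(day), batch)
            )

    if config.n_qc_pool:
        # QC pool = mean of the expected linear group-mean vectors, with only
        # technical noise, mirroring a pooled internal standard.
        group_means = np.exp(mu[None, :] + shift)
        pool = group_means.mean(axis=0)
        sigma_t = np.sqrt(np.log1p(config.qc_cv**2))
        for i in range(config.n_qc_pool):
            noise = rng.normal(0.0, sigma_t, size=p)
            rows.append(pool * np.exp(noise - sigma_t**2 / 2))
            metas.append(SampleMeta(f"d{day}_qc_{i:02d}", 0.0, int(day), 1, True))

    feature_ids = [f"spot{j:04d}" for j in range(p)]
    return LabeledMatrix(np.vstack(rows), feature_ids, meta_frame(metas))


def default_seldi_peaks(
    n_peaks: int = 120,
    mz_min: float = 1800.0,
    mz_max: float = 10000.0,
    seed: int = 12345,
    snr_range: tuple[float, float] = (4.0, 60.0),
    noise_sd: float = 1.0,
    cv: float = 0.3,
) -> list[PeakSpec]:
    """A realistic fully-present peak population: log-spaced masses with
    small random offsets, log-uniform apex intensities."""
    rng = np.random.default_rng(seed)
    log_pos = np.linspace(np.log(mz_min * 1.02), np.log(mz_max * 0.98), n_peaks)
    log_pos += rng.uniform(-0.2, 0.2, n_peaks) * np.diff(log_pos).mean()
    mzs = np.sort(np.exp(log_pos))
    amps = noise_sd * np.exp(
        rng.uniform(np.log(snr_range[0]), np.log(snr_range[1]), n_peaks)
    )
    return [PeakSpec(float(m), float(a), cv) for m, a in zip(mzs, amps)]


def _add_gaussian(out: np.ndarray, grid: np.ndarray, pos: float, amp: float, sigma: float) -> None:
    lo = np.searchsorted(grid, pos - 5 * sigma)
    hi = np.searchsorted(grid, pos + 5 * sigma)
    if hi > lo:
        out[lo:hi] += amp * np.exp(-0.5 * ((grid[lo:hi] - pos) / sigma) ** 2)


def generate_seldi_spectra(
    config: SeldiSimConfig,
) -> tuple[SpectrumSet, LabeledMatrix]:
    """Simulate per-sample spectra plus the latent true peak-intensity matrix.

    Returns
    -------
    spectra : SpectrumSet
        One spectrum per animal (doses x n_per_group) followed by
        ``n_qc_replicates`` QC-pool spectra.
    truth : LabeledMatrix
        Latent per-sample apex intensities of every true peak (0 where the
        peak is absent from that spectrum), for oracle comparisons.
    """
    config.validate()
    peaks = list(
        config.true_peaks
        if config.true_peaks is not None
        else default_seldi_peaks(
            mz_min=config.mz_min, mz_max=config.mz_max, noise_sd=config.noise_sd
        )
    )
    rng = _rng([config.seed, 7])
    grid = np.linspace(config.mz_min, config.mz_max, config.grid_points)
    doses = [float(d) for d in config.doses]
    n_samples = len(doses) * config.n_per_group
    k = len(peaks)

    baseline = config.baseline_amplitude * np.exp(
        -3.0 * (grid - config.mz_min) / (config.mz_max - config.mz_min)
    )

    metas, traces, truth_rows = [], [], []
    for gi, dose in enumerate(doses):
        for i in range(config.n_per_group):
            batch = BATCH_LEVELS[0] if i < config.n_per_group // 2 else BATCH_LEVELS[1]
            metas.append(
                SampleMeta(f"s_d{config.day}_g{int(dose):02d}_{i:02d}", dose, config.day, batch)
            )
    for i in range(config.n_qc_replicates):
        metas.append(SampleMeta(f"s_d{config.day}_qc_{i:02d}", 0.0, config.day, 1, True))

    for si in range(n_samples + config.n_qc_replicates):
        is_qc = si >= n_samples
        trace = baseline + rng.normal(0.0, config.noise_sd, size=grid.size)
        truth = np.zeros(k)
        for pi, pk in enumerate(peaks):
            if is_qc:
                present = True
                sigma_ln = np.sqrt(np.log1p(config.qc_cv**2))
            else:
                present = bool(rng.random() < pk.presence)
                sigma_ln = np.sqrt(np.log1p(pk.cv**2))
            # draw even when absent to keep the random stream per-sample stable
            amp = pk.mean_intensity * np.exp(
                rng.normal(0.0, sigma_ln) - sigma_ln**2 / 2
            )
            pos = pk.mz * (1.0 + rng.uniform(-config.mass_jitter_frac, config.mass_jitter_frac))
            if present:
                truth[pi] = amp
                _add_gaussian(trace, grid, pos, amp, config.peak_width_frac * pk.mz)
        traces.append(trace)
        truth_rows.append(truth)

    meta = meta_frame(metas)
    spectra = SpectrumSet(grid, np.vstack(traces), meta)
    truth_ids = [f"peak{pi:03d}_{pk.mz:.1f}" for pi, pk in enumerate(peaks)]
    truth_m = LabeledMatrix(np.vstack(truth_rows), truth_ids, meta.copy())
    return spectra, truth_m
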