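"""Core in-memory containers shared by every pipeline stage.

The study design is fixed by the experiment being emulated: mice receive a
single localized skin dose of 0, 20, 40 or 80 Gy, serum is sampled on day 3
or day 7 post-irradiation, and animals come from one of two independent
experimental series (batches).  Quantitative data arrive either as a
samples x features intensity matrix (gel spot volumes or clustered MS peak
intensities, linear scale) or as per-sample m/z--intensity traces on a
shared, strictly ascending mass grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DOSE_LEVELS = (0.0, 20.0, 40.0, 80.0)
DAY_LEVELS = (3, 7)
BATCH_LEVELS = (1, 2)

META_COLUMNS = ["sample_id", "dose_gy", "day", "batch", "is_qc_pool"]


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class DesignError(ValueError):
    """A requested analysis is impossible under the declared study design."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: identity, dose, sampling day, series, QC flag."""

    sample_id: str
    dose_gy: float
    day: int
    batch: int
    is_qc_pool: bool = False

    def __post_init__(self) -> None:
        if self.dose_gy not in DOSE_LEVELS:
            raise ConfigurationError(
                f"dose_gy={self.dose_gy} not in declared levels {DOSE_LEVELS}"
            )
        if self.day not in DAY_LEVELS:
            raise ConfigurationError(f"day={self.day} not in declared levels {DAY_LEVELS}")
        if self.batch not in BATCH_LEVELS:
            raise ConfigurationError(f"batch={self.batch} not in declared levels {BATCH_LEVELS}")


def meta_frame(metas: Iterable[SampleMeta]) -> pd.DataFrame:
    """Assemble a metadata DataFrame from SampleMeta records."""
    rows = [
        (m.sample_id, float(m.dose_gy), int(m.day), int(m.batch), bool(m.is_qc_pool))
        for m in metas
    ]
    return pd.DataFrame(rows, columns=META_COLUMNS)


@dataclass
class LabeledMatrix:
    """A samples x features matrix of linear-scale, non-negative intensities.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Normalized abundances (spot volume ratios or peak intensities).
    feature_ids : list of str
        One identifier per column.
    meta : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``dose_gy``, ``day``,
        ``batch``, ``is_qc_pool``.  Accepts an iterable of
        :class:`SampleMeta` as well.
    """

    values: np.ndarray
    feature_ids: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = meta_frame(self.meta)
        self.meta = self.meta.reset_index(drop=True)
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D samples x features array")
        if self.values.shape[0] != len(self.meta):
            raise ConfigurationError(
                f"{self.values.shape[0]} rows but {len(self.meta)} metadata records"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ConfigurationError(
                f"{self.values.shape[1]} columns but {len(self.feature_ids)} feature ids"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ConfigurationError(f"metadata is missing columns {missing}")
        ids = self.meta["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate sample_id {dup!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ConfigurationError("feature_ids are not unique")
        if np.isnan(self.values).any():
            raise ConfigurationError("values contain missing entries")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    def log_values(self) -> np.ndarray:
        """Natural-log intensities; statistics downstream run on this scale."""
        if (self.values <= 0).any():
            raise ValueError("non-positive intensity; cannot log-transform")
        return np.log(self.values)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, mask: np.ndarray) -> "LabeledMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LabeledMatrix(
            self.values[idx], list(self.feature_ids), self.meta.iloc[idx].reset_index(drop=True)
        )

    def subset_features(self, features: Sequence[str] | Sequence[int]) -> "LabeledMatrix":
        if len(features) and isinstance(features[0], str):
            lookup = {f: j for j, f in enumerate(self.feature_ids)}
            idx = [lookup[f] for f in features]
        else:
            idx = list(features)  # type: ignore[arg-type]
        return LabeledMatrix(
            self.values[:, idx], [self.feature_ids[j] for j in idx], self.meta.copy()
        )

    def cell_mask(self, cells: Iterable[tuple[float, int]], include_qc: bool = False) -> np.ndarray:
        """Boolean mask of samples belonging to any (dose, day) design cell."""
        cells = {(float(d), int(t)) for d, t in cells}
        pairs = list(zip(self.meta["dose_gy"], self.meta["day"]))
        mask = np.array([(float(d), int(t)) in cells for d, t in pairs])
        if not include_qc:
            mask &= ~self.meta["is_qc_pool"].to_numpy(dtype=bool)
        return mask


@dataclass
class Spectrum:
    """One m/z--intensity trace with a strictly ascending mass axis."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("empty spectrum")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz axis must be strictly ascending")


@dataclass
class SpectrumSet:
    """Per-sample spectra on one shared ascending m/z grid."""

    mz: np.ndarray
    intensities: np.ndarray  # (n_samples, n_points)
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = meta_frame(self.meta)
        self.meta = self.meta.reset_index(drop=True)
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("shared mz grid must be strictly ascending")
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.mz.size:
            raise ValueError("intensities must be (n_samples, n_grid_points)")
        if self.intensities.shape[0] != len(self.meta):
            raise ValueError("one metadata record per spectrum required")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.mz, self.intensities[i])

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(self.mz, intensities, self.meta.copy())


@dataclass(frozen=True)
class Peak:
    """A detected local maximum: position, apex intensity, signal-to-noise."""

    mz: float
    intensity: float
    snr: float


@dataclass
class PeakMatrix:
    """Clusters x samples intensity table with representative cluster masses.

    ``provenance`` records for every cluster whether it survived the strict
    first detection pass or was added by the lenient completion pass.
    """

    cluster_mz: np.ndarray
    values: np.ndarray  # (n_clusters, n_samples)
    provenance: list[str]
    sample_ids: list[str]
    window_frac: float = 0.003

    def __post_init__(self) -> None:
        self.cluster_mz = np.asarray(self.cluster_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.cluster_mz.size, len(self.sample_ids)):
            raise ValueError("values must be (n_clusters, n_samples)")
        if len(self.provenance) != self.cluster_mz.size:
            raise ValueError("one provenance label per cluster required")
        if np.any(np.diff(self.cluster_mz) <= 0):
            raise ValueError("cluster masses must be strictly ascending")
        gaps = np.diff(self.cluster_mz)
        limits = self.window_frac * self.cluster_mz[1:]
        if np.any(gaps <= limits):
            raise ValueError("adjacent clusters closer than the cluster window")

    @property
    def n_clusters(self) -> int:
        return self.cluster_mz.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "provenance", self.provenance)
        df.insert(0, "cluster_mz", self.cluster_mz)
        return df
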