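"""Per-feature screening statistics over declared group comparisons.

Comparisons are declared as two disjoint sets of (dose, day) design cells,
e.g. all sham-irradiated vs. all irradiated animals of one sampling day,
or 20 Gy vs. the pooled 40+80 Gy groups.  For every feature the module
computes a one-way fixed-effects ANOVA p-value, a Monte-Carlo permutation
p-value for the two-sided difference of group means, a
Benjamini--Yekutieli FDR-adjusted q-value (valid under arbitrary
dependence, applied over the totality of the features), and a signed
linear-scale fold change (+2 and -2 are symmetric two-fold changes).
Tests run on log-transformed intensities; fold changes are reported on
the linear scale.  Candidate features are the union, over comparisons, of
features with unadjusted ANOVA p below a threshold (0.05 by default),
matching the screening stage whose redundancy-deduplicated union feeds
the multivariate selectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DesignError, LabeledMatrix

__all__ = [
    "Comparison",
    "AnovaResult",
    "anova_per_feature",
    "fold_change_signed",
    "permutation_test",
    "by_adjust",
    "comparison_stats",
    "select_candidates",
]

Cell = tuple[float, int]


@dataclass(frozen=True)
class Comparison:
    """A named two-sided contrast between sets of (dose_gy, day) cells."""

    name: str
    left: frozenset[Cell]
    right: frozenset[Cell]

    def __post_init__(self) -> None:
        left = frozenset((float(d), int(t)) for d, t in self.left)
        right = frozenset((float(d), int(t)) for d, t in self.right)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        if not left or not right:
            raise DesignError(f"comparison {self.name!r} has an empty side")
        if left & right:
            raise DesignError(f"comparison {self.name!r} has overlapping sides")

    def sides(self, m: LabeledMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (left, right), excluding QC-pool rows."""
        lm, rm = m.cell_mask(self.left), m.cell_mask(self.right)
        if lm.sum() == 0 or rm.sum() == 0:
            raise DesignError(f"comparison {self.name!r}: no samples on one side")
        return lm, rm

    def labels(self, m: LabeledMatrix) -> tuple[np.ndarray, np.ndarray]:
        """(row mask of involved samples, binary labels with left=1)."""
        lm, rm = self.sides(m)
        mask = lm | rm
        return mask, lm[mask].astype(int)


class AnovaResult(NamedTuple):
    p: np.ndarray
    degenerate: np.ndarray  # features with zero variance everywhere


def anova_per_feature(values: np.ndarray, grouping: np.ndarray) -> AnovaResult:
    """One-way fixed-effects ANOVA p-value per column.

    ``values`` should already be log-transformed.  Features whose within-
    group variance is zero with equal group means carry no information;
    they are flagged and assigned p = 1.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    levels = np.unique(grouping)
    if levels.size < 2:
        raise DesignError("ANOVA needs at least two groups")
    groups = [values[grouping == g] for g in levels]
    if min(g.shape[0] for g in groups) < 2:
        raise DesignError("ANOVA needs at least two samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs raise a scipy warning
        f, p = stats.f_oneway(*groups, axis=0)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    return AnovaResult(p, degenerate)


def fold_change_signed(
    m: LabeledMatrix, comparison: Comparison
) -> np.ndarray:
    """Signed linear fold change per feature: +r when mean(left)/mean(right)
    = r >= 1, else -1/r; equal means give +1.0 (displayed '=')."""
    lm, rm = comparison.sides(m)
    left = m.values[lm].mean(axis=0)
    right = m.values[rm].mean(axis=0)
    if (left <= 0).any() or (right <= 0).any():
        raise ValueError("non-positive group mean; fold change undefined")
    r = left / right
    return np.where(r >= 1.0, r, -1.0 / r)


def format_fold_change(fc: float) -> str:
    """Table-style display: '=' for no change, signed ratio otherwise."""
    if np.isclose(abs(fc), 1.0):
        return "="
    return f"{fc:+.1f}"


def permutation_test(
    values: np.ndarray,
    side_labels: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = 0,
    stratify: np.ndarray | None = None,
) -> np.ndarray:
    """Monte-Carlo permutation p-values for |difference of group means|.

    Labels are permuted jointly across features, so the permutation null
    preserves the between-feature correlation.  p = (b + 1) / (B + 1)
    where b counts permuted statistics >= the observed one.  ``stratify``
    optionally restricts permutations to within-stratum swaps (e.g. the
    experimental series) without changing the statistic.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    values = np.asarray(values, dtype=float)
    y = np.asarray(side_labels).astype(bool)
    n = y.size
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise DesignError("each side needs at least two samples")
    obs = np.abs(values[y].mean(axis=0) - values[~y].mean(axis=0))

    rng = np.random.default_rng(seed)
    perm_y = np.empty((n_perm, n), dtype=bool)
    base = y.copy()
    if stratify is None:
        for b in range(n_perm):
            perm_y[b] = rng.permutation(base)
    else:
        strata = np.asarray(stratify)
        for b in range(n_perm):
            row = base.copy()
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                row[idx] = row[idx[rng.permutation(idx.size)]]
            perm_y[b] = row

    pf = perm_y.astype(float)
    sums1 = pf @ values  # (n_perm, n_features)
    counts1 = pf.sum(axis=1, keepdims=True)
    total = values.sum(axis=0, keepdims=True)
    means1 = sums1 / counts1
    means0 = (total - sums1) / (n - counts1)
    perm_stat = np.abs(means1 - means0)
    exceed = (perm_stat >= obs[None, :] - 1e-12).sum(axis=0)
    return (exceed + 1.0) / (n_perm + 1.0)


def by_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini--Yekutieli step-up adjusted q-values (arbitrary dependence).

    q_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) with the harmonic
    factor c(m) = sum_{k<=m} 1/k; delegates to the standard step-up
    implementation.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def comparison_stats(
    m: LabeledMatrix,
    comparison: Comparison,
    n_perm: int = 9999,
    seed: int | None = 0,
    stratify_by_batch: bool = False,
) -> pd.DataFrame:
    """Full per-feature statistics table for one comparison.

    Columns: p_anova, p_perm, q_by (BY over all features of the
    comparison, applied to the permutation p-values), fold_change,
    mean_left, mean_right, degenerate.
    """
    mask, labels = comparison.labels(m)
    sub = m.subset_samples(mask)
    logv = sub.log_values()
    anova = anova_per_feature(logv, labels)
    strat = sub.meta["batch"].to_numpy() if stratify_by_batch else None
    p_perm = permutation_test(logv, labels, n_perm=n_perm, seed=seed, stratify=strat)
    fc = fold_change_signed(m, comparison)
    lmask, rmask = comparison.sides(m)
    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "p_anova": anova.p,
            "p_perm": p_perm,
            "q_by": by_adjust(p_perm),
            "fold_change": fc,
            "mean_left": m.values[lmask].mean(axis=0),
            "mean_right": m.values[rmask].mean(axis=0),
            "degenerate": anova.degenerate,
        }
    ).set_index("feature_id")


def select_candidates(
    tables: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[list[str], dict[str, int]]:
    """Union of features with unadjusted ANOVA p < alpha over comparisons.

    Returns the deduplicated candidate id list (in feature order of the
    first table) and the per-comparison selected counts.  An empty union
    is reported with a warning, not an error.
    """
    counts: dict[str, int] = {}
    chosen: set[str] = set()
    order: list[str] = []
    for name, table in tables.items():
        hits = table.index[table["p_anova"] < alpha]
        counts[name] = int(len(hits))
        for f in hits:
            if f not in chosen:
                chosen.add(f)
                order.append(f)
    if not chosen:
        warnings.warn("candidate union is empty at the requested alpha")
    return order, counts
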