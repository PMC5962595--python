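"""Equal-weight multi-model combination, inter-model spread, and scenario tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import LatLonGrid


@dataclass
class EnsembleSet:
    """Same-typed gridded fields, one per model, with normalized weights.

    Default weights are equal (1/N). Missing-cell policy is strict
    intersection: a cell missing in any member is missing in every derived
    statistic unless ``ensemble_mean(..., skip_missing=True)``.
    """

    grid: LatLonGrid
    label_year: int
    members: np.ndarray  # (n_models, n_lat, n_lon)
    model_ids: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 3 or self.members.shape[1:] != self.grid.shape:
            raise ValueError("members must have shape (n_models, n_lat, n_lon)")
        n = self.members.shape[0]
        if not self.model_ids:
            self.model_ids = [f"model_{i}" for i in range(n)]
        if len(self.model_ids) != n:
            raise ValueError("model_ids length must match member count")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights must be one per member")
            if not np.isclose(self.weights.sum(), 1.0):
                raise ValueError("weights must sum to 1")

    @property
    def n_models(self) -> int:
        return self.members.shape[0]

    @classmethod
    def from_gdd_fields(cls, fields, model_ids=None, weights=None) -> "EnsembleSet":
        first = fields[0]
        for f in fields[1:]:
            if f.grid != first.grid:
                raise ValueError("ensemble members must share a grid")
            if f.label_year != first.label_year:
                raise ValueError("ensemble members must share a label_year")
        return cls(
            first.grid,
            first.label_year,
            np.stack([f.gdd for f in fields]),
            list(model_ids) if model_ids else [],
            weights,
        )


def _any_missing(ens: EnsembleSet) -> np.ndarray:
    return np.isnan(ens.members).any(axis=0)


def ensemble_mean(ens: EnsembleSet, skip_missing: bool = False) -> np.ndarray:
    """Cellwise weighted mean. Strict policy: any member missing -> NaN;
    ``skip_missing=True`` renormalizes weights over present members."""
    if skip_missing:
        w = ens.weights[:, None, None]
        ok = ~np.isnan(ens.members)
        wsum = (w * ok).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.nansum(w * ens.members, axis=0) / wsum
        out[wsum == 0] = np.nan
        return out
    out = (ens.weights[:, None, None] * ens.members).sum(axis=0)
    out[_any_missing(ens)] = np.nan
    return out


def ensemble_range(ens: EnsembleSet) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise (min, max) across members; strict missing policy."""
    bad = _any_missing(ens)
    lo = np.min(np.where(np.isnan(ens.members), np.inf, ens.members), axis=0)
    hi = np.max(np.where(np.isnan(ens.members), -np.inf, ens.members), axis=0)
    lo[bad] = np.nan
    hi[bad] = np.nan
    return lo, hi


def ensemble_cv(ens: EnsembleSet) -> np.ndarray:
    """Coefficient of variation: sample sd (n-1 denominator) / mean, cellwise.

    NaN where the mean is zero or any member is missing.
    """
    if ens.n_models < 2:
        raise ValueError("ensemble_cv requires at least 2 members")
    mean = ens.members.mean(axis=0)
    sd = ens.members.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / np.where(mean != 0, mean, 1), np.nan)
    cv[_any_missing(ens)] = np.nan
    return cv


@dataclass
class ScenarioSummary:
    """One summary number per period for a scenario family."""

    scenario: str  # e.g. "emission" or "transient"
    period_labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.period_labels),):
            raise ValueError("one value per period label required")


def compare_scenarios(a: ScenarioSummary, b: ScenarioSummary) -> dict:
    """Two-sided variance-ratio F test plus pooled-variance two-sample t test.

    Returns ``{"f_statistic", "f_pvalue", "t_statistic", "t_pvalue",
    "degenerate"}``; ``degenerate`` is True when both samples have zero
    variance (t undefined; t fields are NaN then).
    """
    if len(a.values) != len(b.values):
        raise ValueError("scenario summaries must have equal period counts")
    if len(a.values) < 2:
        raise ValueError("need at least 2 periods per scenario")
    xa, xb = a.values, b.values
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    dfa, dfb = len(xa) - 1, len(xb) - 1
    if va == 0 and vb == 0:
        f_stat, f_p = 1.0, 1.0
        return {
            "f_statistic": f_stat,
            "f_pvalue": f_p,
            "t_statistic": float("nan"),
            "t_pvalue": float("nan"),
            "degenerate": True,
        }
    if vb == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = va / vb
        cdf = stats.f.cdf(f_stat, dfa, dfb)
        f_p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    t_stat, t_p = stats.ttest_ind(xa, xb, equal_var=True)
    return {
        "f_statistic": float(f_stat),
        "f_pvalue": float(f_p),
        "t_statistic": float(t_stat),
        "t_pvalue": float(t_p),
        "degenerate": False,
    }
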