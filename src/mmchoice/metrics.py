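"""Relative attribute importance and minimal-acceptable-benefit trade-offs.

Relative attribute importance (RAI) summarizes part-worth utilities: an
attribute's utility range (best minus worst level, reference included at
zero) divided by the sum of all ranges, as a percentage.  RAI is
conditional on the level ranges shown and sums to 100%.

The minimal acceptable benefit (MAB, a marginal rate of substitution) is
the gain on a benefit attribute's numeric scale that exactly offsets the
utility loss of a specified risk or administration change.  The benefit
utility is linearized over its full level range, so one scale unit is
worth ``range / scale_width`` utils — e.g. per ORR percentage point,
``range_ORR / 60``.  Uncertainty for both quantities comes from
Krinsky–Robb simulation: coefficient vectors are drawn from the estimated
multivariate normal and the metric recomputed per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attributes import AttributeSpec
from .estimate import ECLFit
from .model import UtilityParameters

__all__ = [
    "STUDY_RAI_PERCENT",
    "RAIResult",
    "MABResult",
    "compute_rai",
    "rai_confidence_intervals",
    "compute_mab",
    "params_from_fit",
]

# Relative-importance scores reported by the multinational RRMM preference
# study this package models (duration of response is the remainder to 100).
STUDY_RAI_PERCENT: dict[str, float] = {
    "orr": 29.8,
    "os": 20.4,
    "administration": 12.4,
    "crs": 11.9,
    "neuropathy": 9.2,
    "vision": 7.1,
    "diarrhea": 3.0,
    "dor": 6.2,
}


@dataclass
class RAIResult:
    """Per-attribute importance (percent, summing to 100) with optional
    Krinsky–Robb percentile confidence intervals."""

    table: pd.DataFrame  # columns: attribute, importance_percent[, ci_low, ci_high]
    n_kr_draws: int = 0
    seed: int | None = None

    def importance(self, attribute: str) -> float:
        row = self.table.loc[self.table["attribute"] == attribute]
        if row.empty:
            raise KeyError(f"no attribute {attribute!r}")
        return float(row["importance_percent"].iloc[0])


@dataclass
class MABResult:
    """A benefit-for-risk trade-off: the benefit-scale gain offsetting the
    utility change of moving ``attribute`` from ``from_level`` to
    ``to_level``."""

    attribute: str
    from_level: str
    to_level: str
    benefit_attribute: str
    benefit_scale: str
    required_benefit: float
    ci_low: float | None = None
    ci_high: float | None = None


def _ranges(params: UtilityParameters, catalog: list[AttributeSpec]) -> np.ndarray:
    return np.array([params.utility_range(a) for a in catalog])


def compute_rai(params: UtilityParameters, catalog: list[AttributeSpec]) -> RAIResult:
    """RAI_k = 100 * range_k / sum of ranges, range over level utilities
    with the reference level included at zero."""
    r = _ranges(params, catalog)
    total = r.sum()
    if total <= 0:
        raise ValueError("all utility ranges are zero: no preference information")
    tab = pd.DataFrame(
        {"attribute": [a.name for a in catalog], "importance_percent": 100.0 * r / total}
    )
    return RAIResult(table=tab)


def params_from_fit(fit: ECLFit, catalog: list[AttributeSpec]) -> UtilityParameters:
    """Base part-worths from a fit's coefficient labels (interactions ignored)."""
    pw: dict[str, dict[int, float]] = {a.name: {} for a in catalog}
    for lab, val in fit.estimates.items():
        parts = lab.split(":")
        if len(parts) == 2 and parts[0] in pw:
            pw[parts[0]][int(parts[1])] = float(val)
    return UtilityParameters(part_worths=pw, sigma=float(fit.estimates.get("sigma", 0.0)))


def _kr_draws(fit: ECLFit, n_draws: int, seed: int) -> np.ndarray:
    """Krinsky–Robb coefficient draws from N(estimates, covariance)."""
    if fit.covariance is None:
        raise ValueError("fit has no covariance matrix")
    mean = fit.estimates.to_numpy(dtype=float)
    cov = fit.covariance.to_numpy(dtype=float)
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        warnings.warn("covariance not positive semidefinite; nearest-PSD repair applied")
    cov = (V * np.clip(w, 0.0, None)) @ V.T
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=n_draws, method="eigh")


def _vector_params(vec: np.ndarray, labels: list[str], catalog: list[AttributeSpec]) -> UtilityParameters:
    pw: dict[str, dict[int, float]] = {a.name: {} for a in catalog}
    for lab, val in zip(labels, vec):
        parts = lab.split(":")
        if len(parts) == 2 and parts[0] in pw:
            pw[parts[0]][int(parts[1])] = float(val)
    return UtilityParameters(part_worths=pw)


def rai_confidence_intervals(
    fit: ECLFit,
    catalog: list[AttributeSpec],
    n_draws: int = 2000,
    seed: int = 0,
) -> RAIResult:
    """Point RAI from the fit plus Krinsky–Robb 95% percentile intervals."""
    point = compute_rai(params_from_fit(fit, catalog), catalog)
    draws = _kr_draws(fit, n_draws, seed)
    labels = fit.labels
    sims = np.empty((n_draws, len(catalog)))
    for d in range(n_draws):
        p = _vector_params(draws[d], labels, catalog)
        r = _ranges(p, catalog)
        sims[d] = 100.0 * r / r.sum()
    lo = np.percentile(sims, 2.5, axis=0)
    hi = np.percentile(sims, 97.5, axis=0)
    tab = point.table.copy()
    tab["ci_low"] = lo
    tab["ci_high"] = hi
    return RAIResult(table=tab, n_kr_draws=n_draws, seed=seed)


def _mab_value(
    params: UtilityParameters,
    catalog_map: dict[str, AttributeSpec],
    attribute: str,
    from_idx: int,
    to_idx: int,
    benefit: AttributeSpec,
    mode: str,
) -> float:
    a = catalog_map[attribute]
    du = params.level_utility(a, from_idx) - params.level_utility(a, to_idx)
    if mode == "linear":
        slope = params.utility_range(benefit) / benefit.scale_width
        if slope == 0:
            raise ValueError(f"benefit attribute {benefit.name!r} has zero utility range")
        return du / slope
    if mode == "piecewise":
        # invert the piecewise-linear utility of the benefit attribute,
        # starting from its reference level
        v = np.asarray(benefit.numeric_values, dtype=float)
        u = params.level_utilities(benefit)
        order = np.argsort(v)
        v, u = v[order], u[order]
        v0 = float(benefit.numeric_values[benefit.reference_index])
        u0 = float(np.interp(v0, v, u))
        target = u0 + du
        if not (u.min() <= target <= u.max()):
            raise ValueError("required benefit exceeds the attribute's level range")
        if not np.all(np.diff(u) >= 0):
            raise ValueError("piecewise mode requires monotone benefit utilities")
        return float(np.interp(target, u, v)) - v0
    raise ValueError(f"unknown mode {mode!r}")


def compute_mab(
    params: UtilityParameters,
    catalog: list[AttributeSpec],
    attribute: str,
    to_level: int | str,
    benefit_attribute: str,
    from_level: int | str | None = None,
    fit: ECLFit | None = None,
    n_kr_draws: int = 2000,
    seed: int = 0,
    mode: str = "linear",
) -> MABResult:
    """Benefit gain required to accept moving ``attribute`` to ``to_level``.

    ``required_benefit = (u(from) - u(to)) / (range_benefit / scale_width)``
    in the default linear mode; ``from_level`` defaults to the attribute's
    reference.  Positive when the queried change loses utility.  Supplying a
    ``fit`` with a covariance adds a Krinsky–Robb 95% interval.  The
    non-default ``mode="piecewise"`` inverts the benefit attribute's
    piecewise-linear utility instead of the full-range linearization.
    """
    cmap = {a.name: a for a in catalog}
    if attribute not in cmap:
        raise ValueError(f"unknown attribute {attribute!r}")
    if benefit_attribute not in cmap:
        raise ValueError(f"unknown attribute {benefit_attribute!r}")
    a = cmap[attribute]
    benefit = cmap[benefit_attribute]
    if benefit.numeric_values is None or benefit.scale_width is None:
        raise ValueError(f"benefit attribute {benefit_attribute!r} has no numeric scale")
    to_idx = a.level_index(to_level)
    from_idx = a.reference_index if from_level is None else a.level_index(from_level)
    value = _mab_value(params, cmap, attribute, from_idx, to_idx, benefit, mode)
    lo = hi = None
    if fit is not None and fit.covariance is not None:
        draws = _kr_draws(fit, n_kr_draws, seed)
        sims = []
        for d in range(n_kr_draws):
            p = _vector_params(draws[d], fit.labels, catalog)
            try:
                sims.append(_mab_value(p, cmap, attribute, from_idx, to_idx, benefit, mode))
            except ValueError:
                continue
        if sims:
            lo = float(np.percentile(sims, 2.5))
            hi = float(np.percentile(sims, 97.5))
    unit = "months" if "month" in str(benefit.levels[0]) else "percentage points"
    return MABResult(
        attribute=attribute,
        from_level=a.levels[from_idx],
        to_level=a.levels[to_idx],
        benefit_attribute=benefit_attribute,
        benefit_scale=unit,
        required_benefit=float(value),
        ci_low=lo,
        ci_high=hi,
    )
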