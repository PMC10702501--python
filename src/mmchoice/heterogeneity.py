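"""Subgroup preference heterogeneity via attribute-by-characteristic
interactions.

One binary respondent characteristic at a time is interacted with every
attribute level in the error-component logit; the joint fit gives the
indicator-0 group the base part-worths and the indicator-1 group base plus
interaction.  Group-specific importance scores then propagate the joint
covariance through Krinsky–Robb simulation.  Interaction z-statistics are
nominal/exploratory — no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .attributes import AttributeSpec
from .estimate import ECLFit, EstimationSettings, estimate
from .metrics import RAIResult, _kr_draws, _vector_params, compute_rai
from .model import UtilityParameters
from .simulate import ChoiceDataset

__all__ = ["SubgroupSpec", "fit_with_interactions", "subgroup_rai", "subgroup_report"]


@dataclass
class SubgroupSpec:
    """A binary split of the respondents.

    ``rule`` maps the covariate column to a boolean series (e.g.
    ``lambda s: s >= 60`` on age, or ``lambda s: s == "US"`` on country);
    ``label_pair`` names the (rule-false, rule-true) groups.
    """

    covariate: str
    rule: Callable[[pd.Series], pd.Series]
    label_pair: tuple[str, str] = ("group0", "group1")

    @property
    def indicator_name(self) -> str:
        return f"ind_{self.covariate}_{self.label_pair[1]}".replace(" ", "_").lower()


def _add_indicator(data: ChoiceDataset, subgroup: SubgroupSpec) -> ChoiceDataset:
    df = data.df
    if subgroup.covariate not in df.columns:
        raise ValueError(f"covariate {subgroup.covariate!r} not in dataset")
    ind = subgroup.rule(df[subgroup.covariate]).astype(int)
    n1 = df.loc[ind == 1, "respondent_id"].nunique()
    n0 = df.loc[ind == 0, "respondent_id"].nunique()
    if n0 == 0 or n1 == 0:
        raise ValueError(
            f"subgroup rule on {subgroup.covariate!r} leaves an empty group "
            f"({subgroup.label_pair[0]}: {n0}, {subgroup.label_pair[1]}: {n1})"
        )
    out = df.copy()
    out[subgroup.indicator_name] = ind
    return ChoiceDataset(
        df=out,
        attribute_names=data.attribute_names,
        covariate_names=data.covariate_names + [subgroup.indicator_name],
    )


def fit_with_interactions(
    data: ChoiceDataset,
    catalog: list[AttributeSpec],
    subgroup: SubgroupSpec,
    settings: EstimationSettings | None = None,
) -> ECLFit:
    """Joint error-component logit with level-by-indicator interaction
    columns; group-1 part-worths are base plus interaction."""
    augmented = _add_indicator(data, subgroup)
    fit = estimate(
        augmented, catalog, settings=settings, interaction_covariate=subgroup.indicator_name
    )
    fit.group_labels = subgroup.label_pair
    return fit


def _group_vector(fit: ECLFit, vec: np.ndarray, group: int) -> np.ndarray:
    """Map a joint coefficient draw to group-specific base-scale labels."""
    labels = fit.labels
    out = np.array(vec, dtype=float)
    if group == 0:
        return out
    base_pos = {lab: i for i, lab in enumerate(labels) if ":x:" not in lab and lab != "sigma"}
    for i, lab in enumerate(labels):
        if ":x:" in lab:
            base_lab = lab.split(":x:")[0]
            out[base_pos[base_lab]] += vec[i]
    return out


def subgroup_rai(
    fit: ECLFit,
    catalog: list[AttributeSpec],
    group: str,
    n_kr_draws: int = 2000,
    seed: int = 0,
) -> RAIResult:
    """Importance scores on one group's utility vector, with Krinsky–Robb
    intervals propagating the joint covariance."""
    if fit.group_labels is None:
        raise ValueError("fit has no subgroup interaction structure")
    try:
        g = fit.group_labels.index(group)
    except ValueError:
        raise ValueError(
            f"unknown group {group!r}; expected one of {fit.group_labels}"
        ) from None
    mean = _group_vector(fit, fit.estimates.to_numpy(dtype=float), g)
    point = compute_rai(_vector_params(mean, fit.labels, catalog), catalog)
    if fit.covariance is None:
        return point
    draws = _kr_draws(fit, n_kr_draws, seed)
    sims = np.empty((n_kr_draws, len(catalog)))
    for d in range(n_kr_draws):
        vec = _group_vector(fit, draws[d], g)
        p = _vector_params(vec, fit.labels, catalog)
        r = np.array([p.utility_range(a) for a in catalog])
        sims[d] = 100.0 * r / r.sum()
    tab = point.table.copy()
    tab["ci_low"] = np.percentile(sims, 2.5, axis=0)
    tab["ci_high"] = np.percentile(sims, 97.5, axis=0)
    return RAIResult(table=tab, n_kr_draws=n_kr_draws, seed=seed)


def subgroup_report(
    fit: ECLFit,
    catalog: list[AttributeSpec],
    n_kr_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group RAI table with CIs plus interaction z-statistics (nominal,
    exploratory)."""
    g0, g1 = fit.group_labels
    r0 = subgroup_rai(fit, catalog, g0, n_kr_draws, seed)
    r1 = subgroup_rai(fit, catalog, g1, n_kr_draws, seed)
    tab = r0.table.merge(r1.table, on="attribute", suffixes=(f"_{g0}", f"_{g1}"))
    zrows = []
    for lab in fit.labels:
        if ":x:" in lab and fit.std_errors is not None:
            attr = lab.split(":")[0]
            z = fit.estimates[lab] / fit.std_errors[lab] if fit.std_errors[lab] > 0 else np.nan
            zrows.append({"attribute": attr, "label": lab, "z": z})
    ztab = pd.DataFrame(zrows)
    if not ztab.empty:
        zmax = ztab.groupby("attribute")["z"].apply(lambda s: s.loc[s.abs().idxmax()])
        tab = tab.merge(zmax.rename("max_abs_interaction_z"), on="attribute", how="left")
    return tab
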