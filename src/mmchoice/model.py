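"""Part-worth utility parameters for the error-component logit model.

Random-utility setup: the utility respondent ``n`` assigns to alternative
``j`` in a choice task is

    U_nj = x_j' (beta + sum_c z_nc gamma_c) + sigma * eta_n * 1[j = A] + eps_nj

where ``x_j`` dummy-codes the alternative's levels against each attribute's
reference level, ``beta`` are part-worth utilities, ``gamma_c`` shift the
part-worths for respondents with characteristic ``z_nc``, ``eta_n`` is a
standard-normal error component drawn once per respondent (spread ``sigma``,
attached to alternative A so it is identifiable in a two-alternative forced
choice), and ``eps_nj`` are independent standard Gumbel errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import AttributeSpec

__all__ = ["UtilityParameters", "TrueModel", "utilities_from_rai"]


@dataclass
class UtilityParameters:
    """Part-worth vector over non-reference levels plus error-component spread.

    ``part_worths[attr][level_index]`` is the utility of that level relative
    to the attribute's reference level (which is implicitly zero and need not
    be listed).  ``interactions[covariate][(attr, level_index)]`` are additive
    shifts applied when the (numeric) covariate is 1.
    """

    part_worths: dict[str, dict[int, float]]
    sigma: float = 0.0
    interactions: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def level_utility(self, attr: AttributeSpec, level_index: int) -> float:
        if level_index == attr.reference_index:
            return 0.0
        return float(self.part_worths.get(attr.name, {}).get(level_index, 0.0))

    def level_utilities(self, attr: AttributeSpec) -> np.ndarray:
        """Utilities of all levels of ``attr`` (reference = 0)."""
        return np.array([self.level_utility(attr, i) for i in range(attr.n_levels)])

    def utility_range(self, attr: AttributeSpec) -> float:
        u = self.level_utilities(attr)
        return float(u.max() - u.min())

    def to_vector(self, catalog: list[AttributeSpec]) -> np.ndarray:
        """Flatten part-worths to the canonical dummy-column order
        (catalog order, then level order, references skipped)."""
        out = []
        for a in catalog:
            for i in range(a.n_levels):
                if i != a.reference_index:
                    out.append(self.level_utility(a, i))
        return np.array(out)

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, catalog: list[AttributeSpec], sigma: float = 0.0
    ) -> "UtilityParameters":
        pw: dict[str, dict[int, float]] = {}
        k = 0
        for a in catalog:
            pw[a.name] = {}
            for i in range(a.n_levels):
                if i != a.reference_index:
                    pw[a.name][i] = float(vec[k])
                    k += 1
        if k != len(vec):
            raise ValueError(f"vector length {len(vec)} != expected {k}")
        return cls(part_worths=pw, sigma=sigma)


@dataclass
class TrueModel(UtilityParameters):
    """Data-generating parameters for the respondent simulator; adds the
    probability that a respondent opts out of a task after the forced choice."""

    optout_rate: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (0.0 <= self.optout_rate <= 1.0):
            raise ValueError("optout_rate must be in [0, 1]")


# fractions of the administration utility range assigned to each level when
# constructing utilities from importance scores; reference (IV/SC q3w) = 0,
# CAR-T = full range, others intermediate (exact placement does not affect
# range-based quantities)
_ADMIN_RANGE_FRACTION = {
    "iv_sc_twice_weekly": 0.30,
    "iv_sc_q3w": 0.0,
    "iv_sc_weekly_plus_oral": 0.55,
    "iv_sc_monthly_plus_oral": 0.40,
    "car_t": 1.0,
}


def utilities_from_rai(
    catalog: list[AttributeSpec],
    rai_percent: dict[str, float],
    scale: float = 1.0,
    sigma: float = 0.0,
) -> UtilityParameters:
    """Build part-worth utilities whose per-attribute ranges are proportional
    to given relative-importance scores.

    Ordered attributes get utilities linear in their numeric level values
    (so the per-unit slope equals range / scale_width exactly); benefits
    increase away from the reference, risks decrease.  The administration
    attribute spans its range from the reference (0) down to the CAR-T
    procedure bundle (-range), with intermediate bundles in between.

    Parameters
    ----------
    rai_percent
        Importance score per attribute name; utility ranges are
        ``scale * rai_percent[name]``.
    scale
        Multiplies every range; choose e.g. 0.05 for realistic logit-scale
        part-worths when the scores sum to 100.
    """
    pw: dict[str, dict[int, float]] = {}
    for a in catalog:
        rng_u = scale * float(rai_percent[a.name])
        levels: dict[int, float] = {}
        if a.ordered:
            v = np.asarray(a.numeric_values, dtype=float)
            v_ref = v[a.reference_index]
            slope = rng_u / a.scale_width
            sign = 1.0 if a.kind == "benefit" else -1.0
            for i in range(a.n_levels):
                if i != a.reference_index:
                    levels[i] = sign * slope * (v[i] - v_ref)
        else:
            for i, lab in enumerate(a.levels):
                if i == a.reference_index:
                    continue
                frac = _ADMIN_RANGE_FRACTION.get(lab)
                if frac is None:
                    # unknown unordered level: spread evenly over the range
                    frac = (i + 1) / a.n_levels
                levels[i] = -rng_u * frac
        pw[a.name] = levels
    return UtilityParameters(part_worths=pw, sigma=sigma)
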