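"""Attribute/level catalog for the RRMM treatment-preference choice experiment.

A discrete choice experiment (DCE) describes hypothetical treatments by a
small set of attributes, each taking one of a few levels.  This module holds
the attribute catalog used throughout the package: three benefit attributes
(overall response rate, duration of response, overall survival), four risk
attributes (peripheral neuropathy, temporary vision change, cytokine release
syndrome, severe diarrhea) and a mode-of-administration attribute, together
with catalog (de)serialization and the randomized presentation order used
when showing attributes to respondents.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "AttributeSpec",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "presentation_order",
    "non_reference_count",
]

KINDS = ("benefit", "risk", "administration")


@dataclass(frozen=True)
class AttributeSpec:
    """One DCE attribute with ordered levels and an optional numeric scale.

    Parameters
    ----------
    name
        Short identifier used in data frames and coefficient labels.
    label
        Human-readable display text.
    kind
        One of ``benefit``, ``risk`` or ``administration``; determines the
        preference direction used for dominance construction (higher benefit
        better, lower risk better, administration unordered).
    levels
        Ordered level labels, unique within the attribute.
    reference_index
        Position of the reference level; part-worth utilities are expressed
        relative to this level, which carries utility zero.
    numeric_values
        Optional per-level numbers on a stated scale (percent for response
        rate and risks, months for response duration and survival).  Must be
        strictly monotone when present.
    scale_width
        Span of the numeric scale, ``max - min`` of ``numeric_values``.
    """

    name: str
    label: str
    kind: str
    levels: tuple[str, ...]
    reference_index: int = 0
    numeric_values: tuple[float, ...] | None = None
    scale_width: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"attribute {self.name!r}: kind must be one of {KINDS}")
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r}: needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r}: duplicate level labels")
        if not (0 <= self.reference_index < len(self.levels)):
            raise ValueError(f"attribute {self.name!r}: reference_index out of range")
        if self.numeric_values is not None:
            if len(self.numeric_values) != len(self.levels):
                raise ValueError(f"attribute {self.name!r}: numeric_values length mismatch")
            diffs = np.diff(self.numeric_values)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError(f"attribute {self.name!r}: numeric_values must be strictly monotone")
            width = float(max(self.numeric_values) - min(self.numeric_values))
            if self.scale_width is None:
                object.__setattr__(self, "scale_width", width)
            elif abs(self.scale_width - width) > 1e-9:
                raise ValueError(f"attribute {self.name!r}: scale_width != max-min of numeric_values")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def ordered(self) -> bool:
        """Whether a preference direction is defined (benefit/risk with numbers)."""
        return self.kind != "administration" and self.numeric_values is not None

    def level_index(self, level: int | str) -> int:
        """Resolve a level given as an index or a label."""
        if isinstance(level, (int, np.integer)):
            if not (0 <= level < self.n_levels):
                raise ValueError(f"attribute {self.name!r}: level index {level} out of range")
            return int(level)
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValueError(f"attribute {self.name!r}: unknown level {level!r}") from None

    def preference_rank(self, level_index: int) -> float:
        """Rank of a level on the preference direction (larger = preferred).

        For benefits larger numeric values are preferred; for risks smaller
        values are preferred.  Undefined (raises) for unordered attributes.
        """
        if not self.ordered:
            raise ValueError(f"attribute {self.name!r} has no preference direction")
        v = self.numeric_values[level_index]
        return v if self.kind == "benefit" else -v

    @property
    def best_level_index(self) -> int:
        return int(max(range(self.n_levels), key=self.preference_rank))

    @property
    def worst_level_index(self) -> int:
        return int(min(range(self.n_levels), key=self.preference_rank))


def default_catalog() -> list[AttributeSpec]:
    """The packaged RRMM attribute catalog (8 attributes, 31 levels).

    Benefits: overall response rate (ORR, 25-85%), duration of response
    (DOR, 3-15 months), overall survival (OS, 6-24 months).  Risks:
    peripheral neuropathy (0-50%), temporary vision change (0-60%), cytokine
    release syndrome (high risk, quantified as an 85% chance of any CRS,
    vs. no risk) and severe diarrhea (0-20%).  Administration has five
    unordered procedure bundles; its reference is IV/SC every 3 weeks.
    """
    return [
        AttributeSpec(
            "orr", "Likelihood of responding to treatment", "benefit",
            ("25%", "40%", "55%", "70%", "85%"),
            reference_index=0, numeric_values=(25.0, 40.0, 55.0, 70.0, 85.0),
        ),
        AttributeSpec(
            "dor", "Length of time in response", "benefit",
            ("3 months", "6 months", "9 months", "1 year", "1.25 years"),
            reference_index=0, numeric_values=(3.0, 6.0, 9.0, 12.0, 15.0),
        ),
        AttributeSpec(
            "os", "Lifespan", "benefit",
            ("6 months", "1 year", "1.5 years", "2 years"),
            reference_index=0, numeric_values=(6.0, 12.0, 18.0, 24.0),
        ),
        AttributeSpec(
            "neuropathy", "Tingling or pain in hands and/or feet", "risk",
            ("0%", "25%", "50%"),
            reference_index=0, numeric_values=(0.0, 25.0, 50.0),
        ),
        AttributeSpec(
            "vision", "Temporary vision change", "risk",
            ("0%", "20%", "40%", "60%"),
            reference_index=0, numeric_values=(0.0, 20.0, 40.0, 60.0),
        ),
        AttributeSpec(
            "crs", "Inflammatory response (CRS)", "risk",
            ("high_risk", "no_risk"),
            reference_index=1, numeric_values=(85.0, 0.0),
        ),
        AttributeSpec(
            "diarrhea", "Severe diarrhea", "risk",
            ("0%", "10%", "20%"),
            reference_index=0, numeric_values=(0.0, 10.0, 20.0),
        ),
        AttributeSpec(
            "administration", "Administration", "administration",
            (
                "iv_sc_twice_weekly",
                "iv_sc_q3w",
                "iv_sc_weekly_plus_oral",
                "iv_sc_monthly_plus_oral",
                "car_t",
            ),
            reference_index=1,
        ),
    ]


def non_reference_count(catalog: list[AttributeSpec]) -> int:
    """Number of dummy-coded part-worth coefficients, sum of (levels - 1)."""
    return sum(a.n_levels - 1 for a in catalog)


# ---------------------------------------------------------------------------
# catalog (de)serialization


def save_catalog(catalog: list[AttributeSpec], path) -> None:
    """Write a catalog to a declarative YAML file."""
    entries = []
    for a in catalog:
        e: dict = {
            "name": a.name,
            "label": a.label,
            "kind": a.kind,
            "levels": list(a.levels),
            "reference_index": a.reference_index,
        }
        if a.numeric_values is not None:
            e["numeric_values"] = [float(v) for v in a.numeric_values]
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump({"attributes": entries}, fh, sort_keys=False)


def load_catalog(path=None) -> list[AttributeSpec]:
    """Read a catalog YAML; with no path, load the packaged default fixture."""
    if path is None:
        ref = importlib.resources.files("mmchoice.data").joinpath("default_catalog.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    catalog = []
    for e in raw["attributes"]:
        catalog.append(
            AttributeSpec(
                name=e["name"],
                label=e.get("label", e["name"]),
                kind=e["kind"],
                levels=tuple(e["levels"]),
                reference_index=int(e.get("reference_index", 0)),
                numeric_values=tuple(e["numeric_values"]) if "numeric_values" in e else None,
            )
        )
    return catalog


def presentation_order(catalog: list[AttributeSpec], seed: int) -> list[str]:
    """Randomized display order: attributes shuffle within their kind group
    and the groups themselves shuffle, so each group stays contiguous.

    Deterministic per seed; both the within-group orders and the group order
    are uniform.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for a in catalog:
        groups.setdefault(a.kind, []).append(a.name)
    kinds = [k for k in KINDS if k in groups]
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    out: list[str] = []
    for k in kinds:
        names = groups[k]
        out.extend(names[i] for i in rng.permutation(len(names)))
    return out
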