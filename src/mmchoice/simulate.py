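"""Synthetic respondents and panel choice data.

The study's raw choice data are not shared, so every downstream stage is
exercised on simulated data.  Respondent covariates follow the published
sample composition: 296 patients across six country strata (US 100, UK 49,
Italy 45, Germany 43, France 39, Spain 20), 84% with a caregiver, 52% male,
a median of 3 (range 2-8) prior treatment lines, and response/fatigue
distributions matching the reported frequencies.  Choices come from the
error-component random-utility process described in :mod:`mmchoice.model`:
Gumbel task-level noise plus a per-respondent normal error component that
induces panel correlation.  Respondents answer the forced choice always;
an opt-out flag is drawn independently and never overwrites the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributes import AttributeSpec
from .design import Design, dummy_code
from .model import TrueModel

__all__ = [
    "RespondentProfile",
    "StrataSpec",
    "default_strata",
    "simulate_profiles",
    "profiles_to_frame",
    "ChoiceDataset",
    "simulate_choices",
    "default_true_model",
]

COUNTRIES = ("US", "UK", "IT", "DE", "FR", "ES")


@dataclass
class RespondentProfile:
    """Simulated respondent covariates (eligibility: adult, >= 2 prior lines)."""

    respondent_id: int
    country: str
    age_years: float
    has_caregiver: bool
    male: bool
    n_prior_lines: int
    response_status: str  # complete | partial | none
    fatigue_severity: int  # 0 none, 1 mild-moderate, 2 severe
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_prior_lines < 2:
            raise ValueError("eligibility requires at least 2 prior treatment lines")
        if self.age_years < 18:
            raise ValueError("eligibility requires age >= 18")


@dataclass
class StrataSpec:
    """Country strata and covariate distributions for the profile simulator."""

    country_counts: dict[str, int]
    # per-country (mean, sd) of age in years, truncated to [38, 85]
    age_by_country: dict[str, tuple[float, float]]
    p_caregiver: float = 0.84
    p_male: float = 0.52
    # prior anti-myeloma lines: pmf over 2..8 (median 3, ~59% with 2-3 lines,
    # ~14.5% with 5 or more)
    prior_lines_pmf: dict[int, float] = field(
        default_factory=lambda: {2: 0.30, 3: 0.295, 4: 0.26, 5: 0.08, 6: 0.04, 7: 0.02, 8: 0.005}
    )
    response_pmf: dict[str, float] = field(
        default_factory=lambda: {"partial": 0.46, "complete": 0.31, "none": 0.23}
    )
    fatigue_pmf: dict[int, float] = field(
        default_factory=lambda: {0: 0.064, 1: 0.493, 2: 0.443}
    )

    def __post_init__(self) -> None:
        for p in (self.p_caregiver, self.p_male):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for pmf in (self.prior_lines_pmf, self.response_pmf, self.fatigue_pmf):
            vals = np.array(list(pmf.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError("pmf must sum to 1")


def default_strata() -> StrataSpec:
    """Strata matching the published sample (n=296 over six countries)."""
    return StrataSpec(
        country_counts={"US": 100, "UK": 49, "IT": 45, "DE": 43, "FR": 39, "ES": 20},
        age_by_country={
            "US": (63.1, 4.9),
            "UK": (60.4, 8.9),
            "IT": (67.4, 5.9),
            "DE": (64.7, 9.7),
            "FR": (65.3, 10.4),
            "ES": (63.2, 10.2),
        },
    )


def _scaled_counts(counts: dict[str, int], n: int) -> dict[str, int]:
    """Scale stratum counts to total n by largest remainder."""
    total = sum(counts.values())
    if n == total:
        return dict(counts)
    raw = {k: v * n / total for k, v in counts.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(out.values())
    for k in sorted(raw, key=lambda kk: raw[kk] - np.floor(raw[kk]), reverse=True)[:short]:
        out[k] += 1
    return out


def simulate_profiles(
    n: int, strata_spec: StrataSpec | None = None, seed: int = 0
) -> list[RespondentProfile]:
    """Draw ``n`` respondent profiles; country counts are exact (scaled by
    largest remainder when ``n`` differs from the spec total), binary
    covariates independent Bernoulli.  Deterministic per seed."""
    spec = strata_spec if strata_spec is not None else default_strata()
    rng = np.random.default_rng(seed)
    counts = _scaled_counts(spec.country_counts, n)
    lines_vals = np.array(sorted(spec.prior_lines_pmf))
    lines_p = np.array([spec.prior_lines_pmf[v] for v in lines_vals])
    resp_vals = list(spec.response_pmf)
    resp_p = np.array([spec.response_pmf[v] for v in resp_vals])
    fat_vals = np.array(sorted(spec.fatigue_pmf))
    fat_p = np.array([spec.fatigue_pmf[v] for v in fat_vals])

    profiles: list[RespondentProfile] = []
    rid = 1
    for country in counts:
        mean, sd = spec.age_by_country.get(country, (63.8, 8.0))
        for _ in range(counts[country]):
            age = float(np.clip(rng.normal(mean, sd), 38.0, 85.0))
            profiles.append(
                RespondentProfile(
                    respondent_id=rid,
                    country=country,
                    age_years=round(age, 1),
                    has_caregiver=bool(rng.random() < spec.p_caregiver),
                    male=bool(rng.random() < spec.p_male),
                    n_prior_lines=int(rng.choice(lines_vals, p=lines_p)),
                    response_status=str(rng.choice(resp_vals, p=resp_p)),
                    fatigue_severity=int(rng.choice(fat_vals, p=fat_p)),
                )
            )
            rid += 1
    return profiles


def profiles_to_frame(profiles: list[RespondentProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "respondent_id": p.respondent_id,
            "country": p.country,
            "age_years": p.age_years,
            "has_caregiver": int(p.has_caregiver),
            "male": int(p.male),
            "n_prior_lines": p.n_prior_lines,
            "response_status": p.response_status,
            "fatigue_severity": p.fatigue_severity,
        }
        row.update(p.extra)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# choice data


@dataclass
class ChoiceDataset:
    """Long-format panel choice records: one row per (respondent, task,
    alternative), with level indices per attribute, the chosen/opt-out
    indicators, validity-task flags and respondent covariates."""

    df: pd.DataFrame
    attribute_names: list[str]
    covariate_names: list[str]

    CORE = ["respondent_id", "task_id", "block_id", "alternative"]
    FLAGS = ["chosen", "optout", "is_stability_repeat", "is_dominance_test"]

    def canonical(self) -> pd.DataFrame:
        cols = self.CORE + self.attribute_names + self.FLAGS + self.covariate_names
        df = self.df[cols].sort_values(
            ["respondent_id", "task_id", "alternative"], kind="mergesort"
        )
        return df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df = self.canonical()
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, catalog: list[AttributeSpec]) -> "ChoiceDataset":
        df = pd.read_csv(path)
        attrs = [a.name for a in catalog]
        covs = [c for c in df.columns if c not in cls.CORE + attrs + cls.FLAGS]
        return cls(df=df, attribute_names=attrs, covariate_names=covs)

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_choice_rows(self) -> int:
        """Number of (respondent, task) choice occasions."""
        return len(self.df) // 2


def default_true_model(sigma: float = 0.8, optout_rate: float = 0.05) -> TrueModel:
    """Data-generating parameters emulating the published preference pattern:
    part-worth ranges proportional to the reported relative-importance
    scores, on a realistic logit scale (largest range ~1.5)."""
    from .metrics import STUDY_RAI_PERCENT
    from .attributes import default_catalog
    from .model import utilities_from_rai

    base = utilities_from_rai(default_catalog(), STUDY_RAI_PERCENT, scale=0.05)
    return TrueModel(
        part_worths=base.part_worths, sigma=sigma, optout_rate=optout_rate
    )


def simulate_choices(
    design: Design,
    profiles: list[RespondentProfile],
    truth: TrueModel,
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate panel choices from the error-component random-utility model.

    Respondents are assigned blocks round-robin (exact balance) and answer
    their block's experimental tasks plus its validity tasks.  For each task
    the alternative with the larger realized utility

        U_j = x_j' beta_n + sigma * eta_n * 1[j=A] + eps_j

    is chosen, with ``beta_n`` the part-worths shifted by the respondent's
    interaction covariates, ``eta_n ~ N(0,1)`` drawn once per respondent and
    ``eps_j`` independent standard Gumbel.  Deterministic per seed.
    """
    if design.n_blocks < 1:
        raise ValueError("design must have at least one block")
    catalog = design.catalog
    rng = np.random.default_rng(seed)
    prof_frame = profiles_to_frame(profiles)
    for cov in truth.interactions:
        if cov not in prof_frame.columns:
            raise ValueError(f"interaction covariate {cov!r} missing from profiles")

    beta = truth.to_vector(catalog)
    # per-covariate interaction vectors in the same dummy order
    gamma = {}
    for cov, shifts in truth.interactions.items():
        g = np.zeros_like(beta)
        k = 0
        for a in catalog:
            for i in range(a.n_levels):
                if i == a.reference_index:
                    continue
                g[k] = shifts.get((a.name, i), 0.0)
                k += 1
        gamma[cov] = g

    # pre-code every task's alternatives
    coded = {
        t.task_id: (dummy_code(t.alternatives[0], catalog), dummy_code(t.alternatives[1], catalog))
        for t in design.tasks
    }

    cov_cols = [c for c in prof_frame.columns if c != "respondent_id"]
    rows = []
    for idx, p in enumerate(profiles):
        block = (idx % design.n_blocks) + 1
        tasks = design.block_tasks(block, include_validity=True)
        beta_n = beta.copy()
        prow = prof_frame.iloc[idx]
        for cov, g in gamma.items():
            beta_n = beta_n + float(prow[cov]) * g
        eta = rng.standard_normal()
        for t in tasks:
            xa, xb = coded[t.task_id]
            va = float(xa @ beta_n) + truth.sigma * eta + rng.gumbel()
            vb = float(xb @ beta_n) + rng.gumbel()
            choice = 0 if va >= vb else 1
            optout = int(rng.random() < truth.optout_rate)
            for j, alt in enumerate(t.alternatives):
                row = {
                    "respondent_id": p.respondent_id,
                    "task_id": t.task_id,
                    "block_id": block,
                    "alternative": "AB"[j],
                    "chosen": int(j == choice),
                    "optout": optout,
                    "is_stability_repeat": int(t.is_stability_repeat),
                    "is_dominance_test": int(t.is_dominance_test),
                }
                for a, lev in zip(catalog, alt):
                    row[a.name] = lev
                for c in cov_cols:
                    row[c] = prow[c]
                rows.append(row)
    df = pd.DataFrame(rows)
    ds = ChoiceDataset(
        df=df, attribute_names=[a.name for a in catalog], covariate_names=cov_cols
    )
    ds.df = ds.canonical()
    return ds
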