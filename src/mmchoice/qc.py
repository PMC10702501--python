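"""Internal-validity checks: stability, dominance and opt-out rates.

The survey embeds two engagement checks per block: a stability task (an
exact repeat of an earlier task — consistency means choosing the same
alternative twice) and a dominance task (one alternative objectively
better — engagement means choosing it).  Rates are reported only; no
respondents are excluded unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import Design
from .simulate import ChoiceDataset

__all__ = ["ValiditySummary", "validity_summary", "filter_failed_validity"]


@dataclass
class ValiditySummary:
    """Aggregate validity rates plus per-respondent pass flags.

    Rates are ``None`` (absent, not zero) when no respondent saw the
    relevant task; each rate is computed only over respondents who did.
    """

    stability_consistency_rate: float | None
    dominance_pass_rate: float | None
    optout_rate: float
    per_respondent: pd.DataFrame  # respondent_id, stability_pass, dominance_pass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["stability_consistency_rate", "dominance_pass_rate", "optout_rate"],
                "value": [
                    self.stability_consistency_rate,
                    self.dominance_pass_rate,
                    self.optout_rate,
                ],
            }
        )


def _chosen_alternative(df: pd.DataFrame) -> pd.Series:
    """Alternative label chosen per (respondent, task)."""
    ch = df[df["chosen"] == 1]
    return ch.set_index(["respondent_id", "task_id"])["alternative"]


def validity_summary(data: ChoiceDataset, design: Design) -> ValiditySummary:
    df = data.df
    chosen = _chosen_alternative(df)
    stab_tasks = {t.task_id: t.stability_source_id for t in design.tasks if t.is_stability_repeat}
    dom_tasks = {t.task_id: t.dominant_alternative for t in design.tasks if t.is_dominance_test}

    rows = []
    for rid, grp in df.groupby("respondent_id"):
        task_ids = set(grp["task_id"])
        stab = None
        for tid, src in stab_tasks.items():
            if tid in task_ids and src in task_ids:
                stab = bool(chosen.loc[(rid, tid)] == chosen.loc[(rid, src)])
                break
        dom = None
        for tid, side in dom_tasks.items():
            if tid in task_ids and side is not None:
                dom = bool(chosen.loc[(rid, tid)] == "AB"[side])
                break
        rows.append({"respondent_id": rid, "stability_pass": stab, "dominance_pass": dom})
    per = pd.DataFrame(rows)

    def rate(col: str) -> float | None:
        seen = per[col].dropna()
        return float(seen.mean()) if len(seen) else None

    # one opt-out flag per (respondent, task): take the A row of each pair
    task_level = df.drop_duplicates(["respondent_id", "task_id"])
    return ValiditySummary(
        stability_consistency_rate=rate("stability_pass"),
        dominance_pass_rate=rate("dominance_pass"),
        optout_rate=float(task_level["optout"].mean()),
        per_respondent=per,
    )


def filter_failed_validity(
    data: ChoiceDataset,
    summary: ValiditySummary,
    require_stability: bool = False,
    require_dominance: bool = True,
) -> ChoiceDataset:
    """Opt-in filter dropping respondents who failed the requested checks."""
    per = summary.per_respondent.set_index("respondent_id")
    keep = pd.Series(True, index=per.index)
    if require_stability:
        keep &= per["stability_pass"].fillna(True).astype(bool)
    if require_dominance:
        keep &= per["dominance_pass"].fillna(True).astype(bool)
    kept_ids = set(per.index[keep])
    df = data.df[data.df["respondent_id"].isin(kept_ids)].reset_index(drop=True)
    return ChoiceDataset(
        df=df, attribute_names=data.attribute_names, covariate_names=data.covariate_names
    )
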