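"""D-efficient choice-task design generation.

The experimental design decides which pairs of hypothetical treatments
respondents see.  A design is scored by its D-error,
``det(I(beta)^-1)^(1/K)`` for the conditional-logit information matrix at
prior coefficients ``beta`` (zero priors give the utility-neutral design);
lower D-error means more information about trade-offs per choice task.
The search is a coordinate-exchange algorithm: starting from random level
assignments, single cells (task, alternative, attribute) are swapped to the
level that most reduces the D-error, sweeping until no improvement.

Designs are blocked (the reference study shows each respondent 12 of 36
tasks) and extended with two internal-validity tasks per block: a stability
repeat (an exact copy of an earlier task) and a dominance test (one
alternative weakly better on every ordered attribute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attributes import AttributeSpec
from .model import UtilityParameters

__all__ = [
    "ChoiceTask",
    "Design",
    "d_error",
    "generate_design",
    "add_validity_tasks",
    "level_balance",
    "check_level_balance",
    "write_design_csv",
    "read_design_csv",
]


@dataclass(frozen=True)
class ChoiceTask:
    """One paired-alternative choice task.

    ``alternatives`` holds exactly two level assignments, each a tuple with
    one level index per catalog attribute (catalog order).
    """

    task_id: int
    block_id: int
    alternatives: tuple[tuple[int, ...], tuple[int, ...]]
    is_stability_repeat: bool = False
    stability_source_id: int | None = None
    is_dominance_test: bool = False
    dominant_alternative: int | None = None

    @property
    def is_validity(self) -> bool:
        return self.is_stability_repeat or self.is_dominance_test


@dataclass
class Design:
    """A blocked set of choice tasks over a fixed attribute catalog."""

    tasks: list[ChoiceTask]
    n_blocks: int
    seed: int
    catalog: list[AttributeSpec]
    d_error: float = float("nan")

    @property
    def experimental_tasks(self) -> list[ChoiceTask]:
        return [t for t in self.tasks if not t.is_validity]

    def block_tasks(self, block_id: int, include_validity: bool = True) -> list[ChoiceTask]:
        return [
            t
            for t in self.tasks
            if t.block_id == block_id and (include_validity or not t.is_validity)
        ]

    def task_by_id(self, task_id: int) -> ChoiceTask:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(f"no task with id {task_id}")


# ---------------------------------------------------------------------------
# dummy coding and D-error


def dummy_code(levels: tuple[int, ...], catalog: list[AttributeSpec]) -> np.ndarray:
    """Dummy-code one alternative's level assignment against references."""
    out = np.zeros(sum(a.n_levels - 1 for a in catalog))
    k = 0
    for a, lev in zip(catalog, levels):
        for i in range(a.n_levels):
            if i == a.reference_index:
                continue
            if i == lev:
                out[k] = 1.0
            k += 1
    return out


def _information_matrix(design: Design, beta: np.ndarray) -> np.ndarray:
    """Conditional-logit Fisher information, sum over tasks of
    ``p(1-p) d d'`` with ``d = x_A - x_B`` (two alternatives, no constant)."""
    K = len(beta)
    info = np.zeros((K, K))
    for t in design.experimental_tasks:
        xa = dummy_code(t.alternatives[0], design.catalog)
        xb = dummy_code(t.alternatives[1], design.catalog)
        d = xa - xb
        p = 1.0 / (1.0 + np.exp(-(d @ beta)))
        info += p * (1.0 - p) * np.outer(d, d)
    return info


def d_error(design: Design, priors: UtilityParameters | None = None) -> float:
    """D-error of a design at prior coefficients: ``det(I^-1)^(1/K)``.

    Lower is better.  Returns ``+inf`` (with a warning) when the information
    matrix is singular, e.g. a design with no level variation.
    """
    if not design.experimental_tasks:
        raise ValueError("design has no experimental tasks")
    catalog = design.catalog
    K = sum(a.n_levels - 1 for a in catalog)
    beta = np.zeros(K) if priors is None else priors.to_vector(catalog)
    info = _information_matrix(design, beta)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular information matrix; D-error is infinite", stacklevel=2)
        return float("inf")
    return float(np.exp(-logdet / K))


# ---------------------------------------------------------------------------
# coordinate-exchange search


def _random_alternative(catalog: list[AttributeSpec], rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(int(rng.integers(a.n_levels)) for a in catalog)


def _random_task_levels(
    catalog: list[AttributeSpec], rng: np.random.Generator
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    while True:
        a = _random_alternative(catalog, rng)
        b = _random_alternative(catalog, rng)
        if a != b:
            return (a, b)


def _task_key(alts) -> tuple:
    # unordered pair: a task equals its alternative-swapped twin
    return tuple(sorted(alts))


def generate_design(
    catalog: list[AttributeSpec],
    n_tasks: int,
    n_blocks: int,
    priors: UtilityParameters | None = None,
    seed: int = 0,
    n_sweeps: int = 20,
    n_restarts: int = 2,
) -> Design:
    """Search for a D-efficient blocked design by coordinate exchange.

    Starts from random level assignments (duplicate tasks and tasks with
    level-identical alternatives re-drawn), then sweeps over every cell
    (task, alternative, attribute) trying all levels and keeping the one
    with the lowest D-error, for up to ``n_sweeps`` passes or until a full
    pass makes no change.  The best of ``n_restarts`` independent starts is
    kept.  Blocks are then assigned greedily to balance level counts.
    Deterministic given ``seed``.
    """
    if len(catalog) < 2:
        raise ValueError("catalog must contain at least 2 attributes")
    if n_tasks % n_blocks != 0:
        raise ValueError("n_tasks must be divisible by n_blocks")
    master = np.random.default_rng(seed)
    best: Design | None = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        cand = _coordinate_exchange(catalog, n_tasks, rng, priors, n_sweeps)
        if best is None or cand[1] < best.d_error:
            best = Design(
                tasks=[
                    ChoiceTask(task_id=i + 1, block_id=0, alternatives=alts)
                    for i, alts in enumerate(cand[0])
                ],
                n_blocks=n_blocks,
                seed=seed,
                catalog=catalog,
                d_error=cand[1],
            )
    _assign_blocks(best)
    return best


def _coordinate_exchange(catalog, n_tasks, rng, priors, n_sweeps):
    K = sum(a.n_levels - 1 for a in catalog)
    beta = np.zeros(K) if priors is None else priors.to_vector(catalog)

    tasks: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    seen: set = set()
    while len(tasks) < n_tasks:
        alts = _random_task_levels(catalog, rng)
        key = _task_key(alts)
        if key in seen:
            continue
        seen.add(key)
        tasks.append(alts)

    def diff_row(alts) -> np.ndarray:
        return dummy_code(alts[0], catalog) - dummy_code(alts[1], catalog)

    D = np.array([diff_row(a) for a in tasks])

    def score(Dmat: np.ndarray) -> float:
        p = 1.0 / (1.0 + np.exp(-(Dmat @ beta)))
        info = (Dmat * (p * (1 - p))[:, None]).T @ Dmat
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0 or not np.isfinite(logdet):
            return float("inf")
        return float(np.exp(-logdet / K))

    current = score(D)
    for _ in range(n_sweeps):
        improved = False
        for ti in range(n_tasks):
            for alt in range(2):
                for ai, attr in enumerate(catalog):
                    base = tasks[ti]
                    for lev in range(attr.n_levels):
                        if lev == base[alt][ai]:
                            continue
                        new_alt = list(base[alt])
                        new_alt[ai] = lev
                        new_alts = list(base)
                        new_alts[alt] = tuple(new_alt)
                        if new_alts[0] == new_alts[1]:
                            continue
                        key = _task_key(new_alts)
                        if any(_task_key(t) == key for j, t in enumerate(tasks) if j != ti):
                            continue
                        old_row = D[ti].copy()
                        D[ti] = diff_row(new_alts)
                        val = score(D)
                        if val < current - 1e-12:
                            tasks[ti] = (new_alts[0], new_alts[1])
                            current = val
                            improved = True
                        else:
                            D[ti] = old_row
        if not improved:
            break
    return tasks, current


def _assign_blocks(design: Design) -> None:
    """Greedy blocking: each task joins the non-full block where it least
    increases the sum over attributes of squared deviations of within-block
    level counts from uniform."""
    catalog = design.catalog
    n_blocks = design.n_blocks
    tasks = design.experimental_tasks
    cap = len(tasks) // n_blocks
    counts = [
        [np.zeros(a.n_levels) for a in catalog] for _ in range(n_blocks)
    ]
    sizes = [0] * n_blocks
    target = [2.0 * cap / a.n_levels for a in catalog]

    def cost_delta(b: int, task: ChoiceTask) -> float:
        delta = 0.0
        for ai, a in enumerate(catalog):
            c = counts[b][ai].copy()
            for alt in task.alternatives:
                c[alt[ai]] += 1
            delta += np.sum((c - target[ai]) ** 2) - np.sum((counts[b][ai] - target[ai]) ** 2)
        return delta

    assignment: dict[int, int] = {}
    for task in tasks:
        open_blocks = [b for b in range(n_blocks) if sizes[b] < cap]
        b = min(open_blocks, key=lambda bb: cost_delta(bb, task))
        assignment[task.task_id] = b + 1
        sizes[b] += 1
        for ai in range(len(catalog)):
            for alt in task.alternatives:
                counts[b][ai][alt[ai]] += 1

    design.tasks = [
        replace(t, block_id=assignment[t.task_id]) if not t.is_validity else t
        for t in design.tasks
    ]


# ---------------------------------------------------------------------------
# validity tasks


def add_validity_tasks(design: Design, repeat_position: int = 3) -> Design:
    """Append a stability repeat and a dominance test to every block.

    The stability task is a level-identical copy of the experimental task at
    1-based ``repeat_position`` within the block (the reference study
    repeated task 3).  The dominance task takes a random experimental task
    from the block and replaces one alternative with one that is weakly
    better on every ordered attribute (strictly better on at least one),
    holding administration equal, so an engaged respondent should pick it.
    """
    catalog = design.catalog
    next_id = max(t.task_id for t in design.tasks) + 1
    new_tasks = list(design.tasks)
    rng = np.random.default_rng(design.seed + 997)
    for b in range(1, design.n_blocks + 1):
        block = design.block_tasks(b, include_validity=False)
        if not (1 <= repeat_position <= len(block)):
            raise ValueError(f"repeat_position {repeat_position} out of range for block of {len(block)}")
        source = block[repeat_position - 1]
        new_tasks.append(
            ChoiceTask(
                task_id=next_id,
                block_id=b,
                alternatives=source.alternatives,
                is_stability_repeat=True,
                stability_source_id=source.task_id,
            )
        )
        next_id += 1
        dom_source = block[int(rng.integers(len(block)))]
        dominated = list(dom_source.alternatives[0])
        ordered_idx = [i for i, a in enumerate(catalog) if a.ordered]
        # ensure room for strict improvement on at least one ordered attribute
        if all(dominated[i] == catalog[i].best_level_index for i in ordered_idx):
            i0 = ordered_idx[0]
            dominated[i0] = catalog[i0].worst_level_index
        dominant = list(dominated)
        for i in ordered_idx:
            dominant[i] = catalog[i].best_level_index
        side = int(rng.integers(2))
        pair = [None, None]
        pair[side] = tuple(dominant)
        pair[1 - side] = tuple(dominated)
        new_tasks.append(
            ChoiceTask(
                task_id=next_id,
                block_id=b,
                alternatives=(pair[0], pair[1]),
                is_dominance_test=True,
                dominant_alternative=side,
            )
        )
        next_id += 1
    return Design(
        tasks=new_tasks,
        n_blocks=design.n_blocks,
        seed=design.seed,
        catalog=catalog,
        d_error=design.d_error,
    )


# ---------------------------------------------------------------------------
# diagnostics and IO


def level_balance(design: Design) -> pd.DataFrame:
    """Frequency of each level of each attribute over experimental tasks."""
    catalog = design.catalog
    rows = []
    tasks = design.experimental_tasks
    denom = 2 * len(tasks)
    for ai, a in enumerate(catalog):
        counts = np.zeros(a.n_levels)
        for t in tasks:
            for alt in t.alternatives:
                counts[alt[ai]] += 1
        for i, lab in enumerate(a.levels):
            rows.append(
                {
                    "attribute": a.name,
                    "level": lab,
                    "count": int(counts[i]),
                    "frequency": counts[i] / denom,
                    "uniform": 1.0 / a.n_levels,
                }
            )
    return pd.DataFrame(rows)


def check_level_balance(design: Design, tol: float = 0.25) -> pd.DataFrame:
    """Soft level-balance check: warn (never fail) when any level's frequency
    deviates from uniform by more than ``tol`` (relative)."""
    tab = level_balance(design)
    off = tab[abs(tab["frequency"] - tab["uniform"]) > tol * tab["uniform"]]
    if len(off):
        worst = off.iloc[(abs(off["frequency"] - off["uniform"])).argmax()]
        warnings.warn(
            f"level balance outside ±{tol:.0%} of uniform for {len(off)} level(s), "
            f"e.g. {worst['attribute']}={worst['level']} at {worst['frequency']:.2f} "
            f"vs {worst['uniform']:.2f}",
            stacklevel=2,
        )
    return tab


def write_design_csv(design: Design, path) -> None:
    """Serialize to CSV: one row per (task, alternative), level indices per
    attribute, canonical column order and formatting (round-trip stable)."""
    rows = []
    for t in design.tasks:
        for j, alt in enumerate(t.alternatives):
            row = {"task_id": t.task_id, "block_id": t.block_id, "alternative": "AB"[j]}
            for a, lev in zip(design.catalog, alt):
                row[a.name] = lev
            row["is_stability_repeat"] = int(t.is_stability_repeat)
            row["stability_source_id"] = t.stability_source_id if t.stability_source_id is not None else -1
            row["is_dominance_test"] = int(t.is_dominance_test)
            row["dominant_alternative"] = t.dominant_alternative if t.dominant_alternative is not None else -1
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# n_blocks={design.n_blocks} seed={design.seed} d_error={design.d_error:.12g}\n")
        df.to_csv(fh, index=False)


def read_design_csv(path, catalog: list[AttributeSpec]) -> Design:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    tasks = []
    for tid, grp in df.groupby("task_id", sort=True):
        grp = grp.sort_values("alternative")
        alts = tuple(
            tuple(int(r[a.name]) for a in catalog) for _, r in grp.iterrows()
        )
        first = grp.iloc[0]
        src = int(first["stability_source_id"])
        dom = int(first["dominant_alternative"])
        tasks.append(
            ChoiceTask(
                task_id=int(tid),
                block_id=int(first["block_id"]),
                alternatives=alts,
                is_stability_repeat=bool(first["is_stability_repeat"]),
                stability_source_id=src if src >= 0 else None,
                is_dominance_test=bool(first["is_dominance_test"]),
                dominant_alternative=dom if dom >= 0 else None,
            )
        )
    tasks.sort(key=lambda t: t.task_id)
    return Design(
        tasks=tasks,
        n_blocks=int(meta["n_blocks"]),
        seed=int(meta["seed"]),
        catalog=catalog,
        d_error=float(meta["d_error"]),
    )
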