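"""Maximum simulated likelihood estimation of the error-component logit.

For two-alternative forced choices the conditional logit depends on the
data only through the dummy-coded difference between the chosen and the
rejected alternative.  The error component ``sigma * eta_n`` (standard
normal, one draw per respondent, attached to alternative A) is integrated
out by simulation: the likelihood of a respondent's task sequence is the
average over quasi-random draws of the product of binary logit
probabilities.  Scrambled Halton draws give low-variance integration; the
analytic gradient keeps quasi-Newton optimization fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtri
from scipy.stats import qmc

from .attributes import AttributeSpec
from .simulate import ChoiceDataset

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "halton_normal_draws",
    "simulated_loglik",
    "EstimationSettings",
    "ECLFit",
    "estimate",
]


@dataclass
class DesignMatrix:
    """Dummy-coded covariates aligned row-by-row with a ChoiceDataset.

    Columns are one indicator per non-reference level in catalog order then
    level order (23 for the default catalog), followed by any interaction
    columns (level indicator times respondent covariate), labelled
    ``attr:level_index`` and ``attr:level_index:x:covariate``.
    """

    values: np.ndarray
    labels: list[str]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def build_design_matrix(
    data: ChoiceDataset,
    catalog: list[AttributeSpec],
    interaction_covariates: list[str] | None = None,
) -> DesignMatrix:
    """Dummy-code each row's level assignment against the reference levels.

    A row sitting at the reference level of every attribute codes to zeros.
    With ``interaction_covariates``, one full set of level-indicator columns
    multiplied by the (numeric) covariate is appended per covariate.
    """
    df = data.df
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for a in catalog:
        lev = df[a.name].to_numpy()
        bad = (lev < 0) | (lev >= a.n_levels)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"row {df.index[i]}: level {lev[i]} invalid for attribute {a.name!r}"
            )
        for i in range(a.n_levels):
            if i == a.reference_index:
                continue
            cols.append((lev == i).astype(float))
            labels.append(f"{a.name}:{i}")
    base = np.column_stack(cols)
    base_labels = list(labels)
    if interaction_covariates:
        for cov in interaction_covariates:
            if cov not in df.columns:
                raise ValueError(f"covariate {cov!r} not in dataset")
            z = df[cov].to_numpy(dtype=float)
            for j, lab in enumerate(base_labels):
                cols.append(base[:, j] * z)
                labels.append(f"{lab}:x:{cov}")
    return DesignMatrix(values=np.column_stack(cols), labels=labels)


def halton_normal_draws(
    n_respondents: int, n_draws: int, seed: int = 0, antithetic: bool = True
) -> np.ndarray:
    """Per-respondent scrambled-Halton standard-normal draws, shape (N, R).

    With ``antithetic`` (and even ``n_draws``) each draw is paired with its
    negation, which halves integration variance and makes the simulated
    likelihood exactly symmetric in the sign of the error-component spread.
    """
    sampler = qmc.Halton(d=1, scramble=True, seed=seed)
    if antithetic and n_draws % 2 == 0:
        u = sampler.random(n_respondents * (n_draws // 2)).ravel()
        u = np.clip(u, 1e-12, 1 - 1e-12)
        half = ndtri(u).reshape(n_respondents, n_draws // 2)
        return np.concatenate([half, -half], axis=1)
    u = sampler.random(n_respondents * n_draws).ravel()
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return ndtri(u).reshape(n_respondents, n_draws)


# ---------------------------------------------------------------------------
# panel arrays


@dataclass
class _PanelArrays:
    """Chosen-minus-rejected difference rows stacked per respondent."""

    D: np.ndarray  # (N, T_max, K) dummy differences, zero-padded
    S: np.ndarray  # (N, T_max) +1 if chosen alternative is A, -1 if B, 0 pad
    M: np.ndarray  # (N, T_max) task mask
    respondent_ids: np.ndarray

    @classmethod
    def build(cls, matrix: DesignMatrix, data: ChoiceDataset) -> "_PanelArrays":
        df = data.df.reset_index(drop=True)
        order = np.lexsort(
            (df["alternative"].to_numpy(), df["task_id"].to_numpy(), df["respondent_id"].to_numpy())
        )
        X = matrix.values[order]
        sdf = df.iloc[order]
        chosen = sdf["chosen"].to_numpy()
        if len(sdf) % 2:
            raise ValueError("dataset rows do not pair into two alternatives per task")
        xA, xB = X[0::2], X[1::2]
        cA = chosen[0::2]
        if not np.all(cA + chosen[1::2] == 1):
            raise ValueError("exactly one alternative must be chosen per task")
        d = np.where(cA[:, None] == 1, xA - xB, xB - xA)
        s = np.where(cA == 1, 1.0, -1.0)
        resp = sdf["respondent_id"].to_numpy()[0::2]
        ids, counts = np.unique(resp, return_counts=True)
        N, T = len(ids), int(counts.max())
        K = X.shape[1]
        D = np.zeros((N, T, K))
        S = np.zeros((N, T))
        M = np.zeros((N, T))
        pos = 0
        for i, c in enumerate(counts):
            D[i, :c] = d[pos : pos + c]
            S[i, :c] = s[pos : pos + c]
            M[i, :c] = 1.0
            pos += c
        return cls(D=D, S=S, M=M, respondent_ids=ids)

    @property
    def n_choices(self) -> int:
        return int(self.M.sum())


def _loglik_parts(theta: np.ndarray, panel: _PanelArrays, draws: np.ndarray):
    """Simulated log-likelihood, its gradient, and per-respondent scores."""
    beta, sigma = theta[:-1], theta[-1]
    D, S, M = panel.D, panel.S, panel.M
    R = draws.shape[1]
    base = D @ beta  # (N, T)
    dv = base[:, :, None] + sigma * S[:, :, None] * draws[:, None, :]
    logp = -np.logaddexp(0.0, -dv) * M[:, :, None]
    per_draw = logp.sum(axis=1)  # (N, R)
    m = per_draw.max(axis=1, keepdims=True)
    w_un = np.exp(per_draw - m)
    sumw = w_un.sum(axis=1)
    ll_n = m[:, 0] + np.log(sumw) - np.log(R)
    w = w_un / sumw[:, None]
    resid = M[:, :, None] * expit(-dv)  # (1 - P) masked
    wt = np.einsum("nr,ntr->nt", w, resid)
    gbeta_n = np.einsum("nt,ntk->nk", wt, D)
    b = np.einsum("ntr,nt->nr", resid, S)
    gsigma_n = np.einsum("nr,nr->n", w, b * draws)
    scores = np.column_stack([gbeta_n, gsigma_n])
    return float(ll_n.sum()), scores.sum(axis=0), scores


def simulated_loglik(
    params: np.ndarray,
    matrix: DesignMatrix,
    data: ChoiceDataset,
    draws: np.ndarray,
) -> float:
    """Panel simulated log-likelihood at ``params = (beta..., sigma)``.

    For each respondent, the product over tasks of the binary logit
    probability of the chosen alternative (at the respondent's error
    component ``sigma * eta``) is averaged over the supplied draws; the
    result is the sum of the logs of these averages.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("parameters must be finite")
    if params.size != matrix.n_columns + 1:
        raise ValueError("params must supply one coefficient per column plus sigma")
    panel = _PanelArrays.build(matrix, data)
    if draws.shape[0] != len(panel.respondent_ids):
        raise ValueError("draws must have one row per respondent")
    ll, _, _ = _loglik_parts(params, panel, draws)
    return ll


@dataclass
class EstimationSettings:
    """Maximum-simulated-likelihood settings.

    ``n_draws`` scrambled Halton draws per respondent (500 default),
    gradient-norm convergence tolerance ``gtol``, and ``start_sigma`` the
    starting value of the error-component spread.  A zero sigma start is a
    stationary point of the (sigma-symmetric) simulated likelihood, so the
    default starts slightly away from it; part-worths start at zero.
    """

    n_draws: int = 500
    seed: int = 0
    gtol: float = 1e-6
    maxiter: int = 1000
    robust: bool = False
    include_validity: bool = False
    start_sigma: float = 0.5
    fix_sigma: bool = False  # constrain sigma = 0 (plain conditional logit)


@dataclass
class ECLFit:
    """Estimation result: coefficients, uncertainty and metadata."""

    estimates: pd.Series
    std_errors: pd.Series | None
    covariance: pd.DataFrame | None
    log_likelihood: float
    n_draws: int
    draw_type: str
    seed: int
    converged: bool
    n_respondents: int
    n_choices: int
    message: str = ""
    interaction_covariate: str | None = None
    group_labels: tuple[str, str] | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.estimates.index)

    def coefficient_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"estimate": self.estimates})
        if self.std_errors is not None:
            tab["std_error"] = self.std_errors
            tab["z"] = tab["estimate"] / tab["std_error"]
        return tab

    def to_json(self, path) -> None:
        payload = {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "std_errors": None
            if self.std_errors is None
            else {k: float(v) for k, v in self.std_errors.items()},
            "covariance": None
            if self.covariance is None
            else self.covariance.to_numpy().tolist(),
            "labels": self.labels,
            "log_likelihood": self.log_likelihood,
            "n_draws": self.n_draws,
            "draw_type": self.draw_type,
            "seed": self.seed,
            "converged": self.converged,
            "n_respondents": self.n_respondents,
            "n_choices": self.n_choices,
            "message": self.message,
            "interaction_covariate": self.interaction_covariate,
            "group_labels": list(self.group_labels) if self.group_labels else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ECLFit":
        with open(path) as fh:
            p = json.load(fh)
        labels = p["labels"]
        cov = (
            pd.DataFrame(np.array(p["covariance"]), index=labels, columns=labels)
            if p["covariance"] is not None
            else None
        )
        return cls(
            estimates=pd.Series(p["estimates"]).reindex(labels),
            std_errors=None
            if p["std_errors"] is None
            else pd.Series(p["std_errors"]).reindex(labels),
            covariance=cov,
            log_likelihood=p["log_likelihood"],
            n_draws=p["n_draws"],
            draw_type=p["draw_type"],
            seed=p["seed"],
            converged=p["converged"],
            n_respondents=p["n_respondents"],
            n_choices=p["n_choices"],
            message=p.get("message", ""),
            interaction_covariate=p.get("interaction_covariate"),
            group_labels=tuple(p["group_labels"]) if p.get("group_labels") else None,
        )


def _numeric_hessian(fun_grad, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    K = theta.size
    H = np.zeros((K, K))
    for k in range(K):
        h = rel_step * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        gp = fun_grad(tp)
        gm = fun_grad(tm)
        H[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def estimate(
    data: ChoiceDataset,
    catalog: list[AttributeSpec],
    settings: EstimationSettings | None = None,
    interaction_covariate: str | None = None,
) -> ECLFit:
    """Fit the error-component logit by maximum simulated likelihood.

    Validity tasks (stability repeats, dominance tests) are excluded from
    the likelihood by default — they are engagement checks, and a repeat
    would double-count its source task.  Opt-out flags are ignored (the
    forced choice is analyzed).  Standard errors come from the inverse
    numerical Hessian; with ``settings.robust`` a respondent-clustered
    sandwich covariance is used instead.  Non-convergence is flagged on the
    result, not raised.
    """
    settings = settings or EstimationSettings()
    df = data.df
    if not settings.include_validity:
        keep = (df["is_stability_repeat"] == 0) & (df["is_dominance_test"] == 0)
        df = df[keep]
    sub = ChoiceDataset(
        df=df.reset_index(drop=True),
        attribute_names=data.attribute_names,
        covariate_names=data.covariate_names,
    )
    if sub.n_respondents < 1:
        raise ValueError("no respondents in dataset")
    tasks_per_resp = sub.df.groupby("respondent_id")["task_id"].nunique()
    if (tasks_per_resp < 2).all():
        raise ValueError("need at least one respondent with >= 2 tasks")

    covs = [interaction_covariate] if interaction_covariate else None
    matrix = build_design_matrix(sub, catalog, interaction_covariates=covs)
    panel = _PanelArrays.build(matrix, sub)
    draws = halton_normal_draws(len(panel.respondent_ids), settings.n_draws, settings.seed)

    K = matrix.n_columns

    if settings.fix_sigma:

        def negloglik_grad(beta):
            ll, g, _ = _loglik_parts(np.concatenate([beta, [0.0]]), panel, draws)
            return -ll, -g[:-1]

        x0 = np.zeros(K)
    else:

        def negloglik_grad(theta):
            ll, g, _ = _loglik_parts(theta, panel, draws)
            return -ll, -g

        x0 = np.zeros(K + 1)
        x0[-1] = settings.start_sigma

    res = optimize.minimize(
        negloglik_grad,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": settings.gtol, "maxiter": settings.maxiter},
    )
    theta = np.concatenate([res.x, [0.0]]) if settings.fix_sigma else res.x
    labels = matrix.labels + ["sigma"]
    # BFGS can stop with "precision loss" once float precision of the
    # likelihood is exhausted; accept if the gradient is numerically flat
    grad_norm = float(np.abs(res.jac).max()) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm < 1e-3

    free = slice(0, K) if settings.fix_sigma else slice(0, K + 1)

    def grad_only(t_free):
        t = np.concatenate([t_free, [0.0]]) if settings.fix_sigma else t_free
        _, g, _ = _loglik_parts(t, panel, draws)
        return g[free]

    H = -_numeric_hessian(grad_only, theta[free])  # Hessian of negative loglik
    cov = None
    se = None
    try:
        cov_arr = np.linalg.inv(H)
        if settings.robust:
            _, _, scores = _loglik_parts(theta, panel, draws)
            B = scores[:, free].T @ scores[:, free]
            cov_arr = cov_arr @ B @ cov_arr
        if settings.fix_sigma:
            padded = np.zeros((K + 1, K + 1))
            padded[:K, :K] = cov_arr
            cov_arr = padded
        cov_arr = 0.5 * (cov_arr + cov_arr.T)
        evals = np.linalg.eigvalsh(cov_arr)
        if evals.min() < -1e-8 * max(1.0, evals.max()):
            warnings.warn("covariance not positive semidefinite; clipping eigenvalues")
            w, V = np.linalg.eigh(cov_arr)
            cov_arr = (V * np.clip(w, 0.0, None)) @ V.T
        diag = np.diag(cov_arr)
        if (diag < 0).any() or not np.all(np.isfinite(cov_arr)):
            raise np.linalg.LinAlgError("bad covariance")
        cov = pd.DataFrame(cov_arr, index=labels, columns=labels)
        se = pd.Series(np.sqrt(diag), index=labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; standard errors unavailable")

    est = pd.Series(theta, index=labels)
    est["sigma"] = abs(est["sigma"])  # sign not identified
    return ECLFit(
        estimates=est,
        std_errors=se,
        covariance=cov,
        log_likelihood=float(-res.fun),
        n_draws=settings.n_draws,
        draw_type="scrambled_halton",
        seed=settings.seed,
        converged=converged,
        n_respondents=int(len(panel.respondent_ids)),
        n_choices=panel.n_choices,
        message=str(res.message),
        interaction_covariate=interaction_covariate,
    )
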