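"""Statistical models linking facing behaviour to socially-learned choice.

The battery mirrors the study's analysis plan:

* binomial GLMMs (logit link, choice counts as weights) of test choices
  against chance and across groups, with likelihood-ratio tests (LRTs) on
  nested fits and post-hoc pairwise Wald contrasts;
* a Gaussian model on the per-bee difference in time facing rewarding vs
  non-rewarding flowers;
* per-group binomial models of choice proportion on the four facing-time
  predictors, with LRT-based factor retention and average marginal effects
  (AMEs) in percentage points per second;
* a binomial test of which category precedes unoccupied-rewarding facing;
* the Fisher-Freeman-Halton exact test for r x c contingency tables of
  first choices.

Fixed-effects binomial fits go through statsmodels GLM.  The random-
intercept binomial GLMM (one grouping factor, e.g. colony) is fitted here by
maximising the exact marginal likelihood with adaptive Gauss-Hermite
quadrature; when the random-effect variance estimates at the boundary the
model falls back to the fixed-effects fit and records that it did.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from scipy.special import gammaln, logsumexp, roots_hermite
from statsmodels.tools.numdiff import approx_hess

from .metrics import FacingSummary, TransitionCounts

__all__ = [
    "ChoiceRecord",
    "ModelResult",
    "LRTResult",
    "ContingencyTable",
    "ConvergenceError",
    "SeparationWarning",
    "CollinearityWarning",
    "TableTooLargeError",
    "fit_binomial_glmm",
    "test_vs_chance",
    "compare_groups",
    "facing_time_difference_test",
    "facing_effect_model",
    "transition_frequency_test",
    "freeman_halton_test",
]

ALPHA = 0.05
_VAR_BOUNDARY = 1e-8
_N_QUAD = 21


class ConvergenceError(RuntimeError):
    """Model failed to converge after restarts."""


class SeparationWarning(UserWarning):
    """Fitted probabilities at 0/1: estimates are effectively infinite."""


class CollinearityWarning(UserWarning):
    """Predictor matrix is near-singular; estimates are unstable."""


class TableTooLargeError(ValueError):
    """Contingency table exceeds the exact-enumeration bound."""


@dataclass(frozen=True)
class ChoiceRecord:
    """One bee's unrewarded-test outcome.

    ``n_yellow`` of ``n_choices`` proboscis-contact choices landed on yellow
    flowers; ``first_choice`` is the colour of the first contact ("none"
    when the bee made no choice).
    """

    bee_id: str
    group: str
    colony_id: str
    n_choices: int
    n_yellow: int
    first_choice: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.n_yellow <= self.n_choices:
            raise ValueError("n_yellow must lie in [0, n_choices]")
        if self.n_choices > 0 and self.first_choice == "none":
            raise ValueError("first_choice required when choices were made")


@dataclass
class ModelResult:
    """Fitted-model summary on the link (logit/identity) scale."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    z_values: dict[str, float]
    p_values: dict[str, float]
    loglik: float
    random_effect_variances: dict[str, float] = field(default_factory=dict)
    convergence_flag: bool = True
    random_effects_dropped: bool = False
    family: str = "binomial"
    n_obs: int = 0
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested maximum-likelihood fits."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative counts (rows: groups, cols: outcomes)."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape must match row/col labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


# ---------------------------------------------------------------------------
# Binomial GLMM core
# ---------------------------------------------------------------------------

def _binll(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-row binomial log-likelihood without the combinatorial constant."""
    return y * eta - n * np.logaddexp(0.0, eta)


def _binll_const(y: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))


def _group_mode(y, n, eta0, sigma2, tol=1e-10, max_iter=60):
    """Newton mode and curvature of the per-group integrand in u."""
    u = 0.0
    for _ in range(max_iter):
        eta = eta0 + u
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = float(np.sum(y - n * p)) - u / sigma2
        hess = -float(np.sum(n * p * (1 - p))) - 1.0 / sigma2
        step = grad / hess
        u -= step
        if abs(step) < tol:
            break
    eta = eta0 + u
    p = 1.0 / (1.0 + np.exp(-eta))
    hess = -float(np.sum(n * p * (1 - p))) - 1.0 / sigma2
    return u, hess


def _marginal_loglik(beta, log_sigma, y, n, X, group_slices, z_nodes, z_w,
                     with_grad=False):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    With ``with_grad`` also returns the gradient in (beta, log_sigma),
    computed as posterior expectations of the complete-data score over the
    same quadrature nodes.
    """
    sigma = math.exp(log_sigma)
    sigma2 = sigma * sigma
    eta_fixed = X @ beta
    total = 0.0
    grad = np.zeros(len(beta) + 1) if with_grad else None
    log_zw = np.log(z_w) + z_nodes ** 2
    for idx in group_slices:
        yg, ng, eg = y[idx], n[idx], eta_fixed[idx]
        u_hat, hess = _group_mode(yg, ng, eg, sigma2)
        s = 1.0 / math.sqrt(-hess)
        u = u_hat + math.sqrt(2.0) * s * z_nodes
        eta = eg[:, None] + u[None, :]
        h = (
            _binll(yg[:, None], ng[:, None], eta).sum(axis=0)
            - 0.5 * u * u / sigma2
            - 0.5 * math.log(2 * math.pi * sigma2)
        )
        lse = logsumexp(log_zw + h)
        total += lse + 0.5 * math.log(2.0) + math.log(s)
        if with_grad:
            w_post = np.exp(log_zw + h - lse)  # normalised node weights
            p = 1.0 / (1.0 + np.exp(-eta))  # (rows, nodes)
            resid = (yg[:, None] - ng[:, None] * p) @ w_post  # per-row score
            grad[:-1] += X[idx].T @ resid
            grad[-1] += float(w_post @ (u * u)) / sigma2 - 1.0
    if with_grad:
        return total, grad
    return total


def _fit_fixed_glm(y, n, X, names):
    endog = np.column_stack([y, n - y])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    mu = res.fittedvalues
    if np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8):
        warnings.warn("fitted probabilities at 0/1 (separation)",
                      SeparationWarning, stacklevel=3)
    params = np.asarray(res.params, float)
    bse = np.asarray(res.bse, float)
    z = np.divide(params, bse, out=np.full_like(params, np.inf), where=bse > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    return ModelResult(
        coefficients=dict(zip(names, params)),
        standard_errors=dict(zip(names, bse)),
        z_values=dict(zip(names, z)),
        p_values=dict(zip(names, p)),
        loglik=float(res.llf),
        random_effect_variances={},
        convergence_flag=bool(res.converged),
        random_effects_dropped=False,
        n_obs=len(y),
    )


def fit_binomial_glmm(
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    groups: np.ndarray | pd.Series | None = None,
    names: list[str] | None = None,
    n_restarts: int = 3,
) -> ModelResult:
    """Weighted logistic fit, optionally with one random-intercept factor.

    ``y`` successes out of ``n`` trials per row, design matrix ``X``
    (intercept column included by the caller), ``groups`` the random-
    intercept grouping labels (e.g. colony) or None for a plain GLM.  The
    mixed fit maximises the adaptive-quadrature marginal likelihood; a
    random-effect variance estimating at the boundary (<= 1e-8) triggers a
    refit without it, recorded via ``random_effects_dropped``.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two records")
    if np.any(n < 1):
        raise ValueError("weights (trial counts) must be >= 1")

    if groups is None:
        return _fit_fixed_glm(y, n, X, names)

    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        res = _fit_fixed_glm(y, n, X, names)
        res.random_effects_dropped = True
        return res
    group_slices = [np.flatnonzero(groups == g) for g in levels]
    z_nodes, z_w = roots_hermite(_N_QUAD)
    const = _binll_const(y, n)

    start = _fit_fixed_glm(y, n, X, names)
    beta0 = np.array([start.coefficients[c] for c in names])

    def negll(theta):
        return -_marginal_loglik(theta[:-1], theta[-1], y, n, X,
                                 group_slices, z_nodes, z_w)

    def negll_grad(theta):
        ll, g = _marginal_loglik(theta[:-1], theta[-1], y, n, X,
                                 group_slices, z_nodes, z_w, with_grad=True)
        return -ll, -g

    best = None
    for attempt, ls0 in enumerate([math.log(0.5), math.log(1.5), math.log(0.1),
                                   0.0][: n_restarts + 1]):
        theta0 = np.concatenate([beta0, [ls0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimize.minimize(
                negll_grad, theta0, method="L-BFGS-B", jac=True,
                bounds=[(None, None)] * len(beta0) + [(math.log(1e-6), math.log(50.0))],
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
        if opt.success and (best is None or opt.fun < best.fun - 1e-9):
            best = opt
        if best is not None and attempt >= 1:
            break
    if best is None:
        raise ConvergenceError("binomial GLMM did not converge after restarts")

    sigma2 = math.exp(2 * best.x[-1])
    if sigma2 <= _VAR_BOUNDARY:
        res = _fit_fixed_glm(y, n, X, names)
        res.random_effects_dropped = True
        res.random_effect_variances = {"group": 0.0}
        return res

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess(best.x, negll)
    k = len(names)
    try:
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[:k], 0, np.inf))
        cov_beta = cov[:k, :k]
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
        cov_beta = np.full((k, k), np.nan)
    params = best.x[:k]
    z = np.divide(params, bse, out=np.full(k, np.inf), where=bse > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    return ModelResult(
        coefficients=dict(zip(names, params)),
        standard_errors=dict(zip(names, bse)),
        z_values=dict(zip(names, z)),
        p_values=dict(zip(names, p)),
        loglik=float(-best.fun + const),
        random_effect_variances={"group": sigma2},
        convergence_flag=True,
        n_obs=len(y),
        extra={"cov_beta": cov_beta},
    )


def _records_frame(records: list[ChoiceRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "bee_id": [r.bee_id for r in records],
            "group": [r.group for r in records],
            "colony_id": [r.colony_id for r in records],
            "n_choices": [r.n_choices for r in records],
            "n_yellow": [r.n_yellow for r in records],
            "first_choice": [r.first_choice for r in records],
        }
    )
    return df[df["n_choices"] > 0].reset_index(drop=True)


def _colony_groups(df: pd.DataFrame) -> np.ndarray | None:
    return df["colony_id"].to_numpy() if df["colony_id"].nunique() > 1 else None


def _attach_chance_lrt(res: ModelResult, y: np.ndarray, n: np.ndarray) -> ModelResult:
    """LRT of the intercept against the chance-level null (p = 0.5).

    Stored alongside the Wald test; it replaces the reported p-value when
    separation makes the Wald statistic collapse (Hauck-Donner), which
    happens e.g. when every bee chose the same colour.
    """
    ll_null = _binll_const(y, n) + math.log(0.5) * float(np.sum(n))
    stat = max(2.0 * (res.loglik - ll_null), 0.0)
    p_lrt = float(sps.chi2.sf(stat, 1))
    res.extra["lrt_vs_chance"] = {"statistic": stat, "df": 1, "p_value": p_lrt}
    se = res.standard_errors["intercept"]
    est = res.coefficients["intercept"]
    if not np.isfinite(se) or se > 25 or abs(est) > 15:
        res.p_values["intercept"] = p_lrt
        res.z_values["intercept"] = math.copysign(math.sqrt(stat), est)
        res.extra["p_method"] = "lrt_vs_chance"
    return res


def test_vs_chance(records: list[ChoiceRecord],
                   use_random_effects: bool = True) -> ModelResult:
    """Intercept-only binomial GLMM of yellow-choice proportion vs chance.

    Chance is 0.5, i.e. intercept 0 on the logit scale; the reported Z and p
    test that intercept (LRT fallback under separation).  Colony enters as a
    random intercept when more than one colony is present.
    """
    df = _records_frame(records)
    X = np.ones((len(df), 1))
    groups = _colony_groups(df) if use_random_effects else None
    y = df["n_yellow"].to_numpy(float)
    n = df["n_choices"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        res = fit_binomial_glmm(y, n, X, groups=groups, names=["intercept"])
    return _attach_chance_lrt(res, y, n)


def compare_groups(
    records: list[ChoiceRecord],
    adjust: str = "none",
    use_random_effects: bool = True,
) -> tuple[LRTResult, pd.DataFrame]:
    """Overall group effect (LRT on nested fits) plus pairwise contrasts.

    The full model regresses yellow-choice proportion on group (treatment
    coding); the null drops group.  Contrasts are single-step Wald z tests
    on the logit scale, optionally Tukey-adjusted (``adjust="tukey"``).
    """
    df = _records_frame(records)
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    groups = _colony_groups(df) if use_random_effects else None
    y = df["n_yellow"].to_numpy()
    n = df["n_choices"].to_numpy()

    dummies = pd.get_dummies(df["group"], dtype=float)[levels]
    X_full = np.column_stack([np.ones(len(df))] +
                             [dummies[g].to_numpy() for g in levels[1:]])
    names_full = ["intercept"] + [f"group[{g}]" for g in levels[1:]]
    full = fit_binomial_glmm(y, n, X_full, groups=groups, names=names_full)
    null = fit_binomial_glmm(y, n, np.ones((len(df), 1)), groups=groups,
                             names=["intercept"])
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    dfree = len(levels) - 1
    lrt = LRTResult(statistic=stat, df=dfree,
                    p_value=float(sps.chi2.sf(stat, dfree)))

    # group means on the logit scale: reference level = intercept
    eff = {levels[0]: full.coefficients["intercept"]}
    for g in levels[1:]:
        eff[g] = full.coefficients["intercept"] + full.coefficients[f"group[{g}]"]
    cov = full.extra.get("cov_beta")
    if cov is None:
        se_map = {name: full.standard_errors[name] for name in names_full}
        k = len(names_full)
        cov = np.zeros((k, k))
        for i, name in enumerate(names_full):
            cov[i, i] = se_map[name] ** 2
    rows = []
    for a, b in itertools.combinations(levels, 2):
        # contrast vector on (intercept, group dummies)
        ca = np.zeros(len(names_full))
        cb = np.zeros(len(names_full))
        ca[0] = cb[0] = 1.0
        if a != levels[0]:
            ca[names_full.index(f"group[{a}]")] = 1.0
        if b != levels[0]:
            cb[names_full.index(f"group[{b}]")] = 1.0
        c = cb - ca
        est = eff[b] - eff[a]
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else math.inf
        if adjust == "tukey":
            p = float(sps.studentized_range.sf(abs(z) * math.sqrt(2.0),
                                               len(levels), np.inf))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        rows.append({"contrast": f"{b} - {a}", "estimate": est, "se": se,
                     "z": z, "p_value": p})
    return lrt, pd.DataFrame(rows)


def facing_time_difference_test(
    summaries: list[FacingSummary],
    use_random_effects: bool = True,
) -> ModelResult:
    """Gaussian model of (rewarding - non-rewarding) facing seconds.

    Response per bee: (t_occ_reward + t_unocc_reward) - (t_occ_nonreward +
    t_unocc_nonreward).  Intercept-only with an optional colony random
    intercept (statsmodels MixedLM); at the variance boundary it reduces to
    a one-sample z test.
    """
    d = np.array([s.t_reward - s.t_nonreward for s in summaries], float)
    colony = np.array([s.colony_id for s in summaries])
    if len(d) < 2:
        raise ValueError("need at least two summaries")
    dropped = True
    est = se = loglik = None
    re_var = {}
    if use_random_effects and len(np.unique(colony)) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mod = sm.MixedLM(d, np.ones((len(d), 1)), groups=colony)
                res = mod.fit(reml=False)
                var = float(np.asarray(res.cov_re).ravel()[0])
                if var > _VAR_BOUNDARY and res.converged:
                    est = float(res.params[0])
                    se = float(res.bse[0])
                    loglik = float(res.llf)
                    re_var = {"colony": var}
                    dropped = False
            except (np.linalg.LinAlgError, ValueError):
                pass
    if dropped:
        est = float(np.mean(d))
        se = float(np.std(d, ddof=1) / math.sqrt(len(d)))
        sigma2 = float(np.var(d, ddof=0))
        loglik = (float(np.sum(sps.norm.logpdf(d, est, math.sqrt(sigma2))))
                  if sigma2 > 0 else math.inf)
    if se > 0:
        z = est / se
    else:
        z = 0.0 if est == 0 else math.copysign(math.inf, est)
    p = float(2 * sps.norm.sf(abs(z)))
    return ModelResult(
        coefficients={"intercept": est},
        standard_errors={"intercept": se},
        z_values={"intercept": z},
        p_values={"intercept": p},
        loglik=loglik,
        random_effect_variances=re_var,
        random_effects_dropped=dropped,
        family="gaussian",
        n_obs=len(d),
    )


FACING_PREDICTORS = ("t_occ_reward", "t_unocc_reward",
                     "t_occ_nonreward", "t_unocc_nonreward")


def facing_effect_model(
    summaries: list[FacingSummary],
    records: list[ChoiceRecord],
    group: str,
    predictors: tuple[str, ...] = FACING_PREDICTORS,
    use_random_effects: bool = True,
    marginal_effect: str = "ame",
    alpha: float = ALPHA,
) -> tuple[ModelResult, pd.DataFrame]:
    """Per-group binomial model of choice proportion on facing times.

    The response is each bee's proportion of choices for the group's
    demonstrated (rewarding) colour, weighted by choice count; predictors
    are facing seconds.  One group at a time, to keep innate colour
    preference out of the slope estimates.  Each predictor's retention is
    judged by a drop-one LRT; its marginal effect is the average marginal
    effect (mean over bees of beta * p_i * (1 - p_i), in percentage points
    per second) or, with ``marginal_effect="at_mean"``, the effect at the
    mean fitted probability.
    """
    rec = {r.bee_id: r for r in records if r.group == group and r.n_choices > 0}
    rows = [s for s in summaries if s.group == group and s.bee_id in rec]
    if len(rows) < len(predictors) + 2:
        raise ValueError("too few bees for the facing-effect model")
    yellow_is_reward = group.lower() == "yellow"
    y = np.array([
        rec[s.bee_id].n_yellow if yellow_is_reward
        else rec[s.bee_id].n_choices - rec[s.bee_id].n_yellow
        for s in rows
    ], dtype=float)
    n = np.array([rec[s.bee_id].n_choices for s in rows], dtype=float)
    colony = np.array([s.colony_id for s in rows])
    T = np.column_stack([[getattr(s, c) for s in rows] for c in predictors])
    Tc = T - T.mean(axis=0)
    scale = Tc.std(axis=0)
    if np.any(scale == 0) or np.linalg.cond(Tc / scale) > 1e6:
        warnings.warn("facing-time predictors are near-collinear",
                      CollinearityWarning, stacklevel=2)
    X = np.column_stack([np.ones(len(rows)), T])
    names = ["intercept"] + list(predictors)
    groups = colony if use_random_effects and len(np.unique(colony)) > 1 else None

    full = fit_binomial_glmm(y, n, X, groups=groups, names=names)
    beta = np.array([full.coefficients[c] for c in names])
    eta = X @ beta
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    if marginal_effect == "at_mean":
        deriv = float(np.mean(p_hat) * (1 - np.mean(p_hat)))
    else:
        deriv = float(np.mean(p_hat * (1 - p_hat)))

    ame_rows = []
    for j, name in enumerate(predictors, start=1):
        X_red = np.delete(X, j, axis=1)
        red = fit_binomial_glmm(y, n, X_red, groups=groups,
                                names=[c for c in names if c != name])
        stat = max(2.0 * (full.loglik - red.loglik), 0.0)
        p_lrt = float(sps.chi2.sf(stat, 1))
        ame_rows.append({
            "predictor": name,
            "coefficient": full.coefficients[name],
            "z": full.z_values[name],
            "p_wald": full.p_values[name],
            "lrt_statistic": stat,
            "p_lrt": p_lrt,
            "retained": p_lrt < alpha,
            "ame_pct_per_s": 100.0 * full.coefficients[name] * deriv,
        })
    return full, pd.DataFrame(ame_rows)


def transition_frequency_test(counts: list[TransitionCounts],
                              colony: np.ndarray | None = None) -> ModelResult:
    """Were unoccupied-rewarding bouts preceded more often by non-rewarding
    than by occupied-rewarding facing?

    Binomial intercept-only model of the per-bee proportion
    nonreward / (nonreward + occ_reward) against 0.5, weighted by the pair
    total; bees without such predecessors drop out.
    """
    y, n, keep = [], [], []
    for i, c in enumerate(counts):
        tot = c.n_preceded_by_nonreward + c.n_preceded_by_occ_reward
        if tot >= 1:
            y.append(c.n_preceded_by_nonreward)
            n.append(tot)
            keep.append(i)
    if len(y) < 2:
        raise ValueError("need >= 2 bees with nonreward/occ-reward predecessors")
    groups = None
    if colony is not None:
        colony = np.asarray(colony)[keep]
        if len(np.unique(colony)) > 1:
            groups = colony
    y = np.array(y, float)
    n = np.array(n, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        res = fit_binomial_glmm(y, n, np.ones((len(y), 1)), groups=groups,
                                names=["intercept"])
    return _attach_chance_lrt(res, y, n)


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton exact test
# ---------------------------------------------------------------------------

def _enumerate_cell_terms(row_sums, col_sums):
    """Yield sum of gammaln(n_ij + 1) over every table with the given margins."""
    n_rows = len(row_sums)

    def rec_rows(r, cols_left, acc):
        if r == n_rows - 1:
            yield acc + float(np.sum(gammaln(np.array(cols_left) + 1.0)))
            return
        for row, term in _row_compositions(row_sums[r], cols_left):
            remaining = tuple(c - v for c, v in zip(cols_left, row))
            yield from rec_rows(r + 1, remaining, acc + term)

    yield from rec_rows(0, tuple(col_sums), 0.0)


def _row_compositions(total, caps):
    """All ways to write ``total`` as a capped composition over len(caps)
    cells, yielding (cells, sum of gammaln(cell + 1))."""
    k = len(caps)

    def rec(i, left, cells, term):
        if i == k - 1:
            if left <= caps[i]:
                yield cells + (left,), term + float(gammaln(left + 1.0))
            return
        lo = max(0, left - sum(caps[i + 1:]))
        hi = min(caps[i], left)
        for v in range(lo, hi + 1):
            yield from rec(i + 1, left - v, cells + (v,),
                           term + float(gammaln(v + 1.0)))

    yield from rec(0, total, (), 0.0)


def freeman_halton_test(table: ContingencyTable | np.ndarray,
                        rel_tol: float = 1e-10) -> float:
    """Exact conditional p-value for an r x c table with fixed margins.

    Enumerates every table on the margin-fixed lattice and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (ties included within a small relative tolerance).  Reduces to the
    classical two-sided Fisher exact test for 2 x 2 tables.  Tables beyond
    4 x 4 raise :class:`TableTooLargeError`.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=np.int64)
    if counts.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if counts.shape[0] > 4 or counts.shape[1] > 4:
        raise TableTooLargeError("exact enumeration supports at most 4 x 4")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    # drop empty rows/columns: they do not change the conditional distribution
    counts = counts[row_sums > 0][:, col_sums > 0]
    if counts.size == 0 or counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    row_sums = tuple(int(v) for v in counts.sum(axis=1))
    col_sums = tuple(int(v) for v in counts.sum(axis=0))
    n_total = int(counts.sum())
    log_margin = (
        float(np.sum(gammaln(np.array(row_sums) + 1.0)))
        + float(np.sum(gammaln(np.array(col_sums) + 1.0)))
        - float(gammaln(n_total + 1.0))
    )
    obs_term = float(np.sum(gammaln(counts + 1.0)))
    logp_obs = log_margin - obs_term
    gate = logp_obs + rel_tol * max(1.0, abs(logp_obs))
    logp_incl = [log_margin - term
                 for term in _enumerate_cell_terms(row_sums, col_sums)
                 if log_margin - term <= gate]
    return float(min(1.0, math.exp(logsumexp(np.array(logp_incl)))))
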