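"""Conditional logistic regression for 1:M matched strata.

The likelihood is conditional on each stratum containing exactly one case:
for stratum *s* with member covariate rows ``x_j`` and case row ``x_case``,

    l_s(beta) = x_case . beta - log sum_j exp(x_j . beta)

which is the Cox partial likelihood restricted to one event per risk set.
Matching variables (anything constant within a stratum) cancel from the
likelihood; such columns are detected and dropped with a log message.

Fitting is Newton-Raphson with analytic score and Hessian, step-halving, a
separation guard on the standardized coefficient scale, and standard errors
from the inverse observed information.  Wald odds ratios, confidence
intervals, and p-values match the usual OR (95% CI) presentation; a
likelihood-ratio test against the null model is available as a secondary
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


class CLRError(ValueError):
    """Invalid stratum structure or design matrix."""


class SeparationError(CLRError):
    """Complete or quasi-complete separation: the MLE diverges.

    ``offending`` names the terms whose standardized coefficients diverged
    (or whose standard errors degenerated), where determinable.
    """

    def __init__(self, message: str, offending: tuple[str, ...] = ()):
        super().__init__(message)
        self.offending = offending


class RankDeficiencyError(CLRError):
    """Design matrix not full rank after dropping stratum-constant columns."""


class NotConvergedError(CLRError):
    """Operation requires a converged fit."""


def _as_strata_array(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # single covariate, (n_strata, m)
        X = X[:, :, None]
    if X.ndim != 3:
        raise CLRError(f"strata array must be (n_strata, m, p), got shape {X.shape}")
    if X.shape[1] < 2:
        raise CLRError("every stratum needs at least 2 members (1 case + >=1 control)")
    return X


def conditional_loglik(beta: np.ndarray, X: np.ndarray) -> float:
    """Conditional log-likelihood; member 0 of each stratum is the case.

    ``X`` has shape ``(n_strata, m, p)`` (or ``(n_strata, m)`` for a single
    covariate).  Numerically stabilized with log-sum-exp.
    """
    X = _as_strata_array(X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta  # (S, m)
    return float(np.sum(eta[:, 0] - logsumexp(eta, axis=1)))


def _score_hessian(beta: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    eta = X @ beta  # (S, m)
    ll = float(np.sum(eta[:, 0] - logsumexp(eta, axis=1)))
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))  # (S, m)
    xbar = np.einsum("sm,smp->sp", p, X)  # within-stratum expected covariate
    score = (X[:, 0, :] - xbar).sum(axis=0)
    # observed information = sum_s cov_p(x) = sum_s E[xx'] - xbar xbar'
    exx = np.einsum("sm,smp,smq->pq", p, X, X)
    info = exx - xbar.T @ xbar
    return ll, score, info


@dataclass
class CLRFit:
    """A converged conditional-logistic fit for one model."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    aic: float
    or_: np.ndarray
    ci95: np.ndarray  # (p, 2)
    p: np.ndarray
    converged: bool
    n_strata: int
    iterations: int
    dropped: tuple[str, ...] = ()
    vcov: np.ndarray | None = None

    @property
    def lr_stat(self) -> float:
        """Likelihood-ratio statistic against the all-zero model."""
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lr_p(self) -> float:
        return float(stats.chi2.sf(self.lr_stat, df=len(self.beta)))

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise CLRError(f"unknown term {term!r}; fit has {self.terms}") from None

    def to_record(self) -> dict:
        rec = {"loglik": self.loglik, "aic": self.aic, "converged": self.converged,
               "n_strata": self.n_strata}
        for i, t in enumerate(self.terms):
            rec[t] = {"beta": float(self.beta[i]), "se": float(self.se[i]),
                      "or": float(self.or_[i]), "lo": float(self.ci95[i, 0]),
                      "hi": float(self.ci95[i, 1]), "p": float(self.p[i])}
        return rec


def fit_conditional_logit(
    X: np.ndarray,
    terms: Sequence[str] | None = None,
    max_iter: int = 60,
    tol_loglik: float = 1e-10,
    tol_score: float = 1e-6,
    separation_guard: float = 15.0,
    drop_constant: bool = True,
) -> CLRFit:
    """Maximize the conditional likelihood; member 0 of each stratum is the case.

    Within-stratum-constant columns are dropped (they cancel from the
    likelihood); a rank-deficient remainder raises
    :class:`RankDeficiencyError`; a standardized coefficient exceeding
    ``separation_guard`` raises :class:`SeparationError`.
    """
    X = _as_strata_array(X)
    S, m, p_all = X.shape
    names = tuple(terms) if terms is not None else tuple(f"x{i}" for i in range(p_all))
    if len(names) != p_all:
        raise CLRError(f"{p_all} columns but {len(names)} term names")

    centered = X - X.mean(axis=1, keepdims=True)
    sd = centered.reshape(-1, p_all).std(axis=0)
    keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        if not drop_constant:
            raise CLRError(f"within-stratum-constant columns: {dropped}")
        logger.info("dropping within-stratum-constant columns (matched out): %s", dropped)
    Xk = X[:, :, keep]
    names_k = tuple(n for n, k in zip(names, keep) if k)
    sd_k = sd[keep]
    p = Xk.shape[2]
    if p == 0:
        raise CLRError("no within-stratum-varying covariates remain")
    flat = (Xk - Xk.mean(axis=1, keepdims=True)).reshape(-1, p)
    if np.linalg.matrix_rank(flat) < p:
        # identify a minimal set of dependent columns for the error message
        bad = []
        rank = 0
        cols: list[int] = []
        for j in range(p):
            trial = flat[:, cols + [j]]
            if np.linalg.matrix_rank(trial) > rank:
                cols.append(j)
                rank += 1
            else:
                bad.append(names_k[j])
        raise RankDeficiencyError(f"design matrix rank-deficient; dependent columns: {bad}")

    # fit on the standardized column scale for a well-conditioned Newton step
    Xs = Xk / sd_k
    beta_s = np.zeros(p)
    ll_null = conditional_loglik(np.zeros(p), Xs)
    ll = ll_null
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, info = _score_hessian(beta_s, Xs)
        if np.max(np.abs(beta_s)) > separation_guard:
            bad = tuple(n for n, b in zip(names_k, beta_s) if abs(b) > separation_guard)
            raise SeparationError(
                "coefficient diverging (|standardized beta| > "
                f"{separation_guard}) for {bad}; likely complete or "
                "quasi-complete separation",
                offending=bad,
            )
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix; flat likelihood") from None
        # step-halving to guarantee ascent; the slack tolerates float-level
        # noise in the flat neighborhood of the optimum
        scale = 1.0
        for _ in range(30):
            ll_new = conditional_loglik(beta_s + scale * step, Xs)
            if ll_new >= ll - 1e-9 * (abs(ll) + 1.0):
                break
            scale *= 0.5
        beta_s = beta_s + scale * step
        if abs(ll_new - ll) <= tol_loglik * (abs(ll) + 1e-12) and np.max(np.abs(score)) < tol_score:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if np.max(np.abs(beta_s)) > separation_guard:
        bad = tuple(n for n, b in zip(names_k, beta_s) if abs(b) > separation_guard)
        raise SeparationError(
            f"coefficient diverged past the separation guard for {bad}", offending=bad
        )

    _, score, info = _score_hessian(beta_s, Xs)
    if not converged and np.max(np.abs(score)) < tol_score:
        converged = True
    try:
        vcov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(info)
        bad = (names_k[int(np.argmax(np.abs(evecs[:, 0])))],)
        raise SeparationError(
            f"singular information at the optimum; flat direction involves {bad}",
            offending=bad,
        ) from None
    diag = np.diag(vcov_s)
    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
        bad = tuple(n for n, d in zip(names_k, diag) if not (np.isfinite(d) and d > 0))
        raise SeparationError(
            f"degenerate standard errors for {bad}; flat or ill-conditioned likelihood",
            offending=bad,
        )
    beta = beta_s / sd_k
    vcov = vcov_s / np.outer(sd_k, sd_k)
    se = np.sqrt(np.diag(vcov))
    with np.errstate(over="ignore"):  # tiny-scale covariates can overflow to inf CI
        ci = np.column_stack([np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)])
        ors = np.exp(beta)
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return CLRFit(
        terms=names_k,
        beta=beta,
        se=se,
        loglik=ll,
        loglik_null=ll_null,
        aic=-2.0 * ll + 2.0 * p,
        or_=ors,
        ci95=ci,
        p=pvals,
        converged=converged,
        n_strata=S,
        iterations=it,
        dropped=dropped,
        vcov=vcov,
    )


def or_ci(fit: CLRFit, term: str | int = 0, scale: float = 1.0) -> tuple[float, float, float, float]:
    """Odds ratio, 95% CI, and Wald p for one term, rescaled to ``scale`` units.

    ``OR = exp(scale * beta)`` with CI ``exp(scale * (beta +- 1.96 se))``; the
    Wald p-value is scale-invariant.
    """
    if not fit.converged:
        raise NotConvergedError("or_ci requires a converged fit")
    i = fit.term_index(term) if isinstance(term, str) else int(term)
    b, s = float(fit.beta[i]), float(fit.se[i])
    with np.errstate(over="ignore"):
        return (
            float(np.exp(scale * b)),
            float(np.exp(scale * (b - Z_95 * s))),
            float(np.exp(scale * (b + Z_95 * s))),
            float(2.0 * stats.norm.sf(abs(b / s))),
        )


# ---------------------------------------------------------------------------
# DataFrame interface and the effect-modifier screening workflow
# ---------------------------------------------------------------------------

#: lags at which squared apparent temperature enters the base model
AT_SQUARED_LAGS = ("0", "1", "01", "04")


@dataclass
class ModelSpec:
    """One CLR model: exposure term, scaling, confounders, screening thresholds.

    ``scale`` is the exposure unit of the reported OR (default: per 10 ug/m3);
    internally the exposure covariate is divided by ``scale`` so the fitted
    coefficient is already per-unit.
    """

    surface: str
    lag: str
    scale: float = 10.0
    confounders: tuple[str, ...] | None = None  # None -> standard base set
    modifier_groups: Mapping[str, tuple[str, ...]] | None = None
    p_screen: float = 0.09
    p_final: float = 0.05

    def __post_init__(self) -> None:
        self.lag = str(self.lag)
        if not (0.0 < self.p_final <= self.p_screen < 1.0):
            raise CLRError("need 0 < p_final <= p_screen < 1")

    @property
    def exposure_col(self) -> str:
        return f"{self.surface}_l{self.lag}"

    def base_covariates(self, available: Sequence[str]) -> list[str]:
        if self.confounders is not None:
            return list(self.confounders)
        covs = []
        at = f"AT_l{self.lag}"
        if at in available:
            covs.append(at)
            if self.lag in AT_SQUARED_LAGS:
                covs.append(at + "_sq")
        covs += [c for c in ("pollen", "holiday", "snowstorm") if c in available]
        return covs


#: The four screening groups of candidate effect modifiers.
DEFAULT_MODIFIER_GROUPS: Mapping[str, tuple[str, ...]] = {
    "comorbidity": ("diabetes", "hypertension", "atherosclerosis"),
    "demographic": ("gender", "age", "race"),
    "socioeconomic": ("insurance", "poverty_pct", "log10_popden"),
    "season": ("season",),
}


def _stratum_matrix(strata: pd.DataFrame, columns: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
    """Reshape the long stratum table into a (S, 4, p) array, case first."""
    needed = ["stratum_id", "is_case", *columns]
    missing = set(needed) - set(strata.columns)
    if missing:
        raise CLRError(f"stratum table missing columns {sorted(missing)}")
    df = strata.sort_values(["stratum_id", "is_case"], ascending=[True, False], kind="stable")
    counts = df.groupby("stratum_id", sort=False).agg(n=("is_case", "size"), k=("is_case", "sum"))
    bad = counts[(counts["k"] != 1)]
    if len(bad):
        raise CLRError(f"strata without exactly one case: {list(bad.index[:5])} ...")
    if counts["n"].nunique() != 1:
        raise CLRError("strata have unequal sizes; expected a fixed 1:M ratio")
    m = int(counts["n"].iloc[0])
    vals = df[list(columns)].to_numpy(dtype=float)
    return vals.reshape(-1, m, len(columns)), df


def _encode(strata: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design columns: pass numerics through, dummy-code categoricals."""
    out = pd.DataFrame(index=strata.index)
    names: list[str] = []
    for col in columns:
        if col not in strata.columns:
            raise CLRError(f"column {col!r} not in stratum table")
        ser = strata[col]
        if ser.dtype == bool:
            out[col] = ser.astype(float)
            names.append(col)
        elif pd.api.types.is_numeric_dtype(ser):
            out[col] = ser.astype(float)
            names.append(col)
        else:
            dummies = pd.get_dummies(ser.astype("category"), prefix=col, drop_first=True)
            for d in dummies.columns:
                out[d] = dummies[d].astype(float)
                names.append(d)
    return out, names


def fit_clr(spec: ModelSpec, strata: pd.DataFrame, extra_terms: Sequence[str] = ()) -> CLRFit:
    """Fit the base CLR model of a :class:`ModelSpec` on a long stratum table."""
    df = strata.copy()
    if spec.exposure_col not in df.columns:
        raise CLRError(f"exposure column {spec.exposure_col!r} not in stratum table")
    at = f"AT_l{spec.lag}"
    if at in df.columns and at + "_sq" not in df.columns:
        # square the centered temperature so the quadratic term is not
        # near-collinear with the linear term
        df[at + "_sq"] = (df[at] - df[at].mean()) ** 2
    df["_exposure"] = df[spec.exposure_col] / spec.scale
    covs = spec.base_covariates(df.columns) + list(extra_terms)
    design, names = _encode(df, covs)
    design.insert(0, "exposure", df["_exposure"])
    names = ["exposure"] + names
    work = pd.concat([df[["stratum_id", "is_case"]], design], axis=1)
    mask = work[names].notna().all(axis=1)
    complete = work.loc[mask.groupby(work["stratum_id"]).transform("all")]
    n_lost = work["stratum_id"].nunique() - complete["stratum_id"].nunique()
    if n_lost:
        logger.info("fit_clr excluded %d strata with missing covariates", n_lost)
    # Referent-month designs can render calendar confounders (holiday,
    # snowstorm, season-linked terms) quasi-separated inside subsets; such
    # confounders are dropped with a warning and the fit retried.  A
    # separating exposure term is a genuine failure and propagates.
    active = list(names)
    for _ in range(len(names)):
        X, _ = _stratum_matrix(complete, active)
        try:
            return fit_conditional_logit(X, terms=active)
        except SeparationError as exc:
            droppable = [t for t in exc.offending if t != "exposure"]
            if not droppable:
                raise
            logger.warning("dropping quasi-separated confounders %s and refitting", droppable)
            active = [t for t in active if t not in droppable]
    raise CLRError("could not obtain a stable fit after dropping confounders")


@dataclass
class ScreeningResult:
    """Outcome of the four-group effect-modifier screen."""

    retained: tuple[str, ...]
    per_group: Mapping[str, Mapping[str, float]]  # group -> term -> p
    failed_groups: tuple[str, ...] = ()


def screen_effect_modifiers(
    spec: ModelSpec,
    strata: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
    mode: str = "auto",
) -> ScreeningResult:
    """Screen candidate effect modifiers group by group at ``p <= p_screen``.

    Each group is fitted as base model + group terms; a modifier is retained
    iff its term's Wald p is at or below the screening threshold.  ``mode``:

    * ``"main"`` — the modifier enters as its own term;
    * ``"interaction"`` — as an exposure x modifier product;
    * ``"auto"`` (default) — main effect where the modifier varies within
      strata, exposure interaction where it is matched out (a case and its
      referent controls are the same person, so person-level modifiers can
      only act through interaction).
    """
    if mode not in ("auto", "main", "interaction"):
        raise CLRError(f"unknown screening mode {mode!r}")
    if groups is None:
        groups = {
            g: tuple(c for c in cols if c in strata.columns)
            for g, cols in DEFAULT_MODIFIER_GROUPS.items()
        }
        groups = {g: cols for g, cols in groups.items() if cols}
    df = strata.copy()
    df["_exposure"] = df[ModelSpec(spec.surface, spec.lag).exposure_col] / spec.scale

    retained: list[str] = []
    per_group: dict[str, dict[str, float]] = {}
    failed: list[str] = []
    for group, cols in groups.items():
        if not cols:
            continue
        encoded, enc_names = _encode(df, list(cols))
        work = pd.concat([df, encoded[[c for c in encoded.columns if c not in df.columns]]], axis=1)
        terms = []
        for name in enc_names:
            varies = (
                work.groupby("stratum_id")[name].transform("nunique") > 1
            ).any()
            use_interaction = mode == "interaction" or (mode == "auto" and not varies)
            if use_interaction:
                iname = f"exposure:{name}"
                work[iname] = work["_exposure"] * work[name]
                terms.append(iname)
            else:
                terms.append(name)
        try:
            fit = fit_clr(spec, work, extra_terms=terms)
        except CLRError as exc:
            logger.warning("screening group %r failed: %s", group, exc)
            failed.append(group)
            continue
        pvals = {}
        for t in terms:
            if t in fit.terms:
                pvals[t] = float(fit.p[fit.term_index(t)])
                if pvals[t] <= spec.p_screen:
                    retained.append(t)
        per_group[group] = pvals
    return ScreeningResult(tuple(retained), per_group, tuple(failed))
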