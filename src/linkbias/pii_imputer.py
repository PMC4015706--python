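"""Prior-informed imputation (PII) of the linked variable of interest.

Instead of accepting a single best-weighted record, PII carries linkage
uncertainty into the analysis.  Admissions are partitioned by their best
candidate's match probability p*: an unequivocal link (p* > 0.9 by
default) fixes the BSI flag to 1, an unequivocal non-link (p* < 0.2, or
no candidates) fixes it to 0, and everything in between is *equivocal*.
For an equivocal admission a two-point prior over the flag is built from
the candidates (P(BSI=1) = max candidate match probability, since any
true link implies an infection); a likelihood P(BSI=1 | covariates) is
fitted by logistic regression on the unequivocal records; and their
normalised product is the modified probability distribution (MPD).  If
the larger MPD mass reaches the MPD threshold the corresponding flag
value is accepted, otherwise the flag is treated as missing and drawn by
standard multiple imputation from the likelihood model alone.  Repeating
the imputation m times (default 5) yields completed datasets whose
analyses are pooled with Rubin's rules.

A low MPD threshold (0.1) gives precedence to the prior (candidate
records); a high threshold (0.9) routes almost every equivocal record
through likelihood-based multiple imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .linkage_core import PairSet

__all__ = [
    "PiiConfig",
    "LinkPartition",
    "Mpd",
    "PooledEstimate",
    "LikelihoodModel",
    "partition_links",
    "build_prior",
    "fit_likelihood_model",
    "modified_probability_distribution",
    "impute_voi",
    "run_pii",
    "rubins_rules",
]

DEFAULT_PREDICTORS = ("age_group", "admission_type", "admission_source",
                      "renal_status", "quarter_year")


@dataclass(frozen=True)
class PiiConfig:
    """PII tuning parameters.

    ``p_upper``/``p_lower`` are the unequivocal-link cut-offs on the
    match-probability scale (strict inequalities); ``mpd_threshold`` is
    the standardised acceptance level in [0, 1] for the MPD maximum;
    ``n_imputations`` completed datasets are produced.  ``improper_mi``
    skips the draw of coefficients from their asymptotic posterior
    before each Bernoulli imputation (kept for comparison; the proper
    draw is the default as it propagates estimation uncertainty into the
    between-imputation variance).
    """

    p_upper: float = 0.9
    p_lower: float = 0.2
    mpd_threshold: float = 0.1
    n_imputations: int = 5
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    improper_mi: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_lower < self.p_upper <= 1:
            raise ValueError("need 0 <= p_lower < p_upper <= 1")
        if not 0 <= self.mpd_threshold <= 1:
            raise ValueError("mpd_threshold must be in [0, 1]")
        if self.n_imputations < 2:
            raise ValueError("n_imputations must be >= 2")


@dataclass
class LinkPartition:
    """Admissions split by linkage certainty.

    The three id arrays partition the admission file; ``candidates``
    holds, for each equivocal admission, its retained candidate pairs
    (match probabilities within [p_lower, p_upper])."""

    unequivocal_links: np.ndarray
    unequivocal_nonlinks: np.ndarray
    equivocal: np.ndarray
    candidates: pd.DataFrame


@dataclass(frozen=True)
class Mpd:
    """Normalised two-point modified probability distribution."""

    p_zero: float
    p_one: float


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate across imputations."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def partition_links(admissions: pd.DataFrame, pairs: PairSet,
                    cfg: PiiConfig) -> LinkPartition:
    """Classify every admission by its maximum candidate match probability."""
    df = pairs.df
    if "match_probability" not in df:
        raise ValueError("pairs carry no match probabilities")
    best = df.groupby("admission_id")["match_probability"].max()
    adm_ids = admissions["admission_id"].to_numpy()
    p_star = pd.Series(best, index=adm_ids).fillna(0.0).to_numpy()

    links = adm_ids[p_star > cfg.p_upper]
    nonlinks = adm_ids[p_star < cfg.p_lower]
    equiv = adm_ids[(p_star >= cfg.p_lower) & (p_star <= cfg.p_upper)]
    cand = df[df["admission_id"].isin(equiv)
              & df["match_probability"].between(cfg.p_lower, cfg.p_upper)]
    return LinkPartition(unequivocal_links=links, unequivocal_nonlinks=nonlinks,
                         equivocal=equiv, candidates=cand.copy())


def build_prior(candidate_probabilities) -> float:
    """Two-point prior for an equivocal admission: P(BSI=1) is the maximum
    candidate match probability (a true link implies infection, so the
    best candidate bounds the admission's infection probability)."""
    probs = np.asarray(candidate_probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("equivocal admission needs at least one candidate")
    return float(probs.max())


class LikelihoodModel:
    """Logistic model of P(BSI=1 | covariates), fitted on unequivocal records.

    Categorical predictors are dummy-coded; a ridge-penalised refit
    (penalty 1e-3) replaces the MLE when the fit does not converge or
    separates.  ``sample_params`` draws from the asymptotic normal
    posterior for proper multiple imputation."""

    def __init__(self, params: np.ndarray, cov: np.ndarray, columns: list,
                 predictors: Sequence[str]):
        self.params = params
        self.cov = cov
        self.columns = columns
        self.predictors = list(predictors)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        if not self.predictors:
            return np.ones((len(data), 1))
        X = pd.get_dummies(data[self.predictors], drop_first=True, dtype=float)
        X = X.reindex(columns=self.columns[1:], fill_value=0.0)
        return np.column_stack([np.ones(len(data)), X.to_numpy()])

    def predict(self, data: pd.DataFrame,
                params: Optional[np.ndarray] = None) -> np.ndarray:
        beta = self.params if params is None else params
        eta = self.design(data) @ beta
        return 1.0 / (1.0 + np.exp(-eta))

    def sample_params(self, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.params, self.cov, method="svd")


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-3):
    """Newton-Raphson ridge logistic fit; returns (beta, cov)."""
    beta = np.zeros(X.shape[1])
    pen = alpha * np.eye(X.shape[1])
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = X.T @ (X * w[:, None]) + 2 * pen
        grad = X.T @ (y - p) - 2 * pen @ beta
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + 2 * pen)
    return beta, cov


def fit_likelihood_model(unequivocal: pd.DataFrame,
                         predictors: Sequence[str] = DEFAULT_PREDICTORS,
                         outcome: str = "voi") -> LikelihoodModel:
    """Fit the BSI likelihood P(VOI=1 | predictors) on unequivocal records."""
    y = unequivocal[outcome].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("unequivocal records must contain both VOI values")
    predictors = [p for p in predictors if p in unequivocal.columns]
    if predictors:
        Xdf = pd.get_dummies(unequivocal[predictors], drop_first=True,
                             dtype=float)
        columns = ["const"] + list(Xdf.columns)
        X = np.column_stack([np.ones(len(unequivocal)), Xdf.to_numpy()])
    else:
        columns = ["const"]
        X = np.ones((len(unequivocal), 1))

    params = cov = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if (res.mle_retvals.get("converged", False)
                    and np.all(np.isfinite(res.params))
                    and np.all(np.isfinite(res.cov_params()))
                    and np.max(np.abs(res.params)) < 15):
                params, cov = np.asarray(res.params), np.asarray(res.cov_params())
        except Exception:
            pass
    if params is None:
        warnings.warn("likelihood logit did not converge; using ridge fit",
                      stacklevel=2)
        params, cov = _ridge_logit(X, y)
    return LikelihoodModel(params=params, cov=cov, columns=columns,
                           predictors=predictors)


def modified_probability_distribution(prior_p_one: float,
                                      likelihood_p: float) -> Mpd:
    """Normalised product of the two-point prior and the likelihood."""
    if not (0 <= prior_p_one <= 1 and 0 <= likelihood_p <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    one = prior_p_one * likelihood_p
    zero = (1 - prior_p_one) * (1 - likelihood_p)
    tot = one + zero
    if tot == 0:
        raise ValueError("degenerate prior/likelihood: both masses are zero")
    return Mpd(p_zero=zero / tot, p_one=one / tot)


def impute_voi(mpd: Mpd, likelihood_p: float, cfg: PiiConfig,
               rng: np.random.Generator):
    """One admission's VOI for one imputation: MPD argmax when its maximum
    reaches the threshold, otherwise a Bernoulli draw from the likelihood."""
    if max(mpd.p_zero, mpd.p_one) >= cfg.mpd_threshold:
        return (1 if mpd.p_one >= mpd.p_zero else 0), "mpd"
    return int(rng.random() < likelihood_p), "mi"


def run_pii(admissions: pd.DataFrame, pairs: PairSet, cfg: PiiConfig,
            rng: Optional[np.random.Generator] = None) -> list[pd.DataFrame]:
    """Produce ``cfg.n_imputations`` completed datasets.

    Each dataset is the admissions file plus columns ``voi`` and
    ``provenance`` ("fixed" for unequivocal records, "mpd" for prior-
    driven acceptances — both constant across imputations — and "mi" for
    multiply-imputed values drawn per imputation)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    part = partition_links(admissions, pairs, cfg)

    voi_fixed = pd.Series(np.nan, index=admissions["admission_id"].to_numpy())
    voi_fixed.loc[part.unequivocal_links] = 1.0
    voi_fixed.loc[part.unequivocal_nonlinks] = 0.0

    uneq = admissions[admissions["admission_id"].isin(
        np.concatenate([part.unequivocal_links, part.unequivocal_nonlinks]))]
    uneq = uneq.assign(voi=voi_fixed.loc[uneq["admission_id"]].to_numpy())

    equiv = admissions[admissions["admission_id"].isin(part.equivocal)]
    if len(equiv) and uneq["voi"].nunique() > 1:
        model = fit_likelihood_model(uneq, cfg.predictors)
        lik_p = model.predict(equiv)
    elif len(equiv):
        # degenerate unequivocal set: flat likelihood
        model = None
        lik_p = np.full(len(equiv), 0.5)
    else:
        model, lik_p = None, np.empty(0)

    prior = (part.candidates.groupby("admission_id")["match_probability"].max()
             .reindex(equiv["admission_id"]).to_numpy()) if len(equiv) else np.empty(0)
    mpd_one = np.empty(len(equiv))
    use_mpd = np.zeros(len(equiv), dtype=bool)
    for i, (pp, lp) in enumerate(zip(prior, lik_p)):
        mpd = modified_probability_distribution(pp, lp)
        mpd_one[i] = mpd.p_one
        use_mpd[i] = max(mpd.p_zero, mpd.p_one) >= cfg.mpd_threshold
    mpd_value = (mpd_one >= 0.5).astype(float)

    datasets = []
    for _ in range(cfg.n_imputations):
        sub = rng.spawn(1)[0]
        voi = voi_fixed.copy()
        prov = pd.Series("fixed", index=voi.index)
        if len(equiv):
            eq_ids = equiv["admission_id"].to_numpy()
            vals = np.empty(len(equiv))
            vals[use_mpd] = mpd_value[use_mpd]
            if (~use_mpd).any():
                if model is not None and not cfg.improper_mi:
                    p_mi = model.predict(equiv, params=model.sample_params(sub))
                else:
                    p_mi = lik_p
                vals[~use_mpd] = (sub.random((~use_mpd).sum())
                                  < p_mi[~use_mpd]).astype(float)
            voi.loc[eq_ids] = vals
            prov.loc[eq_ids] = np.where(use_mpd, "mpd", "mi")
        out = admissions.copy()
        out["voi"] = voi.loc[out["admission_id"]].to_numpy().astype(int)
        out["provenance"] = prov.loc[out["admission_id"]].to_numpy()
        datasets.append(out)
    return datasets


def rubins_rules(estimates, variances) -> PooledEstimate:
    """Pool point estimates and variances across imputations.

    Q-bar = mean estimate; W = mean within-imputation variance; B =
    between-imputation (sample) variance; T = W + (1 + 1/m) B; degrees of
    freedom (m - 1)(1 + W / ((1 + 1/m) B))^2, infinite when B = 0; the
    95% interval uses the t distribution on those df."""
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.size < 2:
        raise ValueError("need m >= 2 paired estimates and variances")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    m = q.size
    qbar = q.mean()
    w = v.mean()
    b = q.var(ddof=1)
    t = w + (1 + 1 / m) * b
    if b == 0:
        dof = np.inf
        crit = scipy.stats.norm.ppf(0.975)
    else:
        with np.errstate(over="ignore"):
            dof = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
        crit = scipy.stats.t.ppf(0.975, dof) if np.isfinite(dof) else \
            scipy.stats.norm.ppf(0.975)
    half = crit * np.sqrt(t)
    return PooledEstimate(point=float(qbar), within_var=float(w),
                          between_var=float(b), total_var=float(t),
                          df=float(dof), ci=(float(qbar - half),
                                             float(qbar + half)))
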