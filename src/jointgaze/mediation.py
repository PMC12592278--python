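"""Quasi-Bayesian causal mediation of group differences by pupil arousal.

Tests whether a group difference in per-trial RJA likelihood runs through
a pupillometric mediator (e.g. baseline pupil size).  Two parametric
models are fit: a linear mediator model at participant level
(mediator ~ treatment + baseline mediator) and an outcome model on the
per-trial rows (logistic RJA ~ treatment + mediator + baseline mediator).
``k`` Monte-Carlo draws of both coefficient vectors from their asymptotic
normal sampling distributions then propagate parameter uncertainty:
for each draw, potential mediator values M(t) are simulated (including
the mediator model's residual error) and potential outcomes Y(t, M(t'))
are averaged over the sample, giving the average causal mediation effect
(ACME), the average direct effect (ADE) and the total effect on the
probability scale.  By construction ACME + ADE equals the total effect in
every draw.  Point estimates are means over draws; confidence intervals
are [2.5%, 97.5%] percentiles; p-values are two-sided tail proportions.

Controlling for the baseline value of the mediator makes this a moderated
mediation: the mediated path reflects *change* in the mediator rather
than its stable level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSummary:
    point: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class MediationResult:
    acme: EffectSummary
    ade: EffectSummary
    total: EffectSummary
    prop_mediated: EffectSummary
    k: int
    mediator: str
    reliable: bool  # False on separation / non-convergence warnings
    draws: pd.DataFrame  # per-draw acme / ade / total


def _summarize(draws: np.ndarray) -> EffectSummary:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    p_low = float(np.mean(draws <= 0.0))
    p_high = float(np.mean(draws >= 0.0))
    p = min(1.0, 2.0 * min(p_low, p_high))
    return EffectSummary(float(np.mean(draws)), float(lo), float(hi), p)


def mediate(data: pd.DataFrame, outcome: str, treatment: str, mediator: str,
            covariates: tuple[str, ...] = (), unit: str = "participant",
            outcome_type: str = "binary", k: int = 1000,
            rng_seed: int = 0) -> MediationResult:
    """Estimate ACME / ADE / total effect of a binary treatment.

    ``data`` holds one row per trial (or per unit for a purely unit-level
    analysis); ``treatment`` must be 0/1.  The mediator model is fit on
    the collapsed unit-level table, the outcome model on the rows as
    given.  ``outcome_type`` "binary" uses a logistic outcome model;
    "continuous" an OLS outcome model (useful for linear-Gaussian checks
    where ACME has the closed form a*b).
    """
    rng = np.random.default_rng(rng_seed)
    tvals = np.sort(data[treatment].unique())
    if len(tvals) != 2 or not np.array_equal(tvals, [0, 1]):
        raise ValueError("treatment must be binary 0/1")

    unit_cols = [treatment, mediator, *covariates]
    units = data.groupby(unit, sort=True)[unit_cols].first().dropna()
    n_units = len(units)

    # mediator model (linear, unit level)
    Xm = sm.add_constant(units[[treatment, *covariates]].to_numpy())
    m_fit = sm.OLS(units[mediator].to_numpy(), Xm).fit()
    sigma_m = float(np.sqrt(m_fit.scale))
    df_m = int(m_fit.df_resid)

    # outcome model (rows as given)
    rows = data[[outcome, treatment, mediator, *covariates]].dropna()
    Xy = sm.add_constant(rows[[treatment, mediator, *covariates]].to_numpy())
    yv = rows[outcome].to_numpy(dtype=float)
    reliable = True
    if outcome_type == "binary":
        try:
            y_fit = sm.GLM(yv, Xy, family=sm.families.Binomial()).fit()
        except Exception as exc:
            raise RuntimeError(f"outcome model failed: {exc}") from exc
        if np.any(np.abs(y_fit.params) > 15.0):
            log.warning("outcome model shows signs of separation; "
                        "mediation flagged unreliable")
            reliable = False
    elif outcome_type == "continuous":
        y_fit = sm.OLS(yv, Xy).fit()
    else:
        raise ValueError("outcome_type must be 'binary' or 'continuous'")

    m_params = np.asarray(m_fit.params)
    m_cov = np.asarray(m_fit.cov_params())
    y_params = np.asarray(y_fit.params)
    y_cov = np.asarray(y_fit.cov_params())

    cov_mat = units[list(covariates)].to_numpy() if covariates else \
        np.empty((n_units, 0))

    def predict_m(theta, t, eps):
        base = theta[0] + theta[1] * t
        if cov_mat.shape[1]:
            base = base + cov_mat @ theta[2:]
        return base + eps

    def predict_y(theta, t, m):
        eta = theta[0] + theta[1] * t + theta[2] * m
        if cov_mat.shape[1]:
            eta = eta + cov_mat @ theta[3:]
        if outcome_type == "binary":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    acme_d = np.empty(k)
    ade_d = np.empty(k)
    total_d = np.empty(k)
    prop_d = np.empty(k)
    for d in range(k):
        th_m = rng.multivariate_normal(m_params, m_cov)
        th_y = rng.multivariate_normal(y_params, y_cov)
        # residual-variance uncertainty for the mediator model
        sig = sigma_m * np.sqrt(df_m / rng.chisquare(df_m))
        eps = rng.normal(0.0, sig, size=(2, n_units))
        m1 = predict_m(th_m, 1.0, eps[0])
        m0 = predict_m(th_m, 0.0, eps[1])
        y_11 = predict_y(th_y, 1.0, m1)
        y_10 = predict_y(th_y, 1.0, m0)
        y_01 = predict_y(th_y, 0.0, m1)
        y_00 = predict_y(th_y, 0.0, m0)
        acme1 = float(np.mean(y_11 - y_10))
        acme0 = float(np.mean(y_01 - y_00))
        ade1 = float(np.mean(y_11 - y_01))
        ade0 = float(np.mean(y_10 - y_00))
        acme_d[d] = 0.5 * (acme1 + acme0)
        ade_d[d] = 0.5 * (ade1 + ade0)
        total_d[d] = float(np.mean(y_11 - y_00))
        prop_d[d] = acme_d[d] / total_d[d] if total_d[d] != 0 else np.nan

    total = _summarize(total_d)
    acme = _summarize(acme_d)
    ade = _summarize(ade_d)
    finite_prop = prop_d[np.isfinite(prop_d)]
    prop_point = acme.point / total.point if total.point != 0 else float("nan")
    prop = EffectSummary(
        prop_point,
        float(np.percentile(finite_prop, 2.5)) if finite_prop.size else np.nan,
        float(np.percentile(finite_prop, 97.5)) if finite_prop.size else np.nan,
        total.p,
    )
    draws = pd.DataFrame({"acme": acme_d, "ade": ade_d, "total": total_d})
    return MediationResult(acme=acme, ade=ade, total=total,
                           prop_mediated=prop, k=k, mediator=mediator,
                           reliable=reliable, draws=draws)
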