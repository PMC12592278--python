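"""Group-level inference on per-trial feature tables.

Covers the analysis layer around the mixed models: model specification
and design-matrix construction, marginalized cell means with bootstrapped
odds-ratio / effect-size contrasts, likelihood-ratio screening of task
condition factors, change-score cascade regressions, dropout ANOVAs and
their analytic power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import MixedModel, MixedModelResult, lr_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification over a feature table."""

    outcome: str
    factors: tuple[str, ...] = ("group", "timepoint")
    interactions: tuple[tuple[str, str], ...] = (("group", "timepoint"),)
    covariates: tuple[str, ...] = ()
    random: tuple[str, ...] = ("participant", "trial")
    family: str = "binomial"


def build_design(data: pd.DataFrame, factors=(), interactions=(),
                 covariates=()) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept.

    Factor levels are ordered by first appearance unless the column is
    already categorical; the first level is the reference.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for f in factors:
        col = data[f]
        if not isinstance(col.dtype, pd.CategoricalDtype):
            col = pd.Categorical(col, categories=pd.unique(col))
        else:
            col = pd.Categorical(col)
        dummies[f] = {}
        for level in col.categories[1:]:
            vec = (np.asarray(col) == level).astype(float)
            dummies[f][str(level)] = vec
            cols.append(vec)
            names.append(f"{f}[{level}]")
    for fa, fb in interactions:
        for la, va in dummies[fa].items():
            for lb, vb in dummies[fb].items():
                cols.append(va * vb)
                names.append(f"{fa}[{la}]:{fb}[{lb}]")
    for c in covariates:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def fit_mixed(data: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """Fit the mixed model a ``ModelSpec`` describes on a feature table."""
    X, names = build_design(data, spec.factors, spec.interactions,
                            spec.covariates)
    y = data[spec.outcome].to_numpy()
    if spec.family == "binomial":
        y = y.astype(float)
    groups = {g: data[g].to_numpy() for g in spec.random}
    model = MixedModel(y, X, groups, family=spec.family, fe_names=names)
    result = model.fit()
    result.spec = spec  # attached for downstream cell predictions
    return result


# ----- marginalized means and contrasts -----


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float  # OR (binomial) or difference Delta-beta (gaussian)
    ci_low: float
    ci_high: float
    z: float
    p: float


def _cell_row(cell: dict, spec: ModelSpec, names: list[str],
              covariate_means: dict) -> np.ndarray:
    """Design row for a factor-level cell, covariates at their means,
    random effects at zero."""
    row = np.zeros(len(names))
    for j, name in enumerate(names):
        if name == "Intercept":
            row[j] = 1.0
        elif name in covariate_means:
            row[j] = covariate_means[name]
        else:
            terms = name.split(":")
            row[j] = 1.0
            for term in terms:
                f, level = term.split("[")
                level = level.rstrip("]")
                if str(cell.get(f)) != level:
                    row[j] = 0.0
                    break
    return row


def marginal_means(result: MixedModelResult, data: pd.DataFrame,
                   cells: list[dict]) -> pd.DataFrame:
    """Marginalized cell means: inverse-link of the fixed-effect prediction
    with random effects fixed at zero."""
    spec = result.spec
    names = result.fe_names
    cov_means = {c: float(data[c].mean()) for c in spec.covariates}
    rows = []
    for cell in cells:
        sub = data
        for f, level in cell.items():
            sub = sub[sub[f] == level]
        if len(sub) == 0:
            raise ValueError(f"cell {cell} has no data")
        x = _cell_row(cell, spec, names, cov_means)
        eta, se, _ = result.wald(x)
        mean = float(1.0 / (1.0 + np.exp(-eta))) if result.family == "binomial" else eta
        rows.append({**cell, "eta": eta, "se": se, "mean": mean})
    return pd.DataFrame(rows)


def _resample_participants(data: pd.DataFrame, rng: np.random.Generator
                           ) -> pd.DataFrame:
    """Cluster bootstrap: resample participants with replacement, giving
    each draw a fresh participant id so random-effect grouping stays
    honest."""
    ids = data["participant"].unique()
    picks = rng.choice(ids, size=len(ids), replace=True)
    parts = []
    for k, pid in enumerate(picks):
        block = data[data["participant"] == pid].copy()
        block["participant"] = f"boot{k}"
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def marginal_contrasts(result: MixedModelResult, data: pd.DataFrame,
                       pairs: list[tuple[dict, dict]],
                       boot_k: int = 1000, seed: int = 0,
                       ) -> list[ContrastResult]:
    """Pairwise contrasts of marginalized cell means.

    For the binomial family the estimate is the odds ratio between the two
    cells' marginal log-odds; for the Gaussian family the difference of
    cell means.  95% confidence intervals are percentile intervals over
    ``boot_k`` cluster-bootstrap refits (participants resampled with
    replacement); z and p are Wald statistics from the fixed-effect
    covariance.
    """
    if not result.converged:
        raise RuntimeError("refusing contrasts on a non-converged fit")
    spec = result.spec
    names = result.fe_names
    cov_means = {c: float(data[c].mean()) for c in spec.covariates}

    def cell_etas(res, table):
        cm = {c: float(table[c].mean()) for c in spec.covariates}
        return [
            (res.predict_fixed(_cell_row(a, spec, res.fe_names, cm)[None, :])[0],
             res.predict_fixed(_cell_row(b, spec, res.fe_names, cm)[None, :])[0])
            for a, b in pairs
        ]

    point = []
    for a, b in pairs:
        for cell in (a, b):
            sub = data
            for f, level in cell.items():
                sub = sub[sub[f] == level]
            if len(sub) == 0:
                raise ValueError(f"cell {cell} has no data")
        xa = _cell_row(a, spec, names, cov_means)
        xb = _cell_row(b, spec, names, cov_means)
        est, se, z = result.wald(xa - xb)
        p = 2.0 * stats.norm.sf(abs(z))
        point.append((est, z, p))

    rng = np.random.default_rng(seed)
    boots = np.full((boot_k, len(pairs)), np.nan)
    for k in range(boot_k):
        sample = _resample_participants(data, rng)
        try:
            res_k = fit_mixed(sample, spec)
        except Exception as exc:  # pragma: no cover - rare degenerate draw
            log.warning("bootstrap refit %d failed: %s", k, exc)
            continue
        for j, (ea, eb) in enumerate(cell_etas(res_k, sample)):
            boots[k, j] = ea - eb

    out = []
    for j, ((a, b), (est, z, p)) in enumerate(zip(pairs, point)):
        draws = boots[:, j]
        draws = draws[np.isfinite(draws)]
        lo, hi = (np.percentile(draws, [2.5, 97.5]) if draws.size
                  else (np.nan, np.nan))
        label = " vs ".join("/".join(str(v) for v in c.values())
                            for c in (a, b))
        if result.family == "binomial":
            out.append(ContrastResult(label, float(np.exp(est)),
                                      float(np.exp(lo)), float(np.exp(hi)),
                                      z, p))
        else:
            out.append(ContrastResult(label, est, float(lo), float(hi), z, p))
    return out


# ----- condition screen -----


def condition_screen(data: pd.DataFrame, spec: ModelSpec,
                     condition_cols=("cueing", "stimulus", "target_side")
                     ) -> pd.DataFrame:
    """Likelihood-ratio screen of task condition factors.

    Each factor is added (alone) to the base model and tested against it;
    single-level factors are skipped with a log message.
    """
    base = fit_mixed(data, spec)
    rows = []
    for col in condition_cols:
        levels = data[col].nunique()
        if levels < 2:
            log.info("condition %s has a single level; skipped", col)
            continue
        ext = ModelSpec(outcome=spec.outcome,
                        factors=spec.factors + (col,),
                        interactions=spec.interactions,
                        covariates=spec.covariates,
                        random=spec.random, family=spec.family)
        full = fit_mixed(data, ext)
        stat, p = lr_test(full, base, df=levels - 1)
        rows.append({"factor": col, "lr_stat": stat, "df": levels - 1,
                     "p": p})
    return pd.DataFrame(rows)


# ----- cascade linear models -----


@dataclass(frozen=True)
class CascadeResult:
    beta: float  # standardized slope
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: int
    r2: float


def cascade_lm(table: pd.DataFrame, outcome_change: str,
               predictor_change: str,
               covariates: tuple[str, ...] = ()) -> CascadeResult:
    """OLS of one change score on another, on standardized variables.

    Used for developmental-cascade questions: does the baseline-to-end-of-
    treatment change in a trial-level measure predict the baseline-to-
    follow-up change in a development outcome?  A covariate-adjusted
    variant (e.g. controlling for the baseline level) is obtained by
    passing covariate columns.
    """
    import statsmodels.api as sm

    cols = [outcome_change, predictor_change, *covariates]
    sub = table[cols].dropna()
    n = len(sub)
    if n <= len(covariates) + 2:
        raise ValueError(f"too few complete cases (n = {n}) for the model")
    z = (sub - sub.mean()) / sub.std(ddof=1)
    X = sm.add_constant(z[[predictor_change, *covariates]].to_numpy())
    fit = sm.OLS(z[outcome_change].to_numpy(), X).fit()
    ci = fit.conf_int()[1]
    return CascadeResult(
        beta=float(fit.params[1]), ci_low=float(ci[0]), ci_high=float(ci[1]),
        t=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
        df=int(fit.df_resid), r2=float(fit.rsquared))


# ----- dropout ANOVA and power -----


def dropout_anova(table: pd.DataFrame, outcome: str,
                  factors: tuple[str, str] = ("group", "retained")
                  ) -> pd.DataFrame:
    """Two-way Type-II ANOVA with interaction (group x retention status).

    Returns one row per term with sum of squares, F, df, p and eta^2.
    An empty design cell is an error naming the cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    fa, fb = factors
    sub = table[[outcome, fa, fb]].dropna()
    for la, lb in product(sub[fa].unique(), sub[fb].unique()):
        cell = sub[(sub[fa] == la) & (sub[fb] == lb)]
        if len(cell) < 2:
            raise ValueError(f"cell ({la}, {lb}) has fewer than 2 rows")
    sub = sub.rename(columns={outcome: "y", fa: "A", fb: "B"})
    fit = ols("y ~ C(A) * C(B)", data=sub).fit()
    table_ = anova_lm(fit, typ=2)
    ss_total = float(table_["sum_sq"].sum())
    out = table_.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})
    out["eta2"] = out["ss"] / ss_total if ss_total > 0 else 0.0
    if ss_total <= 1e-12:  # constant outcome: no variance to attribute
        out.loc[out.index != "Residual", "F"] = 0.0
        out.loc[out.index != "Residual", "p"] = 1.0
        out["eta2"] = 0.0
    out.index = [i.replace("C(A)", fa).replace("C(B)", fb) for i in out.index]
    return out


def anova_power(eta2: float, n_total: int, df1: int, alpha: float = 0.05,
                n_cells: int = 4, method: str = "chi2") -> float:
    """Analytic power of a fixed-effects ANOVA term.

    The effect size is converted as f^2 = eta^2 / (1 - eta^2) with
    noncentrality lambda = f^2 * N.  ``method="chi2"`` (default) uses the
    large-sample noncentral chi-square reference, the convention that
    reproduces the published power for this design; ``method="ncf"`` uses
    the exact noncentral-F distribution with df2 = N - n_cells.
    """
    if not (0.0 <= eta2 < 1.0):
        raise ValueError("eta2 must lie in [0, 1)")
    if n_total <= df1 + n_cells:
        raise ValueError("sample size too small for the design")
    f2 = eta2 / (1.0 - eta2)
    lam = f2 * n_total
    if lam == 0.0:  # central case; scipy's noncentral tails misbehave at 0
        return float(alpha)
    if method == "chi2":
        crit = stats.chi2.ppf(1.0 - alpha, df1)
        return float(stats.ncx2.sf(crit, df1, lam))
    if method == "ncf":
        df2 = n_total - n_cells
        crit = stats.f.ppf(1.0 - alpha, df1, df2)
        return float(stats.ncf.sf(crit, df1, df2, lam))
    raise ValueError("method must be 'chi2' or 'ncf'")
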