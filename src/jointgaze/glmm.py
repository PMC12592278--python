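"""Mixed models with crossed random intercepts.

Per-trial RJA outcomes are modelled as binomial-logit GLMMs and pupil
features as Gaussian LMMs, in both cases with crossed random intercepts
for participant and trial index:

    g(E[y_ij]) = x_ij' beta + u_i + v_j,   u_i ~ N(0, s_p^2), v_j ~ N(0, s_t^2)

Estimation is maximum likelihood.  For the binomial family the marginal
likelihood is approximated by a Laplace expansion around the joint
(beta, u, v) mode, found by penalized Newton iterations; the variance
parameters are profiled by a derivative-free outer optimization on the
log-SD scale.  For the Gaussian family the same penalized decomposition is
exact, with the residual variance profiled out in closed form.  The
optimizer start is deterministic, so a fit is reproducible given the data.

Fixed-effect covariances come from the conditional (joint-mode) Hessian
block, the usual convention for Laplace fits.  Fits that end with a
variance component at (numerically) zero are flagged singular; fits whose
outer optimization fails are flagged non-converged and downstream
contrasts refuse to run on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit

log = logging.getLogger(__name__)

_SD_FLOOR = 1e-4  # variance components below this SD count as zero
_SINGULAR_SD = 1e-3


@dataclass
class MixedModelResult:
    params: pd.Series  # fixed effects (link scale)
    cov_params: pd.DataFrame
    vc: dict[str, float]  # random-intercept variances per factor
    sigma2_resid: float | None  # Gaussian residual variance
    loglik: float
    family: str
    n: int
    converged: bool
    singular: bool
    ranef: dict[str, pd.Series]
    linear_predictor_fixed: np.ndarray = field(repr=False, default=None)

    @property
    def fe_names(self) -> list[str]:
        return list(self.params.index)

    def predict_fixed(self, X: np.ndarray) -> np.ndarray:
        """Fixed-effects linear predictor (random effects at zero)."""
        return np.asarray(X, dtype=float) @ self.params.to_numpy()

    def wald(self, contrast: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and z for a linear combination of fixed effects."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se, est / se if se > 0 else np.nan


def _encode_groups(groups: dict[str, np.ndarray]
                   ) -> tuple[dict[str, np.ndarray], dict[str, list], list[int]]:
    codes, levels, sizes = {}, {}, []
    for name, raw in groups.items():
        cat = pd.Categorical(raw)
        codes[name] = cat.codes.astype(np.int64)
        levels[name] = list(cat.categories)
        sizes.append(len(cat.categories))
    return codes, levels, sizes


def _assemble_hessian(X, w, codes_list, sizes):
    """Dense [X Z]' W [X Z] for indicator random-effect blocks."""
    p = X.shape[1]
    q = int(np.sum(sizes))
    H = np.zeros((p + q, p + q))
    Xw = X * w[:, None]
    H[:p, :p] = X.T @ Xw
    offs = np.concatenate([[0], np.cumsum(sizes)])[:-1] + p
    for g, (codes, qg, off) in enumerate(zip(codes_list, sizes, offs)):
        for j in range(p):
            H[j, off:off + qg] = np.bincount(codes, weights=Xw[:, j],
                                             minlength=qg)
            H[off:off + qg, j] = H[j, off:off + qg]
        H[off:off + qg, off:off + qg] = np.diag(
            np.bincount(codes, weights=w, minlength=qg))
        for h in range(g + 1, len(codes_list)):
            codes2, q2, off2 = codes_list[h], sizes[h], offs[h]
            cross = np.bincount(codes * q2 + codes2, weights=w,
                                minlength=qg * q2).reshape(qg, q2)
            H[off:off + qg, off2:off2 + q2] = cross
            H[off2:off2 + q2, off:off + qg] = cross.T
    return H


def _eta(X, beta, codes_list, b_parts):
    eta = X @ beta
    for codes, b in zip(codes_list, b_parts):
        eta = eta + b[codes]
    return eta


class MixedModel:
    """ML fit of a mixed model with crossed random intercepts.

    Parameters
    ----------
    y : outcome (0/1 for binomial, real for gaussian)
    X : fixed-effects design matrix (include the intercept column)
    groups : mapping factor name -> per-row group labels
    family : "binomial" (logit link) or "gaussian"
    """

    def __init__(self, y, X, groups: dict, family: str = "binomial",
                 fe_names: list[str] | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if family not in ("binomial", "gaussian"):
            raise ValueError("family must be binomial or gaussian")
        if family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binomial family needs a 0/1 outcome")
        self.family = family
        self.codes, self.levels, self.sizes = _encode_groups(
            {k: np.asarray(v) for k, v in groups.items()})
        for name, size in zip(self.codes, self.sizes):
            if size < 2:
                raise ValueError(f"grouping factor {name!r} needs >= 2 levels")
        self.group_names = list(self.codes)
        self.fe_names = fe_names or [f"x{j}" for j in range(self.X.shape[1])]
        self._warm = None

    # ----- binomial (Laplace) -----

    def _penalized_mode(self, prec, u0):
        """Newton maximization of the joint penalized binomial loglik."""
        y, X = self.y, self.X
        p = X.shape[1]
        sizes = self.sizes
        codes_list = [self.codes[g] for g in self.group_names]
        offs = np.concatenate([[0], np.cumsum(sizes)])[:-1] + p
        prec_vec = np.concatenate(
            [np.full(qg, pr) for qg, pr in zip(sizes, prec)])

        def split(u):
            return u[:p], [u[off:off + qg] for off, qg in zip(offs, sizes)]

        def pen_ll(u):
            beta, bs = split(u)
            eta = _eta(X, beta, codes_list, bs)
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            return ll - 0.5 * float((prec_vec * u[p:] ** 2).sum())

        u = u0.copy()
        ll = pen_ll(u)
        converged = False
        for _ in range(200):
            beta, bs = split(u)
            eta = _eta(X, beta, codes_list, bs)
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = y - mu
            grad = np.empty(p + int(np.sum(sizes)))
            grad[:p] = X.T @ resid
            for off, qg, codes in zip(offs, sizes, codes_list):
                grad[off:off + qg] = np.bincount(codes, weights=resid,
                                                 minlength=qg)
            grad[p:] -= prec_vec * u[p:]
            if np.max(np.abs(grad)) < 1e-7 * (1.0 + abs(ll)):
                converged = True
                break
            H = _assemble_hessian(X, w, codes_list, sizes)
            H[p:, p:] += np.diag(prec_vec)
            try:
                step = linalg.solve(H, grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, grad)[0]
            # step halving
            scale = 1.0
            for _ in range(30):
                cand = u + scale * step
                cand_ll = pen_ll(cand)
                if cand_ll >= ll - 1e-12:
                    u, ll = cand, cand_ll
                    break
                scale *= 0.5
            else:
                break
        beta, bs = split(u)
        eta = _eta(X, beta, codes_list, bs)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        return u, ll, w, converged

    def _laplace_loglik(self, theta):
        """Profile (Laplace) log marginal likelihood at log-SDs ``theta``."""
        sd = np.maximum(np.exp(theta), _SD_FLOOR)
        prec = 1.0 / sd ** 2
        p = self.X.shape[1]
        q = int(np.sum(self.sizes))
        u0 = self._warm if self._warm is not None else np.zeros(p + q)
        u, pen_ll, w, inner_ok = self._penalized_mode(prec, u0)
        self._warm = u
        codes_list = [self.codes[g] for g in self.group_names]
        Hbb = _assemble_hessian(self.X, w, codes_list, self.sizes)[p:, p:]
        prec_vec = np.concatenate(
            [np.full(qg, pr) for qg, pr in zip(self.sizes, prec)])
        Hbb = Hbb + np.diag(prec_vec)
        sign, logdet_h = np.linalg.slogdet(Hbb)
        logdet_d = float(sum(qg * 2.0 * np.log(s)
                             for qg, s in zip(self.sizes, sd)))
        return pen_ll - 0.5 * (logdet_d + logdet_h), u, w, inner_ok

    # ----- gaussian (exact) -----

    def _gaussian_profile(self, theta):
        """Exact profile loglik over log-lambdas (lambda = sd_g / sd_e)."""
        lam = np.maximum(np.exp(theta), _SD_FLOOR)
        n = len(self.y)
        p = self.X.shape[1]
        sizes = self.sizes
        codes_list = [self.codes[g] for g in self.group_names]
        prec_vec = np.concatenate(
            [np.full(qg, 1.0 / l ** 2) for qg, l in zip(sizes, lam)])
        H = _assemble_hessian(self.X, np.ones(n), codes_list, sizes)
        Hp = H.copy()
        Hp[p:, p:] += np.diag(prec_vec)
        rhs = np.empty(p + int(np.sum(sizes)))
        rhs[:p] = self.X.T @ self.y
        offs = np.concatenate([[0], np.cumsum(sizes)])[:-1] + p
        for off, qg, codes in zip(offs, sizes, codes_list):
            rhs[off:off + qg] = np.bincount(codes, weights=self.y,
                                            minlength=qg)
        u = linalg.solve(Hp, rhs, assume_a="pos")
        beta = u[:p]
        bs = [u[off:off + qg] for off, qg in zip(offs, sizes)]
        fitted = _eta(self.X, beta, codes_list, bs)
        rss_pen = float(((self.y - fitted) ** 2).sum()
                        + (prec_vec * u[p:] ** 2).sum())
        sigma2 = rss_pen / n
        sign, logdet = np.linalg.slogdet(Hp[p:, p:])
        logdet_lam = float(sum(qg * 2.0 * np.log(l)
                               for qg, l in zip(sizes, lam)))
        ll = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
              - 0.5 * (logdet + logdet_lam))
        return ll, u, sigma2, Hp

    # ----- public API -----

    def fit(self, start_logsd: float = np.log(0.5)) -> MixedModelResult:
        k = len(self.sizes)
        theta0 = np.full(k, start_logsd)

        # outside the clip box the likelihood is flat; a small quadratic
        # pull lets the simplex terminate at a boundary (variance ~ 0)
        def _boxed(theta):
            clipped = np.clip(theta, -8.0, 3.0)
            return clipped, float(np.sum((theta - clipped) ** 2))

        if self.family == "binomial":
            def objective(theta):
                clipped, pen = _boxed(theta)
                return -self._laplace_loglik(clipped)[0] + pen
        else:
            def objective(theta):
                clipped, pen = _boxed(theta)
                return -self._gaussian_profile(clipped)[0] + pen

        opt = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7,
                                         "maxiter": 400 * k})
        if not opt.success:
            # a fresh simplex from the clipped solution settles boundary
            # (variance ~ 0) cases the first pass circles around
            opt = optimize.minimize(objective, np.clip(opt.x, -8.0, 3.0),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-7,
                                             "maxiter": 400 * k})
        theta = np.clip(opt.x, -8.0, 3.0)
        p = self.X.shape[1]
        sizes = self.sizes
        offs = np.concatenate([[0], np.cumsum(sizes)])[:-1] + p
        codes_list = [self.codes[g] for g in self.group_names]

        if self.family == "binomial":
            loglik, u, w, inner_ok = self._laplace_loglik(theta)
            sd = np.maximum(np.exp(theta), _SD_FLOOR)
            prec_vec = np.concatenate(
                [np.full(qg, 1.0 / s ** 2) for qg, s in zip(sizes, sd)])
            H = _assemble_hessian(self.X, w, codes_list, sizes)
            H[p:, p:] += np.diag(prec_vec)
            cov_all = linalg.inv(H)
            sigma2_resid = None
            vc = {g: float(s ** 2) for g, s in zip(self.group_names, sd)}
            converged = bool(opt.success and inner_ok)
        else:
            loglik, u, sigma2, Hp = self._gaussian_profile(theta)
            cov_all = linalg.inv(Hp) * sigma2
            lam = np.maximum(np.exp(theta), _SD_FLOOR)
            vc = {g: float((l ** 2) * sigma2)
                  for g, l in zip(self.group_names, lam)}
            sigma2_resid = float(sigma2)
            converged = bool(opt.success)

        beta = u[:p]
        singular = any(np.sqrt(v) < _SINGULAR_SD for v in vc.values())
        if singular:
            log.warning("singular fit: a random-intercept variance is ~0")
        if not converged:
            log.warning("mixed-model optimizer did not report convergence")
        ranef = {
            g: pd.Series(u[off:off + qg], index=self.levels[g])
            for g, off, qg in zip(self.group_names, offs, sizes)
        }
        params = pd.Series(beta, index=self.fe_names)
        cov = pd.DataFrame(cov_all[:p, :p], index=self.fe_names,
                           columns=self.fe_names)
        return MixedModelResult(
            params=params, cov_params=cov, vc=vc, sigma2_resid=sigma2_resid,
            loglik=float(loglik), family=self.family, n=len(self.y),
            converged=converged, singular=singular, ranef=ranef,
            linear_predictor_fixed=self.X @ beta,
        )


def nakagawa_r2(result: MixedModelResult) -> tuple[float, float]:
    """Marginal and conditional coefficients of determination.

    mR2 relates the fixed-effects variance to the total outcome variance on
    the link scale; cR2 adds the random-intercept variances.  The residual
    ("distribution-specific") variance is pi^2 / 3 for the binomial-logit
    family and the fitted residual variance for the Gaussian family.
    """
    var_fixed = float(np.var(result.linear_predictor_fixed))
    var_random = float(sum(result.vc.values()))
    return nakagawa_r2_from_components(
        var_fixed, var_random,
        family=result.family, sigma2_resid=result.sigma2_resid)


def nakagawa_r2_from_components(var_fixed: float, var_random: float,
                                family: str = "binomial",
                                sigma2_resid: float | None = None
                                ) -> tuple[float, float]:
    """R2 decomposition from raw variance components (closed form)."""
    if family == "binomial":
        resid = np.pi ** 2 / 3.0
    else:
        if sigma2_resid is None:
            raise ValueError("gaussian family needs sigma2_resid")
        resid = sigma2_resid
    denom = var_fixed + var_random + resid
    if denom == 0:
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + var_random) / denom


def lr_test(full: MixedModelResult, reduced: MixedModelResult,
            df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square test between nested fits."""
    from scipy import stats

    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(stats.chi2.sf(stat, df))
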