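"""Two-group inference on microstate topographies and dynamic features.

Topographies are compared by a randomisation test on the global map
dissimilarity of the group-mean normalised maps (TANOVA), with follow-up
electrode-wise t-tests on normalised absolute voltages.  Dynamic features
are compared with pooled-SD Cohen's d, linear mixed-effects models
(random intercept per subject, Wald z per-class group contrasts) for mean
duration and occurrence, and Dirichlet regression for coverage, which is
compositional (sums to 100% within subject).  Family-wise error across
the 3 k* tested effects is controlled at 0.05 / (2 k*): the coverage
contrasts are not counted as independent tests because coverage is
determined by duration and occurrence together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as spstats

__all__ = [
    "cohens_d",
    "tanova",
    "electrodewise_t",
    "lmm_contrasts",
    "DirichletFit",
    "dirichlet_loglik",
    "dirichlet_regression",
    "fwer_threshold",
]


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Pooled-SD Cohen's d, signed group2 minus group1.

    ``d = (mean2 - mean1) / s_p`` with
    ``s_p = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2))``.
    Convention: group 1 = controls, group 2 = patients, so positive d
    means the value is higher in patients.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                     / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((mean2 - mean1) / pooled)


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    centered = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered ** 2, axis=1))
    if np.any(gfp == 0):
        raise ValueError("zero-variance subject map")
    return centered / gfp[:, None]


def _gmd_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Global map dissimilarity of two stacks of normalised subject maps:
    the GFP of the difference between the group-mean maps."""
    diff = a.mean(axis=0) - b.mean(axis=0)
    return float(np.sqrt(np.mean(diff ** 2)))


def tanova(
    maps_group1: np.ndarray,
    maps_group2: np.ndarray,
    n_perm: int = 4999,
    seed: int = 0,
) -> tuple[float, float]:
    """Randomisation test for a topographic group difference.

    Subject mean maps are normalised to unit GFP; the statistic is the
    GFP of the difference between group-mean normalised maps.  The p-value
    counts label permutations reaching the observed statistic:
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.

    Returns ``(p, observed_statistic)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    a = _normalize_rows(maps_group1)
    b = _normalize_rows(maps_group2)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("channel counts differ between groups")
    observed = _gmd_statistic(a, b)
    # canonical within-group order: p must not depend on how subjects
    # happen to be listed (exchangeability of the permutation scheme)
    a = a[np.lexsort(a.T[::-1])]
    b = b[np.lexsort(b.T[::-1])]
    pooled = np.vstack([a, b])
    n1 = a.shape[0]
    n = pooled.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = _gmd_statistic(pooled[perm[:n1]], pooled[perm[n1:]])
        if stat >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), observed


def electrodewise_t(
    maps_group1: np.ndarray, maps_group2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t-tests per electrode on normalised absolute voltage.

    Subject maps are normalised to unit GFP and rectified; each electrode
    gets a two-sided two-sample t (equal-variance).  Electrodes with zero
    variance in both groups get t = 0, p = 1.
    """
    a = np.abs(_normalize_rows(maps_group1))
    b = np.abs(_normalize_rows(maps_group2))
    t, p = spstats.ttest_ind(b, a, axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return t, p


def lmm_contrasts(
    feature_table: pd.DataFrame,
    feature: str,
    reml: bool = False,
) -> pd.DataFrame:
    """Per-class group effects from a linear mixed-effects model.

    Fits ``feature ~ class * group + age + sex`` with a Gaussian random
    intercept per subject, by maximum likelihood (REML behind the flag).
    The per-class group effect is the group main effect plus that class's
    interaction term; each is reported with SE, Wald z, and two-sided p.
    Rows with a missing feature value are dropped.  A singular fit is
    reported in the ``converged`` column, never silently absorbed.
    """
    import statsmodels.formula.api as smf

    if feature not in feature_table.columns:
        raise ValueError(f"unknown feature {feature!r}")
    df = feature_table.dropna(subset=[feature]).copy()
    classes = sorted(df["class_index"].unique())
    if len(classes) < 2:
        # single class: plain linear model, no within-subject factor
        import statsmodels.api as sm
        df["is_patient"] = (df["group"] == "patient").astype(float)
        df["is_male"] = (df["sex"] == "M").astype(float)
        X = sm.add_constant(df[["is_patient", "age", "is_male"]])
        fit = sm.OLS(df[feature], X).fit()
        est = fit.params["is_patient"]
        se = fit.bse["is_patient"]
        z = est / se
        p = 2 * spstats.norm.sf(abs(z))
        return pd.DataFrame([{
            "class_index": classes[0], "estimate": est, "se": se,
            "z": z, "p": p, "converged": True, "singular": False,
        }])

    df["class_index"] = pd.Categorical(df["class_index"], categories=classes)
    formula = (f"{feature} ~ C(class_index) * C(group, Treatment('control'))"
               " + age + C(sex)")
    singular = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["subject"])
            fit = model.fit(reml=reml, method=["lbfgs", "bfgs"])
        names = list(fit.model.exog_names)
        params = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:len(names), :len(names)]
        converged = bool(fit.converged)
        singular = bool(np.asarray(fit.cov_re).min() <= 1e-8)
    except (np.linalg.LinAlgError, ValueError):
        # random-intercept variance collapsed to the boundary: the mixed
        # model degenerates to its fixed part, refit as OLS and say so
        singular = True
        fit = smf.ols(formula, data=df).fit()
        names = list(fit.model.exog_names)
        params = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
    group_term = "C(group, Treatment('control'))[T.patient]"
    rows = []
    for cls in classes:
        L = np.zeros(len(names))
        L[names.index(group_term)] = 1.0
        inter = (f"C(class_index)[T.{cls}]:"
                 f"C(group, Treatment('control'))[T.patient]")
        if inter in names:
            L[names.index(inter)] = 1.0
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se
        p = 2 * spstats.norm.sf(abs(z))
        rows.append({
            "class_index": cls, "estimate": est, "se": se, "z": z, "p": p,
            "converged": converged, "singular": singular,
        })
    return pd.DataFrame(rows)


@dataclass
class DirichletFit:
    """Fitted Dirichlet regression in the common parameterisation."""

    coefficients: pd.DataFrame      # class x covariate
    cov: np.ndarray                 # covariance of the flattened coefficients
    alpha: np.ndarray               # fitted concentrations, subjects x classes
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))


def dirichlet_loglik(alpha: np.ndarray, y: np.ndarray) -> float:
    """Dirichlet log-likelihood of compositions ``y`` (rows on the simplex).

    ``l = sum_j [ log G(sum_c a_jc) - sum_c log G(a_jc)
    + sum_c (a_jc - 1) log y_jc ]`` with ``G`` the gamma function.
    """
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(special.gammaln(alpha.sum(axis=1))
                        - special.gammaln(alpha).sum(axis=1)
                        + ((alpha - 1) * np.log(y)).sum(axis=1)))


def _prepare_design(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    # age standardised for conditioning; binary group/sex untouched, so the
    # group coefficient and its Wald test are unaffected
    age = table["age"].to_numpy(float)
    sd = age.std(ddof=0)
    age_z = (age - age.mean()) / sd if sd > 0 else age * 0.0
    X = np.column_stack([
        np.ones(len(table)),
        (table["group"] == "patient").astype(float),
        age_z,
        (table["sex"] == "M").astype(float),
    ])
    return X, ["intercept", "group", "age_z", "sex"]


def dirichlet_regression(
    coverage_table: pd.DataFrame,
    eps: float = 1e-6,
    max_iter: int = 5000,
    design: tuple[np.ndarray, list[str]] | None = None,
) -> DirichletFit:
    """Dirichlet regression of coverage on group, age, and sex.

    ``coverage_table`` holds one row per subject x class with columns
    subject, group, age, sex, class_index, coverage_pct.  Compositions
    are coverage/100; boundary zeros are nudged by ``eps`` and the
    composition renormalised (the Dirichlet density is undefined on the
    simplex boundary).  The common parameterisation is used: each class's
    concentration is log-linear in the covariates,
    ``alpha_jc = exp(x_j' beta_c)``; the likelihood is maximised
    numerically and Wald z / p for the group coefficient of every class
    come from the inverse observed information (analytic Hessian).
    """
    wide = coverage_table.pivot_table(
        index="subject", columns="class_index", values="coverage_pct")
    classes = list(wide.columns)
    covars = (coverage_table.drop_duplicates("subject")
              .set_index("subject").loc[wide.index])
    y = wide.to_numpy(float) / 100.0
    y = np.clip(y, eps, None)
    y = y / y.sum(axis=1, keepdims=True)
    if design is None:
        X, covar_names = _prepare_design(covars.reset_index())
    else:
        X, covar_names = design
    n, k = y.shape
    q = X.shape[1]

    path: list[float] = []

    def unpack(beta_flat):
        return beta_flat.reshape(k, q)

    def negloglik(beta_flat):
        beta = unpack(beta_flat)
        eta = X @ beta.T
        if not np.all(np.isfinite(eta)) or eta.max() > 500:
            return np.inf  # overflow guard: reject the step
        alpha = np.exp(eta)  # n x k
        return -dirichlet_loglik(alpha, y)

    def grad(beta_flat):
        beta = unpack(beta_flat)
        alpha = np.exp(X @ beta.T)
        a0 = alpha.sum(axis=1, keepdims=True)
        # d l / d alpha_jc = psi(a0_j) - psi(a_jc) + log y_jc
        dl_dalpha = special.digamma(a0) - special.digamma(alpha) + np.log(y)
        # d alpha_jc / d beta_cq = alpha_jc * x_jq
        g = (dl_dalpha * alpha).T @ X  # k x q
        return -g.ravel()

    def observed_information(beta_flat):
        """Analytic negative Hessian of the log-likelihood, (kq, kq)."""
        beta = unpack(beta_flat)
        alpha = np.exp(X @ beta.T)
        a0 = alpha.sum(axis=1, keepdims=True)
        gterm = special.digamma(a0) - special.digamma(alpha) + np.log(y)
        tri0 = special.polygamma(1, a0)  # psi'(a0), n x 1
        tri = special.polygamma(1, alpha)  # psi'(alpha), n x k
        H = np.zeros((k * q, k * q))
        for c in range(k):
            for d2 in range(c, k):
                w = alpha[:, c] * alpha[:, d2] * tri0[:, 0]
                if c == d2:
                    w = w + alpha[:, c] * gterm[:, c] \
                        - alpha[:, c] ** 2 * tri[:, c]
                block = (X * w[:, None]).T @ X
                H[c * q:(c + 1) * q, d2 * q:(d2 + 1) * q] = block
                if d2 != c:
                    H[d2 * q:(d2 + 1) * q, c * q:(c + 1) * q] = block.T
        return -H

    # moment-based start: pooled mean composition at the moment estimate
    # of the precision, alpha0 = mean(1-mean)/var - 1 averaged over classes
    mean_comp = y.mean(axis=0)
    var_comp = y.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = (mean_comp * (1 - mean_comp)) / var_comp - 1.0
    prec = prec[np.isfinite(prec) & (prec > 0)]
    alpha0 = float(np.mean(prec)) if prec.size else 20.0
    alpha0 = min(max(alpha0, 1.0), 1e6)
    beta0 = np.zeros((k, q))
    beta0[:, 0] = np.log(mean_comp * alpha0)
    beta0 = beta0.ravel()

    # damped Newton ascent (Levenberg-Marquardt regularisation of the
    # observed information): monotone in the log-likelihood by
    # construction, robust to the ill-conditioning of high-precision fits
    x = beta0.copy()
    f0 = negloglik(x)
    lam = 1e-3
    n_iter = 0
    gnorm = float(np.max(np.abs(grad(x))))
    tol = 1e-6 * max(1.0, abs(f0))
    eye = np.eye(k * q)
    while n_iter < max_iter and gnorm > tol:
        g = grad(x)
        H = observed_information(x)
        accepted = False
        for _ in range(60):
            try:
                step = np.linalg.solve(H + lam * eye, g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            xn = x - step
            fn = negloglik(xn)
            if np.isfinite(fn) and fn < f0:
                accepted = True
                break
            lam *= 10
        if not accepted:
            break
        x, f0 = xn, fn
        lam = max(lam / 3.0, 1e-10)
        path.append(-f0)
        gnorm = float(np.max(np.abs(grad(x))))
        tol = 1e-6 * max(1.0, abs(f0))
        n_iter += 1
    if gnorm > tol:
        raise RuntimeError(
            f"Dirichlet regression did not converge after {n_iter} "
            f"iterations (gradient max-norm {gnorm:.3e}); the fitted "
            "precisions may be diverging (compositions too close to their "
            "predicted means)")
    cov = np.linalg.pinv(observed_information(x))
    beta = unpack(x)
    alpha = np.exp(X @ beta.T)
    coef = pd.DataFrame(beta, index=[f"class_{c}" for c in classes],
                        columns=covar_names)
    se = np.sqrt(np.maximum(np.diag(cov), 0)).reshape(k, q)
    rows = []
    gi = covar_names.index("group") if "group" in covar_names else None
    if gi is not None:
        for ci, cls in enumerate(classes):
            est = beta[ci, gi]
            s = se[ci, gi]
            z = est / s if s > 0 else np.nan
            p = 2 * spstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"class_index": cls, "estimate": est, "se": s,
                         "z": z, "p": p})
    return DirichletFit(
        coefficients=coef,
        cov=cov,
        alpha=alpha,
        loglik=float(-f0),
        converged=True,
        n_iter=int(n_iter),
        gradient_norm=gnorm,
        contrasts=pd.DataFrame(rows),
        loglik_path=np.asarray(path),
    )


def fwer_threshold(k_star: int) -> tuple[float, int]:
    """Family-wise error cutoff ``0.05 / (2 k*)`` and the tested-effect count.

    3 k* group effects are examined (three features per class), but the
    coverage contrasts are determined by duration and occurrence and are
    not counted as independent tests, leaving 2 k* in the correction.
    """
    if k_star < 1:
        raise ValueError("k_star must be >= 1")
    return 0.05 / (2 * k_star), 3 * k_star
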