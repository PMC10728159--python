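"""Site harmonization (ComBat) and mixed-effects association models.

ComBat removes per-site location and scale differences from a subjects ×
features table while preserving the effects of protected covariates
(age, sex, and family structure here), optionally shrinking the site
estimates with parametric empirical Bayes. The association between a
network's total cortical representation and cognition is modelled with a
random-intercept linear mixed model (intercept per family, accounting for
siblings), with fixed effects for cognition, age, sex and mean framewise
displacement, Wald tests per coefficient, and Bonferroni adjustment across
networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationModel",
    "AssociationResult",
    "combat_harmonize",
    "family_protect_design",
    "fit_total_representation_model",
    "bonferroni",
]


@dataclass
class HarmonizationModel:
    sites: list[str]
    gamma: np.ndarray        # (n_sites, n_features) location adjustments
    delta_sq: np.ndarray     # (n_sites, n_features) squared scale adjustments
    parametric_eb: bool


@dataclass
class AssociationResult:
    """Per-predictor mixed-model estimates for one network's model."""

    table: pd.DataFrame      # index: predictor; columns: beta, se, t, p, p_bonf
    group_var: float         # random-intercept variance
    grouping: str = "family"


# ---------------------------------------------------------------------------
# ComBat


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Standard ComBat EB iteration for one site's (gamma*, delta*²)."""
    n = np.full(g_hat.size, sdat.shape[0], dtype=float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_harmonize(
    features: np.ndarray | pd.DataFrame,
    site: np.ndarray | pd.Series,
    protected: np.ndarray | None = None,
    parametric_eb: bool = True,
) -> tuple[np.ndarray, HarmonizationModel]:
    """Remove per-site location/scale effects, preserving protected covariates.

    Implements the standard ComBat model: per-feature standardization under
    a design retaining the protected covariates; per-site location
    (``gamma``) and scale (``delta``) estimation, shrunk toward the across-
    feature prior when ``parametric_eb`` is set; then adjustment back to
    the original scale. With a single site the transform is the identity.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    site = np.asarray(site)
    sites = sorted(pd.unique(site).tolist())
    n, p = X.shape
    if site.shape[0] != n:
        raise ValueError("site labels must align with feature rows")

    counts = np.array([(site == s).sum() for s in sites], dtype=float)
    if parametric_eb and np.any(counts < 2):
        raise ValueError("every site needs >= 2 subjects in EB mode")

    batch = np.column_stack([(site == s).astype(float) for s in sites])
    design = batch if protected is None else np.column_stack([batch, protected])
    if protected is not None:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("protected covariate design is rank deficient")

    # standardize: per-feature OLS with site indicators + protected covariates
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    grand = (counts / n) @ beta[: len(sites)]              # weighted site means
    protected_fit = np.zeros_like(X)
    if protected is not None:
        protected_fit = np.asarray(protected, dtype=float) @ beta[len(sites):]
    stand_mean = grand[None, :] + protected_fit
    resid = X - design @ beta
    pooled_var = (resid ** 2).sum(axis=0) / n
    pooled_sd = np.sqrt(pooled_var)
    pooled_sd[pooled_sd == 0] = 1.0
    Z = (X - stand_mean) / pooled_sd[None, :]

    # ddof=0 site variances: makes the single-site transform an exact identity
    gamma_hat = np.vstack([Z[site == s].mean(axis=0) for s in sites])
    delta_hat = np.vstack([
        Z[site == s].var(axis=0) if (site == s).sum() > 1 else np.ones(p)
        for s in sites])
    delta_hat[delta_hat <= 0] = 1e-12

    if parametric_eb and len(sites) > 1 and p > 1:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, s in enumerate(sites):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var()
            a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            if t2 == 0 or not np.isfinite([a, b]).all():
                gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
            else:
                gamma_star[i], delta_star[i] = _it_sol(
                    Z[site == s], gamma_hat[i], delta_hat[i], g_bar, t2, a, b)
    else:
        gamma_star, delta_star = gamma_hat, delta_hat

    out = Z.copy()
    for i, s in enumerate(sites):
        sel = site == s
        out[sel] = (Z[sel] - gamma_star[i][None, :]) / np.sqrt(delta_star[i])[None, :]
    out = out * pooled_sd[None, :] + stand_mean

    model = HarmonizationModel(sites=[str(s) for s in sites],
                               gamma=gamma_star, delta_sq=delta_star,
                               parametric_eb=parametric_eb)
    return out, model


def family_protect_design(family_id: np.ndarray | pd.Series) -> np.ndarray:
    """Indicator columns for multi-member families, for ComBat protection.

    Family is a grouping factor with mostly singleton levels; encoding
    every family would make the design rank deficient, so only families
    with more than one member receive an indicator column.
    """
    fam = pd.Series(np.asarray(family_id))
    counts = fam.value_counts()
    multi = counts.index[counts > 1]
    if len(multi) == 0:
        return np.empty((len(fam), 0))
    return np.column_stack([(fam == f).to_numpy(float) for f in multi])


# ---------------------------------------------------------------------------
# mixed model


def fit_total_representation_model(
    total_representation: np.ndarray,
    cognition: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    mean_fd: np.ndarray,
    family: np.ndarray,
    n_comparisons: int = 17,
) -> AssociationResult:
    """Random-intercept mixed model: TCR ~ cognition + age + sex + meanFD.

    The random intercept is per family (siblings share it). Wald z tests
    with a normal reference per fixed effect; Bonferroni adjustment uses
    ``n_comparisons`` (networks per cognitive domain by default).
    """
    import statsmodels.formula.api as smf

    y = np.asarray(total_representation, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome")
    if y.std() == 0:
        raise ValueError("constant outcome")
    df = pd.DataFrame({
        "tcr": y,
        "cognition": np.asarray(cognition, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "mean_fd": np.asarray(mean_fd, dtype=float),
        "family": np.asarray(family),
    })
    if df.drop(columns="family").isna().any().any():
        raise ValueError("non-finite predictor values")
    model = smf.mixedlm("tcr ~ cognition + age + sex + mean_fd", df,
                        groups=df["family"])
    fit = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise RuntimeError("mixed model failed to converge with any optimizer")
    fe = fit.fe_params
    table = pd.DataFrame({
        "beta": fe,
        "se": fit.bse_fe,
        "t": fit.tvalues[fe.index],
        "p": fit.pvalues[fe.index],
    })
    table["p_bonf"] = bonferroni(table["p"].to_numpy(), n_comparisons)
    return AssociationResult(table=table,
                             group_var=float(fit.cov_re.iloc[0, 0]))


def bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p·m) elementwise."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)
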