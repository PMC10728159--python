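"""Ridge prediction of cognition from vertex-wise network loadings.

The estimator is ridge regression with an unpenalized intercept on
training-standardized features, tuned over a 16-point geometric λ grid
(2⁻¹⁰ … 2⁵) by inner two-fold cross-validation: for each λ the mean
held-out Pearson r and mean MAE over the two inner directions are
computed, min–max normalized across the grid, and summed into an inner
prediction accuracy; the λ maximizing it wins (ties toward smaller λ).
Outer two-fold cross-validation between two disjoint samples estimates
generalizability; repeated random half-splits and outcome-permutation
nulls quantify stability and significance. Covariates (age, sex, site,
mean FD) are removed by residualizing the outcome on the training fold
only — no statistic derived from test data ever touches the model.

All ridge solutions along the grid reuse one economy SVD of the centered,
standardized training matrix, which keeps the nested loops cheap even with
many more features than subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictionConfig",
    "ModelFit",
    "SelectionTrace",
    "AccuracyReport",
    "PermutationNull",
    "make_lambda_grid",
    "prepare_features",
    "residualize_covariates",
    "ridge_fit",
    "inner_select_lambda",
    "run_nested_2fcv",
    "repeated_random_2fcv",
    "permutation_null",
    "per_network_accuracy",
    "sum_weights_by_network",
]


@dataclass(frozen=True)
class PredictionConfig:
    lambda_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-10, 6))
    n_repeats: int = 100
    n_perm: int = 1000
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.lambda_grid)
        if g.size and np.any(np.diff(g) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if self.n_repeats < 1 or self.n_perm < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class ModelFit:
    weights: np.ndarray          # on the standardized feature scale
    intercept: float
    chosen_lambda: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kept: np.ndarray             # mask of non-constant feature columns

    def predict(self, features: np.ndarray) -> np.ndarray:
        Z = (features[:, self.kept] - self.feature_mean) / self.feature_sd
        return Z @ self.weights + self.intercept


@dataclass
class SelectionTrace:
    lambdas: np.ndarray
    mean_r: np.ndarray
    mean_mae: np.ndarray
    score: np.ndarray


@dataclass
class AccuracyReport:
    r: float
    mae: float
    predictions: np.ndarray
    observed: np.ndarray
    chosen_lambda: float
    direction: str = ""


@dataclass
class PermutationNull:
    null_accuracies: np.ndarray
    observed: float
    p_value: float


# ---------------------------------------------------------------------------
# primitives


def make_lambda_grid(config: PredictionConfig | None = None) -> np.ndarray:
    """The 16 ascending powers of two from 2^-10 to 2^5."""
    if config is None:
        config = PredictionConfig()
    return np.asarray(config.lambda_grid, dtype=float)


def prepare_features(loadings: list[np.ndarray],
                     networks: list[int] | None = None) -> np.ndarray:
    """Subjects × features matrix of concatenated vertex loadings.

    Column order is fixed (network, vertex): network k's N columns precede
    network k+1's.
    """
    shapes = {V.shape for V in loadings}
    if len(shapes) != 1:
        raise ValueError("all loading matrices must share dimensions")
    K, _ = loadings[0].shape
    sel = list(range(K)) if networks is None else list(networks)
    return np.vstack([V[sel].ravel() for V in loadings])


def residualize_covariates(
    y_train: np.ndarray,
    y_test: np.ndarray,
    cov_train: np.ndarray,
    cov_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove covariate-explained outcome variation, training-fold fit only.

    Covariate columns (site already one-hot encoded by the caller) plus an
    intercept are regressed on the training outcome; the fitted coefficients
    adjust both folds. Features are untouched.
    """
    Xtr = np.column_stack([np.ones(len(y_train)), cov_train])
    Xte = np.column_stack([np.ones(len(y_test)), cov_test])
    if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(Xtr, y_train, rcond=None)
    return y_train - Xtr @ coef, y_test - Xte @ coef


def encode_covariates(age, sex, site, mean_fd) -> np.ndarray:
    """Covariate design with site one-hot encoded (all levels; intercept
    added downstream, so one level is dropped)."""
    import pandas as pd

    site = pd.Series(np.asarray(site))
    levels = sorted(site.unique().tolist())
    onehot = np.column_stack([(site == s).to_numpy(float) for s in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(site), 0))
    return np.column_stack([np.asarray(age, float), np.asarray(sex, float),
                            np.asarray(mean_fd, float), onehot])


def _standardize_train(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = sd > 0
    return (X[:, kept] - mu[kept]) / sd[kept], mu[kept], sd[kept], kept


def _ridge_path(Z: np.ndarray, y: np.ndarray,
                lambdas: np.ndarray) -> tuple[np.ndarray, float]:
    """Ridge weights for every λ from one SVD of the centered matrix.

    Z is standardized training features; the intercept is the training
    outcome mean (unpenalized, features centered). Returns (W, intercept)
    with W of shape (n_lambdas, p).
    """
    ybar = float(y.mean())
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uty = U.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        d = s[None, :] / (s[None, :] ** 2 + lambdas[:, None])
    d[~np.isfinite(d)] = 0.0  # λ=0 with zero singular values → min-norm
    W = (d * uty[None, :]) @ Vt
    return W, ybar


def ridge_fit(features: np.ndarray, outcome: np.ndarray,
              lam: float) -> ModelFit:
    """Ridge regression with training standardization and unpenalized intercept.

    Minimizes ‖y − Zw − b‖² + λ‖w‖² on the standardized features Z;
    zero-variance columns are dropped and recorded in ``kept``.
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Z, mu, sd, kept = _standardize_train(features)
    W, b = _ridge_path(Z, np.asarray(outcome, float), np.array([lam]))
    return ModelFit(weights=W[0], intercept=b, chosen_lambda=float(lam),
                    feature_mean=mu, feature_sd=sd, kept=kept)


def _accuracy(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    mae = float(np.mean(np.abs(pred - obs)))
    if pred.std() == 0 or obs.std() == 0:
        return np.nan, mae
    return float(np.corrcoef(pred, obs)[0, 1]), mae


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def inner_select_lambda(
    features: np.ndarray,
    outcome: np.ndarray,
    grid: np.ndarray,
    seed: int = 0,
) -> tuple[float, SelectionTrace]:
    """Choose λ by inner two-fold cross-validation.

    The training subset is split into two halves; for each λ the model is
    fit on one half and evaluated on the other, in both directions; mean r
    and mean MAE over the two directions are min–max normalized across the
    grid (mean r together with mean 1/MAE), summed into the inner
    prediction accuracy, and the argmax wins with ties toward smaller λ.
    Constant predictions leave r undefined; such entries take the grid's
    minimum defined r before normalization.
    """
    n = features.shape[0]
    if n < 4:
        raise ValueError("inner selection needs >= 4 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = (perm[: n // 2], perm[n // 2:])
    y = np.asarray(outcome, float)
    r_sum = np.zeros(grid.size)
    mae_sum = np.zeros(grid.size)
    r_count = np.zeros(grid.size)
    for tr, te in (halves, halves[::-1]):
        Z, mu, sd, kept = _standardize_train(features[tr])
        W, b = _ridge_path(Z, y[tr], grid)
        Zte = (features[te][:, kept] - mu) / sd
        preds = Zte @ W.T + b
        for j in range(grid.size):
            r, mae = _accuracy(preds[:, j], y[te])
            mae_sum[j] += mae
            if np.isfinite(r):
                r_sum[j] += r
                r_count[j] += 1
    mean_mae = mae_sum / 2.0
    with np.errstate(invalid="ignore"):
        mean_r = np.where(r_count > 0, r_sum / np.maximum(r_count, 1), np.nan)
    if np.isnan(mean_r).all():
        mean_r = np.zeros_like(mean_r)
    else:
        mean_r = np.where(np.isnan(mean_r), np.nanmin(mean_r), mean_r)
    score = _minmax(mean_r) + _minmax(1.0 / mean_mae)
    best = int(np.argmax(score))  # argmax returns the first (smallest λ) tie
    trace = SelectionTrace(lambdas=grid, mean_r=mean_r, mean_mae=mean_mae,
                           score=score)
    return float(grid[best]), trace


# ---------------------------------------------------------------------------
# nested cross-validation


def _fit_and_test(X_tr, y_tr, X_te, y_te, grid, seed, direction):
    lam, _ = inner_select_lambda(X_tr, y_tr, grid, seed=seed)
    fit = ridge_fit(X_tr, y_tr, lam)
    pred = fit.predict(X_te)
    r, mae = _accuracy(pred, y_te)
    return AccuracyReport(r=r, mae=mae, predictions=pred, observed=y_te,
                          chosen_lambda=lam, direction=direction), fit


def run_nested_2fcv(
    features_a: np.ndarray,
    outcome_a: np.ndarray,
    features_b: np.ndarray,
    outcome_b: np.ndarray,
    config: PredictionConfig | None = None,
    covariates_a: np.ndarray | None = None,
    covariates_b: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[AccuracyReport, AccuracyReport]:
    """Nested two-fold CV between two disjoint samples.

    Direction 1 selects λ inside sample A, trains on all of A and predicts
    B; direction 2 is symmetric. When covariates are given, outcomes are
    residualized with coefficients estimated in the training sample only.
    """
    if config is None:
        config = PredictionConfig()
    if seed is None:
        seed = config.seed
    grid = make_lambda_grid(config)
    ya, yb = np.asarray(outcome_a, float), np.asarray(outcome_b, float)
    reports = []
    ss = np.random.SeedSequence(seed).spawn(2)
    for d, (Xt, yt, ct, Xe, ye, ce) in enumerate((
            (features_a, ya, covariates_a, features_b, yb, covariates_b),
            (features_b, yb, covariates_b, features_a, ya, covariates_a))):
        if ct is not None:
            yt, ye = residualize_covariates(yt, ye, ct, ce)
        inner_seed = int(ss[d].generate_state(1)[0] % (2**31))
        rep, _ = _fit_and_test(Xt, yt, Xe, ye, grid, inner_seed,
                               direction="A->B" if d == 0 else "B->A")
        reports.append(rep)
    return reports[0], reports[1]


def repeated_random_2fcv(
    features: np.ndarray,
    outcome: np.ndarray,
    config: PredictionConfig | None = None,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Accuracy distribution over repeated random half-splits.

    Each repeat randomly splits the cohort in half and runs the full
    nested procedure; returns the (n_repeats, 2) array of held-out r per
    direction.
    """
    if config is None:
        config = PredictionConfig()
    if features.shape[0] < 8:
        raise ValueError("need >= 8 subjects")
    rng = np.random.default_rng(config.seed)
    n = features.shape[0]
    out = np.empty((config.n_repeats, 2))
    for i in range(config.n_repeats):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2:]
        ra, rb = run_nested_2fcv(
            features[a], outcome[a], features[b], outcome[b], config,
            covariates[a] if covariates is not None else None,
            covariates[b] if covariates is not None else None,
            seed=int(rng.integers(2**31)))
        out[i] = (ra.r, rb.r)
    return out


def permutation_null(
    features_a: np.ndarray,
    outcome_a: np.ndarray,
    features_b: np.ndarray,
    outcome_b: np.ndarray,
    config: PredictionConfig | None = None,
    covariates_a: np.ndarray | None = None,
    covariates_b: np.ndarray | None = None,
) -> PermutationNull:
    """Outcome-permutation null for the nested-CV accuracy.

    The observed statistic is the mean held-out r over both directions;
    each permutation shuffles outcomes across all subjects and reruns the
    full nested procedure. p uses the add-one rank formula, one-sided
    toward better-than-null accuracy.
    """
    if config is None:
        config = PredictionConfig()
    rng = np.random.default_rng(config.seed)
    obs_a, obs_b = run_nested_2fcv(features_a, outcome_a, features_b,
                                   outcome_b, config, covariates_a,
                                   covariates_b, seed=int(rng.integers(2**31)))
    observed = 0.5 * (obs_a.r + obs_b.r)
    y_all = np.concatenate([outcome_a, outcome_b])
    na = len(outcome_a)
    nulls = np.empty(config.n_perm)
    for i in range(config.n_perm):
        yp = y_all[rng.permutation(y_all.size)]
        ra, rb = run_nested_2fcv(features_a, yp[:na], features_b, yp[na:],
                                 config, covariates_a, covariates_b,
                                 seed=int(rng.integers(2**31)))
        nulls[i] = 0.5 * (ra.r + rb.r)
    p = (1.0 + np.sum(nulls >= observed)) / (1.0 + config.n_perm)
    return PermutationNull(null_accuracies=nulls, observed=observed, p_value=p)


def per_network_accuracy(
    loadings_a: list[np.ndarray],
    outcome_a: np.ndarray,
    loadings_b: list[np.ndarray],
    outcome_b: np.ndarray,
    config: PredictionConfig | None = None,
    covariates_a: np.ndarray | None = None,
    covariates_b: np.ndarray | None = None,
) -> list[tuple[AccuracyReport, AccuracyReport]]:
    """One nested-2F-CV accuracy pair per network, trained on that
    network's vertex loadings alone."""
    K = loadings_a[0].shape[0]
    out = []
    for k in range(K):
        Xa = prepare_features(loadings_a, [k])
        Xb = prepare_features(loadings_b, [k])
        out.append(run_nested_2fcv(Xa, outcome_a, Xb, outcome_b, config,
                                   covariates_a, covariates_b))
    return out


def sum_weights_by_network(fit: ModelFit, K: int,
                           n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed and absolute sums of model weights within each network block.

    The fit must come from the concatenated all-network feature matrix
    whose columns are (network, vertex)-ordered.
    """
    if K * n_vertices != fit.kept.size:
        raise ValueError("block structure does not match the fitted features")
    full = np.zeros(fit.kept.size)
    full[fit.kept] = fit.weights
    blocks = full.reshape(K, n_vertices)
    return blocks.sum(axis=1), np.abs(blocks).sum(axis=1)
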