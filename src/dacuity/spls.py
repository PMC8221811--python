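"""Sparse-PLS prediction of phenotypes from connectivity edges.

The predictive model is sparse partial least squares (SPLS): per component,
the cross-covariance direction z = X'y is soft-thresholded at a fraction
eta of its largest element, scores are extracted and X deflated, and the
final coefficients come from a dense PLS refit on the union of the active
sets. Around that core sit the study's inference machinery:

* target deconfounding (fitted on training folds only, applied to both),
* a univariate correlation prefilter (p < alpha on the training partition),
* bagging over bootstrap resamples with feature-selection frequencies,
* nested cross-validation (outer folds give out-of-sample predictions, an
  inner grid search on the training partition picks eta and the component
  count),
* permutation inference on the Fisher-transformed cross-validated
  correlation (zero-centered Gaussian null whose SD is estimated from
  permutations of the residualized target),
* module-wise "virtual lesion" scans with Benjamini-Hochberg correction,
* partial-correlation specificity of one phenotype's prediction
  controlling the other, and
* transfer of frozen baseline fold-models to follow-up data with the fold
  structure preserved, so no subject is predicted by a model that saw
  their own baseline data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import edge_index, fisher_z, rng_from
from .network import ConnectivityDataset, ConsensusPartition


@dataclass
class SPLSConfig:
    """Pipeline dimensions. Defaults follow the full-scale design:

    20 outer folds, 10 inner folds, 5 repeats, 200 bootstrap resamples and
    100 permutations, with a p < 0.05 univariate prefilter and the 0.3 mm
    mean-FD exclusion threshold.
    """

    eta_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    k_grid: tuple[int, ...] = (1, 2, 3)
    outer_folds: int = 20
    inner_folds: int = 10
    n_repeats: int = 5
    n_boot: int = 200
    n_perm: int = 100
    prefilter_alpha: float = 0.05
    fd_threshold: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not self.eta_grid or not self.k_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0 < self.prefilter_alpha < 1:
            raise ValueError("prefilter_alpha must be in (0, 1)")
        if any(not 0 <= e < 1 for e in self.eta_grid):
            raise ValueError("eta values must lie in [0, 1)")


@dataclass
class FoldModel:
    """Everything needed to apply one outer-fold model to new data."""

    test_idx: np.ndarray
    confound_beta: np.ndarray
    confound_cols: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    keep: np.ndarray          # prefilter mask over features
    coef: np.ndarray          # dense coefficient vector (zeros off active set)
    intercept: float
    eta: float
    k: int
    selection_freq: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        xs = (X - self.x_mean) / self.x_sd
        return xs @ self.coef + self.intercept


@dataclass
class PredictionResult:
    predictions: np.ndarray       # (n_repeats, n_subjects)
    observed_resid: np.ndarray    # (n_repeats, n_subjects) deconfounded target
    folds: np.ndarray             # (n_repeats, n_subjects) outer fold ids
    r_per_repeat: np.ndarray
    r_mean: float
    fold_models: list             # [repeat][fold] -> FoldModel
    selection_freq: np.ndarray    # mean bootstrap selection frequency per feature
    config: SPLSConfig
    p_value: Optional[float] = None
    null_sd: Optional[float] = None


@dataclass
class PermutationNull:
    null_r: np.ndarray
    sd: float
    p_value: float
    null_predictions: Optional[np.ndarray] = None  # (n_perm, n_repeats, n)
    null_targets: Optional[np.ndarray] = None      # (n_perm, n)


# ---------------------------------------------------------------------------
# SPLS core
# ---------------------------------------------------------------------------


def _pls1_coef(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Dense univariate-response PLS regression coefficients."""
    Xk = X.copy()
    Ws, Ps, Qs = [], [], []
    for _ in range(n_components):
        w = Xk.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xk @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p = Xk.T @ t / tt
        Qs.append((t @ y) / tt)
        Xk = Xk - np.outer(t, p)
        Ws.append(w)
        Ps.append(p)
    if not Ws:
        return np.zeros(X.shape[1])
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    return W @ np.linalg.solve(P.T @ W, np.asarray(Qs))


def fit_spls(X: np.ndarray, y: np.ndarray, eta: float, n_components: int) -> np.ndarray:
    """Sparse PLS coefficient vector.

    X must be standardized and y centered. Per component the cross-covariance
    z = X'y is computed on the deflated matrix, features with
    |z| >= eta * max|z| enter the active set, and the direction is the
    normalized soft-thresholded z. The returned dense coefficients come from
    a dense PLS refit with ``n_components`` components on the union active
    set; at eta = 0 this is exactly dense PLS regression.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("zero-variance target")
    if not 0 <= eta < 1:
        raise ValueError("eta must lie in [0, 1)")
    if n_components < 1 or n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} outside [1, min(n, p)]")

    Xk = X.copy()
    active = np.zeros(X.shape[1], bool)
    for _ in range(n_components):
        z = Xk.T @ y
        zmax = np.abs(z).max()
        if zmax < 1e-12:
            break
        thr = eta * zmax
        comp_active = np.abs(z) >= thr
        w = np.sign(z) * np.clip(np.abs(z) - thr, 0.0, None)
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xk @ w
        tt = t @ t
        if tt < 1e-12:
            break
        Xk = Xk - np.outer(t, Xk.T @ t / tt)
        active |= comp_active

    coef = np.zeros(X.shape[1])
    if active.any():
        k_eff = min(n_components, int(active.sum()))
        coef[active] = _pls1_coef(X[:, active], y, k_eff)
    return coef


# ---------------------------------------------------------------------------
# deconfounding
# ---------------------------------------------------------------------------


def confound_design(covariates: pd.DataFrame,
                    interactions: Sequence[tuple[str, str]] = (("age", "sex"),)) -> pd.DataFrame:
    """Numeric design matrix from a covariate table.

    Categorical columns (site and anything non-numeric) become indicator
    contrasts with the reference level dropped; the listed interactions are
    added as products. The subject column is ignored.
    """
    out = pd.DataFrame(index=covariates.index)
    for col in covariates.columns:
        if col == "subject":
            continue
        vals = covariates[col]
        if col == "site" or not pd.api.types.is_numeric_dtype(vals):
            dummies = pd.get_dummies(vals.astype("category"), prefix=col, drop_first=True)
            out = pd.concat([out, dummies.astype(float)], axis=1)
        else:
            out[col] = vals.astype(float)
    for a, b in interactions:
        if a in out.columns and b in out.columns:
            out[f"{a}_x_{b}"] = out[a] * out[b]
    return out


def deconfound(y: np.ndarray, design: pd.DataFrame, train_idx: np.ndarray):
    """Residualize the target on covariates, fitting on training rows only.

    Returns (residuals for all rows, coefficient vector, column names).
    The coefficient vector includes a leading intercept.
    """
    y = np.asarray(y, float)
    train_idx = np.asarray(train_idx)
    if train_idx.dtype == bool:
        train_idx = np.flatnonzero(train_idx)
    if train_idx.size == 0:
        raise ValueError("empty training index")
    Xd = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    cols = ["intercept"] + list(design.columns)
    Xtr = Xd[train_idx]
    rank = np.linalg.matrix_rank(Xtr)
    if rank < Xtr.shape[1]:
        from scipy.linalg import qr as pivoted_qr

        _, _, piv = pivoted_qr(Xtr, mode="economic", pivoting=True)
        bad = [cols[p] for p in piv[rank:]]
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xtr, y[train_idx], rcond=None)
    resid = y - Xd @ beta
    return resid, beta, cols


# ---------------------------------------------------------------------------
# prefilter + bagging
# ---------------------------------------------------------------------------


def _prefilter_mask(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Features significantly (two-sided Pearson test) correlated with y."""
    n = X.shape[0]
    yc = y - y.mean()
    xs = X - X.mean(axis=0)
    denom = np.sqrt((xs**2).sum(axis=0)) * np.sqrt((yc**2).sum())
    r = np.zeros(X.shape[1])
    ok = denom > 0
    r[ok] = xs[:, ok].T @ yc / denom[ok]
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return (p < alpha) & ok


def bagged_fit(X: np.ndarray, y: np.ndarray, eta: float, n_components: int,
               config: SPLSConfig, rng=None, keep: Optional[np.ndarray] = None):
    """Bagged SPLS: average coefficients over bootstrap resamples.

    The prefilter runs once on the full training partition (not per
    resample); each of ``n_boot`` bootstrap resamples is fitted with SPLS on
    the kept features and the coefficient vectors are averaged. Returns
    (dense coefficients, intercept, selection frequencies, keep mask).
    An empty prefilter yields a training-mean predictor with a warning.
    """
    rng = rng_from(config.seed if rng is None else rng)
    n, p = X.shape
    if keep is None:
        keep = _prefilter_mask(X, y, config.prefilter_alpha)
    coef = np.zeros(p)
    freq = np.zeros(p)
    intercept = float(y.mean())
    if not keep.any():
        warnings.warn("prefilter kept no features; model predicts the training mean")
        return coef, intercept, freq, keep
    Xk = X[:, keep]
    yc = y - intercept
    acc = np.zeros(int(keep.sum()))
    sel = np.zeros(int(keep.sum()))
    for _ in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        yb = yc[idx]
        if yb.std() == 0:
            continue
        xb = Xk[idx]
        b = fit_spls(xb, yb - yb.mean(), eta, min(n_components, min(xb.shape)))
        acc += b
        sel += b != 0
    acc /= config.n_boot
    sel /= config.n_boot
    coef[keep] = acc
    freq[keep] = sel
    return coef, intercept, freq, keep


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold ids stratified by target quantile: contiguous blocks of the
    sorted target are scattered across folds."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, int)
    for start in range(0, n, n_folds):
        block = order[start:start + n_folds]
        folds[block] = rng.permutation(n_folds)[: len(block)]
    return folds


def _select_hyperparams(X: np.ndarray, y: np.ndarray, config: SPLSConfig, rng):
    """Inner-CV grid search; winner by minimum MSE, ties to sparser models."""
    combos = [(e, k) for e in config.eta_grid for k in config.k_grid]
    if len(combos) == 1:
        return combos[0]
    folds = _stratified_folds(y, config.inner_folds, rng)
    mse = np.zeros(len(combos))
    for f in range(config.inner_folds):
        tr = folds != f
        va = ~tr
        if va.sum() == 0 or tr.sum() < 3:
            continue
        ytr = y[tr]
        mu = ytr.mean()
        for c, (eta, k) in enumerate(combos):
            kc = min(k, min(X[tr].shape))
            coef = fit_spls(X[tr], ytr - mu, eta, kc)
            pred = X[va] @ coef + mu
            mse[c] += ((pred - y[va]) ** 2).sum()
    best = mse.min()
    # sparser = larger eta, then smaller K
    ordered = sorted(range(len(combos)), key=lambda c: (-combos[c][0], combos[c][1]))
    for c in ordered:
        if mse[c] <= best + 1e-9 * max(best, 1.0):
            return combos[c]
    return combos[int(np.argmin(mse))]


def _fit_fold(X_std: np.ndarray, y_resid: np.ndarray, config: SPLSConfig, rng):
    """Prefilter -> inner-CV hyperparameter choice -> bagged fit, on one
    outer-fold training partition (features already standardized)."""
    keep = _prefilter_mask(X_std, y_resid, config.prefilter_alpha)
    if keep.any():
        eta, k = _select_hyperparams(X_std[:, keep], y_resid, config, rng)
    else:
        eta, k = config.eta_grid[0], config.k_grid[0]
    coef, intercept, freq, keep = bagged_fit(
        X_std, y_resid, eta, k, config, rng=rng, keep=keep
    )
    return coef, intercept, freq, keep, eta, k


def nested_cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame,
    config: SPLSConfig,
    feature_mask: Optional[np.ndarray] = None,
) -> PredictionResult:
    """Repeated nested-CV out-of-sample prediction of y from features.

    Per outer fold: the target is deconfounded (training rows only),
    features are standardized by training statistics, the inner grid search
    picks (eta, K), a bagged SPLS model is fitted and applied to the test
    fold. Every subject is predicted exactly once per repeat; the per-repeat
    r is the correlation between the assembled residualized target and the
    predictions, and r_mean averages over repeats.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("target contains missing values")
    if feature_mask is not None:
        X = X[:, feature_mask]
    design = confound_design(covariates)
    master = rng_from(config.seed)

    preds = np.zeros((config.n_repeats, n))
    obs = np.zeros((config.n_repeats, n))
    fold_ids = np.zeros((config.n_repeats, n), int)
    r_rep = np.zeros(config.n_repeats)
    all_models: list[list[FoldModel]] = []
    freq_acc = np.zeros(X.shape[1])

    for rep in range(config.n_repeats):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        folds = _stratified_folds(y, config.outer_folds, rng)
        sizes = np.bincount(folds, minlength=config.outer_folds)
        if sizes.min() < 3:
            raise ValueError(
                f"outer fold with {sizes.min()} subjects (< 3); reduce outer_folds"
            )
        rep_models = []
        for f in range(config.outer_folds):
            te = folds == f
            tr = ~te
            resid, cbeta, cols = deconfound(y, design, tr)
            x_mean = X[tr].mean(axis=0)
            x_sd = X[tr].std(axis=0)
            x_sd[x_sd == 0] = 1.0
            Xs = (X - x_mean) / x_sd
            coef, intercept, freq, keep, eta, k = _fit_fold(Xs[tr], resid[tr], config, rng)
            preds[rep, te] = Xs[te] @ coef + intercept
            obs[rep, te] = resid[te]
            freq_acc += freq
            rep_models.append(
                FoldModel(
                    test_idx=np.flatnonzero(te),
                    confound_beta=cbeta,
                    confound_cols=cols,
                    x_mean=x_mean,
                    x_sd=x_sd,
                    keep=keep,
                    coef=coef,
                    intercept=intercept,
                    eta=eta,
                    k=k,
                    selection_freq=freq,
                )
            )
        fold_ids[rep] = folds
        r_rep[rep] = _safe_corr(obs[rep], preds[rep])
        all_models.append(rep_models)

    return PredictionResult(
        predictions=preds,
        observed_resid=obs,
        folds=fold_ids,
        r_per_repeat=r_rep,
        r_mean=float(r_rep.mean()),
        fold_models=all_models,
        selection_freq=freq_acc / (config.n_repeats * config.outer_folds),
        config=config,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def _refit_with_target(result: PredictionResult, X: np.ndarray, target: np.ndarray,
                       config: SPLSConfig, rng) -> tuple[float, np.ndarray]:
    """Refit the whole pipeline on a (permuted) residualized target, keeping
    the fold structure and the per-fold feature standardization fixed."""
    n = target.shape[-1]
    r_rep = np.zeros(config.n_repeats)
    preds = np.zeros((config.n_repeats, n))
    for rep in range(config.n_repeats):
        for fm in result.fold_models[rep]:
            te = np.zeros(n, bool)
            te[fm.test_idx] = True
            tr = ~te
            Xs = (X - fm.x_mean) / fm.x_sd
            coef, intercept, _, _, _, _ = _fit_fold(Xs[tr], target[tr], config, rng)
            preds[rep, te] = Xs[te] @ coef + intercept
        r_rep[rep] = _safe_corr(target, preds[rep])
    return float(r_rep.mean()), preds


def permutation_pvalue(
    result: PredictionResult,
    X: np.ndarray,
    config: Optional[SPLSConfig] = None,
    feature_mask: Optional[np.ndarray] = None,
    keep_null_predictions: bool = False,
    seed: Optional[int] = None,
) -> PermutationNull:
    """One-tailed permutation p for the cross-validated correlation.

    The residualized target is permuted across the whole sample (fold
    structure preserved) and the pipeline refitted per permutation. The null
    r values are Fisher-transformed, the SD of the zero-centered Gaussian
    null is estimated from them, and the observed Fisher-z is referred to
    that null.
    """
    config = result.config if config is None else config
    if config.n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable null variance estimate")
    X = np.asarray(X, float)
    if feature_mask is not None:
        X = X[:, feature_mask]
    rng = rng_from(config.seed + 7919 if seed is None else seed)

    # assembled residualized target (per repeat each subject appears once in
    # a test fold; use the first repeat's assembly as the permutation base)
    base_target = result.observed_resid[0]
    null_r = np.zeros(config.n_perm)
    null_preds = [] if keep_null_predictions else None
    null_targets = [] if keep_null_predictions else None
    for b in range(config.n_perm):
        perm = rng.permutation(len(base_target))
        yperm = base_target[perm]
        r, preds = _refit_with_target(result, X, yperm, config, rng)
        null_r[b] = r
        if keep_null_predictions:
            null_preds.append(preds)
            null_targets.append(yperm)

    sd = float(np.sqrt(np.mean(fisher_z(null_r) ** 2)))
    z_obs = float(fisher_z(result.r_mean))
    p = float(stats.norm.sf(z_obs / sd)) if sd > 0 else (0.0 if z_obs > 0 else 1.0)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    result.p_value = p
    result.null_sd = sd
    return PermutationNull(
        null_r=null_r,
        sd=sd,
        p_value=p,
        null_predictions=np.array(null_preds) if keep_null_predictions else None,
        null_targets=np.array(null_targets) if keep_null_predictions else None,
    )


# ---------------------------------------------------------------------------
# virtual lesion scan
# ---------------------------------------------------------------------------


def module_feature_mask(labels: np.ndarray, module: int) -> np.ndarray:
    """Edges with at least one endpoint in the module (intra + inter)."""
    i, j = edge_index(labels.size)
    in_mod = labels == module
    return in_mod[i] | in_mod[j]


def virtual_lesion_scan(
    dataset: ConnectivityDataset,
    target: np.ndarray,
    partition: ConsensusPartition,
    config: SPLSConfig,
) -> pd.DataFrame:
    """Per-module predictive scans with FDR over modules + all-connections.

    Each module's model is trained only on the edges touching that module's
    nodes; the all-connections model joins the family, and
    Benjamini-Hochberg correction runs across all tests.
    """
    if partition.labels.size != dataset.n_nodes:
        raise ValueError("partition does not cover the dataset's nodes")
    X = dataset.features()
    rows = []
    tests = [("all", None)]
    for m, nodes in partition.modules().items():
        if nodes.size < 2:
            warnings.warn(f"module {m} has {nodes.size} node(s); skipped")
            continue
        tests.append((f"module_{m}", module_feature_mask(partition.labels, m)))
    for name, mask in tests:
        res = nested_cv_predict(X, target, dataset.covariates, config, feature_mask=mask)
        null = permutation_pvalue(res, X, config, feature_mask=mask)
        rows.append(
            {
                "test": name,
                "n_features": int(mask.sum()) if mask is not None else X.shape[1],
                "r_mean": res.r_mean,
                "p": null.p_value,
            }
        )
    out = pd.DataFrame(rows)
    rej, p_fdr, *_ = multipletests(out["p"], alpha=0.05, method="fdr_bh")
    out["p_fdr"] = p_fdr
    out["significant_fdr"] = rej
    return out


# ---------------------------------------------------------------------------
# specificity and transfer
# ---------------------------------------------------------------------------


def partial_corr(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Partial correlation of x and y given control = correlation of the
    OLS residuals of each on the control variable(s)."""
    control = np.column_stack([np.ones(len(x)), np.atleast_2d(control).reshape(len(x), -1)])
    rx = x - control @ np.linalg.lstsq(control, x, rcond=None)[0]
    ry = y - control @ np.linalg.lstsq(control, y, rcond=None)[0]
    return _safe_corr(rx, ry)


def specificity_partial(
    result: PredictionResult,
    other_score: np.ndarray,
    null_bundle: PermutationNull,
) -> tuple[float, float]:
    """Partial r between observed and predicted scores controlling the other
    phenotype, with significance from the same permutation machinery.

    ``null_bundle`` must carry null predictions
    (``permutation_pvalue(..., keep_null_predictions=True)``).
    """
    other = np.asarray(other_score, float)
    if other.std() == 0:
        raise ValueError("control score is constant")
    if null_bundle.null_predictions is None:
        raise ValueError("null_bundle lacks stored null predictions")

    n_rep = result.predictions.shape[0]
    obs_r = np.mean([
        partial_corr(result.observed_resid[rep], result.predictions[rep], other)
        for rep in range(n_rep)
    ])
    null_r = np.array([
        np.mean([
            partial_corr(null_bundle.null_targets[b], null_bundle.null_predictions[b, rep], other)
            for rep in range(n_rep)
        ])
        for b in range(null_bundle.null_predictions.shape[0])
    ])
    sd = float(np.sqrt(np.mean(fisher_z(null_r) ** 2)))
    z_obs = float(fisher_z(obs_r))
    p = float(stats.norm.sf(z_obs / sd)) if sd > 0 else (0.0 if z_obs > 0 else 1.0)
    return float(obs_r), min(max(p, np.finfo(float).tiny), 1.0)


def transfer_to_followup(
    result: PredictionResult,
    followup_dataset: ConnectivityDataset,
    followup_target: np.ndarray,
    baseline_subjects: np.ndarray,
    feature_mask: Optional[np.ndarray] = None,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
):
    """Apply frozen baseline fold-models to follow-up data.

    Each follow-up subject is predicted by the baseline model of the fold in
    which they were a *test* subject, so no prediction involves a model that
    saw the subject's own baseline data. Subjects absent at baseline are
    excluded (and returned in the log). Significance comes from permuting
    the residualized follow-up target against the fixed predictions.

    Returns (r_mean, p, per-repeat r, excluded subjects, predictions df).
    """
    config = result.config
    fu_subjects = followup_dataset.subjects
    base_pos = {s: i for i, s in enumerate(baseline_subjects)}
    present = np.array([s in base_pos for s in fu_subjects])
    excluded = list(fu_subjects[~present])
    if not present.any():
        raise ValueError("no follow-up subjects overlap the baseline sample")

    X_fu = followup_dataset.features()
    if feature_mask is not None:
        X_fu = X_fu[:, feature_mask]
    design_fu = confound_design(followup_dataset.covariates)
    y_fu = np.asarray(followup_target, float)

    n_rep = len(result.fold_models)
    n_fu = len(fu_subjects)
    preds = np.full((n_rep, n_fu), np.nan)
    resid = np.full((n_rep, n_fu), np.nan)
    for rep in range(n_rep):
        for fm in result.fold_models[rep]:
            if list(design_fu.columns) != fm.confound_cols[1:]:
                raise ValueError("follow-up covariate design does not match baseline")
            test_base_subjects = set(baseline_subjects[fm.test_idx])
            rows = np.array([
                idx for idx, s in enumerate(fu_subjects)
                if present[idx] and s in test_base_subjects
            ], dtype=int)
            if rows.size == 0:
                continue
            Xd = np.column_stack([np.ones(rows.size), design_fu.to_numpy(float)[rows]])
            resid[rep, rows] = y_fu[rows] - Xd @ fm.confound_beta
            preds[rep, rows] = fm.predict(X_fu[rows])

    covered = ~np.isnan(preds).any(axis=0)
    r_rep = np.array([
        _safe_corr(resid[rep, covered], preds[rep, covered]) for rep in range(n_rep)
    ])
    r_mean = float(r_rep.mean())

    n_perm = config.n_perm if n_perm is None else n_perm
    rng = rng_from(config.seed + 104729 if seed is None else seed)
    null_r = np.zeros(n_perm)
    cov_idx = np.flatnonzero(covered)
    for b in range(n_perm):
        perm = rng.permutation(cov_idx.size)
        null_r[b] = np.mean([
            _safe_corr(resid[rep, cov_idx][perm], preds[rep, cov_idx]) for rep in range(n_rep)
        ])
    sd = float(np.sqrt(np.mean(fisher_z(null_r) ** 2)))
    z_obs = float(fisher_z(r_mean))
    p = float(stats.norm.sf(z_obs / sd)) if sd > 0 else (0.0 if z_obs > 0 else 1.0)
    p = min(max(p, np.finfo(float).tiny), 1.0)

    pred_df = pd.DataFrame({
        "subject": fu_subjects[covered],
        **{f"pred_rep{r + 1}": preds[r, covered] for r in range(n_rep)},
        **{f"resid_rep{r + 1}": resid[r, covered] for r in range(n_rep)},
    })
    return r_mean, p, r_rep, excluded, pred_df
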