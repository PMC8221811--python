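"""Common-factor pipeline for deriving decision acuity.

The pipeline mirrors the classical exploratory-confirmatory psychometric
workflow: parallel analysis bounds the factor count, minimum-residual
(minres) exploratory common factor analysis is fitted on a discovery half,
confirmatory ML factor models freeing only loadings with |exploratory
loading| >= 0.25 are fitted on the disjoint test half, and the retained
model is the largest one that converges and improves BIC. Decision acuity is
the first factor's regression-weight score; the remaining factors are
single-task factors. The exploratory solution is left unrotated by default
(see :func:`fit_ecfa`); oblimin rotation is available where cluster-like
factors are wanted.

Factor models carry a sign/permutation indeterminacy; every comparison here
goes through congruence-based matching (Tucker coefficients + Hungarian
assignment) before loadings or scores are compared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.optimize import linear_sum_assignment

from ._utils import congruence, rng_from
from .synthetic import MEASURE_TASK, measure_columns

CFA_LOADING_THRESHOLD = 0.25


class FactorConvergenceError(RuntimeError):
    pass


@dataclass
class FactorModel:
    k: int
    loadings: np.ndarray            # p x k pattern matrix (oblique)
    uniquenesses: np.ndarray        # length p
    phi: np.ndarray                 # k x k factor correlations
    scoring_weights: np.ndarray     # p x k regression weights
    measure_names: list[str]
    rotation: str = "none"
    fitted_on: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "phi": self.phi.tolist(),
            "scoring_weights": self.scoring_weights.tolist(),
            "measure_names": self.measure_names,
            "rotation": self.rotation,
            "fitted_on": self.fitted_on,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FactorModel":
        from .preprocessing import _read_json_source

        payload = json.loads(_read_json_source(source))
        return cls(
            k=payload["k"],
            loadings=np.asarray(payload["loadings"]),
            uniquenesses=np.asarray(payload["uniquenesses"]),
            phi=np.asarray(payload["phi"]),
            scoring_weights=np.asarray(payload["scoring_weights"]),
            measure_names=list(payload["measure_names"]),
            rotation=payload.get("rotation", "none"),
            fitted_on=payload.get("fitted_on", ""),
        )


@dataclass
class FitIndices:
    k: int
    chi2: float
    df: int
    bic: float
    cfi: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    converged: bool
    n_params: int
    under_identified: bool = False


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _table_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = measure_columns(table)
    if not cols:
        raise ValueError("table contains no battery measures")
    x = table.loc[:, cols].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("factor analysis requires a complete (imputed) table")
    return x, cols


def match_factors(reference: np.ndarray, loadings: np.ndarray):
    """Permute and sign-flip `loadings` columns to best match `reference`.

    Returns (matched loadings, column permutation, signs). Matching maximizes
    total |Tucker congruence| via the Hungarian algorithm.
    """
    k = reference.shape[1]
    c = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            c[a, b] = congruence(reference[:, a], loadings[:, b])
    row, col = linear_sum_assignment(-np.abs(c))
    signs = np.sign(c[row, col])
    signs[signs == 0] = 1.0
    return loadings[:, col] * signs, col, signs


# ---------------------------------------------------------------------------
# parallel analysis
# ---------------------------------------------------------------------------


def parallel_analysis(table: pd.DataFrame, n_reps: int = 100, seed: int = 0,
                      percentile: float = 95.0) -> int:
    """Number of factors whose eigenvalues beat size-matched random data.

    Compares the eigenvalues of the observed correlation matrix against the
    chosen percentile of eigenvalues from ``n_reps`` standard-normal datasets
    of the same shape.
    """
    if n_reps < 20:
        raise ValueError("n_reps < 20 gives an unstable eigenvalue percentile")
    x, _ = _table_matrix(table)
    n, p = x.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = rng_from(seed)
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        z = rng.standard_normal((n, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    cutoff = np.percentile(sims, percentile, axis=0)
    exceeds = obs > cutoff
    # retained count = leading run of eigenvalues above the null envelope
    k = 0
    for e in exceeds:
        if not e:
            break
        k += 1
    return k


# ---------------------------------------------------------------------------
# minres EFA + oblimin rotation
# ---------------------------------------------------------------------------


def _minres_loadings(s: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    sr = s - np.diag(psi)
    vals, vecs = np.linalg.eigh(sr)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _minres_objective(psi, s, k):
    L = _minres_loadings(s, psi, k)
    resid = s - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return 0.5 * float((resid**2).sum())


def _oblimin_criterion(L: np.ndarray, gamma: float = 0.0):
    """Oblimin criterion and its gradient w.r.t. the rotated loadings."""
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    C = np.eye(p) - (gamma / p) * np.ones((p, p)) if gamma != 0 else np.eye(p)
    X = C @ L2 @ N
    f = float(np.sum(L2 * X)) / 4.0
    G = L * X
    return f, G


def _gpa_oblique(A: np.ndarray, max_iter: int = 500, tol: float = 1e-6):
    """Gradient-projection oblique rotation (oblimin, gamma=0).

    Standard GPA iteration over the k x k rotation matrix T with unit-length
    columns; returns (rotated pattern, factor correlation matrix).
    """
    k = A.shape[1]
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            try:
                Xi = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Xi.T
            ft, Gqt = _oblimin_criterion(Lt)
            if ft < f - 0.5 * s**2 * al:
                T, L, f, Gq, Ti = X, Lt, ft, Gqt, Xi
                G = -(L.T @ Gq @ Ti).T
                break
            al /= 2.0
    phi = T.T @ T
    return L, phi


def _order_and_sign(L: np.ndarray, phi: np.ndarray):
    """Order factors by explained variance; sign so salient loadings are mostly positive."""
    ss = (L**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.ones(L.shape[1])
    for a in range(L.shape[1]):
        salient = L[np.abs(L[:, a]) >= CFA_LOADING_THRESHOLD, a]
        ref = salient if salient.size else L[:, a]
        n_pos, n_neg = (ref > 0).sum(), (ref < 0).sum()
        if n_neg > n_pos or (n_neg == n_pos and ref.sum() < 0):
            signs[a] = -1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)
    return L, phi


def regression_weights(R: np.ndarray, L: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Thurstone regression scoring weights W = R^-1 (L Phi) for oblique models."""
    structure = L @ phi
    return np.linalg.solve(R, structure)


def fit_ecfa(table: pd.DataFrame, k: int, rotation: str = "none",
             max_factors: Optional[int] = None) -> FactorModel:
    """Minres exploratory common factor analysis.

    Minimizes the off-diagonal squared residuals of the correlation matrix
    over the uniquenesses (loadings follow from the reduced matrix's top-k
    eigenstructure), orders factors by explained variance, fixes signs, and
    computes regression scoring weights.

    The default keeps the unrotated solution: a broad factor loading across
    many measures — the object of interest here — is exactly what
    simple-structure rotations (oblimin and friends) are built to dissolve
    into cluster factors, so rotation would destroy the construct being
    derived. Pass ``rotation="oblimin"`` for a conventional oblique solution
    when the factors of interest are cluster-like.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, cols = _table_matrix(table)
    if max_factors is not None and k > max_factors:
        warnings.warn(
            f"k={k} exceeds the parallel-analysis bound ({max_factors}); fitting anyway",
            stacklevel=2,
        )
    s = np.corrcoef(x, rowvar=False)
    p = s.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(s))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(s, k),
        method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * p,
        options={"maxiter": 1000},
    )
    if not np.isfinite(res.fun):
        raise FactorConvergenceError(f"minres failed: {res.message} after {res.nit} iterations")
    psi = res.x
    L = _minres_loadings(s, psi, k)
    phi = np.eye(k)
    if rotation == "oblimin" and k > 1:
        L, phi = _gpa_oblique(L)
    elif rotation not in ("none", "oblimin"):
        raise ValueError(f"unknown rotation {rotation!r}")
    L, phi = _order_and_sign(L, phi)
    uniq = np.clip(1.0 - np.diag(L @ phi @ L.T), 0.0, 1.0)
    W = regression_weights(s, L, phi)
    return FactorModel(
        k=k, loadings=L, uniquenesses=uniq, phi=phi,
        scoring_weights=W, measure_names=cols, rotation=rotation,
    )


# ---------------------------------------------------------------------------
# confirmatory factor analysis (ML)
# ---------------------------------------------------------------------------


def _cfa_pack(lam_free, theta, phi_off, mask, k):
    return np.concatenate([lam_free, theta, phi_off])


def _cfa_unpack(params, mask, k):
    p = mask.shape[0]
    n_lam = int(mask.sum())
    lam = np.zeros((p, k))
    lam[mask] = params[:n_lam]
    theta = params[n_lam:n_lam + p]
    phi = np.eye(k)
    iu = np.triu_indices(k, 1)
    phi[iu] = params[n_lam + p:]
    phi[(iu[1], iu[0])] = params[n_lam + p:]
    return lam, theta, phi


def _cfa_objective(params, s, mask, k):
    lam, theta, phi = _cfa_unpack(params, mask, k)
    sigma = lam @ phi @ lam.T + np.diag(theta)
    p = s.shape[0]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e8, np.zeros_like(params)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sinv = np.linalg.inv(sigma)
    sign_s, logdet_s = np.linalg.slogdet(s)
    f = logdet + float(np.trace(s @ sinv)) - logdet_s - p
    omega = sinv - sinv @ s @ sinv  # dF/dSigma
    g_lam = 2.0 * omega @ lam @ phi
    g_theta = np.diag(omega)
    g_phi_full = lam.T @ omega @ lam
    iu = np.triu_indices(k, 1)
    g_phi = 2.0 * g_phi_full[iu]
    grad = np.concatenate([g_lam[mask], g_theta, g_phi])
    return f, grad


def fit_cfa(test_table: pd.DataFrame, exploratory: FactorModel,
            threshold: float = CFA_LOADING_THRESHOLD) -> tuple[FactorModel, FitIndices]:
    """Confirmatory ML fit on the test half, freeing only salient loadings.

    A loading is freed when the exploratory solution gives it
    |loading| >= ``threshold``; factor variances are fixed at 1 and factor
    correlations are free. A factor with no freed loadings makes the model
    under-identified and raises.
    """
    x, cols = _table_matrix(test_table)
    if cols != exploratory.measure_names:
        # allow column-order differences; require same measure set
        if set(cols) != set(exploratory.measure_names):
            raise ValueError("test table and exploratory model measure sets differ")
        x = test_table.loc[:, exploratory.measure_names].to_numpy(float)
        cols = list(exploratory.measure_names)
    n, p = x.shape
    k = exploratory.k
    mask = np.abs(exploratory.loadings) >= threshold
    empty = np.flatnonzero(~mask.any(axis=0))
    if empty.size:
        raise FactorConvergenceError(
            f"under-identified CFA: factor(s) {empty.tolist()} have no loadings >= {threshold}"
        )
    s = np.corrcoef(x, rowvar=False)

    lam0 = np.where(mask, exploratory.loadings, 0.0)[mask]
    theta0 = np.clip(exploratory.uniquenesses, 0.05, 0.95)
    iu = np.triu_indices(k, 1)
    phi0 = np.clip(exploratory.phi[iu], -0.6, 0.6)
    x0 = np.concatenate([lam0, theta0, phi0])
    bounds = (
        [(-2.0, 2.0)] * int(mask.sum())
        + [(1e-3, 1.0)] * p
        + [(-0.95, 0.95)] * len(phi0)
    )
    res = optimize.minimize(
        _cfa_objective, x0, args=(s, mask, k), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam, theta, phi = _cfa_unpack(res.x, mask, k)
    converged = bool(res.success) and res.fun < 1e7

    q = int(mask.sum()) + p + len(phi0)
    df = p * (p + 1) // 2 - q
    chi2 = max((n - 1) * res.fun, 0.0)
    sign_s, logdet_s = np.linalg.slogdet(s)
    f_null = -logdet_s
    chi2_null = max((n - 1) * f_null, 0.0)
    df_null = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_null - df_null, num, np.finfo(float).tiny)
    cfi = 1.0 - num / den
    rmsea = np.sqrt(num / (df * (n - 1))) if df > 0 else np.nan
    lo, hi = _rmsea_interval(chi2, df, n)
    bic = chi2 + q * np.log(n)

    weights = regression_weights(s, lam, phi)
    model = FactorModel(
        k=k, loadings=lam, uniquenesses=theta, phi=phi,
        scoring_weights=weights, measure_names=cols,
        rotation="cfa", fitted_on="test",
    )
    fit = FitIndices(
        k=k, chi2=chi2, df=df, bic=float(bic), cfi=float(cfi),
        rmsea=float(rmsea), rmsea_lo=lo, rmsea_hi=hi,
        converged=converged, n_params=q,
    )
    return model, fit


def _rmsea_interval(chi2: float, df: int, n: int, level: float = 0.90):
    """90% RMSEA interval by inverting the noncentral chi-square."""
    if df <= 0 or chi2 <= 0:
        return 0.0, 0.0
    a = (1 - level) / 2

    def upper_tail(nc, prob):
        return stats.ncx2.sf(chi2, df, nc) - prob

    def solve(prob):
        lo_b, hi_b = 0.0, max(chi2 * 10, 10.0)
        if upper_tail(lo_b, prob) > 0:
            return 0.0
        if upper_tail(hi_b, prob) < 0:
            return hi_b
        return optimize.brentq(upper_tail, lo_b, hi_b, args=(prob,))

    nc_lo = solve(a)         # lower bound of noncentrality
    nc_hi = solve(1 - a)
    lo = np.sqrt(max(nc_lo, 0.0) / (df * (n - 1)))
    hi = np.sqrt(max(nc_hi, 0.0) / (df * (n - 1)))
    return float(min(lo, hi)), float(max(lo, hi))


def confirm_and_select(models: Sequence[FactorModel], test_table: pd.DataFrame,
                       threshold: float = CFA_LOADING_THRESHOLD):
    """Confirmatory testing of exploratory models; pick the retained k.

    Each exploratory model is re-fitted on the disjoint test half with only
    its salient loadings freed. The chosen k is the largest whose fit
    converges and improves BIC over the previous (smaller) converging model.
    Under-identified models are excluded from selection but reported.
    """
    indices: dict[int, FitIndices] = {}
    cfa_models: dict[int, FactorModel] = {}
    for m in sorted(models, key=lambda m: m.k):
        try:
            cfa_model, fit = fit_cfa(test_table, m, threshold=threshold)
        except FactorConvergenceError:
            indices[m.k] = FitIndices(
                k=m.k, chi2=np.nan, df=0, bic=np.inf, cfi=np.nan,
                rmsea=np.nan, rmsea_lo=np.nan, rmsea_hi=np.nan,
                converged=False, n_params=0, under_identified=True,
            )
            continue
        indices[m.k] = fit
        cfa_models[m.k] = cfa_model

    chosen = None
    prev = None
    for k in sorted(indices):
        fit = indices[k]
        if not fit.converged or fit.under_identified:
            continue
        if prev is None or fit.bic < indices[prev].bic:
            chosen = k
        prev = k
    if chosen is None:
        raise FactorConvergenceError("no confirmatory model converged")
    return chosen, indices, cfa_models


# ---------------------------------------------------------------------------
# scoring and stability
# ---------------------------------------------------------------------------


def score_subjects(model: FactorModel, table: pd.DataFrame,
                   task_subset: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Factor scores (regression weights); factor 1 is decision acuity d.

    ``table`` must already be standardized on the model's baseline scale.
    With ``task_subset``, weights for measures outside the listed tasks are
    zeroed and the remaining raw weighted sum is used without renormalization
    (the conservative longitudinal scoring).
    """
    missing = [m for m in model.measure_names if m not in table.columns]
    if missing:
        raise ValueError(f"table is missing model measures: {missing}")
    x = table.loc[:, model.measure_names].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("scoring requires a complete table")
    w = model.scoring_weights.copy()
    if task_subset is not None:
        tasks = set(task_subset)
        keep = np.array([MEASURE_TASK.get(m, m) in tasks for m in model.measure_names])
        if not keep.any():
            raise ValueError("task_subset matches no measures")
        w[~keep, :] = 0.0
    scores = x @ w
    out = pd.DataFrame(scores, columns=[f"f{j + 1}" for j in range(model.k)], index=table.index)
    out.insert(0, "d", out["f1"])
    if "subject" in table.columns:
        out.insert(0, "subject", table["subject"].to_numpy())
    return out


@dataclass
class StabilityResult:
    r_cross: float
    flagged: bool


def stability_cross_scoring(table_a: pd.DataFrame, table_b: pd.DataFrame,
                            k: int = 4, flag_below: float = 0.5) -> StabilityResult:
    """Construct stability of d across two subgroups.

    Fits ECFA separately on A and B, matches B's factors to A's by
    congruence, scores group A's (standardized) data with both weight sets,
    and reports the within-A correlation of the two d scores. Identical
    tables give r = 1 by construction; a low correlation is flagged as a
    construct-instability warning.
    """
    ma = fit_ecfa(table_a, k)
    mb = fit_ecfa(table_b, k)
    if set(ma.measure_names) != set(mb.measure_names):
        raise ValueError("both tables must contain the same measures")
    # align B's model to A's measure order, then match factors
    order = [mb.measure_names.index(m) for m in ma.measure_names]
    lb = mb.loadings[order]
    wb = mb.scoring_weights[order]
    _, col, signs = match_factors(ma.loadings, lb)
    wb = wb[:, col] * signs

    xa = table_a.loc[:, ma.measure_names].to_numpy(float)
    xa = (xa - xa.mean(axis=0)) / xa.std(axis=0)
    own = xa @ ma.scoring_weights[:, 0]
    other = xa @ wb[:, 0]
    if own.std() == 0 or other.std() == 0:
        raise ValueError("degenerate (constant) factor scores")
    r = float(np.corrcoef(own, other)[0, 1])
    return StabilityResult(r_cross=r, flagged=r < flag_below)
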