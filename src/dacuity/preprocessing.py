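"""Measure-table preprocessing.

Gaussianization of marginals (identity / shifted-log / signed-power, chosen
per measure by minimum absolute sample skewness), EM-style iterative low-rank
imputation of the small fraction of missing cells, the random
discovery/testing split, baseline-anchored standardization of follow-up
measures, and the aggregate-performance / IQ composite scores.

The fitted :class:`TransformSpec` is the contract between waves: follow-up
measures are passed through the *baseline* transforms and z-scored with the
*baseline* mean and SD, never their own statistics, so absolute change
between waves stays interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import measure_columns

def _read_json_source(source) -> str:
    """Accept a path to a JSON file or a JSON string."""
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "{" not in source:
        return Path(source).read_text()
    return source


_POWER_EXPONENTS = (1.0 / 3.0, 0.5, 2.0)
#: identity wins unless a competing transform beats its |skew| by this margin
_IDENTITY_MARGIN = 0.05
#: columns with |skew| below this are treated as already near-normal
_SKEW_OK = 0.3


@dataclass
class ColumnTransform:
    family: str  # "identity" | "log" | "power"
    shift: float = 0.0
    exponent: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.family == "identity":
            return x
        if self.family == "log":
            return np.log(x - self.shift)
        if self.family == "power":
            return np.sign(x) * np.abs(x) ** self.exponent
        raise ValueError(f"unknown transform family {self.family!r}")


@dataclass
class TransformSpec:
    """Per-measure transform family + fitted parameters + baseline moments."""

    columns: dict[str, ColumnTransform] = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, tr in self.columns.items():
            if name in out.columns:
                out[name] = tr.apply(out[name].to_numpy())
        return out

    def to_json(self, path=None) -> str:
        payload = {
            name: {
                "family": t.family,
                "shift": t.shift,
                "exponent": t.exponent,
                "mean": t.mean,
                "sd": t.sd,
            }
            for name, t in self.columns.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TransformSpec":
        payload = json.loads(_read_json_source(source))
        return cls(columns={name: ColumnTransform(**kw) for name, kw in payload.items()})


def _abs_skew(x: np.ndarray) -> float:
    if np.nanstd(x) == 0:
        return np.inf
    return abs(float(stats.skew(x[~np.isnan(x)])))


def _fit_column_transform(x: np.ndarray, name: str) -> ColumnTransform:
    obs = x[~np.isnan(x)]
    if obs.size < 3:
        raise ValueError(f"measure {name!r}: need at least 3 non-missing values")
    if obs.std() == 0:
        return ColumnTransform("identity")

    candidates: list[ColumnTransform] = [ColumnTransform("identity")]
    rng_ = obs.max() - obs.min()
    # plain log for strictly positive measures; shift just below the minimum
    # only when needed to make the argument positive
    shift = 0.0 if obs.min() > 0 else obs.min() - 1e-6 * rng_
    candidates.append(ColumnTransform("log", shift=shift))
    for e in _POWER_EXPONENTS:
        candidates.append(ColumnTransform("power", exponent=e))

    skews = [_abs_skew(c.apply(obs)) for c in candidates]
    best = int(np.argmin(skews))
    # prefer identity for near-normal columns, or when it is essentially as
    # good as the best nonlinear candidate
    if best != 0 and (skews[0] < _SKEW_OK or skews[0] <= skews[best] + _IDENTITY_MARGIN):
        best = 0
    return candidates[best]


def impute_lowrank(
    x: np.ndarray,
    ranks=(1, 2, 3, 4, 5, 6),
    max_iter: int = 100,
    tol: float = 1e-6,
    cv_frac: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Iterative low-rank (EM-style) completion of missing cells.

    Columns are z-scored internally; missing cells are initialized at the
    column mean and refined by repeated truncated-SVD reconstruction. The
    rank is chosen by masking a fraction of observed cells and minimizing
    reconstruction RMSE (ties to the smaller rank). Observed cells are
    returned exactly as given.
    """
    x = np.asarray(x, float)
    missing = np.isnan(x)
    if not missing.any():
        return x.copy()
    if np.any(missing.all(axis=0)):
        bad = np.flatnonzero(missing.all(axis=0))
        raise ValueError(f"all-missing column(s) at index {bad.tolist()}")

    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    def complete(zin, miss, rank):
        filled = np.where(miss, 0.0, zin)
        prev = filled.copy()
        for _ in range(max_iter):
            u, s, vt = np.linalg.svd(filled, full_matrices=False)
            approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
            filled = np.where(miss, approx, zin)
            if np.sqrt(np.mean((filled - prev) ** 2)) < tol:
                break
            prev = filled.copy()
        return filled

    usable_ranks = [r for r in ranks if r <= min(x.shape)]
    if len(usable_ranks) > 1:
        rng = np.random.default_rng(seed)
        obs_idx = np.argwhere(~missing)
        n_mask = max(1, int(cv_frac * obs_idx.shape[0]))
        sel = obs_idx[rng.choice(obs_idx.shape[0], size=n_mask, replace=False)]
        miss_cv = missing.copy()
        miss_cv[sel[:, 0], sel[:, 1]] = True
        if np.any(miss_cv.all(axis=0)):  # masking emptied a column; skip CV
            best_rank = usable_ranks[0]
        else:
            errs = []
            for r in usable_ranks:
                rec = complete(z, miss_cv, r)
                errs.append(np.sqrt(np.mean((rec[sel[:, 0], sel[:, 1]] - z[sel[:, 0], sel[:, 1]]) ** 2)))
            best_rank = usable_ranks[int(np.argmin(errs))]
    else:
        best_rank = usable_ranks[0]

    zfull = complete(z, missing, best_rank)
    out = x.copy()
    out[missing] = (zfull * sd + mu)[missing]
    return out


def normalize_measures(table: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, TransformSpec]:
    """Gaussianize marginals and impute missing cells on a baseline table.

    Each measure gets the transform (identity, shifted-log, or signed power)
    minimizing its absolute sample skewness; missing cells are then filled by
    iterative low-rank completion. Observed cells are unchanged by
    imputation. The returned table is on the transformed (not standardized)
    scale; the fitted :class:`TransformSpec` stores each measure's baseline
    mean and SD for standardization and follow-up re-scoring.
    """
    cols = measure_columns(table)
    if not cols:
        raise ValueError("table contains no battery measures")
    out = table.copy()
    spec = TransformSpec()
    for name in cols:
        x = out[name].to_numpy(float)
        if np.isnan(x).all():
            raise ValueError(f"measure {name!r} is entirely missing")
        tr = _fit_column_transform(x, name)
        out[name] = tr.apply(x)
        spec.columns[name] = tr

    vals = out.loc[:, cols].to_numpy(float)
    vals = impute_lowrank(vals, seed=seed)
    out.loc[:, cols] = vals

    for j, name in enumerate(cols):
        tr = spec.columns[name]
        tr.mean = float(vals[:, j].mean())
        tr.sd = float(vals[:, j].std())
        if tr.sd == 0:
            raise ValueError(f"measure {name!r} has zero variance after transform")
    return out, spec


def standardize_baseline(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """z-score an already-transformed baseline table by the spec's moments."""
    out = table.copy()
    for name, tr in spec.columns.items():
        if name in out.columns:
            out[name] = (out[name] - tr.mean) / tr.sd
    return out


def split_discovery_test(table: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half split of subjects into discovery and testing samples.

    Halves are disjoint, their union is the input, and sizes differ by at
    most one (the larger half is the discovery sample).
    """
    subjects = table["subject"].unique() if "subject" in table.columns else np.arange(len(table))
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_disc = (subjects.size + 1) // 2
    disc_ids = set(perm[:n_disc].tolist())
    if "subject" in table.columns:
        mask = table["subject"].isin(disc_ids)
    else:
        mask = pd.Series(np.isin(np.arange(len(table)), list(disc_ids)), index=table.index)
    return table[mask].copy(), table[~mask].copy()


def zscore_followup(followup: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Transform + standardize follow-up measures on the baseline scale.

    Every follow-up measure is passed through the baseline-fitted transform,
    then z-scored with the baseline mean and SD (never follow-up statistics).
    """
    cols = measure_columns(followup)
    unseen = [c for c in cols if c not in spec.columns]
    if unseen:
        raise ValueError(f"measures absent from baseline TransformSpec: {unseen}")
    out = followup.copy()
    for name in cols:
        tr = spec.columns[name]
        out[name] = (tr.apply(out[name].to_numpy(float)) - tr.mean) / tr.sd
    vals = out.loc[:, cols].to_numpy(float)
    if np.isnan(vals).any():
        vals = impute_lowrank(vals)
        out.loc[:, cols] = vals
    return out


def derive_composites(
    winnings_by_task: pd.DataFrame,
    iq_subscores: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Aggregate task performance (mean of within-task t-scores) and IQ composite.

    ``winnings_by_task`` must contain the four tasks with winnings entering
    the aggregate measure (columns ``winnings_gng``, ``winnings_ig``,
    ``winnings_trust``, ``winnings_twostep``); each is t-scored (mean 50,
    SD 10) within the sample and the four t-scores are averaged.
    ``iq_subscores`` must contain ``iq_vocab_raw`` and ``iq_matrix_raw``;
    the composite is the mean of the two z-scored subscores.
    """
    task_cols = [f"winnings_{t}" for t in ("gng", "ig", "trust", "twostep")]
    missing = [c for c in task_cols if c not in winnings_by_task.columns]
    if missing:
        raise ValueError(f"missing winnings columns: {missing}")
    tscores = []
    for c in task_cols:
        x = winnings_by_task[c].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"{c} is constant across subjects; t-score undefined")
        tscores.append(50.0 + 10.0 * (x - x.mean()) / sd)
    performance = pd.Series(np.mean(tscores, axis=0), index=winnings_by_task.index, name="performance")

    for c in ("iq_vocab_raw", "iq_matrix_raw"):
        if c not in iq_subscores.columns:
            raise ValueError(f"missing IQ subscore column: {c}")
    zs = []
    for c in ("iq_vocab_raw", "iq_matrix_raw"):
        x = iq_subscores[c].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"{c} is constant; z-score undefined")
        zs.append((x - x.mean()) / sd)
    iq_composite = pd.Series(np.mean(zs, axis=0), index=iq_subscores.index, name="iq_composite")
    return performance, iq_composite
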