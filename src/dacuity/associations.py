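"""Linear mixed-effects associations between decision acuity and covariates.

The longitudinal design (two waves per retained participant) is modeled with
a participant random intercept. Age enters twice: as each participant's mean
age across their visits (the between-subject, cross-sectional slope) and as
the deviation of each visit from that mean (the within-subject, longitudinal
slope); equal coefficients mean the outcome varies with age in the same way
across and within people, and the equality is directly testable by a Wald
contrast. Random age slopes are omitted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class LMEResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    params_std: pd.Series           # standardized (z-scored variables) betas
    bse_std: pd.Series
    bic: float
    loglik: float
    converged: bool
    singular: bool
    age_equality_p: Optional[float] = None  # within == between age slope
    ols_fallback: Optional[pd.Series] = None


def _decompose_age(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    mean_age = out.groupby("subject")["age"].transform("mean")
    out["age_between"] = mean_age
    out["age_within"] = out["age"] - mean_age
    return out


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0


def fit_lme(
    table: pd.DataFrame,
    outcome: str = "d",
    covariates: Sequence[str] = ("sex",),
    decompose_age: bool = True,
    reml: bool = True,
) -> LMEResult:
    """REML mixed model of the outcome with a participant random intercept.

    ``covariates`` are fixed-effect columns added alongside age (decomposed
    into between- and within-subject terms unless ``decompose_age=False``).
    Returns raw and standardized coefficients, BIC, and the Wald p-value of
    the within-vs-between age slope equality. A singular random-intercept
    fit triggers a warning and an OLS comparison fit.
    """
    required = {"subject", "wave", "age", outcome}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if table.groupby("subject").size().max() < 2:
        raise ValueError("need repeated measurements for at least some subjects")

    df = _decompose_age(table).dropna(subset=[outcome, "age", *covariates])
    age_terms = ["age_between", "age_within"] if decompose_age else ["age"]
    fixed = age_terms + [c for c in covariates if c not in age_terms]

    def run(df_in):
        exog = sm.add_constant(df_in[fixed].astype(float))
        model = sm.MixedLM(df_in[outcome].astype(float), exog, groups=df_in["subject"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return model.fit(reml=reml)
            except np.linalg.LinAlgError:
                return model.fit(reml=reml, method="powell")

    res = run(df)
    singular = bool(res.cov_re.iloc[0, 0] < 1e-8)

    dfz = df.copy()
    for c in [outcome, *fixed]:
        if dfz[c].dtype != object:
            dfz[c] = _zscore(dfz[c].astype(float))
    res_z = run(dfz)

    # BIC for the mixed model (statsmodels does not expose one directly)
    n_par = len(res.params) + 1  # + random-intercept variance (scale profiled)
    bic = float(-2 * res.llf + n_par * np.log(len(df)))

    age_eq_p = None
    if decompose_age:
        names = list(res.params.index)
        c = np.zeros(len(names))
        c[names.index("age_between")] = 1.0
        c[names.index("age_within")] = -1.0
        est = float(c @ res.params.to_numpy())
        var = float(c @ res.cov_params().to_numpy()[: len(c), : len(c)] @ c)
        age_eq_p = float(2 * stats.norm.sf(abs(est) / np.sqrt(var))) if var > 0 else 1.0

    ols_fb = None
    if singular:
        warnings.warn("random-intercept variance ~ 0 (singular fit); reporting OLS comparison")
        exog = sm.add_constant(df[fixed].astype(float))
        ols_fb = sm.OLS(df[outcome].astype(float), exog).fit().params

    return LMEResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        params_std=res_z.params,
        bse_std=res_z.bse,
        bic=bic,
        loglik=float(res.llf),
        converged=bool(res.converged),
        singular=singular,
        age_equality_p=age_eq_p,
        ols_fallback=ols_fb,
    )


def results_table(result: LMEResult) -> pd.DataFrame:
    """Tidy coefficient table (raw + standardized) for writing as TSV."""
    out = pd.DataFrame({
        "beta": result.params,
        "se": result.bse,
        "p": result.pvalues,
        "ci_lo": result.conf_int[0],
        "ci_hi": result.conf_int[1],
    })
    out["beta_std"] = result.params_std.reindex(out.index)
    out["se_std"] = result.bse_std.reindex(out.index)
    return out
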