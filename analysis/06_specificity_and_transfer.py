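"""Phenotype specificity and cross-wave transfer of the connectivity models.

Specificity: partial correlation between observed and predicted d
controlling IQ (and vice versa), with permutation significance. Transfer:
the frozen baseline fold-models predict follow-up d from follow-up scans,
with the baseline fold structure preserved so nobody is predicted by a model
that saw their own baseline data. Writes results/transfer/.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from dacuity.network import ConnectivityDataset, exclude_high_motion
from dacuity.spls import (
    SPLSConfig,
    nested_cv_predict,
    permutation_pvalue,
    specificity_partial,
    transfer_to_followup,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "transfer"

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

load_targets = import_module("05_predict_from_connectivity").load_targets


def followup_d(subjects):
    fu = pd.read_csv(ROOT / "factors" / "scores_followup.tsv", sep="\t").set_index("subject")
    have = [s for s in subjects if s in fu.index]
    return fu.loc[have, "d"], have


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore", message="prefilter kept no features")
    base = ConnectivityDataset.read(ROOT / "cohort" / "connectivity_baseline")
    base, _ = exclude_high_motion(base)
    d, iq = load_targets(base.subjects)
    X = base.features()

    cfg = SPLSConfig(eta_grid=(0.7, 0.9), k_grid=(1, 2), outer_folds=20, inner_folds=5,
                     n_repeats=1, n_boot=50, n_perm=50, seed=seed)
    rows = []
    res_d = nested_cv_predict(X, d, base.covariates, cfg)
    null_d = permutation_pvalue(res_d, X, cfg, keep_null_predictions=True)
    pr_d, pp_d = specificity_partial(res_d, iq, null_d)
    rows.append({"analysis": "d | IQ", "r": pr_d, "p": pp_d})
    print(f"d predicted from rsFC controlling IQ: partial r = {pr_d:.3f}, p = {pp_d:.2e}")

    res_iq = nested_cv_predict(X, iq, base.covariates, cfg)
    null_iq = permutation_pvalue(res_iq, X, cfg, keep_null_predictions=True)
    pr_iq, pp_iq = specificity_partial(res_iq, d, null_iq)
    rows.append({"analysis": "IQ | d", "r": pr_iq, "p": pp_iq})
    print(f"IQ predicted from rsFC controlling d: partial r = {pr_iq:.3f}, p = {pp_iq:.2e}")

    fu = ConnectivityDataset.read(ROOT / "cohort" / "connectivity_followup")
    fu, _ = exclude_high_motion(fu)
    d_fu, have = followup_d(fu.subjects)
    fu = fu.subset(np.isin(fu.subjects, have))
    r_tr, p_tr, r_rep, excluded, preds = transfer_to_followup(
        res_d, fu, d_fu.loc[fu.subjects].to_numpy(), base.subjects
    )
    rows.append({"analysis": "transfer d (baseline models on follow-up)", "r": r_tr, "p": p_tr})
    preds.to_csv(OUT / "transfer_predictions.tsv", sep="\t", index=False)
    print(f"baseline models on follow-up scans: r = {r_tr:.3f}, p = {p_tr:.2e} "
          f"({len(preds)} subjects, {len(excluded)} without baseline scans excluded)")
    pd.DataFrame(rows).to_csv(OUT / "specificity_transfer.tsv", sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
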