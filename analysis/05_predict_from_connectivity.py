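"""Predict decision acuity and IQ from connectivity edges.

Bagged sparse-PLS with nested cross-validation on the motion-cleaned
baseline scans, permutation significance for both phenotypes, and the
module-wise virtual-lesion scan for d. Writes results/prediction/.

Reduced replicate counts relative to the full design (documented in
docs/methods.md) keep the run in the minutes range.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from dacuity.network import ConnectivityDataset, exclude_high_motion
from dacuity.preprocessing import derive_composites
from dacuity.spls import SPLSConfig, nested_cv_predict, permutation_pvalue, virtual_lesion_scan

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "prediction"


def load_targets(subjects):
    scores = pd.read_csv(ROOT / "factors" / "scores_baseline.tsv", sep="\t")
    measures = pd.read_csv(ROOT / "cohort" / "measures.tsv", sep="\t")
    base = measures[measures["wave"] == 1].set_index("subject")
    _, iq = derive_composites(base, base)
    d = scores.set_index("subject").loc[subjects, "d"].to_numpy()
    iq = iq.reindex(pd.Index(base.index)).loc[subjects].to_numpy()
    return d, iq


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore", message="prefilter kept no features")
    ds = ConnectivityDataset.read(ROOT / "cohort" / "connectivity_baseline")
    ds, _ = exclude_high_motion(ds)
    d, iq = load_targets(ds.subjects)
    X = ds.features()

    cfg = SPLSConfig(eta_grid=(0.7, 0.9), k_grid=(1, 2), outer_folds=20, inner_folds=5,
                     n_repeats=2, n_boot=50, n_perm=50, seed=seed)
    rows = []
    results = {}
    for name, target in (("d", d), ("iq", iq)):
        res = nested_cv_predict(X, target, ds.covariates, cfg)
        null = permutation_pvalue(res, X, cfg)
        results[name] = res
        rows.append({"target": name, "r_mean": res.r_mean, "p": null.p_value,
                     "null_sd_fisher_z": null.sd})
        print(f"{name}: cross-validated r = {res.r_mean:.3f}, permutation p = {null.p_value:.2e}")
        pd.DataFrame({
            "subject": ds.subjects,
            "observed_resid": res.observed_resid.mean(axis=0),
            "predicted": res.predictions.mean(axis=0),
        }).to_csv(OUT / f"predictions_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(OUT / "prediction_summary.tsv", sep="\t", index=False)

    part_tab = pd.read_csv(ROOT / "modules" / "modules.tsv", sep="\t")
    from dacuity.network import ConsensusPartition
    labels = part_tab["module"].to_numpy()
    partition = ConsensusPartition(labels=labels, gamma=np.nan,
                                   consensus_matrix=np.eye(labels.size), n_runs=0)
    lesion_cfg = SPLSConfig(eta_grid=(0.7, 0.9), k_grid=(1, 2), outer_folds=10,
                            inner_folds=5, n_repeats=1, n_boot=30, n_perm=30, seed=seed + 1)
    lesion = virtual_lesion_scan(ds, d, partition, lesion_cfg)
    lesion.to_csv(OUT / "virtual_lesion_d.tsv", sep="\t", index=False)
    print("\nvirtual-lesion scan (prediction of d per module):")
    print(lesion.to_string(index=False))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
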