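"""Mixed-effects associations of decision acuity with age, IQ and dispositions.

Builds the longitudinal table from the scored waves, fits the participant
random-intercept models with age decomposed into between- and within-subject
terms, and tests whether the two age slopes agree. Writes results/lme/.
"""

import sys
from pathlib import Path

import pandas as pd

from dacuity.associations import fit_lme, results_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "lme"


def build_table():
    measures = pd.read_csv(ROOT / "cohort" / "measures.tsv", sep="\t")
    sb = pd.read_csv(ROOT / "factors" / "scores_baseline.tsv", sep="\t")[["subject", "d"]]
    sf = pd.read_csv(ROOT / "factors" / "scores_followup.tsv", sep="\t")[["subject", "d"]]
    sb["wave"], sf["wave"] = 1, 2
    scores = pd.concat([sb, sf])
    cov_cols = ["subject", "wave", "age", "sex", "iq_vocab_raw", "iq_matrix_raw",
                "parental_education", "sociality", "aberrant_thinking"]
    tab = measures[cov_cols].merge(scores, on=["subject", "wave"])
    # standardize for interpretable slopes (baseline scale)
    base = tab[tab["wave"] == 1]
    for c in ("age", "iq_vocab_raw", "iq_matrix_raw", "d"):
        tab[c] = (tab[c] - base[c].mean()) / base[c].std()
    return tab


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tab = build_table()
    variants = {
        "age_only": ("sex",),
        "age_iq": ("sex", "iq_vocab_raw", "iq_matrix_raw"),
        "age_iq_dispositions": ("sex", "iq_vocab_raw", "iq_matrix_raw",
                                "sociality", "aberrant_thinking", "parental_education"),
    }
    for name, covs in variants.items():
        res = fit_lme(tab, outcome="d", covariates=covs)
        results_table(res).to_csv(OUT / f"lme_{name}.tsv", sep="\t")
        b, se = res.params["age_between"], res.bse["age_between"]
        print(f"model {name}: beta_age(between) = {b:.3f} (SE {se:.3f}), "
              f"within/between equality p = {res.age_equality_p:.2f}, BIC = {res.bic:.0f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
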