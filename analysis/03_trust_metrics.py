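"""Score the investor-trustee exchanges.

Reads the simulated round-by-round records, computes fractional-change
vectors and whole-exchange scores (initial trust, orientation,
responsiveness, cooperativeness), and summarizes the orientation clusters
the strategy metric is built on. Writes results/trust/.
"""

import sys
from pathlib import Path

import pandas as pd

from dacuity.trust import read_exchanges_tsv, round_vectors, score_exchanges

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "trust"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exchanges = read_exchanges_tsv(ROOT / "cohort" / "trust_exchanges.tsv")
    scores = score_exchanges(exchanges)
    scores.to_csv(OUT / "trust_scores.tsv", sep="\t", index=False)

    classes = []
    for ex in exchanges:
        classes += [c for _, _, c in round_vectors(ex) if c is not None]
    hist = pd.Series(classes).value_counts()
    hist.to_csv(OUT / "round_class_histogram.tsv", sep="\t")
    print("round-vector classes:")
    print(hist.to_string())

    ori = scores["orientation_deg"]
    near_zero = ((ori > -45) & (ori < 45)).mean()
    near_neg135 = ((ori > -180) & (ori < -90)).mean()
    print(f"\norientation clusters: {near_zero:.0%} of exchanges near 0 deg (coaxing), "
          f"{near_neg135:.0%} in the mutual-reduction quadrant (pole at -135 deg)")
    print(f"cooperativeness: mean {scores['cooperativeness'].mean():.2f}, "
          f"responsiveness: mean {scores['responsiveness'].mean():.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
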