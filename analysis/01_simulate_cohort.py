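"""Generate the synthetic cohort: behavioral battery, trust exchanges, connectivity.

Writes the measure table, trust-game exchange records, per-subject
connectivity matrices (manifest + covariates), and the oracle-only ground
truth sidecar under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from dacuity.synthetic import (
    CohortSpec,
    ConnectivitySpec,
    generate_connectivity,
    generate_measure_table,
    generate_trust_exchanges,
    write_ground_truth,
    write_measure_table,
)
from dacuity.trust import write_exchanges_tsv

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = CohortSpec(n_subjects=830, seed=seed)
    table, truth = generate_measure_table(cohort)
    write_measure_table(table, OUT / "measures.tsv")

    conn = ConnectivitySpec(n_nodes=70, n_modules=14, n_signal_edges_d=10,
                            n_signal_edges_iq=10, seed=seed + 1)
    # only part of the cohort is scanned, mirroring the study design
    rng = np.random.default_rng(seed + 3)
    scanned_ids = rng.choice(table.loc[table["wave"] == 1, "subject"].unique(),
                             size=320, replace=False)
    scanned = generate_connectivity(conn, truth, wave=1, subjects=scanned_ids)
    scanned.write(OUT / "connectivity_baseline")
    followup = generate_connectivity(conn, truth, wave=2, subjects=scanned_ids)
    followup.write(OUT / "connectivity_followup")
    write_ground_truth(truth, OUT / "truth")

    exchanges = []
    rng = np.random.default_rng(seed + 2)  # noqa: F811 - fresh stream for the game
    for policy, n in (("coaxing", 40), ("mutual_reduction", 30), ("random", 30)):
        exchanges += generate_trust_exchanges({"policy": policy}, seed=rng, n_subjects=n)
    write_exchanges_tsv(exchanges, OUT / "trust_exchanges.tsv")

    n_base = (table["wave"] == 1).sum()
    n_fu = (table["wave"] == 2).sum()
    print(f"cohort: {n_base} baseline subjects, {n_fu} at follow-up "
          f"({n_fu / n_base:.0%} retention)")
    print(f"connectivity: {scanned.n_subjects} baseline scans, "
          f"{followup.n_subjects} follow-up scans, {conn.n_nodes} nodes")
    print(f"planted signal: {truth.planted_edges_d.size} edges for d "
          f"(slope {truth.effect_d:.3f}), {truth.planted_edges_iq.size} for IQ")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
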