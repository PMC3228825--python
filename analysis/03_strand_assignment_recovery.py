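#!/usr/bin/env python
"""Closed-loop recovery of the mutator's strand from simulated catalogs.

Generates seeded 5-FOA-resistance catalogs with a strand-biased mutator
(10-fold T:dG over A:dC and G:dT over C:dA) assigned to the lagging or
the leading strand, re-tabulates them under the transcribed-strand
hypothesis, and scores the assignment against the same 10-fold prior.
Finding: the generating strand is recovered in essentially every one of
200 seeded catalogs per role at ~170 substitutions per orientation.

Outputs (results/): strand_assignment_recovery.tsv
"""

from pathlib import Path

import numpy as np
import pandas as pd

import forkasym as fa
from forkasym.io import records_from_frame

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

N_CATALOGS = 200
N_MUTANTS = 170
BIASED_RATES = {"T:dG": 10.0, "A:dC": 1.0, "G:dT": 10.0, "C:dA": 1.0}


def main() -> None:
    reference = fa.load_reference()
    geometry = fa.LocusGeometry(0, len(reference), 5000)
    roles = fa.nascent_strand_roles(geometry)
    prior = fa.InVitroBiasPrior(rates=BIASED_RATES)

    rows = []
    for role in ("lagging", "leading"):
        spec = fa.MutatorSpec(
            assigned_role=role,
            mispair_rates=BIASED_RATES,
            class_mix={"substitution": 1.0},
            n_mutants=N_MUTANTS,
        )
        decisions = []
        log_odds = []
        for seed in range(N_CATALOGS):
            catalog, _ = fa.generate_catalog(reference, geometry, spec, seed=seed)
            table = fa.tabulate(records_from_frame(catalog), roles, geometry)
            sa = fa.assign_strand(table, prior)
            decisions.append(sa.decision)
            log_odds.append(sa.log_odds)
        recovered = sum(d == role for d in decisions)
        rows.append(
            {
                "assigned_role": role,
                "n_catalogs": N_CATALOGS,
                "n_substitutions_per_orientation": N_MUTANTS,
                "recovered": recovered,
                "recovery_rate": recovered / N_CATALOGS,
                "median_log_odds": float(np.median(log_odds)),
            }
        )
        print(
            f"mutator on {role}: recovered {recovered}/{N_CATALOGS} "
            f"(median log-odds {np.median(log_odds):+.0f})"
        )
    pd.DataFrame(rows).to_csv(OUT / "strand_assignment_recovery.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
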