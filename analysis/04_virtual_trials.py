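"""Generate the two virtual hydrocortisone/ACTH trials.

Produces an event table on the two cross-over designs (trial 1: four
DEX-suppressed periods with 0.5/2/5/10 mg oral doses; trial 2: an endogenous
24-h profile plus DEX-only, DEX + 20 mg oral and DEX + 20 mg IV periods)
with interindividual, interoccasion and residual variability, applies the
pre-dose ACTH exclusion rule, and writes the table plus the hidden truth.

Writes results/virtual_trial.csv and results/virtual_trial_truth.json.
"""

import json
from pathlib import Path

import pandas as pd

from hpaxis import StructuralParams, VarianceComponents
from hpaxis.io_tables import write_event_table
from hpaxis.synthetic_data import (apply_exclusion_rule, generate_cohort,
                                   generate_trial, trial1_design,
                                   trial2_design)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250
N1, N2 = 16, 14


def main() -> None:
    theta = StructuralParams()
    omega = VarianceComponents()
    c1 = generate_cohort(N1, SEED)
    c2 = generate_cohort(N2, SEED + 1)
    c2["ID"] += N1
    t1, truth1 = generate_trial(trial1_design(), c1, theta, omega,
                                seed=SEED + 2)
    t2, truth2 = generate_trial(trial2_design(), c2, theta, omega,
                                seed=SEED + 3)
    table = pd.concat([t1, t2], ignore_index=True)
    table, excl = apply_exclusion_rule(table)

    write_event_table(table, OUT / "virtual_trial.csv")
    truth = {str(k): {"BW": v["BW"], "age": v["age"], "etas": v["etas"],
                      "occ_mtt_factor": {str(o): f for o, f in
                                         v["occ_mtt_factor"].items()}}
             for k, v in {**truth1, **truth2}.items()}
    (OUT / "virtual_trial_truth.json").write_text(json.dumps(truth, indent=1))

    n_obs = int((table["EVID"] == 0).sum())
    print(f"Wrote {len(table)} rows ({n_obs} observations) for "
          f"{table['ID'].nunique()} subjects; {len(excl)} exclusion(s).")


if __name__ == "__main__":
    main()
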