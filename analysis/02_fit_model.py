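"""Fit the PoP-ORL model hierarchically, one assessment wave at a time.

Reads results/study/sessions.csv (from 01_simulate_cohort.py), runs the
empirical-Bayes hierarchical fit per wave, and writes per-subject
parameter estimates (learning rates also probit-transformed) to
results/study/estimates.csv.

Run:  python analysis/02_fit_model.py
"""

from pathlib import Path

import pandas as pd

from popigt.igt_task import sessions_from_csv
from popigt.pipeline import fit_all_waves

OUT = Path("results/study")


def main() -> None:
    sessions = sessions_from_csv(OUT / "sessions.csv")
    estimates = fit_all_waves(sessions)
    estimates.to_csv(OUT / "estimates.csv", index=False)

    print(f"fit {len(estimates)} subject-wave estimates "
          f"across {estimates['wave'].nunique()} waves")
    means = estimates.groupby("wave")[
        ["A_rew", "A_pun", "beta_f", "beta_b"]].mean().round(3)
    print("per-wave mean estimates:")
    print(means.to_string())
    unconverged = int((~estimates["converged"]).sum())
    print(f"{unconverged} estimates flagged non-converged")


if __name__ == "__main__":
    main()
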