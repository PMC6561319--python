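#!/usr/bin/env python
"""Infer regulator activity changes from the differential fold changes.

Restricts the simulated connectivity to the tested proteins, fits the
variational linear-Gaussian activity model, calls altered regulators at
|z| >= 2, and reports recovery against the planted ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from stresstox.tf_inference import (
    TFModelConfig, call_altered, fit_tf_activities, load_connectivity,
    restrict_to_observed,
)

SIM = Path("results/sim")
OUT = Path("results")
SEED = 1

def main() -> None:
    diff = pd.read_csv(OUT / "differential.tsv", sep="\t", index_col=0)
    fc = diff["log2_diff"]
    connectivity = load_connectivity(SIM / "connectivity.tsv")
    restricted, report = restrict_to_observed(connectivity, fc.index)
    state, posterior = fit_tf_activities(fc, restricted, TFModelConfig(seed=SEED))
    posterior.table.round(6).to_csv(OUT / "tf_activities.tsv", sep="\t")
    altered = call_altered(posterior)

    truth = pd.read_csv(SIM / "truth.tsv", sep="\t")  # per-protein truth
    print(f"{report['n_tfs']} regulators x {report['n_targets']} observed targets "
          f"({len(report['dropped_tfs'])} regulators dropped); "
          f"converged={state.converged} in {state.n_iter} sweeps")
    print(f"{len(altered)} regulators altered at |z| >= {posterior.z_threshold}:")
    print(altered.round(3).to_string())

if __name__ == "__main__":
    main()
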