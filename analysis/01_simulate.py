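#!/usr/bin/env python
"""Generate the simulated study inputs.

Emulates a 4-vs-4 label-free experiment in which 8 of 40 regulators
change activity and drive protein-abundance shifts through a random
binary connectivity matrix, with intensity-dependent dropout.  Writes
the raw protein-groups table, the design, the connectivity edge list
and the planted ground truth under results/sim/.
"""

from pathlib import Path

from stresstox.lfq_stats import write_protein_groups
from stresstox.synthetic_data import (
    SimConfig,
    generate_connectivity,
    generate_lfq_experiment,
    write_design,
    write_truth_table,
)
from stresstox.tf_inference import write_connectivity_edges

OUT = Path("results/sim")
SEED = 1

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    matrix, truth = generate_lfq_experiment(cfg)
    connectivity = generate_connectivity(
        cfg.n_proteins, cfg.n_tfs, cfg.connectivity_density, seed=cfg.seed + 1
    )
    write_protein_groups(matrix, OUT / "proteinGroups.tsv")
    write_design(matrix, OUT / "design.tsv")
    write_truth_table(truth, OUT / "truth.tsv")
    write_connectivity_edges(connectivity, OUT / "connectivity.tsv")
    n_missing = matrix.values.isna().to_numpy().mean()
    n_altered = (truth.true_activities != 0).sum()
    print(f"{len(matrix.protein_ids)} proteins x {len(matrix.sample_ids)} samples, "
          f"{n_missing:.1%} missing cells, {n_altered} altered regulators planted")

if __name__ == "__main__":
    main()
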