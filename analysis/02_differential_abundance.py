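#!/usr/bin/env python
"""Differential protein abundance on the simulated experiment.

Reads results/sim/, runs the standard LFQ workflow (valid-value filter,
log2, median centring, downshifted-normal imputation, S0=1 permutation
test at FDR 0.05), attaches fold changes, and writes the differential
table plus the volcano-plot table under results/.
"""

from pathlib import Path

from stresstox.config import PipelineConfig
from stresstox.lfq_stats import (
    assign_groups, read_design, read_protein_groups, volcano_table,
)
from stresstox.pipeline import differential_abundance

SIM = Path("results/sim")
OUT = Path("results")

def main() -> None:
    matrix = assign_groups(
        read_protein_groups(SIM / "proteinGroups.tsv"),
        read_design(SIM / "design.tsv"),
    )
    _, result = differential_abundance(matrix, PipelineConfig())
    result.table.round(6).to_csv(OUT / "differential.tsv", sep="\t")
    volcano_table(result).round(6).to_csv(OUT / "volcano.tsv", sep="\t")
    sig = result.table[result.table["significant"]]
    up = int((sig["log2_diff"] >= 0).sum())
    print(f"{len(result.table)} proteins tested after filtering; "
          f"{len(sig)} significant at FDR {result.fdr} ({up} up, {len(sig)-up} down)")

if __name__ == "__main__":
    main()
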