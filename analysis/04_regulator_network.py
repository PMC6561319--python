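#!/usr/bin/env python
"""Export the altered-regulator -> significant-protein network.

Joins the differential calls with the altered regulators over the
connectivity matrix and writes the network as TSV, SIF and GraphML.
"""

from pathlib import Path

import pandas as pd

from stresstox.network_io import export_network
from stresstox.tf_inference import (
    ConnectivityMatrix, build_regulator_network, load_connectivity,
    restrict_to_observed,
)

SIM = Path("results/sim")
OUT = Path("results")


class _Result:
    def __init__(self, table):
        self.table = table


def main() -> None:
    diff = pd.read_csv(OUT / "differential.tsv", sep="\t", index_col=0)
    acts = pd.read_csv(OUT / "tf_activities.tsv", sep="\t", index_col=0)
    altered = acts[acts["altered"]]
    connectivity, _ = restrict_to_observed(
        load_connectivity(SIM / "connectivity.tsv"), diff.index
    )
    net = build_regulator_network(_Result(diff), connectivity, altered)
    for fmt in ("tsv", "sif", "graphml"):
        export_network(net, OUT / f"network.{fmt}", fmt)
    print(f"{len(net)} edges between {net['regulator'].nunique()} altered regulators "
          f"and {net['protein'].nunique()} significant proteins")

if __name__ == "__main__":
    main()
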