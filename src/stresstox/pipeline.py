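"""End-to-end driver: simulate -> differential test -> TF inference -> network.

Each stage writes its table under the configured output directory and the
run finishes with a machine-readable manifest (package version, seeds,
input checksums) sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .lfq_stats import (
    assign_groups,
    compute_fold_changes,
    filter_min_valid,
    impute_downshifted_normal,
    log2_transform,
    normalize_median,
    read_design,
    read_protein_groups,
    s0_permutation_test,
    write_protein_groups,
)
from .network_io import export_network
from .synthetic_data import generate_lfq_experiment, write_design, write_truth_table
from .tf_inference import (
    build_regulator_network,
    call_altered,
    fit_tf_activities,
    load_connectivity,
    restrict_to_observed,
    write_connectivity_edges,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "differential_abundance"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def differential_abundance(matrix, config: PipelineConfig):
    """The full quantitative stage on a raw intensity matrix."""
    m = filter_min_valid(matrix, config.test.min_valid)
    m = log2_transform(m)
    m = normalize_median(m, mode=config.normalization_mode)
    m = impute_downshifted_normal(m, config.impute)
    result = s0_permutation_test(m, config.test)
    return m, compute_fold_changes(result)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "package": "stresstox",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "sim": dataclasses.asdict(config.sim),
            "test": dataclasses.asdict(config.test),
            "impute": dataclasses.asdict(config.impute),
            "tf": dataclasses.asdict(config.tf),
            "normalization_mode": config.normalization_mode,
        },
        "stages": [],
        "inputs": {},
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    matrix = truth = connectivity = None
    try:
        if config.run_simulate:
            matrix, truth = generate_lfq_experiment(config.sim)
            from .synthetic_data import generate_connectivity

            connectivity = generate_connectivity(
                config.sim.n_proteins, config.sim.n_tfs,
                config.sim.connectivity_density, seed=config.sim.seed + 1,
            )
            write_protein_groups(matrix, out / "proteinGroups.tsv")
            write_design(matrix, out / "design.tsv")
            write_truth_table(truth, out / "truth.tsv")
            write_connectivity_edges(connectivity, out / "connectivity.tsv")
            for f in ("proteinGroups.tsv", "design.tsv", "truth.tsv", "connectivity.tsv"):
                record("simulate", f, out / f)
            manifest["stages"].append("simulate")
        else:
            matrix = read_protein_groups(config.intensities_path)
            matrix = assign_groups(matrix, read_design(config.design_path))
            for key, p in (("intensities", config.intensities_path),
                           ("design", config.design_path)):
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
            if config.run_tf:
                connectivity = load_connectivity(config.connectivity_path)
                manifest["inputs"]["connectivity"] = {
                    "path": str(config.connectivity_path),
                    "sha256": _sha256(Path(config.connectivity_path)),
                }

        diff_result = None
        if config.run_diff:
            _, diff_result = differential_abundance(matrix, config)
            table = diff_result.table.round(6)
            table.to_csv(out / "differential.tsv", sep="\t")
            record("diff", "differential.tsv", out / "differential.tsv")
            manifest["stages"].append("diff")

        posterior = altered = None
        if config.run_tf:
            if diff_result is None:
                raise ValueError("tf stage requires the diff stage")
            fold = diff_result.table["log2_diff"]
            restricted, report = restrict_to_observed(connectivity, fold.index)
            fc_upper = fold.copy()
            fc_upper.index = fc_upper.index.astype(str).str.upper()
            state, posterior = fit_tf_activities(
                fc_upper.reindex([t for t in restricted.target_ids]),
                restricted, config.tf,
            )
            altered = call_altered(posterior)
            acts = posterior.table.round(6)
            acts.to_csv(out / "tf_activities.tsv", sep="\t")
            record("tf", "tf_activities.tsv", out / "tf_activities.tsv")
            manifest["stages"].append("tf")
            manifest["tf_restriction"] = {
                "n_tfs": report["n_tfs"], "n_targets": report["n_targets"],
                "n_dropped_tfs": len(report["dropped_tfs"]),
            }
            manifest["tf_converged"] = state.converged

            if config.run_network:
                net = build_regulator_network(diff_result, restricted, altered)
                export_network(net, out / "network.tsv", "tsv")
                export_network(net, out / "network.sif", "sif")
                export_network(net, out / "network.graphml", "graphml")
                for f in ("network.tsv", "network.sif"):
                    record("network", f, out / f)
                manifest["stages"].append("network")
    except Exception as exc:  # annotate which stage died
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
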