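"""Ground-truth simulators for every pipeline stage.

The generators emulate the statistical structure a two-condition
label-free proteomics experiment hands to the downstream analysis:

* log-normal LFQ intensities (log2 baselines ~ N(baseline_mean,
  baseline_sd^2));
* group effects driven through a binary regulator->target connectivity
  matrix by latent regulator activities, so the same dataset exercises
  both the differential test and the activity-inference model;
* intensity-dependent (missing-not-at-random) dropout, logistic in log2
  intensity so low-abundance proteins are missing more often;
* Gaussian replicate noise;
* Michaelis-Menten rate curves with proportional (constant-CV) noise.

Every generator takes an explicit seed and draws from a single local
RNG stream — no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzyme_kinetics import KineticsDataset
from .lfq_stats import IntensityMatrix
from .tf_inference import ConnectivityMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_connectivity",
    "generate_tf_dataset",
    "direct_ground_truth",
    "generate_lfq_experiment",
    "generate_mm_dataset",
    "write_truth_table",
    "write_design",
]

CONTROL_GROUP = "control"
TREATED_GROUP = "vanillin"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulators.

    Defaults mirror a 4-vs-4 replicate label-free design at typical
    log2 LFQ magnitudes (baselines N(25, 3^2)), with regulator-driven
    effects of roughly one log2 unit and replicate noise of 0.25 log2
    units.  ``mnar_midpoint``/``mnar_slope`` place dropout in the low
    tail of the intensity distribution.
    """

    n_proteins: int = 1000
    n_tfs: int = 40
    connectivity_density: float = 0.05
    n_altered_tfs: int = 8
    activity_effect_sd: float = 1.0   # log2 units
    coupling_sd: float = 0.2
    noise_sd: float = 0.25            # log2 units
    baseline_mean: float = 25.0       # log2 intensity
    baseline_sd: float = 3.0
    replicates_per_group: int = 4
    mnar_midpoint: float = 21.0       # log2 intensity of 50% dropout
    mnar_slope: float = 1.0           # per log2 unit
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_tfs) < 1:
            raise ValueError("counts must be at least 1")
        if not 0 < self.connectivity_density < 1:
            raise ValueError("connectivity_density must lie in (0, 1)")
        if self.n_altered_tfs < 0 or self.n_altered_tfs > self.n_tfs:
            raise ValueError("n_altered_tfs must lie in [0, n_tfs]")
        for name in ("activity_effect_sd", "coupling_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.replicates_per_group < 3:
            raise ValueError(
                "replicates_per_group must be >= 3 so the valid-value filter "
                "is exercisable"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``true_log2fc`` equals the connectivity-weighted sum of coupling x
    activity for every protein — exact by construction.
    """

    true_activities: pd.Series            # per TF, signed log2 effect
    true_couplings: pd.DataFrame          # targets x TFs, zero off-edges
    true_log2fc: pd.Series                # per protein
    de_labels: pd.Series = field(default=None)  # per protein, truly affected

    def __post_init__(self) -> None:
        if self.de_labels is None:
            object.__setattr__(
                self, "de_labels", self.true_log2fc != 0.0
            )


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def _tf_ids(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(n)]


def generate_connectivity(
    n_proteins: int, n_tfs: int, density: float, seed: int
) -> ConnectivityMatrix:
    """Random binary incidence with i.i.d. Bernoulli(density) entries.

    Columns that come out empty are resampled so every regulator has at
    least one target (required by the inference model).
    """
    if n_proteins < 1 or n_tfs < 1:
        raise ValueError("dimensions must be positive")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if density * n_proteins < 1:
        raise ValueError("density * n_proteins must be >= 1 (expected degree)")
    rng = np.random.default_rng(seed)
    x = (rng.random((n_proteins, n_tfs)) < density).astype(np.int8)
    for t in range(n_tfs):
        while x[:, t].sum() == 0:
            x[:, t] = (rng.random(n_proteins) < density).astype(np.int8)
    edges = pd.DataFrame(x, index=_protein_ids(n_proteins), columns=_tf_ids(n_tfs))
    return ConnectivityMatrix(edges=edges, provenance=f"simulated(density={density}, seed={seed})")


def generate_tf_dataset(
    connectivity: ConnectivityMatrix, config: SimConfig
) -> tuple[GroundTruth, pd.Series]:
    """Plant regulator activities and return noisy protein fold changes.

    ``n_altered_tfs`` regulators receive activities ~ N(0,
    activity_effect_sd^2), resampled while |value| < sd/2 so planted
    effects are detectable; the rest are exactly zero.  Couplings on
    edges are N(1, coupling_sd^2) (activator-dominant).  The observed
    fold change is the exact connectivity-weighted effect plus
    N(0, noise_sd^2) noise.
    """
    x = connectivity.edges.to_numpy(dtype=float)
    n_targets, n_tfs = x.shape
    if config.n_altered_tfs > n_tfs:
        raise ValueError("n_altered_tfs exceeds the number of regulators")
    rng = np.random.default_rng(config.seed)
    activities = np.zeros(n_tfs)
    altered = rng.choice(n_tfs, size=config.n_altered_tfs, replace=False)
    sd = config.activity_effect_sd
    for t in altered:
        val = rng.normal(0.0, sd)
        while sd > 0 and abs(val) < sd / 2:
            val = rng.normal(0.0, sd)
        activities[t] = val
    couplings = np.where(x > 0, rng.normal(1.0, config.coupling_sd, x.shape), 0.0)
    true_fc = (couplings * x) @ activities
    observed = true_fc + rng.normal(0.0, config.noise_sd, n_targets)
    truth = GroundTruth(
        true_activities=pd.Series(activities, index=connectivity.tf_ids),
        true_couplings=pd.DataFrame(
            couplings, index=connectivity.target_ids, columns=connectivity.tf_ids
        ),
        true_log2fc=pd.Series(true_fc, index=connectivity.target_ids),
    )
    return truth, pd.Series(observed, index=connectivity.target_ids)


def direct_ground_truth(
    n_proteins: int, de_fraction: float, effect_log2fc: float, seed: int
) -> GroundTruth:
    """Per-protein effect mode: a fraction of proteins shifted by
    +-effect_log2fc with equal probability, no regulator structure.

    Useful for testing the differential-abundance stage in isolation.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    fc = np.zeros(n_proteins)
    n_de = int(round(de_fraction * n_proteins))
    hit = rng.choice(n_proteins, size=n_de, replace=False)
    fc[hit] = effect_log2fc * rng.choice([-1.0, 1.0], size=n_de)
    return GroundTruth(
        true_activities=pd.Series(dtype=float),
        true_couplings=pd.DataFrame(),
        true_log2fc=pd.Series(fc, index=ids),
    )


def generate_lfq_experiment(
    config: SimConfig, ground_truth: GroundTruth | None = None
) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate a raw two-group LFQ protein-groups matrix.

    Per-protein log2 baselines ~ N(baseline_mean, baseline_sd^2); the
    treated group is shifted by the planted true_log2fc; replicates add
    N(0, noise_sd^2); each cell then drops out independently with
    probability logistic(-mnar_slope * (x - mnar_midpoint)).  Values
    are returned on the linear intensity scale (log2 not yet applied)
    so the full pipeline is exercised.
    """
    if ground_truth is None:
        conn = generate_connectivity(
            config.n_proteins, config.n_tfs, config.connectivity_density,
            seed=config.seed + 1,
        )
        ground_truth, _ = generate_tf_dataset(conn, config)
    ids = list(ground_truth.true_log2fc.index)
    n = len(ids)
    rng = np.random.default_rng(config.seed)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    fc = ground_truth.true_log2fc.to_numpy(dtype=float)
    r = config.replicates_per_group
    ctrl = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n, r))
    trt = (baseline + fc)[:, None] + rng.normal(0.0, config.noise_sd, (n, r))
    log2_vals = np.hstack([ctrl, trt])
    from scipy.special import expit

    p_missing = expit(-config.mnar_slope * (log2_vals - config.mnar_midpoint))
    dropout = rng.random(log2_vals.shape) < p_missing
    linear = np.where(dropout, np.nan, 2.0 ** log2_vals)
    samples = [f"ctrl_{i+1}" for i in range(r)] + [f"van_{i+1}" for i in range(r)]
    values = pd.DataFrame(linear, index=pd.Index(ids, name="Protein IDs"), columns=samples)
    group_of = {s: (CONTROL_GROUP if s.startswith("ctrl") else TREATED_GROUP) for s in samples}
    return IntensityMatrix(values=values, group_of=group_of), ground_truth


def generate_mm_dataset(
    km: float, vmax: float, substrate_levels, noise_cv: float, seed: int,
    substrate_unit: str = "mM", rate_unit: str = "nmol/min/mg",
) -> KineticsDataset:
    """Michaelis-Menten rates with proportional noise.

    rates = vmax*S/(km+S) * (1 + N(0, noise_cv^2)); substrate levels
    must number at least 5 and span both sides of Km.
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    s = np.asarray(substrate_levels, dtype=float)
    if s.size < 5:
        raise ValueError("need at least 5 substrate levels")
    if not (s.min() < km < s.max()):
        raise ValueError("substrate levels must span below and above Km")
    rng = np.random.default_rng(seed)
    v = vmax * s / (km + s) * (1.0 + rng.normal(0.0, noise_cv, s.size))
    return KineticsDataset(
        substrate=s, rate=v, substrate_unit=substrate_unit, rate_unit=rate_unit
    )


def write_truth_table(truth: GroundTruth, path) -> None:
    """TSV of (protein, true_log2fc, de_label) for recovery checks."""
    pd.DataFrame(
        {
            "protein": truth.true_log2fc.index,
            "true_log2fc": truth.true_log2fc.to_numpy(),
            "de_label": truth.de_labels.to_numpy().astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_design(matrix: IntensityMatrix, path) -> None:
    pd.DataFrame(
        {"sample": list(matrix.group_of), "group": list(matrix.group_of.values())}
    ).to_csv(path, sep="\t", index=False)
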