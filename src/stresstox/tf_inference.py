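"""Transcription-factor activity inference from protein fold changes.

The model explains the observed log2 fold change ``y_g`` of each protein
through the regulators known to control its gene:

    y_g = sum_t X_gt * b_gt * c_t + eps_g,     eps_g ~ N(0, 1/tau)

where ``X`` is a binary connectivity (regulon-membership) matrix, ``c_t``
is the latent activity change of regulator t, ``b_gt`` the regulatory
coupling of t on target g, and tau a shared noise precision.  Priors are
c_t ~ N(0, 1) (the unit scale pins down the b*c scale indeterminacy),
b_gt ~ N(0, coupling_prior_sd^2) and tau ~ Gamma(a0, b0).

Inference uses a fully factorized variational approximation
q(c) q(b) q(tau) with closed-form coordinate-ascent updates; the
evidence lower bound (ELBO) is tracked and must be non-decreasing.
The model is sign-unidentifiable (flipping c_t together with b_.t leaves
the likelihood unchanged); after convergence the sign of each regulator
is fixed so that the summed posterior coupling means are non-negative,
i.e. an activator-dominant convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "TFModelConfig",
    "TFModelState",
    "TFActivityPosterior",
    "load_connectivity",
    "write_connectivity_edges",
    "restrict_to_observed",
    "fit_tf_activities",
    "call_altered",
    "build_regulator_network",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Binary regulator->target incidence.

    ``edges`` is a targets x regulators DataFrame of 0/1; identifiers
    are uppercased at load time so gene/protein symbol matching is
    case-insensitive.
    """

    edges: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = self.edges.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("connectivity entries must be binary 0/1")
        if self.edges.columns.has_duplicates or self.edges.index.has_duplicates:
            raise ValueError("duplicate regulator or target identifiers")
        empty = self.edges.columns[(self.edges.sum(axis=0) == 0)].tolist()
        if empty:
            raise ValueError(f"regulators with no targets: {empty}")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.edges.columns)

    @property
    def target_ids(self) -> list[str]:
        return list(self.edges.index)

    @property
    def n_edges(self) -> int:
        return int(self.edges.to_numpy().sum())


def load_connectivity(path, fmt: str = "auto") -> ConnectivityMatrix:
    """Load a connectivity matrix from an edge list or a dense TSV.

    Edge-list format: two or three tab-separated columns
    (regulator, target[, weight in {0,1}]), optional header.  Dense
    format: header row of regulator ids, first column of target ids.
    Duplicate edges are collapsed with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.empty:
        raise ValueError(f"empty connectivity file: {path}")
    if fmt == "auto":
        fmt = "edges" if df.shape[1] <= 3 else "dense"
    if fmt == "edges":
        first = df.iloc[0]
        if str(first.iloc[0]).lower() in {"regulator", "tf", "source"}:
            df = df.iloc[1:]
        df = df.rename(columns={0: "regulator", 1: "target", 2: "weight"})
        if "weight" in df.columns:
            w = pd.to_numeric(df["weight"].fillna(1), errors="raise")
            if not np.isin(w.to_numpy(), (0, 1)).all():
                raise ValueError("edge weights must be binary 0/1")
            df = df[w == 1]
        df = df.assign(
            regulator=df["regulator"].str.upper(), target=df["target"].str.upper()
        )
        n_dup = df.duplicated(["regulator", "target"]).sum()
        if n_dup:
            warnings.warn(f"{n_dup} duplicate edges collapsed", stacklevel=2)
            df = df.drop_duplicates(["regulator", "target"])
        edges = (
            pd.crosstab(df["target"], df["regulator"]).clip(upper=1).astype(np.int8)
        )
        edges.index.name = None
        edges.columns.name = None
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        dense.index = dense.index.astype(str).str.upper()
        dense.columns = dense.columns.astype(str).str.upper()
        edges = dense.astype(float).astype(np.int8)
    cm = ConnectivityMatrix(edges=edges, provenance=str(path))
    logger.info(
        "connectivity: %d regulators, %d targets, %d edges",
        len(cm.tf_ids), len(cm.target_ids), cm.n_edges,
    )
    return cm


def write_connectivity_edges(connectivity: ConnectivityMatrix, path) -> None:
    """Write the incidence as a (regulator, target) edge-list TSV."""
    rows = connectivity.edges.stack()
    rows = rows[rows == 1]
    out = pd.DataFrame(
        {"regulator": rows.index.get_level_values(1),
         "target": rows.index.get_level_values(0)}
    ).sort_values(["regulator", "target"])
    out.to_csv(path, sep="\t", index=False)


def restrict_to_observed(
    connectivity: ConnectivityMatrix, observed_protein_ids
) -> tuple[ConnectivityMatrix, dict]:
    """Drop unobserved targets, then regulators left without any target.

    Returns the restricted matrix and a report listing what was dropped.
    """
    observed = {str(p).upper() for p in observed_protein_ids}
    keep_targets = [t for t in connectivity.target_ids if t in observed]
    if not keep_targets:
        raise ValueError("no connectivity target overlaps the observed proteins")
    sub = connectivity.edges.loc[keep_targets]
    tf_degree = sub.sum(axis=0)
    keep_tfs = tf_degree.index[tf_degree > 0].tolist()
    report = {
        "dropped_targets": sorted(set(connectivity.target_ids) - set(keep_targets)),
        "dropped_tfs": sorted(set(connectivity.tf_ids) - set(keep_tfs)),
        "n_targets": len(keep_targets),
        "n_tfs": len(keep_tfs),
    }
    restricted = ConnectivityMatrix(
        edges=sub[keep_tfs], provenance=connectivity.provenance + " (restricted)"
    )
    return restricted, report


@dataclass(frozen=True)
class TFModelConfig:
    coupling_prior_sd: float = 1.0
    noise_prior_shape: float = 1e-3
    noise_prior_rate: float = 1e-3
    max_iter: int = 1000
    elbo_rel_tol: float = 1e-8
    seed: int = 0
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if min(self.coupling_prior_sd, self.noise_prior_shape, self.noise_prior_rate) <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 < self.elbo_rel_tol < 1:
            raise ValueError("elbo_rel_tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass
class TFModelState:
    """Variational posterior factors and the optimisation trace."""

    c_mean: pd.Series
    c_var: pd.Series
    b_mean: pd.DataFrame
    b_var: pd.DataFrame
    tau_shape: float
    tau_rate: float
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def tau_mean(self) -> float:
        return self.tau_shape / self.tau_rate


@dataclass(frozen=True)
class TFActivityPosterior:
    """Per-regulator posterior activity change summary."""

    table: pd.DataFrame  # post_mean, post_sd, zscore, altered
    z_threshold: float


def _gamma_cross_entropy_terms(a, b, a0, b0, e_log_tau, e_tau):
    """E_q[log p(tau)] - E_q[log q(tau)] for Gamma(shape, rate) factors."""
    log_p = a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * e_log_tau - b0 * e_tau
    # E_q[log q] with b*E[tau] = a
    log_q = a * np.log(b) - gammaln(a) + (a - 1) * e_log_tau - a
    return log_p - log_q


def fit_tf_activities(
    fold_changes: pd.Series,
    connectivity: ConnectivityMatrix,
    config: TFModelConfig = TFModelConfig(),
    fixed_couplings: pd.DataFrame | None = None,
    fixed_tau: float | None = None,
) -> tuple[TFModelState, TFActivityPosterior]:
    """Fit the variational posterior over regulator activity changes.

    ``fold_changes`` must be indexed by (a superset of) the
    connectivity's targets; matching is case-insensitive and unmatched
    entries are dropped with a logged count.  ``fixed_couplings`` clamps
    b_gt to given values (no q(b) update) and ``fixed_tau`` clamps the
    noise precision — both exist so the posterior can be compared
    against analytic Gaussian conditionals.
    """
    X_df = connectivity.edges
    targets = X_df.index
    fc = fold_changes.copy()
    fc.index = fc.index.astype(str).str.upper()
    n_unmatched = len(fc.index.difference(targets))
    if n_unmatched:
        logger.info("dropping %d fold-change entries absent from connectivity", n_unmatched)
    missing = targets.difference(fc.index)
    if len(missing):
        raise ValueError(
            f"fold changes missing for {len(missing)} connectivity targets "
            f"(e.g. {list(missing[:3])}); restrict the connectivity first"
        )
    y = fc.reindex(targets).to_numpy(dtype=float)
    X = X_df.to_numpy(dtype=float)
    G, T = X.shape
    if T < 1:
        raise ValueError("need at least one regulator")
    edge = X > 0
    sigma_b2 = config.coupling_prior_sd ** 2
    a0, b0 = config.noise_prior_shape, config.noise_prior_rate
    rng = np.random.default_rng(config.seed)

    clamp_b = fixed_couplings is not None
    clamp_tau = fixed_tau is not None

    # init: ridge regression of y on X with unit couplings, tie-broken by a
    # tiny seeded jitter; couplings start at 1 on edges
    mc = np.linalg.solve(X.T @ X + np.eye(T), X.T @ y)
    mc = mc + rng.normal(0.0, 1e-4, T)
    vc = np.ones(T)
    if clamp_b:
        Mb = fixed_couplings.reindex(index=targets, columns=X_df.columns).to_numpy(dtype=float)
        Mb = np.where(edge, Mb, 0.0)
        Sb = np.zeros((G, T))
    else:
        Mb = np.where(edge, 1.0, 0.0)
        Sb = np.where(edge, sigma_b2, 0.0)
    if clamp_tau:
        e_tau, e_log_tau = float(fixed_tau), float(np.log(fixed_tau))
        a_n, b_n = np.nan, np.nan
    else:
        a_n, b_n = a0 + G / 2.0, b0 + G / 2.0
        e_tau, e_log_tau = a_n / b_n, digamma(a0 + G / 2.0) - np.log(b0 + G / 2.0)

    fitted = (Mb * X) @ mc  # Mb is zero off-edges, so this is the model mean

    def expected_sq_residual() -> float:
        eb2 = Mb ** 2 + Sb
        ec2 = mc ** 2 + vc
        var_bc = edge * (eb2 * ec2[None, :] - (Mb * mc[None, :]) ** 2)
        return float(np.sum((y - fitted) ** 2) + var_bc.sum())

    def elbo() -> float:
        s = expected_sq_residual()
        val = 0.5 * G * (e_log_tau - np.log(2 * np.pi)) - 0.5 * e_tau * s
        val += 0.5 * np.sum(np.log(vc) + 1.0 - mc ** 2 - vc)
        if not clamp_b:
            sb_e, mb_e = Sb[edge], Mb[edge]
            val += 0.5 * np.sum(
                np.log(sb_e / sigma_b2) + 1.0 - (mb_e ** 2 + sb_e) / sigma_b2
            )
        if not clamp_tau:
            val += _gamma_cross_entropy_terms(a_n, b_n, a0, b0, e_log_tau, e_tau)
        return val

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        ec2 = mc ** 2 + vc
        if not clamp_b:
            # q(b) sweep: within a column the targets are independent, so
            # each column update is an exact coordinate step
            for t in range(T):
                rows = edge[:, t]
                if not rows.any():
                    continue
                resid = y[rows] - (fitted[rows] - Mb[rows, t] * mc[t])
                prec = 1.0 / sigma_b2 + e_tau * ec2[t]
                new_mb = e_tau * mc[t] * resid / prec
                fitted[rows] += (new_mb - Mb[rows, t]) * mc[t]
                Mb[rows, t] = new_mb
                Sb[rows, t] = 1.0 / prec
        # q(c) sweep
        eb2 = Mb ** 2 + Sb
        for t in range(T):
            rows = edge[:, t]
            if not rows.any():
                continue
            resid = y[rows] - (fitted[rows] - Mb[rows, t] * mc[t])
            prec = 1.0 + e_tau * eb2[rows, t].sum()
            new_mc = e_tau * float(Mb[rows, t] @ resid) / prec
            fitted[rows] += Mb[rows, t] * (new_mc - mc[t])
            mc[t] = new_mc
            vc[t] = 1.0 / prec
        # q(tau)
        if not clamp_tau:
            b_n = b0 + 0.5 * expected_sq_residual()
            e_tau = a_n / b_n
            e_log_tau = digamma(a_n) - np.log(b_n)
        val = elbo()
        if np.isnan(val):
            raise RuntimeError("ELBO became NaN; check the inputs for non-finite values")
        trace.append(val)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            if rel < config.elbo_rel_tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"variational fit did not converge in {config.max_iter} iterations",
            stacklevel=2,
        )

    if not clamp_b:
        # resolve the per-regulator sign indeterminacy: majority-positive couplings
        for t in range(T):
            if Mb[edge[:, t], t].sum() < 0:
                Mb[:, t] = -Mb[:, t]
                mc[t] = -mc[t]

    tf_ids = list(X_df.columns)
    state = TFModelState(
        c_mean=pd.Series(mc, index=tf_ids),
        c_var=pd.Series(vc, index=tf_ids),
        b_mean=pd.DataFrame(Mb, index=targets, columns=tf_ids),
        b_var=pd.DataFrame(Sb, index=targets, columns=tf_ids),
        tau_shape=a_n,
        tau_rate=b_n,
        elbo_trace=trace,
        converged=converged,
        n_iter=it,
    )
    sd = np.sqrt(vc)
    z = mc / sd
    post = pd.DataFrame(
        {
            "post_mean": mc,
            "post_sd": sd,
            "zscore": z,
            "altered": np.abs(z) >= config.z_threshold,
        },
        index=pd.Index(tf_ids, name="tf"),
    )
    return state, TFActivityPosterior(table=post, z_threshold=config.z_threshold)


def call_altered(
    posterior: TFActivityPosterior,
    z_threshold: float | None = None,
    annotation: dict[str, str] | None = None,
) -> pd.DataFrame:
    """List regulators whose activity change is credibly non-zero.

    A regulator is altered when |posterior mean| >= z * posterior SD.
    The list is sorted by |z| descending; a regulator-class annotation
    (sigma / global / local) is attached when supplied.
    """
    z = posterior.z_threshold if z_threshold is None else z_threshold
    t = posterior.table.copy()
    t["altered"] = np.abs(t["zscore"]) >= z
    out = t[t["altered"]].copy()
    out = out.iloc[np.argsort(-np.abs(out["zscore"].to_numpy()), kind="stable")]
    if annotation is not None:
        out["class"] = [annotation.get(tf, "") for tf in out.index]
    return out


def build_regulator_network(
    differential_result,
    connectivity: ConnectivityMatrix,
    altered: pd.DataFrame,
) -> pd.DataFrame:
    """Edges linking altered regulators to their significant targets.

    Returns a table (regulator, protein, protein_direction,
    regulator_direction); a protein regulated by several altered
    regulators contributes one edge per regulator.
    """
    sig = differential_result.table[differential_result.table["significant"]]
    sig_dir = {
        str(p).upper(): ("up" if d >= 0 else "down")
        for p, d in sig["log2_diff"].items()
    }
    rows = []
    for tf in altered.index:
        if tf not in connectivity.edges.columns:
            continue
        reg_dir = "up" if altered.loc[tf, "post_mean"] >= 0 else "down"
        targets = connectivity.edges.index[connectivity.edges[tf] == 1]
        for g in targets:
            if g in sig_dir:
                rows.append((tf, g, sig_dir[g], reg_dir))
    return pd.DataFrame(
        rows, columns=["regulator", "protein", "protein_direction", "regulator_direction"]
    )
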