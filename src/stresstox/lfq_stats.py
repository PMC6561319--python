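"""Label-free quantitative proteomics statistics.

The workflow implemented here is the standard Perseus-style analysis of a
two-group LFQ experiment: keep proteins with at least ``min_valid`` valid
intensities in at least one group, log2-transform, median-centre, impute
left-censored missing values from a downshifted normal distribution, and
test each protein with an S0-moderated two-sample statistic whose null
distribution is obtained by permuting group labels.  Fold changes are
computed from the imputed, normalized group means.

All operations take and return :class:`IntensityMatrix`; nothing mutates
its input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "TestConfig",
    "ImputeConfig",
    "DifferentialResult",
    "read_protein_groups",
    "read_design",
    "assign_groups",
    "write_protein_groups",
    "filter_min_valid",
    "log2_transform",
    "normalize_median",
    "impute_downshifted_normal",
    "s0_permutation_test",
    "compute_fold_changes",
    "volcano_table",
    "cog_summary",
]

DEFAULT_ID_COLUMN = "Protein IDs"
DEFAULT_LFQ_PREFIX = "LFQ intensity "


@dataclass(frozen=True)
class IntensityMatrix:
    """Protein-by-sample intensity matrix with a two-group design.

    ``values`` is proteins x samples with ``NaN`` marking missing
    observations (zeros in the raw table are mapped to missing at read
    time).  ``group_of`` maps each sample to one of exactly two groups
    once a design is attached.  ``imputed_mask`` flags cells filled in by
    :func:`impute_downshifted_normal`.
    """

    values: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)
    log2_applied: bool = False
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein identifiers: {dupes}")
        if not self.log2_applied:
            finite = vals.to_numpy(dtype=float)
            if np.any(finite[np.isfinite(finite)] < 0):
                raise ValueError("negative intensities are not a valid LFQ value")
        if self.group_of:
            unknown = set(self.group_of) - set(vals.columns)
            if unknown:
                raise ValueError(f"design references unknown samples: {sorted(unknown)}")
            missing = set(vals.columns) - set(self.group_of)
            if missing:
                raise ValueError(f"samples without a group assignment: {sorted(missing)}")
            if len(set(self.group_of.values())) != 2:
                raise ValueError("exactly two groups are required")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, sorted; by convention (control, treated)."""
        labels = sorted(set(self.group_of.values()))
        if len(labels) != 2:
            raise ValueError("no two-group design attached")
        return labels[0], labels[1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of.get(s) == group]

    def n_valid(self, group: str) -> pd.Series:
        """Per-protein count of observed (non-missing) values in *group*."""
        return self.values[self.samples_in(group)].notna().sum(axis=1)


@dataclass(frozen=True)
class TestConfig:
    """Settings for the moderated permutation test.

    s0 damps the significance of small-difference, low-variance proteins
    by inflating the denominator of the t-like statistic; the defaults
    (s0=1, FDR 0.05, min_valid 3) are the conventional Perseus settings
    for a 4-vs-4 label-free design.
    """

    s0: float = 1.0
    fdr: float = 0.05
    n_permutations: int | str = "exact"
    seed: int = 0
    min_valid: int = 3

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.min_valid < 1:
            raise ValueError("min_valid must be at least 1")
        if self.n_permutations != "exact" and int(self.n_permutations) < 1:
            raise ValueError("n_permutations must be 'exact' or a positive count")


@dataclass(frozen=True)
class ImputeConfig:
    """Downshifted-normal imputation parameters, in per-sample SD units."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.downshift < 0:
            raise ValueError("downshift must be non-negative")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein test output.

    ``table`` columns: mean_ctrl, mean_trt, log2_diff, d_stat, p_perm,
    q_value, significant, and (after :func:`compute_fold_changes`)
    fold_change / direction.  ``control`` and ``treated`` record the
    contrast orientation (log2_diff = treated - control).
    """

    table: pd.DataFrame
    control: str
    treated: str
    fdr: float
    s0: float
    n_permutations: int
    exact: bool


# ---------------------------------------------------------------------------
# I/O


def read_protein_groups(
    path,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
) -> IntensityMatrix:
    """Read a MaxQuant-dialect proteinGroups table.

    Sample columns are those whose header starts with *lfq_prefix*; the
    prefix is stripped to obtain sample names.  Zeros and blanks denote
    missing values and become NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"identifier column {id_column!r} not found in {path}")
    lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
    if len(lfq_cols) < 2:
        raise ValueError(
            f"fewer than 2 sample columns with prefix {lfq_prefix!r} in {path}"
        )
    values = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    values = values.mask(values == 0)  # zeros are missing by LFQ convention
    values.index = pd.Index(df[id_column], name=id_column)
    values.columns = [c[len(lfq_prefix):] for c in lfq_cols]
    return IntensityMatrix(values=values)


def write_protein_groups(
    matrix: IntensityMatrix,
    path,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
) -> None:
    """Write the matrix back out in the dialect read_protein_groups expects.

    Missing values are written as 0 (the on-disk convention), so a
    write -> read round trip is lossless for non-transformed data.
    """
    out = matrix.values.copy()
    out.columns = [lfq_prefix + c for c in out.columns]
    out = out.fillna(0)
    out.insert(0, id_column, matrix.protein_ids)
    out.to_csv(path, sep="\t", index=False)


def read_design(path) -> dict[str, str]:
    """Read a two-column TSV (sample, group) into a sample->group map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"design file {path} needs columns (sample, group)")
    sample_col, group_col = df.columns[0], df.columns[1]
    return dict(zip(df[sample_col], df[group_col]))


def assign_groups(matrix: IntensityMatrix, group_of: dict[str, str]) -> IntensityMatrix:
    return replace(matrix, group_of=dict(group_of))


# ---------------------------------------------------------------------------
# Filtering / transformation


def filter_min_valid(matrix: IntensityMatrix, min_valid: int = 3) -> IntensityMatrix:
    """Keep proteins with >= min_valid observed values in at least one group."""
    a, b = matrix.groups
    n_a, n_b = len(matrix.samples_in(a)), len(matrix.samples_in(b))
    if min_valid > n_a and min_valid > n_b:
        raise ValueError(
            f"min_valid={min_valid} exceeds the replicate count in both groups "
            f"({a}: {n_a}, {b}: {n_b})"
        )
    keep = (matrix.n_valid(a) >= min_valid) | (matrix.n_valid(b) >= min_valid)
    out = replace(matrix, values=matrix.values.loc[keep])
    if matrix.imputed_mask is not None:
        out = replace(out, imputed_mask=matrix.imputed_mask.loc[keep])
    return out


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    if matrix.log2_applied:
        raise ValueError("matrix is already log2-transformed")
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.isfinite(vals) & (vals <= 0)
    if bad.any():
        raise ValueError(
            "non-positive finite intensities present; zeros must be mapped to "
            "missing at read time"
        )
    return replace(
        matrix,
        values=np.log2(matrix.values),
        log2_applied=True,
    )


def normalize_median(matrix: IntensityMatrix, mode: str = "sample") -> IntensityMatrix:
    """Median-centre log2 intensities.

    mode="sample" subtracts each sample's median of observed values;
    mode="group" subtracts, from every sample of a group, the pooled
    median of that group's observed values.
    """
    if not matrix.log2_applied:
        raise ValueError("normalize_median expects log2-transformed data")
    vals = matrix.values
    if mode == "sample":
        medians = vals.median(axis=0, skipna=True)
        if medians.isna().any():
            empty = medians.index[medians.isna()].tolist()
            raise ValueError(f"samples with no observed values: {empty}")
        centred = vals.sub(medians, axis=1)
    elif mode == "group":
        centred = vals.copy()
        for g in matrix.groups:
            cols = matrix.samples_in(g)
            pooled = vals[cols].to_numpy().ravel()
            pooled = pooled[np.isfinite(pooled)]
            if pooled.size == 0:
                raise ValueError(f"group {g!r} has no observed values")
            centred[cols] = vals[cols] - np.median(pooled)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(matrix, values=centred)


def impute_downshifted_normal(
    matrix: IntensityMatrix, config: ImputeConfig = ImputeConfig()
) -> IntensityMatrix:
    """Fill missing values from a per-sample downshifted normal.

    For each sample with observed mean m and SD s, missing cells are
    drawn i.i.d. from N(m - downshift*s, (width*s)^2) — the conventional
    model for left-censored label-free missingness, which places imputed
    values in the low-intensity tail.
    """
    if not matrix.log2_applied:
        raise ValueError("imputation expects log2-transformed data")
    rng = np.random.default_rng(config.seed)
    vals = matrix.values.copy()
    mask = vals.isna()
    for sample in vals.columns:
        col = vals[sample]
        observed = col.dropna()
        missing_idx = col.index[col.isna()]
        if len(missing_idx) == 0:
            continue
        if len(observed) < 2:
            raise ValueError(
                f"sample {sample!r} has fewer than 2 observed values; "
                "downshifted-normal parameters are undefined"
            )
        m, s = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(m - config.downshift * s, config.width * s, len(missing_idx))
        vals.loc[missing_idx, sample] = draws
    return replace(matrix, values=vals, imputed_mask=mask)


# ---------------------------------------------------------------------------
# Testing


def _group_stats(x: np.ndarray, treated_cols: np.ndarray, control_cols: np.ndarray):
    """Mean difference and pooled-SE denominator for one label assignment."""
    xt, xc = x[:, treated_cols], x[:, control_cols]
    n_t, n_c = xt.shape[1], xc.shape[1]
    diff = xt.mean(axis=1) - xc.mean(axis=1)
    var_t = xt.var(axis=1, ddof=1)
    var_c = xc.var(axis=1, ddof=1)
    sp2 = ((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2)
    se = np.sqrt(sp2 * (1.0 / n_t + 1.0 / n_c))
    return diff, se


def s0_permutation_test(
    matrix: IntensityMatrix,
    config: TestConfig = TestConfig(),
    control: str | None = None,
    treated: str | None = None,
) -> DifferentialResult:
    """S0-moderated two-sample test with permutation FDR.

    The statistic is d_i = (mean_treated - mean_control) / (se_i + s0)
    with se_i the pooled two-sample standard error.  The null is formed
    by re-assigning group labels: every distinct assignment is
    enumerated when there are at most 10,000 (a 4-vs-4 design gives 70,
    making the test fully deterministic), otherwise ``n_permutations``
    random assignments are drawn with ``seed``.  Permuted |d*| values
    are pooled across proteins; the q-value of protein i is the mean
    permuted count of |d*| >= |d_i| divided by the observed count of
    |d| >= |d_i|, clipped to 1 and monotonized from least to most
    significant.  Ties in |d| are broken by protein identifier so the
    ranking is deterministic.
    """
    if matrix.values.isna().any().any():
        raise ValueError("run imputation first: matrix still contains missing values")
    g_ctrl, g_trt = matrix.groups
    if control is None and treated is None:
        control, treated = g_ctrl, g_trt
    elif {control, treated} != {g_ctrl, g_trt}:
        raise ValueError(f"contrast ({control}, {treated}) does not match design groups")

    x = matrix.values.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(
            "degenerate input: all intensities identical (constant-everywhere "
            "matrix), the test statistic is undefined"
        )
    samples = list(matrix.values.columns)
    treated_cols = np.array([samples.index(s) for s in matrix.samples_in(treated)])
    control_cols = np.array([samples.index(s) for s in matrix.samples_in(control)])
    n_t = len(treated_cols)
    n = n_t + len(control_cols)

    diff, se = _group_stats(x, treated_cols, control_cols)
    d_obs = diff / (se + config.s0)
    abs_d = np.abs(d_obs)

    from math import comb

    n_exact = comb(n, n_t)
    exact = config.n_permutations == "exact" or n_exact <= 10_000
    if exact:
        assignments = [
            np.array(c) for c in itertools.combinations(range(n), n_t)
        ]
    else:
        rng = np.random.default_rng(config.seed)
        assignments = [
            rng.permutation(n)[:n_t] for _ in range(int(config.n_permutations))
        ]
    n_perm = len(assignments)

    all_cols = np.arange(n)
    perm_abs = np.empty((n_perm, x.shape[0]))
    for k, t_cols in enumerate(assignments):
        c_cols = np.setdiff1d(all_cols, t_cols)
        pdiff, pse = _group_stats(x, t_cols, c_cols)
        perm_abs[k] = np.abs(pdiff / (pse + config.s0))

    pooled = np.sort(perm_abs.ravel())
    # counts of pooled null values >= threshold, and of observed |d| >= threshold
    null_ge = pooled.size - np.searchsorted(pooled, abs_d, side="left")
    p_perm = null_ge / pooled.size

    ids = np.array(matrix.protein_ids)
    # rank 1 = most significant; ties in |d| broken lexically by protein id
    order = np.lexsort((ids, -abs_d))
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)

    q_raw = np.minimum((null_ge / n_perm) / rank, 1.0)
    # monotonize: walking from least to most significant, q may only shrink
    q = q_raw.copy()
    running = np.inf
    for i in order[::-1]:
        running = min(running, q[i])
        q[i] = running

    table = pd.DataFrame(
        {
            "mean_ctrl": x[:, control_cols].mean(axis=1),
            "mean_trt": x[:, treated_cols].mean(axis=1),
            "log2_diff": diff,
            "d_stat": d_obs,
            "p_perm": p_perm,
            "q_value": q,
            "significant": q <= config.fdr,
        },
        index=matrix.values.index,
    )
    return DifferentialResult(
        table=table,
        control=control,
        treated=treated,
        fdr=config.fdr,
        s0=config.s0,
        n_permutations=n_perm,
        exact=exact,
    )


def compute_fold_changes(result: DifferentialResult) -> DifferentialResult:
    """Attach linear fold changes (treated/control) to a test result.

    fold_change = 2^|log2_diff| with the direction recorded separately,
    matching the fold-increase / fold-decrease presentation of printed
    abundance tables.  Group means already include imputed values.
    """
    table = result.table.copy()
    log2_diff = table["log2_diff"].to_numpy()
    table["fold_change"] = 2.0 ** np.abs(log2_diff)
    table["direction"] = np.where(log2_diff >= 0, "increase", "decrease")
    return replace(result, table=table)


def volcano_table(result: DifferentialResult) -> pd.DataFrame:
    """(log2 difference, -log10 p, significance) rows for a volcano plot."""
    t = result.table
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(t["p_perm"].to_numpy())
    return pd.DataFrame(
        {
            "log2_diff": t["log2_diff"],
            "neg_log10_p": neg_log_p,
            "significant": t["significant"],
        },
        index=t.index,
    )


UNASSIGNED = "unassigned"


def cog_summary(
    result: DifferentialResult, annotation: dict[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Count significant up/down proteins per functional category.

    *annotation* maps protein id -> COG category code; proteins without
    an entry are tallied under the reserved "unassigned" bucket.
    """
    if annotation is None:
        annotation = {}
    elif isinstance(annotation, pd.Series):
        annotation = annotation.to_dict()
    t = result.table
    sig = t[t["significant"]]
    counts: dict[str, list[int]] = {}
    for pid, row in sig.iterrows():
        cat = annotation.get(pid, UNASSIGNED)
        up_down = counts.setdefault(cat, [0, 0])
        if row["log2_diff"] >= 0:
            up_down[0] += 1
        else:
            up_down[1] += 1
    out = pd.DataFrame.from_dict(counts, orient="index", columns=["n_up", "n_down"])
    out.index.name = "category"
    return out.sort_index()
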