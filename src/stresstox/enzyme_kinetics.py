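"""Michaelis-Menten kinetics from spectrophotometric assays.

Covers the rate computation from absorbance slopes (with stoichiometric
co-chromophore correction, as needed when the substrate and the redox
reporter absorb at the same wavelength), unweighted nonlinear
least-squares fitting of v = Vmax*S/(Km+S), derivation of kcat and
catalytic efficiency kcat/Km, and jackknife (leave-one-out) error
propagation for the efficiency — which accounts for kcat and Km being
estimated from the same data and hence correlated.

Units: substrate in mM (or uM with a tag), rates in nmol/min/mg or
umol/min/mg, kcat in 1/min, efficiency in 1/(min*mM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AssaySpec",
    "KineticsDataset",
    "MMFitResult",
    "rate_from_absorbance",
    "fit_michaelis_menten",
    "kcat_from_vmax",
    "catalytic_efficiency",
    "format_efficiency",
    "jackknife_efficiency_se",
]

_SUBSTRATE_TO_MM = {"mM": 1.0, "uM": 1e-3, "µM": 1e-3, "μM": 1e-3}
_RATE_TO_UMOL = {"umol/min/mg": 1.0, "µmol/min/mg": 1.0, "μmol/min/mg": 1.0,
                 "nmol/min/mg": 1e-3}


@dataclass(frozen=True)
class AssaySpec:
    """Spectrophotometric assay constants.

    Extinction coefficients are in M^-1 cm^-1 as printed in methods
    sections; they are converted to mM^-1 cm^-1 internally.  A non-zero
    ``epsilon_cochromophore`` models 1:1 stoichiometric co-depletion of
    a second absorbing species (e.g. the substrate aldehyde consumed
    together with NADPH at 340 nm).
    """

    epsilon_reporter: float
    epsilon_cochromophore: float = 0.0
    path_length_cm: float = 1.0
    protein_mass_mg: float | None = None
    assay_volume_ml: float = 1.0
    enzyme_mw: float | None = None  # g/mol, needed for kcat

    def __post_init__(self) -> None:
        if self.epsilon_reporter < 0 or self.epsilon_cochromophore < 0:
            raise ValueError("extinction coefficients must be non-negative")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")


@dataclass(frozen=True)
class KineticsDataset:
    """(substrate, rate) observations from initial-rate assays."""

    substrate: np.ndarray  # concentrations
    rate: np.ndarray
    substrate_unit: str = "mM"
    rate_unit: str = "nmol/min/mg"
    baseline_corrected: bool = True

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "substrate", s)
        object.__setattr__(self, "rate", v)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("substrate and rate must be 1-D arrays of equal length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if self.substrate_unit not in _SUBSTRATE_TO_MM:
            raise ValueError(f"unknown substrate unit {self.substrate_unit!r}")
        if self.rate_unit not in _RATE_TO_UMOL:
            raise ValueError(f"unknown rate unit {self.rate_unit!r}")

    @property
    def n(self) -> int:
        return len(self.substrate)

    def substrate_mM(self) -> np.ndarray:
        return self.substrate * _SUBSTRATE_TO_MM[self.substrate_unit]

    def drop(self, i: int) -> "KineticsDataset":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return KineticsDataset(
            self.substrate[keep], self.rate[keep],
            self.substrate_unit, self.rate_unit, self.baseline_corrected,
        )


@dataclass(frozen=True)
class MMFitResult:
    km: float          # mM
    km_se: float
    vmax: float        # in the dataset's rate unit
    vmax_se: float
    rate_unit: str
    residuals: np.ndarray
    converged: bool
    kcat: float | None = None       # 1/min
    kcat_se: float | None = None
    efficiency: float | None = None  # 1/(min*mM)
    efficiency_se: float | None = None

    def with_kcat(self, enzyme_mw: float) -> "MMFitResult":
        """Derive kcat and kcat/Km given the enzyme molar mass (g/mol)."""
        kcat = kcat_from_vmax(self.vmax, enzyme_mw, self.rate_unit)
        scale = kcat / self.vmax if self.vmax else 0.0
        eff = catalytic_efficiency(kcat, self.km, "mM")
        return MMFitResult(
            km=self.km, km_se=self.km_se, vmax=self.vmax, vmax_se=self.vmax_se,
            rate_unit=self.rate_unit, residuals=self.residuals,
            converged=self.converged,
            kcat=kcat, kcat_se=self.vmax_se * scale, efficiency=eff,
            efficiency_se=None,
        )


def rate_from_absorbance(slope_au_per_min: float, spec: AssaySpec):
    """Convert an absorbance slope to a molar rate (mM/min).

    rate = |slope| / ((eps_reporter + eps_cochromophore) * path), with
    extinction coefficients in mM^-1 cm^-1.  Summing the coefficients
    implements the correction for a species co-depleted 1:1 with the
    reporter: the observed slope is the sum of both contributions, so
    dividing by the summed coefficient recovers the reaction rate.

    Returns (rate_mM_per_min, specific_activity) where specific
    activity is in umol/min/mg when ``protein_mass_mg`` is set, else
    None.
    """
    if not np.isfinite(slope_au_per_min):
        raise ValueError("absorbance slope must be finite")
    eps_mM = (spec.epsilon_reporter + spec.epsilon_cochromophore) / 1000.0
    if eps_mM == 0:
        raise ValueError("at least one extinction coefficient must be non-zero")
    rate = abs(slope_au_per_min) / (eps_mM * spec.path_length_cm)
    specific = None
    if spec.protein_mass_mg is not None:
        # mM/min * mL = umol/min ; divide by mg protein
        specific = rate * spec.assay_volume_ml / spec.protein_mass_mg
    return rate, specific


def _mm(s: np.ndarray, km: float, vmax: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(data: KineticsDataset) -> MMFitResult:
    """Unweighted least-squares fit of the Michaelis-Menten curve.

    Parameters are optimised on the log scale (positivity is built in).
    Initial Vmax is the largest observed rate; initial Km is the
    substrate level where the rates first cross half of it.  Standard
    errors come from the curvature (Gauss-Newton Hessian) at the
    optimum with the usual residual-variance estimate.
    """
    s = data.substrate_mM()
    v = np.asarray(data.rate, dtype=float)
    if data.n < 5:
        raise ValueError("need at least 5 observations to fit")
    if np.unique(s).size < 2:
        raise ValueError("all substrate levels identical; the curve is unidentifiable")

    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates non-positive")
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    above = np.nonzero(v_sorted >= half)[0]
    km0 = float(s_sorted[above[0]]) if above.size else float(np.median(s_sorted))

    def resid(theta):
        km, vmax = np.exp(theta)
        return _mm(s, km, vmax) - v

    sol = least_squares(resid, x0=np.log([km0, vmax0]), method="lm", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    km, vmax = np.exp(sol.x)
    dof = max(data.n - 2, 1)
    sigma2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = sigma2 * np.linalg.inv(jtj)
        # delta method back from log parameters
        km_se = float(np.sqrt(cov_log[0, 0]) * km)
        vmax_se = float(np.sqrt(cov_log[1, 1]) * vmax)
    except np.linalg.LinAlgError:
        km_se = vmax_se = float("nan")
    return MMFitResult(
        km=float(km), km_se=km_se, vmax=float(vmax), vmax_se=vmax_se,
        rate_unit=data.rate_unit, residuals=sol.fun, converged=bool(sol.success),
    )


def kcat_from_vmax(vmax: float, enzyme_mw: float, rate_unit: str = "umol/min/mg") -> float:
    """Turnover number (1/min) from specific activity and molar mass.

    kcat = Vmax[umol/min/mg] * MW[g/mol] * 1e-3 (a dimensional identity:
    umol substrate per minute per mg enzyme, times g enzyme per mol,
    gives mol substrate per minute per mol enzyme).
    """
    if enzyme_mw is None or enzyme_mw <= 0:
        raise ValueError("a positive enzyme molar mass (g/mol) is required for kcat")
    vmax_umol = vmax * _RATE_TO_UMOL[rate_unit]
    return vmax_umol * enzyme_mw * 1e-3


def catalytic_efficiency(kcat: float, km: float, km_unit: str = "mM") -> float:
    """kcat/Km in 1/(min*mM); Km accepted in mM or uM."""
    km_mM = km * _SUBSTRATE_TO_MM[km_unit]
    if km_mM <= 0:
        raise ValueError("Km must be positive")
    return kcat / km_mM


def format_efficiency(value: float, style: str = "table") -> float:
    """Report kcat/Km the way kinetics tables print it.

    style="table": integer, truncated toward zero (how printed tables
    derived from full-precision kcat and Km come out); style="text":
    2 significant figures.
    """
    if style == "table":
        return float(np.trunc(value))
    if style == "text":
        if value == 0:
            return 0.0
        from math import floor, log10
        ndigits = 1 - int(floor(log10(abs(value))))
        return round(value, ndigits)
    raise ValueError(f"unknown style {style!r}")


def jackknife_efficiency_se(
    data: KineticsDataset, enzyme_mw: float
) -> tuple[float, float]:
    """Leave-one-out jackknife estimate and SE of kcat/Km.

    For each observation i the curve is refit without it and the
    efficiency theta_(-i) recomputed from the refit Km and Vmax;
    pseudo-values theta*_i = n*theta - (n-1)*theta_(-i) give the
    estimate mean(theta*) and SE sd(theta*)/sqrt(n).  The jackknife
    propagates the Km-Vmax correlation automatically because each
    pseudo-value carries a full refit.
    """
    n = data.n
    if n < 6:
        raise ValueError("need at least 6 points so each leave-one-out fit has 5")
    full = fit_michaelis_menten(data).with_kcat(enzyme_mw)
    theta = full.efficiency
    loo = []
    failures = 0
    for i in range(n):
        try:
            fit_i = fit_michaelis_menten(data.drop(i)).with_kcat(enzyme_mw)
            if not fit_i.converged:
                raise RuntimeError("leave-one-out fit did not converge")
            loo.append(fit_i.efficiency)
        except (RuntimeError, ValueError):
            failures += 1
    if failures > 0.2 * n:
        raise RuntimeError(
            f"{failures}/{n} leave-one-out fits failed; jackknife SE unreliable"
        )
    if failures:
        warnings.warn(f"{failures} leave-one-out fits excluded", stacklevel=2)
    loo = np.asarray(loo)
    m = len(loo)
    pseudo = n * theta - (n - 1) * loo
    estimate = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(m))
    return estimate, se
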