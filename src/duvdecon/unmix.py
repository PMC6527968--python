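"""Scalable linear-combination deconvolution of a target spectrum.

The target is modelled as a non-negative linear combination of the eight
component standards,

    I_fit = a*Adenine + c*Cytosine + g*Guanine + t*Thymine + u*Uracil
            + f*Phenylalanine + w*Tryptophan + y*Tyrosine,

fitted by least squares over the fingerprint channels.  Goodness of fit is
the unweighted sum of squared residuals (chi-squared) with
dof = n_channels - n_components.  Coefficient standard errors combine the
residual-variance-scaled covariance of the least-squares solution with the
propagated replicate standard deviation of the target, in quadrature.
Standard sets of increasing structural complexity are compared by ranking
their chi-squared; the unexplained residual is summarised as the integrated
absolute residual over the integrated target intensity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .spectra import RamanSpectrum, SpectrumError
from .standards import COMPONENTS, NUCLEIC_TIERS, StandardLibrary

__all__ = [
    "SpectralUnmixer",
    "UnmixResult",
    "fit_linear_combination",
    "compare_standard_sets",
    "coefficient_correlations",
    "residual_fraction",
    "report_fit",
    "render_report",
]


class SpectralUnmixer(RegressorMixin, BaseEstimator):
    """sklearn-style least-squares unmixer with known component spectra.

    ``fit(X, y)`` takes the design matrix ``X`` of shape
    ``(n_channels, n_components)`` — one column per component standard — and
    the target intensities ``y``.  With ``nonneg=True`` (default) the
    coefficients are bounded below by zero (physical scale factors);
    ``nonneg=False`` gives the closed-form ordinary least-squares solution.

    Fitted attributes
    -----------------
    coef_ : (n_components,) fitted scale factors
    stderr_ : combined standard errors (fit + propagated target sd)
    stderr_fit_, stderr_target_ : the two error terms, logged separately
    correlation_ : (p, p) coefficient-estimate correlation matrix
    chi2_ : unweighted sum of squared residuals
    dof_ : n_channels - n_components
    residual_ : y - X @ coef_
    rank_deficient_ : True when the component matrix is numerically singular
    """

    def __init__(self, nonneg: bool = True):
        self.nonneg = nonneg

    def fit(self, X, y, target_sd=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_channels, n_components)")
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError(f"y must have shape ({n},)")
        if n <= p:
            raise ValueError("need more channels than components (dof >= 1)")
        if not np.any(X):
            raise ValueError("component matrix is all-zero")

        rank = np.linalg.matrix_rank(X)
        self.rank_deficient_ = bool(rank < p)
        if self.rank_deficient_:
            warnings.warn(
                "rank-deficient component library: coefficient estimates are "
                "not separately identifiable", stacklevel=2)

        if self.nonneg:
            from scipy.optimize import nnls
            coef, _ = nnls(X, y)
        else:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.coef_ = coef
        self.residual_ = y - X @ coef
        self.chi2_ = float(self.residual_ @ self.residual_)
        self.dof_ = n - p
        s2 = self.chi2_ / self.dof_

        xtx_inv = np.linalg.pinv(X.T @ X)
        cov = s2 * xtx_inv
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.stderr_fit_ = d
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(d, d)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        self.correlation_ = corr

        if target_sd is not None:
            sd = np.asarray(target_sd, dtype=float)
            if sd.shape != (n,):
                raise ValueError(f"target_sd must have shape ({n},)")
            h = xtx_inv @ X.T  # coef = h @ y for the unconstrained problem
            cov_t = (h * sd**2) @ h.T
            self.stderr_target_ = np.sqrt(np.clip(np.diag(cov_t), 0.0, None))
        else:
            self.stderr_target_ = np.zeros(p)
        self.stderr_ = np.sqrt(self.stderr_fit_**2 + self.stderr_target_**2)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_


@dataclass
class UnmixResult:
    """Full deconvolution result for one target against one standard library."""

    tier: str
    coefficients: dict
    coefficient_se: dict
    coefficient_se_fit: dict
    coefficient_se_target: dict
    relative_intensity: dict
    relative_intensity_se: dict
    chi_squared: float
    reduced_chi_squared: float
    dof: int
    residual: RamanSpectrum
    target: RamanSpectrum
    correlation: np.ndarray
    components: tuple = COMPONENTS
    rank_deficient: bool = False
    pooled_groups: list = field(default_factory=list)

    def __post_init__(self):
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if self.chi_squared < 0:
            raise ValueError("chi_squared must be >= 0")

    def coefficient_array(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.components])


def fit_linear_combination(target: RamanSpectrum, library: StandardLibrary,
                           nonneg: bool = True,
                           target_sd=None) -> UnmixResult:
    """Fit the eight-component linear combination to a target spectrum.

    The target and every library spectrum must share one shift axis.  With
    ``nonneg`` off and a full-rank library the solution coincides with the
    closed-form normal-equations estimate.  ``target_sd`` (channelwise
    replicate standard deviation of the mean) feeds the propagated term of
    the coefficient uncertainties.
    """
    if not np.array_equal(target.shift, library.axis):
        raise SpectrumError("axis mismatch between target and standard library")
    X = library.design_matrix()
    est = SpectralUnmixer(nonneg=nonneg).fit(X, target.intensity,
                                             target_sd=target_sd)

    # absolute-value integrals: baseline-processed spectra oscillate around
    # zero, so the signed integral would understate every contribution
    target_integral = float(np.trapezoid(np.abs(target.intensity), target.shift))
    if target_integral == 0:
        raise SpectrumError("target integral is zero")
    comp_integrals = np.trapezoid(np.abs(X), target.shift, axis=0)
    rel = est.coef_ * comp_integrals / target_integral
    rel_se = est.stderr_ * np.abs(comp_integrals) / target_integral

    residual = target.copy(intensity=est.residual_,
                           label=f"{target.label}:residual")
    return UnmixResult(
        tier=library.tier,
        coefficients=dict(zip(COMPONENTS, map(float, est.coef_))),
        coefficient_se=dict(zip(COMPONENTS, map(float, est.stderr_))),
        coefficient_se_fit=dict(zip(COMPONENTS, map(float, est.stderr_fit_))),
        coefficient_se_target=dict(zip(COMPONENTS,
                                       map(float, est.stderr_target_))),
        relative_intensity=dict(zip(COMPONENTS, map(float, rel))),
        relative_intensity_se=dict(zip(COMPONENTS, map(float, rel_se))),
        chi_squared=est.chi2_,
        reduced_chi_squared=est.chi2_ / est.dof_,
        dof=est.dof_,
        residual=residual,
        target=target,
        correlation=est.correlation_,
        rank_deficient=est.rank_deficient_,
    )


def compare_standard_sets(target: RamanSpectrum, libraries,
                          nonneg: bool = True, target_sd=None):
    """Fit every library and rank by ascending chi-squared.

    Ties (within 1e-9 relative) are broken by fewer effective (nonzero)
    components, then by tier order nucleobase < dNTP < ssDNA_10mer.
    Returns a list of (tier, UnmixResult), best fit first.
    """
    libraries = list(libraries)
    if not libraries:
        raise ValueError("need at least one library")
    results = [(lib.tier, fit_linear_combination(target, lib, nonneg, target_sd))
               for lib in libraries]
    tier_rank = {t: i for i, t in enumerate(NUCLEIC_TIERS)}
    scale = max(r.chi_squared for _, r in results) or 1.0

    def key(item):
        tier, r = item
        chi2 = round(r.chi_squared / scale / 1e-9) * 1e-9  # quantize for ties
        n_eff = sum(1 for v in r.coefficients.values() if v > 0)
        return (chi2, n_eff, tier_rank.get(tier, len(tier_rank)))

    return sorted(results, key=key)


def coefficient_correlations(result: UnmixResult, threshold: float = 0.9):
    """Group components whose coefficient estimates are strongly correlated.

    Connected components of the |r| > threshold graph; groups of more than
    one member — e.g. the three aromatic amino acids sharing the ~1600 cm^-1
    ring stretch — are returned with a pooled coefficient (sum) and pooled
    relative intensity, and recorded on ``result.pooled_groups``.
    """
    comps = result.components
    p = len(comps)
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if abs(result.correlation[i, j]) > threshold:
                parent[find(i)] = find(j)
    clusters: dict = {}
    for i in range(p):
        clusters.setdefault(find(i), []).append(i)
    groups = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        names = [comps[i] for i in members]
        groups.append({
            "members": names,
            "pooled_coefficient": float(sum(result.coefficients[n] for n in names)),
            "pooled_relative_intensity": float(
                sum(result.relative_intensity[n] for n in names)),
        })
    groups.sort(key=lambda g: g["members"])
    result.pooled_groups = groups
    return groups


def residual_fraction(result: UnmixResult, lo: float = 800.0,
                      hi: float = 1800.0) -> float:
    """Unexplained intensity fraction: integral |residual| / integral target.

    Integrals are trapezoidal over the fingerprint window [lo, hi].  This is
    the statistic that quantifies how much of a cellular spectrum is *not*
    the sum of its molecular parts.
    """
    m = result.target.window_mask(lo, hi)
    if m.sum() < 2:
        raise SpectrumError("fingerprint window not covered by the fit axis")
    x = result.target.shift[m]
    denom = float(np.trapezoid(np.abs(result.target.intensity[m]), x))
    if denom == 0:
        raise SpectrumError("zero target integral")
    num = float(np.trapezoid(np.abs(result.residual.intensity[m]), x))
    return num / denom


def report_fit(result: UnmixResult) -> dict:
    """Machine-readable fit report: per-component rows plus fit statistics."""
    rows = []
    pooled_members = {m for g in result.pooled_groups for m in g["members"]}
    for c in result.components:
        rows.append({
            "component": c,
            "coefficient": result.coefficients[c],
            "coefficient_se": result.coefficient_se[c],
            "relative_intensity": result.relative_intensity[c],
            "relative_intensity_se": result.relative_intensity_se[c],
            "pooled": c in pooled_members,
        })
    return {
        "tier": result.tier,
        "chi_squared": result.chi_squared,
        "reduced_chi_squared": result.reduced_chi_squared,
        "dof": result.dof,
        "rank_deficient": result.rank_deficient,
        "residual_fraction": residual_fraction(
            result, result.target.shift[0], result.target.shift[-1]),
        "components": rows,
        "pooled_groups": result.pooled_groups,
    }


def render_report(result: UnmixResult) -> str:
    """Human-readable rendering of :func:`report_fit` (same numbers)."""
    rep = report_fit(result)
    lines = [
        f"Fit: {rep['tier']} standards   chi2 = {rep['chi_squared']:.4g} "
        f"(dof = {rep['dof']}, reduced = {rep['reduced_chi_squared']:.4g})",
        f"{'component':<14}{'rel. intensity':>16}{'coefficient':>16}",
    ]
    for row in rep["components"]:
        tag = " [pooled AAA]" if row["pooled"] else ""
        lines.append(
            f"{row['component']:<14}"
            f"{row['relative_intensity']:>9.3f} ± {row['relative_intensity_se']:.3f}"
            f"{row['coefficient']:>11.4f} ± {row['coefficient_se']:.4f}{tag}"
        )
    lines.append(f"residual fraction = {rep['residual_fraction']:.3f}")
    return "\n".join(lines)


def report_to_json(result: UnmixResult) -> str:
    return json.dumps(report_fit(result), indent=2)
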