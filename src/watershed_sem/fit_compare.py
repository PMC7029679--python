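"""Fit indices, information criteria, Akaike weights, and nested tests.

Conventions pinned for reproducibility:

* RMSEA confidence bounds come from root-finding on the noncentral
  chi-square distribution (90% interval: 0.95 / 0.05 tail probabilities);
* CFI uses the independence (free variances, zero covariances) baseline;
* SRMR is computed on correlation-metric residuals with the diagonal
  included;
* p-values use the central chi-square without robust scaling.

Verbal classification thresholds: good = RMSEA < 0.05, CFI > 0.97,
SRMR < 0.05; acceptable = RMSEA in [0.05, 0.08], CFI in [0.95, 0.97],
SRMR in [0.05, 0.10]; otherwise poor.  Boundaries are classified as
acceptable.  Overall rating is the worst of the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .estimation import DataInput, FitResult, fit
from .model_spec import Covariance, ModelSpec, ResidualVariance

__all__ = [
    "FitIndices",
    "ComparisonTable",
    "independence_model",
    "fit_baseline",
    "fit_indices",
    "information_criteria",
    "akaike_weights",
    "lrt_nested",
    "classify_fit",
]

# effect-size bands for standardized estimates (used in report prose)
EFFECT_BANDS = ((0.30, "large"), (0.20, "typical"), (0.10, "small"))


@dataclass
class FitIndices:
    chisq: float
    df: int
    p_value: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    cfi: float
    srmr: float
    aic: float
    bic: float
    n: int
    n_free: int
    rmsea_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "chisq": self.chisq, "df": self.df, "p_value": self.p_value,
            "rmsea": self.rmsea, "rmsea_ci": [self.rmsea_lo, self.rmsea_hi],
            "cfi": self.cfi, "srmr": self.srmr,
            "aic": self.aic, "bic": self.bic,
        }


def independence_model(names: Sequence[str]) -> ModelSpec:
    """Baseline model: free variances, all covariances fixed to zero."""
    names = tuple(names)
    covs = tuple(
        Covariance(a, b, 0.0, None)
        for i, a in enumerate(names) for b in names[i + 1:]
    )
    return ModelSpec(
        latents=(), manifests=names, loadings=(), regressions=(),
        covariances=covs,
        residual_variances=tuple(ResidualVariance(v, None, None) for v in names),
    )


def fit_baseline(data: DataInput, names: Sequence[str] | None = None) -> FitResult:
    names = tuple(names) if names is not None else data.names
    return fit(independence_model(names), data)


def _rmsea_ci(chisq: float, df: int, n: int, level: float = 0.90):
    """Invert the noncentral chi-square CDF in the noncentrality parameter."""
    alpha = (1.0 - level) / 2.0

    def bound(prob: float) -> float:
        # find lambda with P(X_{df,lambda} <= chisq) = prob
        if stats.chi2.cdf(chisq, df) <= prob:
            return 0.0
        lo, hi = 0.0, max(10.0, 2.0 * chisq)
        while stats.ncx2.cdf(chisq, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover
                break
        from scipy.optimize import brentq
        return brentq(lambda lam: stats.ncx2.cdf(chisq, df, lam) - prob, lo, hi,
                      xtol=1e-10)

    lam_lo = bound(1.0 - alpha)   # 0.95
    lam_hi = bound(alpha)         # 0.05
    denom = df * (n - 1)
    return (np.sqrt(lam_lo / denom), np.sqrt(lam_hi / denom))


def _srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    d = np.sqrt(np.diag(S))
    R_obs = S / np.outer(d, d)
    R_imp = Sigma / np.outer(d, d)
    resid = R_obs - R_imp
    iu = np.triu_indices_from(resid)  # diagonal included
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_indices(result: FitResult, baseline: FitResult,
                S: np.ndarray | None = None) -> FitIndices:
    """Absolute and comparative fit indices for one fitted model."""
    if tuple(baseline.data.names) != tuple(result.data.names) or baseline.n != result.n:
        raise ValueError("baseline must be fit to the same variables and data")
    chisq, df, n = result.chisq, result.df, result.n
    p_value = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0

    rmsea_undefined = df == 0
    if rmsea_undefined:
        rmsea, lo, hi = 0.0, 0.0, 0.0
    else:
        rmsea = float(np.sqrt(max(0.0, (chisq - df) / (df * (n - 1)))))
        lo, hi = _rmsea_ci(chisq, df, n)

    num = max(0.0, chisq - df)
    den = max(num, baseline.chisq - baseline.df, np.finfo(float).tiny)
    cfi = float(np.clip(1.0 - num / den, 0.0, 1.0))

    if S is None:
        S = result.sample_cov
    srmr = _srmr(S, result.implied())

    q = result.n_free
    aic = -2.0 * result.loglik + 2.0 * q
    bic = -2.0 * result.loglik + q * np.log(n)
    return FitIndices(chisq=chisq, df=df, p_value=p_value, rmsea=rmsea,
                      rmsea_lo=float(lo), rmsea_hi=float(hi), cfi=cfi,
                      srmr=srmr, aic=float(aic), bic=float(bic), n=n,
                      n_free=q, rmsea_undefined=rmsea_undefined)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ComparisonTable:
    names: tuple[str, ...]
    indices: dict[str, FitIndices]
    weights: dict[str, float]
    nested_tests: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "models": {k: self.indices[k].to_dict() for k in self.names},
            "akaike_weights": {k: self.weights[k] for k in self.names},
            "nested_tests": list(self.nested_tests),
        }

    def to_markdown(self) -> str:
        header = ("| Model | chi2 (df) | RMSEA [90% CI] | CFI | SRMR | AIC | BIC "
                  "| AIC weight |")
        rule = "|" + "---|" * 8
        rows = []
        for k in self.names:
            ix = self.indices[k]
            rows.append(
                f"| {k} | {ix.chisq:.2f} ({ix.df}) "
                f"| {ix.rmsea:.3f} [{ix.rmsea_lo:.3f}-{ix.rmsea_hi:.3f}] "
                f"| {ix.cfi:.3f} | {ix.srmr:.3f} | {ix.aic:.2f} | {ix.bic:.2f} "
                f"| {100 * self.weights[k]:.2f}% |"
            )
        return "\n".join([header, rule, *rows])


def information_criteria(fits: Mapping[str, FitResult],
                         baselines: Mapping[str, FitResult] | None = None
                         ) -> ComparisonTable:
    """AIC/BIC and Akaike weights across models fit to identical data."""
    if not fits:
        raise ValueError("empty model list")
    items = list(fits.items())
    n0 = items[0][1].n
    for name, f in items:
        if f.n != n0:
            raise ValueError(f"model {name!r} fit to different data (n mismatch)")
    indices: dict[str, FitIndices] = {}
    for name, f in items:
        if baselines is not None and name in baselines:
            base = baselines[name]
        else:
            base = fit_baseline(f.data)
        indices[name] = fit_indices(f, base)
    aics = [indices[name].aic for name, _ in items]
    w = akaike_weights(aics)
    return ComparisonTable(
        names=tuple(name for name, _ in items),
        indices=indices,
        weights={name: float(w[k]) for k, (name, _) in enumerate(items)},
    )


def lrt_nested(restricted: FitResult, full: FitResult,
               tol: float = 1e-4) -> tuple[float, int, float]:
    """Chi-square difference test of a restricted against a full model."""
    if tuple(restricted.data.names) != tuple(full.data.names) \
            or restricted.n != full.n:
        raise ValueError("models fit to different data; not comparable")
    ddf = restricted.df - full.df
    if ddf < 0:
        raise ValueError("restricted model has fewer df than full model; not nested")
    dchisq = restricted.chisq - full.chisq
    if dchisq < -tol * max(1.0, abs(full.chisq)):
        raise ValueError(
            f"restricted model fits better (delta chi2 = {dchisq:.4g}); "
            "models are not nested or a fit did not converge"
        )
    dchisq = max(0.0, dchisq)
    p = float(stats.chi2.sf(dchisq, ddf)) if ddf > 0 else 1.0
    return float(dchisq), int(ddf), p


def _classify_rmsea(x: float) -> str:
    if x < 0.05:
        return "good"
    if x <= 0.08:
        return "acceptable"
    return "poor"


def _classify_cfi(x: float) -> str:
    if x > 0.97:
        return "good"
    if x >= 0.95:
        return "acceptable"
    return "poor"


def _classify_srmr(x: float) -> str:
    if x < 0.05:
        return "good"
    if x <= 0.10:
        return "acceptable"
    return "poor"


_ORDER = {"good": 0, "acceptable": 1, "poor": 2}


def classify_fit(ix: FitIndices) -> dict[str, str]:
    """Threshold classification per index; overall = worst of the three."""
    out = {
        "rmsea": _classify_rmsea(ix.rmsea),
        "cfi": _classify_cfi(ix.cfi),
        "srmr": _classify_srmr(ix.srmr),
    }
    out["overall"] = max(out.values(), key=lambda v: _ORDER[v])
    return out


def effect_band(std_estimate: float) -> str:
    """Verbal effect-size band for a standardized estimate."""
    a = abs(std_estimate)
    for cut, label in EFFECT_BANDS:
        if a > cut:
            return label
    return "negligible"
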