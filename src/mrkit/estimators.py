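"""Causal-effect estimators for two-sample Mendelian randomisation.

All estimators consume a harmonised instrument set — per variant j, the
exposure effect β_Xj (SE σ_Xj) and the outcome effect β_Yj (SE σ_Yj), both
on the same effect allele — and return an estimate of the causal effect θ
of the exposure on the outcome, on the outcome's log-odds scale per unit
exposure.

Three complementary methods are provided:

* **IVW** — the inverse-variance weighted mean of per-variant Wald ratios
  θ_j = β_Yj/β_Xj with weights w_j = 1/se(θ_j)²; algebraically identical to
  a weighted regression of β_Y on β_X through the origin with weights
  1/σ_Yj².  Efficient when every instrument is valid.
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept.  Under the InSIDE assumption the slope remains a consistent
  causal estimate in the presence of directional pleiotropy, and the
  intercept estimates the average pleiotropic effect; its z-test is the
  standard pleiotropy diagnostic.
* **Simple median** — the unweighted median of the Wald ratios, consistent
  when more than half the instruments are valid; its SE comes from a
  parametric bootstrap that redraws both effect columns from their
  sampling distributions.

Standard errors are reported either under a fixed-effect model or (default
throughout the pipeline) a multiplicative random-effects model that inflates
SEs by max(1, sqrt(Q/df)) to absorb heterogeneity.  P-values use the normal
reference, the convention for summary-data MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

MODELS = ("fixed", "random")

_P_FLOOR = 1e-300  # keep p-values strictly positive


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the method requires (2 for IVW, 3 otherwise)."""


class DegenerateDesignError(ValueError):
    """No variation in the exposure effects; regression slope undefined."""


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale, with its
    odds-ratio transform."""

    method: str  # ivw | egger | simple_median
    theta: float
    se: float
    pvalue: float
    or_point: float
    ci_low: float
    ci_high: float
    n_instruments: int
    model: str  # fixed | random


@dataclass
class HeterogeneityResult:
    """Cochran's Q across per-instrument ratios, df = J − 1."""

    q_stat: float
    df: int
    pvalue: float


@dataclass
class EggerResult:
    """Egger slope (causal estimate) plus intercept (average directional
    pleiotropy) and its z-test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    q_stat: float
    df: int


ArraysOrInstruments = Union[Sequence, tuple]


def _extract(instruments: ArraysOrInstruments):
    """Pull (β_X, σ_X, β_Y, σ_Y) arrays from harmonised instruments or from
    a 4-tuple of array-likes."""
    if (
        isinstance(instruments, tuple)
        and len(instruments) == 4
        and not hasattr(instruments[0], "beta_exposure")
    ):
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in instruments)
    else:
        seq = list(instruments)
        bx = np.array([i.beta_exposure for i in seq], dtype=float)
        sx = np.array([i.se_exposure for i in seq], dtype=float)
        by = np.array([i.beta_outcome for i in seq], dtype=float)
        sy = np.array([i.se_outcome for i in seq], dtype=float)
    if not (np.all(sx > 0) and np.all(sy > 0)):
        raise ValueError("all standard errors must be positive")
    return bx, sx, by, sy


def wald_ratio(beta_exposure, beta_outcome, se_outcome):
    """Per-variant causal estimate θ = β_Y/β_X with first-order delta-method
    SE σ_Y/|β_X| (exposure-side noise ignored).  Vectorised."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if np.any(bx == 0.0):
        raise ValueError("wald_ratio undefined for beta_exposure == 0")
    theta = by / bx
    se = sy / np.abs(bx)
    if theta.ndim == 0:
        return float(theta), float(se)
    return theta, se


def wald_ratio_exposure_aware(beta_exposure, se_exposure, beta_outcome, se_outcome):
    """Second-order delta-method ratio SE that propagates exposure-side
    noise: sqrt(σ_Y²/β_X² + β_Y²σ_X²/β_X⁴)."""
    bx = np.asarray(beta_exposure, dtype=float)
    sx = np.asarray(se_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if np.any(bx == 0.0):
        raise ValueError("wald_ratio undefined for beta_exposure == 0")
    theta = by / bx
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    if np.ndim(theta) == 0:
        return float(theta), float(se)
    return theta, se


def two_sided_p(theta: float, se: float) -> float:
    """Two-sided normal p-value, 2·(1 − Φ(|θ|/σ))."""
    if not se > 0:
        raise ValueError("se must be positive")
    return float(max(2.0 * stats.norm.sf(abs(theta) / se), _P_FLOOR))


def to_odds_ratio(theta: float, se: float, confidence: float = 0.95):
    """Exponentiate a log-odds estimate into (OR, CI low, CI high) at the
    requested confidence level (z = Φ⁻¹((1+c)/2), 1.959964 at 95%)."""
    if not se > 0:
        raise ValueError("se must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + confidence))
    return (
        float(np.exp(theta)),
        float(np.exp(theta - z * se)),
        float(np.exp(theta + z * se)),
    )


def _make_estimate(
    method: str, theta: float, se: float, n: int, model: str, confidence: float
) -> MREstimate:
    or_point, ci_low, ci_high = to_odds_ratio(theta, se, confidence)
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        pvalue=two_sided_p(theta, se),
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_instruments=int(n),
        model=model,
    )


def _check_model(model: str) -> None:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")


def ivw(
    instruments: ArraysOrInstruments,
    model: str = "random",
    confidence: float = 0.95,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance weighted causal estimate with Cochran's Q.

    θ̂ = Σ w_j θ_j / Σ w_j with θ_j = β_Yj/β_Xj and w_j = β_Xj²/σ_Yj².
    Fixed-effect SE is (Σ w_j)^{-1/2}; the multiplicative random-effects
    model scales it by max(1, sqrt(Q/(J−1))).
    """
    _check_model(model)
    bx, _, by, sy = _extract(instruments)
    j = bx.size
    if j < 2:
        raise InsufficientInstrumentsError(f"IVW requires >= 2 instruments, got {j}")
    theta_j, se_j = wald_ratio(bx, by, sy)
    w = 1.0 / se_j**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    q = float(np.sum(w * (theta_j - theta) ** 2))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if model == "random":
        se *= max(1.0, float(np.sqrt(q / (j - 1))))
    het = HeterogeneityResult(
        q_stat=q, df=j - 1, pvalue=float(stats.chi2.sf(q, j - 1))
    )
    return _make_estimate("ivw", theta, se, j, model, confidence), het


def egger(
    instruments: ArraysOrInstruments,
    model: str = "random",
    confidence: float = 0.95,
) -> EggerResult:
    """MR-Egger regression: weighted fit of β_Y on β_X with intercept.

    Instruments are first oriented so every β_X ≥ 0 (both betas negated
    where needed) because Egger regression is not invariant to allele
    recoding.  Weights are 1/σ_Y².  The intercept estimates average
    directional pleiotropy; under the random model both SEs are inflated by
    max(1, sqrt(Q_egger/(J−2))).
    """
    _check_model(model)
    bx, _, by, sy = _extract(instruments)
    j = bx.size
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {j}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = sign * bx
    y = sign * by
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("no variation in exposure effects")
    w = 1.0 / sy**2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = (float(v) for v in fit.params)
    # statsmodels scales SEs by the estimated residual scale Q/(J-2);
    # undo it for the fixed model, floor it at 1 for the random model
    scale = float(fit.scale)
    se_unscaled = np.asarray(fit.bse, dtype=float) / np.sqrt(scale)
    inflation = max(1.0, np.sqrt(scale)) if model == "random" else 1.0
    intercept_se, slope_se = (float(v) for v in se_unscaled * inflation)
    q = scale * (j - 2)
    return EggerResult(
        slope=_make_estimate("egger", slope, slope_se, j, model, confidence),
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_pvalue=two_sided_p(intercept, intercept_se),
        q_stat=float(q),
        df=j - 2,
    )


def simple_median(
    instruments: ArraysOrInstruments,
    n_boot: int = 10_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> MREstimate:
    """Simple-median causal estimate with parametric-bootstrap SE.

    The point estimate is the unweighted median of the per-variant Wald
    ratios (mean of the central two when J is even).  Each bootstrap
    resample redraws every β_X and β_Y from normal distributions centred on
    the observed values with their reported SEs and recomputes the median
    ratio; the SE is the standard deviation of those medians.  Fully
    reproducible for a given ``seed``.
    """
    bx, sx, by, sy = _extract(instruments)
    j = bx.size
    if j < 3:
        raise InsufficientInstrumentsError(
            f"simple median requires >= 3 instruments, got {j}"
        )
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} < 100 gives an unstable bootstrap SE", stacklevel=2
        )
    theta_j, _ = wald_ratio(bx, by, sy)
    theta = float(np.median(theta_j))
    rng = np.random.default_rng(seed)
    bx_draw = rng.normal(bx, sx, size=(n_boot, j))
    by_draw = rng.normal(by, sy, size=(n_boot, j))
    medians = np.median(by_draw / bx_draw, axis=1)
    se = float(np.std(medians, ddof=1))
    return _make_estimate("simple_median", theta, se, j, "fixed", confidence)
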