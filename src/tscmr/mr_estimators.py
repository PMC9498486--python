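"""Per-SNP Wald ratios and pooled two-sample MR estimators.

Implements the standard summary-data MR toolkit: the Wald ratio
(variant-outcome association divided by variant-exposure association),
fixed-effect inverse-variance-weighted (IVW) pooling, MR-Egger
regression, the weighted median and weighted mode (the latter three
retain consistency under progressively weaker instrument-validity
assumptions), plus Cochran's Q heterogeneity test and the per-variant
F-statistic for instrument strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._errors import InputError

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...

WALD = "wald"
IVW = "ivw"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
WEIGHTED_MODE = "weighted_mode"


@dataclass(frozen=True)
class RatioInput:
    """Variant-exposure and variant-outcome associations for one SNP.

    ``b_gy`` may be a crude or a TSCMR-adjusted variant-outcome
    association; both sides must refer to the same effect allele.
    """

    b_gx: float
    se_gx: float
    b_gy: float
    se_gy: float
    snp_id: str = ""

    def __post_init__(self) -> None:
        if not (self.se_gx > 0 and self.se_gy > 0):
            raise InputError("standard errors must be positive")


@dataclass(frozen=True)
class MREstimate:
    """Pooled (or single-SNP) causal-effect estimate with a 95% normal CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     intercept: float | None = None,
                     intercept_se: float | None = None) -> "MREstimate":
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z_95 * se),
            ci_high=float(beta + Z_95 * se),
            n_snps=n_snps,
            intercept=intercept,
            intercept_se=intercept_se,
        )


def _arrays(rs: Sequence[RatioInput]):
    b_gx = np.array([r.b_gx for r in rs], dtype=float)
    se_gx = np.array([r.se_gx for r in rs], dtype=float)
    b_gy = np.array([r.b_gy for r in rs], dtype=float)
    se_gy = np.array([r.se_gy for r in rs], dtype=float)
    return b_gx, se_gx, b_gy, se_gy


def _ratios_weights(rs: Sequence[RatioInput]):
    """Per-SNP Wald ratios with first-order inverse-variance weights."""
    b_gx, _, b_gy, se_gy = _arrays(rs)
    if np.any(b_gx == 0):
        raise InputError("b_gx must be nonzero for ratio-based estimators")
    ratios = b_gy / b_gx
    weights = b_gx**2 / se_gy**2  # 1 / first-order ratio variance
    return ratios, weights


def wald_ratio(r: RatioInput, se_method: str = "first_order") -> MREstimate:
    """Single-SNP causal estimate b_gy / b_gx.

    ``first_order`` ignores uncertainty in the variant-exposure
    association (``se = se_gy/|b_gx|``); ``delta`` adds the second-order
    term and is never smaller.
    """
    if r.b_gx == 0:
        raise InputError(f"undefined Wald ratio: b_gx is zero for {r.snp_id or 'SNP'}")
    beta = r.b_gy / r.b_gx
    if se_method == "first_order":
        se = r.se_gy / abs(r.b_gx)
    elif se_method == "delta":
        se = np.sqrt(r.se_gy**2 / r.b_gx**2 + r.b_gy**2 * r.se_gx**2 / r.b_gx**4)
    else:
        raise InputError(f"unknown se_method {se_method!r}")
    return MREstimate.from_beta_se(WALD, beta, se, 1)


def ivw(rs: Sequence[RatioInput]) -> MREstimate:
    """Fixed-effect inverse-variance-weighted mean of per-SNP Wald ratios.

    Algebraically identical to a zero-intercept regression of b_gy on
    b_gx weighted by 1/se_gy^2.
    """
    if len(rs) < 2:
        raise InputError("IVW requires at least 2 SNPs; use wald_ratio for one")
    ratios, weights = _ratios_weights(rs)
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))
    return MREstimate.from_beta_se(IVW, beta, se, len(rs))


def egger(rs: Sequence[RatioInput]) -> MREstimate:
    """MR-Egger: weighted regression of b_gy on b_gx with an intercept.

    The slope estimates the causal effect; a nonzero intercept indicates
    directional pleiotropy.  Inputs are oriented internally so that all
    b_gx >= 0 (negating both members of a pair leaves the ratio
    unchanged).  SEs use the regression's estimated residual scale
    (multiplicative random-effects convention).
    """
    if len(rs) < 3:
        raise InputError("MR-Egger requires at least 3 SNPs")
    b_gx, _, b_gy, se_gy = _arrays(rs)
    sign = np.where(b_gx < 0, -1.0, 1.0)
    b_gx, b_gy = b_gx * sign, b_gy * sign
    if np.ptp(b_gx) == 0:
        raise InputError("MR-Egger is undefined when all |b_gx| are identical")
    X = np.column_stack([np.ones_like(b_gx), b_gx])
    fit = sm.WLS(b_gy, X, weights=1.0 / se_gy**2).fit()
    # Residual scale never shrinks SEs below the fixed-effect value.
    scale = max(1.0, np.sqrt(fit.scale))
    se = fit.bse / np.sqrt(fit.scale) * scale
    return MREstimate.from_beta_se(
        EGGER, fit.params[1], se[1], len(rs),
        intercept=float(fit.params[0]), intercept_se=float(se[0]),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with S_j - w_j/2 cumulative-weight pivots."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    rs: Sequence[RatioInput], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios (inverse-variance weights).

    Consistent when instruments carrying at least half the weight are
    valid.  SE by seeded parametric bootstrap of the per-SNP inputs.
    """
    if len(rs) < 3:
        raise InputError("weighted median requires at least 3 SNPs")
    ratios, weights = _ratios_weights(rs)
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_point_se(rs, _weighted_median_point, n_boot, seed)
    return MREstimate.from_beta_se(WEIGHTED_MEDIAN, beta, se, len(rs))


def _mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    """Rule-of-thumb kernel bandwidth on a median-absolute-deviation scale."""
    mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
    return bandwidth_factor * 0.9 * mad * len(ratios) ** (-1 / 5)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float = 1.0
) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)
    if h == 0:  # all ratios (essentially) identical
        return float(np.median(ratios))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 10_000)
    dens = (weights[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    rs: Sequence[RatioInput],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the inverse-variance-weighted kernel density of Wald ratios.

    Consistent when the largest group of instruments sharing one ratio
    value is valid.  The normal-kernel bandwidth is ``bandwidth_factor``
    times a MAD-based rule of thumb; SE by seeded parametric bootstrap.
    """
    if len(rs) < 3:
        raise InputError("weighted mode requires at least 3 SNPs")
    if bandwidth_factor <= 0:
        raise InputError("bandwidth_factor must be positive")
    ratios, weights = _ratios_weights(rs)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = _bootstrap_point_se(
        rs, lambda r, w: _weighted_mode_point(r, w, bandwidth_factor), n_boot, seed
    )
    return MREstimate.from_beta_se(WEIGHTED_MODE, beta, se, len(rs))


def _bootstrap_point_se(rs, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: redraw each SNP's associations, re-estimate."""
    b_gx, se_gx, b_gy, se_gy = _arrays(rs)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        gx = rng.normal(b_gx, se_gx)
        gy = rng.normal(b_gy, se_gy)
        gx[gx == 0] = np.finfo(float).tiny  # measure-zero guard
        est[i] = point_fn(gy / gx, gx**2 / se_gy**2)
    return float(np.std(est, ddof=1))


def cochran_q(rs: Sequence[RatioInput]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the per-SNP Wald ratios.

    Q = sum_j w_j (ratio_j - ivw)^2 with first-order weights; under
    homogeneity Q ~ chi-square with n-1 degrees of freedom.  Used as a
    falsification test for horizontal pleiotropy.
    """
    if len(rs) < 2:
        raise InputError("Cochran's Q requires at least 2 SNPs")
    ratios, weights = _ratios_weights(rs)
    pooled = np.sum(weights * ratios) / np.sum(weights)
    q = float(np.sum(weights * (ratios - pooled) ** 2))
    df = len(rs) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def f_statistic(b_gx: float, se_gx: float) -> float:
    """Instrument-strength F-statistic: squared z-score of the variant-exposure association."""
    if not se_gx > 0:
        raise InputError("se_gx must be positive")
    return (b_gx / se_gx) ** 2


def estimate_all(
    rs: Sequence[RatioInput],
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
) -> list[MREstimate]:
    """Run every estimator the input size permits (Wald for 1 SNP, the
    pooled suite for 2+, Egger/median/mode for 3+)."""
    if len(rs) == 0:
        raise InputError("no ratio inputs")
    if len(rs) == 1:
        return [wald_ratio(rs[0])]
    out = [ivw(rs)]
    if len(rs) >= 3:
        out.append(egger(rs))
        out.append(weighted_median(rs, n_boot=n_boot, seed=seed))
        out.append(weighted_mode(rs, bandwidth_factor=bandwidth_factor,
                                 n_boot=n_boot, seed=seed))
    return out
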