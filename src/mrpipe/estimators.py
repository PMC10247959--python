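"""Summary-data MR estimators and sensitivity diagnostics.

Notation: for instrument *j*, ``bx_j``/``sx_j`` are the SNP-exposure
estimate and SE, ``by_j``/``sy_j`` the SNP-outcome estimate and SE, and
``ratio_j = by_j / bx_j`` the per-SNP Wald ratio. All estimators use
first-order weights that ignore the exposure sampling error, the
standard approximation when weak instruments are screened out upstream
(F > 10).

Implemented:

* :func:`wald_ratio` — single-instrument estimate with the first-order
  delta-method SE ``sy / |bx|``.
* :func:`ivw` — inverse-variance-weighted meta-analysis, equivalently a
  weighted regression of ``by`` on ``bx`` through the origin with
  weights ``1/sy^2``; the random-effects variant inflates the SE
  multiplicatively by ``max(1, sqrt(Q/df))``.
* :func:`cochran_q` — heterogeneity of the per-SNP ratios about a
  reference slope.
* :func:`weighted_median` — the ratio at the 50% point of the
  inverse-variance weight distribution, consistent while valid
  instruments hold a weight majority; SE by seeded parametric
  bootstrap.
* :func:`egger` — weighted regression with a free intercept; a nonzero
  intercept indicates directional pleiotropy (InSIDE assumed).
* :func:`radial_ivw` — the IVW regression in radial form; per-SNP
  contributions to Q are chi-square(1) under homogeneity and flag
  pleiotropic outliers.
* :func:`leave_one_out` / :func:`remove_outliers_and_reestimate` —
  influence and post-outlier re-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from mrpipe.sumstats import HarmonizedInstrument, pvalue_from_z

logger = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the outcome scale of ``beta``.

    For a binary outcome ``beta`` is a log odds ratio; ``odds_ratio``
    and its bounds are the exponentiated point estimate and 95% CI.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int) -> "MREstimate":
        if se <= 0:
            raise ValueError("se must be positive")
        ci_low = beta - _Z975 * se
        ci_high = beta + _Z975 * se
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            pvalue=pvalue_from_z(beta, se),
            odds_ratio=float(math.exp(beta)),
            or_ci_low=float(math.exp(ci_low)),
            or_ci_high=float(math.exp(ci_high)),
            n_snp=int(n_snp),
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass(frozen=True)
class RadialResult:
    estimate: MREstimate
    snp_ids: tuple[str, ...]
    q_contribution: tuple[float, ...]
    is_outlier: tuple[bool, ...]
    outlier_alpha: float

    @property
    def Q(self) -> float:
        return float(sum(self.q_contribution))

    @property
    def outlier_ids(self) -> tuple[str, ...]:
        return tuple(
            s for s, flag in zip(self.snp_ids, self.is_outlier) if flag
        )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exposure for h in instruments], dtype=float)
    sx = np.array([h.se_exposure for h in instruments], dtype=float)
    by = np.array([h.beta_outcome for h in instruments], dtype=float)
    sy = np.array([h.se_outcome for h in instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate ``by / bx``.

    The default SE is the first-order delta approximation ``sy/|bx|``;
    ``second_order=True`` adds the exposure-error term
    ``by^2 sx^2 / bx^4``.
    """
    if inst.beta_exposure == 0:
        raise ValueError(f"degenerate instrument {inst.snp_id}: beta_exposure is 0")
    beta = inst.beta_outcome / inst.beta_exposure
    var = (inst.se_outcome / inst.beta_exposure) ** 2
    if second_order:
        var += inst.beta_outcome**2 * inst.se_exposure**2 / inst.beta_exposure**4
    return MREstimate.from_beta_se("wald_ratio", beta, math.sqrt(var), 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "random",
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    Weighted regression of outcome on exposure effects through the
    origin with weights ``1/sy^2``. ``model='fixed'`` reports the
    fixed-effect SE ``(sum w bx^2)^{-1/2}``; ``model='random'`` applies
    multiplicative overdispersion, inflating the SE by
    ``max(1, sqrt(Q/df))``. A single instrument reduces to the Wald
    ratio with Q = 0 and df = 0.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    n = len(instruments)
    if n == 0:
        raise ValueError("ivw requires at least one instrument")
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("degenerate instrument with beta_exposure = 0")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    if df > 0:
        q_pvalue = float(max(stats.chi2.sf(Q, df), np.finfo(float).tiny))
        scale = max(1.0, math.sqrt(Q / df))
    else:
        Q, q_pvalue, scale = 0.0, 1.0, 1.0
    se = se_fixed * scale if model == "random" else se_fixed
    label = "ivw_re" if model == "random" else "ivw_fe"
    est = MREstimate.from_beta_se(label, beta, se, n)
    return est, HeterogeneityResult(Q=Q, df=df, pvalue=q_pvalue)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta_ref: float
) -> HeterogeneityResult:
    """Cochran's Q of the instruments about a supplied reference slope."""
    if len(instruments) < 2:
        raise ValueError("cochran_q requires at least two instruments")
    bx, _, by, sy = _arrays(instruments)
    w = 1.0 / sy**2
    Q = float(np.sum(w * (by - beta_ref * bx) ** 2))
    df = len(instruments) - 1
    return HeterogeneityResult(
        Q=Q, df=df, pvalue=float(max(stats.chi2.sf(Q, df), np.finfo(float).tiny))
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate with bootstrap SE.

    Wald ratios are ordered and the estimate interpolates the ratio at
    the 50% point of the cumulative inverse-variance weight
    distribution (weights ``bx^2/sy^2``). The estimate is consistent
    when instruments carrying at least half of the total weight are
    valid. The SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples of (bx, by) from normals at their
    reported SEs, with a fixed seed.
    """
    n = len(instruments)
    if n < 3:
        raise ValueError("weighted_median requires at least three instruments")
    bx, sx, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("degenerate instrument with beta_exposure = 0")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, n))
    by_star = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_star[b]
        # guard against pathological resamples crossing zero
        bxb = np.where(bxb == 0, np.finfo(float).eps, bxb)
        boots[b] = _weighted_median_point(by_star[b] / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se <= 0:  # degenerate only for exactly collinear noise-free input
        se = np.finfo(float).eps
    return MREstimate.from_beta_se("weighted_median", beta, se, n)


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Instruments are internally oriented so every ``bx >= 0`` (negating
    both betas of a SNP changes nothing scientifically); weights are
    ``1/sy^2``. Slope and intercept SEs carry the multiplicative
    overdispersion factor ``max(1, sqrt(Q'/(n-2)))`` where Q' is the
    weighted residual sum of squares. A two-sided normal p-value on the
    intercept tests for directional pleiotropy.
    """
    n = len(instruments)
    if n < 3:
        raise ValueError("egger requires at least three instruments")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    if np.allclose(x, x[0]):
        raise ValueError("singular design: no variance in exposure effects")
    w = 1.0 / sy**2

    sw = w.sum()
    swx = float(np.sum(w * x))
    swx2 = float(np.sum(w * x**2))
    swy = float(np.sum(w * y))
    swxy = float(np.sum(w * x * y))
    det = sw * swx2 - swx**2
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    Qp = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(Qp / (n - 2)))
    se_intercept = math.sqrt(swx2 / det) * scale
    se_slope = math.sqrt(sw / det) * scale

    return EggerResult(
        slope=MREstimate.from_beta_se("egger_slope", slope, se_slope, n),
        intercept=float(intercept),
        intercept_se=float(se_intercept),
        intercept_pvalue=pvalue_from_z(intercept, se_intercept),
    )


def radial_ivw(
    instruments: Sequence[HarmonizedInstrument],
    outlier_alpha: float = 0.05,
) -> RadialResult:
    """Radial (Galbraith) reformulation of IVW with per-SNP Q outlier test.

    With first-order weights ``w_j = bx_j^2/sy_j^2`` the regression of
    ``ratio_j * sqrt(w_j)`` on ``sqrt(w_j)`` through the origin has
    slope identical to the IVW estimate. Each SNP's contribution
    ``q_j = w_j (ratio_j - slope)^2`` is chi-square(1) under
    homogeneity; SNPs with upper-tail probability below
    ``outlier_alpha`` are flagged as pleiotropic outliers (no
    multiplicity correction by default; pass e.g. ``0.05/n`` for a
    Bonferroni version).
    """
    n = len(instruments)
    if n < 2:
        raise ValueError("radial_ivw requires at least two instruments")
    if not (0 < outlier_alpha < 1):
        raise ValueError("outlier_alpha must be in (0, 1)")
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("degenerate instrument with beta_exposure = 0")
    ratios = by / bx
    w = bx**2 / sy**2
    slope = float(np.sum(w * ratios) / np.sum(w))
    q = w * (ratios - slope) ** 2
    pvals = stats.chi2.sf(q, 1)
    flags = pvals < outlier_alpha
    Q = float(q.sum())
    df = n - 1
    scale = max(1.0, math.sqrt(Q / df)) if df > 0 else 1.0
    se = float(np.sum(w)) ** -0.5 * scale
    est = MREstimate.from_beta_se("ivw_radial", slope, se, n)
    return RadialResult(
        estimate=est,
        snp_ids=tuple(h.snp_id for h in instruments),
        q_contribution=tuple(float(v) for v in q),
        is_outlier=tuple(bool(f) for f in flags),
        outlier_alpha=float(outlier_alpha),
    )


def remove_outliers_and_reestimate(
    instruments: Sequence[HarmonizedInstrument],
    radial: RadialResult,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Drop radial-MR outliers and rerun random-effects IVW."""
    flagged = set(radial.outlier_ids)
    kept = [h for h in instruments if h.snp_id not in flagged]
    if not kept:
        raise ValueError("all instruments flagged as outliers")
    if flagged:
        logger.info("removed %d radial outlier(s): %s", len(flagged), sorted(flagged))
    return ivw(kept, model="random")


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
) -> list[tuple[str, MREstimate]]:
    """Random-effects IVW excluding each instrument in turn.

    Returns one (left-out snp_id, estimate) pair per instrument; a
    single influential or pleiotropic SNP shows up as the exclusion
    that moves the estimate furthest from the full-set value.
    """
    if len(instruments) < 3:
        raise ValueError("leave_one_out requires at least three instruments")
    results = []
    for i, h in enumerate(instruments):
        subset = [g for j, g in enumerate(instruments) if j != i]
        est, _ = ivw(subset, model="random")
        results.append((h.snp_id, est))
    return results
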