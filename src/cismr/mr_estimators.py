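"""Two-sample Mendelian randomization estimators.

All estimators consume harmonized exposure/outcome pairs and operate on the
per-variant Wald ratios θ_j = β_out,j / β_exp,j with first-order delta-method
standard errors se_j = se_out,j / |β_exp,j|. θ is a log-odds ratio of the
outcome per one SD change of the exposure (per SD *decrease* under this
package's orientation convention, so protective effects are negative).

Implemented:

* fixed-effect and multiplicative-random-effect inverse-variance weighting
  (IVW) with Cochran's Q heterogeneity;
* the weighted median, consistent when valid instruments carry more than half
  of the weight, with a parametric-bootstrap standard error;
* a contamination-mixture profile likelihood where each ratio is modeled as
  either valid, Normal(θ, se_j²), or invalid, Normal(0, se_j² + ψ²);
* MR-PRESSO: a simulation-based residual-sum-of-squares global pleiotropy
  test, per-variant outlier test, and distortion assessment;
* pharmacological scaling of an estimate to a drug's biomarker effect.

Two-sided p-values come from the normal distribution throughout, the usual
convention for summary-statistic MR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats_io import HarmonizedPair

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Single-variant Wald ratio with first-order SE."""

    rsid: str
    theta: float
    se: float


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds scale with 95% CI."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_pval: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.theta <= self.ci_high:
            raise ValueError("CI must bracket theta")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI bounds."""
    return (math.exp(estimate.theta), math.exp(estimate.ci_low), math.exp(estimate.ci_high))


def wald_ratio(pair: HarmonizedPair) -> RatioEstimate:
    """θ_j = β_out/β_exp with se_j = se_out/|β_exp| (first-order delta method)."""
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.rsid}: beta_exp is zero, ratio undefined")
    return RatioEstimate(
        rsid=pair.rsid,
        theta=pair.beta_out / pair.beta_exp,
        se=pair.se_out / abs(pair.beta_exp),
    )


def _ratios(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    est = [wald_ratio(p) for p in pairs]
    return (
        np.array([e.theta for e in est]),
        np.array([e.se for e in est]),
        [e.rsid for e in est],
    )


def cochran_q(ratios: Sequence[RatioEstimate], theta: float) -> tuple[float, float]:
    """Cochran's Q = Σ w_j (θ_j − θ)² with w_j = se_j⁻²; p from χ²(J−1)."""
    if len(ratios) < 2:
        raise ValueError("Cochran's Q needs at least 2 ratio estimates")
    th = np.array([r.theta for r in ratios])
    w = np.array([r.se for r in ratios]) ** -2.0
    q = float(np.sum(w * (th - theta) ** 2))
    pval = float(stats.chi2.sf(q, df=len(ratios) - 1))
    return q, pval


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ivw(
    pairs: Sequence[HarmonizedPair],
    model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance weighted meta-analysis of the Wald ratios.

    θ = Σ w_j θ_j / Σ w_j with w_j = se_j⁻²; the fixed-effect SE is
    (Σ w_j)^(−1/2). Under ``multiplicative_random`` (the default) the SE is
    inflated by sqrt(max(1, Q/(J−1))), so it never drops below the
    fixed-effect SE. Algebraically identical to weighted least squares of
    β_out on β_exp through the origin with weights se_out⁻².
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(pairs) == 0:
        raise ValueError("ivw requires at least one pair")
    th, se, _ = _ratios(pairs)
    w = se ** -2.0
    theta = float(np.sum(w * th) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q_stat = q_pval = None
    se_used = se_fixed
    if len(pairs) >= 2:
        q_stat = float(np.sum(w * (th - theta) ** 2))
        q_pval = float(stats.chi2.sf(q_stat, df=len(pairs) - 1))
        if model == "multiplicative_random":
            se_used = se_fixed * math.sqrt(max(1.0, q_stat / (len(pairs) - 1)))
    label = "ivw_re" if model == "multiplicative_random" else "ivw_fe"
    return MREstimate(
        method=label, theta=theta, se=se_used,
        ci_low=theta - _Z95 * se_used, ci_high=theta + _Z95 * se_used,
        pval=_normal_p(theta / se_used), n_snps=len(pairs),
        q_stat=q_stat, q_pval=q_pval,
    )


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / weights.sum()
    # midpoint cumulative weights: crossing 0.5 with linear interpolation
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(th[0])
    if s[-1] <= 0.5:
        return float(th[-1])
    i = int(np.searchsorted(s, 0.5))
    if s[i] == 0.5:
        return float(th[i])
    return float(th[i - 1] + (th[i] - th[i - 1]) * (0.5 - s[i - 1]) / (s[i] - s[i - 1]))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median MR estimate with a parametric-bootstrap SE.

    Ratios are ordered and the estimate taken where the cumulative
    inverse-variance weight crosses one half, interpolating linearly between
    the bracketing ratios. The SE is the standard deviation of the weighted
    medians across ``n_boot`` draws of (β_exp, β_out) from their normal
    sampling distributions. Consistent as long as valid instruments carry
    more than 50% of the total weight.
    """
    if len(pairs) < 3:
        raise ValueError("weighted_median requires at least 3 pairs")
    if n_boot < 100:
        logger.warning("weighted_median: n_boot=%d is small; SE will be noisy", n_boot)
    th, se, _ = _ratios(pairs)
    w = se ** -2.0
    theta = _weighted_median_point(th, w)

    rng = np.random.default_rng(seed)
    b_exp = np.array([p.beta_exp for p in pairs])
    s_exp = np.array([p.se_exp for p in pairs])
    b_out = np.array([p.beta_out for p in pairs])
    s_out = np.array([p.se_out for p in pairs])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be = rng.normal(b_exp, s_exp)
        bo = rng.normal(b_out, s_out)
        tb = bo / be
        wb = (s_out / np.abs(be)) ** -2.0
        boots[b] = _weighted_median_point(tb, wb)
    se_boot = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median", theta=theta, se=se_boot,
        ci_low=theta - _Z95 * se_boot, ci_high=theta + _Z95 * se_boot,
        pval=_normal_p(theta / se_boot), n_snps=len(pairs),
        extras={"n_boot": n_boot},
    )


# ---------------------------------------------------------------------------
# contamination mixture
# ---------------------------------------------------------------------------

def default_psi(pairs: Sequence[HarmonizedPair]) -> float:
    """Data-driven invalid-component scale: SD of the ratio estimates."""
    th, _, _ = _ratios(pairs)
    sd = float(np.std(th, ddof=1)) if len(th) > 1 else 0.0
    return sd if sd > 0 else 1e-6


def contamination_mixture(
    pairs: Sequence[HarmonizedPair],
    psi: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 5000,
) -> MREstimate:
    """Contamination-mixture profile-likelihood MR estimate.

    For each candidate θ on a grid, every ratio contributes the larger of two
    Gaussian log-densities — valid: Normal(θ, se_j²); invalid:
    Normal(0, se_j² + ψ²) — and the contributions are summed into a profile
    log-likelihood. θ̂ is the grid argmax; the 95% CI collects grid points
    within χ²₁(0.95)/2 ≈ 1.92 log-likelihood units of the maximum (the
    enclosing hull is reported and disjoint regions flagged as multimodal).
    """
    if len(pairs) < 1:
        raise ValueError("contamination_mixture requires at least 1 pair")
    th, se, rsids = _ratios(pairs)
    if psi is None:
        psi = default_psi(pairs)
    if psi <= 0:
        raise ValueError("psi must be > 0")
    if grid is None:
        lo = float(th.min() - 3.0 * se.max())
        hi = float(th.max() + 3.0 * se.max())
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() > th.min() or grid.max() < th.max():
            logger.warning("contamination_mixture: grid does not span all ratio estimates")

    # (n_grid, J) log-densities
    ll_valid = stats.norm.logpdf(th[None, :], loc=grid[:, None], scale=se[None, :])
    ll_invalid = stats.norm.logpdf(th, loc=0.0, scale=np.sqrt(se ** 2 + psi ** 2))
    profile = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)

    i_max = int(np.argmax(profile))
    theta = float(grid[i_max])
    cutoff = profile[i_max] - stats.chi2.ppf(0.95, df=1) / 2.0
    inside = profile >= cutoff
    idx = np.flatnonzero(inside)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = bool(np.any(np.diff(idx) > 1))
    valid_set = [rsids[j] for j in range(len(rsids)) if ll_valid[i_max, j] >= ll_invalid[j]]
    # symmetric-normal summary of the profile CI, for the tabular report
    se_eff = max((ci_high - ci_low) / (2.0 * _Z95), 1e-12)
    return MREstimate(
        method="contamination_mixture", theta=theta, se=se_eff,
        ci_low=ci_low, ci_high=ci_high,
        pval=_normal_p(theta / se_eff), n_snps=len(pairs),
        extras={
            "psi": float(psi),
            "valid_set": valid_set,
            "multimodal_ci": multimodal,
            "n_grid": int(len(grid)),
        },
    )


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_thetas(b_exp: np.ndarray, b_out: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-WLS slopes, vectorized over rows if 2-D."""
    s_xy = np.sum(w * b_exp * b_out, axis=-1, keepdims=True)
    s_xx = np.sum(w * b_exp ** 2, axis=-1, keepdims=True)
    return (s_xy - w * b_exp * b_out) / (s_xx - w * b_exp ** 2)


def _rss_terms(b_exp: np.ndarray, b_out: np.ndarray, w: np.ndarray) -> np.ndarray:
    theta_loo = _loo_thetas(b_exp, b_out, w)
    return w * (b_out - theta_loo * b_exp) ** 2


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> MREstimate:
    """MR-PRESSO global pleiotropy test, outlier test and distortion check.

    The observed residual sum of squares is RSS = Σ_j w_j (β_out,j −
    θ̂₍₋ⱼ₎ β_exp,j)² with leave-one-out IVW slopes θ̂₍₋ⱼ₎ and w_j = se_out,j⁻².
    The null distribution is simulated parametrically: β_exp* ~
    Normal(β_exp,j, se_exp,j), β_out* ~ Normal(θ̂₍₋ⱼ₎·β_exp,j, se_out,j), and
    RSS recomputed; the global p-value is (1 + #{RSS* ≥ RSS_obs})/(n_sim + 1).
    Per-variant outlier p-values compare each observed RSS term with its
    simulated counterparts and are Bonferroni-corrected across variants; the
    returned estimate is the IVW after removing detected outliers (the raw
    IVW when none are found), with the pre/post comparison in ``extras``.
    """
    if len(pairs) < 4:
        raise ValueError("mr_presso requires at least 4 pairs")
    if n_sim < 1000:
        raise ValueError("mr_presso requires n_sim >= 1000")
    rng = np.random.default_rng(seed)
    b_exp = np.array([p.beta_exp for p in pairs])
    s_exp = np.array([p.se_exp for p in pairs])
    b_out = np.array([p.beta_out for p in pairs])
    s_out = np.array([p.se_out for p in pairs])
    rsids = [p.rsid for p in pairs]
    j = len(pairs)
    w = s_out ** -2.0

    obs_terms = _rss_terms(b_exp, b_out, w)
    rss_obs = float(obs_terms.sum())
    theta_loo = _loo_thetas(b_exp, b_out, w).ravel()

    sim_exp = rng.normal(b_exp, s_exp, size=(n_sim, j))
    sim_out = rng.normal(theta_loo * b_exp, s_out, size=(n_sim, j))
    sim_terms = _rss_terms(sim_exp, sim_out, np.broadcast_to(w, (n_sim, j)))
    rss_sim = sim_terms.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(sim_terms >= obs_terms[None, :], axis=0)) / (n_sim + 1)
    p_corr = np.minimum(1.0, p_raw * j)
    outliers = [rsids[k] for k in range(j) if p_corr[k] < outlier_alpha]
    if len(outliers) == j:
        raise ValueError(
            "MR-PRESSO flagged every variant as an outlier; no estimate is "
            f"possible (per-variant corrected p: {dict(zip(rsids, p_corr.round(5)))})"
        )

    raw = ivw(pairs)
    if outliers:
        kept = [p for p in pairs if p.rsid not in outliers]
        corrected = ivw(kept)
        distortion = (raw.theta - corrected.theta) / abs(corrected.theta) if corrected.theta != 0 else math.inf
    else:
        corrected = raw
        distortion = 0.0
    est = replace(corrected)
    est.method = "mr_presso"
    est.n_snps = len(pairs) - len(outliers)
    est.extras = {
        "global_rss": rss_obs,
        "global_pval": global_p,
        "outliers": outliers,
        "outlier_pvals": dict(zip(rsids, p_corr.tolist())),
        "theta_raw": raw.theta,
        "theta_outlier_corrected": corrected.theta,
        "distortion_relative_change": float(distortion),
        "n_sim": n_sim,
    }
    return est


# ---------------------------------------------------------------------------


def scale_to_drug(estimate: MREstimate, scale_factor: float) -> MREstimate:
    """Rescale a per-SD estimate to a drug's biomarker-lowering effect.

    θ, SE and CI bounds are multiplied by ``scale_factor`` (e.g. the SD-units
    CRP reduction achieved by tocilizumab 8 mg/kg); the z-statistic and hence
    the p-value are unchanged.
    """
    if not scale_factor > 0:
        raise ValueError("scale_factor must be > 0")
    out = replace(estimate)
    out.theta = estimate.theta * scale_factor
    out.se = estimate.se * scale_factor
    out.ci_low = estimate.ci_low * scale_factor
    out.ci_high = estimate.ci_high * scale_factor
    out.method = f"{estimate.method}_x{scale_factor:g}"
    out.extras = dict(estimate.extras, scale_factor=scale_factor)
    return out
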