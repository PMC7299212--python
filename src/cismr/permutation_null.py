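"""Permutation test of exposure-independence for a cis instrument set.

When a drug-target instrument set is selected from a biomarker GWAS (e.g.
CRP-lowering variants near IL6R), its outcome effect could in principle
reflect the biomarker itself rather than the target pathway. The test here
builds a null distribution of IVW effects from random k-subsets of *all*
biomarker-associated variants and asks where the observed cis-instrument
effect falls: an effect below the lowest fifth percentile indicates the
signal is not explained by generic biomarker-lowering variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .mr_estimators import MREstimate
from .sumstats_io import HarmonizedPair

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_theta: float
    null_thetas: np.ndarray
    percentile: float
    n_perm: int
    k: int
    seed: int | None
    exhaustive: bool = False

    @property
    def below_fifth_percentile(self) -> bool:
        return self.percentile < 5.0

    def summary(self) -> dict:
        q = np.percentile(self.null_thetas, [1, 5, 25, 50, 75, 95, 99])
        return {
            "observed_theta": self.observed_theta,
            "percentile": self.percentile,
            "below_fifth_percentile": self.below_fifth_percentile,
            "n_perm": int(self.n_perm),
            "k": int(self.k),
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "null_quantiles": {f"p{p:g}": float(v) for p, v in zip([1, 5, 25, 50, 75, 95, 99], q)},
        }


def _ivw_theta_pool(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([p.beta_out / p.beta_exp for p in pairs])
    w = (np.array([p.se_out for p in pairs]) / np.abs([p.beta_exp for p in pairs])) ** -2.0
    return theta, w


def permutation_test(
    pool: Sequence[HarmonizedPair],
    k: int,
    observed: MREstimate,
    n_perm: int = 10_000,
    seed: int | None = None,
    exclude_rsids: Sequence[str] | None = None,
    mode: str = "auto",
) -> PermutationResult:
    """Rank an observed MR estimate against IVW effects of random k-subsets.

    Each permutation samples ``k`` pairs from ``pool`` without replacement
    (independently across permutations) and records the fixed-weights IVW θ.
    The percentile is 100·#{null < observed}/n_perm — strictly-less, ties
    count as not-below. When fewer than ``n_perm`` distinct k-subsets exist,
    the test switches to exhaustive enumeration of all subsets.

    ``exclude_rsids`` removes the observed instruments from the pool first
    (the default pipeline behavior, giving a null untouched by the tested
    set; pass ``None``/empty to leave the pool as provided).

    ``mode`` is ``auto`` (enumerate exhaustively when fewer than ``n_perm``
    distinct subsets exist, otherwise sample), ``sample`` or ``exhaustive``.
    """
    if mode not in ("auto", "sample", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if exclude_rsids:
        excl = set(exclude_rsids)
        pool = [p for p in pool if p.rsid not in excl]
    m = len(pool)
    if k > m:
        raise ValueError(f"pool of size {m} smaller than subset size k={k}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    theta, w = _ivw_theta_pool(pool)
    n_subsets = comb(m, k)
    if mode == "exhaustive" or (mode == "auto" and n_subsets < n_perm):
        logger.info(
            "only %d distinct %d-subsets of %d pool variants: switching to "
            "exhaustive enumeration", n_subsets, k, m,
        )
        idx = np.array(list(combinations(range(m), k)))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        base = np.broadcast_to(np.arange(m), (n_perm, m))
        idx = rng.permuted(base, axis=1)[:, :k]
        exhaustive = False

    th = theta[idx]
    ww = w[idx]
    nulls = (th * ww).sum(axis=1) / ww.sum(axis=1)
    n_eff = len(nulls)
    percentile = 100.0 * float(np.sum(nulls < observed.theta)) / n_eff
    return PermutationResult(
        observed_theta=observed.theta,
        null_thetas=nulls,
        percentile=percentile,
        n_perm=n_eff,
        k=k,
        seed=seed,
        exhaustive=exhaustive,
    )
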