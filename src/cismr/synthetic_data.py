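"""Synthetic two-sample GWAS summary statistics.

Desk-scale stand-ins for the real data a cis drug-target MR study uses: a
biomarker (exposure) GWAS of a cis region with AR(1) linkage disequilibrium,
one strong lead signal plus secondary independent signals, and binary-outcome
summary statistics generated under a configurable causal effect with optional
horizontal pleiotropy. Everything is generated directly on the
summary-statistic scale — no individual-level genotypes — with standard
errors from the analytic single-variant formulas, so generated data match
what the pipeline's estimators assume while remaining fast enough to simulate
thousands of replicates.

The exposure axis is "SD units of biomarker decrease": a positive beta means
the effect allele lowers the biomarker, and a protective causal effect on a
binary outcome appears as a negative log-odds ratio θ, matching the
orientation convention used throughout the package.

Default sample sizes mirror the study templates this generator emulates: a
biomarker GWAS of 204 402 individuals and a stroke-scale case-control outcome
of 34 217 cases / 404 630 controls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .instrument_selection import LDMatrix
from .sumstats_io import HarmonizedPair, VariantAssoc

# non-palindromic allele pairs only, so harmonization never drops by default
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

# sub-stream tags so every operation draws from an independent, reproducible
# stream of the single config seed
_STREAM_INSTRUMENTS = 0
_STREAM_REGION = 1
_STREAM_REGION_OUTCOME = 2


@dataclass
class PleiotropyConfig:
    """Directional pleiotropy for the invalid-instrument subset.

    ``proportion_invalid`` of the instruments (rounded half-up) receive a
    direct outcome effect α ~ Normal(alpha_mean, alpha_sd²) that bypasses the
    exposure.
    """

    proportion_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0

    def n_invalid(self, j: int) -> int:
        if not 0.0 <= self.proportion_invalid <= 1.0:
            raise ValueError("proportion_invalid must lie in [0, 1]")
        return int(math.floor(self.proportion_invalid * j + 0.5))


@dataclass
class CisConfig:
    """Structure of the simulated cis region.

    LD is AR(1): r(i, k) = ar1_rho^|i−k| over evenly spaced variants spanning
    the gene ± 1.2·flank (the outermost variants deliberately fall outside the
    cis window so window filtering is exercised). One lead causal variant sits
    at the gene's center and ``n_secondary`` further causal variants are
    spread across the window with low mutual LD. Noncentralities are z-scale
    marginal association strengths at the causal variants; the defaults give
    single-variant F statistics in the low hundreds, typical of a strong
    biomarker locus.
    """

    n_variants: int = 151
    ar1_rho: float = 0.6
    chrom: str = "1"
    gene_start: int = 154_377_669
    gene_end: int = 154_441_926
    flank: int = 300_000
    n_secondary: int = 2
    lead_ncp: float = 13.0
    secondary_ncp: float | Sequence[float] = 10.0
    causal_indices: tuple[int, ...] | None = None  # explicit override; first = lead

    def secondary_ncps(self) -> list[float]:
        if isinstance(self.secondary_ncp, (int, float)):
            return [float(self.secondary_ncp)] * self.n_secondary
        vals = list(self.secondary_ncp)
        if len(vals) != self.n_secondary:
            raise ValueError("secondary_ncp length must equal n_secondary")
        return [float(v) for v in vals]


@dataclass
class SimulationConfig:
    seed: int = 0
    j_instruments: int = 7
    theta_true: float = -0.30
    gamma_range: tuple[float, float] = (0.03, 0.12)
    maf_range: tuple[float, float] = (0.10, 0.50)
    n_exposure: int = 204_402
    n_cases: int = 34_217
    n_controls: int = 404_630
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    cis: CisConfig = field(default_factory=CisConfig)

    def __post_init__(self) -> None:
        for name in ("n_exposure", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gamma_range", "maf_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate (low, high) interval")
        if not (0.0 < self.maf_range[0] and self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.cis.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")


def se_quantitative(eaf: np.ndarray | float, n: int) -> np.ndarray | float:
    """Analytic SE of a per-allele effect on a standardized quantitative trait."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def se_binary(eaf: np.ndarray | float, n_cases: int, n_controls: int) -> np.ndarray | float:
    """Analytic SE of a per-allele log-OR, 1/(2p(1−p)) · (1/n_cases + 1/n_controls)."""
    return np.sqrt((1.0 / (2.0 * eaf * (1.0 - eaf))) * (1.0 / n_cases + 1.0 / n_controls))


def _two_sided_p(z: np.ndarray | float):
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def _alleles(rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    return [_ALLELE_PAIRS[i] for i in idx]


# ---------------------------------------------------------------------------
# independent instruments with paired outcome
# ---------------------------------------------------------------------------

def simulate_instruments(
    config: SimulationConfig,
) -> tuple[list[VariantAssoc], list[VariantAssoc], dict]:
    """Generate J independent instruments with paired outcome statistics.

    Per instrument j: minor-allele frequency p_j ~ Uniform(maf_range), true
    exposure effect γ_j ~ Uniform(gamma_range) (SD of biomarker decrease per
    allele), observed β_exp,j ~ Normal(γ_j, se_exp,j²) with the analytic
    quantitative-trait SE; outcome β_out,j ~ Normal(θ·γ_j + α_j, se_out,j²)
    with the analytic log-OR SE, where α_j is the pleiotropic offset of the
    invalid subset (the last ``n_invalid`` instruments) and 0 otherwise.

    Returns exposure records, outcome records (same variants, same effect
    alleles), and a truth record with γ, α, the invalid set and θ.
    """
    rng = np.random.default_rng([config.seed, _STREAM_INSTRUMENTS])
    j = config.j_instruments
    if j < 1:
        raise ValueError("j_instruments must be >= 1")
    eaf = rng.uniform(*config.maf_range, size=j)
    gamma = rng.uniform(*config.gamma_range, size=j)
    n_invalid = config.pleiotropy.n_invalid(j)
    alpha = np.zeros(j)
    if n_invalid:
        alpha[j - n_invalid:] = rng.normal(
            config.pleiotropy.alpha_mean, config.pleiotropy.alpha_sd, size=n_invalid
        )
    se_exp = se_quantitative(eaf, config.n_exposure)
    se_out = se_binary(eaf, config.n_cases, config.n_controls)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(config.theta_true * gamma + alpha, se_out)
    alleles = _alleles(rng, j)

    n_out = config.n_cases + config.n_controls
    exposure, outcome = [], []
    for i in range(j):
        rsid = f"rs{1_000_000 + i}"
        ea, oa = alleles[i]
        common = dict(rsid=rsid, chrom="1", pos=1_000_000 * (i + 1),
                      effect_allele=ea, other_allele=oa, eaf=float(eaf[i]))
        exposure.append(VariantAssoc(
            **common, beta=float(beta_exp[i]), se=float(se_exp[i]),
            pval=float(_two_sided_p(beta_exp[i] / se_exp[i])), n=config.n_exposure,
        ))
        outcome.append(VariantAssoc(
            **common, beta=float(beta_out[i]), se=float(se_out[i]),
            pval=float(_two_sided_p(beta_out[i] / se_out[i])), n=n_out,
            n_cases=config.n_cases, n_controls=config.n_controls,
        ))
    truth = {
        "theta_true": config.theta_true,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid_rsids": [exposure[i].rsid for i in range(j) if alpha[i] != 0.0],
        "seed": config.seed,
    }
    return exposure, outcome, truth


def pairs_from_records(
    exposure: Sequence[VariantAssoc], outcome: Sequence[VariantAssoc]
) -> list[HarmonizedPair]:
    """Directly pair co-generated records (identical orientation by construction)."""
    out_by = {r.rsid: r for r in outcome}
    return [
        HarmonizedPair(rsid=e.rsid, beta_exp=e.beta, se_exp=e.se,
                       beta_out=out_by[e.rsid].beta, se_out=out_by[e.rsid].se)
        for e in exposure if e.rsid in out_by
    ]


# ---------------------------------------------------------------------------
# cis region with LD
# ---------------------------------------------------------------------------

def _minimum_separation(rho: float, max_r2: float = 0.05) -> int:
    if rho == 0.0:
        return 1
    return max(1, math.ceil(math.log(max_r2) / (2.0 * math.log(rho))))


def _region_positions(cfg: CisConfig) -> np.ndarray:
    # span gene ± 1.2*flank so the window filter has something to exclude
    lo = cfg.gene_start - int(1.2 * cfg.flank)
    hi = cfg.gene_end + int(1.2 * cfg.flank)
    return np.linspace(lo, hi, cfg.n_variants).round().astype(int)


def _default_causal_indices(cfg: CisConfig, positions: np.ndarray) -> list[int]:
    in_window = np.flatnonzero(
        (positions >= cfg.gene_start - int(0.8 * cfg.flank))
        & (positions <= cfg.gene_end + int(0.8 * cfg.flank))
    )
    n_causal = 1 + cfg.n_secondary
    gene_center = (cfg.gene_start + cfg.gene_end) // 2
    lead_idx = int(np.argmin(np.abs(positions - gene_center)))
    if n_causal == 1:
        return [lead_idx]
    spread = np.linspace(in_window[0], in_window[-1], n_causal).round().astype(int)
    # snap nearest spread point to the gene center: that one is the lead
    snap = int(np.argmin(np.abs(spread - lead_idx)))
    spread[snap] = lead_idx
    return [lead_idx] + [int(s) for i, s in enumerate(spread) if i != snap]


def simulate_cis_region(
    config: SimulationConfig,
) -> tuple[list[VariantAssoc], LDMatrix, dict]:
    """Generate an exposure GWAS of a cis region with AR(1) LD.

    Marginal z-scores follow the standard summary-statistic model under LD:
    z ~ MVN(R·z_causal, R), drawn as R·z_causal + chol(R)·ε with ε standard
    normal, where z_causal holds the planted noncentralities. Betas, SEs and
    p-values are then reconstructed from allele frequencies and the exposure
    sample size. Positions are evenly spaced across gene ± 1.2·flank.
    """
    cfg = config.cis
    if cfg.n_variants < 2:
        raise ValueError("cis.n_variants must be >= 2")
    rng = np.random.default_rng([config.seed, _STREAM_REGION])
    positions = _region_positions(cfg)

    if cfg.causal_indices is not None:
        causal = list(cfg.causal_indices)
    else:
        causal = _default_causal_indices(cfg, positions)
    ncps = [cfg.lead_ncp] + cfg.secondary_ncps()
    if len(causal) != len(ncps):
        raise ValueError("causal_indices length must be 1 + n_secondary")
    min_sep = _minimum_separation(cfg.ar1_rho)
    for a in range(len(causal)):
        for b in range(a + 1, len(causal)):
            if abs(causal[a] - causal[b]) < min_sep:
                raise ValueError(
                    f"causal variants at indices {causal[a]} and {causal[b]} are "
                    f"closer than the LD decay allows (need separation >= {min_sep} "
                    f"at ar1_rho={cfg.ar1_rho} for mutual r^2 < 0.05)"
                )

    k = cfg.n_variants
    r_mat = cfg.ar1_rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    z_causal = np.zeros(k)
    for idx, ncp in zip(causal, ncps):
        z_causal[idx] = ncp
    chol = np.linalg.cholesky(r_mat)
    z = r_mat @ z_causal + chol @ rng.standard_normal(k)

    eaf = rng.uniform(*config.maf_range, size=k)
    se = se_quantitative(eaf, config.n_exposure)
    beta = z * se
    pvals = _two_sided_p(z)
    alleles = _alleles(rng, k)

    records = [
        VariantAssoc(
            rsid=f"rs{100_000 + i}", chrom=cfg.chrom, pos=int(positions[i]),
            effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eaf[i]), beta=float(beta[i]), se=float(se[i]),
            pval=float(pvals[i]), n=config.n_exposure,
        )
        for i in range(k)
    ]
    ld = LDMatrix([r.rsid for r in records], r_mat)
    truth = {
        "causal_indices": [int(i) for i in causal],
        "causal_rsids": [records[i].rsid for i in causal],
        "lead_rsid": records[causal[0]].rsid,
        "ncps": ncps,
        "gamma_per_allele": [float(ncps[t] * se[causal[t]]) for t in range(len(causal))],
        "seed": config.seed,
    }
    return records, ld, truth


def simulate_region_outcome(
    region: Sequence[VariantAssoc],
    ld: LDMatrix,
    truth: dict,
    config: SimulationConfig,
    theta_true: float | None = None,
    stream: int = _STREAM_REGION_OUTCOME,
    quantitative_n: int | None = None,
) -> list[VariantAssoc]:
    """Outcome summary statistics for every variant of a cis region.

    The outcome is caused by the exposure with effect ``theta_true``
    (``config.theta_true`` by default), so the causal variants' true outcome
    effects are θ·γ_j (+ pleiotropic offsets for the configured invalid
    subset), and the marginal outcome z-scores inherit the region's LD:
    z_out ~ MVN(R·z_out,causal, R). By default the outcome is a case-control
    trait on the log-OR scale with the configured case/control counts;
    passing ``quantitative_n`` instead generates a standardized quantitative
    outcome (SD units) of that sample size.
    """
    theta = config.theta_true if theta_true is None else theta_true
    rng = np.random.default_rng([config.seed, stream])
    k = len(region)
    eaf = np.array([r.eaf for r in region])
    if quantitative_n is not None:
        se_out = se_quantitative(eaf, quantitative_n)
    else:
        se_out = se_binary(eaf, config.n_cases, config.n_controls)

    causal = truth["causal_indices"]
    gamma = truth["gamma_per_allele"]
    n_invalid = config.pleiotropy.n_invalid(len(causal))
    alpha = np.zeros(len(causal))
    if n_invalid:
        alpha[len(causal) - n_invalid:] = rng.normal(
            config.pleiotropy.alpha_mean, config.pleiotropy.alpha_sd, size=n_invalid
        )
    z_causal = np.zeros(k)
    for t, idx in enumerate(causal):
        z_causal[idx] = (theta * gamma[t] + alpha[t]) / se_out[idx]
    chol = np.linalg.cholesky(ld.r)
    z = ld.r @ z_causal + chol @ rng.standard_normal(k)
    beta = z * se_out
    pvals = _two_sided_p(z)
    if quantitative_n is not None:
        n_out, n_cases, n_controls = quantitative_n, None, None
    else:
        n_out = config.n_cases + config.n_controls
        n_cases, n_controls = config.n_cases, config.n_controls
    return [
        VariantAssoc(
            rsid=r.rsid, chrom=r.chrom, pos=r.pos,
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=r.eaf, beta=float(beta[i]), se=float(se_out[i]),
            pval=float(pvals[i]), n=n_out,
            n_cases=n_cases, n_controls=n_controls,
        )
        for i, r in enumerate(region)
    ]


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
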