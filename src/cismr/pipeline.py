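"""End-to-end orchestration of the cis-MR analysis across outcomes.

One exposure GWAS is reduced to a cis instrument set once; each outcome study
is then harmonized against the instruments, the configured estimator battery
is run, estimates are scaled to the drug's biomarker effect, and every
outcome is classified against its family's Bonferroni-corrected threshold
(with p-values under the nominal alpha but above the family threshold called
suggestive). Where a biomarker-wide SNP pool is configured, the
permutation-based exposure-independence test is run per outcome. The run
emits a tidy per-method results table and a JSON report carrying per-stage
counts, the resolved configuration and the seed, so reruns are exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instrument_selection import (
    SelectionConfig, SelectionResult, instruments_to_frame, read_ld_matrix,
    select_instruments,
)
from .mr_estimators import (
    MREstimate, contamination_mixture, ivw, mr_presso, scale_to_drug,
    to_odds_ratio, weighted_median,
)
from .permutation_null import permutation_test
from .sumstats_io import (
    HarmonizedPair, harmonization_report, harmonize, orient_to_exposure_decreasing,
    read_sumstats, retained_pairs,
)

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("significant", "suggestive", "null")
KNOWN_METHODS = ("ivw", "weighted_median", "contamination_mixture", "mr_presso")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def classify(result: MREstimate, family_threshold: float, alpha: float) -> str:
    """significant / suggestive / null by strict p-value comparison."""
    if not 0.0 < family_threshold <= alpha:
        raise ValueError("need 0 < family_threshold <= alpha")
    if result.pval < family_threshold:
        return "significant"
    if result.pval < alpha:
        return "suggestive"
    return "null"


def format_threshold(threshold: float) -> str:
    """Thresholds displayed to 2 significant figures (comparison stays exact)."""
    return f"{threshold:.2g}"


@dataclass
class OutcomeSpec:
    label: str
    path: str
    family: str
    dialect: dict | None = None
    run_permutation: bool = True  # only meaningful when a pool is configured


@dataclass
class PermutationSpec:
    pool_path: str
    k: int = 7
    n_perm: int = 10_000
    include_observed_instruments: bool = False
    pool_dialect: dict | None = None


@dataclass
class PipelineConfig:
    exposure_path: str
    ld_path: str
    outcomes: list[OutcomeSpec]
    gene_chrom: str = "1"
    gene_start: int = 0
    gene_end: int = 0
    flank: int = 300_000
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    conditional_alpha: float = 0.05
    conditional_m: int | None = None
    scale_factor: float = 1.0
    alpha: float = 0.05
    methods: tuple[str, ...] = KNOWN_METHODS
    palindrome_eaf_window: float = 0.08
    seed: int = 0
    exposure_dialect: dict | None = None
    permutation: PermutationSpec | None = None

    def __post_init__(self) -> None:
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"outcome labels must be unique, got {labels}")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    def validate_paths(self) -> None:
        missing = [p for p in
                   [self.exposure_path, self.ld_path] + [o.path for o in self.outcomes]
                   + ([self.permutation.pool_path] if self.permutation else [])
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured paths do not exist: {missing}")

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            gene_chrom=self.gene_chrom, gene_start=self.gene_start,
            gene_end=self.gene_end, flank=self.flank,
            p_threshold=self.p_threshold, r2_threshold=self.r2_threshold,
            conditional_alpha=self.conditional_alpha, conditional_m=self.conditional_m,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read the declarative YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
    perm = raw.pop("permutation", None)
    permutation = PermutationSpec(**perm) if perm else None
    gene = raw.pop("gene", {})
    cfg = PipelineConfig(
        outcomes=outcomes, permutation=permutation,
        gene_chrom=str(gene.get("chrom", "1")),
        gene_start=int(gene.get("start", 0)), gene_end=int(gene.get("end", 0)),
        flank=int(gene.get("flank", 300_000)),
        **raw,
    )
    return cfg


@dataclass
class OutcomeResult:
    label: str
    family: str
    estimates: dict[str, MREstimate]
    classification: str
    family_threshold: float
    harmonization: dict
    permutation: dict | None = None
    error: str | None = None


def _run_estimators(
    pairs: Sequence[HarmonizedPair],
    methods: Sequence[str],
    seed: int,
) -> dict[str, MREstimate]:
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    estimates: dict[str, MREstimate] = {}
    estimates["ivw"] = ivw(pairs)
    if "weighted_median" in methods and len(pairs) >= 3:
        estimates["weighted_median"] = weighted_median(pairs, seed=seeds[0])
    if "contamination_mixture" in methods and len(pairs) >= 2:
        estimates["contamination_mixture"] = contamination_mixture(pairs)
    if "mr_presso" in methods and len(pairs) >= 4:
        estimates["mr_presso"] = mr_presso(pairs, seed=seeds[1])
    return estimates


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns (and optionally writes) the run report.

    Instrument selection runs once on the exposure; every outcome is analyzed
    independently and a failure in one outcome does not stop the others (it
    is recorded in the report instead). Family-wise Bonferroni divisors are
    the family sizes observed in the configuration, never hard-coded.
    """
    config.validate_paths()
    exposure = read_sumstats(config.exposure_path, config.exposure_dialect)
    exposure = orient_to_exposure_decreasing(exposure)
    ld = read_ld_matrix(config.ld_path)
    selection: SelectionResult = select_instruments(exposure, ld, config.selection_config())
    instruments = [ins.variant for ins in selection.instruments]
    if not instruments:
        raise RuntimeError("no instruments selected; cannot run MR")

    family_sizes: dict[str, int] = {}
    for spec in config.outcomes:
        family_sizes[spec.family] = family_sizes.get(spec.family, 0) + 1
    thresholds = {fam: bonferroni_threshold(config.alpha, m) for fam, m in family_sizes.items()}

    pool_pairs = None
    if config.permutation is not None:
        pool_records = read_sumstats(config.permutation.pool_path, config.permutation.pool_dialect)
        pool_records = orient_to_exposure_decreasing(pool_records)

    master = np.random.SeedSequence(config.seed)
    outcome_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(len(config.outcomes))]

    results: list[OutcomeResult] = []
    any_failed = False
    for spec, oseed in zip(config.outcomes, outcome_seeds):
        thr = thresholds[spec.family]
        try:
            outcome_records = read_sumstats(spec.path, spec.dialect)
            pairs = harmonize(instruments, outcome_records, config.palindrome_eaf_window)
            used = retained_pairs(pairs)
            if not used:
                raise RuntimeError("all harmonized pairs dropped")
            estimates = _run_estimators(used, config.methods, oseed)
            scaled = {m: scale_to_drug(e, config.scale_factor) for m, e in estimates.items()}
            classification = classify(scaled["ivw"], thr, config.alpha)

            perm_summary = None
            if config.permutation is not None and spec.run_permutation:
                pool_pairs = retained_pairs(harmonize(
                    pool_records, outcome_records, config.palindrome_eaf_window))
                excl = None if config.permutation.include_observed_instruments \
                    else [p.rsid for p in used]
                perm = permutation_test(
                    pool_pairs, k=config.permutation.k, observed=estimates["ivw"],
                    n_perm=config.permutation.n_perm, seed=oseed, exclude_rsids=excl,
                )
                perm_summary = perm.summary()

            results.append(OutcomeResult(
                label=spec.label, family=spec.family, estimates=scaled,
                classification=classification, family_threshold=thr,
                harmonization=harmonization_report(instruments, pairs),
                permutation=perm_summary,
            ))
        except Exception as exc:  # per-outcome isolation is deliberate
            logger.error("outcome %s failed: %s", spec.label, exc)
            any_failed = True
            results.append(OutcomeResult(
                label=spec.label, family=spec.family, estimates={},
                classification="error", family_threshold=thr,
                harmonization={}, error=str(exc),
            ))

    table = results_table(results)
    report = {
        "software": {"package": "cismr", "version": __version__},
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "selection_counts": selection.counts,
        "instruments": instruments_to_frame(selection.instruments).to_dict(orient="records"),
        "family_thresholds": {
            fam: {"m": family_sizes[fam], "threshold": thr,
                  "display": format_threshold(thr)}
            for fam, thr in thresholds.items()
        },
        "outcomes": [_outcome_to_jsonable(r) for r in results],
        "failed": any_failed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False)
        (out_dir / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        instruments_to_frame(selection.instruments).to_csv(
            out_dir / "instruments.tsv", sep="\t", index=False)
    return report


def results_table(results: Sequence[OutcomeResult]) -> pd.DataFrame:
    """Forest-plot-ready tidy table: one row per outcome × method."""
    rows = []
    for res in results:
        for method, est in res.estimates.items():
            or_, or_lo, or_hi = to_odds_ratio(est)
            rows.append({
                "outcome": res.label, "family": res.family, "method": method,
                "theta": est.theta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
                "odds_ratio": or_, "or_ci_low": or_lo, "or_ci_high": or_hi,
                "n_snps": est.n_snps, "q_stat": est.q_stat, "q_pval": est.q_pval,
                "family_threshold": res.family_threshold,
                "classification": res.classification if method == "ivw" else "",
            })
        if res.error:
            rows.append({"outcome": res.label, "family": res.family,
                         "method": "ERROR", "classification": res.error})
    return pd.DataFrame(rows)


def _estimate_to_jsonable(est: MREstimate) -> dict:
    d = dataclasses.asdict(est)
    d["odds_ratio"] = est.odds_ratio
    return d


def _outcome_to_jsonable(res: OutcomeResult) -> dict:
    return {
        "label": res.label, "family": res.family,
        "classification": res.classification,
        "family_threshold": res.family_threshold,
        "estimates": {m: _estimate_to_jsonable(e) for m, e in res.estimates.items()},
        "harmonization": res.harmonization,
        "permutation": res.permutation,
        "error": res.error,
    }


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["methods"] = list(config.methods)
    return d
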