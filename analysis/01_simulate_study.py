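#!/usr/bin/env python
"""Generate the synthetic study all downstream analyses run on.

Emulates the structure of a cis drug-target MR study of IL-6 signaling:

* an exposure GWAS (CRP-like biomarker, 204 402 individuals) of a cis region
  around an IL6R-like gene — 151 variants with AR(1) LD, 7 planted causal
  signals of which 3 lie inside the gene body;
* binary-outcome GWAS tables for 3 stroke subtypes and 9 cardiovascular
  outcomes (MEGASTROKE / CARDIoGRAM-scale case-control counts), plus 3
  quantitative validation biomarkers up- and downstream of the pathway;
* a pool of 187 biomarker-associated SNPs from the rest of the genome with
  no outcome effect, for the exposure-independence permutation test;
* the pipeline configuration (YAML) wiring it all together.

Planted causal effects are protective (negative log-OR per SD biomarker
decrease) for most vascular outcomes, null for cardioembolic stroke and the
thrombotic phenotypes, and positive for the upstream markers — the pattern
the downstream scripts are expected to detect and classify.

Writes everything under results/data/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from cismr.instrument_selection import write_ld_matrix
from cismr.sumstats_io import VariantAssoc, write_sumstats
from cismr.synthetic_data import (
    SimulationConfig, se_binary, simulate_cis_region, simulate_instruments,
    simulate_region_outcome, write_truth,
)
from scipy import stats

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"

SEED = 20200512

# planted causal structure of the cis region: indices into the 151-variant
# grid; first entry is the lead (gene center), entries 1-2 also fall inside
# the gene body, the rest sit in the flanks
CAUSAL_INDICES = (75, 69, 81, 30, 45, 105, 120)
LEAD_NCP = 15.0
SECONDARY_NCPS = (11.0, 9.5, 10.5, 12.0, 9.0, 13.0)
# steeper LD decay than the generator default: with seven causal signals in
# one window, adjacent-signal midpoints must stay below the clumping r^2
AR1_RHO = 0.45

# outcome label -> (family, theta_true, n_cases, n_controls)
BINARY_OUTCOMES = {
    "large_artery_stroke":      ("stroke_subtypes", -0.45, 4373, 404_630),
    "small_vessel_stroke":      ("stroke_subtypes", -0.40, 5386, 404_630),
    "cardioembolic_stroke":     ("stroke_subtypes",  0.00, 7193, 404_630),
    "ischemic_stroke":          ("cardiovascular_outcomes", -0.30, 34_217, 404_630),
    "coronary_artery_disease":  ("cardiovascular_outcomes", -0.30, 60_801, 123_504),
    "myocardial_infarction":    ("cardiovascular_outcomes", -0.35, 43_676, 128_199),
    "aortic_aneurysm":          ("cardiovascular_outcomes", -0.50, 4_000, 317_406),
    "atrial_fibrillation":      ("cardiovascular_outcomes", -0.12, 65_446, 522_744),
    "carotid_plaque":           ("cardiovascular_outcomes", -0.15, 21_540, 47_640),
    "peripheral_artery_disease": ("cardiovascular_outcomes", -0.05, 7_098, 314_308),
    "heart_failure":            ("cardiovascular_outcomes", -0.05, 10_068, 311_338),
    "venous_thromboembolism":   ("cardiovascular_outcomes",  0.00, 9_176, 312_230),
}

# quantitative validation markers: label -> (theta_true, n)
# genetic downregulation of the pathway raises the upstream regulators and
# lowers the downstream acute-phase product
QUANT_OUTCOMES = {
    "il6_levels":        (0.50, 8_293),
    "sil6r_levels":      (0.60, 3_301),
    "fibrinogen_levels": (-0.25, 120_246),
}

# CRP-decreasing effect of IL-6R blockade (tocilizumab 8 mg/kg), in SD units
# of the biomarker: the scaling constant applied to all reported estimates
TOCILIZUMAB_SCALE = 2.0


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    cfg.cis.ar1_rho = AR1_RHO
    cfg.cis.causal_indices = CAUSAL_INDICES
    cfg.cis.n_secondary = len(CAUSAL_INDICES) - 1
    cfg.cis.lead_ncp = LEAD_NCP
    cfg.cis.secondary_ncp = SECONDARY_NCPS

    region, ld, truth = simulate_cis_region(cfg)
    write_sumstats(region, DATA / "exposure.tsv")
    write_ld_matrix(ld, DATA / "ld.tsv")
    write_truth(truth, DATA / "truth.json")
    in_gene = [r for i, r in enumerate(region)
               if i in CAUSAL_INDICES and cfg.cis.gene_start <= r.pos <= cfg.cis.gene_end]
    print(f"cis region: {len(region)} variants, planted {len(CAUSAL_INDICES)} "
          f"causal signals ({len(in_gene)} inside the gene body)")

    # biomarker-wide null pool (187 SNPs); exposure effects are shared across
    # outcomes, outcome draws are made per outcome at that study's case and
    # control counts (the pool has no causal outcome effect)
    pool_cfg = SimulationConfig(seed=SEED + 1, j_instruments=187, theta_true=0.0)
    pool_exp, _, _ = simulate_instruments(pool_cfg)
    write_sumstats(pool_exp, DATA / "crp_pool.tsv")

    def pool_outcome(n_cases: int, n_controls: int, stream: int) -> list[VariantAssoc]:
        rng = np.random.default_rng([SEED + 1, 50, stream])
        recs = []
        for v in pool_exp:
            se = float(se_binary(v.eaf, n_cases, n_controls))
            beta = float(rng.normal(0.0, se))
            recs.append(VariantAssoc(
                rsid=v.rsid, chrom=v.chrom, pos=v.pos,
                effect_allele=v.effect_allele, other_allele=v.other_allele,
                eaf=v.eaf, beta=beta, se=se,
                pval=float(max(2 * stats.norm.sf(abs(beta / se)), 1e-300)),
                n=n_cases + n_controls, n_cases=n_cases, n_controls=n_controls))
        return recs

    outcomes_yaml = []
    for i, (label, (family, theta, n_cases, n_controls)) in enumerate(
            BINARY_OUTCOMES.items()):
        ocfg = dataclasses.replace(cfg, n_cases=n_cases, n_controls=n_controls)
        recs = simulate_region_outcome(region, ld, truth, ocfg,
                                       theta_true=theta, stream=100 + i)
        write_sumstats(list(recs) + pool_outcome(n_cases, n_controls, i),
                       DATA / f"{label}.tsv")
        outcomes_yaml.append({"label": label, "path": str(DATA / f"{label}.tsv"),
                              "family": family})
        print(f"  outcome {label:<26s} theta_true={theta:+.2f} "
              f"({n_cases:,} cases / {n_controls:,} controls)")

    for i, (label, (theta, n)) in enumerate(QUANT_OUTCOMES.items()):
        recs = simulate_region_outcome(region, ld, truth, cfg, theta_true=theta,
                                       stream=200 + i, quantitative_n=n)
        write_sumstats(recs, DATA / f"{label}.tsv")
        outcomes_yaml.append({"label": label, "path": str(DATA / f"{label}.tsv"),
                              "family": "validation_markers",
                              "run_permutation": False})
        print(f"  outcome {label:<26s} theta_true={theta:+.2f} (n={n:,}, SMD)")

    config = {
        "exposure_path": str(DATA / "exposure.tsv"),
        "ld_path": str(DATA / "ld.tsv"),
        "gene": {"chrom": cfg.cis.chrom, "start": cfg.cis.gene_start,
                 "end": cfg.cis.gene_end, "flank": cfg.cis.flank},
        "p_threshold": 5e-8,
        "r2_threshold": 0.1,
        "scale_factor": TOCILIZUMAB_SCALE,
        "alpha": 0.05,
        "seed": SEED,
        "methods": ["ivw", "weighted_median", "contamination_mixture", "mr_presso"],
        "outcomes": outcomes_yaml,
        "permutation": {"pool_path": str(DATA / "crp_pool.tsv"),
                        "k": 7, "n_perm": 10_000},
    }
    (DATA / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    truth_summary = {
        "seed": SEED,
        "theta_true": {k: v[1] for k, v in BINARY_OUTCOMES.items()}
        | {k: v[0] for k, v in QUANT_OUTCOMES.items()},
        "scale_factor": TOCILIZUMAB_SCALE,
    }
    (DATA / "planted_effects.json").write_text(
        json.dumps(truth_summary, indent=2) + "\n")
    print(f"\nwrote study data + config under {DATA}")


if __name__ == "__main__":
    main()
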