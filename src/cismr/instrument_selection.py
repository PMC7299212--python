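"""Cis-instrument selection for drug-target Mendelian randomization.

A drug target's gene region is scanned for variants associated with a
downstream biomarker of the target's activity: the cis window around the gene
is extracted, genome-wide-significant variants kept, greedy LD clumping thins
them to approximate independence, and an approximate conditional analysis
against the lead variant checks that each retained signal carries information
beyond the lead. Instrument strength is summarized by the single-variant
F statistic (beta/se)².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import VariantAssoc

logger = logging.getLogger(__name__)


class LDMatrixError(ValueError):
    pass


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise correlations r (NOT r²) over variants.

    The text representation is a square tab-delimited matrix whose first row
    and first column hold the variant IDs.
    """

    rsids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.rsids)
        if self.r.shape != (k, k):
            raise LDMatrixError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise LDMatrixError("LD matrix not symmetric within 1e-10")
        if not np.allclose(np.diag(self.r), 1.0, atol=0.0):
            raise LDMatrixError("LD matrix diagonal must be exactly 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise LDMatrixError("LD correlations must lie in [-1, 1]")
        eigmin = float(np.linalg.eigvalsh(self.r).min())
        if eigmin < -1e-8:
            logger.warning("LD matrix not PSD (min eigenvalue %.3g)", eigmin)
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def subset(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[rs] for rs in rsids]
        return LDMatrix(list(rsids), self.r[np.ix_(idx, idx)])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    rsids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != rsids:
        raise LDMatrixError(f"{path}: row and column variant IDs differ")
    return LDMatrix(rsids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.rsids, columns=ld.rsids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument with strength and conditional-independence stats."""

    variant: VariantAssoc
    f_stat: float
    conditional_beta: float
    conditional_se: float
    conditional_pval: float
    in_gene: bool
    is_lead: bool = False
    conditional_pass: bool = True

    @property
    def rsid(self) -> str:
        return self.variant.rsid


@dataclass
class SelectionConfig:
    """Thresholds for the selection cascade.

    ``conditional_m`` is the Bonferroni divisor for the in-gene conditional
    threshold; ``None`` means "number of non-lead instruments tested".
    """

    gene_chrom: str
    gene_start: int
    gene_end: int
    flank: int = 300_000
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    conditional_alpha: float = 0.05
    conditional_m: int | None = None


@dataclass
class SelectionResult:
    instruments: list[InstrumentRecord]
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def select_cis(
    records: Sequence[VariantAssoc],
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    flank: int,
) -> list[VariantAssoc]:
    """Variants within ``[gene_start − flank, gene_end + flank]`` (inclusive)
    on the gene's chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    lo, hi = gene_start - flank, gene_end + flank
    out = [r for r in records if r.chrom == gene_chrom and lo <= r.pos <= hi]
    if not out:
        logger.warning("select_cis: no variants in window %s:%d-%d", gene_chrom, lo, hi)
    return out


def filter_significant(records: Sequence[VariantAssoc], p_threshold: float) -> list[VariantAssoc]:
    """Records with pval strictly below ``p_threshold``."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return [r for r in records if r.pval < p_threshold]


def _clump_order_key(rec: VariantAssoc):
    # ties on p broken by position, then rsid, so output is order-invariant
    return (rec.pval, rec.pos, rec.rsid)


def ld_clump(
    records: Sequence[VariantAssoc],
    ld: LDMatrix,
    r2_threshold: float,
) -> list[VariantAssoc]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly retain the smallest-p unretired record and retire every
    unretired record with r² ≥ ``r2_threshold`` against it. The retained set
    is returned in the original input order; every retained pair has
    r² < ``r2_threshold``.
    """
    missing = [r.rsid for r in records if r.rsid not in ld]
    if missing:
        raise LDMatrixError(f"rsids absent from LD matrix: {missing}")
    alive = {r.rsid for r in records}
    retained: set[str] = set()
    for rec in sorted(records, key=_clump_order_key):
        if rec.rsid not in alive:
            continue
        retained.add(rec.rsid)
        alive.discard(rec.rsid)
        for other in list(alive):
            if ld.corr(rec.rsid, other) ** 2 >= r2_threshold:
                alive.discard(other)
    return [r for r in records if r.rsid in retained]


def f_statistic(record: VariantAssoc) -> float:
    """Single-variant instrument-strength F statistic, (beta/se)²."""
    return (record.beta / record.se) ** 2


def conditional_on_lead(
    records: Sequence[VariantAssoc],
    lead_rsid: str,
    ld: LDMatrix,
    gene_start: int | None = None,
    gene_end: int | None = None,
) -> list[InstrumentRecord]:
    """Approximate conditional analysis of each variant against the lead.

    Works on standardized effects: with z_j = beta_j/se_j and r = r(j, lead),
    the effect of variant j adjusted for the lead in a two-variant joint model
    is z_cond = (z_j − r·z_lead) / sqrt(1 − r²), with a two-sided normal
    p-value. The conditional beta/se are recovered on the original scale by
    multiplying by se_j, which sidesteps reference allele frequencies. The
    lead variant keeps its marginal values.
    """
    by_rsid = {r.rsid: r for r in records}
    if lead_rsid not in by_rsid:
        raise ValueError(f"lead rsid {lead_rsid!r} not among records")
    lead = by_rsid[lead_rsid]
    z_lead = lead.zscore
    out: list[InstrumentRecord] = []
    for rec in records:
        in_gene = (
            gene_start is not None and gene_end is not None
            and gene_start <= rec.pos <= gene_end
        )
        if rec.rsid == lead_rsid:
            out.append(InstrumentRecord(
                variant=rec, f_stat=f_statistic(rec),
                conditional_beta=rec.beta, conditional_se=rec.se,
                conditional_pval=rec.pval, in_gene=in_gene, is_lead=True,
            ))
            continue
        r = ld.corr(rec.rsid, lead_rsid)
        if abs(r) >= 1.0:
            raise ValueError(f"{rec.rsid} is collinear with lead (|r| = 1)")
        denom = math.sqrt(1.0 - r * r)
        z_cond = (rec.zscore - r * z_lead) / denom
        pval = 2.0 * stats.norm.sf(abs(z_cond))
        out.append(InstrumentRecord(
            variant=rec, f_stat=f_statistic(rec),
            conditional_beta=z_cond * rec.se, conditional_se=rec.se,
            conditional_pval=float(pval), in_gene=in_gene,
        ))
    return out


def select_instruments(
    records: Sequence[VariantAssoc],
    ld: LDMatrix,
    config: SelectionConfig,
) -> SelectionResult:
    """Full selection cascade: cis window → significance → clumping →
    conditional analysis against the lead.

    The lead is the smallest-p clumped variant. Instruments failing their
    conditional threshold (``conditional_alpha`` overall; Bonferroni-corrected
    ``conditional_alpha / m`` for in-gene variants) are flagged via
    ``conditional_pass`` but never silently removed. The result carries
    per-stage counts.
    """
    counts = {"input": len(records)}
    cis = select_cis(records, config.gene_chrom, config.gene_start, config.gene_end, config.flank)
    counts["cis_window"] = len(cis)
    sig = filter_significant(cis, config.p_threshold)
    counts["significant"] = len(sig)
    if not sig:
        logger.warning("select_instruments: no significant variants in the cis window")
        return SelectionResult([], counts)
    clumped = ld_clump(sig, ld, config.r2_threshold)
    counts["clumped"] = len(clumped)

    lead = min(clumped, key=_clump_order_key)
    instruments = conditional_on_lead(
        clumped, lead.rsid, ld,
        gene_start=config.gene_start, gene_end=config.gene_end,
    )
    n_tested = sum(1 for ins in instruments if not ins.is_lead)
    m = config.conditional_m if config.conditional_m is not None else max(n_tested, 1)
    thr_in_gene = config.conditional_alpha / m
    flagged = []
    for ins in instruments:
        if ins.is_lead:
            flagged.append(ins)
            continue
        thr = thr_in_gene if ins.in_gene else config.conditional_alpha
        flagged.append(InstrumentRecord(
            variant=ins.variant, f_stat=ins.f_stat,
            conditional_beta=ins.conditional_beta,
            conditional_se=ins.conditional_se,
            conditional_pval=ins.conditional_pval,
            in_gene=ins.in_gene, is_lead=False,
            conditional_pass=ins.conditional_pval < thr,
        ))
    counts["instruments"] = len(flagged)
    counts["conditional_fail"] = sum(1 for i in flagged if not i.conditional_pass)
    counts["lead"] = lead.rsid
    counts["conditional_threshold_in_gene"] = thr_in_gene
    return SelectionResult(flagged, counts)


def instruments_to_frame(instruments: Sequence[InstrumentRecord]) -> pd.DataFrame:
    rows = [{
        "rsid": i.rsid, "chrom": i.variant.chrom, "pos": i.variant.pos,
        "effect_allele": i.variant.effect_allele, "other_allele": i.variant.other_allele,
        "eaf": i.variant.eaf, "beta": i.variant.beta, "se": i.variant.se,
        "pval": i.variant.pval, "f_stat": i.f_stat,
        "conditional_beta": i.conditional_beta, "conditional_se": i.conditional_se,
        "conditional_pval": i.conditional_pval,
        "in_gene": i.in_gene, "is_lead": i.is_lead,
        "conditional_pass": i.conditional_pass,
    } for i in instruments]
    return pd.DataFrame(rows)
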