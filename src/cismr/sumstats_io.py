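"""Reading, validation, orientation and harmonization of GWAS summary statistics.

Two-sample MR works on per-variant association records from an exposure study
(here a quantitative trait measured in SD units, e.g. circulating CRP) and an
outcome study (typically binary, effects on the log-odds scale). This module
provides the record containers, a dialect-driven tab/whitespace-delimited
reader, orientation of exposure effects to a single documented direction, and
allele harmonization of exposure/outcome pairs including strand-complement
matching and palindromic-variant handling.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field names a column dialect must map (n_cases/n_controls optional)
MANDATORY_FIELDS = (
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record in one GWAS.

    ``beta`` is the additive effect per copy of ``effect_allele``: SD units for
    quantitative traits, log-odds for binary traits.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    n_cases: float | None = None
    n_controls: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: alleles must be single A/C/G/T bases")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1]")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1]")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G variants cannot be strand-resolved from alleles alone."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a common effect allele.

    ``palindromic_dropped_reason`` is set (and the pair excluded from analysis)
    when harmonization could not establish a trustworthy orientation.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    orientation_flipped: bool = False
    palindromic_dropped_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.palindromic_dropped_reason is None


def retained_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs that survived harmonization (no drop reason)."""
    return [p for p in pairs if p.retained]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _check_pval_consistency(rec: VariantAssoc) -> None:
    # normal-approximation p from |z|; warn when >2 orders of magnitude off
    from scipy import stats

    expected = 2.0 * stats.norm.sf(abs(rec.zscore))
    if expected <= 0 or rec.pval <= 0:
        return
    if abs(math.log10(max(expected, 1e-300)) - math.log10(rec.pval)) > 2.0:
        logger.warning(
            "%s: reported p=%.3g inconsistent with |beta/se| (normal approx %.3g)",
            rec.rsid, rec.pval, expected,
        )


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    check_pvals: bool = False,
) -> list[VariantAssoc]:
    """Read a whitespace/tab-delimited summary-statistics table.

    Parameters
    ----------
    path
        Text file with a header row; ``.gz`` handled transparently.
    dialect
        Mapping from canonical field names (:data:`MANDATORY_FIELDS`, plus
        optionally ``n_cases``/``n_controls``) to the file's column names.
        ``None`` means the file already uses canonical names. Columns are
        never guessed.
    check_pvals
        Also warn when a reported p-value disagrees with |beta/se| by more
        than two orders of magnitude.

    Rows violating a record invariant (se ≤ 0, eaf outside [0,1], bad alleles,
    unparseable numerics) are rejected with a logged reason; a duplicated rsid
    is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(dialect) if dialect else {f: f for f in MANDATORY_FIELDS}
    missing = [f for f in MANDATORY_FIELDS if f not in dialect]
    if missing:
        raise ValueError(f"dialect does not map mandatory fields: {missing}")

    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    absent = [c for c in dialect.values() if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing mandatory columns {absent}")

    records: list[VariantAssoc] = []
    seen: set[str] = set()
    rejects = 0
    for idx, row in df.iterrows():
        try:
            kwargs: dict = {
                "rsid": str(row[dialect["rsid"]]),
                "chrom": str(row[dialect["chrom"]]),
                "pos": int(float(row[dialect["pos"]])),
                "effect_allele": str(row[dialect["effect_allele"]]).upper(),
                "other_allele": str(row[dialect["other_allele"]]).upper(),
                "eaf": float(row[dialect["eaf"]]),
                "beta": float(row[dialect["beta"]]),
                "se": float(row[dialect["se"]]),
                "pval": float(row[dialect["pval"]]),
                "n": float(row[dialect["n"]]),
            }
            for opt in ("n_cases", "n_controls"):
                if opt in dialect and dialect[opt] in df.columns:
                    val = row[dialect[opt]]
                    kwargs[opt] = float(val) if pd.notna(val) else None
            rec = VariantAssoc(**kwargs)
        except (ValueError, TypeError) as exc:
            rejects += 1
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
            continue
        if rec.rsid in seen:
            raise ValueError(f"{path}: duplicate rsid {rec.rsid!r}")
        seen.add(rec.rsid)
        if check_pvals:
            _check_pval_consistency(rec)
        records.append(rec)
    if rejects:
        logger.warning("%s: rejected %d malformed row(s)", path.name, rejects)
    return records


def write_sumstats(records: Sequence[VariantAssoc], path: str | Path) -> None:
    """Write records as a canonical tab-delimited table (gzip by suffix)."""
    rows = []
    for r in records:
        rows.append({
            "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": repr(r.eaf), "beta": repr(r.beta), "se": repr(r.se),
            "pval": repr(r.pval), "n": repr(r.n),
            "n_cases": "" if r.n_cases is None else repr(r.n_cases),
            "n_controls": "" if r.n_controls is None else repr(r.n_controls),
        })
    df = pd.DataFrame(rows)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def write_harmonized(pairs: Sequence[HarmonizedPair], path: str | Path) -> None:
    rows = [{
        "rsid": p.rsid,
        "beta_exp": repr(p.beta_exp), "se_exp": repr(p.se_exp),
        "beta_out": repr(p.beta_out), "se_out": repr(p.se_out),
        "orientation_flipped": p.orientation_flipped,
        "palindromic_dropped_reason": p.palindromic_dropped_reason or "",
    } for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | Path) -> list[HarmonizedPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        reason = row.get("palindromic_dropped_reason")
        out.append(HarmonizedPair(
            rsid=str(row["rsid"]),
            beta_exp=float(row["beta_exp"]), se_exp=float(row["se_exp"]),
            beta_out=float(row["beta_out"]), se_out=float(row["se_out"]),
            orientation_flipped=str(row["orientation_flipped"]) == "True",
            palindromic_dropped_reason=None if pd.isna(reason) or reason == "" else str(reason),
        ))
    return out


# ---------------------------------------------------------------------------
# orientation and harmonization
# ---------------------------------------------------------------------------

def orient_to_exposure_decreasing(records: Sequence[VariantAssoc]) -> list[VariantAssoc]:
    """Orient exposure records so every beta is non-negative.

    Records with beta < 0 have their alleles swapped, eaf replaced by 1−eaf
    and beta negated. Magnitudes, standard errors and p-values are untouched.
    After this step the analysis treats the exposure axis as "one SD of
    exposure decrease", so downstream causal effects are expressed per unit
    decrease (protective effects appear as negative θ).
    """
    out: list[VariantAssoc] = []
    for rec in records:
        if rec.beta < 0:
            out.append(replace(
                rec,
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
                eaf=1.0 - rec.eaf,
                beta=-rec.beta,
            ))
        else:
            if rec.beta == 0:
                logger.warning("%s: beta == 0, uninformative instrument", rec.rsid)
            out.append(rec)
    return out


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def harmonize(
    exposure: Sequence[VariantAssoc],
    outcome: Sequence[VariantAssoc],
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Match exposure and outcome records on rsid and align effect alleles.

    Alignment rules, with (e1, o1) the exposure alleles and (e2, o2) the
    outcome alleles:

    * identical pair → no flip;
    * swapped pair → outcome beta negated;
    * strand complement of identical → no flip;
    * strand complement of swapped → negated;
    * anything else → dropped, reason ``allele-mismatch``.

    Palindromic variants (A/T, C/G) are retained only when the effect-allele
    frequencies in both studies fall on the same side of 0.5 and both lie
    outside ``[0.5 − w, 0.5 + w]`` with ``w = palindrome_eaf_window``;
    otherwise the pair is kept in the output with reason
    ``palindromic-ambiguous`` and excluded from analysis.

    Raises
    ------
    ValueError
        If no rsid matches at all (with a diagnostic listing).
    """
    by_rsid = {r.rsid: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    n_matched = 0
    drops: dict[str, int] = {}

    for exp in exposure:
        out = by_rsid.get(exp.rsid)
        if out is None:
            continue
        n_matched += 1
        e1, o1 = exp.effect_allele, exp.other_allele
        e2, o2 = out.effect_allele, out.other_allele
        ce2, co2 = _complement(e2), _complement(o2)

        flip: bool | None = None
        if (e2, o2) == (e1, o1):
            flip = False
        elif (e2, o2) == (o1, e1):
            flip = True
        elif (ce2, co2) == (e1, o1):
            flip = False
        elif (ce2, co2) == (o1, e1):
            flip = True

        reason: str | None = None
        beta_out = out.beta
        if flip is None:
            reason = "allele-mismatch"
        else:
            if flip:
                beta_out = -out.beta
            if exp.is_palindromic():
                # outcome eaf expressed for the exposure effect allele
                out_eaf = 1.0 - out.eaf if flip else out.eaf
                w = palindrome_eaf_window
                same_side = (exp.eaf - 0.5) * (out_eaf - 0.5) > 0
                both_clear = (abs(exp.eaf - 0.5) > w) and (abs(out_eaf - 0.5) > w)
                if not (same_side and both_clear):
                    reason = "palindromic-ambiguous"

        if reason is not None:
            drops[reason] = drops.get(reason, 0) + 1
        pairs.append(HarmonizedPair(
            rsid=exp.rsid,
            beta_exp=exp.beta, se_exp=exp.se,
            beta_out=beta_out if reason is None else out.beta,
            se_out=out.se,
            orientation_flipped=bool(flip) if flip is not None else False,
            palindromic_dropped_reason=reason,
        ))

    if n_matched == 0:
        exp_ids = sorted(r.rsid for r in exposure)[:10]
        out_ids = sorted(by_rsid)[:10]
        raise ValueError(
            "no variant matched between exposure and outcome; "
            f"exposure rsids (first 10): {exp_ids}; outcome rsids (first 10): {out_ids}"
        )
    unmatched = len(exposure) - n_matched
    if unmatched or drops:
        logger.info("harmonize: %d matched, %d unmatched, drops=%s", n_matched, unmatched, drops)
    return pairs


def harmonization_report(
    exposure: Sequence[VariantAssoc],
    pairs: Sequence[HarmonizedPair],
) -> dict:
    """Match/drop bookkeeping for the JSON run report."""
    drops: dict[str, int] = {}
    for p in pairs:
        if p.palindromic_dropped_reason:
            drops[p.palindromic_dropped_reason] = drops.get(p.palindromic_dropped_reason, 0) + 1
    return {
        "n_exposure": len(exposure),
        "n_matched": len(pairs),
        "n_unmatched": len(exposure) - len(pairs),
        "n_retained": sum(p.retained for p in pairs),
        "drop_reasons": drops,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
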