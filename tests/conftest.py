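import numpy as np
import pytest

from cismr.sumstats_io import HarmonizedPair, VariantAssoc


def make_variant(
    rsid="rs1", chrom="1", pos=100, effect_allele="A", other_allele="G",
    eaf=0.3, beta=0.1, se=0.01, pval=None, n=100_000, **kw,
):
    """Variant record with a self-consistent normal-approximation p-value."""
    if pval is None:
        from scipy import stats
        z = beta / se if se > 0 else 0.0
        pval = float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))
    return VariantAssoc(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
        other_allele=other_allele, eaf=eaf, beta=beta, se=se, pval=pval, n=n, **kw,
    )


def make_pair(rsid="rs1", beta_exp=0.1, se_exp=0.004, beta_out=-0.03, se_out=0.01, **kw):
    return HarmonizedPair(rsid=rsid, beta_exp=beta_exp, se_exp=se_exp,
                          beta_out=beta_out, se_out=se_out, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sumstats_file(tmp_path):
    """Three-row well-formed exposure table in the canonical dialect."""
    path = tmp_path / "exposure.tsv"
    path.write_text(
        "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
        "rs1\t1\t1000\tA\tG\t0.30\t0.10\t0.01\t1e-23\t100000\n"
        "rs2\t1\t2000\tC\tT\t0.45\t-0.08\t0.01\t1.3e-15\t100000\n"
        "rs3\t1\t3000\tG\tA\t0.12\t0.05\t0.012\t3.1e-5\t100000\n"
    )
    return path
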