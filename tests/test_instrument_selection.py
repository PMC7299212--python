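"""Cis window, significance filter, LD clumping, conditional analysis, F stats."""

import numpy as np
import pytest
from scipy import stats

from cismr.instrument_selection import (
    LDMatrix, LDMatrixError, SelectionConfig, conditional_on_lead, f_statistic,
    filter_significant, ld_clump, read_ld_matrix, select_cis, select_instruments,
    write_ld_matrix,
)
from cismr.sumstats_io import orient_to_exposure_decreasing
from cismr.synthetic_data import SimulationConfig, simulate_cis_region
from conftest import make_variant


def ar1_ld(rsids, rho):
    k = len(rsids)
    r = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    return LDMatrix(list(rsids), r)


class TestSelectCis:
    GENE = dict(gene_chrom="1", gene_start=10_000, gene_end=20_000, flank=1_000)

    def test_window_boundaries_inclusive(self):
        at_edge = make_variant(pos=9_000)
        past_edge = make_variant(rsid="rs2", pos=8_999)
        out = select_cis([at_edge, past_edge], **self.GENE)
        assert out == [at_edge]

    def test_other_chromosome_excluded(self):
        rec = make_variant(pos=15_000, chrom="2")
        assert select_cis([rec], **self.GENE) == []

    def test_matches_brute_force_interval_count(self):
        recs = [make_variant(rsid=f"rs{i}", pos=p)
                for i, p in enumerate(range(5_000, 30_000, 2_500))]
        got = select_cis(recs, **self.GENE)
        lo, hi = 9_000, 21_000
        assert got == [r for r in recs if lo <= r.pos <= hi]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            select_cis([], "1", 20, 10, 100)
        with pytest.raises(ValueError):
            select_cis([], "1", 10, 20, -1)


class TestFilterSignificant:
    def test_threshold_is_strict(self):
        exact = make_variant(pval=5e-8)
        below = make_variant(rsid="rs2", pval=4.9e-8)
        assert filter_significant([exact, below], 5e-8) == [below]

    def test_matches_one_line_oracle(self, rng):
        recs = [make_variant(rsid=f"rs{i}", pval=float(p))
                for i, p in enumerate(rng.uniform(1e-10, 1e-6, size=30))]
        thr = 5e-8
        assert filter_significant(recs, thr) == [r for r in recs if r.pval < thr]


def brute_force_clump(records, ld, r2_threshold):
    """Independent re-coding of the textual greedy rule, list-based."""
    remaining = sorted(records, key=lambda r: (r.pval, r.pos, r.rsid))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [r for r in remaining
                     if ld.corr(best.rsid, r.rsid) ** 2 < r2_threshold]
    kept_ids = {r.rsid for r in kept}
    return [r for r in records if r.rsid in kept_ids]


class TestLDClump:
    def test_uncorrelated_all_retained(self):
        recs = [make_variant(rsid=f"rs{i}", pos=i, pval=1e-9 * (i + 1)) for i in range(5)]
        ld = ar1_ld([r.rsid for r in recs], 0.0)
        assert ld_clump(recs, ld, 0.1) == recs

    def test_perfect_ld_collapses_to_smallest_p(self):
        recs = [make_variant(rsid=f"rs{i}", pos=i, pval=p)
                for i, p in enumerate([1e-8, 1e-12, 1e-9])]
        ld = LDMatrix([r.rsid for r in recs], np.ones((3, 3)))
        assert ld_clump(recs, ld, 0.1) == [recs[1]]

    def test_missing_rsid_fatal(self):
        recs = [make_variant(rsid="rsX")]
        ld = ar1_ld(["rsY"], 0.0)
        with pytest.raises(LDMatrixError, match="rsX"):
            ld_clump(recs, ld, 0.1)

    def test_matches_independent_brute_force_oracle(self, rng):
        """Random 8-variant instances against a second implementation."""
        for trial in range(300):
            k = 8
            a = rng.uniform(-1, 1, size=(k, k))
            r = np.corrcoef(a @ a.T + np.eye(k) * 0.5)
            rsids = [f"rs{i}" for i in range(k)]
            ld = LDMatrix(rsids, r)
            recs = [make_variant(rsid=rsids[i], pos=i * 10,
                                 pval=float(rng.uniform(1e-12, 1e-6)))
                    for i in range(k)]
            got = ld_clump(recs, ld, 0.1)
            want = brute_force_clump(recs, ld, 0.1)
            assert got == want, f"trial {trial}"

    def test_output_invariant_to_input_order(self, rng):
        k = 8
        a = rng.uniform(-1, 1, size=(k, k))
        r = np.corrcoef(a @ a.T + np.eye(k))
        rsids = [f"rs{i}" for i in range(k)]
        ld = LDMatrix(rsids, r)
        recs = [make_variant(rsid=rsids[i], pos=i * 10, pval=float(p))
                for i, p in enumerate(rng.uniform(1e-12, 1e-6, size=k))]
        baseline = {x.rsid for x in ld_clump(recs, ld, 0.1)}
        for _ in range(5):
            perm = [recs[i] for i in rng.permutation(k)]
            assert {x.rsid for x in ld_clump(perm, ld, 0.1)} == baseline

    def test_ties_broken_by_position_then_rsid(self):
        recs = [make_variant(rsid="rsB", pos=200, pval=1e-9),
                make_variant(rsid="rsA", pos=100, pval=1e-9)]
        ld = LDMatrix(["rsB", "rsA"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert [r.rsid for r in ld_clump(recs, ld, 0.1)] == ["rsA"]

    def test_retained_pairs_below_threshold(self, rng):
        k = 8
        a = rng.uniform(-1, 1, size=(k, k))
        r = np.corrcoef(a @ a.T + np.eye(k))
        rsids = [f"rs{i}" for i in range(k)]
        ld = LDMatrix(rsids, r)
        recs = [make_variant(rsid=rsids[i], pos=i, pval=float(p))
                for i, p in enumerate(rng.uniform(1e-12, 1e-6, size=k))]
        kept = ld_clump(recs, ld, 0.1)
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                assert ld.corr(x.rsid, y.rsid) ** 2 < 0.1


class TestConditionalOnLead:
    def test_zero_ld_is_identity_on_zscores(self):
        lead = make_variant(rsid="lead", beta=0.12, se=0.005)
        other = make_variant(rsid="other", pos=200, beta=0.05, se=0.006)
        ld = LDMatrix(["lead", "other"], np.eye(2))
        out = {i.rsid: i for i in conditional_on_lead([lead, other], "lead", ld)}
        rec = out["other"]
        assert rec.conditional_beta / rec.conditional_se == pytest.approx(
            other.beta / other.se, abs=1e-10)

    def test_pure_proxy_gets_conditional_p_of_one(self):
        # z_j = r * z_lead exactly -> conditional z = 0
        lead = make_variant(rsid="lead", beta=0.10, se=0.005)
        z_lead = 0.10 / 0.005
        r = 0.6
        other = make_variant(rsid="other", pos=200, beta=r * z_lead * 0.006, se=0.006)
        mat = LDMatrix(["lead", "other"], np.array([[1.0, r], [r, 1.0]]))
        out = {i.rsid: i for i in conditional_on_lead([lead, other], "lead", mat)}
        assert out["other"].conditional_pval == pytest.approx(1.0)
        assert out["other"].conditional_beta == pytest.approx(0.0, abs=1e-12)

    def test_lead_keeps_marginal_values(self):
        lead = make_variant(rsid="lead", beta=0.12, se=0.005)
        other = make_variant(rsid="other", pos=200, beta=0.05, se=0.006)
        ld = ar1_ld(["lead", "other"], 0.4)
        out = {i.rsid: i for i in conditional_on_lead([lead, other], "lead", ld)}
        assert out["lead"].conditional_beta == lead.beta
        assert out["lead"].conditional_pval == lead.pval
        assert out["lead"].is_lead

    def test_collinear_with_lead_fatal(self):
        lead = make_variant(rsid="lead")
        other = make_variant(rsid="other", pos=200)
        ld = LDMatrix(["lead", "other"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="collinear"):
            conditional_on_lead([lead, other], "lead", ld)

    def test_agrees_with_individual_level_regression(self):
        """Summary-level two-variant conditioning vs exact joint least squares
        on individual-level data simulated with r = 0.5, n = 50 000."""
        rng = np.random.default_rng(2024)
        n, r = 50_000, 0.5
        g = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
        y = 0.05 * g[:, 0] + 0.03 * g[:, 1] + rng.standard_normal(n)

        recs = []
        for j, rs in enumerate(["lead", "other"]):
            x = g[:, j]
            b = np.cov(x, y)[0, 1] / np.var(x)
            se = float(np.sqrt(np.var(y - b * x) / (n * np.var(x))))
            recs.append(make_variant(rsid=rs, pos=j + 1, beta=float(b), se=se))
        ld = LDMatrix(["lead", "other"], np.array([[1.0, r], [r, 1.0]]))
        out = {i.rsid: i for i in conditional_on_lead(recs, "lead", ld)}
        z_cond = out["other"].conditional_beta / out["other"].conditional_se

        X = np.column_stack([np.ones(n), g])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        cov = (resid @ resid / (n - 3)) * np.linalg.inv(X.T @ X)
        z_joint = coef[2] / np.sqrt(cov[2, 2])
        assert z_cond == pytest.approx(z_joint, abs=0.2)


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.09, 0.01, 81.0),
        (-0.2, 0.02, 100.0),
    ])
    def test_examples(self, beta, se, expected):
        assert f_statistic(make_variant(beta=beta, se=se)) == pytest.approx(expected)

    def test_zero_beta(self):
        assert f_statistic(make_variant(beta=0.0, pval=1.0)) == 0.0

    def test_nonnegative_and_monotone_in_abs_z(self, rng):
        zs = np.sort(np.abs(rng.normal(size=20)))
        fs = [f_statistic(make_variant(beta=float(z) * 0.01, se=0.01,
                                       pval=float(2 * stats.norm.sf(z)) or 1e-300))
              for z in zs]
        assert all(f >= 0 for f in fs)
        assert all(a <= b + 1e-12 for a, b in zip(fs, fs[1:]))


class TestSelectInstruments:
    def _config(self, cfg):
        return SelectionConfig(gene_chrom=cfg.cis.chrom,
                               gene_start=cfg.cis.gene_start,
                               gene_end=cfg.cis.gene_end,
                               flank=cfg.cis.flank)

    def test_planted_region_yields_exactly_three_instruments(self):
        cfg = SimulationConfig(seed=7)
        region, ld, truth = simulate_cis_region(cfg)
        oriented = orient_to_exposure_decreasing(region)
        res = select_instruments(oriented, ld, self._config(cfg))
        assert sorted(i.rsid for i in res.instruments) == sorted(truth["causal_rsids"])
        lead = [i for i in res.instruments if i.is_lead]
        assert len(lead) == 1 and lead[0].rsid == truth["lead_rsid"]

    def test_empty_after_significance_filter(self):
        recs = [make_variant(rsid=f"rs{i}", pos=15_000 + i, beta=0.001, se=0.01)
                for i in range(3)]
        ld = ar1_ld([r.rsid for r in recs], 0.2)
        res = select_instruments(recs, ld, SelectionConfig(
            gene_chrom="1", gene_start=10_000, gene_end=20_000, flank=1_000))
        assert res.instruments == []
        assert res.counts["significant"] == 0

    def test_all_tagging_lead_collapses_to_one(self):
        recs = [make_variant(rsid=f"rs{i}", pos=15_000 + i, beta=0.1 - 0.001 * i,
                             se=0.01) for i in range(4)]
        ld = ar1_ld([r.rsid for r in recs], 0.95)
        res = select_instruments(recs, ld, SelectionConfig(
            gene_chrom="1", gene_start=10_000, gene_end=20_000, flank=1_000))
        assert len(res.instruments) == 1
        assert res.instruments[0].is_lead

    def test_per_stage_counts_are_reported(self):
        cfg = SimulationConfig(seed=3)
        region, ld, _ = simulate_cis_region(cfg)
        res = select_instruments(orient_to_exposure_decreasing(region), ld,
                                 self._config(cfg))
        c = res.counts
        assert c["input"] >= c["cis_window"] >= c["significant"] >= c["clumped"]
        assert c["instruments"] == len(res.instruments)

    def test_recovery_rate_on_simulated_regions(self):
        """Planted independent signals recovered in >= 95% of seeded replicates."""
        ok = 0
        n_rep = 200
        for s in range(n_rep):
            cfg = SimulationConfig(seed=s)
            region, ld, truth = simulate_cis_region(cfg)
            res = select_instruments(orient_to_exposure_decreasing(region), ld,
                                     self._config(cfg))
            ok += sorted(i.rsid for i in res.instruments) == sorted(truth["causal_rsids"])
        assert ok / n_rep >= 0.95


class TestLDMatrixIO:
    def test_roundtrip(self, tmp_path, rng):
        k = 5
        a = rng.uniform(-1, 1, size=(k, k))
        r = np.corrcoef(a @ a.T + np.eye(k))
        ld = LDMatrix([f"rs{i}" for i in range(k)], r)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.rsids == ld.rsids
        np.testing.assert_allclose(back.r, ld.r, atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        r = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(LDMatrixError, match="symmetric"):
            LDMatrix(["a", "b"], r)

    def test_non_unit_diagonal_rejected(self):
        r = np.array([[1.0, 0.2], [0.2, 0.9]])
        with pytest.raises(LDMatrixError, match="diagonal"):
            LDMatrix(["a", "b"], r)
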