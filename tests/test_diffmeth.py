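import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nactmeth import diffmeth, preprocess as pp
from nactmeth.io_model import MValueMatrix, SampleSheet
from nactmeth.synthetic_cohort import SimulationConfig, generate_cohort


def _dense_gls_oracle(y, x, v):
    """Brute-force GLS via explicit covariance inversion."""
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    r = y - x @ beta
    dof = len(y) - x.shape[1]
    return beta[1], (r @ vi @ r) / dof


def _design_for(sheet, sample_ids, rho):
    x = []
    for sid in sample_ids:
        tp = sheet.data.set_index("sample_id").loc[sid, "timepoint"]
        x.append([1.0, 1.0 if tp == "post" else 0.0])
    x = np.array(x)
    n = len(sample_ids)
    v = np.eye(n)
    pos = {s: i for i, s in enumerate(sample_ids)}
    for pid in sheet.paired_patients():
        i, j = pos[sheet.pairing[pid]["pre"]], pos[sheet.pairing[pid]["post"]]
        v[i, j] = v[j, i] = rho
    return x, v


class TestConsensusCorrelation:
    def test_recovers_planted_correlation(self):
        cfg = SimulationConfig(
            n_patients=40, n_pre_only=0, n_post_only=0, n_cpg=500,
            n_affected_cpgs=1, n_causal_cpgs=1, effect_size_m=0.0, causal_effect_m=0.0,
            intra_patient_correlation=0.5, seed=31,
        )
        cohort = generate_cohort(cfg)
        m = pp.beta_to_m(cohort.beta)
        cons = diffmeth.estimate_consensus_correlation(m, cohort.sheet)
        assert 0.40 <= cons.consensus <= 0.60

    def test_zero_correlation_recovered(self):
        cfg = SimulationConfig(
            n_patients=40, n_pre_only=0, n_post_only=0, n_cpg=500,
            n_affected_cpgs=1, n_causal_cpgs=1, effect_size_m=0.0, causal_effect_m=0.0,
            intra_patient_correlation=0.0, seed=37,
        )
        cohort = generate_cohort(cfg)
        m = pp.beta_to_m(cohort.beta)
        cons = diffmeth.estimate_consensus_correlation(m, cohort.sheet)
        assert abs(cons.consensus) < 0.10

    def test_constant_cpg_excluded(self, paired_sheet_factory):
        sheet = paired_sheet_factory(5)
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 10))
        vals[3] = 1.0  # constant row
        m = MValueMatrix(
            pd.DataFrame(vals, index=[f"cg{i}" for i in range(20)],
                         columns=sheet.sample_ids)
        )
        cons = diffmeth.estimate_consensus_correlation(m, sheet)
        assert cons.n_cpgs_used == 19
        assert "cg3" not in cons.per_cpg.index

    def test_requires_pairing(self):
        rows = [
            {"sample_id": f"s{i}", "patient_id": f"p{i}", "timepoint": tp,
             "survival_group": "survivor", "survival_time": 5.0, "event": 0}
            for i, tp in enumerate(["pre", "pre", "post", "post"])
        ]
        sheet = SampleSheet(pd.DataFrame(rows))
        m = MValueMatrix(
            pd.DataFrame(np.zeros((3, 4)), index=list("abc"),
                         columns=[f"s{i}" for i in range(4)])
        )
        with pytest.raises(ValueError, match="pairing required"):
            diffmeth.estimate_consensus_correlation(m, sheet)


class TestGLSFit:
    def test_matches_dense_oracle(self, paired_sheet_factory):
        sheet = paired_sheet_factory(3)  # 6 samples
        rng = np.random.default_rng(42)
        y = rng.normal(size=(8, 6))
        sample_ids = list(sheet.sample_ids)
        m = MValueMatrix(
            pd.DataFrame(y, index=[f"cg{i}" for i in range(8)], columns=sample_ids)
        )
        fits = diffmeth.fit_gls_per_cpg(m, sheet, 0.5)
        x, v = _design_for(sheet, sample_ids, 0.5)
        for g in range(8):
            eff, s2 = _dense_gls_oracle(y[g], x, v)
            assert fits["effect"].iloc[g] == pytest.approx(eff, abs=1e-8)
            assert fits["s2"].iloc[g] == pytest.approx(s2, abs=1e-8)

    def test_mixed_paired_unpaired_matches_oracle(self):
        rows = []
        for p in ("a", "b"):
            for tp in ("pre", "post"):
                rows.append({"sample_id": f"{p}_{tp}", "patient_id": p,
                             "timepoint": tp, "survival_group": "survivor",
                             "survival_time": 5.0, "event": 0})
        rows.append({"sample_id": "c_pre", "patient_id": "c", "timepoint": "pre",
                     "survival_group": "survivor", "survival_time": 5.0, "event": 0})
        rows.append({"sample_id": "d_post", "patient_id": "d", "timepoint": "post",
                     "survival_group": "survivor", "survival_time": 5.0, "event": 0})
        sheet = SampleSheet(pd.DataFrame(rows))
        rng = np.random.default_rng(1)
        y = rng.normal(size=(5, 6))
        sample_ids = [r["sample_id"] for r in rows]
        m = MValueMatrix(
            pd.DataFrame(y, index=[f"cg{i}" for i in range(5)], columns=sample_ids)
        )
        fits = diffmeth.fit_gls_per_cpg(m, sheet, 0.4)
        x, v = _design_for(sheet, sample_ids, 0.4)
        for g in range(5):
            eff, s2 = _dense_gls_oracle(y[g], x, v)
            assert fits["effect"].iloc[g] == pytest.approx(eff, abs=1e-8)
            assert fits["s2"].iloc[g] == pytest.approx(s2, abs=1e-8)

    def test_zero_consensus_unpaired_equals_mean_difference(self):
        rows = [
            {"sample_id": f"s{i}", "patient_id": f"p{i}",
             "timepoint": "pre" if i < 3 else "post",
             "survival_group": "survivor", "survival_time": 5.0, "event": 0}
            for i in range(6)
        ]
        sheet = SampleSheet(pd.DataFrame(rows))
        rng = np.random.default_rng(2)
        y = rng.normal(size=(4, 6))
        m = MValueMatrix(
            pd.DataFrame(y, index=[f"cg{i}" for i in range(4)],
                         columns=[f"s{i}" for i in range(6)])
        )
        fits = diffmeth.fit_gls_per_cpg(m, sheet, 0.0)
        expected = y[:, 3:].mean(axis=1) - y[:, :3].mean(axis=1)
        np.testing.assert_allclose(fits["effect"].to_numpy(), expected, atol=1e-10)

    def test_high_consensus_approaches_paired_t(self, paired_sheet_factory):
        n = 30
        sheet = paired_sheet_factory(n)
        rng = np.random.default_rng(7)
        rho_true = (2.0**2) / (2.0**2 + 0.2**2)
        y = np.empty((40, 2 * n))
        for g in range(40):
            base = rng.normal(0, 2.0, n)
            y[g, 0::2] = base + rng.normal(0, 0.2, n)
            y[g, 1::2] = base + 0.3 + rng.normal(0, 0.2, n)
        m = MValueMatrix(
            pd.DataFrame(y, index=[f"cg{i}" for i in range(40)],
                         columns=sheet.sample_ids)
        )
        fits = diffmeth.fit_gls_per_cpg(m, sheet, rho_true)
        t_gls = fits["effect"] / (np.sqrt(fits["s2"]) * fits["se_unit"])
        t_paired = np.array(
            [stats.ttest_1samp(y[g, 1::2] - y[g, 0::2], 0).statistic for g in range(40)]
        )
        rel = np.abs(t_gls.to_numpy() - t_paired) / np.abs(t_paired)
        assert np.median(rel) < 0.15

    def test_missing_values_skip_underpowered_cpgs(self, paired_sheet_factory):
        sheet = paired_sheet_factory(4)
        rng = np.random.default_rng(3)
        y = rng.normal(size=(3, 8))
        y[0, [1, 3, 5]] = np.nan  # only one post sample left
        m = MValueMatrix(
            pd.DataFrame(y, index=[f"cg{i}" for i in range(3)],
                         columns=sheet.sample_ids)
        )
        fits = diffmeth.fit_gls_per_cpg(m, sheet, 0.3)
        assert "cg0" not in fits.index
        assert len(fits) == 2


class TestModeration:
    def _fits(self, s2, df=10):
        n = len(s2)
        return pd.DataFrame(
            {"effect": np.ones(n), "s2": s2, "df": df, "se_unit": 1.0},
            index=[f"cg{i}" for i in range(n)],
        )

    def test_identical_variances_give_infinite_prior_df(self):
        params, mod = diffmeth.empirical_bayes_moderate(self._fits(np.full(50, 0.7)))
        assert np.isinf(params.d0)
        np.testing.assert_allclose(params.posterior_sq, 0.7, atol=1e-12)

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(8)
        s2 = 0.5 * rng.chisquare(6, 200) / 6
        params, _ = diffmeth.empirical_bayes_moderate(self._fits(s2, df=6))
        lo = np.minimum(s2, params.s0_sq)
        hi = np.maximum(s2, params.s0_sq)
        assert ((params.posterior_sq >= lo - 1e-12) & (params.posterior_sq <= hi + 1e-12)).all()

    def test_weak_prior_limit_matches_ordinary_t(self):
        # huge spread in variances drives the prior df toward zero, and the
        # moderated t then collapses to the ordinary t wherever the prior
        # term d0*s0^2 is negligible against d*s^2
        rng = np.random.default_rng(9)
        s2 = np.exp(rng.normal(0, 4, 300))
        fits = self._fits(s2, df=20)
        params, mod = diffmeth.empirical_bayes_moderate(fits)
        assert params.d0 < 1.0
        t_ord = fits["effect"] / np.sqrt(fits["s2"])
        keep = s2 >= params.s0_sq
        ratio = (mod["t"][keep] / t_ord[keep]).to_numpy()
        assert np.abs(ratio - 1).max() < 0.05

    def test_requires_ten_cpgs(self):
        with pytest.raises(ValueError, match="at least 10"):
            diffmeth.empirical_bayes_moderate(self._fits(np.ones(5)))

    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(
            n_patients=40, n_pre_only=0, n_post_only=0, n_cpg=1000,
            n_affected_cpgs=1, n_causal_cpgs=1, effect_size_m=0.0, causal_effect_m=0.0, seed=41,
        )
        cohort = generate_cohort(cfg)
        m = pp.beta_to_m(cohort.beta)
        table = diffmeth.run_comparison(m, cohort.sheet)
        assert 0.035 <= (table["p"] < 0.05).mean() <= 0.065


class TestBHAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            diffmeth.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert diffmeth.bh_adjust([0.3])[0] == 0.3

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        adj = diffmeth.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(
            diffmeth.bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffmeth.bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        n_cpg=500, n_affected_cpgs=80, effect_distribution="fixed", seed=43
    )
    cohort = generate_cohort(cfg)
    m = pp.beta_to_m(cohort.beta)
    results = diffmeth.run_group_comparisons(m, cohort.sheet, beta=cohort.beta)
    return cohort, results


class TestGroupComparisons:

    def test_survivor_signal_recovered(self, planted):
        cohort, results = planted
        table = results["survivor"]
        planted_ids = cohort.truth.affected_direction.index
        sens = table.loc[
            table.index.intersection(planted_ids), "significant"
        ].mean()
        assert sens > 0.9

    def test_non_survivors_mostly_null(self, planted):
        cohort, results = planted
        table = results["non_survivor"]
        # only the handful of risk-coupled causal CpGs may reach significance
        assert table["significant"].mean() <= 0.02

    def test_direction_matches_planted_sign(self, planted):
        cohort, results = planted
        table = results["survivor"]
        sig = table[table["significant"]]
        truth = cohort.truth.affected_direction
        common = sig.index.intersection(truth.index)
        expected = np.where(truth.loc[common] > 0, "gain", "loss")
        agree = (sig.loc[common, "direction"] == expected).mean()
        assert agree > 0.95

    def test_alpha_one_flags_everything(self, planted):
        cohort, _ = planted
        m = pp.beta_to_m(cohort.beta)
        table = diffmeth.run_comparison(m, cohort.sheet, alpha=1.0)
        assert table["significant"].all()

    def test_single_level_grouping_equals_whole_cohort(self, planted):
        cohort, _ = planted
        m = pp.beta_to_m(cohort.beta)
        sheet = cohort.sheet
        df = sheet.data.copy()
        df["cohort"] = "all"
        sheet2 = SampleSheet(df)
        grouped = diffmeth.run_group_comparisons(m, sheet2, groups="cohort")
        whole = diffmeth.run_comparison(m, sheet2)
        np.testing.assert_allclose(
            grouped["all"]["p"].to_numpy(), whole["p"].to_numpy(), atol=1e-12
        )

    def test_row_permutation_invariance(self, planted):
        cohort, results = planted
        rng = np.random.default_rng(12)
        m = pp.beta_to_m(cohort.beta)
        perm_rows = rng.permutation(m.values.index)
        perm_cols = rng.permutation(m.values.columns)
        m_perm = MValueMatrix(m.values.loc[perm_rows, perm_cols])
        table = diffmeth.run_comparison(m_perm, cohort.sheet)
        base = diffmeth.run_comparison(m, cohort.sheet)
        joined = base[["p"]].join(table[["p"]], rsuffix="_perm")
        np.testing.assert_allclose(joined["p"], joined["p_perm"], atol=1e-10)
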