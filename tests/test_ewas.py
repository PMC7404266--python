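import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tsmeth.ewas import (
    bonferroni_threshold,
    discovery_replication,
    dmp_association,
    select_probes_in_regions,
)
from tsmeth.gene_model import PromoterRegion


def make_pheno(n_cases, n_controls, rng, age=None):
    n = n_cases + n_controls
    return pd.DataFrame(
        {
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "age": rng.normal(50, 8, n) if age is None else age,
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        },
        index=[f"s{i}" for i in range(n)],
    )


def make_betas(values, samples):
    values = np.atleast_2d(values)
    return pd.DataFrame(
        values, index=[f"p{i}" for i in range(len(values))], columns=samples
    )


class TestSelectProbes:
    REGIONS = [PromoterRegion("g1", "expanded", "chr1", 800, 1050, "+")]

    def manifest(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions},
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe"),
        )

    def test_inside_and_boundary_membership(self):
        sel = select_probes_in_regions(self.manifest([900, 1050, 1051, 800]), self.REGIONS)
        # 1-based 900 and 1050 inside [800,1050); 1051 beyond; 800 not (> start)
        assert sorted(sel.index.unique()) == ["cg0", "cg1"]

    def test_probe_in_two_genes_recorded_for_both(self):
        regions = self.REGIONS + [PromoterRegion("g2", "expanded", "chr1", 850, 1200, "+")]
        sel = select_probes_in_regions(self.manifest([900]), regions)
        assert sorted(sel.loc["cg0", "gene_id"]) == ["g1", "g2"]
        assert list(sel.index.unique()) == ["cg0"]

    def test_empty_selection_allowed(self):
        sel = select_probes_in_regions(self.manifest([5000]), self.REGIONS)
        assert sel.empty


class TestDmpAssociation:
    def test_planted_shift_detected_with_positive_sign(self):
        rng = np.random.default_rng(31)
        pheno = make_pheno(200, 200, rng)
        base = rng.normal(0.5, 0.03, 400)
        beta = base + 0.08 * (pheno.status == "case").to_numpy()
        res = dmp_association(make_betas(beta, pheno.index), pheno)
        assert res.p.iloc[0] < 1e-10
        assert res.effect.iloc[0] > 0

    def test_matches_statsmodels_ols(self):
        """Closed-form Wald test agrees with an independent OLS fit."""
        rng = np.random.default_rng(32)
        pheno = make_pheno(40, 60, rng)
        Y = rng.uniform(0.2, 0.8, (5, 100))
        res = dmp_association(make_betas(Y, pheno.index), pheno)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "outcome": (pheno.status == "case").astype(float),
                    "age": pheno.age,
                    "sex": pheno.sex.map({"F": 0.0, "M": 1.0}),
                }
            )
        )
        for i in range(5):
            fit = sm.OLS(Y[i], X).fit()
            assert res.effect.iloc[i] == pytest.approx(fit.params["outcome"], abs=1e-10)
            assert res.se.iloc[i] == pytest.approx(fit.bse["outcome"], abs=1e-10)
            assert res.p.iloc[i] == pytest.approx(fit.pvalues["outcome"], abs=1e-10)

    def test_null_type_one_error_calibrated(self):
        """Null probes reject at alpha=0.05 within +/-1.5 points (1000 reps)."""
        rng = np.random.default_rng(33)
        pheno = make_pheno(50, 50, rng)
        Y = rng.uniform(0.3, 0.7, (1000, 100))
        res = dmp_association(make_betas(Y, pheno.index), pheno)
        rate = (res.p < 0.05).mean()
        assert abs(rate - 0.05) <= 0.015

    def test_age_confounding_removed_by_adjustment(self):
        """Age drives beta but is balanced between classes: effect ~ 0."""
        rng = np.random.default_rng(34)
        age = np.concatenate([rng.normal(50, 8, 200), rng.normal(50, 8, 200)])
        pheno = make_pheno(200, 200, rng, age=age)
        beta = 0.4 + 0.005 * (age - 50) + rng.normal(0, 0.01, 400)
        res = dmp_association(make_betas(beta, pheno.index), pheno)
        assert abs(res.effect.iloc[0]) < 0.01

    def test_constant_probe_flagged_with_missing_p(self):
        rng = np.random.default_rng(35)
        pheno = make_pheno(10, 10, rng)
        res = dmp_association(make_betas(np.full(20, 0.5), pheno.index), pheno)
        assert bool(res.constant.iloc[0])
        assert np.isnan(res.p.iloc[0])

    def test_small_outcome_class_rejected(self):
        rng = np.random.default_rng(36)
        pheno = make_pheno(1, 10, rng)
        with pytest.raises(ValueError, match="outcome class"):
            dmp_association(make_betas(rng.random(11), pheno.index), pheno)

    def test_location_invariance(self):
        rng = np.random.default_rng(37)
        pheno = make_pheno(30, 30, rng)
        y = rng.uniform(0.1, 0.5, 60)
        a = dmp_association(make_betas(y, pheno.index), pheno)
        b = dmp_association(make_betas(y + 0.3, pheno.index), pheno)
        assert a.p.iloc[0] == pytest.approx(b.p.iloc[0], abs=1e-12)

    def test_missing_covariates_dropped_listwise(self):
        rng = np.random.default_rng(38)
        pheno = make_pheno(20, 20, rng)
        pheno.loc["s0", "age"] = np.nan
        res = dmp_association(make_betas(rng.random(40), pheno.index), pheno)
        assert res.n.iloc[0] == 39

    def test_t2d_outcome_with_bmi_covariate(self):
        rng = np.random.default_rng(39)
        pheno = make_pheno(50, 50, rng)
        pheno["t2d"] = ["case", "control"] * 50
        pheno["bmi"] = rng.normal(27, 3, 100)
        res = dmp_association(
            make_betas(rng.random(100), pheno.index),
            pheno,
            outcome="t2d",
            covariates=["age", "sex", "bmi"],
        )
        assert np.isfinite(res.p.iloc[0])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_simple_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_promoter_cpg_count_threshold_printed_precision(self):
        # 0.05 / 4443 = 1.13e-5 at 3 significant figures
        assert float(f"{bonferroni_threshold(0.05, 4443):.3g}") == 1.13e-05

    def test_strictly_decreasing_in_m(self):
        ts = [bonferroni_threshold(0.05, m) for m in (1, 10, 100, 4443)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def stage(probes, ps, effects):
    return pd.DataFrame({"p": ps, "effect": effects}, index=pd.Index(probes, name="probe"))


class TestDiscoveryReplication:
    def test_concordant_probe_validated(self):
        disc = stage(["a", "b"], [1e-8, 0.5], [0.1, 0.1])
        rep = stage(["a", "b"], [0.01, 0.01], [0.2, 0.2])
        res = discovery_replication(disc, rep)
        assert bool(res.loc["a", "validated"])
        assert not bool(res.loc["b", "discovery_pass"])

    def test_opposite_sign_blocks_validation(self):
        disc = stage(["a"], [1e-8], [0.1])
        rep = stage(["a"], [0.04], [-0.2])
        res = discovery_replication(disc, rep)
        assert not bool(res.loc["a", "validated"])
        res2 = discovery_replication(disc, rep, require_sign_concordance=False)
        assert bool(res2.loc["a", "validated"])

    def test_m_counts_only_tested_probes(self):
        disc = stage(["a", "b", "c"], [0.02, np.nan, 0.5], [1, np.nan, 1])
        rep = stage(["a", "b", "c"], [0.01, 0.01, 0.01], [1, 1, 1])
        res = discovery_replication(disc, rep)
        assert res.m_tested.iloc[0] == 2
        assert res.bonferroni_p.iloc[0] == pytest.approx(0.025)
        assert bool(res.loc["a", "discovery_pass"])

    def test_replication_only_probe_warned_and_ignored(self):
        disc = stage(["a"], [1e-8], [1.0])
        rep = stage(["a", "zzz"], [0.01, 0.01], [1.0, 1.0])
        with pytest.warns(UserWarning, match="zzz"):
            res = discovery_replication(disc, rep)
        assert "zzz" not in res.index

    def test_planted_dmps_exactly_recovered(self, ewas_sim):
        """End-to-end: the 3 planted DMPs validate; no null probe does."""
        disc = dmp_association(ewas_sim.discovery_betas, ewas_sim.discovery_pheno)
        rep = dmp_association(ewas_sim.replication_betas, ewas_sim.replication_pheno)
        res = discovery_replication(disc, rep)
        truth = ewas_sim.truth_probes.set_index("probe")
        validated = set(res.index[res.validated])
        planted = set(truth.index[truth.is_dmp])
        assert validated == planted
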