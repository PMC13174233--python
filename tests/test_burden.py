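"""Burden scores, conditional logistic regression, LRT, pseudo-R2, meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from longvar.burden import (
    bootstrap_ci,
    fit_conditional_logistic,
    lrt_burden,
    meta_analyze,
    nagelkerke_r2,
    null_conditional_loglik,
    sv_burden_scores,
)
from longvar.genotype import GenotypeCall, ReadSupport
from longvar.merge import SVRecord
from longvar.simulate import simulate_family_cohort


def matched_pairs(n_exposed_case: int, n_exposed_control: int,
                  n_concordant: int = 5) -> pd.DataFrame:
    """1:1 matched pairs with a binary exposure."""
    rows = []
    fid = 0
    for _ in range(n_exposed_case):  # case exposed, control not
        rows += [
            {"fid": f"F{fid}", "phenotype": 1, "burden": 1},
            {"fid": f"F{fid}", "phenotype": 0, "burden": 0},
        ]
        fid += 1
    for _ in range(n_exposed_control):
        rows += [
            {"fid": f"F{fid}", "phenotype": 1, "burden": 0},
            {"fid": f"F{fid}", "phenotype": 0, "burden": 1},
        ]
        fid += 1
    for _ in range(n_concordant):  # exposure-concordant pairs: uninformative
        rows += [
            {"fid": f"F{fid}", "phenotype": 1, "burden": 1},
            {"fid": f"F{fid}", "phenotype": 0, "burden": 1},
        ]
        fid += 1
    return pd.DataFrame(rows)


class TestConditionalLogistic:
    def test_matched_pair_fit_equals_discordant_pair_estimator(self):
        df = matched_pairs(10, 5)
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        assert fit.params["burden"] == pytest.approx(math.log(10 / 5), abs=1e-4)

    @pytest.mark.parametrize("a,b", [(8, 2), (6, 6), (3, 9)])
    def test_discordant_pair_oracle_across_tables(self, a, b):
        fit = fit_conditional_logistic(
            matched_pairs(a, b), "phenotype", ["burden"]
        )
        assert fit.params["burden"] == pytest.approx(math.log(a / b), abs=1e-4)

    def test_null_effect_is_near_zero(self):
        df = simulate_family_cohort(300, burden_beta=0.0, seed=21)
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        assert abs(fit.params["burden"]) < 3 * fit.bse["burden"] + 0.05

    def test_simulated_effect_recovered(self):
        df = simulate_family_cohort(400, burden_beta=0.8, seed=22)
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        assert fit.params["burden"] == pytest.approx(0.8, abs=3 * fit.bse["burden"])

    def test_duplicated_column_is_rank_deficient(self):
        df = matched_pairs(10, 5)
        df["burden2"] = df["burden"]
        with pytest.raises(ValueError, match="collinear"):
            fit_conditional_logistic(df, "phenotype", ["burden", "burden2"])

    def test_too_few_informative_strata(self):
        df = matched_pairs(1, 0, n_concordant=0)
        df.loc[df["fid"] == "F0", "phenotype"] = [1, 0]
        with pytest.raises(ValueError, match="strata"):
            fit_conditional_logistic(df.assign(phenotype=1), "phenotype",
                                     ["burden"])

    def test_null_loglik_closed_form(self):
        df = matched_pairs(4, 4, n_concordant=3)
        # all 11 pairs are phenotype-discordant, each contributing -log C(2,1)
        assert null_conditional_loglik(df, "phenotype", "fid") == pytest.approx(
            -11 * math.log(2)
        )
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        assert fit.llnull == pytest.approx(-11 * math.log(2))


class TestLRT:
    def test_identical_models_give_p_one(self):
        df = matched_pairs(10, 5)
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        assert lrt_burden(fit, fit, df_diff=0) == 1.0

    def test_df_mismatch_is_an_error(self):
        df = matched_pairs(10, 5)
        full = fit_conditional_logistic(df, "phenotype", ["burden"])
        with pytest.raises(ValueError):
            lrt_burden(full, full.llf + 5.0, df_diff=0)
        with pytest.raises(ValueError):
            lrt_burden(full, full, df_diff=-1)

    def test_simulated_effect_detected(self):
        pvals = []
        for i in range(10):
            df = simulate_family_cohort(200, burden_beta=0.8, seed=40 + i)
            fit = fit_conditional_logistic(df, "phenotype", ["burden"])
            pvals.append(lrt_burden(fit, fit.llnull, df_diff=1))
        assert np.median(pvals) < 0.05


class TestNagelkerke:
    def test_no_improvement_is_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 80) == (0.0, 0.0)

    def test_printed_formula_case(self):
        cs, ngk = nagelkerke_r2(-100.0, -90.0, 100)
        assert cs == pytest.approx(1 - math.exp(-0.2), rel=1e-12)
        assert ngk == pytest.approx(cs / (1 - math.exp(-2.0)), rel=1e-12)
        assert (round(cs, 4), round(ngk, 4)) == (0.1813, 0.2096)

    def test_ngk_at_least_cs(self, rng):
        for _ in range(50):
            ll0 = -rng.uniform(10, 200)
            llm = ll0 + rng.uniform(0, 30)
            n = int(rng.integers(10, 500))
            cs, ngk = nagelkerke_r2(ll0, llm, n)
            assert 0 <= cs <= ngk < 1

    def test_monotone_in_full_loglik(self):
        values = [nagelkerke_r2(-100.0, llm, 100)[1]
                  for llm in (-99.0, -95.0, -90.0, -80.0)]
        assert values == sorted(values)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-90.0, -100.0, 100)


class TestBootstrap:
    def statistic(self, df):
        fit = fit_conditional_logistic(df, "phenotype", ["burden"])
        return fit.params["burden"]

    def test_seed_reproducible(self):
        df = simulate_family_cohort(80, burden_beta=0.5, seed=30)
        ci1 = bootstrap_ci(self.statistic, df, n_boot=120, seed=7)
        ci2 = bootstrap_ci(self.statistic, df, n_boot=120, seed=7)
        assert ci1 == ci2

    def test_interval_covers_point_estimate(self):
        df = simulate_family_cohort(80, burden_beta=0.5, seed=31)
        lo, hi = bootstrap_ci(self.statistic, df, n_boot=150, seed=8)
        assert lo < self.statistic(df) < hi

    def test_too_few_resamples_rejected(self):
        df = simulate_family_cohort(20, seed=32)
        with pytest.raises(ValueError):
            bootstrap_ci(self.statistic, df, n_boot=10, seed=1)

    def test_degenerate_data_errors(self):
        df = matched_pairs(0, 0, n_concordant=6)
        with pytest.raises(ValueError):
            bootstrap_ci(self.statistic, df, n_boot=100, seed=1)


class TestMetaAnalysis:
    def test_identical_strata_halve_variance(self):
        out = meta_analyze([(1.0, 1.0), (1.0, 1.0)])
        assert out["beta"] == pytest.approx(1.0)
        assert out["se"] == pytest.approx(1 / math.sqrt(2))

    def test_opposite_effects_cancel(self):
        out = meta_analyze([(0.7, 0.5), (-0.7, 0.5)])
        assert out["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_inverse_variance_weights(self):
        out = meta_analyze([(1.0, 1.0), (0.0, 2.0)])
        assert out["beta"] == pytest.approx(0.8)  # weights 4:1

    def test_single_stratum_passthrough(self):
        out = meta_analyze([(0.5, 0.2)])
        assert out["beta"] == 0.5 and "note" in out


class TestBurdenScores:
    def make_sv(self, i, start, end, sq=30.0, gt="0/1", subject="s1"):
        call = GenotypeCall(gt=gt, posteriors=(0.1, 0.8, 0.1), gq=10.0, sq=sq)
        return SVRecord(
            id=f"sv{i}", svtype="DEL", chrom="chr1", start=start, end=end,
            length=end - start, genotypes={subject: call},
            support={subject: ReadSupport(3, 3)},
        )

    MASKS = {"coding": {"chr1": [(500, 600)]}}

    def test_rare_high_quality_hit_counted(self):
        svs = [self.make_sv(1, 450, 650)]
        counts = sv_burden_scores(svs, ["s1", "s2"], self.MASKS, {"sv1": 0.01})
        assert counts.loc["s1", "coding"] == 1
        assert counts.loc["s2", "coding"] == 0

    def test_low_sq_never_counted(self):
        svs = [self.make_sv(1, 450, 650, sq=19.0)]
        counts = sv_burden_scores(svs, ["s1"], self.MASKS, {"sv1": 0.01})
        assert counts.loc["s1", "coding"] == 0

    def test_common_variant_excluded(self):
        svs = [self.make_sv(1, 450, 650)]
        counts = sv_burden_scores(svs, ["s1"], self.MASKS, {"sv1": 0.06})
        assert counts.loc["s1", "coding"] == 0

    def test_paired_segdup_breakpoints_excluded(self):
        svs = [self.make_sv(1, 450, 650)]
        pairs = [(("chr1", 400, 470), ("chr1", 630, 700))]
        counts = sv_burden_scores(
            svs, ["s1"], self.MASKS, {"sv1": 0.01}, segdup_pairs=pairs
        )
        assert counts.loc["s1", "coding"] == 0

    def test_extra_karyotype_event(self):
        counts = sv_burden_scores(
            [], ["s1"], self.MASKS, {}, extra_events={"s1": {"coding": 1}}
        )
        assert counts.loc["s1", "coding"] == 1

    def test_matches_bruteforce_interval_scan(self, rng):
        svs = []
        afs = {}
        for i in range(60):
            start = int(rng.integers(0, 5000))
            sv = self.make_sv(i, start, start + int(rng.integers(50, 400)),
                              sq=float(rng.uniform(10, 40)))
            svs.append(sv)
            afs[sv.id] = float(rng.uniform(0, 0.1))
        mask = {"cat": {"chr1": [(1000, 1500), (3000, 3200)]}}
        counts = sv_burden_scores(svs, ["s1"], mask, afs)
        brute = sum(
            1
            for sv in svs
            if afs[sv.id] < 0.05
            and sv.genotypes["s1"].sq > 20
            and any(
                sv.start < e and sv.end > s
                for s, e in mask["cat"]["chr1"]
            )
        )
        assert counts.loc["s1", "cat"] == brute
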