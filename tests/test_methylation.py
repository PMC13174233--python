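"""Haplotype methylation fractions, exact skew test, XCI profile, FMR1 models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from longvar.methylation import (
    MethylRead,
    MethylReadSet,
    binomial_skew_test,
    classify_cgg,
    classify_read,
    fmr1_association,
    haplotype_fractions,
    xci_profile,
)
from longvar.simulate import simulate_methylation_reads, simulate_xci_panel, stream_rng


def readset(h1=(), h2=(), unphased=()):
    reads = (
        [MethylRead("H1", [0.95] if m else [0.05]) for m in h1]
        + [MethylRead("H2", [0.95] if m else [0.05]) for m in h2]
        + [MethylRead("unphased", [0.95] if m else [0.05]) for m in unphased]
    )
    return MethylReadSet("locus", reads)


def enumeration_pvalue(x, n):
    """Two-sided exact binomial p at p=1/2 by full outcome enumeration."""
    probs = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    obs = probs[x]
    return sum(p for p in probs if p <= obs + 1e-12)


class TestReadClassification:
    def test_high_likelihoods_methylated(self):
        assert classify_read(MethylRead("H1", [0.9, 0.95, 0.99]))

    def test_low_likelihoods_unmethylated(self):
        assert not classify_read(MethylRead("H1", [0.1, 0.0]))

    def test_boundary_mean_is_unmethylated(self):
        assert not classify_read(MethylRead("H1", [0.5, 0.5]))

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            MethylRead("H1", [])


class TestFractions:
    def test_extreme_fractions(self):
        hm = haplotype_fractions(readset(h1=[0] * 5, h2=[1] * 5))
        assert hm.fraction("H1") == 0.0 and hm.fraction("H2") == 1.0

    def test_half(self):
        hm = haplotype_fractions(readset(h1=[1, 1, 0, 0]))
        assert hm.fraction("H1") == 0.5

    def test_unphased_excluded_from_haplotypes(self):
        hm = haplotype_fractions(readset(unphased=[1, 1]))
        assert hm.fraction("H1") is None and hm.fraction("H2") is None
        assert hm.counts["unphased"] == (2, 2)


class TestSkewTest:
    def test_fully_skewed_ten_reads(self):
        p = binomial_skew_test(readset(h1=[0] * 5, h2=[1] * 5))
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)
        assert f"{p:.2g}" == "0.002"

    def test_balanced_is_one(self):
        p = binomial_skew_test(readset(h1=[1, 1, 0, 0], h2=[1, 1, 0, 0]))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_single_read_is_one(self):
        assert binomial_skew_test(readset(h1=[1])) == pytest.approx(1.0)

    def test_no_phased_reads_errors(self):
        with pytest.raises(ValueError):
            binomial_skew_test(readset(unphased=[1, 0]))

    def test_matches_enumeration_up_to_n25(self):
        for n1 in range(0, 13):
            for m1 in range(n1 + 1):
                n2 = min(25 - n1, 12)
                rs = readset(h1=[1] * m1 + [0] * (n1 - m1), h2=[1] * n2)
                if n1 + n2 == 0:
                    continue
                x = m1 + 0  # all H2 methylated -> 0 unmethylated H2
                p = binomial_skew_test(rs)
                assert p == pytest.approx(
                    enumeration_pvalue(x, n1 + n2), rel=1e-9
                )

    def test_full_skew_closed_form(self):
        for n in range(2, 12):
            h1 = [0] * (n // 2)
            h2 = [1] * (n - n // 2)
            p = binomial_skew_test(readset(h1=h1, h2=h2))
            assert p == pytest.approx(2.0 ** (1 - n), rel=1e-12)

    def test_haplotype_relabeling_invariance(self):
        a = readset(h1=[1, 1, 1, 0], h2=[0, 0, 1])
        b = readset(h1=[0, 0, 1], h2=[1, 1, 1, 0])
        assert binomial_skew_test(a) == pytest.approx(binomial_skew_test(b))

    def test_null_scenario_rarely_significant(self):
        rng = stream_rng(5, 0)
        hits = 0
        for _ in range(50):
            rs = simulate_methylation_reads("random", 10, rng=rng)
            hits += binomial_skew_test(rs) < 0.05
        assert hits <= 5  # >=90% of replicates non-significant


class TestXCIProfile:
    def test_chromosome_average_is_gene_mean(self):
        genes = {
            "g1": readset(h1=[1, 0, 0, 0, 0], h2=[0, 0, 0]),
            "g2": readset(h1=[1, 1, 0, 0, 0], h2=[0, 0, 0]),
        }
        prof = xci_profile(genes, (30, 25))
        assert prof.average["H1"] == pytest.approx(0.3)
        assert prof.long_haplotype == "H1"

    def test_extreme_skew_is_plus_one(self):
        genes = {f"g{i}": readset(h1=[1] * 4, h2=[0] * 4) for i in range(3)}
        prof = xci_profile(genes, (49, 28))
        assert prof.skewness == pytest.approx(1.0)

    def test_symmetric_fractions_zero_skew(self):
        genes = {f"g{i}": readset(h1=[1, 0], h2=[0, 1], unphased=[])
                 for i in range(3)}
        prof = xci_profile(genes, (40, 20), min_reads=2)
        assert prof.skewness == pytest.approx(0.0)

    def test_min_read_rule_excludes_thin_genes(self):
        genes = {
            "thin": readset(h1=[1], h2=[0]),
            "ok": readset(h1=[1, 1, 1], h2=[0, 0, 0]),
        }
        prof = xci_profile(genes, (30, 25))
        assert list(prof.gene_fractions.index) == ["ok"]

    def test_no_usable_genes_errors(self):
        with pytest.raises(ValueError):
            xci_profile({"thin": readset(h1=[1], h2=[0])}, (30, 25))

    def test_simulated_skew_panel_is_directional(self):
        panel = simulate_xci_panel([f"g{i}" for i in range(8)], skew=0.5,
                                   seed=4)
        prof = xci_profile(panel, (49, 28))
        assert prof.average["H1"] > 0.9 and prof.average["H2"] < 0.1


class TestCGGClasses:
    @pytest.mark.parametrize(
        "count,cls",
        [
            (49, "gray-zone"), (30, "intermediate"), (29, "intermediate"),
            (25, "short"), (18, "short"), (35, "gray-zone"),
            (54, "gray-zone"), (55, "above-gray-zone"), (26, "intermediate"),
        ],
    )
    def test_boundaries(self, count, cls):
        assert classify_cgg(count) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cgg(-1)


class TestFMR1Association:
    def simulate_table(self, n=200, seed=7, beta_xci=0.5, beta_cgg=0.01):
        rng = np.random.default_rng(seed)
        xci = rng.uniform(0.2, 0.8, n)
        cgg = rng.uniform(20, 55, n)
        y = beta_xci * xci + beta_cgg * cgg + rng.normal(0, 0.1, n)
        return pd.DataFrame(
            {
                "frac_hap_methyl_fmr1": y,
                "frac_hap_methyl_xci": xci,
                "fmr1_mean_repeat_length": cgg,
            }
        )

    def test_parameter_recovery_within_3se(self):
        fit = fmr1_association(self.simulate_table())["ols"]
        est, se = fit.params, fit.bse
        assert abs(est["frac_hap_methyl_xci"] - 0.5) < 3 * se["frac_hap_methyl_xci"]
        assert abs(est["fmr1_mean_repeat_length"] - 0.01) < 3 * se[
            "fmr1_mean_repeat_length"
        ]

    def test_constant_response_gives_zero_effects(self):
        t = self.simulate_table()
        t["frac_hap_methyl_fmr1"] = 0.4
        out = fmr1_association(t)
        assert out["ols"].params[1:].abs().max() < 1e-10
        assert out["r_squared"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_design_names_columns(self):
        t = self.simulate_table()
        t["frac_hap_methyl_xci"] = t["fmr1_mean_repeat_length"]
        with pytest.raises(ValueError, match="collinear"):
            fmr1_association(t)

    def test_partial_r2_positive_for_real_effects(self):
        out = fmr1_association(self.simulate_table())
        assert all(v > 0 for v in out["partial_r2"].values())

    def test_null_logistic_pvalues_uniform(self):
        rng = np.random.default_rng(13)
        pvals = []
        for i in range(150):
            t = self.simulate_table(n=200, seed=1000 + i)
            t["phenotype"] = rng.permutation([0, 1] * 100)
            fit = fmr1_association(t, phenotype_col="phenotype")["logistic"]
            pvals.append(fit.pvalues["fmr1_mean_repeat_length"])
        assert kstest(pvals, "uniform").pvalue > 0.01
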