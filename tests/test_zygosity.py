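import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bctwohit import zygosity as zy
from bctwohit.simulate import STATE_TEMPLATES, simulate_reads

from conftest import binom_interval_oracle


class TestExpectedVaf:
    @pytest.mark.parametrize("phi,m,tcn,expected", [
        (1.0, 1, 2, 0.5),
        (0.0, 0, 1, 0.5),      # purity 0: germline heterozygous expectation
        (0.0, 3, 4, 0.5),
        (0.6, 2, 2, 0.8),
        (0.6, 0, 1, 2 / 7),
        (1.0, 3, 4, 0.75),     # pure tumor: m / TCN
    ])
    def test_closed_form_values(self, phi, m, tcn, expected):
        assert zy.expected_vaf(phi, m, tcn) == pytest.approx(expected)

    def test_no_tumor_dna_raises(self):
        with pytest.raises(ValueError, match="no tumor DNA"):
            zy.expected_vaf(1.0, 0, 0)

    @given(phi=st.floats(0, 1), tcn=st.integers(1, 8))
    def test_monotone_in_mutant_copies(self, phi, tcn):
        vals = [zy.expected_vaf(phi, m, tcn) for m in range(tcn + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    @given(m=st.integers(0, 6), tcn=st.integers(1, 6))
    def test_purity_zero_always_half(self, m, tcn):
        m = min(m, tcn)
        assert zy.expected_vaf(0.0, m, tcn) == pytest.approx(0.5)


class TestAcceptanceInterval:
    def test_center_always_covered(self):
        lo, hi = zy.acceptance_interval(0.5, 10)
        assert lo <= 0.5 <= hi

    def test_degenerate_p_one_collapses(self):
        assert zy.acceptance_interval(1.0, 50) == (1.0, 1.0)
        assert zy.acceptance_interval(0.0, 50) == (0.0, 0.0)

    @pytest.mark.parametrize("p", [0.05, 0.25, 0.5, 0.75, 0.95])
    @pytest.mark.parametrize("depth", [10, 37, 100, 200])
    def test_matches_exhaustive_cdf_enumeration(self, p, depth):
        assert zy.acceptance_interval(p, depth) == pytest.approx(
            binom_interval_oracle(p, depth), abs=1e-12)

    def test_intervals_shrink_with_depth(self):
        widths = [np.diff(zy.acceptance_interval(0.4, d))[0]
                  for d in (50, 200, 1000, 5000)]
        assert all(b <= a for a, b in zip(widths, widths[1:]))

    def test_coverage_at_least_nominal(self, rng):
        """P(observed VAF inside the interval) >= level under binomial sampling."""
        for p, depth in [(0.3, 80), (0.5, 200), (0.9, 150)]:
            lo, hi = zy.acceptance_interval(p, depth)
            draws = rng.binomial(depth, p, size=4000) / depth
            cover = ((draws >= lo - 1e-12) & (draws <= hi + 1e-12)).mean()
            assert cover >= 0.95 - 0.02  # Monte-Carlo slack


class TestClassifyZygosity:
    def _call(self, alt, depth, phi, tcn, lcn, single_segment, hom=False):
        profile = zy.TumorProfile("T1", phi, 2.0, single_segment(tcn, lcn))
        return zy.classify_zygosity(zy.ObservedAllele(alt, depth), profile,
                                    "chr1", 500, genotype_homozygous=hom)

    def test_balanced_het_called_heterozygous(self, single_segment):
        call = self._call(500, 1000, 0.8, 2, 1, single_segment)
        assert call.state == "heterozygous"
        assert call.mutant_copies == 1

    def test_loss_of_wild_type_at_high_vaf(self, single_segment):
        call = self._call(950, 1000, 0.9, 2, 0, single_segment)
        assert call.state == "loss_of_WT"
        assert call.mutant_copies == 2

    def test_loss_of_mutant_at_low_vaf(self, single_segment):
        # TCN=1, LCN=0, mutant lost: expected VAF = (1-phi)/(phi+2(1-phi))
        phi = 0.6
        p = zy.expected_vaf(phi, 0, 1)
        call = self._call(int(round(1000 * p)), 1000, phi, 1, 0, single_segment)
        assert call.state == "loss_of_mutant"

    def test_asi_with_mutant_on_major_allele(self, single_segment):
        phi = 0.7
        p = zy.expected_vaf(phi, 3, 4)
        call = self._call(int(round(1000 * p)), 1000, phi, 4, 1, single_segment)
        assert call.state == "ASI_two_hit"
        assert call.mutant_copies == 3

    def test_gain_diluted_het_still_heterozygous(self, single_segment):
        # TCN=4 balanced would be m=2 (VAF 0.5 at phi=1); a germline variant on
        # one of four copies gives VAF below the balanced band -> heterozygous
        call = self._call(250, 1000, 1.0, 4, 2, single_segment)
        assert call.state == "heterozygous"

    def test_no_segment_is_indeterminate(self):
        profile = zy.TumorProfile("T1", 0.8, 2.0,
                                  pd.DataFrame(columns=["sample", "chrom", "start",
                                                        "end", "tcn", "lcn"]))
        call = zy.classify_zygosity(zy.ObservedAllele(50, 100), profile, "chr1", 500)
        assert call.state == "indeterminate"
        assert "segment" in call.evidence

    def test_missing_purity_is_indeterminate(self, single_segment):
        profile = zy.TumorProfile("T1", None, 2.0, single_segment(2, 1))
        call = zy.classify_zygosity(zy.ObservedAllele(50, 100), profile, "chr1", 500)
        assert call.state == "indeterminate"

    def test_homozygous_germline_is_indeterminate(self, single_segment):
        call = self._call(990, 1000, 0.8, 2, 1, single_segment, hom=True)
        assert call.state == "indeterminate"
        assert "homozygous" in call.evidence

    def test_deterministic(self, single_segment):
        a = self._call(700, 1000, 0.8, 2, 0, single_segment)
        b = self._call(700, 1000, 0.8, 2, 0, single_segment)
        assert a == b

    def test_overlapping_segments_raise(self):
        seg = pd.DataFrame([
            {"sample": "T1", "chrom": "chr1", "start": 1, "end": 1000, "tcn": 2, "lcn": 1},
            {"sample": "T1", "chrom": "chr1", "start": 400, "end": 2000, "tcn": 3, "lcn": 1}])
        profile = zy.TumorProfile("T1", 0.8, 2.0, seg)
        with pytest.raises(ValueError, match="overlapping"):
            zy.classify_zygosity(zy.ObservedAllele(50, 100), profile, "chr1", 500)

    def test_planted_state_recovery_at_depth_500(self, rng, single_segment):
        """>= 90% of planted states recovered at depth 500, purity 0.4-0.9."""
        states = list(STATE_TEMPLATES)
        ok = 0
        n = 1000
        for i in range(n):
            s = states[i % len(states)]
            tcn, lcn, _ = STATE_TEMPLATES[s]
            phi = rng.uniform(0.4, 0.9)
            alt, depth = simulate_reads(s, phi, 500, tcn, lcn, rng.integers(2 ** 31))
            profile = zy.TumorProfile("T1", phi, 2.0, single_segment(tcn, lcn))
            call = zy.classify_zygosity(zy.ObservedAllele(alt, depth), profile, "chr1", 500)
            call = zy.integrate_compound(call, s == "biallelic_compound")
            ok += call.state == s
        assert ok / n >= 0.90


class TestCompoundAndSummary:
    def _somatic(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "variant_class",
                                           "chrom", "pos", "ref", "alt", "functional"])

    def test_truncating_somatic_hit_in_same_gene(self):
        som = self._somatic([("P1", "BRCA2", "frameshift", "chr13", 1, "A", "T", True)])
        assert zy.detect_biallelic_compound("P1", "BRCA2", som)

    def test_other_gene_or_silent_does_not_count(self):
        som = self._somatic([("P1", "TP53", "missense", "chr17", 1, "A", "T", True),
                             ("P1", "BRCA2", "silent", "chr13", 1, "A", "T", False)])
        assert not zy.detect_biallelic_compound("P1", "BRCA2", som)

    def test_compound_upgrades_het_but_not_asi(self):
        het = zy.ZygosityCall("heterozygous", 1)
        asi = zy.ZygosityCall("ASI_two_hit", 3)
        assert zy.integrate_compound(het, True).state == "biallelic_compound"
        assert zy.integrate_compound(asi, True).state == "ASI_two_hit"
        assert zy.integrate_compound(het, False).state == "heterozygous"

    def test_two_hit_fraction_arithmetic(self):
        calls = pd.DataFrame({
            "gene": ["BRCA1"] * 4,
            "state": ["ASI_two_hit", "loss_of_WT", "biallelic_compound", "heterozygous"]})
        out = zy.summarize_two_hit(calls)
        assert out.loc[0, "two_hit_fraction"] == pytest.approx(0.75)

    def test_all_indeterminate_reports_na(self):
        calls = pd.DataFrame({"gene": ["ATM"] * 3, "state": ["indeterminate"] * 3})
        out = zy.summarize_two_hit(calls)
        assert out.loc[0, "n_classifiable"] == 0
        assert np.isnan(out.loc[0, "two_hit_fraction"])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            zy.summarize_two_hit(pd.DataFrame(columns=["gene", "state"]))

    def test_gene_set_fraction_pools_members(self):
        calls = pd.DataFrame({
            "gene": ["BRCA1", "BRCA2", "TP53", "ATM"],
            "state": ["ASI_two_hit", "loss_of_WT", "heterozygous", "heterozygous"]})
        out = zy.summarize_two_hit(calls, gene_sets={"BCDG": ["BRCA1", "BRCA2", "TP53"]})
        row = out[out["group"] == "BCDG"].iloc[0]
        assert row["n_two_hit"] == 2 and row["n_classifiable"] == 3
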