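"""SNP classification, MAF spectra and the panel filter cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diagpanel as dp
from diagpanel.genotype_io import HET, HOM_ALT, HOM_REF, MISSING
from diagpanel.panel_design import LocusFreqSummary, PopLocusStats, SnpCategory

from conftest import build_matrix, catalog_for

A, B = dp.Population.SPECIES_A, dp.Population.SPECIES_B


def summary_of(gm, locus_id="L0"):
    return dp.summarize_locus(gm, locus_id)


class TestSummarizeLocus:
    def test_fixed_difference(self):
        gm = build_matrix([[HOM_REF]] * 10, [[HOM_ALT]] * 10)
        s = summary_of(gm)
        assert s.pop(A).p_ref == 1.0 and s.pop(B).p_ref == 0.0
        assert s.pop(A).obs_het == 0.0 and s.pop(B).obs_het == 0.0

    def test_hand_counted_frequencies(self):
        """5 HOM_REF + 5 HET = 15 ref alleles of 20 -> p_ref 0.75,
        Ho = 5/10, He = 2 * 0.75 * 0.25."""
        gm = build_matrix([[HOM_REF]] * 5 + [[HET]] * 5, [[HOM_REF]])
        s = summary_of(gm)
        assert s.pop(A).p_ref == pytest.approx(0.75)
        assert s.pop(A).obs_het == pytest.approx(0.5)
        assert s.pop(A).exp_het == pytest.approx(0.375)
        assert s.pop(A).n_called == 10

    def test_all_missing_population_flagged(self):
        gm = build_matrix([[HOM_REF]] * 3, [[MISSING]] * 4)
        s = summary_of(gm)
        assert s.pop(B).n_called == 0
        assert math.isnan(s.pop(B).p_ref)
        assert math.isnan(s.pop(B).maf)

    def test_missing_calls_excluded_from_frequencies(self):
        gm = build_matrix([[HET], [MISSING], [HOM_ALT]], [[HOM_REF]])
        s = summary_of(gm)
        assert s.pop(A).n_called == 2
        assert s.pop(A).p_ref == pytest.approx(0.25)

    def test_unknown_locus_raises(self):
        gm = build_matrix([[0]], [[0]])
        with pytest.raises(KeyError):
            dp.summarize_locus(gm, "nope")


def make_summary(p_ref_a, p_ref_b, n_a=30, n_b=15):
    def stats(p, n):
        if n == 0:
            return PopLocusStats(0, float("nan"), float("nan"), float("nan"))
        return PopLocusStats(n, p, 0.0, 2 * p * (1 - p))

    return LocusFreqSummary("L", {A: stats(p_ref_a, n_a), B: stats(p_ref_b, n_b)})


class TestClassifySnp:
    CFG = dp.PanelFilterConfig(min_called_A=30, min_called_B=15)

    @pytest.mark.parametrize(
        "pa,pb,na,nb,expected",
        [
            (1.0, 0.0, 30, 15, SnpCategory.DIAGNOSTIC),
            (0.0, 1.0, 30, 15, SnpCategory.DIAGNOSTIC),
            (0.9, 1.0, 30, 15, SnpCategory.PRIVATE_A),
            (1.0, 0.4, 30, 15, SnpCategory.PRIVATE_B),
            (0.5, 0.5, 30, 15, SnpCategory.SHARED_POLY),
            (1.0, 1.0, 30, 15, SnpCategory.MONOMORPHIC),
            (0.0, 0.0, 30, 15, SnpCategory.MONOMORPHIC),
            (1.0, 0.0, 30, 14, SnpCategory.UNCLASSIFIED_LOW_CALLS),
            (1.0, 0.0, 29, 15, SnpCategory.UNCLASSIFIED_LOW_CALLS),
        ],
    )
    def test_categories(self, pa, pb, na, nb, expected):
        assert dp.classify_snp(make_summary(pa, pb, na, nb), self.CFG) is expected

    @settings(max_examples=60, derandomize=True)
    @given(
        pa=st.one_of(st.sampled_from([0.0, 1.0]), st.floats(0.01, 0.99)),
        pb=st.one_of(st.sampled_from([0.0, 1.0]), st.floats(0.01, 0.99)),
    )
    def test_population_swap_symmetry(self, pa, pb):
        """Swapping species labels maps DIAGNOSTIC to itself and
        PRIVATE_A <-> PRIVATE_B (equal thresholds)."""
        cfg = dp.PanelFilterConfig(min_called_A=10, min_called_B=10)
        c1 = dp.classify_snp(make_summary(pa, pb, 10, 10), cfg)
        c2 = dp.classify_snp(make_summary(pb, pa, 10, 10), cfg)
        swap = {
            SnpCategory.PRIVATE_A: SnpCategory.PRIVATE_B,
            SnpCategory.PRIVATE_B: SnpCategory.PRIVATE_A,
        }
        assert c2 is swap.get(c1, c1)


class TestMafSpectrum:
    def _privates(self, category, mafs):
        out = []
        for i, m in enumerate(mafs):
            p_poly = 1 - m  # polymorphic population ref frequency
            if category is SnpCategory.PRIVATE_A:
                s = make_summary(p_poly, 1.0)
            else:
                s = make_summary(1.0, p_poly)
            s.category = category
            out.append(s)
        return out

    def test_published_private_counts_reproduce_percentages(self):
        """1190 of 1658 private SNPs at MAF >= 0.05 -> 71.8% (28.2% rare);
        3028 of 10000 -> 30.3% (69.7% rare)."""
        mafs = [0.05] * 1190 + [0.01] * (1658 - 1190)
        spectrum_ = dp.maf_spectrum(self._privates(SnpCategory.PRIVATE_A, mafs),
                               SnpCategory.PRIVATE_A)
        assert (spectrum_.n_total, spectrum_.n_at_or_above) == (1658, 1190)
        assert spectrum_.percent_at_or_above == 71.8
        assert spectrum_.percent_below == 28.2

        mafs = [0.3] * 3028 + [0.02] * (10000 - 3028)
        spectrum_ = dp.maf_spectrum(self._privates(SnpCategory.PRIVATE_B, mafs),
                               SnpCategory.PRIVATE_B)
        assert (spectrum_.n_total, spectrum_.n_at_or_above) == (10000, 3028)
        assert spectrum_.percent_at_or_above == 30.3
        assert spectrum_.percent_below == 69.7

    def test_empty_input_undefined(self):
        spectrum_ = dp.maf_spectrum([], SnpCategory.PRIVATE_A)
        assert spectrum_.n_total == 0 and math.isnan(spectrum_.proportion_at_or_above)

    def test_rejects_non_private_category(self):
        with pytest.raises(ValueError):
            dp.maf_spectrum([], SnpCategory.DIAGNOSTIC)


def test_brute_force_tally_oracle():
    """An independent per-locus pure-Python tally reproduces every
    summarize_all field on a 20 x 50 random matrix."""
    rng = np.random.default_rng(11)
    calls = rng.choice([0, 1, 2, -1], size=(20, 50), p=[0.35, 0.3, 0.2, 0.15])
    gm = build_matrix(calls[:12], calls[12:])
    summaries = {s.locus_id: s for s in dp.summarize_all(gm)}
    for j, locus in enumerate(gm.loci):
        for pop, rows in ((A, range(12)), (B, range(12, 20))):
            obs = [int(gm.calls[i, j]) for i in rows if gm.calls[i, j] != -1]
            st_ = summaries[locus.locus_id].pop(pop)
            assert st_.n_called == len(obs)
            if not obs:
                assert math.isnan(st_.p_ref)
                continue
            n_ref = sum({0: 2, 1: 1, 2: 0}[c] for c in obs)
            p = n_ref / (2 * len(obs))
            assert st_.p_ref == pytest.approx(p)
            assert st_.obs_het == pytest.approx(sum(c == 1 for c in obs) / len(obs))
            assert st_.exp_het == pytest.approx(2 * p * (1 - p))
            assert st_.maf == pytest.approx(min(p, 1 - p))


class TestCascade:
    def _two_tag_matrix(self):
        # tag "ta": one diagnostic SNP only; tag "tb": diagnostic + private
        calls_a = [[HOM_REF, HOM_REF, HET] for _ in range(30)]
        calls_b = [[HOM_ALT, HOM_ALT, HOM_REF] for _ in range(15)]
        gm = build_matrix(calls_a, calls_b,
                          tag_of={0: "ta", 1: "tb", 2: "tb"})
        return gm, catalog_for(gm)

    def test_tag_with_extra_polymorphism_removed_at_stage_2(self):
        gm, cat = self._two_tag_matrix()
        panel = dp.run_cascade(gm, cat, dp.PanelFilterConfig())
        assert panel.marker_ids == ["L0"]
        stages = dict((s, (i, o)) for s, i, o in panel.provenance)
        assert stages["diagnostic"] == (3, 2)
        assert stages["single_snp_tag"] == (2, 1)

    def test_multimapping_tag_removed_at_stage_4(self):
        gm, _ = self._two_tag_matrix()
        cat = catalog_for(gm, n_hits={"ta": 2, "tb": 1})
        panel = dp.run_cascade(gm, cat, dp.PanelFilterConfig())
        assert panel.marker_ids == []
        stages = dict((s, (i, o)) for s, i, o in panel.provenance)
        assert stages["unique_alignment"] == (1, 0)

    def test_low_call_locus_removed_at_stage_3_not_1(self):
        """Fixation is tested on observed calls at stage 1; the per-species
        call-count thresholds act at their own stage."""
        calls_a = [[HOM_REF]] * 30
        calls_b = [[HOM_ALT]] * 14 + [[MISSING]]
        gm = build_matrix(calls_a, calls_b)
        panel = dp.run_cascade(gm, catalog_for(gm), dp.PanelFilterConfig())
        stages = dict((s, (i, o)) for s, i, o in panel.provenance)
        assert stages["diagnostic"] == (1, 1)
        assert stages["call_count"] == (1, 0)

    def test_counts_monotone_and_alleles_oriented(self):
        cfg = dp.SimulationConfig(n_tags=80, seed=2, missing_rate=0.02,
                                  n_ind_A=40, n_ind_B=20)
        gm, cat, _ = dp.simulate_two_species(cfg)
        panel = dp.run_cascade(
            gm, cat, dp.PanelFilterConfig(min_called_A=35, min_called_B=18))
        ns = [n for _, n, _ in panel.provenance] + [panel.provenance[-1][2]]
        assert all(x >= y for x, y in zip(ns, ns[1:]))
        by_locus = {l.locus_id: l for l in gm.loci}
        for m in panel:
            locus = by_locus[m.locus_id]
            assert {m.allele_A, m.allele_B} == {locus.ref_allele, locus.alt_allele}

    def test_category_counts_partition_loci(self):
        cfg = dp.SimulationConfig(n_tags=60, seed=9, n_ind_A=25, n_ind_B=12)
        gm, _, _ = dp.simulate_two_species(cfg)
        cfgf = dp.PanelFilterConfig(min_called_A=20, min_called_B=10)
        cats = [dp.classify_snp(s, cfgf) for s in dp.summarize_all(gm)]
        assert len(cats) == gm.n_loci

    def test_n_final_random_exceeding_survivors_errors(self):
        gm, cat = self._two_tag_matrix()
        with pytest.raises(ValueError, match="cannot draw 5"):
            dp.run_cascade(gm, cat, dp.PanelFilterConfig(n_final_random=5))


class TestRandomSubset:
    def _panel(self, n):
        return dp.DiagnosticPanel(markers=[
            dp.DiagnosticMarker(f"m{i}", f"m{i}", f"t{i}", "A", "G")
            for i in range(n)
        ])

    def test_identity_and_determinism(self):
        panel = self._panel(6)
        assert dp.random_subset(panel, 6, seed=1).marker_ids == panel.marker_ids
        s1 = dp.random_subset(panel, 3, seed=7)
        s2 = dp.random_subset(panel, 3, seed=7)
        assert s1.marker_ids == s2.marker_ids
        assert s1.provenance[-1] == ("random_subset", 6, 3)

    def test_oversized_draw_errors(self):
        with pytest.raises(ValueError):
            dp.random_subset(self._panel(3), 4, seed=0)

    def test_selection_frequencies_binomial(self):
        """Drawing 20 of 46 markers over 1000 seeds: each marker's
        empirical selection frequency is 20/46 within 3 s.e."""
        panel = self._panel(46)
        counts = {m: 0 for m in panel.marker_ids}
        for seed in range(1000):
            for m in dp.random_subset(panel, 20, seed=seed).marker_ids:
                counts[m] += 1
        p = 20 / 46
        se = math.sqrt(p * (1 - p) / 1000)
        for m, c in counts.items():
            assert abs(c / 1000 - p) <= 3 * se, m
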