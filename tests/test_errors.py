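"""Error-rate estimators on hand-enumerable call sets."""

import numpy as np
import pytest

from scwga import (ado_allele_bias, allelic_dropout_rate, consensus_fp_rate,
                   errors_per_megabase, false_positive_rate, fp_spectrum,
                   recurrence_analysis)
from scwga.io import HET, HOM_ALT, HOM_REF
from conftest import make_cell, make_reference


def het_reference(n=4, depth=30):
    return make_reference([("chr1", 100 * (i + 1), "A", "T", HET, depth)
                           for i in range(n)])


class TestAllelicDropout:
    def test_error_free_cell_has_zero_adr(self):
        ref = het_reference()
        cell = make_cell([("chr1", 100 * (i + 1), "A", "T", HET, 20, 10)
                          for i in range(4)])
        est = allelic_dropout_rate([cell], ref)
        assert est.mean == 0.0

    def test_two_cell_hand_enumeration(self):
        ref = het_reference(4)
        c1 = make_cell([("chr1", 100, "A", "T", HOM_ALT, 20, 19),
                        ("chr1", 200, "A", "T", HET, 20, 10),
                        ("chr1", 300, "A", "T", HET, 20, 10),
                        ("chr1", 400, "A", "T", HET, 20, 10)], "c1")
        c2 = make_cell([("chr1", 100, "A", "T", HOM_REF, 20, 0),
                        ("chr1", 200, "A", "T", HOM_ALT, 20, 20),
                        ("chr1", 300, "A", "T", HET, 20, 10),
                        ("chr1", 400, "A", "T", HET, 20, 10)], "c2")
        est = allelic_dropout_rate([c1, c2], ref)
        assert est.values == [0.25, 0.5]
        assert est.mean == 0.375

    def test_restricted_requires_depth_in_both_samples(self):
        ref = make_reference([("chr1", 100, "A", "T", HET, 30),
                              ("chr1", 200, "A", "T", HET, 5)])  # ref too shallow
        cell = make_cell([("chr1", 100, "A", "T", HOM_ALT, 5, 5),  # cell too shallow
                          ("chr1", 200, "A", "T", HOM_ALT, 20, 19)])
        est = allelic_dropout_rate([cell], ref, restricted=True)
        assert est.per_cell == {}  # no qualifying sites at all
        assert np.isnan(est.mean)

    def test_unrestricted_counts_no_call_as_dropout(self):
        ref = het_reference(4)
        # genotyped het at 2 sites, hom at 1, absent at 1
        cell = make_cell([("chr1", 100, "A", "T", HET, 20, 10),
                          ("chr1", 200, "A", "T", HET, 20, 10),
                          ("chr1", 300, "A", "T", HOM_ALT, 20, 19)])
        est = allelic_dropout_rate([cell], ref, restricted=False)
        assert est.values == [0.5]  # (1 hom + 1 no-call) / 4

    def test_bias_fraction_count(self):
        ref = het_reference(4)
        cell = make_cell([("chr1", 100, "A", "T", HOM_ALT, 20, 19),
                          ("chr1", 200, "A", "T", HOM_ALT, 20, 19),
                          ("chr1", 300, "A", "T", HOM_ALT, 20, 19),
                          ("chr1", 400, "A", "T", HOM_REF, 20, 0)])
        assert ado_allele_bias([cell], ref) == 0.75


class TestFalsePositiveRate:
    def test_no_fp_calls_gives_zero(self):
        ref = make_reference([("chr1", 100 * (i + 1), "A", "T", HOM_REF, 30)
                              for i in range(10)])
        cell = make_cell([("chr1", 100, "A", "T", HOM_REF, 20, 0)])
        assert false_positive_rate([cell], ref).mean == 0.0

    def test_hand_enumeration_one_in_ten(self):
        ref = make_reference([("chr1", 100 * (i + 1), "A", "T", HOM_REF, 30)
                              for i in range(10)])
        cell = make_cell([("chr1", 100 * (i + 1), "A", "T",
                           HET if i == 0 else HOM_REF, 20, 10 if i == 0 else 0)
                          for i in range(10)])
        assert false_positive_rate([cell], ref).mean == pytest.approx(0.1)

    def test_explicit_callable_denominator_takes_precedence(self):
        ref = make_reference([])
        cell = make_cell([("chr1", 50, "C", "T", HET, 20, 10)],
                         hom_ref_callable_bp=1000)
        assert false_positive_rate([cell], ref).mean == pytest.approx(1 / 1000)

    def test_het_at_ref_het_site_is_not_a_false_positive(self):
        ref = make_reference([("chr1", 100, "A", "T", HET, 30)])
        cell = make_cell([("chr1", 100, "A", "T", HET, 20, 10)],
                         hom_ref_callable_bp=1000)
        assert false_positive_rate([cell], ref).mean == 0.0


class TestSpectrum:
    def test_direct_count(self):
        ref = make_reference([])
        cell = make_cell([("chr1", 10, "C", "T", HET, 20, 10),
                          ("chr1", 30, "C", "T", HET, 20, 10),
                          ("chr1", 50, "G", "A", HET, 20, 10),
                          ("chr1", 70, "A", "G", HET, 20, 10)],
                         hom_ref_callable_bp=100)
        rep = fp_spectrum([cell], ref)
        assert rep.counts["C>T"] == 2 and rep.counts["G>A"] == 1
        assert rep.transition_fraction == 0.75

    def test_empty_fp_set_reports_absent_fraction(self):
        rep = fp_spectrum([make_cell([])], make_reference([]))
        assert rep.total == 0
        assert rep.transition_fraction is None


class TestRecurrence:
    def test_hand_enumeration(self):
        rep = recurrence_analysis([{("chr1", 5)}, {("chr1", 5)}, {("chr1", 9)}])
        assert rep.fraction_recurrent == 0.5
        assert rep.mean_cells_per_recurrent_site == 2.0

    def test_all_unique_events(self):
        rep = recurrence_analysis([{("chr1", 1)}, {("chr1", 2)}, {("chr1", 3)}])
        assert rep.fraction_recurrent == 0.0

    def test_fully_shared_site(self):
        n = 7
        rep = recurrence_analysis([{("chr1", 42)} for _ in range(n)])
        assert rep.fraction_recurrent == 1.0
        assert rep.mean_cells_per_recurrent_site == n

    def test_empty_input_gives_zeros(self):
        rep = recurrence_analysis([])
        assert (rep.fraction_recurrent, rep.mean_cells_per_recurrent_site) == (0, 0)


class TestRecurrenceUnderIndependence:
    def test_fp_recurrence_near_zero_at_realistic_rate(self):
        """Independent uniform FP injection at 3.2e-5 on a 1 Mb target
        leaves essentially no recurrent FP sites."""
        from scwga import (FilterConfig, SimulationConfig, apply_site_filters,
                           fp_event_sites, simulate_experiment)
        for seed in (1, 2, 3):
            config = SimulationConfig(target_size_bp=1_000_000, n_cells=5,
                                      n_het_snvs=0, n_hom_snvs=0,
                                      n_het_indels=0, n_hom_indels=0,
                                      fp_rate=3.2e-5, seed=seed)
            exp = simulate_experiment(config)
            cells = [apply_site_filters(c, FilterConfig()) for c in exp.cells]
            rep = recurrence_analysis(fp_event_sites(cells, exp.reference))
            assert rep.fraction_recurrent < 0.01

    def test_hotspot_free_ado_multiplicity_matches_binomial_oracle(self):
        """Without hotspots, the number of cells sharing a dropout site is
        Binomial(n_cells, p); the mean multiplicity among recurrent sites
        must match E[X | X >= 2] at the empirically observed p."""
        from scipy import stats
        from scwga import (FilterConfig, SimulationConfig, apply_site_filters,
                           ado_event_sites, simulate_experiment)
        n_cells, n_het = 5, 20_000
        config = SimulationConfig(target_size_bp=200_000, n_cells=n_cells,
                                  n_het_snvs=n_het, n_hom_snvs=0,
                                  n_het_indels=0, n_hom_indels=0,
                                  ado_rate=0.25, ado_hotspot_fraction=0.0,
                                  seed=19)
        exp = simulate_experiment(config)
        cells = [apply_site_filters(c, FilterConfig()) for c in exp.cells]
        sites = ado_event_sites(cells, exp.reference)
        rep = recurrence_analysis(sites)
        p_hat = sum(len(s) for s in sites) / (n_cells * n_het)
        k = np.arange(n_cells + 1)
        pmf = stats.binom.pmf(k, n_cells, p_hat)
        expected = float((k[2:] * pmf[2:]).sum() / pmf[2:].sum())
        assert rep.mean_cells_per_recurrent_site == pytest.approx(expected,
                                                                  abs=0.05)


class TestClosedForms:
    def test_consensus_two_cells_reproduces_printed_value(self):
        v = consensus_fp_rate(3.2e-5, 2)
        assert v == pytest.approx(1.024e-9)
        assert f"{v:.3g}" == "1.02e-09"

    def test_consensus_identity_at_one_cell(self):
        assert consensus_fp_rate(0.37, 1) == 0.37

    def test_consensus_closed_form(self):
        assert consensus_fp_rate(0.1, 3) == pytest.approx(1e-3)

    def test_consensus_strictly_decreasing_in_n(self):
        vals = [consensus_fp_rate(0.2, n) for n in range(1, 8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("p,expected", [(3.2e-5, 32.0), (0.0, 0.0), (1e-6, 1.0)])
    def test_errors_per_megabase(self, p, expected):
        assert errors_per_megabase(p) == pytest.approx(expected)

    def test_consensus_input_validation(self):
        with pytest.raises(ValueError):
            consensus_fp_rate(1.5, 2)
        with pytest.raises(ValueError):
            consensus_fp_rate(0.5, 0)
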