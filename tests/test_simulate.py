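"""Generator contracts: configured event rates, determinism, ground-truth
consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scwga import (ConfigurationError, SimulationConfig, simulate_depth_profile,
                   simulate_experiment, simulate_population_reference,
                   simulate_qc_matrix, simulate_single_cell_calls,
                   qc_matrix_from_counts, write_vcf)
from scwga.config import SUBSTITUTION_CLASSES
from scwga.coverage import coverage_breadth
from scwga.io import HET, HOM_ALT, HOM_REF, SNV


def small_config(**kw):
    params = dict(target_size_bp=20_000, n_cells=2, n_het_snvs=100,
                  n_hom_snvs=50, n_het_indels=10, n_hom_indels=5,
                  ado_hotspot_fraction=0.0, mq_fail_rate=0.0, bq_fail_rate=0.0,
                  seed=7)
    params.update(kw)
    return SimulationConfig(**params)


class TestPopulationReference:
    def test_zero_variant_case(self):
        config = small_config(n_het_snvs=0, n_hom_snvs=0, n_het_indels=0,
                              n_hom_indels=0)
        assert len(simulate_population_reference(config)) == 0

    def test_counts_positions_unique_and_het(self):
        config = SimulationConfig(target_size_bp=10_000, n_het_snvs=100,
                                  n_hom_snvs=0, n_het_indels=0, n_hom_indels=0,
                                  seed=7)
        ref = simulate_population_reference(config)
        assert len(ref) == 100
        assert ref.df["pos"].is_unique
        assert ref.df["pos"].between(1, 10_000).all()
        assert (ref.df["gt"] == HET).all()
        assert (ref.df["vtype"] == SNV).all()

    def test_reference_is_fully_callable(self):
        ref = simulate_population_reference(small_config())
        assert (ref.df["depth"] >= 6).all()

    def test_variant_count_exceeding_target_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(target_size_bp=50)

    def test_configured_type_counts(self):
        ref = simulate_population_reference(small_config())
        counts = ref.df.groupby(["vtype", "gt"]).size()
        assert counts[(SNV, HET)] == 100
        assert counts[(SNV, HOM_ALT)] == 50
        assert counts[("indel", HET)] == 10
        assert counts[("indel", HOM_ALT)] == 5

    def test_seed_determinism_byte_identical_vcf(self, tmp_path):
        paths = []
        for run in range(2):
            config = small_config(fp_rate=1e-3)
            exp = simulate_experiment(config)
            p = tmp_path / f"run{run}.vcf"
            write_vcf(p, exp.reference, exp.cells)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestDepthProfile:
    def test_degenerate_dispersion_is_constant(self):
        config = small_config(depth_dispersion=0.0, depth_zero_fraction=0.0,
                              depth_mean=17.0)
        profile = simulate_depth_profile(config, 0)
        assert (profile.all_depths() == 17).all()

    def test_zero_fraction_within_binomial_bound(self):
        config = SimulationConfig(target_size_bp=1_000_000, n_cells=1,
                                  depth_zero_fraction=0.04, seed=11)
        profile = simulate_depth_profile(config, 0)
        observed = float((profile.all_depths() == 0).mean())
        se = np.sqrt(0.04 * 0.96 / 1e6)
        assert abs(observed - 0.04) <= 3 * se

    def test_breadth_is_one_minus_zero_fraction(self):
        config = small_config()
        profile = simulate_depth_profile(config, 1)
        observed_zero = float((profile.all_depths() == 0).mean())
        assert coverage_breadth(profile, min_depth=1) == pytest.approx(
            1.0 - observed_zero, abs=1e-12)

    def test_cell_index_validation(self):
        with pytest.raises(ConfigurationError):
            simulate_depth_profile(small_config(), 5)


class TestSingleCellCalls:
    def test_no_error_limit_reproduces_reference(self):
        config = small_config(ado_rate=0.0, fp_rate=0.0)
        ref = simulate_population_reference(config)
        depth = simulate_depth_profile(config, 0)
        cell, truth = simulate_single_cell_calls(ref, depth, config, 0)
        assert truth.empty
        j = ref.df.merge(cell.df, on=["chrom", "pos"], suffixes=("_ref", ""))
        # every covered reference site is called with the reference genotype
        covered = depth.depth_at(config.chrom, ref.df["pos"].to_numpy()) >= 1
        assert len(j) == int(covered.sum())
        assert (j["gt"] == j["gt_ref"]).all()

    def test_fp_count_within_poisson_bound(self):
        config = SimulationConfig(target_size_bp=2_000_000, n_cells=1,
                                  n_het_snvs=0, n_hom_snvs=0, n_het_indels=0,
                                  n_hom_indels=0, fp_rate=3.2e-5,
                                  depth_zero_fraction=0.0, seed=13)
        ref = simulate_population_reference(config)
        depth = simulate_depth_profile(config, 0)
        _, truth = simulate_single_cell_calls(ref, depth, config, 0)
        lam = 2e6 * 3.2e-5
        assert abs((truth["event"] == "fp_injected").sum() - lam) <= 3 * np.sqrt(lam)

    def test_full_bb_bias_gives_no_aa_dropouts(self):
        config = small_config(ado_rate=0.25, ado_bb_bias=1.0)
        ref = simulate_population_reference(config)
        depth = simulate_depth_profile(config, 0)
        _, truth = simulate_single_cell_calls(ref, depth, config, 0)
        events = truth["event"].value_counts()
        assert events.get("ado_to_AA", 0) == 0
        assert events.get("ado_to_BB", 0) > 0

    def test_truth_and_calls_mutually_consistent(self):
        config = small_config(fp_rate=2e-3, ado_rate=0.3, mq_fail_rate=0.01,
                              bq_fail_rate=0.01)
        exp = simulate_experiment(config)
        for cell in exp.cells:
            t = exp.truth[exp.truth["cell_id"] == cell.cell_id]
            calls = cell.df.set_index("pos")
            fp = t[t["event"] == "fp_injected"]["pos"]
            assert (calls.loc[fp, "gt"] == HET).all()
            aa = t[t["event"] == "ado_to_AA"]["pos"]
            assert (calls.loc[aa, "gt"] == HOM_REF).all()
            bb = t[t["event"] == "ado_to_BB"]["pos"]
            assert (calls.loc[bb, "gt"] == HOM_ALT).all()

    def test_fp_spectrum_chi_square_goodness_of_fit(self):
        # ~10,000 injected FPs against the configured 12-class weights
        config = SimulationConfig(target_size_bp=1_000_000, n_cells=1,
                                  n_het_snvs=0, n_hom_snvs=0, n_het_indels=0,
                                  n_hom_indels=0, fp_rate=0.01,
                                  depth_zero_fraction=0.0, seed=17)
        ref = simulate_population_reference(config)
        depth = simulate_depth_profile(config, 0)
        cell, truth = simulate_single_cell_calls(ref, depth, config, 0)
        assert len(truth) > 9_000
        classes = cell.df["ref"].str.cat(cell.df["alt"], sep=">")
        observed = classes.value_counts().reindex(SUBSTITUTION_CLASSES,
                                                  fill_value=0).to_numpy()
        expected = config.fp_spectrum * observed.sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_mismatched_target_rejected(self):
        config = small_config()
        ref = simulate_population_reference(config)
        other = simulate_depth_profile(small_config(target_size_bp=30_000), 0)
        with pytest.raises(ValueError):
            simulate_single_cell_calls(ref, other, config, 0)

    def test_event_rate_matches_configured_ado(self):
        config = SimulationConfig(target_size_bp=400_000, n_cells=1,
                                  n_het_snvs=100_000, n_hom_snvs=0,
                                  n_het_indels=0, n_hom_indels=0,
                                  ado_rate=0.2, ado_hotspot_fraction=0.0,
                                  depth_zero_fraction=0.0, fp_rate=0.0, seed=3)
        ref = simulate_population_reference(config)
        depth = simulate_depth_profile(config, 0)
        _, truth = simulate_single_cell_calls(ref, depth, config, 0)
        rate = len(truth) / 100_000
        se = np.sqrt(0.2 * 0.8 / 100_000)
        assert abs(rate - 0.2) <= 3 * se


class TestQCMatrix:
    def test_all_pass_probability_one(self):
        qc = simulate_qc_matrix(5, [1.0] * 22, seed=1)
        assert (qc.positives_per_cell() == 22).all()

    def test_all_fail_probability_zero(self):
        qc = simulate_qc_matrix(5, [0.0] * 22, seed=1)
        assert (qc.positives_per_cell() == 0).all()

    def test_explicit_fixture_counts(self):
        qc = qc_matrix_from_counts(n_full=14, n_partial=6)
        assert qc.n_cells == 20
        assert int((qc.positives_per_cell() == 22).sum()) == 14

    def test_wrong_probability_length_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_qc_matrix(5, [0.5] * 21, seed=1)
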