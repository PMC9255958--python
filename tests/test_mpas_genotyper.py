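"""Genotyping rules: exact CIs, population threshold, mosaic calls,
SNP genotypes, blastocyst calls and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonomosaic.mpas_genotyper import (
    GenotypingThresholds,
    PopulationThreshold,
    call_blastocyst,
    call_tissue_mosaic,
    classify_variant,
    exact_binomial_ci,
    exact_binomial_ci_arrays,
    genotype_snp,
    population_threshold,
    qc_blastocyst,
    run_genotyping,
)
from gonomosaic.synthetic_cohort import SimulationConfig, simulate_cohort

from oracles import clopper_pearson_oracle

THR = GenotypingThresholds()


class TestExactBinomialCI:
    def test_boundaries(self):
        assert exact_binomial_ci(0, 100)[0] == 0.0
        assert exact_binomial_ci(100, 100)[1] == 1.0

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(0, 0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            depth = int(rng.integers(1, 5000))
            alt = int(rng.integers(0, depth + 1))
            lo, hi = exact_binomial_ci(alt, depth)
            olo, ohi = clopper_pearson_oracle(alt, depth)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert hi == pytest.approx(ohi, abs=1e-9)

    def test_vectorised_agrees_with_scalar(self):
        alt = np.array([0, 5, 50, 100])
        depth = np.array([100, 100, 100, 100])
        lo, hi = exact_binomial_ci_arrays(alt, depth)
        for i in range(4):
            slo, shi = exact_binomial_ci(int(alt[i]), int(depth[i]))
            assert lo[i] == pytest.approx(slo, abs=1e-12)
            assert hi[i] == pytest.approx(shi, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(depth=st.integers(1, 2000), alt=st.integers(0, 2000))
    def test_ci_lower_monotone_in_alt_count(self, depth, alt):
        alt = min(alt, depth)
        lo, hi = exact_binomial_ci(alt, depth)
        assert 0.0 <= lo <= alt / depth <= hi <= 1.0
        if alt < depth:
            lo2, _ = exact_binomial_ci(alt + 1, depth)
            assert lo2 >= lo  # more alt reads never weaken the call


class TestPopulationThreshold:
    def test_all_zero_noise_gives_zero(self):
        thr = population_threshold([0.0] * 50)
        assert thr.value == 0.0 and thr.n_sites_used == 50

    def test_binomial_noise_stays_small(self):
        rng = np.random.default_rng(11)
        afs = rng.binomial(1000, 0.001, size=500) / 1000
        thr = population_threshold(afs)
        # an independent quantile computation on the same sample
        assert thr.value == float(np.quantile(afs, 0.95, method="higher"))
        assert thr.value < 0.01

    def test_invariant_under_duplication(self):
        afs = [0.0, 0.001, 0.002, 0.004, 0.01]
        assert population_threshold(afs).value == population_threshold(afs * 3).value

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            population_threshold([])


def _obs(alt, depth):
    lo, hi = exact_binomial_ci(alt, depth)
    return {"depth": depth, "af": alt / depth, "ci_lower": lo, "ci_upper": hi}


class TestTissueMosaicCall:
    def test_depth_below_100_never_mosaic(self):
        pop = PopulationThreshold(0.001, 10)
        assert call_tissue_mosaic(_obs(50, 99), [_obs(0, 1000)], pop, THR) is False

    def test_clear_signal_over_clean_controls(self):
        pop = PopulationThreshold(0.005, 10)
        obs = _obs(50, 1000)        # AF 0.05, ci_lower ~0.037
        ctrls = [_obs(0, 1000), _obs(0, 1000)]
        assert obs["ci_lower"] > max(pop.value, max(c["ci_upper"] for c in ctrls))
        assert call_tissue_mosaic(obs, ctrls, pop, THR) is True

    def test_signal_in_both_controls_fails_criterion_three(self):
        pop = PopulationThreshold(0.005, 10)
        obs = _obs(300, 1000)
        ctrls = [_obs(100, 1000), _obs(100, 1000)]  # ci_lower ~0.082 > pop
        assert all(c["ci_lower"] > pop.value for c in ctrls)
        assert call_tissue_mosaic(obs, ctrls, pop, THR) is False

    def test_no_controls_means_uncallable(self):
        pop = PopulationThreshold(0.005, 10)
        assert call_tissue_mosaic(_obs(50, 1000), [], pop, THR) is None

    def test_tie_with_threshold_rejected(self):
        # "did not overlap" is strict: ci_lower == threshold is not mosaic
        obs = _obs(50, 1000)
        pop = PopulationThreshold(obs["ci_lower"], 10)
        assert call_tissue_mosaic(obs, [_obs(0, 100000)], pop, THR) is False


@pytest.mark.parametrize("sperm,soma,expected", [
    (True, False, "sperm_only"),
    (True, True, "shared"),
    (False, True, "soma_only"),
    (False, False, "rejected"),
])
def test_classify_variant(sperm, soma, expected):
    assert classify_variant(sperm, soma) == expected


class TestSnpGenotyping:
    @pytest.mark.parametrize("af,expected", [
        (0.19, "ref_hom"),
        (0.2, "het"),    # closed-left boundary
        (0.79, "het"),
        (0.8, "alt_hom"),  # closed-left boundary
        (1.0, "alt_hom"),
    ])
    def test_af_bands(self, af, expected):
        assert genotype_snp({"depth": 500, "af": af}, THR) == expected

    def test_low_depth_uncallable(self):
        assert genotype_snp({"depth": 99, "af": 0.5}, THR) is None


class TestBlastocystCall:
    def test_depth_19_is_no_data(self):
        assert call_blastocyst(_obs(10, 19), THR) == "no_data"

    def test_depth_20_half_alt_positive(self):
        obs = _obs(10, 20)  # ci_lower ~0.27
        assert obs["ci_lower"] > 0.25
        assert call_blastocyst(obs, THR, mode="mosaic") == "positive"

    def test_mosaic_and_snp_modes_diverge(self):
        obs = _obs(2, 20)  # af 0.10 but ci_lower ~0.012
        assert call_blastocyst(obs, THR, mode="mosaic") == "negative"
        assert call_blastocyst(obs, THR, mode="snp") == "positive"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(depth=st.integers(20, 500), alt=st.integers(0, 499))
    def test_monotone_in_alt_count(self, depth, alt):
        alt = min(alt, depth - 1)
        first = call_blastocyst(_obs(alt, depth), THR, mode="mosaic")
        second = call_blastocyst(_obs(alt + 1, depth), THR, mode="mosaic")
        assert not (first == "positive" and second == "negative")


class TestBlastocystQC:
    def test_no_coverage_fails(self):
        import pandas as pd
        obs = pd.DataFrame({"depth": []})
        ok, frac = qc_blastocyst(obs, panel_size=50)
        assert (ok, frac) == (False, 0.0)

    def test_exactly_ten_percent_passes(self):
        import pandas as pd
        obs = pd.DataFrame({"depth": [25] * 5 + [5] * 45})
        ok, frac = qc_blastocyst(obs, panel_size=50)
        assert ok and frac == pytest.approx(0.10)

    def test_low_quality_blastocysts_excluded(self, default_genotyping):
        qc = default_genotyping.blastocyst_qc
        failed = qc[~qc["qc_pass"]]
        assert len(failed) == 2
        assert set(failed["donor_id"]) == {"F02"}
        # and they are absent from the donor's transmission matrix
        assert set(failed["sample_id"]).isdisjoint(
            default_genotyping.matrices["F02"].calls.columns)


class TestCohortAccuracy:
    def test_sensitivity_and_specificity_on_clean_cohort(self):
        """Detection of true sperm mosaics with AF >= 0.03 at deep coverage."""
        config = SimulationConfig(
            n_donors=2, n_mosaic_per_donor=30, n_soma_only_per_donor=5,
            af_min=0.03, af_max=0.25, n_snps=60,
            n_blastocysts_per_donor=2, n_low_quality_blastocysts=0,
            depth_mean_tissue=3000.0, seq_error_rate=0.001, seed=42)
        cohort = simulate_cohort(config)
        geno = run_genotyping(cohort.manifest, cohort.panel, cohort.observations)
        truth = cohort.truth_variants
        gonadal_truth = truth[(truth["category_true"] != "soma_only")
                              & (truth["true_sperm_af"] >= 0.03)]
        called = geno.gonadal_calls()
        called_keys = set(zip(called["donor_id"], called["variant_id"]))
        hits = sum((r.donor_id, r.variant_id) in called_keys
                   for r in gonadal_truth.itertuples(index=False))
        sensitivity = hits / len(gonadal_truth)
        # negatives: every (donor, candidate) pair that is not a true sperm mosaic
        true_keys = set(zip(truth.loc[truth["category_true"] != "soma_only",
                                      "donor_id"],
                            truth.loc[truth["category_true"] != "soma_only",
                                      "variant_id"]))
        all_pairs = set(zip(geno.mosaic_calls["donor_id"],
                            geno.mosaic_calls["variant_id"]))
        negatives = all_pairs - true_keys
        false_pos = sum(k in called_keys for k in negatives)
        specificity = 1 - false_pos / len(negatives)
        assert sensitivity >= 0.95
        assert specificity >= 0.90

    def test_transmission_matrix_cells_partition(self, default_genotyping):
        for m in default_genotyping.matrices.values():
            counts = m.cell_counts()
            assert sum(counts.values()) == m.n_variants * m.n_blastocysts
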