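"""Transmission expectation: AF-to-probability, Poisson-binomial Monte
Carlo with Gaussian histogram fit, observed-vs-expected verdicts, and
the AF-transmission correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gonomosaic.mpas_genotyper import TransmissionMatrix
from gonomosaic.transmission_model import (
    af_transmission_correlation,
    compare_observed,
    expectation_from_matrix,
    expected_transmissions,
    pooled_expectation_from_matrices,
    transmission_probability,
)

from oracles import poisson_binomial_moments


class TestTransmissionProbability:
    def test_autosome_identity(self):
        assert transmission_probability(0.0) == 0.0
        assert transmission_probability(0.247, "chr7") == 0.247

    def test_sex_chromosome_doubles_with_warning(self):
        with pytest.warns(UserWarning, match="sex-chromosome"):
            assert transmission_probability(0.1, "chrX") == pytest.approx(0.2)
        with pytest.warns(UserWarning):
            assert transmission_probability(0.7, "chrY") == 1.0  # capped

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            transmission_probability(1.2)


class TestExpectedTransmissions:
    def test_certain_transmission_is_degenerate(self):
        res = expected_transmissions([1.0], n_units=10, n_draws=500, seed=0)
        assert res.mc_mean == 10.0 and res.mc_sd == 0.0
        assert res.gaussian_mean == 10.0 and res.gaussian_sd == 0.0
        assert res.exact_mean == 10.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            expected_transmissions([], n_units=5)

    def test_matches_binomial_oracle(self):
        """4 variants at p=0.5 over 2 units is Binomial(8, 0.5)."""
        res = expected_transmissions([0.5] * 4, n_units=2, n_draws=20_000, seed=3)
        counts = np.bincount(res_totals(res), minlength=9)[:9]
        expected = stats.binom.pmf(np.arange(9), 8, 0.5) * 20_000
        chi2 = stats.chisquare(counts, expected)
        assert chi2.pvalue > 0.01

    def test_poisson_binomial_moments_within_4se(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.3, size=25)
        n_i = rng.integers(5, 15, size=25)
        res = expected_transmissions(p, n_units_per_variant=n_i,
                                     n_units=int(n_i.max()),
                                     n_draws=10_000, seed=11)
        mean, sd = poisson_binomial_moments(p, n_i)
        assert res.exact_mean == pytest.approx(mean, abs=1e-12)
        assert res.exact_sd == pytest.approx(sd, abs=1e-12)
        assert abs(res.mc_mean - mean) <= 4 * sd / np.sqrt(10_000)
        assert res.mc_sd == pytest.approx(sd, rel=0.1)

    def test_gaussian_fit_close_to_exact_mean(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            p = rng.uniform(0.02, 0.25, size=20)
            res = expected_transmissions(p, n_units=10, n_draws=10_000,
                                         seed=trial)
            if res.exact_mean >= 2:
                assert abs(res.gaussian_mean - res.exact_mean) <= 0.5

    def test_scale_equivariance(self):
        p = [0.1, 0.2, 0.05]
        a = expected_transmissions(p, n_units=7, n_draws=200, seed=0)
        b = expected_transmissions(p, n_units=14, n_draws=200, seed=0)
        assert b.exact_mean == pytest.approx(2 * a.exact_mean, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = expected_transmissions([0.1, 0.3], n_units=5, n_draws=1000, seed=9)
        b = expected_transmissions([0.1, 0.3], n_units=5, n_draws=1000, seed=9)
        assert a.mc_mean == b.mc_mean and a.gaussian_mean == b.gaussian_mean


def res_totals(res):
    """Re-draw the Monte Carlo totals a result was built from."""
    rng = np.random.default_rng(res.seed)
    return rng.binomial(res.n_units_per_variant, res.p_vector,
                        size=(res.n_draws, len(res.p_vector))).sum(axis=1)


class TestCompareObserved:
    def test_mean_is_within_ci(self):
        res = expected_transmissions([0.2] * 10, n_units=10, n_draws=5000, seed=0)
        assert compare_observed(res, round(res.gaussian_mean)) == "within_ci"

    def test_extremes_flagged(self):
        res = expected_transmissions([0.2] * 10, n_units=10, n_draws=5000, seed=0)
        assert compare_observed(res, 0) == "under"
        assert compare_observed(res, 100) == "over"


def _matrix(donor, cells, variants=None, blastocysts=None):
    variants = variants or [f"v{i}" for i in range(len(cells))]
    blastocysts = blastocysts or [f"{donor}_b{i}" for i in range(len(cells[0]))]
    grid = pd.DataFrame(cells, index=variants, columns=blastocysts, dtype=object)
    return TransmissionMatrix(donor_id=donor, calls=grid)


def _calls(donor, afs, variants=None):
    variants = variants or [f"v{i}" for i in range(len(afs))]
    return pd.DataFrame([
        {"donor_id": donor, "variant_id": v, "chrom": "chr1", "sperm_af": a,
         "category": "sperm_only"}
        for v, a in zip(variants, afs)])


class TestMatrixExpectation:
    def test_no_data_cells_shrink_the_denominator(self):
        m = _matrix("D1", [["positive", "no_data"], ["negative", "negative"]])
        calls = _calls("D1", [0.5, 0.25])
        res = expectation_from_matrix(m, calls, n_draws=100, seed=0)
        # variant v0 has 1 unit with data, v1 has 2
        assert res.exact_mean == pytest.approx(1 * 0.5 + 2 * 0.25)
        assert res.observed_total == 1

    def test_pooled_mean_is_sum_over_families(self):
        """Offspring mode: 8 families with 1-3 children each pool additively."""
        rng = np.random.default_rng(4)
        matrices, frames = {}, []
        expected_mean = 0.0
        for f in range(8):
            n_child = int(rng.integers(1, 4))
            n_var = int(rng.integers(2, 6))
            afs = rng.uniform(0.01, 0.2, size=n_var)
            cells = [["negative"] * n_child for _ in range(n_var)]
            donor = f"FAM{f}"
            matrices[donor] = _matrix(donor, cells)
            frames.append(_calls(donor, afs))
            expected_mean += n_child * afs.sum()
        pooled = pooled_expectation_from_matrices(
            matrices, pd.concat(frames, ignore_index=True),
            n_draws=100, seed=0)
        assert pooled.exact_mean == pytest.approx(expected_mean, abs=1e-9)

    def test_father_without_variants_contributes_nothing(self):
        matrices = {
            "F1": _matrix("F1", [["negative", "negative"]]),
            "F2": TransmissionMatrix(
                donor_id="F2",
                calls=pd.DataFrame(dtype=object)),
        }
        pooled = pooled_expectation_from_matrices(
            matrices, _calls("F1", [0.1]), n_draws=100, seed=0)
        assert pooled.exact_mean == pytest.approx(0.2)


class TestCorrelation:
    def test_all_zero_rates_degenerate_not_an_exception(self):
        m = _matrix("D1", [["negative"] * 4 for _ in range(5)])
        res = af_transmission_correlation({"D1": m},
                                          _calls("D1", [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert res.degenerate and np.isnan(res.r)

    def test_perfectly_linear_rates(self):
        cells = [
            ["negative"] * 4,
            ["positive"] + ["negative"] * 3,
            ["positive"] * 2 + ["negative"] * 2,
            ["positive"] * 3 + ["negative"],
        ]
        m = _matrix("D1", cells)
        res = af_transmission_correlation(
            {"D1": m}, _calls("D1", [0.0, 0.125, 0.25, 0.375]))
        assert res.r == pytest.approx(1.0)

    def test_too_few_variants_rejected(self):
        m = _matrix("D1", [["positive"], ["negative"]])
        with pytest.raises(ValueError, match=">= 3"):
            af_transmission_correlation({"D1": m}, _calls("D1", [0.1, 0.2]))

    def test_positive_on_study_scale_cohort(self, default_genotyping):
        res = af_transmission_correlation(default_genotyping.matrices,
                                          default_genotyping.mosaic_calls)
        assert res.r > 0
        assert res.n_variants >= 40
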