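"""DOSY fast-exchange binding chain and its oracles.

The equilibrium solver is checked against a bisection root-finder on the
mass-action equation, and the closed-form chain against an exact
generate-then-invert round trip.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrbind import (
    BindingExperiment,
    DiffusionRecord,
    analyze_binding,
    binding_constant,
    check_concentration_trend,
    complex_concentration,
    free_fraction,
    solve_equilibrium,
)
from nmrbind.dosy import (
    DegenerateContrastError,
    SaturationError,
    experiment_from_records,
    select_free_ligand_record,
)
from nmrbind.datasets import load_free_diffusion


def bisect_equilibrium(ka, c_dna, c_l):
    """Oracle: root of Ka x^2 - (Ka(CD+CL)+1) x + Ka CD CL in [0, min)."""
    if ka == 0:
        return 0.0

    def f(x):
        return ka * x * x - (ka * (c_dna + c_l) + 1.0) * x + ka * c_dna * c_l

    lo, hi = 0.0, min(c_dna, c_l)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestFreeFraction:
    def test_study_inputs_give_86_percent_bound(self):
        mf = free_fraction(0.93, 2.12, 0.74)
        assert mf == pytest.approx(0.1377, abs=5e-4)
        assert 1.0 - mf == pytest.approx(0.86, abs=0.005)

    def test_fully_free_and_fully_bound(self):
        assert free_fraction(2.12, 2.12, 0.74) == 1.0
        assert free_fraction(0.74, 2.12, 0.74) == 0.0

    def test_degenerate_contrast_raises(self):
        with pytest.raises(DegenerateContrastError):
            free_fraction(1.0, 0.9, 0.9)

    def test_clip_within_noise_warns(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert free_fraction(0.72, 2.12, 0.74, noise=0.05) == 0.0

    def test_outside_noise_raises(self):
        with pytest.raises(ValueError, match="fast-exchange"):
            free_fraction(0.50, 2.12, 0.74, noise=0.05)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_common_rescaling(self, scale):
        base = free_fraction(0.93, 2.12, 0.74)
        assert free_fraction(0.93 * scale, 2.12 * scale, 0.74 * scale) == \
            pytest.approx(base, rel=1e-9)


class TestClosedFormChain:
    def test_complex_concentration(self):
        assert complex_concentration(0.90, 0.60) == pytest.approx(0.54)
        assert complex_concentration(0.0, 0.60) == 0.0
        assert complex_concentration(1.0, 0.60) == 0.60
        with pytest.raises(ValueError):
            complex_concentration(1.2, 0.60)

    def test_binding_constant_values(self):
        assert binding_constant(0.54, 0.60, 0.60) == pytest.approx(150.0)
        # the 86%-bound equimolar case
        cc = (1.0 - free_fraction(0.93, 2.12, 0.74)) * 0.60
        assert binding_constant(cc, 0.60, 0.60) == pytest.approx(76.0, abs=0.5)
        assert binding_constant(0.0, 0.60, 0.60) == 0.0

    def test_binding_constant_saturation(self):
        with pytest.raises(SaturationError):
            binding_constant(0.60, 0.60, 0.60)

    def test_monotone_in_observed_ligand_coefficient(self):
        # slower apparent ligand diffusion (more bound) never lowers Ka
        kas = []
        for d_obs in np.linspace(1.8, 0.80, 20):
            mf = free_fraction(d_obs, 2.12, 0.74)
            kas.append(binding_constant(complex_concentration(1 - mf, 0.6),
                                        0.6, 0.6))
        assert np.all(np.diff(kas) >= 0)


class TestAnalyzeBinding:
    def test_study_row_compound1(self, dosy_1):
        result = analyze_binding(dosy_1)
        assert result.mf_bound == pytest.approx(0.86, abs=0.005)
        assert result.ka == pytest.approx(76.0, abs=0.5)
        assert not result.no_binding
        assert result.assumptions  # echoed in every result

    def test_study_row_compound2(self, dosy_2):
        result = analyze_binding(dosy_2)
        assert result.mf_bound == pytest.approx(0.90, abs=0.005)
        assert result.ka == pytest.approx(150.0, abs=0.5)

    def test_no_binding_flag(self):
        exp = BindingExperiment(c_ligand=0.6, c_dna=0.6, d_obs_ligand=2.12,
                                d_obs_dna=0.75, d_free_ligand=2.12,
                                d_free_dna=0.75)
        result = analyze_binding(exp)
        assert result.no_binding
        assert result.ka == 0.0

    def test_delta_method_sigma_within_factor_2_of_monte_carlo(self, dosy_1, dosy_2):
        """10^4-sample MC propagation of the stated coefficient errors.

        Ka is a steep ratio near saturation, so the MC distribution is
        heavy-tailed and its plain standard deviation diverges; the spread
        is measured as half the central 68.3% interval, the robust
        equivalent of one sigma.
        """
        rng = np.random.default_rng(20240901)
        for exp in (dosy_1, dosy_2):
            res = analyze_binding(exp)
            n = 10_000
            dol = exp.d_obs_ligand + rng.normal(0, exp.sigma_d["d_obs_ligand"], n)
            dod = exp.d_obs_dna + rng.normal(0, exp.sigma_d["d_obs_dna"], n)
            dfl = exp.d_free_ligand + rng.normal(0, exp.sigma_d["d_free_ligand"], n)
            mf = np.clip((dol - dod) / (dfl - dod), 1e-6, 1 - 1e-6)
            cc = (1 - mf) * exp.c_ligand
            ka = cc / ((exp.c_dna - cc) * (exp.c_ligand - cc))
            q16, q84 = np.quantile(ka, [0.15865, 0.84135])
            mc_spread = 0.5 * (q84 - q16)
            assert 0.5 < mc_spread / res.ka_sigma < 2.0


class TestSolveEquilibrium:
    def test_study_scale_value(self):
        assert solve_equilibrium(150.0, 0.60, 0.60) == pytest.approx(0.54, abs=1e-3)

    def test_zero_ka(self):
        assert solve_equilibrium(0.0, 0.6, 0.6) == 0.0

    def test_stoichiometric_limit(self):
        assert solve_equilibrium(1e9, 0.6, 0.4) == pytest.approx(0.4, rel=1e-4)

    @given(ka=st.floats(0.1, 500.0), c_dna=st.floats(0.1, 2.0),
           c_l=st.floats(0.1, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_bisection_oracle(self, ka, c_dna, c_l):
        assert solve_equilibrium(ka, c_dna, c_l) == pytest.approx(
            bisect_equilibrium(ka, c_dna, c_l), rel=1e-8, abs=1e-12)

    @given(ka=st.floats(1.0, 500.0), c_dna=st.floats(0.1, 2.0),
           c_l=st.floats(0.1, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_exact_round_trip_recovers_ka(self, ka, c_dna, c_l):
        """generate exact averaged coefficients -> analyze -> same Ka.

        The complex coefficient is supplied exactly, so the inversion is
        algebraic and must agree to 1e-6 relative.
        """
        d_free_l, d_complex, d_free_dna = 2.1, 0.70, 0.75
        cc = solve_equilibrium(ka, c_dna, c_l)
        mf_free = (c_l - cc) / c_l
        d_obs_l = mf_free * d_free_l + (1 - mf_free) * d_complex
        mf_free_dna = (c_dna - cc) / c_dna
        d_obs_dna = mf_free_dna * d_free_dna + (1 - mf_free_dna) * d_complex
        exp = BindingExperiment(c_ligand=c_l, c_dna=c_dna, d_obs_ligand=d_obs_l,
                                d_obs_dna=d_obs_dna, d_free_ligand=d_free_l,
                                d_free_dna=d_free_dna)
        result = analyze_binding(exp, d_complex=d_complex)
        assert result.ka == pytest.approx(ka, rel=1e-6)


class TestConcentrationTrend:
    def test_study_series_is_aggregation_consistent(self):
        report = check_concentration_trend(load_free_diffusion("1"))
        assert report.monotone_decreasing
        assert not report.violations
        assert "self-aggregation" in report.conclusion

    def test_constant_coefficients_show_no_trend(self):
        recs = [DiffusionRecord("x", c, 2.0, 0.0) for c in (0.1, 0.2, 0.4)]
        report = check_concentration_trend(recs)
        assert not report.monotone_decreasing
        assert "no concentration trend" in report.conclusion

    def test_increasing_coefficients_flagged(self):
        recs = [DiffusionRecord("x", c, d, 0.01)
                for c, d in [(0.1, 1.5), (0.3, 1.8), (0.6, 2.2)]]
        report = check_concentration_trend(recs)
        assert report.violations
        assert "inconsistent" in report.conclusion

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            check_concentration_trend([DiffusionRecord("x", 0.1, 2.0)])

    def test_mixed_species_is_an_error(self):
        recs = [DiffusionRecord("x", 0.1, 2.0), DiffusionRecord("y", 0.2, 1.9)]
        with pytest.raises(ValueError, match="mix"):
            check_concentration_trend(recs)


class TestExperimentAssembly:
    def test_free_ligand_comes_from_most_dilute_row(self):
        recs = [DiffusionRecord("ligand_free", 0.78, 1.78, 0.05),
                DiffusionRecord("ligand_free", 0.05, 2.12, 0.10)]
        assert select_free_ligand_record(recs).d_coef == 2.12

    def test_assembled_experiment_matches_manual(self, dosy_1):
        assert dosy_1.d_free_ligand == 2.12  # the 0.05 mM value, not 1.78
        assert dosy_1.d_obs_ligand == 0.93
        assert dosy_1.sigma_d["d_free_ligand"] == 0.10

    def test_missing_species_rows_rejected(self):
        recs = [DiffusionRecord("ligand_obs", 0.6, 0.93, 0.05)]
        with pytest.raises(ValueError, match="lacks species"):
            experiment_from_records(recs, c_ligand=0.6, c_dna=0.6)
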