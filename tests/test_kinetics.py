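import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scmskit as sk
from scmskit.errors import (
    CrossoverNotFoundError,
    InvalidParameterError,
    InvalidStateError,
)

from oracles import euler_bivalent, langmuir_occupancy


class TestLocalConcentration:
    def test_reference_radius(self):
        # one molecule in a half-sphere of 180 A: 1/(N_A * (2/3)*pi*(1.8e-7 dm)^3)
        assert sk.local_concentration(180.0) == pytest.approx(1.360e-4, rel=1e-3)

    def test_cubic_scaling(self):
        assert sk.local_concentration(360.0) == pytest.approx(
            sk.local_concentration(180.0) / 8.0, rel=1e-12
        )

    def test_monotone_vanishing_at_large_radius(self):
        radii = np.logspace(1, 6, 30)
        vals = [sk.local_concentration(r) for r in radii]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-12

    @pytest.mark.parametrize("r", [0.0, -5.0])
    def test_nonpositive_radius_rejected(self, r):
        with pytest.raises(InvalidParameterError):
            sk.local_concentration(r)


class TestCompositeK2:
    def test_reference_value(self):
        assert sk.composite_k2(1.85e5, 180.0, 185.0) == pytest.approx(0.136, abs=1e-3)

    def test_no_penalty_identity(self):
        k1, r = 3.3e5, 240.0
        assert sk.composite_k2(k1, r, 1.0) == pytest.approx(
            k1 * sk.local_concentration(r), rel=1e-12
        )

    def test_penalty_proportionality(self):
        assert sk.composite_k2(1e5, 180.0, 370.0) == pytest.approx(
            sk.composite_k2(1e5, 180.0, 185.0) / 2.0, rel=1e-12
        )

    def test_zero_penalty_rejected(self):
        with pytest.raises(InvalidParameterError):
            sk.composite_k2(1e5, 180.0, 0.0)


class TestIntrinsicKd:
    def test_reference_value(self):
        assert sk.intrinsic_kd(1.85e5, 0.0085) == pytest.approx(4.59e-8, abs=5e-11)

    def test_irreversible_limit(self):
        assert sk.intrinsic_kd(1.85e5, 0.0) == 0.0

    def test_unit_ratio(self):
        assert sk.intrinsic_kd(2.0, 2.0) == 1.0

    def test_zero_k1_rejected(self):
        with pytest.raises(InvalidParameterError):
            sk.intrinsic_kd(0.0, 0.0085)


class TestRateParameters:
    def test_derived_quantities_consistent(self, ref_params):
        assert ref_params.k2 == pytest.approx(
            ref_params.k1 * ref_params.L / ref_params.f, rel=1e-12
        )
        assert ref_params.kd_int == pytest.approx(
            ref_params.k_off / ref_params.k1, rel=1e-12
        )

    def test_explicit_k2_mismatch_warns(self):
        with pytest.warns(UserWarning, match="differs from derived"):
            sk.RateParameters(k1=1.85e5, k_off=0.0085, k2_override=0.2)

    def test_explicit_k2_close_is_silent(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            p = sk.RateParameters(k1=1.85e5, k_off=0.0085, k2_override=0.136)
        assert p.k2 == 0.136

    def test_invalid_rejected(self):
        with pytest.raises(InvalidParameterError):
            sk.RateParameters(k1=-1.0, k_off=0.0085)
        with pytest.raises(InvalidParameterError):
            sk.RateParameters(k1=1e5, k_off=0.0085, f=0.5)


class TestDerivatives:
    def test_nothing_to_bind(self, ref_params):
        assert sk.derivatives((1.0, 0.0, 0.0, 0.0), ref_params, 0.0) == (0, 0, 0, 0)

    def test_pure_bivalent_only_opens(self, ref_params):
        dU, dG, dR, dB = sk.derivatives((0.0, 0.0, 1.0, 0.0), ref_params, 0.0)
        assert dR < 0 and dG > 0
        assert dU == 0.0 and dB == 0.0

    @given(
        u=st.floats(0, 1),
        g=st.floats(0, 1),
        r=st.floats(0, 1),
        aa=st.floats(0, 1e-6),
        logk1=st.floats(3, 7),
        logkoff=st.floats(-4, 0),
    )
    def test_conservation_by_construction(self, u, g, r, aa, logk1, logkoff):
        total = u + g + r
        if total > 1:
            u, g, r = u / total, g / total, r / total
        b = max(1.0 - u - g - r, 0.0)
        params = sk.RateParameters(k1=10**logk1, k_off=10**logkoff)
        rates = sk.derivatives((u, g, r, b), params, aa)
        scale = max(sum(abs(x) for x in rates), 1.0)
        assert abs(sum(rates)) <= 1e-14 * scale

    def test_negative_state_rejected(self, ref_params):
        with pytest.raises(InvalidStateError):
            sk.derivatives((-0.1, 0.5, 0.3, 0.3), ref_params, 1e-8)


class TestSimulateTimeCourse:
    def test_zero_ligand_gives_zero_signal(self, ref_params):
        tc = sk.simulate_time_course(
            ref_params, sk.BulkLigandSchedule(0.0, 120.0), np.linspace(0, 120, 20)
        )
        assert np.all(tc.signal == 0.0)

    def test_conservation_and_nonnegativity(self, ref_params):
        sched = sk.BulkLigandSchedule(2e-7, 120.0, washout=True, t_washout=600.0)
        tc = sk.simulate_time_course(ref_params, sched)
        total = tc.U + tc.G + tc.R + tc.B
        assert np.max(np.abs(total - 1.0)) <= 1e-8
        assert tc.U.min() >= -1e-10 and tc.B.min() >= -1e-10

    def test_washout_signal_non_increasing(self, ref_params):
        sched = sk.BulkLigandSchedule(2e-7, 120.0, washout=True, t_washout=600.0)
        tc = sk.simulate_time_course(ref_params, sched)
        wash = tc.signal[tc.times >= 120.0]
        assert np.all(np.diff(wash) <= 1e-10)

    @pytest.mark.filterwarnings("ignore:explicit k2")
    def test_monovalent_limit_matches_langmuir(self):
        # bivalent pathway disabled: single-site isotherm with Kd = k_off/k1
        params = sk.RateParameters(k1=1.85e5, k_off=0.0085, k2_override=0.0)
        kd = params.kd_int
        for aa in np.logspace(-9, -6, 20):
            tc = sk.simulate_time_course(
                params,
                sk.BulkLigandSchedule(aa, 1e5),
                [1e5],
                stat_factors=(1, 1, 0, 1),
            )
            assert tc.G[-1] == pytest.approx(langmuir_occupancy(aa, kd), rel=5e-3)

    def test_matches_euler_oracle(self, ref_params):
        sched = sk.BulkLigandSchedule(2e-7, 120.0)
        times = np.arange(10.0, 121.0, 10.0)
        tc = sk.simulate_time_course(ref_params, sched, times)
        euler = euler_bivalent(
            ref_params.k1, ref_params.k_off, ref_params.k2,
            2e-7, 120.0, dt=1e-3, sample_every=10.0,
        )
        sig_euler = np.array([g + r + 2 * b for (_, u, g, r, b) in euler])
        peak = sig_euler.max()
        assert np.max(np.abs(tc.signal - sig_euler)) <= 0.005 * peak

    def test_sample_times_validated(self, ref_params):
        sched = sk.BulkLigandSchedule(1e-8, 120.0)
        with pytest.raises(InvalidParameterError):
            sk.simulate_time_course(ref_params, sched, [0.0, 150.0])
        with pytest.raises(InvalidParameterError):
            sk.simulate_time_course(ref_params, sched, [50.0, 50.0])

    def test_conservation_over_random_parameter_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            params = sk.RateParameters(
                k1=10 ** rng.uniform(4, 7),
                k_off=10 ** rng.uniform(-4, 0),
                r=rng.uniform(60, 500),
                f=rng.uniform(1, 1000),
            )
            aa = 10 ** rng.uniform(-9, -6)
            tc = sk.simulate_time_course(
                params, sk.BulkLigandSchedule(aa, 120.0), np.linspace(0, 120, 30)
            )
            assert np.max(np.abs(tc.U + tc.G + tc.R + tc.B - 1.0)) <= 1e-8


class TestSaturationCurve:
    def test_monotone_in_concentration(self, ref_params):
        grid = np.logspace(-9, -6, 30)
        sim = sk.simulate_saturation_curve(ref_params, grid)
        assert np.all(np.diff(sim.total_signal) >= -1e-10)

    def test_ternary_dominates_at_saturating_conc(self, ref_params):
        sim = sk.simulate_saturation_curve(
            ref_params, np.logspace(-5.5, -3, 6)
        )
        assert sim.B[-1] > sim.R[-1] and sim.B[-1] > sim.G[-1]
        assert sim.B[-1] > 0.9

    def test_zero_incubation_gives_zero(self, ref_params):
        sim = sk.simulate_saturation_curve(ref_params, np.logspace(-9, -6, 6), 0.0)
        assert np.all(sim.total_signal == 0.0)
        assert np.all(sim.U == 1.0)

    def test_grid_validation(self, ref_params):
        with pytest.raises(InvalidParameterError):
            sk.simulate_saturation_curve(ref_params, [1e-9, 2e-9, 3e-9])
        with pytest.raises(InvalidParameterError):
            sk.simulate_saturation_curve(ref_params, np.linspace(1e-9, 5e-9, 8))


class TestCrossover:
    def test_reference_crossover_location(self, ref_params):
        x = sk.find_species_crossover(ref_params)
        # below the crossover red dominates, above it blue dominates
        lo = sk.simulate_time_course(
            ref_params, sk.BulkLigandSchedule(x / 3, 120.0), [120.0]
        ).final_state
        hi = sk.simulate_time_course(
            ref_params, sk.BulkLigandSchedule(x * 3, 120.0), [120.0]
        ).final_state
        assert lo.R > lo.B and hi.B > hi.R

    @pytest.mark.filterwarnings("ignore:explicit k2")
    def test_no_bivalent_pathway_raises(self):
        params = sk.RateParameters(k1=1.85e5, k_off=0.0085, k2_override=0.0)
        with pytest.raises(CrossoverNotFoundError):
            sk.find_species_crossover(params)


class TestMonovalent:
    def test_isotherm_midpoint(self, ref_params):
        aa = ref_params.kd_int
        tc = sk.simulate_monovalent(ref_params, sk.BulkLigandSchedule(aa, 1e5), [1e5])
        assert tc.signal[-1] == pytest.approx(0.5, rel=1e-4)

    def test_zero_ligand_zero_occupancy(self, ref_params):
        tc = sk.simulate_monovalent(
            ref_params, sk.BulkLigandSchedule(0.0, 120.0), [60.0, 120.0]
        )
        assert np.all(tc.signal == 0.0)

    def test_matches_pseudo_first_order_closed_form(self, ref_params):
        aa = 5e-8
        times = np.linspace(1.0, 120.0, 40)
        tc = sk.simulate_monovalent(ref_params, sk.BulkLigandSchedule(aa, 120.0), times)
        k_obs = ref_params.k1 * aa + ref_params.k_off
        eq = aa / (aa + ref_params.kd_int)
        closed = eq * (1.0 - np.exp(-k_obs * times))
        assert np.max(np.abs(tc.signal - closed)) <= 1e-6

    def test_no_bivalent_species(self, ref_params):
        tc = sk.simulate_monovalent(
            ref_params, sk.BulkLigandSchedule(1e-7, 120.0), np.linspace(0, 120, 10)
        )
        assert np.all(tc.R == 0.0) and np.all(tc.B == 0.0)
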