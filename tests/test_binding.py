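"""Unit and property tests for the cassette equilibrium solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edaffinity.binding import (
    AntibodySites,
    BindingSystem,
    DialysisGeometry,
    Ligand,
    correction_factor,
    level_scale_factor,
    muller_kd,
    predict_inhibition_curve,
    solve_equilibrium,
)
from edaffinity.oracle import oracle_equilibrium


def bisect_tracer_only(site_conc, kd, amount, v_sample=100.0, v_total=400.0):
    """Independent 1-D bisection on 400·f + v_s·S·f/(K+f) = amount."""
    lo, hi = 0.0, amount / v_total
    for _ in range(200):
        f = 0.5 * (lo + hi)
        if f * v_total + v_sample * site_conc * f / (kd + f) < amount:
            lo = f
        else:
            hi = f
    return 0.5 * (lo + hi)


class TestSolveEquilibrium:
    def test_no_binder_is_passive_split(self):
        st_ = solve_equilibrium(BindingSystem.standard(0.0, 2.0))
        assert st_.free_tracer == pytest.approx(500.0 / 400.0, abs=1e-9)
        assert st_.bound_tracer == 0.0

    def test_worked_case_matches_independent_bisection(self, worked_system):
        f_expected = bisect_tracer_only(2.4, 2.0, 500.0)
        st_ = solve_equilibrium(worked_system)
        assert st_.free_tracer == pytest.approx(f_expected, abs=1e-9)
        assert st_.bound_tracer == pytest.approx(
            2.4 * f_expected / (2.0 + f_expected), abs=1e-9
        )
        # the canonical numbers: free ≈ 1.044 nM, bound ≈ 0.823 nM
        assert st_.free_tracer == pytest.approx(1.0442, abs=5e-4)
        assert st_.bound_tracer == pytest.approx(0.8232, abs=5e-4)

    def test_huge_kd_limits_to_no_binder(self):
        weak = solve_equilibrium(BindingSystem.standard(2.4, 1e9))
        assert weak.free_tracer == pytest.approx(1.25, abs=1e-6)
        assert weak.bound_tracer == pytest.approx(0.0, abs=1e-6)

    def test_mass_conservation_with_inhibitor(self):
        sys_ = BindingSystem.standard(
            10.0, 1.5, inhibitor_kd=3.0, inhibitor_amount=2000.0
        )
        st_ = solve_equilibrium(sys_)
        tracer_amount = st_.free_tracer * 400.0 + st_.bound_tracer * 100.0
        inhib_amount = st_.free_inhibitor * 400.0 + st_.bound_inhibitor * 100.0
        assert tracer_amount == pytest.approx(500.0, rel=1e-9)
        assert inhib_amount == pytest.approx(2000.0, rel=1e-9)

    def test_bound_tracer_decreases_with_inhibitor(self):
        bounds = [
            solve_equilibrium(
                BindingSystem.standard(2.4, 2.0, inhibitor_kd=2.0, inhibitor_amount=a)
            ).bound_tracer
            for a in (0.0, 100.0, 1000.0, 10000.0)
        ]
        assert all(b1 > b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_b_increases_with_site_conc(self):
        bs = []
        for site in (0.5, 2.0, 8.0, 32.0):
            st_ = solve_equilibrium(BindingSystem.standard(site, 2.0))
            bs.append(st_.bound_tracer / st_.total_tracer_sample)
        assert all(b1 < b2 for b1, b2 in zip(bs, bs[1:]))

    def test_vanishing_sites_gives_even_concentration_split(self):
        st_ = solve_equilibrium(BindingSystem.standard(1e-9, 2.0))
        pct_sample = (
            100.0
            * st_.total_tracer_sample
            / (st_.total_tracer_sample + st_.total_tracer_buffer)
        )
        assert pct_sample == pytest.approx(50.0, abs=1e-4)


class TestOracleEquivalence:
    def test_worked_case_agreement(self, worked_system):
        s = solve_equilibrium(worked_system)
        o = oracle_equilibrium(worked_system)
        assert abs(s.free_tracer - o.free_tracer) < 1e-6
        assert abs(s.bound_tracer - o.bound_tracer) < 1e-6

    def test_symmetric_ligands_bind_equally(self):
        geom = DialysisGeometry()
        tracer = Ligand("A", 2.0, 300.0, "sample")
        inhib = Ligand("B", 2.0, 300.0, "sample")
        st_ = oracle_equilibrium(BindingSystem(geom, AntibodySites(5.0), tracer, inhib))
        assert st_.bound_tracer == pytest.approx(st_.bound_inhibitor, abs=1e-9)
        assert st_.free_tracer == pytest.approx(st_.free_inhibitor, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        site=st.floats(0.0, 50.0),
        kd_t=st.floats(0.1, 100.0),
        kd_i=st.floats(0.1, 100.0),
        amt_t=st.floats(10.0, 1e4),
        amt_i=st.floats(10.0, 1e4),
    )
    def test_solver_matches_oracle_on_grid(self, site, kd_t, kd_i, amt_t, amt_i):
        sys_ = BindingSystem(
            DialysisGeometry(),
            AntibodySites(site),
            Ligand("tracer", kd_t, amt_t, "sample"),
            Ligand("inhibitor", kd_i, amt_i, "buffer"),
        )
        s = solve_equilibrium(sys_)
        o = oracle_equilibrium(sys_)
        assert abs(s.free_tracer - o.free_tracer) < 1e-6
        assert abs(s.free_inhibitor - o.free_inhibitor) < 1e-6
        assert abs(s.bound_tracer - o.bound_tracer) < 1e-6
        assert abs(s.bound_inhibitor - o.bound_inhibitor) < 1e-6
        # mass conservation at 1e-9 relative
        assert s.free_tracer * 400 + s.bound_tracer * 100 == pytest.approx(
            amt_t, rel=1e-9
        )
        assert s.free_inhibitor * 400 + s.bound_inhibitor * 100 == pytest.approx(
            amt_i, rel=1e-9
        )


class TestMullerAlgebra:
    @pytest.mark.parametrize(
        "b,expected",
        [(0.0, 1.0), (1.0, 0.0), (0.41, 0.46905), (0.5, 0.375)],
    )
    def test_correction_factor(self, b, expected):
        assert correction_factor(b) == pytest.approx(expected, abs=1e-12)

    def test_correction_factor_factorized_form(self):
        for b in np.linspace(0.0, 1.0, 21):
            assert correction_factor(b) == pytest.approx(
                (1 - b) * (1 - b / 2), abs=1e-12
            )

    def test_correction_factor_domain(self):
        with pytest.raises(ValueError):
            correction_factor(-0.1)
        with pytest.raises(ValueError):
            correction_factor(1.1)

    @pytest.mark.parametrize(
        "i50,tt,b,expected",
        [
            (3.25, 1.25, 0.0, 2.0),
            (1.25, 1.25, 0.7, 0.0),
            (5.43, 1.25, 0.41, 1.960629),
        ],
    )
    def test_muller_kd(self, i50, tt, b, expected):
        assert muller_kd(i50, tt, b) == pytest.approx(expected, abs=1e-6)

    def test_muller_kd_rejects_negative(self):
        with pytest.raises(ValueError):
            muller_kd(1.0, 1.25, 0.5)


class TestInhibitionCurve:
    def test_endpoints_and_saturation(self, worked_system):
        sys_ = BindingSystem.standard(2.4, 2.0, inhibitor_kd=2.0)
        curve = predict_inhibition_curve(sys_, [0.0, 10.0, 1e6])
        assert curve.mean_inhibition[0] == 0.0
        assert curve.mean_inhibition[-1] > 99.0

    def test_self_competition_crosses_50_at_oracle_i50(self):
        """The model curve must cross 50 % at the I50 found by a fine
        brute-force scan with the independent oracle solver."""
        sys_ = BindingSystem.standard(2.4, 2.0, inhibitor_kd=2.0)
        bound0 = oracle_equilibrium(sys_).bound_tracer
        amounts = np.logspace(2.5, 3.7, 120)  # nM·µL around the crossing
        bound = np.array(
            [
                oracle_equilibrium(
                    BindingSystem.standard(
                        2.4, 2.0, inhibitor_kd=2.0, inhibitor_amount=a
                    )
                ).bound_tracer
                for a in amounts
            ]
        )
        inhibition = 100 * (1 - bound / bound0)
        i_cross = np.searchsorted(inhibition, 50.0)
        a_lo, a_hi = amounts[i_cross - 1], amounts[i_cross]
        # log-linear refinement of the brute-force bracket
        y_lo, y_hi = inhibition[i_cross - 1], inhibition[i_cross]
        a50 = 10 ** (
            np.log10(a_lo)
            + (50 - y_lo) / (y_hi - y_lo) * (np.log10(a_hi) - np.log10(a_lo))
        )

        curve = predict_inhibition_curve(sys_, [0.0, *amounts], scale="buffer-initial")
        levels, y = curve.levels[1:], curve.mean_inhibition[1:]
        j = np.searchsorted(y, 50.0)
        model_a50 = 10 ** (
            np.log10(levels[j - 1])
            + (50 - y[j - 1]) / (y[j] - y[j - 1]) * (np.log10(levels[j]) - np.log10(levels[j - 1]))
        )
        assert model_a50 * 300.0 == pytest.approx(a50, rel=1e-4)

    def test_no_antibody_curve_is_error(self):
        sys_ = BindingSystem.standard(0.0, 2.0, inhibitor_kd=2.0)
        with pytest.raises(ValueError):
            predict_inhibition_curve(sys_, [0.0, 100.0])

    def test_level_scales(self, geometry):
        assert level_scale_factor(geometry, "total-volume") == 400.0
        assert level_scale_factor(geometry, "buffer-initial") == 300.0
        with pytest.raises(ValueError):
            level_scale_factor(geometry, "nonsense")


class TestDomainTypes:
    def test_geometry_rejects_nonpositive_volumes(self):
        with pytest.raises(ValueError):
            DialysisGeometry(0.0, 300.0)

    def test_ligand_invariants(self):
        with pytest.raises(ValueError):
            Ligand("x", -1.0, 10.0)
        with pytest.raises(ValueError):
            Ligand("x", 2.0, -5.0)
        lig = Ligand.from_concentration("t", 2.0, 5.0, 100.0)
        assert lig.initial_amount == 500.0

    def test_sites_invariants(self):
        with pytest.raises(ValueError):
            AntibodySites(-1.0)
        assert AntibodySites(2.4, valence=2.0).effective_conc == 4.8
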