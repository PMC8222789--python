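"""Parameterisation: non-dimensionalisation, timescales, derived coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoflow import (
    DimensionalParameters,
    ParameterError,
    build_dimensionless,
    cell_density,
    longwave_coefficients,
    redimensionalise,
    timescale_table,
    transit_time,
)
from organoflow.params import N0_HIGH, N0_LOW, U_BAR


class TestDimensionlessGroups:
    def test_typical_values_match_printed_table(self, default_groups):
        g = default_groups
        assert g.mu == pytest.approx(0.96, abs=5e-3)
        assert g.d_CH == pytest.approx(6.4e-3, abs=5e-5)
        assert g.d_CM == pytest.approx(6.4e-3, abs=5e-5)
        assert g.d_WH == pytest.approx(1.28e-2, abs=5e-5)
        assert g.d_WM == pytest.approx(1.49e-2, abs=5e-5)
        assert g.P == pytest.approx(1.0 / 3.0, abs=5e-3)
        assert g.eps == pytest.approx(1.0 / 30.0, rel=1e-12)
        assert g.H_H == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert g.W_tol == 0.7

    def test_uptake_group_spans_seeding_range(self, default_dim):
        lo = build_dimensionless(default_dim.replace(N0=N0_LOW)).rho
        hi = build_dimensionless(default_dim.replace(N0=N0_HIGH)).rho
        assert lo == pytest.approx(0.22, abs=5e-3)
        assert hi == pytest.approx(0.32, abs=5e-3)
        # the default seeding density gives the standard line's uptake
        assert build_dimensionless(default_dim).rho == pytest.approx(0.27, rel=1e-12)

    def test_zero_flow_limit(self, default_dim):
        assert build_dimensionless(default_dim.replace(u_max=0.0)).mu == 0.0

    def test_invalid_inputs_name_the_field(self):
        with pytest.raises(ParameterError, match="h_H"):
            DimensionalParameters(h_H=-1e-3)
        with pytest.raises(ParameterError, match="h_H.*smaller"):
            DimensionalParameters(h_H=5e-3)
        with pytest.raises(ParameterError, match="L"):
            DimensionalParameters(L=0.0)

    def test_thick_geometry_warns(self, default_dim):
        with pytest.warns(UserWarning, match="longwave"):
            build_dimensionless(default_dim.replace(L=1e-2))

    def test_round_trip_recovers_inputs(self, default_dim):
        g = build_dimensionless(default_dim)
        d2 = redimensionalise(
            g,
            L=default_dim.L,
            t_scale=default_dim.t_scale,
            c_inf=default_dim.c_inf,
            nu_C=default_dim.nu_C,
        )
        for name in ("D_CH", "D_CM", "D_WH", "D_WM", "u_max", "h_H", "h_M", "N0", "p"):
            assert getattr(d2, name) == pytest.approx(
                getattr(default_dim, name), rel=1e-12
            )

    @settings(max_examples=50, deadline=None)
    @given(
        u=st.floats(1e-8, 1e-4),
        L=st.floats(1e-2, 1.0),
        hM=st.floats(1e-4, 1e-3),
        frac=st.floats(0.05, 0.95),
        N0=st.floats(1e9, 1e11),
    )
    def test_round_trip_property(self, u, L, hM, frac, N0):
        dim = DimensionalParameters(u_max=u, L=L, h_M=hM, h_H=frac * hM, N0=N0)
        g1 = build_dimensionless(dim)
        g2 = build_dimensionless(
            redimensionalise(g1, L=L, t_scale=dim.t_scale, nu_C=dim.nu_C)
        )
        for name in ("eps", "mu", "rho", "P", "d_CH", "d_WM", "H_H"):
            assert getattr(g2, name) == pytest.approx(getattr(g1, name), rel=1e-10)


class TestTimescales:
    # (process, printed seconds) rows of the physical-process table
    PRINTED = [
        ("z diffusion glucose in hydrogel", 1.5e4),
        ("z diffusion glucose in media", 1.5e4),
        ("z diffusion lactate in hydrogel", 7.5e3),
        ("z diffusion lactate in media", 6.4e3),
        ("flow", 9.0e4),
        ("glucose consumption", None),
        ("lactate production", None),
        ("cell proliferation", 2.6e5),
        ("x diffusion glucose in hydrogel", 1.4e7),
        ("x diffusion glucose in media", 1.4e7),
        ("x diffusion lactate in hydrogel", 6.8e6),
        ("x diffusion lactate in media", 5.8e6),
    ]

    def test_matches_printed_values_to_two_significant_figures(self, default_dim):
        table = timescale_table(default_dim)
        assert [r.process for r in table] == [p for p, _ in self.PRINTED]
        for row, (_, printed) in zip(table, self.PRINTED):
            if printed is not None:
                assert row.seconds == pytest.approx(printed, rel=0.05), row.process

    def test_metabolic_rows_span_seeding_range(self, default_dim):
        table = {r.process: r for r in timescale_table(default_dim)}
        cons = table["glucose consumption"]
        assert cons.seconds_low == pytest.approx(2.7e5, rel=0.05)
        assert cons.seconds_high == pytest.approx(4.0e5, rel=0.05)
        prod = table["lactate production"]
        assert prod.seconds_low == pytest.approx(1.3e5, rel=0.05)
        assert prod.seconds_high == pytest.approx(2.0e5, rel=0.05)
        # production is stoichiometrically twice as fast as consumption
        assert prod.seconds == pytest.approx(cons.seconds / 2.0, rel=1e-12)

    def test_hours_and_groupings(self, default_dim):
        table = timescale_table(default_dim)
        groups = [r.group for r in table]
        assert groups == ["hour"] * 4 + ["day"] * 4 + ["month"] * 4
        by_name = {r.process: r for r in table}
        assert by_name["z diffusion glucose in hydrogel"].hours == pytest.approx(
            4.2, rel=0.05
        )
        assert by_name["flow"].hours == pytest.approx(25.0, rel=0.05)
        assert by_name["x diffusion glucose in media"].hours == pytest.approx(
            3800.0, rel=0.05
        )

    def test_flow_timescale_linear_in_length(self, default_dim):
        t1 = {r.process: r for r in timescale_table(default_dim)}["flow"].seconds
        longer = default_dim.replace(L=2 * default_dim.L)
        t2 = {r.process: r for r in timescale_table(longer)}["flow"].seconds
        assert t2 == pytest.approx(2 * t1, rel=1e-12)


class TestLongwaveCoefficients:
    def test_derived_values_for_standard_line(self, default_coeffs):
        c = default_coeffs
        assert c.theta == pytest.approx(0.5, rel=1e-12)
        assert c.alpha == pytest.approx(1.5, rel=1e-12)
        assert c.beta == pytest.approx(0.32, rel=1e-12)
        assert c.gamma == pytest.approx(0.135, rel=1e-12)
        assert c.U_bar == pytest.approx(1.0 / 3.0, rel=1e-15)

    def test_equal_diffusivities_identity(self, default_groups):
        g = default_groups.replace(d_CM=default_groups.d_CH)
        c = longwave_coefficients(g)
        assert c.delta_C == pytest.approx(c.alpha * g.d_CM, rel=1e-12)

    def test_no_hydrogel_limit(self, default_groups):
        c = longwave_coefficients(default_groups.replace(H_H=1e-9))
        assert c.theta == pytest.approx(0.0, abs=2e-9)
        assert c.alpha == pytest.approx(1.0, abs=2e-9)

    def test_thick_hydrogel_rejected(self, default_groups):
        with pytest.raises(ParameterError, match="H_H"):
            default_groups.replace(H_H=1.0)

    def test_depth_averaged_velocity_is_exact(self):
        # U_bar is the exact mean of the half-Poiseuille profile over the
        # media layer, independent of where the interface sits
        for H_H in (0.1, 1.0 / 3.0, 0.8):
            z = np.linspace(H_H, 1.0, 20001)
            mean = np.trapezoid(((z - H_H) / (1.0 - H_H)) ** 2, z) / (1.0 - H_H)
            assert mean == pytest.approx(U_BAR, abs=1e-8)


class TestCellGrowthAndTransit:
    def test_cell_density_examples(self):
        assert cell_density(0.0, 1.0) == 1.0
        assert cell_density(4.0, 1.0) == pytest.approx(math.e**4, rel=1e-12)
        assert cell_density(4.0, 1.0) == pytest.approx(55.0, rel=0.02)
        assert cell_density(3.0, 1.0 / 3.0) == pytest.approx(math.e, rel=1e-12)
        with pytest.raises(ValueError):
            cell_density(-0.1, 1.0)

    def test_transit_time_default(self, default_coeffs):
        assert transit_time(default_coeffs) == pytest.approx(4.6875, rel=1e-12)

    def test_transit_time_scalings(self, default_coeffs):
        assert transit_time(
            default_coeffs.replace(alpha=0.32, beta=0.32)
        ) == pytest.approx(1.0)
        doubled = default_coeffs.replace(beta=2 * default_coeffs.beta)
        assert transit_time(doubled) == pytest.approx(
            transit_time(default_coeffs) / 2.0, rel=1e-12
        )

    def test_transit_exceeds_flow_timescale(self, default_coeffs, default_dim):
        # fresh-media influence moves with the depth-averaged velocity, so the
        # transit time exceeds the maximum-velocity flow timescale
        flow_days = (default_dim.L / default_dim.u_max) / default_dim.t_scale
        assert transit_time(default_coeffs) > flow_days

    def test_no_flow_sentinel(self, default_coeffs):
        with pytest.warns(UserWarning, match="transit"):
            assert transit_time(default_coeffs.replace(beta=0.0)) == math.inf
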