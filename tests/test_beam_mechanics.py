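"""Cantilever bending forward model and bending-stiffness inversion."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from hyphabend.beam_mechanics import (
    DeflectionMeasurement,
    HyphaGeometry,
    deflection_distributed,
    fit_bending_stiffness,
    forward_model,
    tip_deflection_total,
    tip_force_neglect_bias,
    unit_response,
    validity_filter,
    read_hypha_table,
    read_measurement_table,
    write_hypha_table,
    write_measurement_table,
)
from hyphabend.channel_flow import ChannelGeometry, FlowCondition
from hyphabend.drag_model import DistributedLoad, distributed_load
from hyphabend.errors import FitError, ValidationError


def _const_load(f0, geom, flow):
    return DistributedLoad(
        profile=lambda y: np.full_like(np.asarray(y, dtype=float), f0),
        configuration=geom.configuration,
        n_max=11,
        flow=flow,
        geometry=geom,
        radius=1.4,
    )


def _bvp_tip_deflection(f_arc, L, k_b, alpha1=0.0):
    """Independent fine-mesh boundary-value solve of the cantilever."""

    def rhs(s, y):
        return np.vstack(
            [y[1], y[2], y[3], math.cos(alpha1) * f_arc(s) / k_b]
        )

    def bc(ya, yb):
        return np.array([ya[0], ya[1], yb[2], yb[3]])

    s = np.linspace(0.0, L, 400)
    sol = solve_bvp(rhs, bc, s, np.zeros((4, s.size)), tol=1e-10, max_nodes=40000)
    assert sol.success
    return float(sol.sol(L)[0])


class TestDeflectionDistributed:
    def test_uniform_load_closed_form(self, center_geom, flow, hypha):
        f0, kb = 1e-6, 2.0
        load = _const_load(f0, center_geom, flow)
        _, _, w_tip = deflection_distributed(load, kb, hypha)
        assert w_tip == pytest.approx(
            f0 * hypha.length**4 / (8.0 * kb), rel=1e-6
        )

    def test_linearity_in_load(self, center_geom, flow, hypha):
        l1 = _const_load(1e-6, center_geom, flow)
        l2 = _const_load(2e-6, center_geom, flow)
        _, w1, _ = deflection_distributed(l1, 2.0, hypha)
        _, w2, _ = deflection_distributed(l2, 2.0, hypha)
        np.testing.assert_allclose(w2, 2.0 * w1, rtol=1e-12)

    def test_inverse_homogeneity_in_stiffness(self, center_geom, flow, hypha):
        load = _const_load(1e-6, center_geom, flow)
        _, _, w1 = deflection_distributed(load, 2.0, hypha)
        _, _, w2 = deflection_distributed(load, 4.0, hypha)
        assert w2 == pytest.approx(w1 / 2.0, rel=1e-12)

    def test_series_load_against_bvp_oracle(self, center_geom, water, hypha):
        flow = FlowCondition.from_ul_min(5.0)
        load = distributed_load(center_geom, water, flow, hypha.radius)
        kb = 18.3
        _, _, w_tip = deflection_distributed(load, kb, hypha)
        ref = _bvp_tip_deflection(
            lambda s: load(np.asarray(s, dtype=float)), hypha.length, kb
        )
        assert w_tip == pytest.approx(ref, rel=1e-5)

    def test_random_load_profiles_against_bvp_oracle(
        self, center_geom, flow, hypha, rng
    ):
        # smooth random polynomial loads, positive over the span
        for _ in range(8):
            coeff = rng.uniform(0.1, 1.0, 4)
            def f_arc(s, c=coeff):
                s = np.asarray(s, dtype=float) / hypha.length
                return 1e-6 * (c[0] + c[1] * s + c[2] * s**2 + c[3] * s**3)
            load = DistributedLoad(
                profile=f_arc, configuration="center", n_max=11,
                flow=flow, geometry=center_geom, radius=hypha.radius,
            )
            _, _, w_tip = deflection_distributed(load, 5.0, hypha)
            ref = _bvp_tip_deflection(f_arc, hypha.length, 5.0)
            assert w_tip == pytest.approx(ref, rel=1e-5)

    def test_nonpositive_stiffness_rejected(self, center_geom, flow, hypha):
        load = _const_load(1e-6, center_geom, flow)
        with pytest.raises(ValidationError):
            deflection_distributed(load, 0.0, hypha)


class TestTipDeflectionTotal:
    def test_uniform_load_superposition(self, center_geom, flow, hypha):
        f0, kb = 1e-6, 2.0
        load = _const_load(f0, center_geom, flow)
        td = tip_deflection_total(load, kb, hypha)
        L, r = hypha.length, hypha.radius
        assert td.w_distributed == pytest.approx(f0 * L**4 / (8 * kb), rel=1e-6)
        assert td.w_tip_force == pytest.approx(
            f0 * r * L**3 / (3 * kb), rel=1e-9
        )
        assert td.w_max == pytest.approx(
            f0 * L**4 / (8 * kb) + f0 * r * L**3 / (3 * kb), rel=1e-6
        )

    def test_point_force_term_is_cantilever_end_load(
        self, center_geom, flow, hypha
    ):
        f0, kb = 1e-6, 2.0
        load = _const_load(f0, center_geom, flow)
        td = tip_deflection_total(load, kb, hypha)
        assert td.tip_force == pytest.approx(f0 * hypha.radius, rel=1e-9)
        assert td.w_tip_force == pytest.approx(
            td.tip_force * hypha.length**3 / (3 * kb), rel=1e-12
        )

    def test_diminished_load_factor_applies_to_tip_force(
        self, center_geom, flow, hypha
    ):
        load = _const_load(1e-6, center_geom, flow)
        a1 = 0.3
        td0 = tip_deflection_total(load, 2.0, hypha, alpha1=0.0)
        td1 = tip_deflection_total(load, 2.0, hypha, alpha1=a1)
        assert td1.w_max == pytest.approx(td0.w_max * math.cos(a1), rel=1e-9)


class TestForwardModel:
    def test_zero_flow_is_undeflected(self, center_geom, water, hypha):
        res = forward_model(
            hypha, center_geom, water, FlowCondition(0.0), 18.3
        )
        assert res.x_displacement == 0.0
        assert res.alpha1 == hypha.alpha0

    def test_small_flow_matches_static_solution(self, center_geom, water):
        hypha = HyphaGeometry(1.4, 0.287, 50.0, alpha0=0.0)
        flow = FlowCondition.from_ul_min(0.05)
        res = forward_model(hypha, center_geom, water, flow, 18.3)
        load = distributed_load(center_geom, water, flow, hypha.radius)
        td = tip_deflection_total(load, 18.3, hypha, alpha1=res.alpha1)
        assert res.x_displacement == pytest.approx(td.w_max, rel=1e-6)

    def test_displacement_increases_with_flow(self, center_geom, water, hypha):
        rates = [1.0, 2.0, 4.0, 6.0, 8.0]
        resp = unit_response(hypha, center_geom, water)
        disps = [
            forward_model(
                hypha, center_geom, water, FlowCondition.from_ul_min(q),
                18.3, response=resp,
            ).x_displacement
            for q in rates
        ]
        assert np.all(np.diff(disps) > 0)

    def test_tilted_hypha_projects_displacement(self, center_geom, water):
        a0 = math.radians(20.0)
        hypha = HyphaGeometry(1.4, 0.287, 50.0, alpha0=a0)
        flow = FlowCondition.from_ul_min(1.0)
        res = forward_model(hypha, center_geom, water, flow, 18.3)
        assert res.x_displacement == pytest.approx(
            res.w_max * math.cos(a0), rel=1e-12
        )
        assert res.alpha1 > a0


def _synthetic_measurements(hypha, geom, fluid, kb, rates_ul_min):
    resp = unit_response(hypha, geom, fluid)
    out = []
    for q in rates_ul_min:
        flow = FlowCondition.from_ul_min(q)
        res = forward_model(hypha, geom, fluid, flow, kb, response=resp)
        out.append(DeflectionMeasurement(flow, res.x_displacement, res.alpha1))
    return out


class TestFitBendingStiffness:
    RATES = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]

    def test_noiseless_round_trip(self, center_geom, water, hypha):
        kb = 18.3
        meas = _synthetic_measurements(hypha, center_geom, water, kb, self.RATES)
        fit = fit_bending_stiffness(meas, hypha, center_geom, water)
        assert fit.k_b == pytest.approx(kb, rel=1e-4)

    def test_forward_inverse_consistency_random_draws(
        self, center_geom, water, rng
    ):
        for _ in range(20):
            kb = rng.uniform(5.0, 40.0)
            hypha = HyphaGeometry(
                radius=rng.uniform(1.0, 1.8),
                wall_thickness=0.287,
                length=rng.uniform(30.0, 150.0),
                alpha0=rng.uniform(-0.3, 0.3),
            )
            # dial the pump per specimen: top rate targets w_max ~ 0.2 L
            resp = unit_response(hypha, center_geom, water)
            q_top = 0.2 * hypha.length * kb / resp / (1e9 / 60.0)
            rates = [q_top * k / 6.0 for k in range(1, 7)]
            meas = _synthetic_measurements(
                hypha, center_geom, water, kb, rates
            )
            fit = fit_bending_stiffness(meas, hypha, center_geom, water)
            assert fit.k_b == pytest.approx(kb, rel=1e-4)

    def test_mean_recovery_under_noise(self, center_geom, water, hypha, rng):
        kb = 18.3
        clean = _synthetic_measurements(
            hypha, center_geom, water, kb, self.RATES
        )
        estimates = []
        for _ in range(500):
            noisy = [
                DeflectionMeasurement(
                    m.flow,
                    m.x_displacement * (1.0 + rng.normal(0.0, 0.05)),
                    m.alpha1,
                )
                for m in clean
            ]
            estimates.append(
                fit_bending_stiffness(noisy, hypha, center_geom, water).k_b
            )
        assert np.mean(estimates) == pytest.approx(kb, rel=0.02)

    def test_overdeflected_point_is_filtered_without_changing_fit(
        self, center_geom, water, hypha
    ):
        kb = 18.3
        meas = _synthetic_measurements(hypha, center_geom, water, kb, self.RATES)
        bad = DeflectionMeasurement(
            FlowCondition.from_ul_min(50.0), 0.30 * hypha.length, 0.1
        )
        fit_ref = fit_bending_stiffness(meas, hypha, center_geom, water)
        fit_bad = fit_bending_stiffness(
            meas + [bad], hypha, center_geom, water
        )
        assert fit_bad.k_b == fit_ref.k_b
        reasons = [r for _, r in fit_bad.points_excluded]
        assert any("validity filter" in r for r in reasons)

    def test_fewer_than_two_points_lists_reasons(
        self, center_geom, water, hypha
    ):
        only = DeflectionMeasurement(
            FlowCondition.from_ul_min(5.0), 1.0, 0.01
        )
        with pytest.raises(FitError, match="need >= 2"):
            fit_bending_stiffness([only], hypha, center_geom, water)

    def test_all_points_filtered_is_dedicated_error(
        self, center_geom, water, hypha
    ):
        meas = [
            DeflectionMeasurement(
                FlowCondition.from_ul_min(q), 0.5 * hypha.length, 0.2
            )
            for q in (10.0, 20.0)
        ]
        with pytest.raises(FitError, match="validity filter"):
            fit_bending_stiffness(meas, hypha, center_geom, water)

    def test_off_center_hypha_is_invalid(self, center_geom, water):
        hypha = HyphaGeometry(1.4, 0.287, 50.0, dz=12.0)
        meas = [
            DeflectionMeasurement(FlowCondition.from_ul_min(q), 0.5, 0.01)
            for q in (5.0, 10.0)
        ]
        with pytest.raises(FitError, match="center plane"):
            fit_bending_stiffness(meas, hypha, center_geom, water)


class TestValidityFilter:
    def test_boundary_ratio_is_kept(self):
        hypha = HyphaGeometry(1.4, 0.287, 100.0)
        kept = DeflectionMeasurement(FlowCondition.from_ul_min(1.0), 25.0, 0.2)
        gone = DeflectionMeasurement(FlowCondition.from_ul_min(1.0), 26.0, 0.2)
        res = validity_filter([kept, gone], hypha)
        assert kept in res.kept
        assert gone in [m for m, _ in res.excluded]

    def test_center_plane_tolerance_flags_hypha(self):
        hypha = HyphaGeometry(1.4, 0.287, 50.0, dz=12.0)
        res = validity_filter([], hypha, configuration="center")
        assert not res.hypha_valid
        # the same offset is irrelevant in the floor configuration
        res_floor = validity_filter([], hypha, configuration="floor")
        assert res_floor.hypha_valid


class TestTipForceNeglect:
    def test_bias_positive_and_growing_for_short_hyphae(
        self, center_geom, water
    ):
        biases = [
            tip_force_neglect_bias(
                HyphaGeometry(1.4, 0.287, L), center_geom, water
            )
            for L in (40.0, 80.0, 120.0)
        ]
        assert all(b > 0 for b in biases)
        assert biases[0] > biases[1] > biases[2]


class TestCenterPlaneForceDeviation:
    def test_offset_deviation_small_only_for_tall_chamber(self, water, flow):
        from hyphabend.channel_flow import velocity_field

        dz = 10.0
        for h, small in ((90.0, True), (45.0, False)):
            geom = ChannelGeometry(500.0, h, "center")
            u_mid = velocity_field(geom, water, flow, 250.0, h / 2)
            u_off = velocity_field(geom, water, flow, 250.0, h / 2 + dz)
            deviation = abs(1.0 - u_off / u_mid)
            assert (deviation < 0.05) is small


def test_measurement_and_hypha_tables_round_trip(tmp_path):
    import pandas as pd

    hyphae = {
        "h000": HyphaGeometry(1.4, 0.287, 50.0, alpha0=math.radians(5.0)),
        "h001": HyphaGeometry(1.2, 0.25, 80.0, dz=-3.0),
    }
    hpath = tmp_path / "hyphae.csv"
    write_hypha_table(hyphae, hpath)
    back = read_hypha_table(hpath)
    assert back["h001"].length == pytest.approx(80.0)
    assert back["h000"].alpha0 == pytest.approx(math.radians(5.0))

    df = pd.DataFrame(
        {
            "hypha_id": ["h000", "h000"],
            "Q_uL_min": [0.0, 5.0],
            "x_disp_um": [0.0, 1.2],
            "alpha0_deg": [5.0, 5.0],
            "alpha1_deg": [5.0, 6.5],
            "exclude": [0, 0],
        }
    )
    mpath = tmp_path / "meas.csv"
    write_measurement_table(df, mpath)
    back_df = read_measurement_table(mpath)
    assert len(back_df) == 2
    assert back_df["x_disp_um"].iloc[1] == pytest.approx(1.2)
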