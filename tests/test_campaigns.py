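"""Sweep tables, monotone inversion and expression arithmetic (fast paths)."""

import numpy as np
import pytest

import aquadiff as aq
from aquadiff.campaigns import SweepTable, _pava_increasing
from aquadiff.errors import ConfigurationError, OutOfRangeError


def _toy_sweep(adc_vals, P_vals=None):
    P = np.asarray(P_vals if P_vals is not None else np.linspace(0.0, 0.5, len(adc_vals)))
    adc = np.asarray(adc_vals, dtype=float)[:, None]
    return SweepTable(
        axis_name="permeability",
        axis_values=P,
        delta_eff_values=np.array([398.0]),
        adc=adc,
        adc_se=np.full_like(adc, 5.0),
        n_walkers=1000,
    )


class TestInversion:
    def test_grid_point_identity(self):
        sw = _toy_sweep([400.0, 600.0, 800.0, 900.0])
        for P, adc in zip(sw.axis_values, sw.adc[:, 0]):
            assert aq.invert_adc_to_permeability(adc, sw) == pytest.approx(P, abs=1e-12)

    def test_midpoint_is_linear_interpolation(self):
        sw = _toy_sweep([400.0, 600.0], P_vals=[0.1, 0.3])
        assert aq.invert_adc_to_permeability(500.0, sw) == pytest.approx(0.2)

    def test_out_of_range_raises_with_brackets(self):
        sw = _toy_sweep([400.0, 600.0])
        with pytest.raises(OutOfRangeError, match="outside simulated range"):
            aq.invert_adc_to_permeability(700.0, sw)
        with pytest.raises(OutOfRangeError):
            aq.invert_adc_to_permeability(300.0, sw)

    def test_monte_carlo_wiggle_is_monotonised(self):
        # a local inversion from noise must not break the mapping
        sw = _toy_sweep([400.0, 520.0, 510.0, 700.0])
        p = aq.invert_adc_to_permeability(515.0, sw)
        assert 0.0 < p < 0.5

    def test_requires_permeability_axis(self):
        sw = _toy_sweep([400.0, 600.0])
        sw.axis_name = "fraction"
        with pytest.raises(ConfigurationError):
            aq.invert_adc_to_permeability(500.0, sw)


def test_pava_pools_violators():
    assert np.allclose(_pava_increasing(np.array([1.0, 3.0, 2.0, 4.0])), [1.0, 2.5, 2.5, 4.0])
    y = np.array([1.0, 2.0, 3.0])
    assert np.allclose(_pava_increasing(y), y)


def test_sweep_table_json_and_csv_round_trip(tmp_path):
    sw = _toy_sweep([400.0, 600.0, 800.0])
    back = SweepTable.from_json(sw.to_json())
    assert np.allclose(back.adc, sw.adc)
    assert np.allclose(back.axis_values, sw.axis_values)
    sw.to_csv(tmp_path / "sweep.csv")
    df = sw.to_frame()
    assert {"permeability", "delta_eff_ms", "adc_um2_per_s"} <= set(df.columns)


def test_fraction_sweep_endpoints_match_uniform_sweeps(default_lattice):
    """A 0% (100%) labelled population is the same physical system as a
    uniform low- (high-) permeability lattice; on shared geometry the two
    code paths must agree within Monte Carlo error."""
    t_eff = 98.0
    sim = aq.SimulationParams(n_walkers=3000)
    uni = aq.permeability_sweep(
        [0.039, 0.14], [t_eff], sim=sim, seed=301, lattice=default_lattice
    )
    mix = aq.fraction_sweep(
        [0.0, 1.0], n_arrangements=3, delta_eff_values_ms=[t_eff],
        sim=sim, seed=302, lattice=default_lattice,
    )
    u_adc, u_se = uni.column(t_eff)
    m_adc, m_se = mix.column(t_eff)
    for k in range(2):
        assert abs(m_adc[k] - u_adc[k]) < 2 * np.hypot(u_se[k], m_se[k]) + 1e-9


class TestExpression:
    def test_zero_permeability(self):
        est = aq.permeability_to_concentration(0.0)
        assert est.volumetric_flow == 0.0
        assert est.concentration_uM == 0.0

    def test_flow_and_channel_count_hand_values(self):
        est = aq.permeability_to_concentration(0.55)
        assert est.volumetric_flow == pytest.approx(209.0, rel=1e-12)
        assert est.channels_per_cell == pytest.approx(209.0 / 6e-5, rel=1e-12)

    def test_concentration_for_both_cell_volume_conventions(self):
        # sphere matching the 380 um^2 surface area: V ~ 697 um^3
        est_a = aq.permeability_to_concentration(0.55)
        assert est_a.assumptions["cell_volume_um3"] == pytest.approx(696.6, abs=0.5)
        assert est_a.concentration_uM == pytest.approx(8.30, rel=0.01)
        # pellet-model mean radius 6.8 um: V ~ 1317 um^3
        v68 = 4 / 3 * np.pi * 6.8**3
        est_b = aq.permeability_to_concentration(0.55, cell_volume_um3=v68)
        assert est_b.concentration_uM == pytest.approx(4.39, rel=0.01)

    def test_linear_in_permeability_and_conductance(self):
        e1 = aq.permeability_to_concentration(0.1)
        e2 = aq.permeability_to_concentration(0.2)
        assert e2.concentration_uM == pytest.approx(2 * e1.concentration_uM, rel=1e-12)
        e3 = aq.permeability_to_concentration(0.1, unit_conductance_um3_per_ms=1.2e-4)
        assert e3.concentration_uM == pytest.approx(e1.concentration_uM / 2, rel=1e-12)

    def test_multimer_factor_divides(self):
        mono = aq.permeability_to_concentration(0.2, multimer_factor=1.0)
        tetra = aq.permeability_to_concentration(0.2, multimer_factor=4.0)
        assert tetra.concentration_uM == pytest.approx(mono.concentration_uM / 4, rel=1e-12)

    def test_dose_response_extrapolation(self):
        assert aq.extrapolate_low_dose_concentration(2.54, 0.18) == pytest.approx(0.4572)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            aq.permeability_to_concentration(-0.1)
        with pytest.raises(ConfigurationError):
            aq.permeability_to_concentration(0.1, surface_area_um2=0.0)
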