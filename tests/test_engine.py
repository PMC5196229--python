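"""Random-walk engine: step statistics, membrane rule, conservation laws."""

import dataclasses

import numpy as np
import pytest

import aquadiff as aq
from aquadiff.errors import ConfigurationError
from aquadiff.lattice import EXTRACELLULAR, LOW_PERM


class TestStepScale:
    def test_intracellular_scale(self):
        assert aq.step_sigma(554.7, 50.0) == pytest.approx(0.23552, rel=1e-4)

    def test_extracellular_scale(self):
        assert aq.step_sigma(1664.2, 50.0) == pytest.approx(0.40796, rel=1e-4)

    def test_scale_vanishes_with_tau(self):
        taus = [50.0, 5.0, 0.5, 0.05]
        sigmas = [aq.step_sigma(554.7, t) for t in taus]
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            aq.step_sigma(-1.0, 50.0)
        with pytest.raises(ConfigurationError):
            aq.step_sigma(554.7, 0.0)


class TestTransmissionProbability:
    def test_zero_permeability(self):
        assert aq.transmission_probability(0.0) == 0.0

    @pytest.mark.parametrize(
        "P,expected", [(0.039, 0.02076), (0.14, 0.07451), (0.55, 0.29273)]
    )
    def test_reference_values(self, P, expected):
        assert aq.transmission_probability(P, 554.7, 50.0) == pytest.approx(
            expected, rel=1e-3
        )

    def test_probability_above_one_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="smaller time step"):
            aq.transmission_probability(0.39, 554.7, 2000.0)


class TestInitWalkers:
    def test_deterministic(self, default_lattice):
        a = aq.init_walkers(default_lattice, 500, seed=4)
        b = aq.init_walkers(default_lattice, 500, seed=4)
        assert np.array_equal(a.start_positions, b.start_positions)
        assert np.array_equal(a.compartments, b.compartments)

    def test_single_walker(self, default_lattice):
        e = aq.init_walkers(default_lattice, 1, seed=0)
        assert e.n_walkers == 1

    def test_occupancy_proportional_to_volume(self, default_lattice):
        n = 100_000
        e = aq.init_walkers(default_lattice, n, seed=11)
        f = default_lattice.intracellular_fraction
        frac = np.mean(e.compartments != EXTRACELLULAR)
        assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / n)


def _uniform_sphere_points(rng, center, radius, n):
    pts = np.empty((n, 3))
    k = 0
    while k < n:
        cand = rng.uniform(-1, 1, size=(n, 3))
        good = cand[(cand**2).sum(axis=1) <= 1.0]
        take = min(len(good), n - k)
        pts[k : k + take] = good[:take]
        k += take
    return center + radius * pts


class TestPropagate:
    def test_zero_steps_is_identity(self, default_lattice):
        e = aq.init_walkers(default_lattice, 200, seed=1)
        out = aq.propagate(e, default_lattice, aq.SimulationParams(n_walkers=200), 0)
        assert np.array_equal(out.positions, e.positions)
        assert np.array_equal(out.compartments, e.compartments)

    def test_deterministic_for_fixed_seed(self, default_lattice):
        p = aq.SimulationParams(n_walkers=300, seed=5)
        e = aq.init_walkers(default_lattice, 300, seed=6)
        a = aq.propagate(e, default_lattice, p, 200)
        b = aq.propagate(e, default_lattice, p, 200)
        assert np.array_equal(a.positions, b.positions)

    def test_walker_count_and_displacement_bookkeeping(self, default_lattice):
        e = aq.init_walkers(default_lattice, 400, seed=2)
        out = aq.propagate(e, default_lattice, aq.SimulationParams(seed=3), 300)
        assert out.n_walkers == 400
        assert np.array_equal(out.displacement, out.positions - out.start_positions)

    def test_compartment_tags_consistent_with_locate(self, default_lattice):
        e = aq.init_walkers(default_lattice, 2000, seed=7)
        out = aq.propagate(e, default_lattice, aq.SimulationParams(seed=8), 500)
        wrapped = out.positions % default_lattice.box_lengths
        located = np.asarray(default_lattice.locate(wrapped))
        # tangent-sphere contact points allow rare reassignments at the
        # nanometre nudge scale; demand near-perfect agreement
        assert np.mean(located != out.compartments) < 1e-3

    def test_free_diffusion_recovers_input_diffusivity(self, default_lattice):
        D = 1664.2
        params = aq.SimulationParams(
            d_in_um2s=D,
            d_ex_um2s=D,
            transmission_by_label={LOW_PERM: 1.0},
            seed=21,
        )
        e = aq.init_walkers(default_lattice, 5000, seed=22)
        n_steps = 600
        out = aq.propagate(e, default_lattice, params, n_steps)
        t_ms = n_steps * 0.05
        d_axis = out.displacement
        D_hat = (d_axis**2).mean(axis=0) / (2 * t_ms) * 1e3
        # SE of the per-axis MSD estimator (chi^2 statistics)
        se = D * np.sqrt(2.0 / len(d_axis))
        assert np.all(np.abs(D_hat - D) < 3 * se)

    def test_impermeable_sphere_msd_plateau(self, default_lattice):
        lat = default_lattice
        r = lat.radii[0]
        rng = np.random.default_rng(13)
        n = 2000
        start = _uniform_sphere_points(rng, lat.centers[0], r, n)
        ens = aq.WalkerEnsemble(
            start_positions=start,
            positions=start.copy(),
            compartments=np.zeros(n, dtype=np.int64),
        )
        params = aq.SimulationParams(permeability_by_label={LOW_PERM: 0.0}, seed=14)
        steps = [2000, 4000]  # 100 and 200 ms, both >> r^2/(2 D_in) ~ 42 ms
        out = aq.propagate(ens, lat, params, max(steps), record_steps=steps)
        plateau = 2 * r**2 / 5
        for s in steps:
            msd = (out.snapshots[s] ** 2).mean(axis=0)
            se = plateau * np.sqrt(2.0 / n)  # variance of squared displacement
            assert np.all(np.abs(msd - plateau) < 3 * se)
        # all walkers stayed inside the sphere
        assert np.all(out.compartments == 0)

    def test_equilibrium_occupancy_detailed_balance(self, default_lattice):
        # with equal compartment diffusivities the membrane rule must keep
        # the uniform (volume-proportional) occupancy stationary
        D = 1000.0
        params = aq.SimulationParams(
            d_in_um2s=D, d_ex_um2s=D,
            permeability_by_label={LOW_PERM: 0.1}, seed=31,
        )
        n = 4000
        e = aq.init_walkers(default_lattice, n, seed=32)
        out = aq.propagate(e, default_lattice, params, 4000)  # 200 ms
        f = default_lattice.intracellular_fraction
        frac = np.mean(out.compartments != EXTRACELLULAR)
        assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / n)

    def test_msd_monotone_in_permeability(self, default_lattice):
        msds, ses = [], []
        for P in (0.02, 0.14, 0.6):
            params = aq.SimulationParams(
                permeability_by_label={LOW_PERM: P}, seed=41
            )
            e = aq.init_walkers(default_lattice, 3000, seed=42)
            out = aq.propagate(e, default_lattice, params, 3000)  # 150 ms
            sq = (out.displacement**2).sum(axis=1)
            msds.append(sq.mean())
            ses.append(sq.std(ddof=1) / np.sqrt(len(sq)))
        assert msds[1] - msds[0] > -2 * np.hypot(ses[0], ses[1])
        assert msds[2] - msds[1] > -2 * np.hypot(ses[1], ses[2])
        # and strictly increasing overall
        assert msds[2] > msds[0]
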